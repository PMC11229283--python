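"""Built-in matcher, spanning-read classification and support tallies."""

import numpy as np
import pytest

from mitorecomb.read_support import (
    AlignmentRecord,
    QuartetIndex,
    classify_read,
    count_support,
    match_read,
)
from mitorecomb.repeat_model import build_quartet, revcomp

from conftest import build_toy_genome


@pytest.fixture()
def quartet(toy_direct):
    genome, rp = toy_direct
    return build_quartet(genome, rp)


def _slice_path(quartet, pid, margin):
    p = quartet.paths[pid]
    return p.sequence[p.repeat_start - margin : p.repeat_end + margin]


class TestMatchRead:
    def test_error_free_read_matches_perfectly(self, quartet):
        read = _slice_path(quartet, "m1", 400)
        recs = {r.path_id: r for r in match_read(read, quartet, read_id="r1")}
        m1 = recs["m1"]
        assert m1.matches == m1.block_len == len(read)
        assert m1.strand == "+"
        p = quartet.paths["m1"]
        assert (m1.path_start, m1.path_end) == (p.repeat_start - 400, p.repeat_end + 400)

    def test_reverse_complement_same_interval_minus_strand(self, quartet):
        read = _slice_path(quartet, "m1", 400)
        fwd = {r.path_id: r for r in match_read(read, quartet)}
        rev = {r.path_id: r for r in match_read(revcomp(read), quartet)}
        assert rev["m1"].strand == "-"
        assert (rev["m1"].path_start, rev["m1"].path_end) == (
            fwd["m1"].path_start,
            fwd["m1"].path_end,
        )

    def test_empty_and_too_short_reads_rejected(self, quartet):
        with pytest.raises(ValueError):
            match_read("", quartet)
        with pytest.raises(ValueError):
            match_read("ACGT", quartet)

    def test_coordinates_within_five_bases_at_five_percent_error(self):
        from mitorecomb.pipeline import build_quartets
        from mitorecomb.synthetic_data import (
            RepeatSpec,
            SimulationConfig,
            generate_master_circle,
            simulate_reads,
        )

        config = SimulationConfig(
            genome_length=60_000,
            repeat_specs=(RepeatSpec(1000, "+", 0.0),),
            read_count=1000,
            read_length_median=8000,
            error_rate=0.05,
            mode="junction",
            seed=21,
        )
        genome, repeats, model = generate_master_circle(config, seed=21)
        reads, truth = simulate_reads(model, config, seed=22)
        quartet = build_quartets(genome, repeats)["LR1"]
        index = QuartetIndex(quartet)
        starts = genome.sequence.find  # master coordinates
        l1 = repeats[0].locus1
        checked = within = 0
        for read in reads:
            rt = truth.reads[read.id]
            # restrict to reads truly spanning locus1 with ample margin
            off = (l1.start - 150 - rt.start) % len(genome)
            if not off + l1.length + 300 <= rt.length:
                continue
            recs = [r for r in index.match(read.id, read.sequence) if r.path_id == "m1"]
            if not recs:
                continue
            rec = recs[0]
            p = quartet.paths["m1"]
            # where the read should start on the m1 path, from truth
            expected_read_repeat_offset = (l1.start - rt.start) % len(genome)
            got = p.repeat_start - (
                rec.path_start - (rec.read_start if rt.strand == "+" else len(read.sequence) - rec.read_end)
            )
            checked += 1
            if abs(got - expected_read_repeat_offset) <= 5:
                within += 1
        assert checked >= 300
        assert within / checked >= 0.99


class TestClassifyRead:
    def _record(self, quartet, pid, up, down, identity=1.0, primary=True):
        p = quartet.paths[pid]
        ps = p.repeat_start - up
        pe = p.repeat_end + down
        block = pe - ps
        return AlignmentRecord(
            read_id="r",
            repeat_id=quartet.repeat_id,
            path_id=pid,
            read_start=0,
            read_end=block,
            path_start=ps,
            path_end=pe,
            strand="+",
            matches=int(block * identity),
            block_len=block,
        )

    def test_single_satisfied_path_wins(self, quartet):
        rec = self._record(quartet, "s2", 150, 150)
        assert classify_read([rec], quartet).label == "s2"

    def test_99bp_flank_is_not_enough(self, quartet):
        rec = self._record(quartet, "m1", 100, 99)
        assert classify_read([rec], quartet).label == "none"
        rec2 = self._record(quartet, "m1", 100, 100)
        assert classify_read([rec2], quartet).label == "m1"

    def test_low_identity_record_ignored(self, quartet):
        rec = self._record(quartet, "m1", 200, 200, identity=0.5)
        assert classify_read([rec], quartet).label == "none"

    def test_secondary_records_ignored(self, quartet):
        rec = self._record(quartet, "m1", 200, 200)
        rec.is_primary = False
        assert classify_read([rec], quartet).label == "none"

    def test_two_satisfied_paths_are_ambiguous(self, quartet):
        recs = [
            self._record(quartet, "m1", 150, 150),
            self._record(quartet, "s1", 150, 150),
        ]
        assert classify_read(recs, quartet).label == "ambiguous"

    def test_degenerate_quartet_always_ambiguous(self, rng):
        import warnings

        from mitorecomb.repeat_model import CircularGenome, Contig, Locus, RepeatPair
        from conftest import random_dna

        rep = random_dna(rng, 300)
        shared = random_dna(rng, 1500)
        seq = shared + rep + shared + rep
        genome = CircularGenome(
            seq,
            [
                Contig("X", 0, 1500),
                Contig("R.1", 1500, 1800),
                Contig("Y", 1800, 3300),
                Contig("R.2", 3300, 3600),
            ],
        )
        rp = RepeatPair("R", "+", Locus(1500, 1800), Locus(3300, 3600))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = build_quartet(genome, rp)
        read = _slice_path(q, "m1", 300)
        label = classify_read(match_read(read, q, read_id="r"), q)
        assert label.label == "ambiguous"

    def test_unknown_path_and_mixed_reads_rejected(self, quartet):
        rec = self._record(quartet, "m1", 150, 150)
        rec.path_id = "m3"
        with pytest.raises(ValueError):
            classify_read([rec], quartet)
        a = self._record(quartet, "m1", 150, 150)
        b = self._record(quartet, "m1", 150, 150)
        b.read_id = "other"
        with pytest.raises(ValueError):
            classify_read([a, b], quartet)

    def test_strand_invariance_on_simulated_reads(self, quartet, rng):
        index = QuartetIndex(quartet)
        for pid in ("m1", "m2", "s1", "s2"):
            for margin in (120, 500):
                read = _slice_path(quartet, pid, margin)
                l1 = classify_read(index.match("a", read), quartet)
                l2 = classify_read(index.match("a", revcomp(read)), quartet)
                assert l1.label == l2.label

    def test_increasing_min_flank_never_rescues_none(self, quartet):
        read = _slice_path(quartet, "m1", 130)
        recs = match_read(read, quartet, read_id="r")
        previous_supported = True
        for flank in (50, 100, 131, 200, 500):
            label = classify_read(recs, quartet, min_flank=flank).label
            supported = label in ("m1", "m2", "s1", "s2", "ambiguous")
            assert previous_supported or not supported
            previous_supported = supported


class TestCountSupport:
    def test_published_style_tally(self, quartet):
        from mitorecomb.read_support import SupportLabel

        labels = (
            [SupportLabel(f"a{i}", "R", "m1") for i in range(413)]
            + [SupportLabel(f"b{i}", "R", "m2") for i in range(347)]
            + [SupportLabel(f"c{i}", "R", "s1") for i in range(12)]
            + [SupportLabel(f"d{i}", "R", "s2") for i in range(57)]
            + [SupportLabel("x", "R", "ambiguous"), SupportLabel("y", "R", "none")]
        )
        c = count_support(labels)
        assert (c.m1, c.m2, c.s1, c.s2) == (413, 347, 12, 57)
        # partition: supported + ambiguous + none accounts for every read
        supported = c.m1 + c.m2 + c.s1 + c.s2
        assert supported + 2 == len(labels)

    def test_empty_is_all_zero(self):
        c = count_support([])
        assert (c.m1, c.m2, c.s1, c.s2) == (0, 0, 0, 0)

    def test_mixed_repeat_ids_rejected(self):
        from mitorecomb.read_support import SupportLabel

        with pytest.raises(ValueError):
            count_support(
                [SupportLabel("a", "R1", "m1"), SupportLabel("b", "R2", "m1")]
            )

    def test_simulated_counts_near_binomial_expectation(self):
        from mitorecomb.pipeline import build_quartets, classify_reads
        from mitorecomb.synthetic_data import (
            RepeatSpec,
            SimulationConfig,
            generate_master_circle,
            simulate_reads,
        )

        f = 0.2
        config = SimulationConfig(
            genome_length=60_000,
            repeat_specs=(RepeatSpec(500, "-", f),),
            read_count=2300,
            read_length_median=9000,
            mode="junction",
            seed=31,
        )
        genome, repeats, model = generate_master_circle(config, seed=31)
        reads, truth = simulate_reads(model, config, seed=32)
        quartets = build_quartets(genome, repeats)
        focal = {rt.read_id: rt.focal_repeat for rt in truth.reads.values()}
        labels = classify_reads(
            quartets, [(r.id, r.sequence) for r in reads], focal=focal
        )
        c = count_support([l for l in labels if l.repeat_id == "MR1"])
        n = c.m1 + c.m2 + c.s1 + c.s2
        assert n >= 2000
        s_total = c.s1 + c.s2
        se = np.sqrt(n * f * (1 - f))
        assert abs(s_total - n * f) <= 3 * se
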