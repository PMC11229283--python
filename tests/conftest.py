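"""Shared fixtures: small handcrafted genomes and one mid-sized simulation.

Everything is generated programmatically and seeded; the only shipped data
is the published floating-bamboo repeat-support table inside the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitorecomb.repeat_model import CircularGenome, Contig, Locus, RepeatPair, revcomp


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def build_toy_genome(
    rng: np.random.Generator,
    repeat_len: int = 400,
    orientation: str = "+",
    contig_len: int = 1500,
) -> tuple[CircularGenome, RepeatPair]:
    """Circle U1 R.1 U2 U3 R.2 U4 with explicit contig table."""
    rep = random_dna(rng, repeat_len)
    u = [random_dna(rng, contig_len) for _ in range(4)]
    copy2 = rep if orientation == "+" else revcomp(rep)
    seq = u[0] + rep + u[1] + u[2] + copy2 + u[3]
    contigs, pos = [], 0
    for name, s in [
        ("U1", u[0]),
        ("R.1", rep),
        ("U2", u[1]),
        ("U3", u[2]),
        ("R.2", copy2),
        ("U4", u[3]),
    ]:
        contigs.append(Contig(name, pos, pos + len(s)))
        pos += len(s)
    genome = CircularGenome(seq, contigs)
    l1 = Locus(len(u[0]), len(u[0]) + repeat_len)
    start2 = len(u[0]) + repeat_len + len(u[1]) + len(u[2])
    rp = RepeatPair("R", orientation, l1, Locus(start2, start2 + repeat_len))
    return genome, rp


@pytest.fixture()
def toy_direct(rng):
    return build_toy_genome(rng, orientation="+")


@pytest.fixture()
def toy_inverted(rng):
    return build_toy_genome(rng, orientation="-")


@pytest.fixture(scope="session")
def recovery_run():
    """One mid-sized simulated dataset pushed through the full pipeline.

    A ~100 kb circle with five repeats switching at f = 0, 0.05, 0.2, 0.35
    and 0.5; 3,200 junction reads per repeat, error-free, so that at least
    2,000 reads span each repeat with 100 bp flanks (a read spans only when
    the length draw covers repeat + flanks, so the allocation is padded).
    Shared by the parameter-recovery and oracle-agreement tests (it is the
    expensive fixture of the suite).
    """
    from mitorecomb.pipeline import build_quartets, classify_reads, summarize
    from mitorecomb.synthetic_data import (
        RepeatSpec,
        SimulationConfig,
        generate_master_circle,
        simulate_reads,
    )

    specs = (
        RepeatSpec(300, "+", 0.0),
        RepeatSpec(450, "+", 0.05),
        RepeatSpec(800, "-", 0.2),
        RepeatSpec(1769, "-", 0.35),
        RepeatSpec(3000, "+", 0.5),
    )
    config = SimulationConfig(
        genome_length=100_000,
        repeat_specs=specs,
        read_count=16_000,
        read_length_median=12_000,
        error_rate=0.0,
        mode="junction",
        seed=1,
    )
    genome, repeats, model = generate_master_circle(config, seed=1)
    reads, truth = simulate_reads(model, config, seed=2)
    quartets = build_quartets(genome, repeats)
    focal = {rt.read_id: rt.focal_repeat for rt in truth.reads.values()}
    labels = classify_reads(
        quartets, [(r.id, r.sequence) for r in reads], focal=focal
    )
    counts, report, corr = summarize(labels, repeats, quartets)
    return {
        "config": config,
        "genome": genome,
        "repeats": repeats,
        "model": model,
        "reads": reads,
        "truth": truth,
        "quartets": quartets,
        "labels": labels,
        "counts": counts,
        "report": report,
    }
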