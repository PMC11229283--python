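"""Synthetic circular mitogenomes, conformational mixtures and long reads.

The generator emulates the data regime of a repeat-rich plant mitogenome
studied by long reads: a circular master sequence (50 kb - 600 kb) of unique
contigs (>= ~1.5 kb) separated by planted repeat pairs (direct ``+`` or
inverted ``-``), a population of molecules in which each repeat independently
adopts its recombined (secondary) arrangement with fraction ``f``, and long
reads sampled uniformly from circular molecules with substitution errors and
full truth labels.

Molecules are modelled as circular lists of oriented segments (unique contigs
and repeat copies).  Recombination is then exact algebra on the segment list:

* a **direct** repeat pair on one circle fissions it into two circles, one
  carrying the ``s1`` junction and the other ``s2``;
* an **inverted** repeat pair reverse-complements the segment run between its
  two copies, producing one circle carrying both ``s1`` and ``s2`` junctions.

This segment representation doubles as the brute-force oracle for the
analysis pipeline: :func:`toggle_conformation` materialises true secondary
molecules, and :func:`truth_classify` labels a read from its recorded origin
coordinates alone, independently of any alignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .repeat_model import (
    CircularGenome,
    Contig,
    Locus,
    RepeatPair,
    classify_repeat,
    revcomp,
)

__all__ = [
    "RepeatSpec",
    "SimulationConfig",
    "Segment",
    "Molecule",
    "MasterModel",
    "SimRead",
    "ReadTruth",
    "SimulationTruth",
    "generate_master_circle",
    "toggle_conformation",
    "simulate_reads",
    "truth_classify",
]

#: No two unique regions may share an exact match of this length or longer.
ACCIDENTAL_REPEAT_K = 30

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatSpec:
    """One planted repeat pair: length, orientation, secondary fraction f."""

    length: int
    orientation: str  # '+' direct, '-' inverted
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("repeat length must be positive")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        if not 0.0 <= self.f <= 0.5:
            raise ValueError("switching fraction f must lie in [0, 0.5]")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a mid-sized plant mitogenome sequenced with Nanopore-style
    long reads: a ~100 kb circle, unique contigs >= 1.5 kb, a lognormal read
    length distribution with median ~12 kb (N50 in the 10-30 kb range) and
    substitution-only errors.
    """

    genome_length: int = 100_000
    repeat_specs: tuple[RepeatSpec, ...] = ()
    contig_min: int = 1500
    read_count: int = 2000
    read_length_median: int = 12_000
    read_length_sigma: float = 0.35
    read_length_min: int = 1000
    error_rate: float = 0.0
    mode: str = "molecule"  # 'molecule' or 'junction'
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.mode not in ("molecule", "junction"):
            raise ValueError("mode must be 'molecule' or 'junction'")
        k = len(self.repeat_specs)
        budget = self.genome_length - 2 * sum(r.length for r in self.repeat_specs)
        need = (2 * k + 1) * self.contig_min if k else self.contig_min
        if budget < need:
            raise ValueError(
                f"infeasible config: {2 * k + 1} unique contigs of >= "
                f"{self.contig_min} bp need {need} bp but only {budget} bp remain "
                f"after planting {k} repeat pairs in {self.genome_length} bp"
            )

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["repeat_specs"] = [list(r.__dict__.values()) for r in self.repeat_specs]
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# Segment / molecule model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """A sequence block of the master circle, in master orientation."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def _least_rotation(s: str) -> str:
    """Lexicographically least rotation of ``s`` (Booth's algorithm)."""
    s2 = s + s
    f = [-1] * len(s2)
    k = 0
    for j in range(1, len(s2)):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s2[k : k + len(s)]


def _flip(item: tuple[str, str]) -> tuple[str, str]:
    sid, st = item
    return (sid, "-" if st == "+" else "+")


class Molecule:
    """A circular molecule as an ordered list of oriented segments."""

    def __init__(self, name: str, items: Sequence[tuple[str, str]], model: "MasterModel"):
        self.name = name
        self.items = tuple(items)
        self.model = model
        self._seq: str | None = None
        self._starts: list[int] | None = None

    @property
    def sequence(self) -> str:
        if self._seq is None:
            parts = []
            for sid, st in self.items:
                s = self.model.segments[sid].seq
                parts.append(s if st == "+" else revcomp(s))
            self._seq = "".join(parts)
        return self._seq

    def __len__(self) -> int:
        return sum(len(self.model.segments[sid]) for sid, _ in self.items)

    def segment_starts(self) -> list[int]:
        """Start offset of each item on the molecule sequence."""
        if self._starts is None:
            starts, pos = [], 0
            for sid, _ in self.items:
                starts.append(pos)
                pos += len(self.model.segments[sid])
            self._starts = starts
        return self._starts

    def copy_indices(self, repeat_id: str) -> list[int]:
        wanted = {f"{repeat_id}.1", f"{repeat_id}.2"}
        return [i for i, (sid, _) in enumerate(self.items) if sid in wanted]

    def effective_repeat_orientation(self, index: int) -> str:
        """Orientation of the repeat consensus at item ``index`` ('+'/'-')."""
        sid, strand = self.items[index]
        intrinsic = self.model.copy_orientation[sid]
        return "+" if intrinsic == strand else "-"

    def junction_label(self, index: int) -> str:
        """Which quartet path (m1/m2/s1/s2) the repeat copy at ``index`` forms.

        The copy's neighbors are normalised to the repeat-forward frame and
        compared with the master circle's neighbor patterns for the two loci.
        """
        n = len(self.items)
        sid, _ = self.items[index]
        rid = sid.rsplit(".", 1)[0]
        up, down = self._norm_flanks(index)
        pats = self.model.junction_patterns(rid)
        u = pats["up"].get(up)
        d = pats["down"].get(down)
        if u is None or d is None:
            return "other"
        return {("1", "1"): "m1", ("2", "2"): "m2", ("1", "2"): "s1", ("2", "1"): "s2"}[(u, d)]

    def _norm_flanks(self, index: int) -> tuple[tuple[str, str], tuple[str, str]]:
        n = len(self.items)
        prev = self.items[(index - 1) % n]
        nxt = self.items[(index + 1) % n]
        if self.effective_repeat_orientation(index) == "+":
            return prev, nxt
        return _flip(nxt), _flip(prev)

    def canonical(self) -> str:
        """Rotation/strand-invariant string form (for equality of circles)."""
        s, t = self.sequence, revcomp(self.sequence)
        return min(_least_rotation(s), _least_rotation(t))


@dataclass
class MasterModel:
    """Master circle plus the segment bookkeeping needed for simulation."""

    segments: dict[str, Segment]
    master_items: tuple[tuple[str, str], ...]
    repeats: tuple[RepeatPair, ...]
    copy_orientation: dict[str, str]  # segment id -> intrinsic repeat orientation

    def __post_init__(self) -> None:
        self._master: Molecule | None = None
        self._patterns: dict[str, dict] = {}

    @property
    def master(self) -> Molecule:
        if self._master is None:
            self._master = Molecule("master", self.master_items, self)
        return self._master

    def repeat_by_id(self, repeat_id: str) -> RepeatPair:
        for r in self.repeats:
            if r.id == repeat_id:
                return r
        raise KeyError(f"unknown repeat {repeat_id!r}")

    def junction_patterns(self, repeat_id: str) -> dict[str, dict]:
        """Normalised (upstream, downstream) neighbor ids of the two loci."""
        if repeat_id not in self._patterns:
            self.repeat_by_id(repeat_id)
            mol = self.master
            idxs = mol.copy_indices(repeat_id)
            if len(idxs) != 2:
                raise ValueError(f"repeat {repeat_id} does not have 2 copies on master")
            up: dict[tuple[str, str], str] = {}
            down: dict[tuple[str, str], str] = {}
            for which, idx in zip(("1", "2"), idxs):
                u, d = mol._norm_flanks(idx)
                up[u] = which
                down[d] = which
            self._patterns[repeat_id] = {"up": up, "down": down}
        return self._patterns[repeat_id]

    def to_genome(self) -> tuple[CircularGenome, list[RepeatPair]]:
        """Materialise the master circle as a genome + repeat annotations."""
        contigs = []
        pos = 0
        locus_of_copy: dict[str, Locus] = {}
        for sid, strand in self.master_items:
            seg = self.segments[sid]
            contigs.append(Contig(id=sid, start=pos, end=pos + len(seg)))
            locus_of_copy[sid] = Locus(pos, pos + len(seg))
            pos += len(seg)
        repeats = []
        for r in self.repeats:
            repeats.append(
                RepeatPair(
                    id=r.id,
                    orientation=r.orientation,
                    locus1=locus_of_copy[f"{r.id}.1"],
                    locus2=locus_of_copy[f"{r.id}.2"],
                )
            )
        return CircularGenome(self.master.sequence, contigs), repeats


# ---------------------------------------------------------------------------
# generate_master_circle
# ---------------------------------------------------------------------------


def _random_unique_seq(
    rng: np.random.Generator, length: int, kmer_bank: set[str], max_tries: int = 60
) -> str:
    """Random DNA with no >=30 bp exact match (either strand) to the bank."""
    for _ in range(max_tries):
        seq = "".join(
            np.frombuffer(_BASES[rng.integers(0, 4, size=length)].tobytes(), dtype="S1")
            .astype(str)
            .tolist()
        )
        kmers = {
            seq[i : i + ACCIDENTAL_REPEAT_K]
            for i in range(0, length - ACCIDENTAL_REPEAT_K + 1)
        }
        rc = revcomp(seq)
        kmers |= {
            rc[i : i + ACCIDENTAL_REPEAT_K]
            for i in range(0, length - ACCIDENTAL_REPEAT_K + 1)
        }
        if kmers.isdisjoint(kmer_bank) and len(kmers) == 2 * max(
            0, length - ACCIDENTAL_REPEAT_K + 1
        ):
            kmer_bank |= kmers
            return seq
    raise RuntimeError("could not generate a collision-free unique sequence")


def generate_master_circle(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CircularGenome, list[RepeatPair], MasterModel]:
    """Build a random circular master with planted repeat pairs.

    Layout: the first copy of every repeat is planted in the first half of the
    circle and the second copy in the second half, each copy separated from
    its neighbors by a unique contig.  Copy 2 is reverse-complemented on the
    master when the repeat is inverted.  Unique regions are rejection-sampled
    so no exact match of >= 30 bp occurs between (or within) them, or against
    a repeat sequence, keeping junction evidence unambiguous.

    Deterministic for a given config and seed.  Returns the genome (with a
    contig table tiling the circle; repeat copies are their own contigs named
    ``<id>.1``/``<id>.2``), the repeat annotations, and the
    :class:`MasterModel` used by the simulator.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k = len(config.repeat_specs)
    n_unique = 2 * k + 1 if k else 1
    unique_total = config.genome_length - 2 * sum(r.length for r in config.repeat_specs)
    extra = unique_total - n_unique * config.contig_min
    # spread the spare bases over the unique contigs at random
    shares = rng.multinomial(extra, np.full(n_unique, 1.0 / n_unique)) if extra else [0] * n_unique
    lengths = [config.contig_min + int(s) for s in shares]

    kmer_bank: set[str] = set()
    # repeat consensus sequences first, so unique contigs avoid them too
    names: list[str] = []
    by_class: dict[str, int] = {}
    repeat_seqs: list[str] = []
    for spec in config.repeat_specs:
        cls = classify_repeat(spec.length)
        by_class[cls] = by_class.get(cls, 0) + 1
        names.append(f"{cls}{by_class[cls]}")
        repeat_seqs.append(_random_unique_seq(rng, spec.length, kmer_bank))

    segments: dict[str, Segment] = {}
    copy_orientation: dict[str, str] = {}
    items: list[tuple[str, str]] = []
    ui = 0

    def add_unique() -> None:
        nonlocal ui
        seq = _random_unique_seq(rng, lengths[ui], kmer_bank)
        sid = f"U{ui + 1}"
        segments[sid] = Segment(sid, seq)
        copy_orientation[sid] = "+"
        items.append((sid, "+"))
        ui += 1

    # Palindromic plant order (A.1 B.1 C.1 ... C.2 B.2 A.2): the arc between
    # any repeat's two copies then contains other repeats' copies either both
    # or neither, so conformation toggles compose without interacting.
    triples = list(zip(names, config.repeat_specs, repeat_seqs))
    plant_order = [(name, spec, rseq, 1) for name, spec, rseq in triples] + [
        (name, spec, rseq, 2) for name, spec, rseq in reversed(triples)
    ]
    add_unique()
    for name, spec, rseq, copy in plant_order:
        sid = f"{name}.{copy}"
        if copy == 2 and spec.orientation == "-":
            segments[sid] = Segment(sid, revcomp(rseq))
            copy_orientation[sid] = "-"
        else:
            segments[sid] = Segment(sid, rseq)
            copy_orientation[sid] = "+"
        items.append((sid, "+"))
        if ui < n_unique:
            add_unique()

    specs_by_name = dict(zip(names, config.repeat_specs))
    reps = tuple(
        RepeatPair(
            id=name,
            orientation=specs_by_name[name].orientation,
            locus1=Locus(0, specs_by_name[name].length),  # placeholder, fixed below
            locus2=Locus(0, specs_by_name[name].length),
        )
        for name in names
    )
    model = MasterModel(
        segments=segments,
        master_items=tuple(items),
        repeats=reps,
        copy_orientation=copy_orientation,
    )
    genome, repeats = model.to_genome()
    model.repeats = tuple(repeats)
    return genome, repeats, model


# ---------------------------------------------------------------------------
# toggle_conformation
# ---------------------------------------------------------------------------


def toggle_conformation(molecule: Molecule | MasterModel, repeat_id: str) -> list[Molecule]:
    """Recombine one repeat pair on a circular molecule.

    Direct pair -> fission into two circles (one carries the s1 junction, the
    other s2).  Inverted pair -> one circle with the inter-repeat segment run
    reverse-complemented (carries both s1 and s2).  Total bases are conserved.
    Toggling an inverted repeat twice restores the original circle.
    """
    if isinstance(molecule, MasterModel):
        molecule = molecule.master
    model = molecule.model
    model.repeat_by_id(repeat_id)  # raises on unknown repeat
    idxs = molecule.copy_indices(repeat_id)
    if len(idxs) != 2:
        raise ValueError(
            f"repeat {repeat_id} does not have two copies on molecule {molecule.name}"
        )
    i, j = idxs
    items = molecule.items
    eff_i = molecule.effective_repeat_orientation(i)
    eff_j = molecule.effective_repeat_orientation(j)
    if eff_i == eff_j:
        # direct-type event: fission
        a = items[i:j]
        b = items[j:] + items[:i]
        return [
            Molecule(f"{molecule.name}/{repeat_id}:fissA", a, model),
            Molecule(f"{molecule.name}/{repeat_id}:fissB", b, model),
        ]
    # inverted-type event: reverse-complement the run strictly between copies
    between = items[i + 1 : j]
    new_items = items[: i + 1] + tuple(_flip(x) for x in reversed(between)) + items[j:]
    return [Molecule(f"{molecule.name}/{repeat_id}:inv", new_items, model)]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    id: str
    sequence: str


@dataclass
class ReadTruth:
    """True origin of one simulated read."""

    read_id: str
    molecule: str
    state: tuple[int, ...]  # one bit per repeat, 1 = secondary
    start: int  # origin offset on the molecule (forward strand)
    length: int
    strand: str
    focal_repeat: str | None = None  # set in junction mode


@dataclass
class SimulationTruth:
    reads: dict[str, ReadTruth]
    molecules: dict[str, Molecule]
    model: MasterModel

    def molecule_of(self, read_id: str) -> Molecule:
        return self.molecules[self.reads[read_id].molecule]


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        cur = arr[hit]
        repl = _BASES[rng.integers(0, 4, size=hit.size)]
        clash = repl == cur
        while np.any(clash):
            repl[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = repl == cur
        arr[hit] = repl
    return arr.tobytes().decode()


def _draw_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    ln = rng.lognormal(mean=np.log(config.read_length_median), sigma=config.read_length_sigma)
    return max(config.read_length_min, int(ln))


def _circular_slice(seq: str, start: int, length: int) -> str:
    n = len(seq)
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    return seq[start:] + seq[: start + length - n]


def _state_molecules(
    model: MasterModel, state: tuple[int, ...]
) -> list[Molecule]:
    """Molecule(s) of a conformation state vector (inversions then fission)."""
    mol = model.master
    direct_toggle = None
    for bit, rp in zip(state, model.repeats):
        if not bit:
            continue
        if rp.orientation == "+":
            if direct_toggle is not None:
                raise ValueError(
                    "molecule mode supports at most one toggled direct repeat "
                    "per molecule; use junction mode for arbitrary f combinations"
                )
            direct_toggle = rp.id
        else:
            (mol,) = toggle_conformation(mol, rp.id)
    if direct_toggle is not None:
        return toggle_conformation(mol, direct_toggle)
    return [mol]


def simulate_reads(
    model: MasterModel,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[SimRead], SimulationTruth]:
    """Sample long reads from a conformational mixture with truth labels.

    ``molecule`` mode draws one conformation state vector per molecule (each
    repeat secondary with probability ``f``, independently), materialises the
    molecule(s) and samples a read uniformly from the circle(s), length-
    weighted across fission products.  At most one *direct* repeat may have
    f > 0 in this mode (fission products would otherwise separate other
    direct-repeat copies onto different circles).

    ``junction`` mode allocates reads round-robin over repeats; each read is
    centred on one junction of its focal repeat (the secondary junction with
    probability ``f``), which yields spanning-read evidence for arbitrary
    combinations of switching fractions.

    Substitution errors at ``config.error_rate``; deterministic given seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.mode == "molecule":
        n_direct_switching = sum(
            1 for s, r in zip(config.repeat_specs, model.repeats)
            if r.orientation == "+" and s.f > 0
        )
        if n_direct_switching > 1:
            raise ValueError(
                "molecule mode supports at most one direct repeat with f > 0; "
                "use junction mode"
            )
    fs = np.array([s.f for s in config.repeat_specs], dtype=float)
    reads: list[SimRead] = []
    truths: dict[str, ReadTruth] = {}
    molecules: dict[str, Molecule] = {}
    mol_cache: dict[tuple[int, ...], list[Molecule]] = {}
    warned_truncate = False

    def register(mol: Molecule) -> str:
        if mol.name not in molecules:
            molecules[mol.name] = mol
        return mol.name

    n_rep = len(model.repeats)
    for ridx in range(config.read_count):
        rid = f"read{ridx:06d}"
        if config.mode == "molecule":
            state = tuple(int(b) for b in (rng.random(n_rep) < fs)) if n_rep else ()
            if state not in mol_cache:
                mol_cache[state] = _state_molecules(model, state)
            mols = mol_cache[state]
            lens = np.array([len(m) for m in mols], dtype=float)
            mol = mols[int(rng.choice(len(mols), p=lens / lens.sum()))]
            length = _draw_length(config, rng)
            if length > len(mol):
                if not warned_truncate:
                    warnings.warn(
                        "read length draw exceeds molecule length; truncating",
                        UserWarning,
                    )
                    warned_truncate = True
                length = len(mol)
            start = int(rng.integers(0, len(mol)))
            focal = None
        else:
            j = ridx % n_rep
            rp = model.repeats[j]
            secondary = bool(rng.random() < fs[j])
            state = tuple(1 if (secondary and t == j) else 0 for t in range(n_rep))
            if state not in mol_cache:
                mol_cache[state] = _state_molecules(model, state)
            mols = mol_cache[state]
            # pick one of the repeat's two junctions uniformly
            copies: list[tuple[Molecule, int]] = []
            for m in mols:
                for idx in m.copy_indices(rp.id):
                    copies.append((m, idx))
            mol, idx = copies[int(rng.integers(0, len(copies)))]
            seg_start = mol.segment_starts()[idx]
            seg_len = len(model.segments[mol.items[idx][0]])
            mid = seg_start + seg_len // 2
            length = _draw_length(config, rng)
            if length > len(mol):
                length = len(mol)
            start = int((mid - rng.integers(0, length)) % len(mol))
            focal = rp.id
        raw = _circular_slice(mol.sequence, start, length)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = revcomp(raw)
        seq = _apply_errors(raw, config.error_rate, rng)
        reads.append(SimRead(rid, seq))
        truths[rid] = ReadTruth(
            read_id=rid,
            molecule=register(mol),
            state=state,
            start=start,
            length=length,
            strand=strand,
            focal_repeat=focal,
        )
    return reads, SimulationTruth(reads=truths, molecules=molecules, model=model)


# ---------------------------------------------------------------------------
# truth_classify
# ---------------------------------------------------------------------------


def truth_classify(
    truth: SimulationTruth,
    read_id: str,
    repeat_id: str,
    min_flank: int = 100,
) -> str:
    """Oracle support label from true read coordinates alone.

    A read supports a junction path iff its true span covers the repeat copy
    plus ``min_flank`` bases on both sides; the path identity (m1/m2/s1/s2)
    is read off the copy's neighbors on the origin molecule.  Returns one of
    ``m1, m2, s1, s2, ambiguous, none``.
    """
    if read_id not in truth.reads:
        raise KeyError(f"no truth recorded for read {read_id!r}")
    rt = truth.reads[read_id]
    mol = truth.molecules[rt.molecule]
    n = len(mol)
    starts = mol.segment_starts()
    covered: list[str] = []
    for idx in mol.copy_indices(repeat_id):
        seg_len = len(mol.model.segments[mol.items[idx][0]])
        need_start = starts[idx] - min_flank
        need_len = seg_len + 2 * min_flank
        if need_len > rt.length:
            continue
        off = (need_start - rt.start) % n
        if off + need_len <= rt.length:
            covered.append(mol.junction_label(idx))
    covered = [c for c in covered if c != "other"]
    if not covered:
        return "none"
    if len(set(covered)) > 1 or len(covered) > 1:
        return "ambiguous"
    return covered[0]
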