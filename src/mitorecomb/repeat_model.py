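"""Domain model for repeat-mediated recombination in circular mitogenomes.

Plant mitochondrial genomes are conventionally drawn as a single "master
circle", but in vivo they are a mixture of arrangements interconverted by
homologous recombination (HR) between pairs of near-identical repeats.  Each
repeat pair defines four junction paths: ``m1``/``m2`` are the two junctions of
the primary (master-circle) arrangement, ``s1``/``s2`` the two junctions of the
recombined (secondary) arrangement.  Long reads that span a junction plus
flanking sequence are the evidence used to weigh the two arrangements.

This module provides the domain types (contigs, repeat pairs, conformation
quartets, assembly graphs) and the operations on the master circle:

* :func:`classify_repeat` -- SR/MR/LR/CR size classes;
* :func:`build_quartet` -- construct the four junction path sequences with
  flank contigs extended to a minimum length;
* :func:`detect_candidate_repeats` -- assembly-graph candidates from doubled
  coverage depth and multi-way connections;
* :func:`find_complex_repeats` -- maximal exact repeated substring pairs of a
  circular sequence, annotated with the elementary repeats they contain.

Coordinates are 0-based half-open throughout and wrap around the circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "revcomp",
    "Locus",
    "Contig",
    "RepeatPair",
    "CircularGenome",
    "QuartetPath",
    "ConformationQuartet",
    "GraphNode",
    "GraphLink",
    "GenomeGraph",
    "CandidateRepeat",
    "classify_repeat",
    "build_quartet",
    "detect_candidate_repeats",
    "find_complex_repeats",
    "SIZE_CLASS_SMALL_MAX",
    "SIZE_CLASS_MIDDLE_MAX",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Size-class boundaries (half-open bins): SR < 500 <= MR < 1000 <= LR.
SIZE_CLASS_SMALL_MAX = 500
SIZE_CLASS_MIDDLE_MAX = 1000


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class DegenerateQuartetWarning(UserWarning):
    """Raised when a quartet's secondary paths equal its primary paths."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Locus:
    """A genome interval, 0-based half-open, on the master circle."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted locus [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    """A unique segment of the master circle with optional coverage depth."""

    id: str
    start: int
    end: int
    depth: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatPair:
    """One annotated repeat: two loci on the master circle plus orientation.

    ``orientation`` is ``"+"`` (direct: both copies co-oriented), ``"-"``
    (inverted: locus2 carries the reverse complement) or ``"?"`` (unknown,
    handled as direct with a warning).  ``composition`` lists the elementary
    repeat/contig ids making up a complex repeat (empty otherwise).
    """

    id: str
    orientation: str
    locus1: Locus
    locus2: Locus
    composite: bool = False
    composition: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-", "?"):
            raise ValueError(f"orientation must be +, - or ?, got {self.orientation!r}")
        if self.locus1.length != self.locus2.length:
            raise ValueError(
                f"repeat {self.id}: locus lengths differ "
                f"({self.locus1.length} vs {self.locus2.length})"
            )

    @property
    def length(self) -> int:
        return self.locus1.length

    @property
    def size_class(self) -> str:
        return classify_repeat(self.length, composite=self.composite)

    def effective_orientation(self) -> str:
        """Orientation used for path construction ('?' treated as direct)."""
        if self.orientation == "?":
            warnings.warn(
                f"repeat {self.id} has unknown orientation; treating as direct",
                UserWarning,
                stacklevel=2,
            )
            return "+"
        return self.orientation


class CircularGenome:
    """A circular master sequence partitioned into contigs.

    The contig table must tile ``[0, len)`` contiguously; repeat copies are
    represented by their own contig entries so that repeat loci coincide with
    contig boundaries and flanks can be named.
    """

    def __init__(self, sequence: str, contigs: Sequence[Contig], name: str = "master"):
        self.sequence = sequence.upper()
        self.name = name
        self.contigs = sorted(contigs, key=lambda c: c.start)
        self._validate_tiling()
        self._start_index = {c.start: i for i, c in enumerate(self.contigs)}
        self._end_index = {c.end % len(self.sequence): i for i, c in enumerate(self.contigs)}

    def _validate_tiling(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ValueError("empty genome sequence")
        if not self.contigs:
            raise ValueError("genome has no contigs")
        pos = 0
        seen: set[str] = set()
        for c in self.contigs:
            if c.id in seen:
                raise ValueError(f"duplicate contig id {c.id!r}")
            seen.add(c.id)
            if c.start != pos:
                raise ValueError(
                    f"contig table does not tile the genome: gap/overlap at {pos} (contig {c.id})"
                )
            if c.end <= c.start:
                raise ValueError(f"contig {c.id} has non-positive length")
            pos = c.end
        if pos != n:
            raise ValueError(f"contig table ends at {pos}, genome length is {n}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Wrap-aware slice; the interval may cross the origin."""
        n = len(self.sequence)
        span = end - start
        if span < 0 or span > n:
            raise ValueError(f"invalid interval [{start}, {end}) on circle of {n}")
        start %= n
        stop = start + span
        if stop <= n:
            return self.sequence[start:stop]
        return self.sequence[start:] + self.sequence[: stop - n]

    def contig_starting_at(self, pos: int) -> Contig:
        i = self._start_index.get(pos % len(self.sequence))
        if i is None:
            raise KeyError(f"no contig starts at position {pos}")
        return self.contigs[i]

    def contig_ending_at(self, pos: int) -> Contig:
        i = self._end_index.get(pos % len(self.sequence))
        if i is None:
            raise KeyError(f"no contig ends at position {pos}")
        return self.contigs[i]

    def locus_sequence(self, locus: Locus) -> str:
        return self.fetch(locus.start, locus.end)


@dataclass
class QuartetPath:
    """One hypothetical junction path: flank + repeat + flank."""

    label: str
    sequence: str
    repeat_start: int
    repeat_end: int
    contig_labels: tuple[str, ...]

    @property
    def upstream_flank(self) -> str:
        return self.sequence[: self.repeat_start]

    @property
    def downstream_flank(self) -> str:
        return self.sequence[self.repeat_end :]

    @property
    def repeat_sequence(self) -> str:
        return self.sequence[self.repeat_start : self.repeat_end]


@dataclass
class ConformationQuartet:
    """The four junction paths m1/m2/s1/s2 for one repeat pair."""

    repeat_id: str
    paths: dict[str, QuartetPath]
    degenerate: bool = False

    PATH_IDS = ("m1", "m2", "s1", "s2")

    def __post_init__(self) -> None:
        missing = set(self.PATH_IDS) - set(self.paths)
        if missing:
            raise ValueError(f"quartet {self.repeat_id} missing paths {sorted(missing)}")
        reps = {p.repeat_sequence for p in self.paths.values()}
        if len(reps) != 1:
            raise ValueError(
                f"quartet {self.repeat_id}: repeat substring differs between paths"
            )

    @property
    def repeat_length(self) -> int:
        p = self.paths["m1"]
        return p.repeat_end - p.repeat_start

    def flank_lengths(self) -> dict[str, tuple[int, int]]:
        return {
            k: (p.repeat_start, len(p.sequence) - p.repeat_end)
            for k, p in self.paths.items()
        }


@dataclass
class GraphNode:
    id: str
    length: int
    depth: float | None = None
    sequence: str | None = None


@dataclass(frozen=True)
class GraphLink:
    """GFA-style link: ``from`` node (with orientation) to ``to`` node."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str


class GenomeGraph:
    """Assembly graph: contig nodes with depth, end-to-end links."""

    def __init__(self, nodes: Iterable[GraphNode], links: Iterable[GraphLink]):
        self.nodes: dict[str, GraphNode] = {n.id: n for n in nodes}
        self.links: list[GraphLink] = list(links)
        for l in self.links:
            if l.from_id not in self.nodes or l.to_id not in self.nodes:
                raise ValueError(f"link references unknown node: {l}")

    def neighbors(self, node_id: str, end: str) -> set[str]:
        """Distinct neighbor ids attached to one end ('start' or 'end')."""
        out: set[str] = set()
        for l in self.links:
            if l.from_id == node_id:
                side = "end" if l.from_orient == "+" else "start"
                if side == end:
                    out.add(l.to_id)
            if l.to_id == node_id:
                side = "start" if l.to_orient == "+" else "end"
                if side == end:
                    out.add(l.from_id)
        return out


@dataclass
class CandidateRepeat:
    node_id: str
    depth: float
    multiplicity: int
    neighbors_start: int
    neighbors_end: int


# ---------------------------------------------------------------------------
# classify_repeat
# ---------------------------------------------------------------------------


def classify_repeat(length: int, composite: bool = False) -> str:
    """Size class of a repeat: SR (<500 bp), MR (500-1000 bp), LR (>=1000 bp).

    Complex repeats (multi-contig composites) are CR regardless of length.
    Boundaries use half-open bins SR < 500 <= MR < 1000 <= LR.
    """
    if length <= 0:
        raise ValueError(f"repeat length must be positive, got {length}")
    if composite:
        return "CR"
    if length < SIZE_CLASS_SMALL_MAX:
        return "SR"
    if length < SIZE_CLASS_MIDDLE_MAX:
        return "MR"
    return "LR"


# ---------------------------------------------------------------------------
# build_quartet
# ---------------------------------------------------------------------------


def _circular_overlap(n: int, a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Do two wrap-aware half-open intervals on a circle of size n intersect?"""

    def segments(iv: tuple[int, int]) -> list[tuple[int, int]]:
        s, e = iv[0] % n, iv[0] % n + (iv[1] - iv[0])
        if e <= n:
            return [(s, e)]
        return [(s, n), (0, e - n)]

    for s1, e1 in segments(a):
        for s2, e2 in segments(b):
            if s1 < e2 and s2 < e1:
                return True
    return False


def _walk_flank(
    genome: CircularGenome,
    repeat: RepeatPair,
    anchor: int,
    direction: str,
    min_flank_contig: int,
) -> tuple[str, tuple[str, ...], tuple[int, int]]:
    """Collect whole contigs up-/downstream of ``anchor`` until >= min length.

    Returns (sequence, contig labels in path order, interval on the circle).
    Raises if the flank would run into either locus of the same repeat or
    exhaust the circle.
    """
    n = len(genome)
    labels: list[str] = []
    total = 0
    pos = anchor
    loci = [
        (repeat.locus1.start, repeat.locus1.end),
        (repeat.locus2.start, repeat.locus2.end),
    ]
    while total < min_flank_contig:
        if direction == "up":
            contig = genome.contig_ending_at(pos)
            iv = (contig.start, contig.start + contig.length)
            labels.insert(0, contig.id)
            pos = contig.start
        else:
            contig = genome.contig_starting_at(pos)
            iv = (contig.start, contig.start + contig.length)
            labels.append(contig.id)
            pos = contig.end % n
        if any(_circular_overlap(n, iv, l) for l in loci):
            raise ValueError(
                f"flank extension for repeat {repeat.id} reaches one of its own loci"
            )
        total += contig.length
        if total >= n:
            raise ValueError(
                f"flank extension for repeat {repeat.id} exhausted the circle"
            )
    if direction == "up":
        start = (anchor - total) % n
        seq = genome.fetch(start, start + total)
        iv_out = (start, start + total)
    else:
        seq = genome.fetch(anchor, anchor + total)
        iv_out = (anchor, anchor + total)
    return seq, tuple(labels), iv_out


def build_quartet(
    genome: CircularGenome,
    repeat: RepeatPair,
    min_flank_contig: int = 1000,
) -> ConformationQuartet:
    """Construct the four junction paths (m1/m2/s1/s2) for one repeat pair.

    Each path is the repeat sequence with its neighboring contigs on both
    sides; a flank shorter than ``min_flank_contig`` is extended with further
    contigs (whole contigs are always used, so alignments have enough unique
    anchor sequence).  All four paths carry the repeat in the same orientation
    (locus1's strand); for inverted repeats the m2 path is therefore the
    reverse complement of the master-circle segment around locus2, and the
    crossover paths are uniformly

    * ``s1`` = m1's upstream flank + repeat + m2's downstream flank,
    * ``s2`` = m2's upstream flank + repeat + m1's downstream flank,

    with m2's flanks taken in the path frame.  Reverse-complemented flank
    contigs are marked with a trailing apostrophe in the contig labels.
    """
    orientation = repeat.effective_orientation()
    r1 = genome.locus_sequence(repeat.locus1)
    r2 = genome.locus_sequence(repeat.locus2)
    expected = r2 if orientation == "+" else revcomp(r2)
    if r1 != expected:
        raise ValueError(
            f"repeat {repeat.id}: locus sequences are not identical under "
            f"orientation {repeat.orientation!r}"
        )
    rep = r1

    up1, up1_labels, _ = _walk_flank(genome, repeat, repeat.locus1.start, "up", min_flank_contig)
    down1, down1_labels, _ = _walk_flank(genome, repeat, repeat.locus1.end, "down", min_flank_contig)
    up2m, up2_labels, _ = _walk_flank(genome, repeat, repeat.locus2.start, "up", min_flank_contig)
    down2m, down2_labels, _ = _walk_flank(genome, repeat, repeat.locus2.end, "down", min_flank_contig)

    if orientation == "+":
        m2_up, m2_down = up2m, down2m
        m2_up_labels, m2_down_labels = up2_labels, down2_labels
    else:
        # Path frame = reverse complement of the master segment around locus2.
        m2_up, m2_down = revcomp(down2m), revcomp(up2m)
        m2_up_labels = tuple(lab + "'" for lab in reversed(down2_labels))
        m2_down_labels = tuple(lab + "'" for lab in reversed(up2_labels))

    def make_path(label: str, up: str, down: str, up_l: tuple[str, ...], down_l: tuple[str, ...]) -> QuartetPath:
        return QuartetPath(
            label=label,
            sequence=up + rep + down,
            repeat_start=len(up),
            repeat_end=len(up) + len(rep),
            contig_labels=up_l + (repeat.id,) + down_l,
        )

    paths = {
        "m1": make_path("m1", up1, down1, up1_labels, down1_labels),
        "m2": make_path("m2", m2_up, m2_down, m2_up_labels, m2_down_labels),
        "s1": make_path("s1", up1, m2_down, up1_labels, m2_down_labels),
        "s2": make_path("s2", m2_up, down1, m2_up_labels, down1_labels),
    }

    degenerate = (
        paths["s1"].sequence == paths["m1"].sequence
        or paths["s2"].sequence == paths["m2"].sequence
        or paths["s1"].sequence == paths["m2"].sequence
        or paths["s2"].sequence == paths["m1"].sequence
    )
    if degenerate:
        warnings.warn(
            f"repeat {repeat.id}: secondary paths are sequence-identical to "
            f"primary paths (shared flanks); support counts will be ambiguous",
            DegenerateQuartetWarning,
            stacklevel=2,
        )
    return ConformationQuartet(repeat_id=repeat.id, paths=paths, degenerate=degenerate)


# ---------------------------------------------------------------------------
# detect_candidate_repeats
# ---------------------------------------------------------------------------


def detect_candidate_repeats(
    graph: GenomeGraph, depth_ratio: float = 1.75
) -> list[CandidateRepeat]:
    """Repeat candidates from assembly-graph topology and coverage depth.

    A node is a candidate when its depth is at least ``depth_ratio`` times the
    median depth of non-candidate nodes AND it has >= 2 distinct neighbors on
    each end (the signature of a collapsed repeat).  The single-copy baseline
    is the median depth of non-candidate nodes, iterated to a fixed point; the
    multiplicity estimate is depth / baseline rounded to the nearest integer
    (floored at 2).
    """
    import statistics

    if not graph.nodes:
        raise ValueError("empty graph")
    for n in graph.nodes.values():
        if n.depth is None:
            raise ValueError(f"node {n.id} has no depth; depths are required")

    def eligible(nid: str) -> bool:
        return (
            len(graph.neighbors(nid, "start")) >= 2
            and len(graph.neighbors(nid, "end")) >= 2
        )

    topo_ok = {nid for nid in graph.nodes if eligible(nid)}
    candidates: set[str] = set()
    for _ in range(10):
        rest = [graph.nodes[n].depth for n in graph.nodes if n not in candidates]
        if not rest:
            break
        baseline = statistics.median(rest)
        new = {
            nid
            for nid in topo_ok
            if graph.nodes[nid].depth >= depth_ratio * baseline
        }
        if new == candidates:
            break
        candidates = new
    rest = [graph.nodes[n].depth for n in graph.nodes if n not in candidates]
    baseline = statistics.median(rest) if rest else statistics.median(
        [n.depth for n in graph.nodes.values()]
    )
    out = []
    for nid in sorted(candidates):
        node = graph.nodes[nid]
        mult = max(2, round(node.depth / baseline))
        out.append(
            CandidateRepeat(
                node_id=nid,
                depth=node.depth,
                multiplicity=mult,
                neighbors_start=len(graph.neighbors(nid, "start")),
                neighbors_end=len(graph.neighbors(nid, "end")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# find_complex_repeats
# ---------------------------------------------------------------------------


def _merge_runs(positions: list[int], k: int) -> list[tuple[int, int]]:
    """Merge sorted consecutive k-mer start positions into (start, length)."""
    runs = []
    s = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
        else:
            runs.append((s, prev - s + k))
            s = prev = p
    runs.append((s, prev - s + k))
    return runs


@dataclass
class _MatchPair:
    start1: int
    start2: int
    length: int
    orientation: str  # '+' direct, '-' inverted


def _circular_merge_runs(hits: list[int], k: int, n: int) -> list[tuple[int, int]]:
    """Run-merge k-mer hit positions on a circle (joins runs across origin)."""
    runs = _merge_runs(hits, k)
    if len(runs) > 1 and hits[0] == 0 and hits[-1] == n - 1:
        first = runs.pop(0)
        last_s, last_len = runs.pop()
        runs.append((last_s, last_len - k + 1 + first[1]))
    return runs


def find_complex_repeats(
    master: CircularGenome | str,
    elementary: Sequence[RepeatPair] = (),
    min_len: int = 1000,
    k: int = 31,
) -> list[RepeatPair]:
    """Maximal exactly-repeated substring pairs of a circular master sequence.

    Both orientations are searched.  Pairs fully contained (both intervals) in
    a longer reported pair are suppressed.  Each reported pair is annotated
    with the elementary repeats and contigs it spans (``composition``), and
    classified CR when it is a multi-element composite.
    """
    if isinstance(master, CircularGenome):
        seq = master.sequence
        contigs = master.contigs
    else:
        seq = master.upper()
        contigs = []
    n = len(seq)
    if min_len > n:
        return []
    if 2 * min_len > n:
        return []
    k = min(k, min_len)
    pairs: list[_MatchPair] = []
    seq2 = seq + seq

    # --- direct orientation: group circular k-mer starts by k-mer ---
    idx: dict[str, list[int]] = {}
    for i in range(n):
        idx.setdefault(seq2[i : i + k], []).append(i)
    diag_hits: dict[int, list[int]] = {}
    for positions in idx.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                p, q = positions[a], positions[b]
                d = (q - p) % n
                if d == 0:
                    continue
                diag_hits.setdefault(d, []).append(p)
    for d, hits in diag_hits.items():
        hits = sorted(set(hits))
        for s, length in _circular_merge_runs(hits, k, n):
            q = (s + d) % n
            # cap the length so the two copies stay disjoint on the circle
            length = min(length, d, n - d)
            pairs.append(_MatchPair(s % n, q, length, "+"))

    # --- inverted orientation: S vs revcomp(S) ---
    rc = revcomp(seq)
    rc2 = rc + rc
    rc_idx: dict[str, list[int]] = {}
    for i in range(n):
        rc_idx.setdefault(rc2[i : i + k], []).append(i)
    anti_hits: dict[int, list[int]] = {}
    for kmer, positions in idx.items():
        rpos = rc_idx.get(kmer)
        if not rpos:
            continue
        for p in positions:
            for q in rpos:
                # rc window q corresponds to forward window starting at j:
                j = (n - q - k) % n
                if j == p:
                    continue
                c = (p + j) % n
                anti_hits.setdefault(c, []).append(p)
    for c, hits in anti_hits.items():
        hits = sorted(set(hits))
        for s, length in _circular_merge_runs(hits, k, n):
            # forward interval [s, s+length); its reverse-complement partner
            # starts where the last matching k-mer's rc window begins
            j_start = (c - (s + length - k)) % n
            pairs.append(_MatchPair(s, j_start, length, "-"))

    # normalise, dedupe, filter, suppress contained
    cleaned: dict[tuple[int, int, int, str], _MatchPair] = {}
    for mp in pairs:
        if mp.length < min_len:
            continue
        a, b = (mp.start1, mp.start2)
        if mp.orientation == "+" and ((b - a) % n) > n - ((b - a) % n):
            a, b = b, a
        if mp.orientation == "-" and b < a:
            a, b = b, a
        if _circular_overlap(n, (a, a + mp.length), (b, b + mp.length)):
            continue
        cleaned[(a, b, mp.length, mp.orientation)] = _MatchPair(a, b, mp.length, mp.orientation)
    result = list(cleaned.values())
    result.sort(key=lambda m: -m.length)

    def contained(small: _MatchPair, big: _MatchPair) -> bool:
        if small.orientation != big.orientation:
            return False

        def inside(s: tuple[int, int], b: tuple[int, int]) -> bool:
            off = (s[0] - b[0]) % n
            return off + (s[1] - s[0]) <= b[1] - b[0]

        i1 = (small.start1, small.start1 + small.length)
        i2 = (small.start2, small.start2 + small.length)
        b1 = (big.start1, big.start1 + big.length)
        b2 = (big.start2, big.start2 + big.length)
        return (inside(i1, b1) and inside(i2, b2)) or (inside(i1, b2) and inside(i2, b1))

    kept: list[_MatchPair] = []
    for mp in result:
        if any(contained(mp, other) for other in kept):
            continue
        kept.append(mp)

    out: list[RepeatPair] = []
    for i, mp in enumerate(sorted(kept, key=lambda m: (m.start1, m.start2)), start=1):
        comp = _composition(n, (mp.start1, mp.start1 + mp.length), elementary, contigs)
        out.append(
            RepeatPair(
                id=f"CR{i}",
                orientation=mp.orientation,
                locus1=Locus(mp.start1, mp.start1 + mp.length),
                locus2=Locus(mp.start2, mp.start2 + mp.length),
                composite=True,
                composition=comp,
            )
        )
    return out


def _composition(
    n: int,
    interval: tuple[int, int],
    elementary: Sequence[RepeatPair],
    contigs: Sequence[Contig],
) -> tuple[str, ...]:
    """Ordered elementary repeats / contigs overlapping an interval."""
    items: list[tuple[int, str]] = []
    for rp in elementary:
        for locus in (rp.locus1, rp.locus2):
            if _circular_overlap(n, interval, (locus.start, locus.end)):
                off = (locus.start - interval[0]) % n
                items.append((off, rp.id))
                break
    for c in contigs:
        if _circular_overlap(n, interval, (c.start, c.end)):
            off = (c.start - interval[0]) % n
            items.append((off, c.id))
    items.sort()
    seen = set()
    ordered = []
    for _, name in items:
        if name not in seen:
            seen.add(name)
            ordered.append(name)
    return tuple(ordered)
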