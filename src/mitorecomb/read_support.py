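"""Read-vs-path alignment, spanning-read classification and support tallies.

A long read supports one of a repeat's four junction paths (m1/m2/s1/s2) only
when a single primary alignment covers the entire repeat plus at least
``min_flank`` bases (default 100 bp) on both sides at sufficient identity.
Reads satisfying several paths are ambiguous; reads satisfying none carry no
evidence.  Ambiguous and uninformative reads are excluded from the support
counts.

Alignments can come from an external long-read aligner (PAF input, see
:mod:`mitorecomb.io`) or from the built-in k-mer-anchored matcher
(:func:`match_read`), which is exact for substitution-only reads: anchors
shared between read and path vote for an offset (diagonal), the best diagonal
defines the aligned interval, and matches are counted base-by-base over the
overlap.  The matcher handles both strands and is deliberately gap-free -- the
synthetic read model is substitution-only, and the spanning criterion is
evaluated per single contiguous alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .repeat_model import ConformationQuartet, revcomp

__all__ = [
    "AlignmentRecord",
    "SupportLabel",
    "QuartetIndex",
    "match_read",
    "classify_read",
    "count_support",
]


@dataclass
class AlignmentRecord:
    """One read-vs-path alignment (PAF-like coordinates).

    ``read_start``/``read_end`` are on the original read; ``strand`` records
    which read strand matched the path forward strand.
    """

    read_id: str
    repeat_id: str
    path_id: str  # m1 / m2 / s1 / s2
    read_start: int
    read_end: int
    path_start: int
    path_end: int
    strand: str
    matches: int
    block_len: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.read_end <= self.read_start or self.path_end <= self.path_start:
            raise ValueError(f"empty alignment interval for read {self.read_id}")
        if self.matches > self.block_len:
            raise ValueError("matches exceed block length")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len


@dataclass(frozen=True)
class SupportLabel:
    """Per-(read, repeat) outcome: m1/m2/s1/s2, ambiguous, or none."""

    read_id: str
    repeat_id: str
    label: str


def _best_segment(eq: np.ndarray, mismatch_penalty: float = 2.0) -> tuple[int, int]:
    """Maximum-scoring contiguous segment of a match profile (Kadane).

    ``eq`` is a boolean per-base match array along one alignment diagonal;
    scoring +1 per match and -``mismatch_penalty`` per mismatch.  Returns the
    half-open index range of the best segment ((0, 0) if all-negative).
    """
    score = np.where(eq, 1.0, -mismatch_penalty)
    cs = np.concatenate(([0.0], np.cumsum(score)))
    run_min = np.minimum.accumulate(cs[:-1])
    gains = cs[1:] - run_min
    j = int(np.argmax(gains))
    if gains[j] <= 0:
        return 0, 0
    i = int(np.argmin(cs[: j + 1]))
    return i, j + 1


class QuartetIndex:
    """K-mer index over a quartet's four paths for the built-in matcher.

    Build once per quartet, then stream reads through :meth:`match`.
    """

    def __init__(self, quartet: ConformationQuartet, k: int = 15):
        if k < 4:
            raise ValueError("k must be >= 4")
        self.quartet = quartet
        self.k = k
        self.paths: dict[str, str] = {
            pid: p.sequence.upper() for pid, p in quartet.paths.items()
        }
        self.arrays: dict[str, np.ndarray] = {
            pid: np.frombuffer(seq.encode(), dtype=np.uint8)
            for pid, seq in self.paths.items()
        }
        self.index: dict[str, dict[str, list[int]]] = {}
        for pid, seq in self.paths.items():
            idx: dict[str, list[int]] = {}
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i : i + k], []).append(i)
            self.index[pid] = idx

    def match(
        self,
        read_id: str,
        read: str,
        stride: int | None = None,
        min_anchors: int = 3,
    ) -> list[AlignmentRecord]:
        """Anchor a read (either strand) on each path; one record per path.

        Anchors vote for a diagonal (read offset - path offset); the winning
        diagonal defines the aligned interval and matches are counted by
        direct base comparison over the overlap.
        """
        if not read:
            raise ValueError("empty read")
        k = self.k
        if len(read) < 2 * k:
            raise ValueError(f"read shorter than 2k ({2 * k} bp)")
        read = read.upper()
        records: list[AlignmentRecord] = []
        seqs = {"+": read, "-": revcomp(read)}
        if stride is None:
            stride = max(1, (len(read) - k) // 512)
        for pid, path in self.paths.items():
            idx = self.index[pid]
            best: tuple[int, int, str] | None = None  # votes, diag, strand
            for strand, seq in seqs.items():
                votes: dict[int, int] = {}
                for i in range(0, len(seq) - k + 1, stride):
                    for p in idx.get(seq[i : i + k], ()):
                        d = i - p
                        votes[d] = votes.get(d, 0) + 1
                if votes:
                    d, v = max(votes.items(), key=lambda kv: (kv[1], -abs(kv[0])))
                    if v >= min_anchors and (best is None or v > best[0]):
                        best = (v, d, strand)
            if best is None:
                continue
            _, d, strand = best
            seq = seqs[strand]
            p0 = max(0, -d)
            p1 = min(len(path), len(seq) - d)
            if p1 <= p0:
                continue
            r0, r1 = p0 + d, p1 + d
            a = np.frombuffer(seq.encode(), dtype=np.uint8)[r0:r1]
            b = self.arrays[pid][p0:p1]
            eq = (a == b)
            # local-alignment semantics: clip the diagonal to its maximum-
            # scoring contiguous segment (+1 match, -2 mismatch), so the
            # alignment breaks at a junction instead of running through a
            # mismatching flank
            lo, hi = _best_segment(eq)
            if hi - lo < k:
                continue
            p0, p1 = p0 + lo, p0 + hi
            r0, r1 = p0 + d, p1 + d
            matches = int(np.count_nonzero(eq[lo:hi]))
            if strand == "-":
                r0, r1 = len(read) - r1, len(read) - r0
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    repeat_id=self.quartet.repeat_id,
                    path_id=pid,
                    read_start=r0,
                    read_end=r1,
                    path_start=p0,
                    path_end=p1,
                    strand=strand,
                    matches=matches,
                    block_len=p1 - p0,
                )
            )
        return records


def match_read(
    read: str,
    quartet: ConformationQuartet | QuartetIndex,
    read_id: str = "read",
    k: int = 15,
    stride: int | None = None,
    min_anchors: int = 3,
) -> list[AlignmentRecord]:
    """Align one read against a quartet's four paths (built-in matcher).

    Convenience wrapper over :class:`QuartetIndex`; build the index yourself
    when matching many reads against the same quartet.
    """
    index = quartet if isinstance(quartet, QuartetIndex) else QuartetIndex(quartet, k=k)
    return index.match(read_id, read, stride=stride, min_anchors=min_anchors)


def classify_read(
    records: Sequence[AlignmentRecord],
    quartet: ConformationQuartet,
    min_flank: int = 100,
    min_identity: float = 0.7,
    read_id: str | None = None,
) -> SupportLabel:
    """Label one read against one quartet with the spanning criterion.

    A path is *satisfied* iff a single primary record covers
    ``[repeat_start - min_flank, repeat_end + min_flank]`` on that path with
    identity >= ``min_identity``.  Exactly one satisfied path gives that
    label; two or more give ``ambiguous``; none gives ``none``.
    """
    read_ids = {r.read_id for r in records}
    if len(read_ids) > 1:
        raise ValueError(f"records for several reads passed together: {sorted(read_ids)}")
    if records:
        read_id = records[0].read_id
    elif read_id is None:
        read_id = ""
    satisfied: list[str] = []
    for pid in ConformationQuartet.PATH_IDS:
        path = quartet.paths[pid]
        lo = path.repeat_start - min_flank
        hi = path.repeat_end + min_flank
        for rec in records:
            if rec.path_id != pid:
                continue
            if rec.path_id not in quartet.paths:
                raise ValueError(f"record references unknown path {rec.path_id!r}")
            if not rec.is_primary:
                continue
            if rec.path_start <= lo and rec.path_end >= hi and rec.identity >= min_identity:
                satisfied.append(pid)
                break
    unknown = {r.path_id for r in records} - set(ConformationQuartet.PATH_IDS)
    if unknown:
        raise ValueError(f"records reference unknown paths {sorted(unknown)}")
    if len(satisfied) == 1:
        label = satisfied[0]
    elif len(satisfied) >= 2:
        label = "ambiguous"
    else:
        label = "none"
    return SupportLabel(read_id=read_id, repeat_id=quartet.repeat_id, label=label)


def count_support(labels: Iterable[SupportLabel]):
    """Tally m1/m2/s1/s2 labels for one repeat into a SupportCounts.

    Ambiguous and uninformative reads are excluded.  All labels must refer to
    the same repeat.
    """
    from .recomb_stats import SupportCounts

    labels = list(labels)
    repeat_ids = {l.repeat_id for l in labels}
    if len(repeat_ids) > 1:
        raise ValueError(f"labels for several repeats passed together: {sorted(repeat_ids)}")
    repeat_id = labels[0].repeat_id if labels else ""
    tally = {"m1": 0, "m2": 0, "s1": 0, "s2": 0}
    for l in labels:
        if l.label in tally:
            tally[l.label] += 1
    return SupportCounts(repeat_id=repeat_id, **tally)
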