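"""Codon-usage-bias statistics for CDS collections.

Implements the classic desk statistics used to characterise organelle
protein-coding genes: positional GC content (GC, GC1, GC2, GC3, GC12, GC3s),
Wright's effective number of codons (ENC, 20 = one codon per amino acid,
61 = uniform synonymous usage), relative synonymous codon usage (RSCU), the
ENC-plot expected curve, parity-rule-2 (PR2) coordinates over fourfold-
degenerate codon boxes, and neutrality-plot points (GC12 vs GC3) with an OLS
fit.

Conventions (configurable where they differ between tools):

* standard genetic code by default (``table`` selects any NCBI table);
* GC3s excludes Met, Trp and the stop codons (no synonymous choice there);
* six-codon families (Leu, Ser, Arg) are treated as single families;
* ENC uses Wright's estimator F = (n * sum(p^2) - 1) / (n - 1) per family,
  averaged within degeneracy classes; families observed fewer than twice are
  dropped, and a missing 3-fold class (Ile) is imputed as the mean of the
  2- and 4-fold class averages; the result is capped at 61;
* PR2 uses the third positions of the eight fourfold-degenerate codon boxes
  (CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN in the standard code).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "GcPartition",
    "CodonUsageProfile",
    "NeutralityFit",
    "GeneticCode",
    "codon_counts",
    "gc_partition",
    "enc",
    "enc_expected",
    "rscu",
    "pr2_coordinates",
    "neutrality_points",
    "profile_gene",
]

_GC = frozenset("GCgc")
_VALID = frozenset("ACGT")


class GeneticCode:
    """Synonymous-family structure of an NCBI translation table."""

    def __init__(self, table: int = 1):
        t = CodonTable.unambiguous_dna_by_id[table]
        self.table_id = table
        self.stop_codons = frozenset(t.stop_codons)
        self.codon_to_aa: dict[str, str] = dict(t.forward_table)
        families: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            families.setdefault(aa, []).append(codon)
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(cs)) for aa, cs in families.items()
        }
        # codons with no synonymous alternative (Met, Trp in the standard code)
        self.nonsynonymous = frozenset(
            c for aa, cs in self.families.items() if len(cs) == 1 for c in cs
        )
        self.fourfold_boxes: tuple[tuple[str, ...], ...] = tuple(
            tuple(sorted(g))
            for g in self._boxes()
        )

    def _boxes(self) -> list[list[str]]:
        """Fourfold-degenerate codon boxes: prefix XY with all 4 endings
        coding the same amino acid."""
        out = []
        for p1 in "TCAG":
            for p2 in "TCAG":
                codons = [p1 + p2 + p3 for p3 in "TCAG"]
                aas = {self.codon_to_aa.get(c) for c in codons}
                if len(aas) == 1 and None not in aas:
                    out.append(codons)
        return out


_STANDARD = GeneticCode(1)


def _codons(cds: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def codon_counts(cds: str) -> dict[str, int]:
    """64-entry codon count table (codons with ambiguous bases skipped)."""
    counts = {
        a + b + c: 0 for a in "TCAG" for b in "TCAG" for c in "TCAG"
    }
    skipped = 0
    for codon in _codons(cds):
        if set(codon) <= _VALID:
            counts[codon] += 1
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} codons with ambiguous bases", UserWarning)
    return counts


class GcPartition(NamedTuple):
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float | None


def gc_partition(cds: str, code: GeneticCode = _STANDARD) -> GcPartition:
    """Positional GC percentages of a CDS.

    GC1/2/3 are per codon position over all codons; GC12 is their first/second
    mean; GC3s is restricted to third positions of synonymous codons (Met,
    Trp and stops excluded) and is None when no such codon is present.
    Ambiguous bases are excluded from denominators (with a warning).
    """
    codons = _codons(cds)
    pos_gc = [0, 0, 0]
    pos_n = [0, 0, 0]
    ambiguous = 0
    s_gc = s_n = 0
    for codon in codons:
        for i, base in enumerate(codon):
            if base not in _VALID:
                ambiguous += 1
                continue
            pos_n[i] += 1
            if base in _GC:
                pos_gc[i] += 1
        if (
            set(codon) <= _VALID
            and codon not in code.stop_codons
            and codon not in code.nonsynonymous
        ):
            s_n += 1
            if codon[2] in _GC:
                s_gc += 1
    if ambiguous:
        warnings.warn(
            f"{ambiguous} ambiguous bases excluded from GC denominators", UserWarning
        )
    if sum(pos_n) == 0:
        raise ValueError("no unambiguous bases in CDS")
    gc1, gc2, gc3 = (
        100.0 * g / n if n else float("nan") for g, n in zip(pos_gc, pos_n)
    )
    gc = 100.0 * sum(pos_gc) / sum(pos_n)
    gc3s = 100.0 * s_gc / s_n if s_n else None
    return GcPartition(gc=gc, gc1=gc1, gc2=gc2, gc3=gc3, gc12=(gc1 + gc2) / 2.0, gc3s=gc3s)


def enc(counts: Mapping[str, int], code: GeneticCode = _STANDARD) -> float | None:
    """Wright's effective number of codons from a codon count table.

    Per family with n >= 2 observations, F = (n * sum(p^2) - 1) / (n - 1);
    class averages over families grouped by degeneracy; ENC = 2 + 9/F2 +
    1/F3 + 5/F4 + 3/F6, capped at 61.  Returns None when too few families are
    observed to estimate the composite.
    """
    class_f: dict[int, list[float]] = {}
    for aa, codons in code.families.items():
        size = len(codons)
        if size == 1:
            continue
        ns = np.array([counts.get(c, 0) for c in codons], dtype=float)
        n = ns.sum()
        if n < 2:
            continue
        p = ns / n
        f_hat = (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)
        class_f.setdefault(size, []).append(f_hat)

    n_singleton = sum(1 for cs in code.families.values() if len(cs) == 1)
    class_sizes = sorted({len(cs) for cs in code.families.values() if len(cs) > 1})
    avg: dict[int, float] = {}
    for size in class_sizes:
        fs = class_f.get(size, [])
        if fs:
            avg[size] = float(np.mean(fs))
    # impute a missing 3-fold class from the 2- and 4-fold averages
    if 3 in class_sizes and 3 not in avg and 2 in avg and 4 in avg:
        avg[3] = (avg[2] + avg[4]) / 2.0
    n_families = {
        size: sum(1 for cs in code.families.values() if len(cs) == size)
        for size in class_sizes
    }
    total = float(n_singleton)
    for size in class_sizes:
        if size not in avg:
            return None
        if avg[size] <= 0:
            return None
        total += n_families[size] / avg[size]
    return min(total, 61.0)


def enc_expected(gc3s: float) -> float:
    """Expected ENC under mutation pressure alone at a given GC3s fraction:
    2 + s + 29 / (s^2 + (1 - s)^2)."""
    s = float(gc3s)
    if not 0.0 < s < 1.0:
        raise ValueError(f"gc3s must lie in (0, 1), got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def rscu(
    counts: Mapping[str, int], code: GeneticCode = _STANDARD
) -> dict[str, float]:
    """Relative synonymous codon usage over the sense codons.

    RSCU(c) = observed(c) / (family total / family size).  Families with zero
    observations get RSCU 0 for all members (flagged with a warning).
    """
    out: dict[str, float] = {}
    empty: list[str] = []
    for aa, codons in code.families.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            empty.append(aa)
            for c in codons:
                out[c] = 0.0
            continue
        expected = total / len(codons)
        for c in codons:
            out[c] = counts.get(c, 0) / expected
    if empty:
        warnings.warn(
            f"no observations for amino acid(s) {sorted(empty)}; RSCU set to 0",
            UserWarning,
        )
    return out


def pr2_coordinates(
    cds: str, code: GeneticCode = _STANDARD
) -> tuple[float | None, float | None]:
    """PR2-plot coordinates (x = G3/(G3+C3), y = A3/(A3+T3)) over third
    positions of fourfold-degenerate codon boxes; None on a zero denominator
    (with a warning)."""
    codons = _codons(cds)
    four = {c for box in code.fourfold_boxes for c in box}
    if not any(c in four for c in codons):
        raise ValueError("CDS contains no fourfold-degenerate codon")
    tally = {b: 0 for b in "ACGT"}
    for codon in codons:
        if codon in four:
            tally[codon[2]] += 1
    gc3 = tally["G"] + tally["C"]
    at3 = tally["A"] + tally["T"]
    x = tally["G"] / gc3 if gc3 else None
    y = tally["A"] / at3 if at3 else None
    if x is None or y is None:
        warnings.warn("zero denominator in PR2 coordinates", UserWarning)
    return x, y


@dataclass
class CodonUsageProfile:
    """Per-gene codon-usage summary."""

    gene_id: str
    gc: GcPartition
    enc: float | None
    codon_counts: dict[str, int]
    rscu: dict[str, float]
    pr2: tuple[float | None, float | None]

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "GC": self.gc.gc,
            "GC1": self.gc.gc1,
            "GC2": self.gc.gc2,
            "GC3": self.gc.gc3,
            "GC12": self.gc.gc12,
            "GC3s": self.gc.gc3s,
            "ENC": self.enc,
            "PR2_x": self.pr2[0],
            "PR2_y": self.pr2[1],
        }


def profile_gene(gene_id: str, cds: str, code: GeneticCode = _STANDARD) -> CodonUsageProfile:
    """Full codon-usage profile for one CDS."""
    counts = codon_counts(cds)
    try:
        pr2 = pr2_coordinates(cds, code)
    except ValueError:
        pr2 = (None, None)
    return CodonUsageProfile(
        gene_id=gene_id,
        gc=gc_partition(cds, code),
        enc=enc(counts, code),
        codon_counts=counts,
        rscu=rscu(counts, code),
        pr2=pr2,
    )


@dataclass
class NeutralityFit:
    points: pd.DataFrame  # gene_id, GC3, GC12
    slope: float
    intercept: float
    r: float


def neutrality_points(profiles: Sequence[CodonUsageProfile]) -> NeutralityFit:
    """Neutrality-plot data: per-gene (GC3, GC12) and the OLS fit of GC12 on
    GC3 (slope near 1 indicates mutation pressure, near 0 selection)."""
    if len(profiles) < 3:
        raise ValueError("need >= 3 genes for a neutrality fit")
    df = pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles],
            "GC3": [p.gc.gc3 for p in profiles],
            "GC12": [p.gc.gc12 for p in profiles],
        }
    )
    if df["GC3"].nunique() == 1:
        # vertical column of points: slope undefined, report 0 against the mean
        return NeutralityFit(points=df, slope=0.0, intercept=float(df["GC12"].mean()), r=0.0)
    fit = stats.linregress(df["GC3"], df["GC12"])
    return NeutralityFit(
        points=df,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
    )
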