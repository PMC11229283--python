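"""Conformation frequencies, the recombination-rate statistic and reports.

For one repeat pair with spanning-read support counts (m1, m2, s1, s2), the
conformation frequencies keep only the better-supported junction of each
arrangement:

    F_m = max(m1, m2),    F_s = max(s1, s2)

and the recombination rate is

    rate = 100 * min(F_m, F_s) / (F_m + F_s)   [percent]

which by construction lies in [0, 50]: 50% means the two arrangements are at
parity, 0% means no spanning read supports the rarer one.  A repeat with
primary support but zero secondary support is called inactive (a false
positive of graph-based repeat detection); a repeat with no spanning reads at
all carries no data and its rate is undefined.

The repeat-length vs rate relationship is summarised by the Pearson
correlation with a two-sided t-test (n - 2 degrees of freedom).
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "SupportCounts",
    "RecombinationRecord",
    "CorrelationResult",
    "conformation_frequencies",
    "recombination_rate",
    "classify_activity",
    "length_rate_correlation",
    "count_high_freq_configurations",
    "make_report",
    "round_half_up",
]


def _check_counts(m1: int, m2: int, s1: int, s2: int) -> None:
    for name, v in (("m1", m1), ("m2", m2), ("s1", s1), ("s2", s2)):
        if v < 0 or int(v) != v:
            raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")


def conformation_frequencies(m1: int, m2: int, s1: int, s2: int) -> tuple[int, int]:
    """(F_m, F_s): the better-supported junction of each conformation."""
    _check_counts(m1, m2, s1, s2)
    return max(m1, m2), max(s1, s2)


def recombination_rate(m1: int, m2: int, s1: int, s2: int) -> float | None:
    """Recombination rate in percent, in [0, 50]; None when no read supports
    either conformation."""
    f_m, f_s = conformation_frequencies(m1, m2, s1, s2)
    if f_m + f_s == 0:
        return None
    return 100.0 * min(f_m, f_s) / (f_m + f_s)


def classify_activity(m1: int, m2: int, s1: int, s2: int) -> str:
    """'active', 'inactive_no_secondary' (one conformation only), 'no_data'."""
    f_m, f_s = conformation_frequencies(m1, m2, s1, s2)
    if f_m == 0 and f_s == 0:
        return "no_data"
    if min(f_m, f_s) > 0:
        return "active"
    return "inactive_no_secondary"


@dataclass
class SupportCounts:
    """Spanning-read support for one repeat's four junction paths."""

    repeat_id: str
    m1: int
    m2: int
    s1: int
    s2: int

    def __post_init__(self) -> None:
        _check_counts(self.m1, self.m2, self.s1, self.s2)

    @property
    def f_m(self) -> int:
        return max(self.m1, self.m2)

    @property
    def f_s(self) -> int:
        return max(self.s1, self.s2)

    @property
    def rate(self) -> float | None:
        return recombination_rate(self.m1, self.m2, self.s1, self.s2)

    @property
    def activity(self) -> str:
        return classify_activity(self.m1, self.m2, self.s1, self.s2)


@dataclass
class RecombinationRecord:
    """Per-repeat summary: length, orientation, rate and activity call."""

    repeat_id: str
    length: int
    orientation: str
    rate: float | None
    activity: str


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("correlation needs at least 3 points")


def length_rate_correlation(
    records: Sequence[RecombinationRecord],
) -> CorrelationResult:
    """Pearson correlation of repeat length (bp) vs recombination rate (%).

    Records with undefined rates (no spanning reads) are excluded and
    reported; zero rates are genuine observations and stay in.  p is the
    two-sided t-test p-value with n - 2 degrees of freedom.
    """
    usable = [r for r in records if r.rate is not None]
    excluded = tuple(r.repeat_id for r in records if r.rate is None)
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 records with defined rates, got {len(usable)}"
        )
    x = [r.length for r in usable]
    y = [r.rate for r in usable]
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=len(usable), excluded=excluded
    )


def count_high_freq_configurations(k: int) -> int:
    """Number of genome configurations from k independently recombining
    repeat pairs: 2**k."""
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    return 2 ** int(k)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention), e.g. 0.125 -> 0.13."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def make_report(
    counts: Iterable[SupportCounts],
    repeats: dict | None = None,
    quartets: dict | None = None,
) -> pd.DataFrame:
    """Per-repeat summary table (one row per repeat).

    ``repeats`` optionally maps repeat_id to a RepeatPair (length,
    orientation, size class); ``quartets`` optionally maps repeat_id to a
    ConformationQuartet whose contig labels are reported as path
    compositions.  Repeat ids present in ``repeats``/``quartets`` but not in
    ``counts`` (or vice versa when metadata is given) raise an error.
    """
    counts = list(counts)
    ids = [c.repeat_id for c in counts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate repeat ids in counts")
    for mapping, what in ((repeats, "repeats"), (quartets, "quartets")):
        if mapping is not None:
            missing = set(ids) - set(mapping)
            if missing:
                raise ValueError(f"{what} missing entries for {sorted(missing)}")
    rows = []
    for c in counts:
        rp = repeats.get(c.repeat_id) if repeats else None
        q = quartets.get(c.repeat_id) if quartets else None
        rate = c.rate
        row = {
            "repeat_id": c.repeat_id,
            "length": rp.length if rp else None,
            "orientation": rp.orientation if rp else None,
            "size_class": rp.size_class if rp else None,
            "m1": c.m1,
            "m2": c.m2,
            "s1": c.s1,
            "s2": c.s2,
            "F_m": c.f_m,
            "F_s": c.f_s,
            "rate_percent": round_half_up(rate, 2) if rate is not None else math.nan,
            "activity": c.activity,
        }
        if q is not None:
            for pid in ("m1", "m2", "s1", "s2"):
                row[f"{pid}_path"] = "-".join(q.paths[pid].contig_labels)
        rows.append(row)
    columns = [
        "repeat_id",
        "length",
        "orientation",
        "size_class",
        "m1",
        "m2",
        "s1",
        "s2",
        "F_m",
        "F_s",
        "rate_percent",
        "activity",
    ]
    if quartets is not None:
        columns += ["m1_path", "m2_path", "s1_path", "s2_path"]
    return pd.DataFrame(rows, columns=columns)
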