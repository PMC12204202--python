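"""Comparative statistics over per-species transducer records.

Conventions (stated because the underlying study reports only the results):
median for even n is the midpoint of the two central order statistics;
quartiles use Tukey's inclusive hinges; all tests are two-sided; reported
percentages are rounded to integers with the raw fraction retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class CohortRecord:
    """One species-level transducer entry (one TolA and at most one
    representative TonB per species)."""

    species: str
    clade: str
    protein_class: str  # TolA | TonB
    d2_length: int
    helix_pct: float
    proline_pct: float
    composition_class: str = ""
    lipo_class: str = "none"


@dataclass(frozen=True)
class CohortSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float
    min_species: str
    max_species: str


def _tukey_hinges(sorted_vals: Sequence[float]) -> tuple[float, float, float]:
    """(q1, median, q3) by the inclusive (Tukey) method."""
    n = len(sorted_vals)

    def mid(vals: Sequence[float]) -> float:
        m = len(vals)
        if m % 2:
            return float(vals[m // 2])
        return (vals[m // 2 - 1] + vals[m // 2]) / 2.0

    median = mid(sorted_vals)
    half = (n + 1) // 2  # lower half includes the median element when n is odd
    lower = sorted_vals[:half]
    upper = sorted_vals[n - half:]
    return mid(lower), median, mid(upper)


def length_summary(
    records: Iterable[CohortRecord] | pd.DataFrame,
    group_by: str | Sequence[str] = "protein_class",
    value: str = "d2_length",
) -> list[CohortSummary]:
    """Median / quartile / extreme summary per group, extremes labelled by
    species.  Empty groups are skipped."""
    df = _as_frame(records)
    if isinstance(group_by, str):
        group_by = [group_by]
    out: list[CohortSummary] = []
    for key, grp in df.groupby(list(group_by), sort=True):
        if grp.empty:
            continue
        grp = grp.sort_values([value, "species"], kind="mergesort")
        vals = grp[value].to_numpy(dtype=float)
        q1, med, q3 = _tukey_hinges(list(vals))
        label = key if isinstance(key, str) else "/".join(map(str, key))
        out.append(CohortSummary(
            group=label, n=len(vals), median=med, q1=q1, q3=q3,
            min=float(vals[0]), max=float(vals[-1]),
            min_species=str(grp.iloc[0]["species"]),
            max_species=str(grp.iloc[-1]["species"]),
        ))
    return out


def _as_frame(records: Iterable[CohortRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


def pearson(pairs: Sequence[tuple[float, float]]) -> float:
    """Product-moment correlation of paired values.

    Requires n >= 3 and nonzero variance in both margins.
    """
    if len(pairs) < 3:
        raise StatsError(f"need >= 3 pairs, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("zero variance in a margin; correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


_EXACT_LIMIT = 400  # n1*n2 above which the normal approximation is used


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    ``exact`` enumerates the null distribution of U (valid without ties);
    ``normal`` uses the tie-corrected normal approximation with continuity
    correction.  ``auto`` picks exact when n1*n2 <= 400 and the pooled
    sample has no ties.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    if not a or not b:
        raise StatsError("both samples must be nonempty")
    has_ties = len(set(a + b)) < len(a) + len(b)
    if mode == "auto":
        mode = "exact" if (len(a) * len(b) <= _EXACT_LIMIT and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            raise StatsError("exact mode is invalid in the presence of ties")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def proportion_stats(
    items: Sequence,
    predicate: Callable[[object], bool],
    denominator_predicate: Callable[[object], bool] = lambda _: True,
) -> tuple[int, int, Optional[int], Optional[float]]:
    """(k, n, rounded pct, raw fraction) of items satisfying ``predicate``
    among those satisfying ``denominator_predicate``.

    n = 0 leaves the percentage undefined (None, reported as NA).
    """
    denom = [x for x in items if denominator_predicate(x)]
    n = len(denom)
    k = sum(1 for x in denom if predicate(x))
    if n == 0:
        return 0, 0, None, None
    frac = k / n
    pct = int(math.floor(100.0 * frac + 0.5))  # round half up, not banker's
    return k, n, pct, frac


def summaries_to_frame(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
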