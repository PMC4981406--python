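"""Group comparisons of per-cell MI values.

Implements the two Wilcoxon tests used for the study-style contrasts:

* :func:`paired_signed_rank` — matched per-cell comparisons (e.g. LFP
  amplitude MI vs PSP amplitude MI in the same cells).  Exact null
  distribution by enumeration of all sign assignments for n <= 15
  (after dropping zero differences); normal approximation with tie and
  continuity corrections for larger n.
* :func:`unpaired_rank_sum` — independent-group comparisons (e.g.
  pentobarbital vs urethane cells).  Exact by enumeration of all group
  assignments for m + n <= 12; tie-corrected normal approximation
  otherwise.

The thresholds put study-scale inputs (33 pairs; 16 vs 17 cells) on the
approximation path, as any standard implementation would, while the
exact modes double as enumeration oracles in the test-suite.

An MI table is a plain DataFrame with columns
``cell_id, signal_type, feature, group, value_bits`` (one row per key);
:func:`summarize` reduces a selection of it to mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

MI_TABLE_COLUMNS = ["cell_id", "signal_type", "feature", "group", "value_bits"]


@dataclass
class ComparisonResult:
    test: str  # 'signed_rank' | 'rank_sum'
    tails: str  # 'one' | 'two'
    direction: str  # 'greater' | 'less' (first argument vs second)
    n: int  # pairs used (signed rank) or (m, n) total (rank sum)
    statistic: float
    p_value: float
    group_means: tuple[float, float]
    group_sems: tuple[float, float]
    exact: bool
    n_zeros_dropped: int = 0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _mean_sem(v: np.ndarray) -> tuple[float, float]:
    v = np.asarray(v, dtype=float)
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def summarize(table: pd.DataFrame, **key) -> tuple[float, float, int]:
    """Mean, SEM (sd/sqrt(n); 0 for a single row) and n of matching rows.

    ``key`` filters on equality of any MI-table columns, e.g.
    ``summarize(t, signal_type='LFP', feature='amplitude')``.
    """
    sel = table
    for col, val in key.items():
        sel = sel[sel[col] == val]
    if len(sel) == 0:
        raise ValueError(f"no rows match {key!r}")
    mean, sem = _mean_sem(sel["value_bits"].to_numpy())
    return mean, sem, len(sel)


# -- signed rank -------------------------------------------------------


def _signed_rank_exact_sf(ranks: np.ndarray, w_obs: float, lower: bool) -> float:
    """P(W+ <= or >= w_obs) over all 2^n equiprobable sign assignments."""
    n = len(ranks)
    count = 0
    for mask in range(1 << n):
        w = 0.0
        mm = mask
        i = 0
        while mm:
            if mm & 1:
                w += ranks[i]
            mm >>= 1
            i += 1
        hit = w <= w_obs + 1e-9 if lower else w >= w_obs - 1e-9
        count += hit
    return count / (1 << n)


def paired_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    direction: str = "greater",
    tails: str = "one",
    exact_threshold: int = 15,
) -> ComparisonResult:
    """Wilcoxon signed-rank test on matched pairs.

    ``direction='greater'`` tests the alternative that x tends to exceed
    y.  Zero differences are dropped and their count reported; if every
    difference is zero the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and matched in length")
    if direction not in ("greater", "less") or tails not in ("one", "two"):
        raise ValueError("direction must be greater|less, tails one|two")
    gm, gs = _mean_sem(x), _mean_sem(y)
    d = x - y
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        return ComparisonResult(
            "signed_rank", tails, direction, 0, 0.0, 1.0,
            (gm[0], gs[0]), (gm[1], gs[1]), exact=True,
            n_zeros_dropped=n_zero, degenerate=True,
        )
    ranks = sst.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    exact = n <= exact_threshold
    if exact:
        p_hi = _signed_rank_exact_sf(ranks, w_pos, lower=False)
        p_lo = _signed_rank_exact_sf(ranks, w_pos, lower=True)
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = np.unique(np.abs(d), return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            ((tie_counts**3 - tie_counts).sum()) / 48.0
        )
        sd = np.sqrt(var)
        p_hi = float(sst.norm.sf((w_pos - mu - 0.5) / sd))
        p_lo = float(sst.norm.cdf((w_pos - mu + 0.5) / sd))
    if tails == "one":
        p = p_hi if direction == "greater" else p_lo
    else:
        p = min(1.0, 2.0 * min(p_hi, p_lo))
    return ComparisonResult(
        "signed_rank", tails, direction, n, w_pos, p,
        (gm[0], gs[0]), (gm[1], gs[1]), exact=exact, n_zeros_dropped=n_zero,
    )


# -- rank sum ----------------------------------------------------------


def _rank_sum_exact_sf(ranks: np.ndarray, m: int, w_obs: float, lower: bool) -> float:
    """P(W_a <= or >= w_obs) over all C(m+n, m) group assignments."""
    total = 0
    hits = 0
    for comb in combinations(range(len(ranks)), m):
        w = float(ranks[list(comb)].sum())
        hits += w <= w_obs + 1e-9 if lower else w >= w_obs - 1e-9
        total += 1
    return hits / total


def unpaired_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    tails: str = "two",
    direction: str = "greater",
    exact_threshold: int = 12,
) -> ComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney) test between independent groups.

    The statistic is the rank sum of group ``a`` in the pooled ranking;
    ``direction='greater'`` tests the alternative that ``a`` tends to
    exceed ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if direction not in ("greater", "less") or tails not in ("one", "two"):
        raise ValueError("direction must be greater|less, tails one|two")
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sst.rankdata(pooled)
    w_a = float(ranks[:m].sum())
    exact = (m + n) <= exact_threshold
    if exact:
        p_hi = _rank_sum_exact_sf(ranks, m, w_a, lower=False)
        p_lo = _rank_sum_exact_sf(ranks, m, w_a, lower=True)
    else:
        big_n = m + n
        mu = m * (big_n + 1) / 2.0
        tie_counts = np.unique(pooled, return_counts=True)[1]
        tie_term = float((tie_counts**3 - tie_counts).sum()) / (
            (big_n) * (big_n - 1)
        )
        var = m * n / 12.0 * ((big_n + 1) - tie_term)
        sd = np.sqrt(var)
        p_hi = float(sst.norm.sf((w_a - mu - 0.5) / sd))
        p_lo = float(sst.norm.cdf((w_a - mu + 0.5) / sd))
    if tails == "one":
        p = p_hi if direction == "greater" else p_lo
    else:
        p = min(1.0, 2.0 * min(p_hi, p_lo))
    return ComparisonResult(
        "rank_sum", tails, direction, m + n, w_a, p,
        _mean_sem(a), _mean_sem(b), exact=exact,
    )


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Optional Bonferroni adjustment (the core analyses apply none)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)
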