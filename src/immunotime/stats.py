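"""Group-comparison and correlation statistics: two-tailed Mann-Whitney,
Spearman correlation, and Fisher's exact test (2×2 and small r×c by full
enumeration of tables with fixed margins).

The two-sided Fisher p follows the point-probability criterion (sum of the
probabilities of all margin-compatible tables no more probable than the
observed one), the convention shared by R's ``fisher.test`` and SPSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .io import ValidationError

logger = logging.getLogger("immunotime")

#: significance stars at the figure-legend levels
STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test → (U of x, p).

    Exact enumeration when n_x + n_y ≤ 20 and there are no ties; otherwise
    the normal approximation with mid-rank tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("paired samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("spearman: %d incomplete pairs dropped", dropped)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError("Spearman needs ≥3 complete pairs")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        logger.warning("spearman: constant input — correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), n)
    r, p = sps.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), n)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

_ENUMERATION_BOUND = 200
_REL_TOL = 1e-7


def table_log_probability(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a table given its margins:
    log[ ∏ rowsum! ∏ colsum! / (N! ∏ cell!) ]."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def fill_row(i, remaining_cols, current):
        if i == r - 1:
            last = remaining_cols
            if (last >= 0).all() and last.sum() == row_sums[i]:
                yield current + [last.copy()]
            return
        target = row_sums[i]

        def compositions(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from compositions(j + 1, left - v, row + [v])

        for row in compositions(0, target, []):
            row = np.array(row)
            yield from fill_row(i + 1, remaining_cols - row, current + [row])

    yield from fill_row(0, np.asarray(col_sums).copy(), [])


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for an r×c count table (total ≤ 200).

    All tables with the observed margins are enumerated; the p-value sums
    the probabilities of tables whose hypergeometric probability does not
    exceed the observed table's (within relative tolerance 1e-7).
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("Fisher test needs an r×c table with r,c ≥ 2")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or (table < 0).any():
            raise ValidationError("table entries must be non-negative integers")
        table = np.round(table).astype(int)
    total = int(table.sum())
    if total == 0:
        raise ValidationError("empty table")
    if total > _ENUMERATION_BOUND:
        raise ValidationError(
            f"table total {total} exceeds the enumeration bound "
            f"{_ENUMERATION_BOUND}; use a chi-square test instead"
        )
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    logp_obs = table_log_probability(table)
    cutoff = logp_obs + np.log1p(_REL_TOL)
    p = 0.0
    for t in _enumerate_tables(row_sums, col_sums):
        logp = table_log_probability(np.array(t))
        if logp <= cutoff:
            p += np.exp(logp)
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------


def compare_feature_by_group(
    features: pd.DataFrame, grouping: pd.Series, test: str = "mann_whitney"
) -> pd.DataFrame:
    """Per-feature two-group comparison (tidy output with significance stars).

    ``features``: samples × features; ``grouping``: sample → level (exactly
    two levels). Missing feature values are dropped per feature and counted.
    """
    levels = pd.unique(grouping.dropna())
    if len(levels) != 2:
        raise ValidationError(f"grouping must have exactly 2 levels, got {list(levels)}")
    if test != "mann_whitney":
        raise ValidationError(f"unknown test {test!r}")
    a_ids = grouping.index[grouping == levels[0]]
    b_ids = grouping.index[grouping == levels[1]]
    rows = []
    for feat in features.columns:
        a = features.loc[features.index.intersection(a_ids), feat].to_numpy(float)
        b = features.loc[features.index.intersection(b_ids), feat].to_numpy(float)
        n_missing = int(np.isnan(a).sum() + np.isnan(b).sum())
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) == 0 or len(b) == 0:
            logger.warning("feature %s: a group has no data — skipped", feat)
            continue
        u, p = mann_whitney(a, b)
        rows.append(
            {
                "feature": feat,
                "test": "mann_whitney",
                "group_a": str(levels[0]),
                "group_b": str(levels[1]),
                "n_a": len(a),
                "n_b": len(b),
                "n_missing": n_missing,
                "statistic_u": u,
                "p_value": p,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)
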