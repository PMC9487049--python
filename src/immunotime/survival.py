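"""Outcome analysis: median dichotomization, Kaplan-Meier estimation,
log-rank (Mantel-Cox) testing and univariate Cox proportional-hazards
regression on disease-free survival (DFS, months from last treatment to
death or relapse).

Conventions: values equal to the median dichotomize to the low group; Cox
ties are handled by Efron's method; the many per-variable survival screens
report raw p-values (a BH-adjusted column is emitted alongside for
transparency, but calling is based on raw p as in the source analyses);
subjects with DFS time 0 are shifted to 0.01 months to avoid risk-set
degeneracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ImmunotimeError, ValidationError
from .gep import bh_adjust

logger = logging.getLogger("immunotime")

LOW, HIGH = "low", "high"


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    n_events: int
    converged: bool = True  # False flags monotone-likelihood / separation


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------


def dichotomize_by_median(
    values: dict[str, float], tie_rule: str = "le_median_is_low"
) -> dict[str, str]:
    """Split patients at the median: low iff value ≤ median.

    Missing (NaN) values are excluded and logged. The median is the
    midpoint of the two central order statistics for even n, so the split
    is invariant under strictly increasing transforms of the values.
    """
    if tie_rule != "le_median_is_low":
        raise ValidationError(f"unknown tie rule {tie_rule!r}")
    clean = {k: v for k, v in values.items() if v is not None and np.isfinite(v)}
    dropped = set(values) - set(clean)
    if dropped:
        logger.warning("dichotomize: %d missing values excluded: %s", len(dropped), sorted(dropped))
    if len(clean) < 2:
        raise ImmunotimeError("need ≥2 non-missing values to dichotomize")
    med = float(np.median(list(clean.values())))
    return {k: (LOW if v <= med else HIGH) for k, v in clean.items()}


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class KMCurve:
    """Right-continuous product-limit step function S(t)."""

    def __init__(self, times: np.ndarray, survival: np.ndarray):
        self.times = times  # step locations (event times), increasing
        self.survival = survival  # S just after each step

    def __call__(self, t: float) -> float:
        if t < 0:
            raise ValidationError("negative time")
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``times`` in months (≥0); ``events`` truthy for death/relapse, falsy
    for censoring.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValidationError("empty group")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(float)
    s = sf.iloc[:, 0].to_numpy(float)
    return KMCurve(t, s)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test → (chi-square, p).

    p is NaN (with a warning) when no events occurred.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {list(levels)}")
    a = groups == levels[0]
    if a.all() or (~a).all():
        raise ValidationError("one group is empty")
    if not events.any():
        logger.warning("log-rank: zero events — p undefined")
        return 0.0, float("nan")
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------


def cox_univariate(times, events, covariate) -> CoxResult:
    """Univariate Cox PH fit of a binary (or numeric) covariate.

    Efron tie handling; HR = exp(β); 95% CI = exp(β ± 1.96·SE); Wald p.
    Monotone likelihood (complete separation of events) yields a flagged
    result with an infinite HR instead of a silent non-convergence.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    cov = np.asarray(covariate, dtype=float)
    if len(np.unique(cov)) < 2:
        raise ValidationError("covariate is constant")
    if not events.any():
        raise ValidationError("no events")
    df = pd.DataFrame({"time": times, "event": events.astype(int), "x": cov})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        logger.warning("Cox fit: monotone likelihood / separation — HR unbounded")
        beta = np.inf if _events_increase_with(cov, events) else -np.inf
        hr = float(np.exp(beta)) if np.isfinite(beta) else (np.inf if beta > 0 else 0.0)
        return CoxResult(hr, 0.0, np.inf, float("nan"),
                         len(times), int(events.sum()), converged=False)
    s = cph.summary.loc["x"]
    if abs(float(s["coef"])) > 15:
        # numerically converged but the likelihood is monotone in practice
        logger.warning("Cox fit: effectively unbounded coefficient — separation")
        return CoxResult(
            float(np.inf) if s["coef"] > 0 else 0.0,
            0.0, np.inf, float("nan"), len(times), int(events.sum()),
            converged=False,
        )
    return CoxResult(
        hazard_ratio=float(s["exp(coef)"]),
        ci_lower=float(s["exp(coef) lower 95%"]),
        ci_upper=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        n=len(times),
        n_events=int(events.sum()),
    )


def _events_increase_with(cov: np.ndarray, events: np.ndarray) -> bool:
    return cov[events].mean() >= cov[~events].mean() if (~events).any() else True


# ---------------------------------------------------------------------------
# Screening driver
# ---------------------------------------------------------------------------


def km_curve_table(
    features: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Per-variable KM curve coordinates (variable, group, time, survival,
    n at risk at entry) for plotting the median-split curves."""
    rows = []
    for var in features.columns:
        vals = features[var].to_dict()
        try:
            groups = dichotomize_by_median(vals)
        except ImmunotimeError:
            continue
        for level in (LOW, HIGH):
            pats = [p for p in survival.index if groups.get(p) == level]
            if not pats:
                continue
            t = survival.loc[pats, "dfs_time_months"].to_numpy(float)
            e = survival.loc[pats, "dfs_event"].to_numpy(bool)
            curve = km_estimate(t, e).as_frame()
            curve.insert(0, "variable", var)
            curve.insert(1, "group", level)
            curve["n_at_entry"] = len(pats)
            rows.append(curve)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["variable", "group", "time_months", "survival", "n_at_entry"]
    )


def survival_screen(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Per-variable median split → KM/log-rank/Cox.

    ``features``: patients × immune variables (index = patient_id).
    ``survival``: index = patient_id, columns dfs_time_months, dfs_event,
    plus optional strata columns (e.g. hpv_status, sex).

    Returns one row per variable (× stratum when ``stratify_by`` is given)
    with the median cutoff, group sizes, log-rank χ²/p, HR and 95% CI.
    Raw p-values are primary; a BH-adjusted column is appended.
    """
    if features.empty or features.shape[1] == 0:
        raise ValidationError("no variables to screen")
    strata: list[tuple[str, pd.Index]] = []
    if stratify_by is None:
        strata.append(("all", survival.index))
    else:
        for level in pd.unique(survival[stratify_by]):
            strata.append((str(level), survival.index[survival[stratify_by] == level]))

    rows = []
    for stratum, idx in strata:
        surv = survival.loc[idx]
        for var in features.columns:
            vals = features.loc[features.index.intersection(idx), var].to_dict()
            try:
                groups = dichotomize_by_median(vals)
            except ImmunotimeError as exc:
                logger.warning("screen %s [%s]: %s", var, stratum, exc)
                continue
            pats = [p for p in surv.index if p in groups]
            g = np.array([groups[p] for p in pats])
            t = surv.loc[pats, "dfs_time_months"].to_numpy(float)
            e = surv.loc[pats, "dfs_event"].to_numpy(bool)
            t = np.where(t == 0, 0.01, t)
            if (t != surv.loc[pats, "dfs_time_months"].to_numpy(float)).any():
                logger.warning("screen %s [%s]: zero DFS times shifted to 0.01", var, stratum)
            row = {
                "variable": var,
                "stratum": stratum,
                "median_cutoff": float(np.median([v for v in vals.values() if np.isfinite(v)])),
                "n_low": int((g == LOW).sum()),
                "n_high": int((g == HIGH).sum()),
                "n_events": int(e.sum()),
            }
            try:
                chi2, p = logrank_test(t, e, g)
                row["logrank_chi2"], row["logrank_p"] = chi2, p
            except ValidationError as exc:
                logger.warning("screen %s [%s]: log-rank failed (%s)", var, stratum, exc)
                row["logrank_chi2"] = row["logrank_p"] = float("nan")
            try:
                cox = cox_univariate(t, e, (g == HIGH).astype(float))
                row.update(
                    hazard_ratio=cox.hazard_ratio,
                    hr_ci_lower=cox.ci_lower,
                    hr_ci_upper=cox.ci_upper,
                    cox_p=cox.p_value,
                    cox_converged=cox.converged,
                )
            except ValidationError as exc:
                logger.warning("screen %s [%s]: Cox failed (%s)", var, stratum, exc)
                row.update(
                    hazard_ratio=float("nan"), hr_ci_lower=float("nan"),
                    hr_ci_upper=float("nan"), cox_p=float("nan"), cox_converged=False,
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        valid = out["logrank_p"].notna()
        out["logrank_p_bh"] = np.nan
        if valid.any():
            out.loc[valid, "logrank_p_bh"] = bh_adjust(out.loc[valid, "logrank_p"].to_numpy())
    return out
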