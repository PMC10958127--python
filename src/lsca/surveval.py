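"""Survival validation of a sample score.

Wraps the standard survival-analysis machinery behind the pipeline's
containers: Kaplan-Meier curves per group, the two-group log-rank test,
multivariate Cox proportional hazards with Wald hazard-ratio confidence
intervals (Efron ties, the R ``survival`` default), and IPCW
cumulative/dynamic time-dependent AUC with a paired-bootstrap test for
AUC differences between two scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .io import SurvivalTable

__all__ = [
    "KMCurve",
    "CoxResult",
    "TimedAUC",
    "kaplan_meier",
    "logrank_test",
    "cox_multivariate",
    "time_dependent_auc",
    "compare_auc",
]

#: Reference levels for categorical clinical covariates.
REFERENCE_LEVELS = {"sex": "Female", "cytogenetic_risk": "Favorable"}


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    group: str
    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        assert self.survival[0] <= 1.0 + 1e-12
        assert np.all(np.diff(self.survival) <= 1e-12), "S(t) must be non-increasing"

    def at(self, t: float) -> float:
        """S(t): the last estimate at or before t."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    """Multivariate Cox fit: per-covariate HR, 95% CI and Wald p."""

    table: pd.DataFrame  # index covariate; columns coef, hr, ci_low, ci_high, p
    reference_levels: dict[str, str] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0

    def summary(self) -> pd.DataFrame:
        return self.table


@dataclass
class TimedAUC:
    """Cumulative/dynamic AUC(t) over a grid of horizons."""

    times: np.ndarray
    auc: np.ndarray  # NaN where no cases or no controls
    weighting: str = "ipcw-km"


def kaplan_meier(survival: SurvivalTable, groups: pd.Series | None = None) -> dict[str, KMCurve]:
    """Kaplan-Meier curves, one per group (a single 'all' group when None)."""
    if groups is None:
        groups = pd.Series("all", index=survival.sample_ids)
    groups = pd.Series(groups).reindex(survival.sample_ids)
    curves = {}
    for g in pd.unique(groups.dropna()):
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[mask], survival.event[mask])
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
        curves[str(g)] = KMCurve(group=str(g), timeline=timeline,
                                 survival=surv, at_risk=at_risk)
    return curves


def logrank_test(survival: SurvivalTable, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    groups = pd.Series(groups).reindex(survival.sample_ids)
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    m = (groups == levels[0]).to_numpy()
    if survival.event.sum() < 1:
        raise ValueError("no events observed")
    res = _ll_logrank(survival.time[m], survival.time[~m],
                      survival.event[m], survival.event[~m])
    return float(res.test_statistic), float(res.p_value)


def _expand_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Dummy-code categoricals against their declared reference level."""
    out = {}
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            out[cov] = col.astype(float)
        else:
            levels = list(pd.unique(col.dropna()))
            ref = REFERENCE_LEVELS.get(cov)
            if ref in levels:
                levels.remove(ref)
                levels = [ref] + sorted(levels)
            else:
                levels = sorted(levels)
            for lvl in levels[1:]:
                out[f"{cov}[{lvl}]"] = (col == lvl).astype(float)
    return pd.DataFrame(out, index=df.index)


def cox_multivariate(survival: SurvivalTable, covariates: pd.DataFrame | list[str]) -> CoxResult:
    """Multivariate Cox PH fit with Efron ties and Wald intervals.

    ``covariates`` is either a DataFrame of per-sample columns or a list of
    column names taken from the survival table itself.  Categorical columns
    are expanded against a reference level (sex=Female,
    cytogenetic_risk=Favorable by default; otherwise the first sorted
    level).  Rows with any missing covariate are dropped with a warning.
    """
    if isinstance(covariates, list):
        cov_df = survival.data[covariates]
    else:
        cov_df = covariates.reindex(survival.sample_ids)
    X = _expand_covariates(cov_df, list(cov_df.columns))
    keep = X.notna().all(axis=1)
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} samples with missing covariates")
    X = X.loc[keep]
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more covariates than usable samples")
    arr = X.to_numpy(dtype=float)
    if (arr.std(axis=0) == 0).any():
        const = X.columns[arr.std(axis=0) == 0].tolist()
        raise ValueError(f"constant covariates: {const}")
    if np.linalg.matrix_rank(np.column_stack([arr - arr.mean(axis=0)])) < arr.shape[1]:
        raise ValueError("rank-deficient covariate matrix (collinear columns)")
    surv = survival.align(X.index)
    frame = X.assign(time=surv.time, event=surv.event)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")  # Efron ties
    s = cph.summary
    table = pd.DataFrame({
        "coef": s["coef"],
        "hr": np.exp(s["coef"]),
        "ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
        "ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        "p": s["p"],
    })
    table.index.name = "covariate"
    return CoxResult(table=table, reference_levels=dict(REFERENCE_LEVELS),
                     n=int(frame.shape[0]), n_events=int(surv.event.sum()))


def time_dependent_auc(scores: pd.DataFrame | pd.Series, survival: SurvivalTable,
                       times) -> TimedAUC:
    """Cumulative/dynamic AUC(t) with KM-based censoring weights.

    Cases at horizon t are subjects with an observed event at or before t,
    controls those still under observation beyond t; censoring is handled
    by inverse-probability-of-censoring weights estimated from the KM
    curve of the censoring distribution.  With no censoring this is the
    Mann-Whitney statistic of the score for cases vs controls.  Horizons
    with no cases or no controls report NaN.
    """
    s = scores["score"] if isinstance(scores, pd.DataFrame) else pd.Series(scores)
    s = s.reindex(survival.sample_ids).to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    y = Surv.from_arrays(event=survival.event.astype(bool), time=survival.time)
    auc = np.full(len(times), np.nan)
    t_obs, e_obs = survival.time, survival.event
    for i, t in enumerate(times):
        has_cases = bool(((t_obs <= t) & (e_obs == 1)).any())
        has_controls = bool((t_obs > t).any())
        if not (has_cases and has_controls):
            continue
        try:
            a, _ = cumulative_dynamic_auc(y, y, s, [t])
            auc[i] = float(a[0])
        except ValueError:
            pass  # horizon outside the estimable follow-up window
    return TimedAUC(times=times, auc=auc)


def compare_auc(scores_a, scores_b, survival: SurvivalTable, times,
                n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Paired-bootstrap test for AUC_A(t) - AUC_B(t) at each horizon.

    Patients are resampled with replacement; both scores are re-evaluated
    on each resample, and a two-sided p-value comes from the bootstrap
    distribution of the difference (add-one smoothing).  An approximation
    to analytic AUC-comparison tests.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a very coarse bootstrap p-value")
    a = (scores_a["score"] if isinstance(scores_a, pd.DataFrame) else pd.Series(scores_a))
    b = (scores_b["score"] if isinstance(scores_b, pd.DataFrame) else pd.Series(scores_b))
    a = a.reindex(survival.sample_ids).to_numpy(dtype=float)
    b = b.reindex(survival.sample_ids).to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    base_a = time_dependent_auc(pd.Series(a, index=survival.sample_ids), survival, times).auc
    base_b = time_dependent_auc(pd.Series(b, index=survival.sample_ids), survival, times).auc
    observed = base_a - base_b
    rng = np.random.default_rng(seed)
    n = len(survival)
    diffs = np.full((n_boot, len(times)), np.nan)
    for bi in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot_ids = [f"r{i}" for i in range(n)]
        surv_b = SurvivalTable(survival.data.iloc[idx].set_axis(boot_ids),
                               time_unit=survival.time_unit)
        sa = pd.Series(a[idx], index=boot_ids)
        sb = pd.Series(b[idx], index=boot_ids)
        diffs[bi] = (time_dependent_auc(sa, surv_b, times).auc
                     - time_dependent_auc(sb, surv_b, times).auc)
    pvals = np.full(len(times), np.nan)
    for i in range(len(times)):
        d = diffs[:, i]
        d = d[~np.isnan(d)]
        if len(d) == 0 or np.isnan(observed[i]):
            continue
        lo = float((np.sum(d <= 0) + 1) / (len(d) + 1))
        hi = float((np.sum(d >= 0) + 1) / (len(d) + 1))
        pvals[i] = min(1.0, 2.0 * min(lo, hi))
    return pd.DataFrame({"time": times, "auc_a": base_a, "auc_b": base_b,
                         "difference": observed, "p": pvals}).set_index("time")
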