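"""Prognostic-score modelling: stability-selected LASSO Cox on cell-type fractions.

The scoring model is a sparse linear combination of deconvoluted cell-type
fractions whose weights come from L1-penalized Cox regression of overall
survival on the fractions.  Because a single lasso fit is unstable in the
small-p, correlated-fraction setting, the procedure is repeated (default
100 times) with re-randomised 10-fold cross-validation choosing the
penalty each round; cell types whose coefficient is exactly zero in more
than ``zero_limit`` (default 5) rounds are discarded, and the final weight
of each surviving cell type is the mean of its per-round coefficients.

Two entry points:

* :class:`LassoCoxModel` — one dataset, methods for a single penalized fit,
  the coefficient path and cross-validated penalty selection.
* :class:`StabilityLassoCox` — the full repeated procedure; ``fit()``
  returns a :class:`ScoreModel` results object with coefficients,
  zero-counts, the per-iteration record and a ``summary()`` table.

:data:`PUBLISHED_COEFFICIENTS` carries the published five-cell-type score
(GMP -2.15, CMP -1.64, RApos +0.37, MEP +0.49, MPP +4.52); scoring a
sample is the dot product of those weights with its fraction vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _coxnet
from .deconv import FractionMatrix
from .io import SurvivalTable

__all__ = [
    "PUBLISHED_COEFFICIENTS",
    "published_model",
    "LassoCoxFit",
    "ScoreModel",
    "ScoreTable",
    "LassoCoxModel",
    "StabilityLassoCox",
    "aggregate_stability",
    "fit_lasso_cox",
    "cv_select_lambda",
    "stability_select",
    "compute_score",
    "split_by_threshold",
]

#: Published score weights over deconvoluted fractions:
#: score = -2.15 F_GMP - 1.64 F_CMP + 0.37 F_RApos + 0.49 F_MEP + 4.52 F_MPP
PUBLISHED_COEFFICIENTS = {
    "GMP": -2.15,
    "CMP": -1.64,
    "RApos": 0.37,
    "MEP": 0.49,
    "MPP": 4.52,
}

ScoreTable = pd.DataFrame  # index: sample_id; columns: score [, group]


@dataclass
class LassoCoxFit:
    """One cross-validated lasso Cox fit."""

    lambda_grid: np.ndarray
    cv_deviance: np.ndarray
    lambda_min: float
    coefficients: pd.Series

    def __post_init__(self) -> None:
        assert self.lambda_min in self.lambda_grid


@dataclass
class ScoreModel:
    """Results of stability selection: the final score coefficients.

    ``coefficients`` holds retained cell types only; ``zero_counts`` and
    ``per_iteration_coefficients`` keep the full provenance.
    """

    coefficients: dict[str, float]
    zero_counts: dict[str, int] = field(default_factory=dict)
    per_iteration_coefficients: pd.DataFrame | None = None
    n_iterations: int = 0
    zero_limit: int = 5
    name: str = "custom"

    def summary(self) -> pd.DataFrame:
        """Per-cell-type table: final coefficient, zero count, retention."""
        cts = list(self.zero_counts) or list(self.coefficients)
        rows = []
        for ct in cts:
            retained = ct in self.coefficients
            row = {
                "cell_type": ct,
                "coefficient": self.coefficients.get(ct, np.nan),
                "zero_count": self.zero_counts.get(ct, np.nan),
                "retained": retained,
            }
            if self.per_iteration_coefficients is not None and ct in self.per_iteration_coefficients:
                row["coef_sd"] = float(self.per_iteration_coefficients[ct].std(ddof=1))
            rows.append(row)
        return pd.DataFrame(rows).set_index("cell_type")

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "coefficients": self.coefficients,
            "zero_counts": self.zero_counts,
            "n_iterations": self.n_iterations,
            "zero_limit": self.zero_limit,
        }
        if self.per_iteration_coefficients is not None:
            payload["per_iteration_coefficients"] = {
                c: self.per_iteration_coefficients[c].tolist()
                for c in self.per_iteration_coefficients.columns
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            payload = json.load(fh)
        per_iter = payload.get("per_iteration_coefficients")
        return cls(
            coefficients=dict(payload["coefficients"]),
            zero_counts=dict(payload.get("zero_counts", {})),
            per_iteration_coefficients=pd.DataFrame(per_iter) if per_iter else None,
            n_iterations=int(payload.get("n_iterations", 0)),
            zero_limit=int(payload.get("zero_limit", 5)),
            name=payload.get("name", "custom"),
        )


def published_model() -> ScoreModel:
    """The packaged published coefficient vector as a ready-to-use model."""
    return ScoreModel(coefficients=dict(PUBLISHED_COEFFICIENTS), name="lsca-published")


def _align(X, survival: SurvivalTable) -> tuple[pd.DataFrame, SurvivalTable]:
    Xdf = X.values if isinstance(X, FractionMatrix) else pd.DataFrame(X)
    surv = survival.align(Xdf.index)
    return Xdf, surv


class LassoCoxModel:
    """L1-penalized Cox proportional-hazards model on one dataset.

    Parameters
    ----------
    X : FractionMatrix or DataFrame
        Samples x features design (cell-type fractions share the [0, 1]
        scale, so features enter unstandardized by default).
    survival : SurvivalTable
        Time-to-event outcomes, aligned on the design's sample ids.
    """

    def __init__(self, X, survival: SurvivalTable, standardize: bool = False):
        self.X, self.survival = _align(X, survival)
        self.feature_names = list(self.X.columns)
        arr = self.X.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite values in the design matrix")
        if self.survival.event.sum() < 1:
            raise ValueError("no observed events")
        self._mu = arr.mean(axis=0) if standardize else np.zeros(arr.shape[1])
        sd = arr.std(axis=0, ddof=0)
        self._sd = np.where(sd > 0, sd, 1.0) if standardize else np.ones(arr.shape[1])
        self._arr = (arr - self._mu) / self._sd
        self.standardize = standardize

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_cols: list[str],
                       time_col: str = "time", event_col: str = "event", **kw):
        surv = SurvivalTable(df[[time_col, event_col]]
                             .rename(columns={time_col: "time", event_col: "event"}))
        return cls(df[feature_cols], surv, **kw)

    @property
    def lambda_max(self) -> float:
        return _coxnet.lambda_max(self._arr, self.survival.time, self.survival.event)

    def fit(self, lam: float, objective_trace: list | None = None) -> pd.Series:
        """Coefficients at one penalty value (original feature scale)."""
        beta = _coxnet.fit_penalized_cox(
            self._arr, self.survival.time, self.survival.event, lam,
            objective_trace=objective_trace,
        )
        return pd.Series(beta / self._sd, index=self.feature_names, name="coef")

    def fit_path(self, lambdas=None, n_lambda: int = 100,
                 lambda_min_ratio: float | None = None):
        lambdas, betas = _coxnet.fit_path(
            self._arr, self.survival.time, self.survival.event,
            lambdas=lambdas, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
        )
        return lambdas, pd.DataFrame(betas / self._sd, columns=self.feature_names)

    def _fold_assignment(self, n_folds: int, rng: np.random.Generator,
                         max_retries: int = 20) -> np.ndarray:
        """Random folds with at least one event per held-out and training part."""
        n = len(self.survival)
        if n_folds > n:
            raise ValueError("more folds than samples")
        event = self.survival.event
        for _ in range(max_retries):
            folds = rng.permutation(np.arange(n) % n_folds)
            ok = all(event[folds != k].sum() >= 1 and event[folds == k].sum() >= 1
                     for k in range(n_folds))
            if ok:
                return folds
        raise RuntimeError(
            f"could not build {n_folds} folds with events in every fold; try fewer folds"
        )

    def fit_cv(self, n_folds: int = 10, n_lambda: int = 100,
               lambda_min_ratio: float | None = None, seed: int = 0) -> LassoCoxFit:
        """Select the penalty by K-fold cross-validated partial-likelihood deviance.

        The held-out deviance of fold k uses the difference between the
        full-data and training-data partial log-likelihoods at the
        training-fold coefficients (the cross-validated partial-likelihood
        construction), which stays well-defined for small held-out risk sets.
        The grid is the full-data path truncated by the fractional-deviance
        stopping rule, so near-saturated penalties are never candidates.
        """
        rng = np.random.default_rng(seed)
        folds = self._fold_assignment(n_folds, rng)
        time, event = self.survival.time, self.survival.event
        grid, betas_full = _coxnet.fit_path(self._arr, time, event,
                                            n_lambda=n_lambda,
                                            lambda_min_ratio=lambda_min_ratio)
        keep = _coxnet.truncate_path(grid, betas_full, self._arr, time, event)
        grid = grid[:keep]
        cv_dev = np.zeros(len(grid))
        sc_full = _coxnet._SortedCox(time, event)
        X_full_sorted = self._arr[sc_full.order]
        for k in range(n_folds):
            train = folds != k
            _, betas = _coxnet.fit_path(self._arr[train], time[train], event[train],
                                        lambdas=grid)
            sc_tr = _coxnet._SortedCox(time[train], event[train])
            X_tr_sorted = self._arr[train][sc_tr.order]
            ll_full = sc_full.pll_many(betas @ X_full_sorted.T)
            ll_train = sc_tr.pll_many(betas @ X_tr_sorted.T)
            cv_dev += -2.0 * (ll_full - ll_train)
        cv_dev /= n_folds
        i_min = int(np.argmin(cv_dev))
        lam_min = float(grid[i_min])
        # report the warm-started full-data path solution at lambda_min
        # (a cold restart can flip borderline-zero coefficients)
        coef = pd.Series(betas_full[i_min] / self._sd, index=self.feature_names,
                         name="coef")
        return LassoCoxFit(lambda_grid=grid, cv_deviance=cv_dev,
                           lambda_min=lam_min, coefficients=coef)


class StabilityLassoCox:
    """Repeated cross-validated lasso Cox with zero-count filtering.

    ``fit(seed)`` runs ``n_iter`` rounds of penalty selection, each on a
    bootstrap resample of the patients with freshly randomised folds
    (``resample=False`` keeps the original patients and re-randomises
    folds only; with fixed data the rounds are nearly perfectly correlated,
    which defeats the zero-count filter).  It records the coefficient
    vector at each round's best penalty, drops features that were exactly
    zero in more than ``zero_limit`` rounds (strict inequality), and
    averages each retained feature's coefficients over all rounds.
    """

    def __init__(self, X, survival: SurvivalTable, n_iter: int = 100,
                 zero_limit: int = 5, n_folds: int = 10, n_lambda: int = 100,
                 resample: bool = True, standardize: bool = False):
        self.X = X.values if isinstance(X, FractionMatrix) else pd.DataFrame(X)
        self.survival = survival.align(self.X.index)
        self.n_iter = n_iter
        self.zero_limit = zero_limit
        self.n_folds = n_folds
        self.n_lambda = n_lambda
        self.resample = resample
        self.standardize = standardize

    def fit(self, seed: int = 0) -> ScoreModel:
        rng = np.random.default_rng(seed)
        records = []
        n = len(self.X)
        for _ in range(self.n_iter):
            iter_seed = int(rng.integers(0, 2**31 - 1))
            if self.resample:
                idx = np.random.default_rng(iter_seed).integers(0, n, size=n)
                Xb = self.X.iloc[idx].set_axis([f"b{i}" for i in range(n)])
                sb = SurvivalTable(
                    self.survival.data.iloc[idx].set_axis([f"b{i}" for i in range(n)]),
                    time_unit=self.survival.time_unit,
                )
                model = LassoCoxModel(Xb, sb, standardize=self.standardize)
            else:
                model = LassoCoxModel(self.X, self.survival, standardize=self.standardize)
            fit = model.fit_cv(n_folds=self.n_folds, n_lambda=self.n_lambda,
                               seed=iter_seed)
            records.append(fit.coefficients)
        per_iter = pd.DataFrame(records).reset_index(drop=True)
        return aggregate_stability(per_iter, self.zero_limit)


def aggregate_stability(per_iter: pd.DataFrame, zero_limit: int = 5,
                        mean_over: str = "all") -> ScoreModel:
    """Zero-count filter + coefficient averaging over the iteration record.

    Features with exact zeros in strictly more than ``zero_limit`` rounds
    are dropped (a feature zero in exactly ``zero_limit`` rounds stays).
    ``mean_over='all'`` averages a retained feature over every round,
    zeros included (the literal reading); ``'nonzero'`` averages only the
    rounds where it was selected.
    """
    zero_counts = {c: int((per_iter[c] == 0.0).sum()) for c in per_iter.columns}
    retained = [c for c in per_iter.columns if zero_counts[c] <= zero_limit]
    if not retained:
        raise RuntimeError(f"all features filtered out; zero counts: {zero_counts}")
    if mean_over == "all":
        coefficients = {c: float(per_iter[c].mean()) for c in retained}
    elif mean_over == "nonzero":
        coefficients = {c: float(per_iter.loc[per_iter[c] != 0.0, c].mean())
                        for c in retained}
    else:
        raise ValueError("mean_over must be 'all' or 'nonzero'")
    return ScoreModel(
        coefficients=coefficients,
        zero_counts=zero_counts,
        per_iteration_coefficients=per_iter,
        n_iterations=len(per_iter),
        zero_limit=zero_limit,
    )


# ---------------------------------------------------------------------------
# functional wrappers

def fit_lasso_cox(X, survival: SurvivalTable, lam: float, **kw) -> pd.Series:
    """Named coefficients of a single penalized Cox fit at penalty ``lam``."""
    return LassoCoxModel(X, survival, **kw).fit(lam)


def cv_select_lambda(X, survival: SurvivalTable, n_folds: int = 10,
                     n_lambda: int = 100, seed: int = 0, **kw) -> LassoCoxFit:
    """Cross-validated penalty selection; see :meth:`LassoCoxModel.fit_cv`."""
    return LassoCoxModel(X, survival, **kw).fit_cv(n_folds=n_folds,
                                                   n_lambda=n_lambda, seed=seed)


def stability_select(X, survival: SurvivalTable, n_iter: int = 100,
                     zero_limit: int = 5, n_folds: int = 10, seed: int = 0,
                     **kw) -> ScoreModel:
    """Run the full repeated-selection procedure; see :class:`StabilityLassoCox`."""
    return StabilityLassoCox(X, survival, n_iter=n_iter, zero_limit=zero_limit,
                             n_folds=n_folds, **kw).fit(seed=seed)


def compute_score(model: ScoreModel, fractions: FractionMatrix) -> ScoreTable:
    """Per-sample score: sum over model cell types of coefficient x fraction."""
    missing = set(model.coefficients) - set(fractions.cell_types)
    if missing:
        raise ValueError(f"model cell types absent from fractions: {sorted(missing)}")
    F = fractions.values
    score = sum(beta * F[ct].to_numpy(dtype=float)
                for ct, beta in model.coefficients.items())
    return pd.DataFrame({"score": score}, index=fractions.sample_ids)


def split_by_threshold(scores: ScoreTable, method: str = "median") -> ScoreTable:
    """Split samples into high (> threshold) and low (<= threshold) groups.

    ``method`` picks the threshold as the median (default for composite
    scores) or mean (used for single-cell-type abundance splits, which
    often have a zero median).
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to split")
    s = scores["score"].to_numpy(dtype=float)
    if np.all(s == s[0]):
        raise ValueError("all scores identical; no split possible")
    if method == "median":
        threshold = float(np.median(s))
    elif method == "mean":
        threshold = float(np.mean(s))
    else:
        raise ValueError("method must be 'median' or 'mean'")
    out = scores.copy()
    out["group"] = np.where(s > threshold, "high", "low")
    out.attrs["threshold"] = threshold
    out.attrs["n_high"] = int((out["group"] == "high").sum())
    out.attrs["n_low"] = int((out["group"] == "low").sum())
    return out
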