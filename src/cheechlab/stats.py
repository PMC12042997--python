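"""Regression inference layer.

Standardized OLS with diagnostics (VIF, Cook's distance), all-subsets
dominance analysis with general dominance weights, leave-one-out
cross-validation, paired t tests, and reliability coefficients
(Cronbach's α, KR20, ICC, Pearson matrices).

Ordinary least-squares fits are delegated to statsmodels; dominance
analysis, LOOCV, and the reliability closed forms are implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import (
    OLSInfluence,
    variance_inflation_factor,
)

COOKS_DISTANCE_THRESHOLD = 0.5
VIF_CONCERN_THRESHOLD = 5.0


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


def zscore(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """z-standardize with population SD (cohort mean 0, SD 1 exactly)."""
    a = np.asarray(a, dtype=float)
    return (a - a.mean(axis=axis, keepdims=True)) / a.std(axis=axis, keepdims=True)


@dataclass
class RegressionFit:
    """A fitted (optionally standardized) multiple regression."""

    predictor_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    intercept: float
    intercept_se: float
    r2: float
    adj_r2: float
    residuals: np.ndarray
    hat_diag: np.ndarray
    n: int
    p_predictors: int
    standardized: bool
    _sm_results: object = field(default=None, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.coef,
                "se": self.se,
                "t": self.tvalues,
                "p": self.pvalues,
            },
            index=self.predictor_names,
        )


def fit_ols(X, y, standardize: bool = True) -> RegressionFit:
    """Closed-form least squares of ``y`` on ``X`` with an intercept.

    With ``standardize=True`` all variables are z-scored first, so the
    coefficients are standardized betas and the intercept is numerically
    zero.  Rank-deficient design matrices are rejected, naming the
    collinear columns.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(Xm) < p:
        r = np.linalg.qr(Xm, mode="r")
        bad = [names[j] for j in range(p) if abs(r[j, j]) < 1e-10 * abs(r[0, 0])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    if standardize:
        Xm = zscore(Xm)
        yv = zscore(yv)

    model = sm.OLS(yv, sm.add_constant(Xm)).fit()
    infl = OLSInfluence(model)
    return RegressionFit(
        predictor_names=names,
        coef=model.params[1:],
        se=model.bse[1:],
        tvalues=model.tvalues[1:],
        pvalues=model.pvalues[1:],
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        residuals=np.asarray(model.resid),
        hat_diag=np.asarray(infl.hat_matrix_diag),
        n=n,
        p_predictors=p,
        standardized=standardize,
        _sm_results=model,
    )


@dataclass
class DiagnosticsReport:
    vif: dict[str, float]
    cooks_distance: np.ndarray
    flagged_observations: list[int]
    max_vif: float

    @property
    def collinearity_concern(self) -> bool:
        return self.max_vif > VIF_CONCERN_THRESHOLD


def diagnostics(fit: RegressionFit, X) -> DiagnosticsReport:
    """VIFs (1/(1−R²_j) of predictor j on the rest) and Cook's distances,
    flagging observations with D above the 0.5 influence threshold."""
    Xm, names = _as_matrix(X)
    Xc = sm.add_constant(zscore(Xm) if fit.standardized else Xm)
    vif = {
        name: float(variance_inflation_factor(Xc, j + 1))
        for j, name in enumerate(names)
    }
    cooks = np.asarray(OLSInfluence(fit._sm_results).cooks_distance[0])
    flagged = [int(i) for i in np.flatnonzero(cooks > COOKS_DISTANCE_THRESHOLD)]
    return DiagnosticsReport(vif, cooks, flagged, max(vif.values()))


# ---------------------------------------------------------------------------
# Dominance analysis


def _subset_r2(X: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    """R² of the OLS of y on the given predictor columns (with intercept).

    Rank-deficient subsets fall back to the attained span via lstsq.
    """
    if not cols:
        return 0.0
    A = np.column_stack([np.ones(len(y)), X[:, cols]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / sst


@dataclass
class DominanceResult:
    """General dominance weights and the size-conditional ΔR² table.

    The GDWs sum exactly to the full-model R²; individual weights can be
    negative under suppression and are not constrained.
    """

    predictor_names: list[str]
    gdw: dict[str, float]
    conditional: pd.DataFrame  # rows: subset size, cols: predictors
    full_r2: float


def dominance_analysis(X, y) -> DominanceResult:
    """All-subsets dominance analysis.

    For every predictor j and every subset S not containing j (including
    the empty model), the incremental ΔR²(S, j) = R²(S ∪ {j}) − R²(S) is
    computed; increments are averaged within each subset size and the p
    size-averages are averaged into the general dominance weight.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    p = Xm.shape[1]
    if p > 15:
        raise ValueError(f"{p} predictors require 2^{p} subset fits; limit is 15")

    r2_cache: dict[tuple[int, ...], float] = {}
    for size in range(p + 1):
        for cols in itertools.combinations(range(p), size):
            r2_cache[cols] = _subset_r2(Xm, yv, cols)

    conditional = np.zeros((p, p))  # [size of S, predictor]
    counts = np.zeros((p, p))
    for cols, r2 in r2_cache.items():
        for j in range(p):
            if j in cols:
                continue
            with_j = tuple(sorted(cols + (j,)))
            conditional[len(cols), j] += r2_cache[with_j] - r2
            counts[len(cols), j] += 1
    conditional /= counts
    gdw_values = conditional.mean(axis=0)

    full = r2_cache[tuple(range(p))]
    cond_df = pd.DataFrame(
        conditional, columns=names, index=pd.Index(range(p), name="subset_size")
    )
    return DominanceResult(
        predictor_names=names,
        gdw={name: float(g) for name, g in zip(names, gdw_values)},
        conditional=cond_df,
        full_r2=full,
    )


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class LoocvResult:
    rmse: float
    predictions: np.ndarray
    errors: np.ndarray


def loocv_rmse(X, y, standardize: bool = True) -> LoocvResult:
    """Leave-one-out cross-validation by explicit refitting.

    Each observation is predicted from a model fitted to the other n − 1;
    the RMSE of the held-out errors summarizes predictive accuracy.  For a
    linear model this equals the PRESS closed form e_i/(1 − h_ii), which
    the test suite uses as an independent identity check.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 for leave-one-out fits (n={n}, p={p})")
    if standardize:
        Xm = zscore(Xm)
        yv = zscore(yv)

    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        A = np.column_stack([np.ones(n - 1), Xm[mask]])
        if np.linalg.matrix_rank(A) < p + 1:
            raise ValueError(f"leave-one-out design dropping row {i} is rank deficient")
        coef, *_ = np.linalg.lstsq(A, yv[mask], rcond=None)
        preds[i] = np.concatenate([[1.0], Xm[i]]) @ coef
    errors = yv - preds
    return LoocvResult(float(np.sqrt(np.mean(errors**2))), preds, errors)


# ---------------------------------------------------------------------------
# Paired tests


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float
    flags: tuple[str, ...] = ()


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> PairedTResult:
    """Paired t from summary statistics: t = d̄/(s_d/√n), df = n − 1."""
    if n < 2:
        raise ValueError("need n >= 2")
    flags = ()
    if sd_diff == 0:
        return PairedTResult(np.inf, n - 1, 0.0, mean_diff, sd_diff, ("zero-variance differences",))
    t = mean_diff / (sd_diff / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return PairedTResult(float(t), n - 1, float(p), mean_diff, sd_diff, flags)


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired t test on equal-length samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D samples")
    d = a - b
    return paired_t_from_summary(float(d.mean()), float(d.std(ddof=1)), len(d))


# ---------------------------------------------------------------------------
# Reliability


@dataclass
class ReliabilityResult:
    kind: str
    value: float
    detail: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def reliability(data, kind: str) -> ReliabilityResult:
    """Internal-consistency and agreement coefficients.

    ``data`` is subjects × items (or subjects × raters/stories for the
    ICC).  Kinds:

    * ``alpha`` — Cronbach's α = k/(k−1) · (1 − Σσ²_i / σ²_total);
    * ``kr20`` — the dichotomous-item analog using item pass rates;
    * ``icc_consistency`` — two-way random, single-measure consistency
      ICC(C,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E);
    * ``icc_agreement`` — absolute-agreement ICC(A,1), which additionally
      penalizes rater/story mean offsets;
    * ``pearson`` — pairwise correlation matrix with two-sided p-values.
    """
    M = np.asarray(data, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("data must be subjects × items with at least 2 of each")
    n, k = M.shape
    flags: list[str] = []

    if kind == "alpha":
        total_var = M.sum(axis=1).var(ddof=1)
        if total_var == 0:
            raise ValueError("zero total-score variance; alpha undefined")
        item_var = M.var(axis=0, ddof=1).sum()
        value = k / (k - 1) * (1 - item_var / total_var)
        return ReliabilityResult(kind, float(value), {"n": n, "k": k}, flags)

    if kind == "kr20":
        if not np.isin(M, (0, 1)).all():
            raise ValueError("KR20 requires dichotomous (0/1) items")
        total_var = M.sum(axis=1).var(ddof=1)
        if total_var == 0:
            raise ValueError("zero total-score variance; KR20 undefined")
        pq = (M.mean(axis=0) * (1 - M.mean(axis=0))).sum()
        value = k / (k - 1) * (1 - pq / total_var)
        return ReliabilityResult(kind, float(value), {"n": n, "k": k}, flags)

    if kind in ("icc_consistency", "icc_agreement"):
        grand = M.mean()
        ms_rows = k * ((M.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((M.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        resid = M - M.mean(axis=1, keepdims=True) - M.mean(axis=0, keepdims=True) + grand
        ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
        if ms_rows == 0 and ms_err == 0:
            raise ValueError("degenerate data; ICC undefined")
        if kind == "icc_consistency":
            value = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        else:
            value = (ms_rows - ms_err) / (
                ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
            )
        return ReliabilityResult(
            kind,
            float(value),
            {"ms_rows": ms_rows, "ms_cols": ms_cols, "ms_err": ms_err, "n": n, "k": k},
            flags,
        )

    if kind == "pearson":
        r = np.eye(k)
        p = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                ri, pi = sps.pearsonr(M[:, i], M[:, j])
                r[i, j] = r[j, i] = ri
                p[i, j] = p[j, i] = pi
        return ReliabilityResult(kind, float("nan"), {"r": r, "p": p}, flags)

    raise ValueError(f"unknown reliability kind {kind!r}")
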