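"""Robust standardized dose-response estimation: AUC and IC50 per
sample x drug.

The estimation pipeline mirrors an ex-vivo viability screen read-out:

1. *Standardize* raw viability signal by the median of the plate's
   control wells, so untreated viability sits at 1.
2. *Flag outliers* with a degree-4 polynomial robust regression in log
   dose (IRLS with a redescending bisquare psi-function and a
   high-breakdown MAD scale); wells with robust weight < 0.4 are outliers.
3. *Fit* the standardized response as a function of log dose on an
   M-spline (non-negative) basis by least squares; an optional
   monotone-decreasing constraint fits on the integrated I-spline basis
   with sign-constrained coefficients.
4. *AUC* is the exact integral of the fitted curve over the observed log
   dose range (the I-spline antiderivative in closed form) divided by the
   range, so a constant curve at 1 has AUC 1.  *IC50* is the lowest dose
   at which the fitted curve crosses 0.5; if viability stays above 0.5 on
   the whole range the IC50 is censored.
5. A five-parameter log-logistic (5PL) fit serves as a cross-check.

Doses are handled on the natural-log scale internally; the normalized AUC
is invariant to the log base.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.cluster import hierarchy
from scipy.interpolate import BSpline
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: wells with robust regression weight below this are outliers
OUTLIER_WEIGHT_THRESHOLD: float = 0.4
#: standardized-viability level defining the IC50
IC50_LEVEL: float = 0.5
#: bisquare tuning constant (95% Gaussian efficiency)
BISQUARE_C: float = 4.685
#: spline order (4 = cubic)
SPLINE_ORDER: int = 4


# -- containers ---------------------------------------------------------------

@dataclass
class DosePlate:
    """One sample x drug plate: control wells plus a dose series.

    ``wells``: DataFrame with columns dose (molar; 0 or NaN for control),
    replicate, signal, is_control.
    """

    sample_id: str
    drug_id: str
    wells: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.wells
        if not w["is_control"].any():
            raise ValueError("plate has no control wells")
        doses = w.loc[~w["is_control"], "dose"]
        if doses.nunique() < 4:
            raise ValueError(
                f"need >=4 distinct positive doses, got {doses.nunique()}")
        if (doses <= 0).any():
            raise ValueError("test-well doses must be positive")
        if (w["signal"] < 0).any():
            raise ValueError("raw signal must be non-negative")


@dataclass
class MSplineFit:
    """Least-squares M-spline fit of standardized response vs log dose."""

    knots: np.ndarray          # full knot vector
    coefficients: np.ndarray   # B-spline coefficients of the fitted curve
    domain: tuple              # (log_dose_min, log_dose_max)
    monotone: bool = False
    _spline: BSpline = field(repr=False, default=None)

    def __call__(self, log_dose):
        x = np.clip(np.asarray(log_dose, dtype=float),
                    self.domain[0], self.domain[1])
        return self._spline(x)

    def integral(self) -> float:
        """Exact integral over the domain via the spline antiderivative
        (equivalently, the I-spline representation of the fit)."""
        anti = self._spline.antiderivative()
        return float(anti(self.domain[1]) - anti(self.domain[0]))


@dataclass
class DoseResponseResult:
    sample_id: str
    drug_id: str
    standardized: pd.DataFrame        # wells with 'response' column added
    outlier_flags: np.ndarray         # over non-control wells
    robust_weights: np.ndarray        # over non-control wells
    fit: MSplineFit | None
    auc: float
    ic50: float                       # molar; NaN when censored
    ic50_censored: bool
    diagnostics: dict = field(default_factory=dict)


# -- standardization ----------------------------------------------------------

def standardize(plate: DosePlate) -> pd.DataFrame:
    """Divide every well's raw signal by the median control signal.

    Returns a copy of the well table with a ``response`` column; control
    wells thus have median response exactly 1.  A non-positive control
    median rejects the plate.
    """
    wells = plate.wells.copy()
    control_median = wells.loc[wells["is_control"], "signal"].median()
    if not np.isfinite(control_median) or control_median <= 0:
        raise ValueError(
            f"control median must be positive, got {control_median}")
    wells["response"] = wells["signal"] / control_median
    return wells


# -- robust outlier flagging --------------------------------------------------

def flag_outliers(log_doses: np.ndarray, responses: np.ndarray,
                  weight_threshold: float = OUTLIER_WEIGHT_THRESHOLD,
                  c: float = BISQUARE_C,
                  scale_est: str = "huber") -> tuple[np.ndarray, np.ndarray]:
    """Robust weights and outlier flags from a degree-4 polynomial fit.

    Fits response ~ poly(log dose, 4) by iteratively reweighted least
    squares with Tukey's redescending bisquare psi.  The residual scale
    is Huber's proposal-2 estimate by default (``scale_est='huber'``);
    the iterated normalized-MAD alternative (``'mad'``) is available but
    under-estimates the scale on heteroscedastic plates once the
    redescending weights kick in, inflating false flags.  Returns
    ``(weights, flags)`` with weights in [0, 1]; a well is flagged iff
    its weight falls below ``weight_threshold``.  Non-convergence falls
    back to a pass-through (all weights 1, nothing flagged) with a
    logged warning.
    """
    x = np.asarray(log_doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) < 6:
        raise ValueError("need >=6 wells for a degree-4 robust fit")
    # centre/scale the predictor for conditioning of the Vandermonde matrix
    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    X = np.vander(xs, N=5, increasing=True)
    # perfectly (or near) collinear responses: zero residual scale, keep all
    ols_resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    mad = np.median(np.abs(ols_resid - np.median(ols_resid)))
    if mad < 1e-10 * max(1.0, np.abs(y).max()):
        return np.ones_like(y), np.zeros(len(y), dtype=bool)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=c))
            scale = (sm.robust.scale.HuberScale() if scale_est == "huber"
                     else "mad")
            res = rlm.fit(scale_est=scale, maxiter=200)
        weights = np.clip(np.asarray(res.weights), 0.0, 1.0)
        if not np.all(np.isfinite(weights)):
            raise ValueError("non-finite robust weights")
    except Exception as exc:  # non-convergence / numerical failure
        logger.warning("robust fit failed (%s); no outliers flagged", exc)
        return np.ones_like(y), np.zeros(len(y), dtype=bool)
    return weights, weights < weight_threshold


# -- M-spline fit -------------------------------------------------------------

def _knot_vector(log_doses: np.ndarray, order: int = SPLINE_ORDER) -> np.ndarray:
    """Clamped knot vector with interior knots at quantiles of the
    observed log doses; interior count = max(1, n_distinct - order)."""
    distinct = np.unique(log_doses)
    a, b = distinct[0], distinct[-1]
    n_interior = max(1, len(distinct) - order)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(distinct, qs)
    return np.concatenate([[a] * order, interior, [b] * order])


def _mspline_design(x: np.ndarray, t: np.ndarray,
                    order: int = SPLINE_ORDER) -> np.ndarray:
    """M-spline design matrix: B-splines rescaled to integrate to one,
    M_i(x) = order / (t[i+order] - t[i]) * B_i(x)."""
    k = order - 1
    n_basis = len(t) - order
    X = BSpline.design_matrix(x, t, k, extrapolate=False).toarray()
    scale = order / (t[order:order + n_basis] - t[:n_basis])
    return X * scale


def fit_monotone_spline(log_doses: np.ndarray, responses: np.ndarray,
                        monotone: bool = False,
                        order: int = SPLINE_ORDER) -> MSplineFit:
    """Least-squares fit on the M-spline basis over the observed range.

    With ``monotone=True`` the curve is written as
    ``c0 + sum_i a_i I_i(x)`` with I-splines (integrals of M-splines) and
    coefficients constrained ``a_i <= 0`` — a monotone non-increasing fit.
    The default is unconstrained.
    """
    x = np.asarray(log_doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    distinct = np.unique(x)
    if len(distinct) < 4:
        raise ValueError(
            f"need >=4 distinct doses after outlier removal, got {len(distinct)}")
    t = _knot_vector(x, order)
    a, b = t[0], t[-1]
    xc = np.clip(x, a, b)
    n_basis = len(t) - order
    scale = order / (t[order:order + n_basis] - t[:n_basis])

    if not monotone:
        M = _mspline_design(xc, t, order)
        coef_m, *_ = np.linalg.lstsq(M, y, rcond=None)
        bspl = BSpline(t, coef_m * scale, order - 1)
    else:
        # I-spline columns: antiderivatives of the M-spline basis members
        cols = []
        for i in range(n_basis):
            e = np.zeros(n_basis)
            e[i] = scale[i]
            cols.append(BSpline(t, e, order - 1).antiderivative()(xc)
                        - BSpline(t, e, order - 1).antiderivative()(a))
        D = np.column_stack([np.ones_like(xc)] + cols)
        lb = np.r_[-np.inf, np.full(n_basis, -np.inf)]
        ub = np.r_[np.inf, np.zeros(n_basis)]
        sol = optimize.lsq_linear(D, y, bounds=(lb, ub))
        c0, acoef = sol.x[0], sol.x[1:]
        # curve = c0 + sum a_i I_i ; represent as derivative-integrated spline
        deriv = BSpline(t, acoef * scale, order - 1)
        anti = deriv.antiderivative()
        const = c0 - float(anti(a))
        bspl = BSpline(anti.t, anti.c + const, anti.k)
    fit = MSplineFit(knots=t, coefficients=bspl.c, domain=(float(a), float(b)),
                     monotone=monotone, _spline=bspl)
    return fit


# -- AUC / IC50 ---------------------------------------------------------------

def auc(fit: MSplineFit) -> float:
    """Normalized area under the fitted curve: the exact I-spline
    integral divided by the log-dose range (constant 1 -> AUC 1)."""
    a, b = fit.domain
    return fit.integral() / (b - a)


def ic50(fit: MSplineFit, level: float = IC50_LEVEL,
         n_grid: int = 512) -> tuple[float, bool]:
    """Lowest dose (molar) where the fitted curve crosses ``level``.

    Returns ``(dose, censored)``.  Censored (NaN dose) when the fitted
    viability stays above the level across the whole dose range.  The
    first (lowest-dose) crossing is returned when there are several.
    """
    a, b = fit.domain
    grid = np.linspace(a, b, n_grid)
    vals = fit(grid) - level
    if vals[0] <= 0:
        return float(np.exp(a)), False
    below = np.nonzero(vals <= 0)[0]
    if len(below) == 0:
        return float("nan"), True
    i = below[0]
    root = optimize.brentq(lambda z: fit(z) - level, grid[i - 1], grid[i])
    return float(np.exp(root)), False


# -- five-parameter log-logistic cross-check ----------------------------------

def loglogistic5(log_dose, b, c, d, e, f):
    """5PL curve on the log-dose axis: c + (d-c)/(1+exp(b*(x-e)))**f.

    ``c``/``d`` lower/upper asymptotes, ``b`` slope, ``e`` log-inflection,
    ``f`` asymmetry (> 0; f = 1 gives the symmetric 4PL)."""
    x = np.asarray(log_dose, dtype=float)
    z = b * (x - e)
    # (1+exp(z))^-f computed in log space to avoid overflow
    return c + (d - c) * np.exp(-f * np.logaddexp(0.0, z))


@dataclass
class LogLogistic5Fit:
    params: np.ndarray  # (b, c, d, e, f)
    converged: bool
    auc: float = float("nan")
    ic50: float = float("nan")
    ic50_censored: bool = False

    def __call__(self, log_dose):
        return loglogistic5(log_dose, *self.params)


def fit_loglogistic5(log_doses: np.ndarray, responses: np.ndarray,
                     level: float = IC50_LEVEL) -> LogLogistic5Fit:
    """Nonlinear least-squares 5PL fit with AUC/IC50 on the same
    conventions as the spline estimator (normalized integral; lowest
    crossing of ``level``; censored if none)."""
    x = np.asarray(log_doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need >=5 distinct doses for the 5PL fit")
    a_dom, b_dom = x.min(), x.max()
    c0, d0 = max(y.min(), 0.0), y.max()
    p0 = np.array([1.0, c0, d0, np.median(x), 1.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.least_squares(
                lambda p: loglogistic5(x, *p) - y, p0,
                bounds=([-50, -1.0, 0.0, a_dom - 10, 1e-3],
                        [50, 2.0, 5.0, b_dom + 10, 1e3]),
                max_nfev=5000)
        ok = res.success and np.all(np.isfinite(res.x))
    except Exception:
        ok = False
    if not ok:
        logger.warning("5PL fit did not converge; cross-check unavailable")
        return LogLogistic5Fit(params=p0, converged=False)
    fit = LogLogistic5Fit(params=res.x, converged=True)
    integral, _ = integrate.quad(fit, a_dom, b_dom, limit=200)
    fit.auc = integral / (b_dom - a_dom)
    grid = np.linspace(a_dom, b_dom, 512)
    vals = fit(grid) - level
    if vals[0] <= 0:
        fit.ic50 = float(np.exp(a_dom))
    else:
        below = np.nonzero(vals <= 0)[0]
        if len(below) == 0:
            fit.ic50_censored = True
        else:
            i = below[0]
            root = optimize.brentq(lambda z: fit(z) - level,
                                   grid[i - 1], grid[i])
            fit.ic50 = float(np.exp(root))
    return fit


# -- plate-level driver -------------------------------------------------------

def analyze_plate(plate: DosePlate, monotone: bool = False,
                  crosscheck_5pl: bool = False,
                  weight_threshold: float = OUTLIER_WEIGHT_THRESHOLD,
                  ic50_level: float = IC50_LEVEL) -> DoseResponseResult:
    """Full per-plate pipeline: standardize, flag outliers, spline fit,
    AUC/IC50 (and optionally the 5PL cross-check in ``diagnostics``)."""
    wells = standardize(plate)
    test = wells[~wells["is_control"]]
    log_d = np.log(test["dose"].values.astype(float))
    resp = test["response"].values.astype(float)
    weights, flags = flag_outliers(log_d, resp, weight_threshold)
    keep = ~flags
    diagnostics: dict = {"n_outliers": int(flags.sum())}
    try:
        fit = fit_monotone_spline(log_d[keep], resp[keep], monotone=monotone)
    except ValueError as exc:
        logger.warning("plate %s/%s censored: %s",
                       plate.sample_id, plate.drug_id, exc)
        return DoseResponseResult(
            sample_id=plate.sample_id, drug_id=plate.drug_id,
            standardized=wells, outlier_flags=flags, robust_weights=weights,
            fit=None, auc=float("nan"), ic50=float("nan"), ic50_censored=True,
            diagnostics={**diagnostics, "censor_reason": str(exc)})
    auc_val = auc(fit)
    ic50_val, censored = ic50(fit, level=ic50_level)
    diagnostics["knots"] = fit.knots.tolist()
    if crosscheck_5pl and len(np.unique(log_d[keep])) >= 5:
        pl5 = fit_loglogistic5(log_d[keep], resp[keep], level=ic50_level)
        diagnostics["ll5"] = {
            "converged": pl5.converged, "auc": pl5.auc, "ic50": pl5.ic50,
            "ic50_censored": pl5.ic50_censored,
            "auc_discrepancy": abs(pl5.auc - auc_val)
            if pl5.converged else float("nan"),
        }
    return DoseResponseResult(
        sample_id=plate.sample_id, drug_id=plate.drug_id,
        standardized=wells, outlier_flags=flags, robust_weights=weights,
        fit=fit, auc=auc_val, ic50=ic50_val, ic50_censored=censored,
        diagnostics=diagnostics)


# -- cohort heatmap inputs ----------------------------------------------------

@dataclass
class HeatmapInputs:
    zscores: pd.DataFrame         # samples x drugs, per-drug Z of AUC
    sample_linkage: np.ndarray
    drug_linkage: np.ndarray
    sample_order: list
    drug_order: list
    drug_correlation: pd.DataFrame


def drug_response_heatmap_inputs(auc_table: pd.DataFrame) -> HeatmapInputs:
    """Z-scores and complete-linkage clustering orders for an AUC matrix.

    ``auc_table``: samples x drugs AUC values.  Per-drug Z-scores are
    computed across samples (constant drugs are dropped with a warning).
    Drugs cluster by complete linkage on Euclidean distances between rows
    of the drug-drug Spearman correlation matrix; samples by complete
    linkage on Euclidean distances between Z-score rows.
    """
    if auc_table.isna().all(axis=0).any() or auc_table.isna().all(axis=1).any():
        raise ValueError("AUC table has an all-missing row or column")
    sd = auc_table.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("dropping constant drug columns: %s", constant)
    kept = auc_table.drop(columns=constant)
    z = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    corr, _ = spearmanr(kept.values, axis=0)
    corr = np.atleast_2d(corr)
    corr_df = pd.DataFrame(corr, index=kept.columns, columns=kept.columns)
    drug_link = hierarchy.linkage(pdist(corr, metric="euclidean"),
                                  method="complete")
    sample_link = hierarchy.linkage(pdist(z.values, metric="euclidean"),
                                    method="complete")
    return HeatmapInputs(
        zscores=z,
        sample_linkage=sample_link, drug_linkage=drug_link,
        sample_order=z.index[hierarchy.leaves_list(sample_link)].tolist(),
        drug_order=kept.columns[hierarchy.leaves_list(drug_link)].tolist(),
        drug_correlation=corr_df)
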