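"""Causal-effect estimators for two-sample summary-data MR.

Every estimator regresses SNP-outcome coefficients on SNP-exposure
coefficients (implicitly or explicitly) and returns the causal effect
``theta`` on the beta scale.  They are written as scikit-learn style
estimators (``fit``, fitted ``theta_``/``se_``/``estimate_`` attributes,
``get_params``/``set_params``) so they compose with sklearn tooling; the
module-level functions ``ivw``, ``mr_egger``, ... are thin wrappers that
take a :class:`~mrkit.datatypes.HarmonizedDataset` and return a
:class:`~mrkit.datatypes.MrEstimate`.

Implemented methods
-------------------
- inverse-variance weighted (IVW), fixed or multiplicative random effects
- penalized robust IVW (heterogeneity-penalized weights + Huber regression)
- MR-Egger regression (unconstrained intercept = directional pleiotropy)
- simple and weighted median of the per-SNP ratio estimates
- weighted mode-based estimate (mode of the smoothed ratio density)

Per-SNP ratio (Wald) estimates theta_j = beta_Yj / beta_Xj use the
first-order standard error sigma_Yj / |beta_Xj| by default (the NOME
convention: SNP-exposure coefficients treated as measured without error);
a second-order correction including exposure-side uncertainty is available
via ``second_order=True``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
import statsmodels.api as sm

from .datatypes import (
    EggerEstimate,
    HarmonizedDataset,
    InterceptEstimate,
    MrEstimate,
    wald_estimate,
)
from .errors import ConfigurationError, InsufficientInstrumentsError, ValidationError
from .harmonize import orient_positive

_Z95 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# shared kernels
# ---------------------------------------------------------------------------

def ratio_estimates(
    data: HarmonizedDataset, second_order: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates theta_j = beta_Yj/beta_Xj and their SEs.

    First-order SE: sigma_Yj/|beta_Xj|.  With ``second_order=True`` the
    exposure-side term sigma_Xj^2 beta_Yj^2 / beta_Xj^4 is added under the
    square root.
    """
    zero = np.flatnonzero(data.beta_exposure == 0)
    if zero.size:
        raise ValidationError(
            f"zero exposure beta for {[data.snp_ids[i] for i in zero]}"
        )
    theta = data.beta_outcome / data.beta_exposure
    var = data.se_outcome**2 / data.beta_exposure**2
    if second_order:
        var = var + (data.se_exposure**2 * data.beta_outcome**2) / data.beta_exposure**4
    return theta, np.sqrt(var)


def _ivw_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    w = 1.0 / sy**2
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def _cochran_q(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, theta: float) -> float:
    # equals sum_j w_j (theta_j - theta)^2 with w_j = bx_j^2/sy_j^2
    return float(np.sum((by - theta * bx) ** 2 / sy**2))


def _unpack(X, y, se_outcome, se_exposure):
    """Accept either a HarmonizedDataset or raw (X, y, se) arrays."""
    if isinstance(X, HarmonizedDataset):
        return X.beta_exposure, X.se_exposure, X.beta_outcome, X.se_outcome
    bx = np.asarray(X, dtype=float).reshape(-1)
    if y is None or se_outcome is None:
        raise ConfigurationError(
            "array input requires y (outcome betas) and se_outcome"
        )
    by = np.asarray(y, dtype=float).reshape(-1)
    sy = np.asarray(se_outcome, dtype=float).reshape(-1)
    sx = (
        np.zeros_like(bx)
        if se_exposure is None
        else np.asarray(se_exposure, dtype=float).reshape(-1)
    )
    if not (bx.shape == by.shape == sy.shape == sx.shape):
        raise ValidationError("beta/se vectors must have identical length")
    if np.any(sy <= 0):
        raise ValidationError("all outcome standard errors must be > 0")
    return bx, sx, by, sy


class _SummaryMREstimator(RegressorMixin, BaseEstimator):
    """Base class: unpacking, the fit contract, and prediction."""

    _method_name = "base"
    _min_instruments = 1

    def fit(self, X, y=None, se_outcome=None, se_exposure=None):
        bx, sx, by, sy = _unpack(X, y, se_outcome, se_exposure)
        if bx.size < self._min_instruments:
            raise InsufficientInstrumentsError(
                self._method_name, self._min_instruments, bx.size
            )
        self.n_snps_ = int(bx.size)
        self._fit(bx, sx, by, sy)
        self.estimate_ = wald_estimate(self._method_name, self.theta_, self.se_, self.n_snps_)
        self.ci_ = (self.estimate_.ci_low, self.estimate_.ci_high)
        self.pvalue_ = self.estimate_.pvalue
        return self

    def _fit(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X):
        """Predicted outcome betas theta_ * beta_exposure."""
        bx = X.beta_exposure if isinstance(X, HarmonizedDataset) else np.asarray(X, float).reshape(-1)
        return self.theta_ * bx


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

class IVWEstimator(_SummaryMREstimator):
    """Inverse-variance weighted estimator.

    Weighted regression of outcome on exposure betas through the origin
    with weights 1/sigma_Yj^2.  ``effects_model='fixed'`` uses the analytic
    fixed-effects SE; ``'multiplicative_random'`` (default) inflates it by
    max(1, sqrt(Q/(J-1))) so that between-instrument heterogeneity widens
    the interval but can never shrink it.
    """

    _method_name = "ivw"
    _min_instruments = 1

    def __init__(self, effects_model: str = "multiplicative_random"):
        self.effects_model = effects_model

    def _fit(self, bx, sx, by, sy):
        if self.effects_model not in ("fixed", "multiplicative_random"):
            raise ConfigurationError(
                f"unknown effects_model {self.effects_model!r}"
            )
        theta = _ivw_point(bx, by, sy)
        se_fixed = float(np.sqrt(1.0 / np.sum(bx**2 / sy**2)))
        q = _cochran_q(bx, by, sy, theta)
        scale = 1.0
        if self.effects_model == "multiplicative_random" and bx.size > 1:
            scale = max(1.0, np.sqrt(q / (bx.size - 1)))
        self.theta_ = theta
        self.se_ = se_fixed * scale
        self.q_ = q


class PenalizedRobustIVWEstimator(_SummaryMREstimator):
    """IVW with heterogeneity-penalized weights and Huber robust regression.

    Each instrument's inverse-variance weight is multiplied by
    min(1, penalty_scale * q_j) where q_j is the upper-tail chi-square(1)
    probability of its heterogeneity contribution at the unpenalized IVW
    estimate — instruments whose ratio estimate is far from the consensus
    lose weight.  The point estimate then comes from an M-estimated
    (Huber, tuning ``robust_tuning``) regression through the origin on the
    penalized-weight-transformed data; the SE is the penalized-weight
    analytic SE with multiplicative random-effects scaling.
    """

    _method_name = "ivw_penalized_robust"
    _min_instruments = 3

    def __init__(self, penalty_scale: float = 20.0, robust_tuning: float = 1.345):
        self.penalty_scale = penalty_scale
        self.robust_tuning = robust_tuning

    def _fit(self, bx, sx, by, sy):
        if self.penalty_scale <= 0 or self.robust_tuning <= 0:
            raise ConfigurationError("penalty_scale and robust_tuning must be > 0")
        theta0 = _ivw_point(bx, by, sy)
        w = bx**2 / sy**2
        ratios = by / bx
        q_contrib = w * (ratios - theta0) ** 2
        tail = stats.chi2.sf(q_contrib, df=1)
        penalty = np.minimum(1.0, self.penalty_scale * tail)
        w_pen = penalty / sy**2  # regression-scale weights

        q0 = _cochran_q(bx, by, sy, theta0)
        if q0 < 1e-12:
            # exact-fit data: robust scale degenerates, IVW is already exact
            self.theta_ = theta0
            self.se_ = float(np.sqrt(1.0 / np.sum(bx**2 / sy**2)))
            self.weights_ = penalty
            return

        sw = np.sqrt(w_pen)
        rlm = sm.RLM(by * sw, bx * sw, M=sm.robust.norms.HuberT(t=self.robust_tuning))
        theta = float(rlm.fit().params[0])

        denom = np.sum(w_pen * bx**2)
        q_pen = float(np.sum(w_pen * (by - theta * bx) ** 2))
        scale = max(1.0, np.sqrt(q_pen / (bx.size - 1)))
        self.theta_ = theta
        self.se_ = float(np.sqrt(1.0 / denom)) * scale
        self.weights_ = penalty


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

class EggerEstimator(_SummaryMREstimator):
    """MR-Egger: the IVW weighted regression with the intercept unconstrained.

    The slope is a pleiotropy-robust causal estimate (consistent under the
    InSIDE assumption); the intercept estimates the average directional
    pleiotropic effect, and an intercept distinguishable from zero signals
    directional pleiotropy.  Instruments are first oriented so every
    exposure beta is positive (intercept sign is otherwise arbitrary).
    Inference uses the t distribution with J-2 degrees of freedom and
    multiplicative random-effects scaling max(1, sqrt(Q'/(J-2))).
    """

    _method_name = "mr_egger"
    _min_instruments = 3

    def fit(self, X, y=None, se_outcome=None, se_exposure=None):
        bx, sx, by, sy = _unpack(X, y, se_outcome, se_exposure)
        if bx.size < self._min_instruments:
            raise InsufficientInstrumentsError(self._method_name, 3, bx.size)
        # orient to positive exposure effects; ratios are invariant
        sign = np.sign(bx)
        if np.any(sign == 0):
            raise ValidationError("zero exposure beta: orient_positive undefined")
        bx, by = bx * sign, by * sign

        w = 1.0 / sy**2
        sw = np.sum(w)
        mx = np.sum(w * bx) / sw
        my = np.sum(w * by) / sw
        sxx = np.sum(w * (bx - mx) ** 2)
        if sxx <= 1e-14 * np.sum(w * bx**2):
            raise ValidationError(
                "exposure betas are collinear (all identical after orientation)"
            )
        sxy = np.sum(w * (bx - mx) * (by - my))
        slope = float(sxy / sxx)
        intercept = float(my - slope * mx)

        j = bx.size
        rss = float(np.sum(w * (by - intercept - slope * bx) ** 2))
        scale = max(1.0, np.sqrt(rss / (j - 2)))
        se_slope = float(np.sqrt(1.0 / sxx)) * scale
        se_int = float(np.sqrt(1.0 / sw + mx**2 / sxx)) * scale

        df = j - 2
        tq = float(stats.t.ppf(0.975, df))
        p_slope = float(2 * stats.t.sf(abs(slope) / se_slope, df))
        p_int = float(2 * stats.t.sf(abs(intercept) / se_int, df))

        self.n_snps_ = j
        self.theta_ = slope
        self.se_ = se_slope
        self.intercept_ = intercept
        self.intercept_se_ = se_int
        self.intercept_pvalue_ = p_int
        self.pvalue_ = p_slope
        self.ci_ = (slope - tq * se_slope, slope + tq * se_slope)
        self.residual_scale_ = scale
        slope_est = MrEstimate(
            method=self._method_name,
            theta=slope,
            se=se_slope,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            pvalue=p_slope,
            n_snps=j,
        )
        int_est = InterceptEstimate(
            estimate=intercept,
            se=se_int,
            ci_low=intercept - tq * se_int,
            ci_high=intercept + tq * se_int,
            pvalue=p_int,
        )
        self.estimate_ = EggerEstimate(slope=slope_est, intercept=int_est)
        return self


# ---------------------------------------------------------------------------
# median estimators
# ---------------------------------------------------------------------------

def _weighted_median_rows(R: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with cumulative-weight interpolation.

    For each row: sort ratios, standardize weights, compute
    s_j = cumsum(w)_j - w_j/2, and linearly interpolate ratio against s
    at s = 0.5.
    """
    order = np.argsort(R, axis=1)
    th = np.take_along_axis(R, order, axis=1)
    w = np.take_along_axis(W, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - w / 2.0
    out = np.empty(R.shape[0])
    for i in range(R.shape[0]):
        out[i] = np.interp(0.5, s[i], th[i])
    return out


def _mbe_rows(R: np.ndarray, W: np.ndarray, phi: float, n_grid: int = 512) -> np.ndarray:
    """Row-wise weighted mode of the kernel-smoothed ratio density.

    Normal kernel; bandwidth h = phi * 0.9 * min(sd*, mad*) * J^(-1/5) with
    weighted SD and scaled weighted MAD of the ratios.  The mode is the
    argmax over a fixed grid spanning [min-3h, max+3h]; density ties break
    to the smallest grid index.
    """
    n, j = R.shape
    W = W / W.sum(axis=1, keepdims=True)
    out = np.empty(n)
    for i in range(n):
        th, w = R[i], W[i]
        m = np.sum(w * th)
        sd = np.sqrt(np.sum(w * (th - m) ** 2))
        wm = _weighted_median_rows(th[None, :], w[None, :])[0]
        mad = 1.4826 * _weighted_median_rows(np.abs(th - wm)[None, :], w[None, :])[0]
        spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
        if spread == 0.0:
            out[i] = th[0]  # all ratios identical
            continue
        h = phi * 0.9 * spread * j ** (-0.2)
        grid = np.linspace(th.min() - 3 * h, th.max() + 3 * h, n_grid)
        dens = np.exp(-0.5 * ((grid[:, None] - th[None, :]) / h) ** 2) @ w
        out[i] = grid[np.argmax(dens)]
    return out


class _BootstrapRatioEstimator(_SummaryMREstimator):
    """Shared machinery: point estimate on ratios + parametric-bootstrap SE.

    The bootstrap redraws both exposure and outcome betas from normal
    distributions centred at their observed values with their reported
    standard errors, recomputes ratios, weights, and the point estimate,
    and takes the SD over replicates.  Deterministic given ``random_state``.
    """

    _min_instruments = 3

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def _points(self, BX: np.ndarray, BY: np.ndarray, SY: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _fit(self, bx, sx, by, sy):
        if self.n_boot < 2:
            raise ConfigurationError("n_boot must be at least 2")
        theta = float(self._points(bx[None, :], by[None, :], sy[None, :])[0])
        rng = np.random.default_rng(self.random_state)
        j = bx.size
        BX = bx + sx * rng.standard_normal((self.n_boot, j))
        BY = by + sy * rng.standard_normal((self.n_boot, j))
        SY = np.broadcast_to(sy, BX.shape)
        boot = self._points(BX, BY, SY)
        self.theta_ = theta
        self.se_ = float(np.std(boot, ddof=1))
        self.boot_estimates_ = boot


class SimpleMedianEstimator(_BootstrapRatioEstimator):
    """Median of the per-SNP ratio estimates; consistent if >50% of the
    weight of information comes from valid instruments."""

    _method_name = "simple_median"

    def _points(self, BX, BY, SY):
        return np.median(BY / BX, axis=1)


class WeightedMedianEstimator(_BootstrapRatioEstimator):
    """Inverse-variance weighted median of the ratio estimates; consistent
    if valid instruments contribute >50% of the total weight."""

    _method_name = "weighted_median"

    def _points(self, BX, BY, SY):
        return _weighted_median_rows(BY / BX, BX**2 / SY**2)


class WeightedModeEstimator(_BootstrapRatioEstimator):
    """Weighted mode-based estimate: the mode of the inverse-variance
    weighted smoothed empirical density of the ratio estimates, robust when
    the largest group of instruments sharing a ratio value is valid.

    ``phi`` multiplies the modified-Silverman bandwidth; smaller values
    trade variance for robustness.
    """

    _method_name = "weighted_mbe"

    def __init__(self, phi: float = 1.0, n_boot: int = 1000, random_state: int | None = None):
        super().__init__(n_boot=n_boot, random_state=random_state)
        self.phi = phi

    def _points(self, BX, BY, SY):
        if self.phi <= 0:
            raise ConfigurationError("phi must be > 0")
        return _mbe_rows(BY / BX, BX**2 / SY**2, self.phi)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def ivw(data: HarmonizedDataset, effects_model: str = "multiplicative_random") -> MrEstimate:
    return IVWEstimator(effects_model=effects_model).fit(data).estimate_


def ivw_penalized_robust(
    data: HarmonizedDataset, penalty_scale: float = 20.0, robust_tuning: float = 1.345
) -> MrEstimate:
    est = PenalizedRobustIVWEstimator(penalty_scale=penalty_scale, robust_tuning=robust_tuning)
    return est.fit(data).estimate_


def mr_egger(data: HarmonizedDataset) -> EggerEstimate:
    """Egger regression on positively oriented data (orientation applied
    internally; per-SNP ratios are unaffected)."""
    return EggerEstimator().fit(orient_positive(data)).estimate_


def simple_median(data: HarmonizedDataset, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    return SimpleMedianEstimator(n_boot=n_boot, random_state=seed).fit(data).estimate_


def weighted_median(data: HarmonizedDataset, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(data).estimate_


def weighted_mbe(
    data: HarmonizedDataset, phi: float = 1.0, n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    return WeightedModeEstimator(phi=phi, n_boot=n_boot, random_state=seed).fit(data).estimate_


def to_odds_ratio(est: MrEstimate) -> tuple[float, float, float]:
    """(OR, lower, upper) = exp(theta), exp(theta -/+ z*se), z = Phi^-1(0.975)."""
    return (
        float(np.exp(est.theta)),
        float(np.exp(est.theta - _Z95 * est.se)),
        float(np.exp(est.theta + _Z95 * est.se)),
    )
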