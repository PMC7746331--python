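"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

The global test compares the observed leave-one-out residual sum of
squares (RSS) of the IVW fit against a Monte-Carlo null in which each
SNP's exposure and outcome betas are redrawn from normal distributions
consistent with no pleiotropy.  The per-SNP outlier test does the same for
each SNP's own RSS contribution (Bonferroni-adjusted); flagged outliers
are removed and the IVW estimate recomputed.  The distortion test asks
whether removing the flagged set changes the estimate more than removing
random sets of the same size would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HarmonizedDataset, MrEstimate
from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import IVWEstimator


@dataclass(frozen=True)
class MrPressoResult:
    global_rss: float
    global_p: float
    outlier_pvalues: np.ndarray  # Bonferroni-adjusted, one per SNP
    outlier_indices: tuple[int, ...]
    corrected: MrEstimate | None  # None when every SNP is flagged
    raw: MrEstimate
    distortion_p: float | None  # None when no outliers flagged
    n_sim: int
    seed: int | None

    @property
    def all_snps_flagged(self) -> bool:
        return self.corrected is None

    def outlier_report(self, data: HarmonizedDataset) -> pd.DataFrame:
        flagged = set(self.outlier_indices)
        obs = _loo_contributions(
            data.beta_exposure, data.beta_outcome, data.se_outcome
        )[1]
        return pd.DataFrame(
            {
                "rsid": data.snp_ids,
                "contribution": obs,
                "adjusted_p": self.outlier_pvalues,
                "flagged": [i in flagged for i in range(data.n_snps)],
            }
        )


def _loo_thetas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Fixed-effects IVW estimate excluding each SNP in turn, via sum updates."""
    w = 1.0 / sy**2
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx**2)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def _loo_contributions(bx, by, sy) -> tuple[float, np.ndarray]:
    """Observed RSS and per-SNP contributions using leave-one-out predictions."""
    t_loo = _loo_thetas(bx, by, sy)
    contrib = (by - t_loo * bx) ** 2 / sy**2
    return float(np.sum(contrib)), contrib


def _simulate_contributions(
    bx, sx, by, sy, t_loo, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_sim, J) matrix of per-SNP RSS contributions under the no-pleiotropy null.

    Each replicate redraws beta_Xj* ~ N(beta_Xj, sigma_Xj) and
    beta_Yj* ~ N(theta_loo_j * beta_Xj, sigma_Yj), then recomputes the
    leave-one-out contributions on the simulated dataset.
    """
    j = bx.size
    BX = bx + sx * rng.standard_normal((n_sim, j))
    BY = t_loo * bx + sy * rng.standard_normal((n_sim, j))
    w = 1.0 / sy**2
    s1 = np.sum(w * BX * BY, axis=1, keepdims=True)
    s2 = np.sum(w * BX**2, axis=1, keepdims=True)
    T = (s1 - w * BX * BY) / (s2 - w * BX**2)
    return (BY - T * BX) ** 2 * w


def presso_null_distribution(
    data: HarmonizedDataset, theta_by_loo: np.ndarray, n_sim: int, seed: int | None = None
) -> np.ndarray:
    """Simulated null RSS vector (length n_sim); exposed for testing."""
    if n_sim < 1:
        raise ConfigurationError("n_sim must be >= 1")
    if data.n_snps < 4:
        raise InsufficientInstrumentsError("mr_presso", 4, data.n_snps)
    rng = np.random.default_rng(seed)
    contrib = _simulate_contributions(
        data.beta_exposure, data.se_exposure, data.beta_outcome, data.se_outcome,
        np.asarray(theta_by_loo, float), n_sim, rng,
    )
    return contrib.sum(axis=1)


def mr_presso(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    outlier_threshold: float = 0.05,
    seed: int | None = None,
    n_distortion: int = 1000,
    effects_model: str = "multiplicative_random",
) -> MrPressoResult:
    """Global heterogeneity test, outlier detection, corrected estimate.

    ``global_p`` is the Monte-Carlo tail probability
    (1 + #{simulated RSS >= observed}) / (n_sim + 1); per-SNP p-values are
    computed the same way on each SNP's contribution and
    Bonferroni-adjusted across the J instruments.
    """
    if data.n_snps < 4:
        raise InsufficientInstrumentsError("mr_presso", 4, data.n_snps)
    if n_sim < 1:
        raise ConfigurationError("n_sim must be >= 1")
    if not (0 < outlier_threshold < 1):
        raise ConfigurationError("outlier_threshold must lie in (0, 1)")

    bx, sx = data.beta_exposure, data.se_exposure
    by, sy = data.beta_outcome, data.se_outcome
    j = data.n_snps
    rng = np.random.default_rng(seed)

    t_loo = _loo_thetas(bx, by, sy)
    rss_obs, contrib_obs = _loo_contributions(bx, by, sy)
    sim_contrib = _simulate_contributions(bx, sx, by, sy, t_loo, n_sim, rng)
    sim_rss = sim_contrib.sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(sim_contrib >= contrib_obs, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * j)
    outliers = tuple(int(i) for i in np.flatnonzero(p_adj < outlier_threshold))

    raw = IVWEstimator(effects_model=effects_model).fit(data).estimate_

    corrected = None
    distortion_p = None
    if len(outliers) < j:
        keep = np.setdiff1d(np.arange(j), outliers)
        sub = data.subset(keep)
        corrected_est = IVWEstimator(effects_model=effects_model).fit(sub).estimate_
        corrected = MrEstimate(
            method="mr_presso",
            theta=corrected_est.theta,
            se=corrected_est.se,
            ci_low=corrected_est.ci_low,
            ci_high=corrected_est.ci_high,
            pvalue=corrected_est.pvalue,
            n_snps=corrected_est.n_snps,
        )
        if outliers:
            distortion_p = _distortion_test(
                data, len(outliers), raw.theta, corrected.theta, n_distortion, rng
            )
    return MrPressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_pvalues=p_adj,
        outlier_indices=outliers,
        corrected=corrected,
        raw=raw,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def _distortion_test(
    data: HarmonizedDataset,
    k: int,
    theta_raw: float,
    theta_corrected: float,
    n_draws: int,
    rng: np.random.Generator,
) -> float:
    """Tail probability that removing a random size-k SNP set shifts the
    estimate at least as much as removing the flagged outliers did."""
    d_obs = abs(theta_raw - theta_corrected)
    w = 1.0 / data.se_outcome**2
    s1 = np.sum(w * data.beta_exposure * data.beta_outcome)
    s2 = np.sum(w * data.beta_exposure**2)
    per1 = w * data.beta_exposure * data.beta_outcome
    per2 = w * data.beta_exposure**2
    count = 0
    for _ in range(n_draws):
        drop = rng.choice(data.n_snps, size=k, replace=False)
        theta_b = (s1 - per1[drop].sum()) / (s2 - per2[drop].sum())
        if abs(theta_raw - theta_b) >= d_obs:
            count += 1
    return float((1 + count) / (n_draws + 1))


class MRPressoEstimator(IVWEstimator):
    """sklearn-style wrapper: IVW after MR-PRESSO outlier removal.

    Fitted attributes expose the corrected estimate (``theta_``, ``se_``)
    plus the full :class:`MrPressoResult` as ``presso_result_``.
    """

    _method_name = "mr_presso"

    def __init__(
        self,
        n_sim: int = 1000,
        outlier_threshold: float = 0.05,
        random_state: int | None = None,
        effects_model: str = "multiplicative_random",
    ):
        super().__init__(effects_model=effects_model)
        self.n_sim = n_sim
        self.outlier_threshold = outlier_threshold
        self.random_state = random_state

    def fit(self, X, y=None, se_outcome=None, se_exposure=None):
        if not isinstance(X, HarmonizedDataset):
            from .estimators import _unpack

            bx, sx, by, sy = _unpack(X, y, se_outcome, se_exposure)
            X = HarmonizedDataset(
                [f"snp{i}" for i in range(bx.size)], bx, np.where(sx > 0, sx, 1e-12), by, sy
            )
        res = mr_presso(
            X,
            n_sim=self.n_sim,
            outlier_threshold=self.outlier_threshold,
            seed=self.random_state,
            effects_model=self.effects_model,
        )
        self.presso_result_ = res
        est = res.corrected if res.corrected is not None else res.raw
        self.theta_ = est.theta
        self.se_ = est.se
        self.pvalue_ = est.pvalue
        self.ci_ = (est.ci_low, est.ci_high)
        self.n_snps_ = est.n_snps
        self.estimate_ = est
        return self
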