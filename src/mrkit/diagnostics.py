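"""Heterogeneity, influence, and per-variant diagnostics.

Cochran's Q measures dispersion of the per-SNP ratio estimates around the
fixed-effects IVW estimate; excess Q signals heterogeneity, often caused
by pleiotropic instruments.  The leave-one-out analysis re-estimates the
causal effect J times, each time omitting one instrument, to expose
single-variant influence.  ``variant_effect_table`` exports the per-variant
exposure/outcome effects with CIs for scatter-style rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HarmonizedDataset, MrEstimate
from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import _cochran_q, _ivw_point, ratio_estimates

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    pvalue: float


def q_contributions(data: HarmonizedDataset, theta: float | None = None) -> np.ndarray:
    """Per-SNP heterogeneity contributions w_j (theta_j - theta)^2 at the
    fixed-effects IVW estimate (or a supplied theta)."""
    if theta is None:
        theta = _ivw_point(data.beta_exposure, data.beta_outcome, data.se_outcome)
    th, se = ratio_estimates(data)
    return (th - theta) ** 2 / se**2


def cochran_q(data: HarmonizedDataset) -> HeterogeneityResult:
    """Cochran's Q with J-1 degrees of freedom, fixed-effects IVW centre."""
    if data.n_snps < 2:
        raise InsufficientInstrumentsError("cochran_q", 2, data.n_snps)
    theta = _ivw_point(data.beta_exposure, data.beta_outcome, data.se_outcome)
    q = _cochran_q(data.beta_exposure, data.beta_outcome, data.se_outcome, theta)
    df = data.n_snps - 1
    return HeterogeneityResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


@dataclass(frozen=True)
class LeaveOneOutTable:
    """One re-estimate per excluded instrument plus the all-SNP row."""

    table: pd.DataFrame  # columns: excluded_rsid, theta, se, ci_low, ci_high, p, outside_full_ci
    full: MrEstimate

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def leave_one_out(data: HarmonizedDataset, method: str = "ivw", **method_kwargs) -> LeaveOneOutTable:
    """Re-estimate with each instrument omitted in turn.

    Rows whose confidence interval excludes the full-set point estimate are
    flagged in the ``influential`` column.
    """
    from . import estimators as est_mod

    if data.n_snps < 3:
        raise InsufficientInstrumentsError("leave_one_out", 3, data.n_snps)
    registry = {
        "ivw": est_mod.ivw,
        "ivw_penalized_robust": est_mod.ivw_penalized_robust,
        "simple_median": est_mod.simple_median,
        "weighted_median": est_mod.weighted_median,
        "weighted_mbe": est_mod.weighted_mbe,
    }
    if method not in registry:
        raise ConfigurationError(
            f"unknown leave-one-out method {method!r}; choose from {sorted(registry)}"
        )
    fn = registry[method]

    full = fn(data, **method_kwargs)
    rows = []
    for i, rsid in enumerate(data.snp_ids):
        try:
            est = fn(data.drop(i), **method_kwargs)
        except Exception as exc:
            raise type(exc)(f"leave-one-out excluding {rsid}: {exc}") from exc
        rows.append(
            {
                "excluded_rsid": rsid,
                "theta": est.theta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.pvalue,
                "influential": not (est.ci_low <= full.theta <= est.ci_high),
            }
        )
    rows.append(
        {
            "excluded_rsid": "(none)",
            "theta": full.theta,
            "se": full.se,
            "ci_low": full.ci_low,
            "ci_high": full.ci_high,
            "p": full.pvalue,
            "influential": False,
        }
    )
    return LeaveOneOutTable(table=pd.DataFrame(rows), full=full)


def variant_effect_table(data: HarmonizedDataset, est: MrEstimate) -> pd.DataFrame:
    """Per-variant effects with outcome CIs plus the fitted slope, for
    scatter plots of SNP-outcome against SNP-exposure associations."""
    return pd.DataFrame(
        {
            "rsid": data.snp_ids,
            "beta_exposure": data.beta_exposure,
            "se_exposure": data.se_exposure,
            "beta_outcome": data.beta_outcome,
            "se_outcome": data.se_outcome,
            "outcome_ci_low": data.beta_outcome - _Z95 * data.se_outcome,
            "outcome_ci_high": data.beta_outcome + _Z95 * data.se_outcome,
            "slope": est.theta,
        }
    )
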