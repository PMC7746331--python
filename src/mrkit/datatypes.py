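"""Core data containers for two-sample Mendelian randomization.

The unit of analysis is a set of J independent genetic instruments, each
carrying an estimated association with the exposure (``beta_exposure``,
``se_exposure``) and with the outcome (``beta_outcome``, ``se_outcome``),
already expressed for the same effect allele in both studies
(:class:`HarmonizedDataset`).  Estimators consume this container and return
:class:`MrEstimate` records: a causal effect ``theta`` on the beta scale
(log odds of the outcome per unit of exposure for a binary outcome),
its standard error, Wald confidence bounds, and an odds-ratio view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_VALID_BASES = frozenset("ACGT")
_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's association summary in a single study.

    ``beta`` is on the study's reporting scale: log-odds per effect allele
    for a binary trait, SD or trait units for a quantitative trait.
    ``eaf`` (effect-allele frequency) and ``pvalue`` may be missing (None).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None

    def __post_init__(self):
        from .errors import ValidationError

        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in _VALID_BASES or oa not in _VALID_BASES:
            raise ValidationError(
                f"{self.rsid}: alleles must be single bases in A/C/G/T, "
                f"got {ea!r}/{oa!r}"
            )
        if ea == oa:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta is not a finite number")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.rsid}: standard error must be > 0")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.rsid}: eaf must lie in [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class ExclusionList:
    """Variants to remove before analysis (e.g. a pleiotropy look-up screen)."""

    rsids: frozenset[str]
    reasons: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        from .errors import ValidationError

        object.__setattr__(self, "rsids", frozenset(self.rsids))
        extra = set(self.reasons) - set(self.rsids)
        if extra:
            raise ValidationError(
                f"reasons given for rsids not in the exclusion list: {sorted(extra)}"
            )

    def reason_for(self, rsid: str) -> str:
        return self.reasons.get(rsid, "excluded")

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.rsids

    def __len__(self) -> int:
        return len(self.rsids)


class HarmonizedDataset:
    """Aligned per-SNP exposure/outcome effects — the input to every estimator.

    All four coefficient vectors have identical length J; effects are
    expressed per copy of the same effect allele in both studies.
    """

    def __init__(
        self,
        snp_ids: Sequence[str],
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        trait_name: str = "",
        exposure_scale: str = "",
    ):
        from .errors import ValidationError

        self.trait_name = trait_name
        self.exposure_scale = exposure_scale
        self.snp_ids = list(map(str, snp_ids))
        self.beta_exposure = np.asarray(beta_exposure, dtype=float)
        self.se_exposure = np.asarray(se_exposure, dtype=float)
        self.beta_outcome = np.asarray(beta_outcome, dtype=float)
        self.se_outcome = np.asarray(se_outcome, dtype=float)

        j = len(self.snp_ids)
        if j < 1:
            raise ValidationError("a harmonized dataset needs at least one SNP")
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            v = getattr(self, name)
            if v.ndim != 1 or v.shape[0] != j:
                raise ValidationError(f"{name} must be a length-{j} vector")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} contains non-finite values")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValidationError("all standard errors must be > 0")
        if len(set(self.snp_ids)) != j:
            dupes = sorted({s for s in self.snp_ids if self.snp_ids.count(s) > 1})
            raise ValidationError(f"duplicated snp_ids: {dupes}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep) -> "HarmonizedDataset":
        """Row-subset by boolean mask or integer index array."""
        idx = np.arange(self.n_snps)[keep] if np.asarray(keep).dtype == bool else np.asarray(keep)
        return HarmonizedDataset(
            [self.snp_ids[i] for i in idx],
            self.beta_exposure[idx],
            self.se_exposure[idx],
            self.beta_outcome[idx],
            self.se_outcome[idx],
            trait_name=self.trait_name,
            exposure_scale=self.exposure_scale,
        )

    def drop(self, index: int) -> "HarmonizedDataset":
        mask = np.ones(self.n_snps, dtype=bool)
        mask[index] = False
        return self.subset(mask)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.snp_ids,
                "beta_exposure": self.beta_exposure,
                "se_exposure": self.se_exposure,
                "beta_outcome": self.beta_outcome,
                "se_outcome": self.se_outcome,
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, trait_name: str = "", exposure_scale: str = ""
    ) -> "HarmonizedDataset":
        return cls(
            df["rsid"].tolist(),
            df["beta_exposure"].to_numpy(),
            df["se_exposure"].to_numpy(),
            df["beta_outcome"].to_numpy(),
            df["se_outcome"].to_numpy(),
            trait_name=trait_name,
            exposure_scale=exposure_scale,
        )

    def __repr__(self) -> str:
        name = f" {self.trait_name!r}" if self.trait_name else ""
        return f"<HarmonizedDataset{name}: J={self.n_snps}>"

    def __eq__(self, other) -> bool:
        if not isinstance(other, HarmonizedDataset):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and np.array_equal(self.beta_exposure, other.beta_exposure)
            and np.array_equal(self.se_exposure, other.se_exposure)
            and np.array_equal(self.beta_outcome, other.beta_outcome)
            and np.array_equal(self.se_outcome, other.se_outcome)
        )


@dataclass(frozen=True)
class MrEstimate:
    """A causal estimate on the beta (log-OR) scale with its OR-scale view."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    def __post_init__(self):
        from .errors import ValidationError

        if self.se <= 0:
            raise ValidationError(f"{self.method}: standard error must be > 0")
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValidationError(f"{self.method}: CI does not bracket the estimate")

    @property
    def or_view(self) -> tuple[float, float, float]:
        """(OR, lower, upper) — exponentiated point estimate and CI."""
        return (float(np.exp(self.theta)), float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))

    def to_row(self) -> dict:
        o, lo, hi = self.or_view
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.pvalue,
            "OR": o,
            "OR_low": lo,
            "OR_high": hi,
        }


def wald_estimate(method: str, theta: float, se: float, n_snps: int) -> MrEstimate:
    """Build a Wald-type estimate: CI = theta ± z·se, p from the normal."""
    z = _Z95
    p = 2.0 * stats.norm.sf(abs(theta) / se)
    return MrEstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - z * se),
        ci_high=float(theta + z * se),
        pvalue=float(p),
        n_snps=int(n_snps),
    )


@dataclass(frozen=True)
class InterceptEstimate:
    """The pleiotropy intercept of an Egger regression, log-odds-per-SNP scale."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float

    @property
    def or_view(self) -> tuple[float, float, float]:
        return (
            float(np.exp(self.estimate)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )


@dataclass(frozen=True)
class EggerEstimate:
    """Slope (causal effect) and intercept (directional pleiotropy) of one fit."""

    slope: MrEstimate
    intercept: InterceptEstimate

    @property
    def intercept_or_view(self) -> tuple[float, float, float]:
        return self.intercept.or_view
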