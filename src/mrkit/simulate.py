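"""Synthetic two-sample GWAS summary statistics with known causal effect.

The generative model mirrors the structural assumptions of an MR study
with J independent instruments:

    true beta_Xj  ~ Normal(mu_X, sd_X), truncated to |beta_Xj| >= 0.01
    alpha_j       = direct (pleiotropic) effect; 0 for valid instruments
    true beta_Yj  = theta_true * beta_Xj + alpha_j
    observed beta ~ Normal(true beta, reported se)

Pleiotropy modes: ``none`` (all instruments valid), ``balanced``
(alpha ~ Normal(0, sd)), ``directional`` (alpha ~ Normal(mean, sd)).
``inside_violation`` induces correlation between alpha_j and the
instrument strength beta_Xj, breaking the InSIDE condition that Egger
regression relies on.  Draws are keyed per SNP index from one global
seed, so SNP j's values do not depend on J.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .datatypes import HarmonizedDataset, SnpAssociation
from .errors import ConfigurationError
from .io import write_summary_table

_PLEIOTROPY_MODES = ("none", "balanced", "directional")
# ordered allele pairs that are never strand-ambiguous
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic two-sample MR dataset.

    Defaults emulate a well-powered quantitative-trait exposure GWAS
    (per-allele effects around 0.07 SD with SEs of a few thousandths) and
    a large binary-outcome GWAS (log-OR SEs of 0.02-0.05), with a causal
    effect of 0.3 log-OR per exposure SD.
    """

    n_snps: int = 30
    theta_true: float = 0.3
    exposure_effect_dist: tuple[float, float] = (0.07, 0.02)
    se_exposure_range: tuple[float, float] = (0.004, 0.010)
    se_outcome_range: tuple[float, float] = (0.020, 0.050)
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.03
    pleiotropy_mean: float = 0.0
    invalid_fraction: float = 0.0
    inside_violation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ConfigurationError(
                f"pleiotropy_mode must be one of {_PLEIOTROPY_MODES}"
            )
        for name in ("se_exposure_range", "se_outcome_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must be positive and ordered")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ConfigurationError("invalid_fraction must lie in [0, 1]")
        if not (-1.0 <= self.inside_violation <= 1.0):
            raise ConfigurationError("inside_violation must lie in [-1, 1]")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected key-value pairs")
        for key in ("exposure_effect_dist", "se_exposure_range", "se_outcome_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

    def to_file(self, path) -> None:
        d = asdict(self)
        for key in ("exposure_effect_dist", "se_exposure_range", "se_outcome_range"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass(frozen=True)
class SimulationTruth:
    """Latent values behind one simulated dataset."""

    theta_true: float
    true_beta_exposure: np.ndarray
    alpha: np.ndarray
    invalid: np.ndarray  # boolean mask
    config: SimulationConfig = field(repr=False)


def _per_snp_rngs(seed: int, j: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(j)
    return [np.random.default_rng(c) for c in children]


def simulate_summary_data(
    config: SimulationConfig,
) -> tuple[HarmonizedDataset, SimulationTruth]:
    """Draw one dataset; deterministic given ``config.seed``."""
    j = config.n_snps
    mu, sd = config.exposure_effect_dist
    rngs = _per_snp_rngs(config.seed, j)

    n_invalid = int(round(config.invalid_fraction * j))
    invalid = np.zeros(j, dtype=bool)
    if config.pleiotropy_mode != "none":
        invalid[:n_invalid] = True

    true_bx = np.empty(j)
    sx = np.empty(j)
    sy = np.empty(j)
    alpha = np.zeros(j)
    obs_bx = np.empty(j)
    obs_by = np.empty(j)
    rho = config.inside_violation
    for i, rng in enumerate(rngs):
        b = mu + sd * rng.standard_normal()
        while abs(b) < 0.01:  # avoid weak-instrument degeneracy in ratios
            b = mu + sd * rng.standard_normal()
        true_bx[i] = b
        sx[i] = rng.uniform(*config.se_exposure_range)
        sy[i] = rng.uniform(*config.se_outcome_range)
        z_alpha = rng.standard_normal()
        if invalid[i]:
            mean_a = 0.0 if config.pleiotropy_mode == "balanced" else config.pleiotropy_mean
            z_x = (b - mu) / sd if sd > 0 else 0.0
            alpha[i] = mean_a + config.pleiotropy_sd * (
                rho * z_x + np.sqrt(1.0 - rho**2) * z_alpha
            )
        obs_bx[i] = b + sx[i] * rng.standard_normal()
        obs_by[i] = (
            config.theta_true * b + alpha[i] + sy[i] * rng.standard_normal()
        )

    data = HarmonizedDataset(
        snp_ids=[f"rs{i + 1:04d}" for i in range(j)],
        beta_exposure=obs_bx,
        se_exposure=sx,
        beta_outcome=obs_by,
        se_outcome=sy,
        trait_name="simulated-exposure",
        exposure_scale="1-SD",
    )
    truth = SimulationTruth(
        theta_true=config.theta_true,
        true_beta_exposure=true_bx,
        alpha=alpha,
        invalid=invalid,
        config=config,
    )
    return data, truth


def simulate_study_tables(
    config: SimulationConfig,
    out_dir,
    allele_scramble: bool = False,
    write_truth: bool = False,
) -> tuple[Path, Path]:
    """Emit exposure/outcome summary tables in the on-disk format.

    Allele labels are random non-palindromic pairs; with
    ``allele_scramble`` a random subset of outcome rows is re-expressed on
    the other allele (labels swapped, beta negated, eaf complemented),
    which harmonization must undo exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data, truth = simulate_summary_data(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    exposure, outcome = [], []
    for i, rsid in enumerate(data.snp_ids):
        ea, oa = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
        eaf = float(rng.uniform(0.05, 0.95))
        bx, sx = float(data.beta_exposure[i]), float(data.se_exposure[i])
        by, sy = float(data.beta_outcome[i]), float(data.se_outcome[i])
        exposure.append(
            SnpAssociation(
                rsid=rsid, effect_allele=ea, other_allele=oa, eaf=eaf,
                beta=bx, se=sx, pvalue=float(2 * stats.norm.sf(abs(bx) / sx)),
            )
        )
        flip = allele_scramble and rng.random() < 0.5
        outcome.append(
            SnpAssociation(
                rsid=rsid,
                effect_allele=oa if flip else ea,
                other_allele=ea if flip else oa,
                eaf=1.0 - eaf if flip else eaf,
                beta=-by if flip else by,
                se=sy,
                pvalue=float(2 * stats.norm.sf(abs(by) / sy)),
            )
        )

    exp_path = out_dir / "exposure.tsv"
    out_path = out_dir / "outcome.tsv"
    write_summary_table(exposure, exp_path)
    write_summary_table(outcome, out_path)
    if write_truth:
        (out_dir / "truth.json").write_text(
            json.dumps(
                {
                    "theta_true": truth.theta_true,
                    "invalid": truth.invalid.tolist(),
                    "alpha": truth.alpha.tolist(),
                },
                indent=2,
            )
        )
    return exp_path, out_path
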