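"""Orchestration: many traits x many methods from one configuration.

Mirrors the workflow of a multi-trait two-sample MR study: for each
exposure trait, read and filter instruments, harmonize against the shared
outcome study, run every requested estimator whose instrument-count
precondition holds (methods beyond plain IVW need more than 2 variants;
MR-PRESSO needs at least 4), plus heterogeneity, leave-one-out and
per-variant diagnostics.  Skips and failures are recorded, never silent,
and a manifest makes the run reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import EggerEstimate, HarmonizedDataset, MrEstimate
from .diagnostics import LeaveOneOutTable, cochran_q, leave_one_out, variant_effect_table
from .errors import ConfigurationError, InsufficientInstrumentsError, MrkitError
from .estimators import (
    ivw,
    ivw_penalized_robust,
    mr_egger,
    simple_median,
    weighted_mbe,
    weighted_median,
)
from .harmonize import apply_exclusions, harmonize
from .io import read_exclusion_list, read_summary_table
from .presso import mr_presso

ALL_METHODS = (
    "ivw",
    "ivw_penalized_robust",
    "mr_egger",
    "simple_median",
    "weighted_median",
    "weighted_mbe",
    "mr_presso",
)

#: minimum instrument count per method; sensitivity methods need > 2
#: variants, MR-PRESSO needs leave-one-out fits on >= 3
MIN_SNPS = {
    "ivw": 1,
    "ivw_penalized_robust": 3,
    "mr_egger": 3,
    "simple_median": 3,
    "weighted_median": 3,
    "weighted_mbe": 3,
    "mr_presso": 4,
}


@dataclass(frozen=True)
class TraitConfig:
    name: str
    exposure_path: str
    exclusion_path: str | None = None
    exposure_scale: str = ""
    flip_exposure: bool = False  # report per 1-unit *lower* exposure
    leave_one_out: bool = False
    column_map: dict | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    traits: tuple[TraitConfig, ...]
    outcome_path: str
    methods: tuple[str, ...] = ALL_METHODS
    seed: int | None = None
    outcome_column_map: dict | None = None
    n_boot: int = 1000
    n_sim: int = 1000
    phi: float = 1.0
    outlier_threshold: float = 0.05
    penalty_scale: float = 20.0
    robust_tuning: float = 1.345
    effects_model: str = "multiplicative_random"
    palindromic_policy: str = "infer_by_eaf"
    eaf_threshold: float = 0.42

    def __post_init__(self):
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ConfigurationError("trait names must be unique")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
        stochastic = {"simple_median", "weighted_median", "weighted_mbe", "mr_presso"}
        if stochastic & set(self.methods) and self.seed is None:
            raise ConfigurationError(
                "seed is required when a stochastic method is requested"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping")
        traits = tuple(TraitConfig(**t) for t in raw.pop("traits", []))
        if not traits:
            raise ConfigurationError(f"{path}: at least one trait is required")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        try:
            return cls(traits=traits, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc


@dataclass
class TraitResults:
    name: str
    data: HarmonizedDataset
    rows: list[dict] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)
    heterogeneity: object | None = None
    loo: LeaveOneOutTable | None = None
    variant_table: pd.DataFrame | None = None
    harmonization_report: object | None = None
    presso_result: object | None = None


@dataclass
class ResultsBundle:
    per_trait: dict[str, TraitResults]
    failures: dict[str, str]
    manifest: dict

    @property
    def results_table(self) -> pd.DataFrame:
        rows = []
        for name, tr in self.per_trait.items():
            for row in tr.rows:
                rows.append({"trait": name, **row})
        df = pd.DataFrame(rows)
        if not df.empty:
            df["significant"] = df["p"] < 0.05
        return df


def _estimate_rows(name: str, est) -> list[dict]:
    if isinstance(est, EggerEstimate):
        slope_row = est.slope.to_row()
        slope_row["parameter"] = "OR"
        o, lo, hi = est.intercept_or_view
        int_row = {
            "method": "mr_egger",
            "parameter": "Odds (intercept)",
            "n_snps": est.slope.n_snps,
            "theta": est.intercept.estimate,
            "se": est.intercept.se,
            "ci_low": est.intercept.ci_low,
            "ci_high": est.intercept.ci_high,
            "p": est.intercept.pvalue,
            "OR": o,
            "OR_low": lo,
            "OR_high": hi,
        }
        return [slope_row, int_row]
    row = est.to_row()
    row["parameter"] = "OR"
    return [row]


def _analyze_trait(
    tc: TraitConfig, outcome_records, config: AnalysisConfig
) -> TraitResults:
    exposure = read_summary_table(tc.exposure_path, column_map=tc.column_map)
    if tc.exclusion_path:
        exclusions = read_exclusion_list(tc.exclusion_path)
        exposure, _ = apply_exclusions(exposure, exclusions)
    data, report = harmonize(
        exposure,
        outcome_records,
        palindromic_policy=config.palindromic_policy,
        eaf_threshold=config.eaf_threshold,
        trait_name=tc.name,
        exposure_scale=tc.exposure_scale,
    )
    if tc.flip_exposure:
        # report per 1-unit-lower exposure: negate the exposure coefficients
        data = HarmonizedDataset(
            data.snp_ids,
            -data.beta_exposure,
            data.se_exposure,
            data.beta_outcome,
            data.se_outcome,
            trait_name=data.trait_name,
            exposure_scale=data.exposure_scale,
        )
    tr = TraitResults(name=tc.name, data=data, harmonization_report=report)

    runners = {
        "ivw": lambda d: ivw(d, effects_model=config.effects_model),
        "ivw_penalized_robust": lambda d: ivw_penalized_robust(
            d, penalty_scale=config.penalty_scale, robust_tuning=config.robust_tuning
        ),
        "mr_egger": mr_egger,
        "simple_median": lambda d: simple_median(d, n_boot=config.n_boot, seed=config.seed),
        "weighted_median": lambda d: weighted_median(d, n_boot=config.n_boot, seed=config.seed),
        "weighted_mbe": lambda d: weighted_mbe(
            d, phi=config.phi, n_boot=config.n_boot, seed=config.seed
        ),
    }
    for method in config.methods:
        need = MIN_SNPS[method]
        if data.n_snps < need:
            tr.skipped[method] = f"requires more than {need - 1} variants (J={data.n_snps})"
            continue
        if method == "mr_presso":
            res = mr_presso(
                data,
                n_sim=config.n_sim,
                outlier_threshold=config.outlier_threshold,
                seed=config.seed,
                effects_model=config.effects_model,
            )
            tr.presso_result = res
            if res.corrected is None:
                tr.skipped[method] = "all instruments flagged as outliers"
            else:
                tr.rows.extend(_estimate_rows(tc.name, res.corrected))
        else:
            tr.rows.extend(_estimate_rows(tc.name, runners[method](data)))

    if data.n_snps >= 2:
        tr.heterogeneity = cochran_q(data)
    if tc.leave_one_out and data.n_snps >= 3:
        tr.loo = leave_one_out(data, method="ivw", effects_model=config.effects_model)
    if "ivw" in config.methods and data.n_snps >= 1:
        ivw_est = ivw(data, effects_model=config.effects_model)
        tr.variant_table = variant_effect_table(data, ivw_est)
    return tr


def run_analysis(config: AnalysisConfig) -> ResultsBundle:
    """Run every trait; individual trait failures do not stop the run."""
    outcome_records = read_summary_table(config.outcome_path, column_map=config.outcome_column_map)
    per_trait: dict[str, TraitResults] = {}
    failures: dict[str, str] = {}
    for tc in config.traits:
        try:
            per_trait[tc.name] = _analyze_trait(tc, outcome_records, config)
        except MrkitError as exc:
            failures[tc.name] = str(exc)

    n_requested = len(config.traits) * len(config.methods)
    n_skipped = sum(len(tr.skipped) for tr in per_trait.values())
    n_failed = len(failures) * len(config.methods)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "methods": list(config.methods),
        "traits": [t.name for t in config.traits],
        "counts": {
            "requested": n_requested,
            "run": n_requested - n_skipped - n_failed,
            "skipped": n_skipped,
            "failed": n_failed,
        },
        "skips": {name: tr.skipped for name, tr in per_trait.items() if tr.skipped},
        "failures": failures,
    }
    return ResultsBundle(per_trait=per_trait, failures=failures, manifest=manifest)


def _format_or(or_, lo, hi) -> str:
    return f"{or_:.2f}({lo:.2f}-{hi:.2f})"


def render_outputs(
    bundle: ResultsBundle, out_dir, formats: set[str] | None = None
) -> list[Path]:
    """Write tables and figures; returns the paths written.

    Formats: ``table`` (full-precision and display-rounded results tables,
    manifest, reports), ``forest`` (across-trait forest data and figure),
    ``scatter`` (per-trait variant scatter data and figure).
    """
    from . import plots

    formats = {"table", "forest", "scatter"} if formats is None else set(formats)
    unknown = formats - {"table", "forest", "scatter"}
    if unknown:
        raise ConfigurationError(f"unknown output formats: {sorted(unknown)}")
    if not bundle.per_trait:
        raise ConfigurationError("results bundle is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    df = bundle.results_table
    if "table" in formats:
        p = out_dir / "results.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
        if not df.empty:
            disp = df.copy()
            disp["OR (95% CI)"] = [
                _format_or(o, lo, hi)
                for o, lo, hi in zip(disp["OR"], disp["OR_low"], disp["OR_high"])
            ]
            disp["P value"] = [
                "<0.001" if p_ < 0.001 else f"{p_:.2f}" for p_ in disp["p"]
            ]
            disp = disp[["trait", "method", "parameter", "n_snps", "OR (95% CI)", "P value"]]
            p = out_dir / "results_formatted.tsv"
            disp.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(bundle.manifest, indent=2))
        written.append(p)
        for name, tr in bundle.per_trait.items():
            if tr.harmonization_report is not None:
                p = out_dir / f"harmonization_{name}.tsv"
                tr.harmonization_report.write(p)
                written.append(p)
            if tr.loo is not None:
                p = out_dir / f"leave_one_out_{name}.tsv"
                tr.loo.write(p)
                written.append(p)
            if tr.variant_table is not None:
                p = out_dir / f"variants_{name}.tsv"
                tr.variant_table.to_csv(p, sep="\t", index=False)
                written.append(p)

    if "forest" in formats and not df.empty:
        ivw_rows = df[(df["method"] == "ivw") & (df["parameter"] == "OR")]
        if not ivw_rows.empty:
            p = out_dir / "forest_data.tsv"
            ivw_rows.to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out_dir / "forest.png"
            plots.forest_plot(ivw_rows, p)
            written.append(p)

    if "scatter" in formats:
        for name, tr in bundle.per_trait.items():
            if tr.variant_table is not None:
                p = out_dir / f"scatter_{name}.png"
                plots.scatter_plot(tr.variant_table, p, title=name)
                written.append(p)
    return written
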