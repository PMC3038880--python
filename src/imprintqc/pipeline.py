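"""Configuration-driven end-to-end analysis run.

Sequences the full workflow — catalog summary, standards-based validation,
differential-window derivation, tissue classification, genomic-feature
association, population outlier screening and treatment-response scoring —
writing one CSV per stage plus a machine-readable JSON summary and a run
log. Inputs not supplied as files are simulated from the packaged
generators under the run seed, so the pipeline is runnable end-to-end with
no external data.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import dmr, population, simulate, validation

__all__ = ["RunConfig", "PipelineError", "run_analysis", "load_run_config"]

#: Assays never observed in the differential range in any tissue; excluded
#: from DMR-restricted feature associations by default.
DEFAULT_EXCLUSIONS = ("UBE3A", "BLCAP", "CDKN1C", "TCEB3C", "RTL")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    output_dir: Path
    catalog_path: Path | None = None          # None -> packaged catalog
    tissue_table: Path | None = None          # None -> simulate
    blood_table: Path | None = None           # None -> simulate
    standards_table: Path | None = None       # None -> simulate
    window_source: str = "from_standards"     # or "fixed"
    fixed_window: tuple[float, float] | None = None
    window_k: float = 1.5
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    levels: tuple[float, ...] = (0.95, 0.99)
    seed: int = 0

    def validate(self) -> None:
        if self.window_source not in ("from_standards", "fixed"):
            raise ValueError(f"unknown window_source {self.window_source!r}")
        if self.window_source == "fixed":
            if self.fixed_window is None:
                raise ValueError("fixed window_source requires fixed_window bounds")
            lo, hi = self.fixed_window
            if lo >= hi:
                raise ValueError(f"fixed window lower {lo} >= upper {hi}")
        for path in (self.catalog_path, self.tissue_table, self.blood_table,
                     self.standards_table):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input path does not exist: {path}")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    fixed = raw.get("fixed_window")
    return RunConfig(
        output_dir=Path(raw["output_dir"]),
        catalog_path=Path(raw["catalog_path"]) if raw.get("catalog_path") else None,
        tissue_table=Path(raw["tissue_table"]) if raw.get("tissue_table") else None,
        blood_table=Path(raw["blood_table"]) if raw.get("blood_table") else None,
        standards_table=Path(raw["standards_table"]) if raw.get("standards_table") else None,
        window_source=raw.get("window_source", "from_standards"),
        fixed_window=tuple(fixed) if fixed else None,
        window_k=float(raw.get("window_k", 1.5)),
        exclusions=tuple(raw.get("exclusions", DEFAULT_EXCLUSIONS)),
        levels=tuple(raw.get("levels", (0.95, 0.99))),
        seed=int(raw.get("seed", 0)),
    )


def _round_df(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(2)
    return out


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline; returns the machine-readable summary dict.

    Deterministic given inputs and seed. On a stage failure the partially
    written output directory is removed and a :class:`PipelineError` names
    the stage and cause.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: dict = {"seed": config.seed}

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{stage}] {message}")

    stage = "catalog"
    try:
        assay_catalog = cat.load_assay_catalog(config.catalog_path)
        log(stage, f"loaded {len(assay_catalog)} assays")
        full_summary = cat.summarize_catalog(assay_catalog)
        excl_summary = cat.summarize_catalog(assay_catalog, config.exclusions) \
            if set(config.exclusions) <= {a.name for a in assay_catalog} else None
        summary["catalog"] = {
            "n_assays": len(assay_catalog),
            "germline_count": full_summary.count("timing", cat.Timing.GERMLINE),
            "germline_qualified_count": full_summary.count("timing", cat.Timing.GERMLINE_QUALIFIED),
            "somatic_count": full_summary.count("timing", cat.Timing.SOMATIC),
        }
        if excl_summary is not None:
            summary["catalog"]["variable_ctcf_after_exclusion"] = \
                excl_summary.count("ctcf_class", cat.CtcfClass.VARIABLE)
            summary["catalog"]["constitutive_ctcf_after_exclusion"] = \
                excl_summary.count("ctcf_class", cat.CtcfClass.CONSTITUTIVE)

        stage = "standards"
        if config.standards_table is not None:
            standards = cat.read_methylation_table(config.standards_table)
        else:
            standards, _ = simulate.generate_standards(
                noise_sd=1.0, reps=3, masses_ng=(10.0, 5.0, 2.5, 1.0),
                seed=config.seed,
            )
        log(stage, f"{len(standards)} standard readings")

        stage = "validation"
        std_df = standards.data
        if "expected_percent" in std_df.columns:
            per_sample = std_df.groupby("sample").agg(
                observed=("percent", "mean"), expected=("expected_percent", "first"),
            )
            series = per_sample[per_sample["expected"].isin(validation.STANDARD_SERIES)]
            linearity = validation.assess_linearity(
                series["expected"].to_numpy(), series["observed"].to_numpy()
            )
            summary["validation"] = {
                "slope": linearity.slope,
                "intercept": linearity.intercept,
                "r_squared": linearity.r_squared,
                "n_points": linearity.n_points,
            }
            if "replicate" in std_df.columns:
                mix = std_df[std_df["template_mass_ng"].isna()] \
                    if "template_mass_ng" in std_df.columns else std_df
                wide = mix.pivot_table(index=["expected_percent", "cpg_index"],
                                       columns="replicate", values="percent")
                if wide.shape[1] >= 2 and len(wide) >= 3:
                    reps = wide.iloc[:, :2].dropna()
                    agreement = validation.replicate_agreement(
                        reps.iloc[:, 0].to_numpy(), reps.iloc[:, 1].to_numpy()
                    )
                    summary["validation"]["replicate_bias"] = agreement.bias
                    summary["validation"]["replicate_r_squared"] = agreement.r_squared
            log(stage, f"linearity over {linearity.n_points} standards")
        else:
            summary["validation"] = {}
            log(stage, "standards table carries no expected_percent; skipped")

        stage = "window"
        if config.window_source == "fixed":
            lo, hi = config.fixed_window  # type: ignore[misc]
            window = dmr.DmrWindow.from_bounds(lo, hi, k=config.window_k)
        else:
            if "expected_percent" not in std_df.columns:
                raise ValueError("no 50% standards available to derive the window")
            fifty = std_df[std_df["expected_percent"] == 50.0]
            if "template_mass_ng" in fifty.columns:
                fifty = fifty[fifty["template_mass_ng"].isna()]
            if fifty.empty:
                raise ValueError("no 50% standards available to derive the window")
            window = dmr.derive_dmr_window(fifty["percent"].to_numpy(), k=config.window_k)
        summary["window"] = {
            "center": window.center, "spread": window.spread, "k": window.k,
            "lower": window.lower_rounded, "upper": window.upper_rounded,
        }
        log(stage, f"window [{window.lower_rounded}, {window.upper_rounded}]")

        stage = "sensitivity"
        if "template_mass_ng" in std_df.columns and std_df["template_mass_ng"].notna().any():
            mass_rows = std_df[std_df["template_mass_ng"].notna()]
            sens = validation.titration_sensitivity(
                cat.MethylationDataset(mass_rows), window
            )
            summary["sensitivity"] = {
                "min_reliable_mass_ng": sens.min_reliable_mass_ng,
                "n_masses": len(sens.per_mass),
            }
            log(stage, f"min reliable mass {sens.min_reliable_mass_ng} ng")

        stage = "classification"
        if config.tissue_table is not None:
            panel = cat.read_methylation_table(config.tissue_table)
        else:
            panel, _ = simulate.generate_tissue_panel(
                simulate.default_tissue_panel_config(seed=config.seed)
            )
        table = dmr.classify_dataset(panel, window)
        table_out = table.table.copy()
        table_out["category"] = table_out["category"].map(str)
        table_out["ever_differential"] = table_out["assay"].map(table.ever_differential)
        _round_df(table_out).to_csv(out / "classification.csv", index=False)
        counts = table.table["category"].value_counts()
        summary["classification"] = {
            "n_assays": len(table.ever_differential),
            "never_differential": table.never_differential,
            "category_counts": {str(dmr.MethylationCategory(k)): int(v)
                                for k, v in counts.items()},
        }
        log(stage, f"{len(table.table)} assay x tissue calls")

        stage = "features"
        feature_rows = []
        for feature in ("ctcf", "cpg_island", "position", "density"):
            try:
                res = dmr.feature_association(assay_catalog, feature, config.exclusions)
            except ValueError as exc:
                log(stage, f"{feature}: skipped ({exc})")
                continue
            feature_rows.append({
                "feature": feature, "test": res.test_name,
                "statistic": res.statistic, "p_value": res.p_value,
                "r_squared": res.r_squared, "n": res.n,
            })
        features_df = pd.DataFrame(feature_rows)
        _round_df(features_df).to_csv(out / "feature_associations.csv", index=False)
        summary["features"] = {
            row["feature"]: {"p_value": row["p_value"], "r_squared": row["r_squared"]}
            for row in feature_rows
        }
        log(stage, f"{len(feature_rows)} feature associations")

        stage = "population"
        if config.blood_table is not None:
            blood = cat.read_methylation_table(config.blood_table)
        else:
            blood, _ = simulate.generate_blood_cohort(
                simulate.default_blood_cohort_config(seed=config.seed)
            )
        report = population.flag_population_outliers(blood, config.levels)
        _round_df(report.flags).to_csv(out / "outliers.csv", index=False)
        burden = population.individual_burden(blood, report)
        clusters = population.cis_cluster_correlation(blood, assay_catalog)
        summary["population"] = {
            "n_individuals": int(blood.samples.shape[0]),
            "n_assays": len(blood.assays),
            "n_flags": {str(lv): int(len(report.flags_at(lv))) for lv in config.levels},
            "assays_with_outliers": {
                str(lv): len(report.assays_with_outliers(lv)) for lv in config.levels
            },
            "burden_anova_p": burden.anova_p,
            "max_cis_r_squared": clusters.max_r_squared,
        }
        log(stage, f"{len(report.flags)} outlier flags")

        stage = "treatment"
        treat_cfg = simulate.SyntheticConfig(
            n_individuals=1, tissues=("cell_line",),
            assays=tuple(
                simulate.AssaySpec(f"locus{i + 1}", "maternal", "germline",
                                   {"cell_line": 50.0 + 2.0 * i})
                for i in range(6)
            ),
            treatment_effect={f"locus{i + 1}": frac for i, frac in
                              enumerate((0.5, 0.4, 0.6, 0.3, 0.15, 0.55))},
            seed=config.seed,
        )
        control, treated, _ = simulate.generate_treatment_panel(treat_cfg)
        reduction = population.treatment_reduction(control, treated)
        _round_df(reduction.as_frame()).to_csv(out / "treatment_reduction.csv", index=False)
        summary["treatment"] = {
            "mean_percent_reduction": reduction.mean_reduction(),
            "n_records": len(reduction.records),
        }
        log(stage, f"{len(reduction.records)} reduction records")

    except Exception as exc:  # noqa: BLE001 - single abort path per contract
        shutil.rmtree(out, ignore_errors=True)
        raise PipelineError(stage, exc) from exc

    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, default=float)
    with open(out / "run.log", "w") as handle:
        handle.write("\n".join(log_lines) + "\n")
    return summary
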