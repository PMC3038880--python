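"""Population outlier analysis and demethylation-treatment response.

A cohort of healthy individuals defines, per DMR, a reference interval
(mean +/- z*SD at 95% and 99% by default); individuals falling outside are
flagged as methylation outliers. A two-way ANOVA without replication on
per-assay z-scores tests whether any individual shows a systematic shift
across DMRs. Same-cluster DMR pairs are checked for cis correlation of
per-individual means. Treatment response to a demethylating agent
(e.g. 5-azacytidine) is scored as percent reduction of the control mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import AssayDefinition, MethylationDataset

__all__ = [
    "OutlierReport",
    "BurdenResult",
    "ReductionResult",
    "reference_interval",
    "flag_population_outliers",
    "individual_burden",
    "cis_cluster_correlation",
    "treatment_reduction",
]


def reference_interval(
    values: Sequence[float],
    level: float,
    method: str = "parametric",
) -> tuple[float, float]:
    """Population reference range at the given coverage level.

    ``parametric``: mean +/- z_{(1+level)/2} * sample SD (a normal reference
    range for individuals, not a confidence interval of the mean).
    ``percentile``: empirical ((1-level)/2, (1+level)/2) quantiles.
    Bounds are truncated to [0, 100].
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 3:
        raise ValueError("need at least 3 values for a reference interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if method == "parametric":
        z = stats.norm.ppf((1.0 + level) / 2.0)
        mu, sd = float(np.mean(arr)), float(np.std(arr, ddof=1))
        low, high = mu - z * sd, mu + z * sd
    elif method == "percentile":
        alpha = (1.0 - level) / 2.0
        low, high = np.quantile(arr, [alpha, 1.0 - alpha])
    else:
        raise ValueError(f"unknown method {method!r}")
    return (max(0.0, float(low)), min(100.0, float(high)))


@dataclass
class OutlierReport:
    """Per-assay reference intervals and flagged sample x DMR outliers."""

    intervals: dict[tuple[str, float], tuple[float, float]]  # (assay, level) -> (low, high)
    flags: pd.DataFrame  # columns: assay, sample, value, level_exceeded
    sample_counts: dict[str, int] = field(default_factory=dict)
    skipped_assays: list[str] = field(default_factory=list)

    def flags_at(self, level: float) -> pd.DataFrame:
        return self.flags[self.flags["level_exceeded"] == level]

    def assays_with_outliers(self, level: float) -> list[str]:
        return sorted(self.flags_at(level)["assay"].unique())


def flag_population_outliers(
    dataset: MethylationDataset,
    levels: Sequence[float] = (0.95, 0.99),
    method: str = "parametric",
    leave_one_out: bool = False,
) -> OutlierReport:
    """Flag individuals outside per-assay reference intervals.

    Each individual contributes one value per assay (mean over CpGs). By
    default the interval includes the tested individual; with
    ``leave_one_out`` each individual is tested against the interval of the
    remaining cohort. Assays with fewer than 3 individuals are skipped.
    """
    levels = sorted(levels)
    per = dataset.sample_means()
    intervals: dict[tuple[str, float], tuple[float, float]] = {}
    rows = []
    counts: dict[str, int] = {s: 0 for s in per["sample"].unique()}
    skipped: list[str] = []
    for assay, sub in per.groupby("assay"):
        vals = sub["mean_percent"].to_numpy()
        if len(vals) < 3:
            skipped.append(str(assay))
            continue
        for level in levels:
            intervals[(str(assay), level)] = reference_interval(vals, level, method)
        for _, rec in sub.iterrows():
            v = float(rec["mean_percent"])
            if leave_one_out:
                rest = sub.loc[sub["sample"] != rec["sample"], "mean_percent"].to_numpy()
                if len(rest) < 3:
                    continue
                ref = {lv: reference_interval(rest, lv, method) for lv in levels}
            else:
                ref = {lv: intervals[(str(assay), lv)] for lv in levels}
            for level in levels:
                low, high = ref[level]
                if v < low or v > high:
                    rows.append((str(assay), rec["sample"], v, level))
                    counts[rec["sample"]] = counts.get(rec["sample"], 0) + 1
    if skipped:
        import warnings

        warnings.warn(f"assays skipped (<3 individuals): {skipped}")
    flags = pd.DataFrame(rows, columns=["assay", "sample", "value", "level_exceeded"])
    return OutlierReport(intervals=intervals, flags=flags,
                         sample_counts=counts, skipped_assays=skipped)


@dataclass(frozen=True)
class BurdenResult:
    sample_counts: dict[str, int]
    anova_p: float
    anova_f: float
    max_count_sample: str | None


def individual_burden(
    dataset: MethylationDataset,
    report: OutlierReport,
) -> BurdenResult:
    """Is any individual over-represented among outliers / shifted overall?

    Runs a two-way ANOVA without replication on per-assay z-scores, with
    individual and assay as crossed factors, and reports the individual
    main effect (a repeated-measures view of a consistent per-individual
    gain or loss across DMRs). More than 20% missing cells is an error —
    the unreplicated two-way layout needs a near-complete matrix.
    """
    per = dataset.sample_means()
    wide = per.pivot_table(index="sample", columns="assay", values="mean_percent")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 individuals and >= 2 assays")
    missing_frac = float(wide.isna().to_numpy().mean())
    if missing_frac > 0.20:
        raise ValueError(
            f"{missing_frac:.0%} of individual x assay cells missing; "
            "unbalanced design unsupported"
        )
    # z-score within assay so assays with different baselines are comparable
    z = (wide - wide.mean(axis=0)) / wide.std(axis=0, ddof=1)
    z = z.fillna(0.0)  # constant assays carry no information

    long = z.reset_index().melt(id_vars="sample", var_name="assay", value_name="z")
    long = long.dropna(subset=["z"])
    n_ind = z.shape[0]
    n_assay = z.shape[1]
    grand = long["z"].mean()
    ind_means = long.groupby("sample")["z"].mean()
    assay_means = long.groupby("assay")["z"].mean()
    ss_ind = n_assay * float(((ind_means - grand) ** 2).sum())
    ss_assay = n_ind * float(((assay_means - grand) ** 2).sum())
    ss_tot = float(((long["z"] - grand) ** 2).sum())
    ss_err = ss_tot - ss_ind - ss_assay
    df_ind = n_ind - 1
    df_err = (n_ind - 1) * (n_assay - 1)
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if ms_err <= 0 or not np.isfinite(ms_err):
        f_stat, p = 0.0, 1.0
    else:
        f_stat = (ss_ind / df_ind) / ms_err
        p = float(stats.f.sf(f_stat, df_ind, df_err))
    counts = dict(report.sample_counts)
    max_sample = max(counts, key=counts.get) if counts and max(counts.values()) > 0 else None
    return BurdenResult(sample_counts=counts, anova_p=float(p),
                        anova_f=float(f_stat), max_count_sample=max_sample)


@dataclass(frozen=True)
class ClusterCorrelation:
    pairs: pd.DataFrame  # columns: cluster_id, assay_a, assay_b, r_squared, n
    max_r_squared: float | None

    @property
    def empty(self) -> bool:
        return self.pairs.empty


def cis_cluster_correlation(
    dataset: MethylationDataset,
    catalog: Sequence[AssayDefinition],
) -> ClusterCorrelation:
    """Correlation of per-individual means between same-cluster DMR pairs.

    For every pair of assays sharing a ``cluster_id``, the r^2 of the two
    vectors of per-individual means is computed (pairs with < 3 shared
    individuals are skipped); the global maximum summarizes whether a loss
    or gain at one DMR propagates in cis to its neighbours.
    """
    clusters: dict[str, list[str]] = {}
    for a in catalog:
        if a.cluster_id:
            clusters.setdefault(a.cluster_id, []).append(a.name)
    per = dataset.sample_means().pivot_table(
        index="sample", columns="assay", values="mean_percent"
    )
    rows = []
    for cid, members in sorted(clusters.items()):
        present = [m for m in members if m in per.columns]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                sub = per[[a, b]].dropna()
                if len(sub) < 3:
                    continue
                x, y = sub[a].to_numpy(), sub[b].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                rows.append((cid, a, b, r * r, len(sub)))
    pairs = pd.DataFrame(rows, columns=["cluster_id", "assay_a", "assay_b",
                                        "r_squared", "n"])
    max_r2 = float(pairs["r_squared"].max()) if not pairs.empty else None
    return ClusterCorrelation(pairs=pairs, max_r_squared=max_r2)


@dataclass(frozen=True)
class ReductionRecord:
    assay: str
    dose_label: str
    control_mean: float
    treated_mean: float
    percent_reduction: float  # NaN when control is 0
    reduction_range: tuple[float, float] | None = None  # across replicate runs


@dataclass(frozen=True)
class ReductionResult:
    records: tuple[ReductionRecord, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "assay": r.assay,
                    "dose_label": r.dose_label,
                    "control_mean": r.control_mean,
                    "treated_mean": r.treated_mean,
                    "percent_reduction": r.percent_reduction,
                    "range_low": r.reduction_range[0] if r.reduction_range else np.nan,
                    "range_high": r.reduction_range[1] if r.reduction_range else np.nan,
                }
                for r in self.records
            ]
        )

    def mean_reduction(self) -> float:
        vals = [r.percent_reduction for r in self.records
                if np.isfinite(r.percent_reduction)]
        return float(np.mean(vals)) if vals else float("nan")


def treatment_reduction(
    control: Mapping[str, float],
    treated: Mapping[str, Mapping[str, float]],
    replicate_pairs: Mapping[str, Mapping[str, Sequence[tuple[float, float]]]] | None = None,
) -> ReductionResult:
    """Percent methylation lost under demethylating treatment.

    percent_reduction = 100 * (control - treated) / control per assay and
    dose; a gain reports as a negative reduction, and a zero control mean
    is flagged undefined (NaN) rather than 0. ``replicate_pairs`` optionally
    supplies (control, treated) pairs from repeat experiments, whose
    per-experiment reductions set the reported range.
    """
    records: list[ReductionRecord] = []
    for dose_label, per_assay in treated.items():
        for assay, t_mean in per_assay.items():
            if assay not in control:
                raise KeyError(f"assay {assay!r} missing from control means")
            c_mean = float(control[assay])
            if not 0.0 <= c_mean <= 100.0:
                raise ValueError(f"control mean {c_mean} outside [0, 100]")
            if c_mean == 0.0:
                reduction = float("nan")
            else:
                reduction = 100.0 * (c_mean - float(t_mean)) / c_mean
            rng = None
            if replicate_pairs and dose_label in replicate_pairs \
                    and assay in replicate_pairs[dose_label]:
                reds = [
                    100.0 * (c - t) / c
                    for c, t in replicate_pairs[dose_label][assay]
                    if c != 0
                ]
                if reds:
                    rng = (float(min(reds)), float(max(reds)))
            records.append(ReductionRecord(assay, str(dose_label), c_mean,
                                           float(t_mean), reduction, rng))
    return ReductionResult(records=tuple(records))
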