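"""DMR window derivation, classification and feature associations.

The differential window is derived from 50% mixture standards: an assay x
tissue mean inside [center - k*SD, center + k*SD] (k = 1.5 by default) is
"differential", i.e. consistent with one methylated and one unmethylated
parental allele; below is hypomethylated, above hypermethylated. On the
published standards (mean 50.38%, SD 9.7667) the window is 35.73-65.03%.

Also here: intra-CpG variability (the per-assay SD across CpG positions,
larger at paternally than maternally methylated DMRs), tissue-deviation
testing (e.g. testis erasure of maternal germ-line marks), CpG density over
a 500 bp amplicon-centred window, and association of average somatic
methylation with CTCF binding, island status, genomic position and CpG
density. Raw p-values are reported throughout; no multiplicity correction
is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import AssayDefinition, CtcfClass, MethylationDataset

__all__ = [
    "DmrWindow",
    "MethylationCategory",
    "ClassificationTable",
    "TestResult",
    "derive_dmr_window",
    "classify_value",
    "classify_dataset",
    "intra_cpg_sd",
    "intra_cpg_variability",
    "compare_parental_variability",
    "tissue_deviation_test",
    "cpg_density",
    "feature_association",
]


class MethylationCategory(IntEnum):
    """Ordered methylation call relative to a differential window."""

    HYPOMETHYLATED = 0
    DIFFERENTIAL = 1
    HYPERMETHYLATED = 2

    def __str__(self) -> str:  # CSV-friendly
        return self.name.lower()


@dataclass(frozen=True)
class DmrWindow:
    """Differential-methylation calling interval: center +/- k * spread.

    Bounds are kept at full precision internally; ``lower_rounded`` /
    ``upper_rounded`` give the 2-decimal reporting form.
    """

    center: float
    spread: float
    k: float = 1.5

    @property
    def lower(self) -> float:
        return self.center - self.k * self.spread

    @property
    def upper(self) -> float:
        return self.center + self.k * self.spread

    @property
    def lower_rounded(self) -> float:
        return round(self.lower, 2)

    @property
    def upper_rounded(self) -> float:
        return round(self.upper, 2)

    @classmethod
    def from_bounds(cls, lower: float, upper: float, k: float = 1.5) -> "DmrWindow":
        """Reconstruct a window from its printed bounds."""
        if lower > upper:
            raise ValueError(f"lower {lower} > upper {upper}")
        center = (lower + upper) / 2.0
        return cls(center=center, spread=(upper - lower) / (2.0 * k), k=k)


def derive_dmr_window(standard_readings: Sequence[float], k: float = 1.5) -> DmrWindow:
    """Window from 50% standard readings: mean +/- k * sample SD."""
    readings = np.asarray(standard_readings, dtype=float)
    readings = readings[~np.isnan(readings)]
    if len(readings) < 2:
        raise ValueError("need at least 2 standard readings")
    if k <= 0:
        raise ValueError("k must be positive")
    return DmrWindow(center=float(np.mean(readings)),
                     spread=float(np.std(readings, ddof=1)), k=float(k))


def classify_value(value: float, window: DmrWindow) -> MethylationCategory:
    """Call a methylation percentage against a window (bounds inclusive)."""
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"value {value} outside [0, 100]")
    if value < window.lower:
        return MethylationCategory.HYPOMETHYLATED
    if value > window.upper:
        return MethylationCategory.HYPERMETHYLATED
    return MethylationCategory.DIFFERENTIAL


@dataclass
class ClassificationTable:
    """Per assay x tissue mean and category, plus per-assay summary flags."""

    table: pd.DataFrame            # columns: assay, tissue, mean, category
    ever_differential: dict[str, bool]

    @property
    def never_differential(self) -> list[str]:
        return sorted(a for a, flag in self.ever_differential.items() if not flag)


def classify_dataset(dataset: MethylationDataset, window: DmrWindow) -> ClassificationTable:
    """Classify every assay x tissue mean against the window.

    Means average each individual over CpGs first, then individuals within
    a tissue. An assay is ``ever_differential`` when at least one tissue
    mean lies in the window; assays with no values are dropped with a
    warning.
    """
    means = dataset.tissue_means()
    if means.empty:
        raise ValueError("dataset has no classifiable values")
    records = []
    for row in means.itertuples(index=False):
        cat = classify_value(float(row.mean_percent), window)
        records.append((row.assay, row.tissue, float(row.mean_percent), cat))
    table = pd.DataFrame(records, columns=["assay", "tissue", "mean", "category"])
    ever = {
        assay: bool((sub["category"] == MethylationCategory.DIFFERENTIAL).any())
        for assay, sub in table.groupby("assay")
    }
    missing = set(dataset.assays) - set(ever)
    if missing:
        warnings.warn(f"assays with no values excluded: {sorted(missing)}")
    return ClassificationTable(table=table, ever_differential=ever)


def intra_cpg_sd(values: Sequence[float]) -> float:
    """Sample SD across CpG positions; NaN with <2 non-missing CpGs."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        return float("nan")
    return float(np.std(arr, ddof=1))


def intra_cpg_variability(dataset: MethylationDataset) -> pd.DataFrame:
    """Per (assay, sample) SD across CpGs, with tissue metadata if present."""
    df = dataset.data
    meta = [c for c in ("tissue", "individual") if c in df.columns]
    out = (
        df.groupby(["assay", "sample"] + meta, dropna=False)["percent"]
        .apply(lambda v: intra_cpg_sd(v.to_numpy()))
        .reset_index()
        .rename(columns={"percent": "intra_cpg_sd"})
    )
    return out


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n: int


def compare_parental_variability(
    records: pd.DataFrame,
    pairing: str = "by_sample",
) -> TestResult:
    """Test maternal vs paternal intra-CpG variability.

    ``records`` needs columns ``sample``, ``parental_mark`` and
    ``intra_cpg_sd``. With ``pairing='by_sample'`` each sample contributes
    its mean SD over maternal assays and over paternal assays, compared by
    a matched-pair t-test; ``'unpaired'`` runs Welch's t-test on the raw
    per-record SDs.
    """
    marks = {str(m) for m in records["parental_mark"].unique()}
    for needed in ("maternal", "paternal"):
        if needed not in marks:
            raise ValueError(f"no records with parental_mark={needed!r}")
    rec = records.dropna(subset=["intra_cpg_sd"])
    if pairing == "by_sample":
        per = rec.pivot_table(
            index="sample", columns="parental_mark", values="intra_cpg_sd",
            aggfunc="mean",
        ).dropna(subset=["maternal", "paternal"])
        if len(per) < 2:
            raise ValueError("matched-pair test needs >= 2 samples with both classes")
        mat = per["maternal"].to_numpy()
        pat = per["paternal"].to_numpy()
        if np.allclose(mat, pat):
            return TestResult(0.0, 1.0, "paired t-test", len(per))
        t, p = stats.ttest_rel(mat, pat)
        return TestResult(float(t), float(p), "paired t-test", len(per))
    elif pairing == "unpaired":
        mat = rec.loc[rec["parental_mark"] == "maternal", "intra_cpg_sd"].to_numpy()
        pat = rec.loc[rec["parental_mark"] == "paternal", "intra_cpg_sd"].to_numpy()
        if np.ptp(np.concatenate([mat, pat])) == 0:
            return TestResult(0.0, 1.0, "welch t-test", len(mat) + len(pat))
        t, p = stats.ttest_ind(mat, pat, equal_var=False)
        return TestResult(float(t), float(p), "welch t-test", len(mat) + len(pat))
    raise ValueError(f"unknown pairing {pairing!r}")


def tissue_deviation_test(
    dataset: MethylationDataset,
    focal_tissue: str,
    assay_subset: Iterable[str] | None = None,
) -> TestResult:
    """Matched-pair t-test of one tissue against the mean of the others.

    For each assay the pair is (focal-tissue mean, mean over all other
    tissues); pairing is across assays. Used e.g. to show testis deviates
    from somatic tissues at germ-line DMRs (sperm erase maternal marks).
    """
    means = dataset.tissue_means()
    if assay_subset is not None:
        means = means[means["assay"].isin(list(assay_subset))]
    tissues = set(means["tissue"].unique())
    if focal_tissue not in tissues:
        raise ValueError(f"focal tissue {focal_tissue!r} absent from dataset")
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    focal = means[means["tissue"] == focal_tissue].set_index("assay")["mean_percent"]
    others = (
        means[means["tissue"] != focal_tissue]
        .groupby("assay")["mean_percent"].mean()
    )
    common = focal.index.intersection(others.index)
    if len(common) < 2:
        raise ValueError("need at least 2 assays present in focal and other tissues")
    a = focal.loc[common].to_numpy()
    b = others.loc[common].to_numpy()
    if np.allclose(a, b):
        return TestResult(0.0, 1.0, "paired t-test", len(common))
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), float(p), "paired t-test", len(common))


def cpg_density(sequence: str, midpoint: int, flank: int = 250) -> float:
    """CpGs per 100 bp in [midpoint - flank, midpoint + flank).

    Counts 'CG' dinucleotides whose first base lies in the window (top
    strand only; CG is its own reverse complement, so this equals
    both-strand site counting) and divides by the window length in units
    of 100 bp — with the default 500 bp window, count / 5.
    """
    seq = sequence.upper()
    lo, hi = midpoint - flank, midpoint + flank
    if lo < 0 or hi > len(seq):
        raise ValueError(
            f"window [{lo}, {hi}) exceeds sequence of length {len(seq)}"
        )
    count = sum(1 for i in range(lo, hi) if seq[i : i + 2] == "CG")
    return count / (2 * flank / 100.0)


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    test_name: str
    statistic: float
    p_value: float | None
    r_squared: float | None
    n: int
    group_means: dict[str, float] | None = None


def feature_association(
    catalog: Sequence[AssayDefinition],
    feature: str,
    exclusions: Iterable[str] = (),
) -> AssociationResult:
    """Associate average somatic methylation with a genomic feature.

    feature='ctcf'     : two-sample t-test, CTCF binding (variable and
                         constitutive pooled) vs none.
    feature='cpg_island': two-sample t-test, island vs non-island.
    feature='position' : one-way ANOVA over location categories (groups
                         with n < 2 dropped with a warning).
    feature='density'  : OLS of methylation on CpG density, r^2 reported.
    """
    exclusions = set(exclusions)
    kept = [a for a in catalog if a.name not in exclusions]
    meth = np.array([a.avg_somatic_methylation for a in kept])
    n = len(kept)

    if feature == "ctcf":
        binding = meth[[a.ctcf_class != CtcfClass.NONE for a in kept]]
        none = meth[[a.ctcf_class == CtcfClass.NONE for a in kept]]
        if len(binding) < 2 or len(none) < 2:
            raise ValueError("both CTCF groups need n >= 2")
        if np.ptp(meth) == 0 or (np.ptp(binding) == 0 and np.ptp(none) == 0
                                 and binding.mean() == none.mean()):
            return AssociationResult(feature, "t-test", 0.0, 1.0, None, n,
                                     {"binding": float(binding.mean()),
                                      "none": float(none.mean())})
        t, p = stats.ttest_ind(binding, none, equal_var=False)
        return AssociationResult(feature, "t-test", float(t), float(p), None, n,
                                 {"binding": float(binding.mean()),
                                  "none": float(none.mean())})

    if feature == "cpg_island":
        island = meth[[a.cpg_island for a in kept]]
        rest = meth[[not a.cpg_island for a in kept]]
        if len(island) < 2 or len(rest) < 2:
            raise ValueError("both island groups need n >= 2")
        t, p = stats.ttest_ind(island, rest, equal_var=False)
        return AssociationResult(feature, "t-test", float(t), float(p), None, n,
                                 {"island": float(island.mean()),
                                  "non_island": float(rest.mean())})

    if feature == "position":
        groups: dict[str, list[float]] = {}
        for a in kept:
            groups.setdefault(a.location_category.value, []).append(
                a.avg_somatic_methylation
            )
        usable = {k: v for k, v in groups.items() if len(v) >= 2}
        dropped = sorted(set(groups) - set(usable))
        if dropped:
            warnings.warn(f"location groups with n<2 dropped: {dropped}")
        if len(usable) < 2:
            raise ValueError("need >= 2 location groups with n >= 2")
        f, p = stats.f_oneway(*usable.values())
        return AssociationResult(
            feature, "one-way ANOVA", float(f), float(p), None,
            sum(len(v) for v in usable.values()),
            {k: float(np.mean(v)) for k, v in usable.items()},
        )

    if feature == "density":
        dens = np.array([a.cpg_density for a in kept])
        if np.ptp(dens) == 0:
            raise ValueError("constant predictor: CpG density has no variation")
        fit = stats.linregress(dens, meth)
        return AssociationResult(feature, "OLS", float(fit.slope),
                                 float(fit.pvalue), float(fit.rvalue**2), n)

    raise ValueError(f"unknown feature {feature!r}")
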