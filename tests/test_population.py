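"""Reference intervals, cohort outlier flagging, burden ANOVA, cis
correlation and treatment-response scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imprintqc import catalog as cat
from imprintqc.population import (
    cis_cluster_correlation,
    flag_population_outliers,
    individual_burden,
    reference_interval,
    treatment_reduction,
)
from imprintqc.simulate import default_blood_cohort_config, generate_blood_cohort


class TestReferenceInterval:
    def test_constant_values_collapse(self):
        assert reference_interval([50.0] * 5, 0.95) == (50.0, 50.0)

    def test_parametric_interval_mean50_sd5(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, 400)
        values = (values - values.mean()) / values.std(ddof=1) * 5 + 50
        low, high = reference_interval(values, 0.95)
        assert low == pytest.approx(50 - 1.959964 * 5, abs=1e-4)
        assert high == pytest.approx(50 + 1.959964 * 5, abs=1e-4)

    def test_99_contains_95(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(30, 70, 30)
        lo95, hi95 = reference_interval(values, 0.95)
        lo99, hi99 = reference_interval(values, 0.99)
        assert lo99 < lo95 and hi95 < hi99

    def test_truncated_to_percent_scale(self):
        low, high = reference_interval([1.0, 2.0, 3.0, 98.0, 99.0], 0.99)
        assert low >= 0.0 and high <= 100.0

    def test_percentile_method(self):
        values = list(range(101))
        low, high = reference_interval(values, 0.90, method="percentile")
        assert low == pytest.approx(5.0)
        assert high == pytest.approx(95.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            reference_interval([50.0, 51.0], 0.95)


def _cohort(values_by_assay, n_cpgs=3):
    """values_by_assay: assay -> list of per-individual means."""
    rows = []
    for assay, values in values_by_assay.items():
        for i, value in enumerate(values):
            for cpg in range(1, n_cpgs + 1):
                rows.append((assay, f"ind{i}", cpg, value, f"ind{i}"))
    return cat.MethylationDataset(
        pd.DataFrame(rows, columns=["assay", "sample", "cpg_index", "percent",
                                    "individual"])
    )


class TestOutlierFlagging:
    def test_uniform_cohort_has_no_flags(self):
        ds = _cohort({"A": [50.0] * 50, "B": [50.0] * 50})
        report = flag_population_outliers(ds)
        assert report.flags.empty

    def test_spiked_individual_flagged_at_both_levels(self):
        rng = np.random.default_rng(5)
        values = list(50 + rng.normal(0, 3, 50))
        values[7] = float(np.mean(values) + 6 * np.std(values, ddof=1))
        report = flag_population_outliers(_cohort({"A": values, "B": [50.0 + v
                                                  for v in rng.normal(0, 3, 50)]}))
        flagged = report.flags[report.flags["assay"] == "A"]
        assert set(flagged["sample"]) == {"ind7"}
        assert sorted(flagged["level_exceeded"]) == [0.95, 0.99]

    def test_flags_nested_across_levels(self):
        rng = np.random.default_rng(6)
        ds = _cohort({a: list(50 + rng.normal(0, 4, 40)) for a in "ABCD"})
        report = flag_population_outliers(ds)
        keys99 = set(map(tuple, report.flags_at(0.99)[["assay", "sample"]].values))
        keys95 = set(map(tuple, report.flags_at(0.95)[["assay", "sample"]].values))
        assert keys99 <= keys95

    def test_small_assays_skipped_with_warning(self):
        ds = _cohort({"A": [40.0, 50.0], "B": [40.0, 45.0, 50.0, 55.0]})
        with pytest.warns(UserWarning, match="skipped"):
            report = flag_population_outliers(ds)
        assert report.skipped_assays == ["A"]


class TestIndividualBurden:
    def test_identical_individuals_null(self):
        ds = _cohort({"A": [50.0] * 10, "B": [60.0] * 10})
        report = flag_population_outliers(ds)
        burden = individual_burden(ds, report)
        assert burden.anova_f == 0.0
        assert burden.anova_p == 1.0

    def test_shifted_individual_detected(self):
        rng = np.random.default_rng(8)
        assays = [f"D{i}" for i in range(23)]  # 23-DMR cohort layout
        values = {a: list(50 + rng.normal(0, 3, 50)) for a in assays}
        for a in values:
            values[a][11] += 10.0
        ds = _cohort(values)
        report = flag_population_outliers(ds)
        burden = individual_burden(ds, report)
        assert burden.anova_p < 0.001
        assert burden.max_count_sample == "ind11"

    def test_single_assay_rejected(self):
        ds = _cohort({"A": [40.0, 50.0, 60.0]})
        report = flag_population_outliers(ds)
        with pytest.raises(ValueError, match=">= 2"):
            individual_burden(ds, report)

    def test_null_p_values_uniform(self):
        # under the null the individual-effect p should be U(0,1)
        p_values = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            ds = _cohort({a: list(50 + rng.normal(0, 3, 12)) for a in "ABCDE"},
                         n_cpgs=1)
            report = flag_population_outliers(ds)
            p_values.append(individual_burden(ds, report).anova_p)
        ks = stats.kstest(p_values, "uniform")
        assert ks.pvalue > 0.01


def _mini_catalog_with_clusters(cluster_by_assay):
    return [
        cat.AssayDefinition(
            name=name, chromosome="1", position=i + 1,
            parental_mark=cat.ParentalMark.MATERNAL, timing=cat.Timing.GERMLINE,
            avg_somatic_methylation=50.0,
            location_category=cat.LocationCategory.PROMOTER,
            cpg_island=True, ctcf_class=cat.CtcfClass.NONE, cpg_density=5.0,
            cluster_id=cluster,
        )
        for i, (name, cluster) in enumerate(cluster_by_assay.items())
    ]


class TestCisClusterCorrelation:
    def test_identical_assays_give_r2_one(self):
        values = list(np.linspace(40, 60, 20))
        ds = _cohort({"A": values, "B": values})
        catalog = _mini_catalog_with_clusters({"A": "c1", "B": "c1"})
        result = cis_cluster_correlation(ds, catalog)
        assert result.max_r_squared == pytest.approx(1.0)

    def test_no_clusters_gives_empty_result(self):
        ds = _cohort({"A": [40.0, 50.0, 60.0], "B": [45.0, 50.0, 55.0]})
        catalog = _mini_catalog_with_clusters({"A": None, "B": None})
        result = cis_cluster_correlation(ds, catalog)
        assert result.empty and result.max_r_squared is None

    def test_independent_assays_rarely_exceed_point_two(self):
        catalog = _mini_catalog_with_clusters({"A": "c1", "B": "c1"})
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ds = _cohort({"A": list(50 + rng.normal(0, 3, 50)),
                          "B": list(50 + rng.normal(0, 3, 50))}, n_cpgs=1)
            result = cis_cluster_correlation(ds, catalog)
            if result.max_r_squared < 0.2:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_synthetic_cohort_clusters_uncorrelated(self):
        config = default_blood_cohort_config(seed=31)
        dataset, _ = generate_blood_cohort(config)
        catalog = _mini_catalog_with_clusters(
            {a.name: a.cluster_id for a in config.assays}
        )
        result = cis_cluster_correlation(dataset, catalog)
        assert not result.empty
        assert result.max_r_squared < 0.5


class TestTreatmentReduction:
    def test_half_loss(self):
        result = treatment_reduction({"A": 50.0}, {"#1": {"A": 25.0}})
        assert result.records[0].percent_reduction == pytest.approx(50.0)

    def test_no_change(self):
        result = treatment_reduction({"A": 40.0}, {"#1": {"A": 40.0}})
        assert result.records[0].percent_reduction == pytest.approx(0.0)

    def test_gain_reports_negative_reduction(self):
        result = treatment_reduction({"A": 50.0}, {"#1": {"A": 60.0}})
        assert result.records[0].percent_reduction == pytest.approx(-20.0)

    def test_zero_control_flagged_undefined(self):
        result = treatment_reduction({"A": 0.0}, {"#1": {"A": 5.0}})
        assert math.isnan(result.records[0].percent_reduction)

    def test_invariant_under_common_rescaling(self):
        base = treatment_reduction({"A": 60.0}, {"#1": {"A": 30.0}})
        scaled = treatment_reduction({"A": 30.0}, {"#1": {"A": 15.0}})
        assert base.records[0].percent_reduction == pytest.approx(
            scaled.records[0].percent_reduction
        )

    def test_replicate_range_reported(self):
        result = treatment_reduction(
            {"A": 50.0}, {"#1": {"A": 25.0}},
            replicate_pairs={"#1": {"A": [(50.0, 24.0), (50.0, 26.0)]}},
        )
        assert result.records[0].reduction_range == (48.0, 52.0)

    def test_missing_control_assay_rejected(self):
        with pytest.raises(KeyError):
            treatment_reduction({"A": 50.0}, {"#1": {"B": 25.0}})
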