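"""Window derivation, classification, variability tests and feature associations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintqc import catalog as cat
from imprintqc.dmr import (
    DmrWindow,
    MethylationCategory,
    classify_dataset,
    classify_value,
    compare_parental_variability,
    cpg_density,
    derive_dmr_window,
    feature_association,
    intra_cpg_sd,
    intra_cpg_variability,
    tissue_deviation_test,
)
from imprintqc.simulate import default_tissue_panel_config, generate_tissue_panel

PRINTED_WINDOW = DmrWindow.from_bounds(35.73, 65.03)


class TestDeriveWindow:
    def test_printed_bounds_from_center_and_spread(self):
        # readings whose mean is 50.38 and sample SD (65.03 - 50.38) / 1.5
        spread = (65.03 - 50.38) / 1.5
        readings = [50.38 - spread, 50.38, 50.38 + spread]
        window = derive_dmr_window(readings, k=1.5)
        assert window.center == pytest.approx(50.38)
        assert window.lower_rounded == 35.73
        assert window.upper_rounded == 65.03

    def test_zero_spread(self):
        window = derive_dmr_window([50, 50, 50], k=1.5)
        assert (window.lower, window.upper) == (50.0, 50.0)

    def test_sample_sd_with_k_one(self):
        window = derive_dmr_window([40, 50, 60], k=1.0)
        assert window.spread == pytest.approx(10.0)
        assert (window.lower, window.upper) == (40.0, 60.0)

    def test_single_reading_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            derive_dmr_window([50.0])

    @given(st.floats(0.1, 1.4), st.floats(1.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_window_monotone_in_k(self, k1, k2):
        readings = [41.2, 48.8, 52.5, 57.1, 49.9]
        small = derive_dmr_window(readings, k=k1)
        large = derive_dmr_window(readings, k=k2)
        assert large.lower <= small.lower and small.upper <= large.upper


class TestClassifyValue:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (45.23, MethylationCategory.DIFFERENTIAL),    # H19 average
            (12.07, MethylationCategory.HYPOMETHYLATED),  # CDKN1C
            (88.27, MethylationCategory.HYPERMETHYLATED), # RTL
            (35.73, MethylationCategory.DIFFERENTIAL),    # bounds inclusive
            (65.03, MethylationCategory.DIFFERENTIAL),
        ],
    )
    def test_printed_averages(self, value, expected):
        assert classify_value(value, PRINTED_WINDOW) is expected

    @given(st.floats(0, 100, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_and_mutually_exclusive(self, value):
        category = classify_value(value, PRINTED_WINDOW)
        assert category in MethylationCategory
        below = value < PRINTED_WINDOW.lower
        above = value > PRINTED_WINDOW.upper
        assert category is (
            MethylationCategory.HYPOMETHYLATED if below
            else MethylationCategory.HYPERMETHYLATED if above
            else MethylationCategory.DIFFERENTIAL
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_value(101.0, PRINTED_WINDOW)


def _flat_dataset(values_by_assay_tissue):
    rows = []
    for (assay, tissue), value in values_by_assay_tissue.items():
        for cpg in (1, 2, 3):
            rows.append((assay, f"{tissue}_s", cpg, value, tissue))
    return cat.MethylationDataset(
        pd.DataFrame(rows, columns=["assay", "sample", "cpg_index", "percent", "tissue"])
    )


class TestClassifyDataset:
    def test_ever_differential_flags(self):
        ds = _flat_dataset({("A", t): 50.0 for t in ("brain", "liver")}
                           | {("B", t): 90.0 for t in ("brain", "liver")})
        table = classify_dataset(ds, PRINTED_WINDOW)
        assert table.ever_differential == {"A": True, "B": False}
        assert table.never_differential == ["B"]

    def test_single_tissue_differential_counts(self):
        # differential in brain only, as at brain-restricted somatic DMRs
        values = {("N", t): 70.0 for t in ("breast", "colon", "heart", "kidney",
                                           "liver", "placenta", "testis")}
        values[("N", "brain")] = 50.0
        table = classify_dataset(_flat_dataset(values), PRINTED_WINDOW)
        assert table.ever_differential["N"]
        diff_rows = table.table[table.table["category"] == MethylationCategory.DIFFERENTIAL]
        assert list(diff_rows["tissue"]) == ["brain"]

    def test_recovers_truth_categories_at_low_noise(self):
        config = default_tissue_panel_config(seed=9)
        dataset, truth = generate_tissue_panel(config)
        table = classify_dataset(dataset, PRINTED_WINDOW)
        observed = {(r.assay, r.tissue): r.category
                    for r in table.table.itertuples(index=False)}
        expected = truth.categorize(PRINTED_WINDOW, config.tissues)
        assert observed == expected


class TestIntraCpgSd:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([50, 50, 50], 0.0),
            ([40, 50, 60], 10.0),
            ([48, 52], math.sqrt(8.0)),  # sample SD of two points 4 apart
        ],
    )
    def test_sample_sd(self, values, expected):
        assert intra_cpg_sd(values) == pytest.approx(expected)

    def test_single_cpg_gives_missing(self):
        assert math.isnan(intra_cpg_sd([50.0]))


class TestParentalVariability:
    def _records(self, maternal_sds, paternal_sds):
        rows = []
        for i, (m, p) in enumerate(zip(maternal_sds, paternal_sds)):
            rows.append({"sample": f"s{i}", "parental_mark": "maternal",
                         "assay": "M", "intra_cpg_sd": m})
            rows.append({"sample": f"s{i}", "parental_mark": "paternal",
                         "assay": "P", "intra_cpg_sd": p})
        return pd.DataFrame(rows)

    def test_identical_classes_give_null_result(self):
        records = self._records([2.0, 2.5, 3.0], [2.0, 2.5, 3.0])
        result = compare_parental_variability(records, "by_sample")
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_single_sample_rejected_when_paired(self):
        records = self._records([2.0], [4.0])
        with pytest.raises(ValueError, match=">= 2 samples"):
            compare_parental_variability(records, "by_sample")

    def test_detects_doubled_paternal_sd(self):
        rng = np.random.default_rng(17)
        records = self._records(rng.normal(2.0, 0.3, 50), rng.normal(4.0, 0.6, 50))
        result = compare_parental_variability(records, "by_sample")
        assert result.p_value < 0.01

    def test_paired_t_matches_closed_form(self):
        records = self._records([2.1, 2.6, 1.9, 2.4], [4.8, 3.9, 5.2, 4.1])
        result = compare_parental_variability(records, "by_sample")
        diffs = np.array([2.1 - 4.8, 2.6 - 3.9, 1.9 - 5.2, 2.4 - 4.1])
        t_ref = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert result.statistic == pytest.approx(t_ref, abs=1e-10)


class TestTissueDeviation:
    def test_no_deviation_gives_null(self):
        ds = _flat_dataset({(a, t): 50.0 for a in ("A", "B", "C")
                            for t in ("brain", "liver", "testis")})
        result = tissue_deviation_test(ds, "testis")
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_testis_erasure_detected(self):
        config = default_tissue_panel_config(seed=13)
        dataset, _ = generate_tissue_panel(config)
        maternal_germline = [a.name for a in config.assays
                             if a.timing == "germline" and a.parental_mark == "maternal"]
        result = tissue_deviation_test(dataset, "testis", maternal_germline)
        assert result.p_value < 0.01

    def test_single_assay_rejected(self):
        ds = _flat_dataset({("A", "brain"): 50.0, ("A", "testis"): 10.0})
        with pytest.raises(ValueError, match="at least 2 assays"):
            tissue_deviation_test(ds, "testis")

    def test_missing_focal_tissue_rejected(self):
        ds = _flat_dataset({("A", "brain"): 50.0, ("B", "brain"): 60.0})
        with pytest.raises(ValueError, match="absent"):
            tissue_deviation_test(ds, "testis")


class TestCpgDensity:
    def test_constructed_29_cpg_window(self):
        # 29 CGs spaced every 17 bp fills just under 500 bp
        island = ("CG" + "A" * 15) * 29
        seq = "T" * 10 + island + "T" * 10
        midpoint = 10 + 250
        assert cpg_density(seq, midpoint, 250) == pytest.approx(5.8)

    def test_no_cpg_window(self):
        assert cpg_density("AT" * 300, 300, 250) == 0.0

    def test_saturated_window(self):
        assert cpg_density("CG" * 300, 300, 250) == pytest.approx(50.0)

    def test_window_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cpg_density("ACGT" * 10, 20, 250)

    def test_matches_brute_force_count_on_random_sequences(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=700))
            mid = int(rng.integers(260, 440))
            flank = int(rng.integers(50, 250))
            expected = sum(
                1 for i in range(mid - flank, mid + flank) if seq[i : i + 2] == "CG"
            ) / (2 * flank / 100)
            assert cpg_density(seq, mid, flank) == pytest.approx(expected, abs=1e-10)


def _mini_catalog(rows):
    return [
        cat.AssayDefinition(
            name=name, chromosome="1", position=i + 1,
            parental_mark=cat.ParentalMark.MATERNAL, timing=cat.Timing.GERMLINE,
            avg_somatic_methylation=meth,
            location_category=cat.LocationCategory(location),
            cpg_island=island, ctcf_class=cat.CtcfClass(ctcf), cpg_density=density,
        )
        for i, (name, meth, location, island, ctcf, density) in enumerate(rows)
    ]


class TestFeatureAssociation:
    def test_identical_ctcf_groups_give_p_one(self):
        rows = [(f"A{i}", 50.0, "promoter", True, ctcf, 5.0 + i)
                for i, ctcf in enumerate(["none", "none", "variable", "constitutive"])]
        result = feature_association(_mini_catalog(rows), "ctcf")
        assert result.p_value == pytest.approx(1.0)

    def test_density_r_squared_matches_closed_form(self, packaged_catalog):
        result = feature_association(packaged_catalog, "density")
        dens = np.array([a.cpg_density for a in packaged_catalog])
        meth = np.array([a.avg_somatic_methylation for a in packaged_catalog])
        r = np.corrcoef(dens, meth)[0, 1]
        assert result.r_squared == pytest.approx(r * r, abs=1e-12)

    def test_constant_density_rejected(self):
        rows = [(f"A{i}", 40.0 + i, "promoter", True, "none", 5.0) for i in range(4)]
        with pytest.raises(ValueError, match="constant predictor"):
            feature_association(_mini_catalog(rows), "density")

    def test_position_anova_drops_small_groups(self):
        rows = [("A1", 40.0, "promoter", True, "none", 5.0),
                ("A2", 45.0, "promoter", True, "none", 5.2),
                ("A3", 60.0, "intergenic", False, "none", 2.0),
                ("A4", 55.0, "intergenic", False, "none", 2.2),
                ("A5", 50.0, "gene_body_exonic", True, "none", 6.0)]
        with pytest.warns(UserWarning, match="dropped"):
            result = feature_association(_mini_catalog(rows), "position")
        assert result.n == 4
        assert 0 <= result.p_value <= 1

    def test_variable_and_constitutive_pool_as_binding(self, packaged_catalog):
        result = feature_association(packaged_catalog, "ctcf")
        n_binding = sum(a.ctcf_class is not cat.CtcfClass.NONE for a in packaged_catalog)
        assert result.group_means is not None
        binding_vals = [a.avg_somatic_methylation for a in packaged_catalog
                        if a.ctcf_class is not cat.CtcfClass.NONE]
        assert result.group_means["binding"] == pytest.approx(np.mean(binding_vals))
        assert n_binding == 24  # 14 variable + 10 constitutive in the full catalog
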