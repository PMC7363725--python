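"""Statistics tests: ICC against independent oracles, Pearson, ANOVA, reports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oralsurf.phantom import generate_rater_table
from oralsurf.stats import (
    AnovaResult,
    IccUndefinedError,
    MeasurementTable,
    aggregate_report,
    icc,
    interpret_correlation,
    interpret_icc,
    median_icc,
    one_way_anova,
    p_from_r,
    pearson_test,
    total_from_region_means,
)

TOY_TABLE = np.array(
    [
        [9.0, 10.0],
        [10.0, 12.0],
        [12.0, 11.0],
        [15.0, 16.0],
    ]
)


def oracle_icc_avg(x: np.ndarray) -> float:
    """Independent hand computation of the absolute-agreement average ICC."""
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((row.mean() - grand) ** 2 for row in x) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestIcc:
    def test_identical_columns_give_one(self):
        table = MeasurementTable(np.column_stack([[1.0, 5.0, 9.0]] * 2))
        assert icc(table).estimate == pytest.approx(1.0)

    def test_toy_table_matches_hand_oracle(self):
        result = icc(MeasurementTable(TOY_TABLE))
        assert result.estimate == pytest.approx(oracle_icc_avg(TOY_TABLE), rel=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        table = generate_rater_table(12, (1.0, 0.3, 0.2), 3, seed=8)
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": table.values.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="score")
        ref = ref.set_index("Type")["ICC"]
        assert icc(table, unit="average").estimate == pytest.approx(ref["ICC(A,k)"], abs=1e-9)
        assert icc(table, unit="single").estimate == pytest.approx(ref["ICC(A,1)"], abs=1e-9)

    def test_simulation_recovery(self):
        estimates = [
            icc(generate_rater_table(20, (1.0, 0.25, 0.25), 2, seed=s)).estimate
            for s in range(200)
        ]
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.05)

    def test_mixed_and_random_models_coincide(self):
        table = MeasurementTable(TOY_TABLE)
        assert icc(table, model="two_way_random").estimate == pytest.approx(
            icc(table, model="two_way_mixed").estimate
        )

    def test_rows_with_missing_cells_dropped_and_counted(self):
        values = np.vstack([TOY_TABLE, [np.nan, 3.0]])
        result = icc(MeasurementTable(values))
        assert result.n_dropped_rows == 1
        assert result.n_subjects == 4
        assert result.estimate == pytest.approx(oracle_icc_avg(TOY_TABLE), rel=1e-12)

    def test_constant_table_undefined(self):
        with pytest.raises(IccUndefinedError):
            icc(MeasurementTable(np.full((5, 2), 7.0)))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc(MeasurementTable(np.array([[1.0, 2.0]])))

    def test_shift_and_scale_invariance(self):
        base = icc(MeasurementTable(TOY_TABLE)).estimate
        shifted = icc(MeasurementTable(TOY_TABLE + 100.0)).estimate
        scaled = icc(MeasurementTable(TOY_TABLE * 3.5)).estimate
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_estimate_never_exceeds_one(self):
        for seed in range(25):
            table = generate_rater_table(10, (0.5, 0.5, 0.5), 2, seed=seed)
            assert icc(table).estimate <= 1.0


class TestInterpretIcc:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.77, "good"),
            (0.64, "moderate"),
            (0.95, "excellent"),
            (0.49, "poor"),
            (0.5, "moderate"),
            (0.75, "moderate"),
            (0.9, "good"),
            (0.91, "excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_bins(self, value, label):
        assert interpret_icc(value) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            interpret_icc(1.2)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        result = pearson_test(x, 3 * x + 2)
        assert result.r == pytest.approx(1.0)

    def test_p_brackets_for_reported_pairs(self):
        assert 0.040 <= p_from_r(0.59, 12) <= 0.050
        assert 0.030 <= p_from_r(0.50, 18) <= 0.040

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        mine = pearson_test(x, y)
        ref = sps.pearsonr(x, y)
        assert mine.r == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_affine_invariance_and_sign_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=15), rng.normal(size=15)
        base = pearson_test(x, y)
        transformed = pearson_test(2.0 * x + 7.0, 0.5 * y - 3.0)
        assert transformed.r == pytest.approx(base.r, rel=1e-9)
        flipped = pearson_test(x, -y)
        assert flipped.r == pytest.approx(-base.r, rel=1e-9)
        assert flipped.p == pytest.approx(base.p, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_pairwise_complete(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.1, np.nan]
        assert pearson_test(x, y).n == 3


class TestInterpretCorrelation:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.59, "moderate"),
            (0.50, "moderate"),
            (0.15, "negligible"),
            (0.3, "fair"),
            (0.85, "very strong"),
            (-0.6, "moderate"),
            (0.0, "negligible"),
        ],
    )
    def test_bins(self, r, label):
        assert interpret_correlation(r) == label


class TestAnova:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0]
        result = one_way_anova([g, list(g)])
        assert result.f == pytest.approx(0.0)
        assert result.p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 9)
        result = one_way_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert result.f == pytest.approx(t.statistic**2, rel=1e-10)
        assert result.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, size=n) for m, n in ((0, 8), (0.5, 10), (1.0, 7))]
        result = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert result.f == pytest.approx(ref.statistic, rel=1e-10)
        assert result.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_summary_equals_raw(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(0, 1, 9), rng.normal(1, 2, 11)]
        raw = one_way_anova(groups)
        summ = one_way_anova(
            summary=[(g.mean(), g.std(ddof=1), len(g)) for g in groups]
        )
        assert summ.f == pytest.approx(raw.f, rel=1e-10)
        assert summ.p == pytest.approx(raw.p, rel=1e-10)

    def test_mandibular_length_summary_verdict(self):
        # female (14.4, 0.47, 8) vs male (15.8, 0.56, 5): significant at 0.05,
        # agreeing with the reported highly significant difference
        result = one_way_anova(summary=[(14.4, 0.47, 8), (15.8, 0.56, 5)])
        assert result.significant
        assert result.p < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], [3.0]])

    def test_exactly_one_input_route(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2]], summary=[(1, 1, 2)])
        assert isinstance(one_way_anova(summary=[(1, 1, 5), (2, 1, 5)]), AnovaResult)


class TestAggregation:
    def test_total_from_region_means(self):
        means = {"palate": 20.0, "tongue": 35.2, "hard_tissue": 21.5, "mucosa": 96.6}
        assert total_from_region_means(means) == pytest.approx(173.3)

    def test_median_icc(self):
        assert median_icc([0.77, 0.90, 0.95, 0.95, 0.99]) == pytest.approx(0.95)

    def _demo_areas(self):
        rng = np.random.default_rng(9)
        subjects = [f"c{i}" for i in range(20)]
        areas = pd.DataFrame(
            {
                "palate": rng.normal(20, 3, 20),
                "tongue": rng.normal(35, 5, 20),
                "hard_tissue": rng.normal(21, 10, 20).clip(1),
                "mucosa": rng.normal(96, 12, 20),
            },
            index=subjects,
        )
        groups = {s: ("female" if i < 8 else "male" if i < 13 else None)
                  for i, s in enumerate(subjects)}
        return areas, groups

    def test_report_structure_and_conservation(self):
        areas, groups = self._demo_areas()
        tables = {
            name: generate_rater_table(20, (1.0, 0.05, 0.05), 2, seed=i)
            for i, name in enumerate(["palate", "tongue", "hard_tissue", "mucosa", "total"])
        }
        report = aggregate_report(areas, groups, tables)
        # total row mean equals the sum of region means
        region_means = {r: report.table.loc[r, "mean"] for r in
                        ("palate", "tongue", "hard_tissue", "mucosa")}
        assert report.table.loc["total", "mean"] == pytest.approx(
            total_from_region_means(region_means)
        )
        # per-subject totals are exact sums
        np.testing.assert_allclose(report.per_subject_totals, areas.sum(axis=1))
        # soft-tissue subtotal = total - hard tissue
        assert report.soft_tissue_subtotal_mean == pytest.approx(
            report.table.loc["total", "mean"] - report.table.loc["hard_tissue", "mean"]
        )
        assert report.icc_median == pytest.approx(
            np.median(report.table["icc"].dropna())
        )
        assert report.table.loc["total", "n_female"] == 8
        assert report.table.loc["total", "n_male"] == 5
        assert np.isfinite(report.table["anova_p"]).all()

    def test_unknown_group_excluded_from_contrast_kept_in_total(self):
        areas, groups = self._demo_areas()
        report = aggregate_report(areas, groups)
        assert report.table.loc["palate", "n"] == 20
        assert report.table.loc["palate", "n_female"] + report.table.loc[
            "palate", "n_male"
        ] == 13
        assert any("unknown group" in n for n in report.notes)

    def test_single_subject_group_sd_missing(self):
        areas = pd.DataFrame(
            {
                "palate": [20.0, 21.0, 22.0],
                "tongue": [35.0, 34.0, 36.0],
                "hard_tissue": [20.0, 22.0, 21.0],
                "mucosa": [95.0, 97.0, 96.0],
            },
            index=["a", "b", "c"],
        )
        report = aggregate_report(areas, {"a": "female", "b": "male", "c": "male"})
        assert np.isnan(report.table.loc["palate", "sd_female"])
        assert np.isnan(report.table.loc["palate", "anova_p"])  # female group too small

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report(pd.DataFrame(columns=["palate", "tongue", "hard_tissue", "mucosa"]))

    def test_json_export(self):
        areas, groups = self._demo_areas()
        payload = aggregate_report(areas, groups).to_json_dict()
        assert "rows" in payload and len(payload["rows"]) == 5
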