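import numpy as np
import pandas as pd
import pytest

from hetfx import metrics, regression_core, subgroup_analysis
from hetfx.empirical_bayes import shrink_all
from hetfx.subgroup_analysis import (
    ABS_ERROR_EDGES,
    SIGNED_ERROR_EDGES,
    DegenerateSplitError,
    ai_error_bin_analysis,
    assign_bins,
    bin_labels,
    combined_characteristics_split,
    high_prevalence_filter,
    median_split,
    oracle_split,
    subgroup_effect_report,
)
from hetfx.synthetic_data import AIErrorModel, SimConfig, generate_study

from conftest import make_bundle


class TestMedianSplit:
    def test_le_rule(self):
        assignment = median_split(pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]))
        assert assignment.groups.tolist() == ["low", "low", "high"]

    def test_experience_style_split(self):
        years = pd.Series([2, 4, 6, 6, 8, 10], index=list("abcdef"), dtype=float)
        assignment = median_split(years)
        # median 6; ties go low per the <=-median rule
        assert set(assignment.groups[assignment.groups == "low"].index) == {"a", "b", "c", "d"}

    def test_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            median_split(pd.Series([2.0, 2.0, 2.0]))

    def test_lt_tie_rule(self):
        assignment = median_split(pd.Series([1.0, 2.0, 2.0, 3.0]), tie_rule="lt")
        assert assignment.group_sizes == {"high": 3, "low": 1}


class TestOracleSplit:
    def _shrinkage(self, values):
        frame = pd.DataFrame(
            {
                "radiologist_id": [f"r{i}" for i in range(len(values))],
                "value": values,
                "se": [0.5] * len(values),
            }
        )
        return shrink_all(frame)

    def test_hand_partition(self):
        result = self._shrinkage([-1.0, -1.0, 1.0, 1.0])
        assignment = oracle_split(result)
        groups = assignment.groups
        assert set(groups[groups == "low"].index) == {"r0", "r1"}
        assert set(groups[groups == "high"].index) == {"r2", "r3"}

    def test_symmetric_values_equal_groups(self):
        assignment = oracle_split(self._shrinkage([-2.0, -1.0, 1.0, 2.0]))
        sizes = assignment.group_sizes
        assert sizes["low"] == sizes["high"] == 2

    def test_high_group_mean_not_lower(self):
        assignment = oracle_split(self._shrinkage([-2.0, 0.3, 1.0, 2.0]))
        result = self._shrinkage([-2.0, 0.3, 1.0, 2.0])
        post = result.posterior_means
        assert post[assignment.groups == "high"].mean() >= post[assignment.groups == "low"].mean()


class TestCombinedCharacteristicsSplit:
    def _profiles(self, n, thoracic):
        return pd.DataFrame(
            {
                "radiologist_id": [f"r{i}" for i in range(n)],
                "years_experience": np.tile([3.0, 9.0], n // 2),
                "thoracic_subspecialty": thoracic,
                "ai_experience": np.tile([0, 1], n // 2),
            }
        )

    def test_deterministic_given_seed(self):
        n = 40
        rng = np.random.default_rng(0)
        prof = self._profiles(n, rng.integers(0, 2, n))
        tes = pd.Series(rng.normal(size=n), index=prof["radiologist_id"])
        a1 = combined_characteristics_split(prof, tes, seed=9)
        a2 = combined_characteristics_split(prof, tes, seed=9)
        pd.testing.assert_series_equal(a1.groups, a2.groups)

    def test_planted_thoracic_signal_recovered(self):
        n = 40
        thoracic = np.tile([0, 1], n // 2)
        prof = self._profiles(n, thoracic)
        tes = pd.Series(thoracic.astype(float), index=prof["radiologist_id"])
        assignment = combined_characteristics_split(prof, tes, seed=2)
        expected = np.where(thoracic == 1, "high", "low")
        assert (assignment.groups.loc[prof["radiologist_id"]].to_numpy() == expected).all()

    def test_every_profiled_reader_assigned(self):
        n = 30
        rng = np.random.default_rng(1)
        prof = self._profiles(n, rng.integers(0, 2, n))
        tes = pd.Series(rng.normal(size=n), index=prof["radiologist_id"])
        assignment = combined_characteristics_split(prof, tes, seed=0)
        assert set(assignment.groups.index) == set(prof["radiologist_id"])
        assert len(assignment.details["folds"]) == 2

    def test_constant_column_dropped_with_warning(self, caplog):
        n = 20
        prof = self._profiles(n, np.zeros(n, dtype=int))  # thoracic constant
        rng = np.random.default_rng(2)
        tes = pd.Series(rng.normal(size=n), index=prof["radiologist_id"])
        with caplog.at_level("WARNING"):
            assignment = combined_characteristics_split(prof, tes, seed=0)
        assert any("constant" in rec.message for rec in caplog.records)
        for fold in assignment.details["folds"]:
            assert "thoracic" not in fold["columns"]


def _homogeneous_bundle(te=1.0, n_cases=40, seed=0):
    """Repeated-design reads where assisted error = unassisted - te exactly,
    with AI errors spread over the absolute bins."""
    rng = np.random.default_rng(seed)
    rows, truths, ai = [], [], []
    for r in ("r1", "r2"):
        for i in range(n_cases):
            case = f"c{i}"
            u = float(rng.uniform(te + 0.5, 20 + te))
            for assisted, err in ((0, u), (1, u - te)):
                rows.append(
                    {
                        "radiologist_id": r,
                        "case_id": case,
                        "pathology": "abnormal",
                        "design": "repeated",
                        "assisted": assisted,
                        "predicted_prob": 50 + err,
                    }
                )
    for i in range(n_cases):
        truths.append({"case_id": f"c{i}", "pathology": "abnormal", "truth_prob": 50.0})
        ai.append(
            {"case_id": f"c{i}", "pathology": "abnormal", "ai_prob": float((i * 97) % 101)}
        )
    return make_bundle(rows, truths, ai)


class TestBinAssignment:
    def test_boundaries(self):
        idx = assign_bins(np.array([0.0, 19.999, 20.0, 100.0]), ABS_ERROR_EDGES)
        assert idx.tolist() == [0, 0, 1, 4]

    def test_signed_edges_cover(self):
        idx = assign_bins(np.array([-100.0, -0.001, 0.0, 100.0]), SIGNED_ERROR_EDGES)
        assert idx.tolist() == [0, 4, 5, 9]

    def test_outside_span_errors(self):
        with pytest.raises(ValueError):
            assign_bins(np.array([101.0]), ABS_ERROR_EDGES)

    def test_non_monotone_edges_error(self):
        with pytest.raises(ValueError):
            assign_bins(np.array([1.0]), (0.0, 5.0, 5.0))

    def test_labels(self):
        assert bin_labels((0, 20, 100))[-1] == "[20,100]"


class TestAiErrorBinAnalysis:
    def test_homogeneous_effect_equal_bins_p_one(self):
        bundle = _homogeneous_bundle(te=1.0)
        result = ai_error_bin_analysis(bundle)
        np.testing.assert_allclose(result.table["te"], 1.0, atol=1e-9)
        assert result.joint_test.p_value == pytest.approx(1.0)
        assert result.table["n"].sum() == len(bundle.reads)

    def test_single_covering_bin_reproduces_overall_te(self):
        bundle = _homogeneous_bundle(te=2.5)
        result = ai_error_bin_analysis(bundle, edges=(0.0, 100.0))
        table = metrics.error_table(bundle)
        overall = regression_core.treatment_effect_model(table)
        assert result.table.loc[0, "te"] == pytest.approx(overall.extra["te"], abs=1e-9)

    def test_empty_bins_dropped_with_note(self):
        bundle = _homogeneous_bundle()
        # AI probs within [0, 100] and truth 50 -> ai abs error <= 51
        result = ai_error_bin_analysis(bundle, edges=(0.0, 60.0, 80.0, 100.0))
        assert "[60,80)" in result.dropped_bins or "[80,100]" in result.dropped_bins

    def test_bins_disjoint_and_ordered(self):
        bundle = _homogeneous_bundle()
        result = ai_error_bin_analysis(bundle)
        assert result.labels == [l for l in bin_labels(ABS_ERROR_EDGES) if l in result.labels]

    def test_mechanistic_bad_ai_hurts(self):
        # with readers leaning on the AI, worse AI bins have worse effects
        corrs = []
        for seed in range(3):
            cfg = SimConfig(
                n_readers_nonrepeated=40,
                n_readers_repeated=0,
                case_pool_size=200,
                pathology_prevalences={"abnormal": 0.5},
                ai_error_model=AIErrorModel(scale=100, dist="uniform"),
                mode="mechanistic",
                seed=40 + seed,
            )
            bundle, _ = generate_study(cfg)
            result = ai_error_bin_analysis(bundle)
            te = result.table["te"].to_numpy()
            ranks = np.arange(len(te))
            corrs.append(np.corrcoef(ranks, te)[0, 1])
        assert np.mean(corrs) < -0.5


class TestSubgroupEffectReport:
    def test_flipped_duplicate_labels_equalize(self):
        bundle = _homogeneous_bundle()
        readers = ["r1", "r2"]
        table = metrics.error_table(bundle)
        flipped = table.copy()
        flipped["radiologist_id"] = flipped["radiologist_id"].map({"r1": "r2b", "r2": "r1b"})
        flipped["case_id"] = flipped["case_id"] + "f"
        both = pd.concat([table, flipped], ignore_index=True)
        groups = pd.Series(
            {"r1": "g1", "r2": "g2", "r1b": "g2", "r2b": "g1"}, name="group"
        )
        assignment = subgroup_analysis.SubgroupAssignment(groups=groups, splitter="test")
        report = subgroup_effect_report(assignment, both)
        tes = report["subgroup_tes"]
        assert tes["g1"]["te"] == pytest.approx(tes["g2"]["te"])

    def test_oracle_report_includes_t_test(self, sim_bundle):
        bundle, _ = sim_bundle
        eff = metrics.reader_summaries(bundle)
        eff = eff[eff["condition"] == "effect"]
        shrinkage = shrink_all(eff)
        assignment = oracle_split(shrinkage)
        report = subgroup_effect_report(
            assignment, bundle, shrunk_tes=shrinkage.posterior_means
        )
        assert "t_test" in report
        assert report["shrunk_group_difference"] <= 0  # low minus high


class TestHighPrevalenceFilter:
    def _truths(self, prevalences, n=100):
        rows = []
        for label, prev in prevalences.items():
            for i in range(n):
                rows.append(
                    {
                        "case_id": f"c{i}",
                        "pathology": label,
                        "truth_prob": 90.0 if i < round(prev * n) else 10.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_above_threshold_included(self):
        truths = self._truths({"edema": 0.12})
        assert high_prevalence_filter(truths) == ["edema"]

    def test_exact_threshold_excluded(self):
        truths = self._truths({"edema": 0.10})
        assert high_prevalence_filter(truths) == []

    def test_all_zero(self):
        truths = self._truths({"edema": 0.0, "lesion": 0.0})
        assert high_prevalence_filter(truths) == []


def test_null_pvalues_roughly_uniform():
    """Random subgroup labels on null data: heterogeneity p-values are not
    concentrated near zero (small-scale calibration check)."""
    ps = []
    for seed in range(30):
        cfg = SimConfig(
            n_readers_nonrepeated=40,
            n_readers_repeated=0,
            case_pool_size=160,
            pathology_prevalences={"abnormal": 0.5},
            seed=700 + seed,
        )
        bundle, _ = generate_study(cfg)
        table = metrics.error_table(bundle)
        rng = np.random.default_rng(seed)
        readers = table["radiologist_id"].unique()
        labels = np.where(rng.permutation(len(readers)) < len(readers) // 2, "a", "b")
        groups = pd.Series(labels, index=readers)
        table["subgroup"] = groups.reindex(table["radiologist_id"]).to_numpy()
        fit = regression_core.subgroup_te_model(table)
        res = regression_core.wald_joint_equality(
            fit, [f"treatment:subgroup[{l}]" for l in fit.extra["levels"]]
        )
        ps.append(res.p_value)
    ps = np.asarray(ps)
    assert (ps < 0.05).mean() <= 0.2
    assert ps.mean() > 0.25
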