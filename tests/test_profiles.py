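import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfsubtypes import profiles
from csfsubtypes.profiles import (
    NON_SPECIFIC,
    NOT_DETECTED,
    SubtypeAssignment,
    celltype_specificity,
    compare_characteristics,
    detect_loading_outliers,
    label_proteins,
    overlap_coefficient,
    subtype_specific_proteins,
)


class TestLoadingOutliers:
    def _frame(self, values):
        return pd.DataFrame({"subtype1": values}, index=[f"s{i}" for i in range(len(values))])

    def test_homogeneous_loadings_clean(self, rng):
        loadings = self._frame(rng.uniform(0.4, 0.6, size=50))
        assert detect_loading_outliers(loadings) == []

    def test_extreme_loading_flagged(self, rng):
        values = list(rng.uniform(0.4, 0.6, size=49)) + [5.0]
        loadings = self._frame(values)
        x = np.array(values)
        med, mad = np.median(x), np.median(np.abs(x - np.median(x)))
        assert 0.6745 * (5.0 - med) / mad > 3.5  # robust-z oracle
        assert detect_loading_outliers(loadings) == ["s49"]

    def test_infinite_threshold_flags_nothing(self, rng):
        loadings = self._frame(list(rng.uniform(0, 1, 20)) + [100.0])
        assert detect_loading_outliers(loadings, threshold=np.inf) == []

    def test_mass_flagging_raises(self):
        # half the cohort far from the rest: refuse silent exclusion
        loadings = self._frame([0.5] * 6 + [50.0, 51.0, 52.0, 49.0])
        with pytest.raises(ValueError, match="refusing"):
            detect_loading_outliers(loadings, threshold=1.0)

    def test_assignment_disjointness_enforced(self):
        labels = pd.Series([1, 2], index=["a", "b"])
        loadings = pd.DataFrame({"subtype1": [1.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            SubtypeAssignment(labels=labels, loadings=loadings, outliers=["a"])


class TestLabelProteins:
    def test_argmax_of_subtype_means(self):
        matrix = pd.DataFrame(
            {"prot": [1.2, 1.2, 0.1, 0.1, -0.3, -0.3]},
            index=[f"s{i}" for i in range(6)],
        )
        labels = pd.Series([1, 1, 2, 2, 3, 3], index=matrix.index)
        assert label_proteins(matrix, labels)["prot"] == 1

    def test_tie_left_unlabelled(self):
        matrix = pd.DataFrame({"prot": [1.0, 1.0]}, index=["a", "b"])
        labels = pd.Series([1, 2], index=matrix.index)
        assert np.isnan(label_proteins(matrix, labels)["prot"])

    def test_clean_signature_recovered(self, clean_cohort):
        matrix = clean_cohort.protein_matrix
        assigned = label_proteins(matrix, clean_cohort.true_labels)
        for subtype, proteins in clean_cohort.signature.items():
            assert (assigned[proteins] == subtype).all()


class TestSubtypeSpecific:
    def test_strong_effect_detected_and_matches_permutation_oracle(self, rng):
        n = 90
        labels = pd.Series(np.repeat([1, 2, 3], 30), index=[f"s{i}" for i in range(n)])
        values = rng.standard_normal(n)
        values[:30] += 3.0  # 3 SD shift in subtype 1
        matrix = pd.DataFrame({"prot": values}, index=labels.index)
        result = subtype_specific_proteins(matrix, labels)
        assert result[1]["increased"] == ["prot"]
        # permutation oracle for each pairwise contrast
        for other in (2, 3):
            obs = values[:30].mean() - values[labels == other].mean()
            pooled = np.concatenate([values[:30], values[labels == other]])
            perm = []
            prng = np.random.default_rng(0)
            for _ in range(2000):
                shuffled = prng.permutation(pooled)
                perm.append(shuffled[:30].mean() - shuffled[30:].mean())
            p_perm = np.mean(np.abs(perm) >= abs(obs))
            assert p_perm < 0.05 and obs > 0

    def test_partial_elevation_excluded(self, rng):
        n = 90
        labels = pd.Series(np.repeat([1, 2, 3], 30), index=[f"s{i}" for i in range(n)])
        values = rng.standard_normal(n)
        values[:30] += 3.0
        values[30:60] += 3.0  # subtype 1 not higher than subtype 2
        matrix = pd.DataFrame({"prot": values}, index=labels.index)
        result = subtype_specific_proteins(matrix, labels)
        assert result[1]["increased"] == []

    def test_increased_and_decreased_disjoint(self, default_cohort):
        cohort = default_cohort
        result = subtype_specific_proteins(cohort.protein_matrix, cohort.true_labels)
        for sets in result.values():
            assert not set(sets["increased"]) & set(sets["decreased"])

    def test_signature_proteins_found(self, default_cohort):
        cohort = default_cohort
        result = subtype_specific_proteins(cohort.protein_matrix, cohort.true_labels)
        for subtype, proteins in cohort.signature.items():
            found = set(result[subtype]["increased"])
            assert len(found & set(proteins)) / len(proteins) > 0.9

    def test_small_subtype_skipped(self, rng):
        labels = pd.Series([1] * 20 + [2] * 20 + [3] * 2, index=[f"s{i}" for i in range(42)])
        matrix = pd.DataFrame({"prot": rng.standard_normal(42)}, index=labels.index)
        with pytest.warns(UserWarning, match="skipped"):
            result = subtype_specific_proteins(matrix, labels)
        assert 3 not in result

    def test_bh_correction_is_more_conservative(self, rng):
        n = 60
        labels = pd.Series(np.repeat([1, 2], 30), index=[f"s{i}" for i in range(n)])
        matrix = pd.DataFrame(
            rng.standard_normal((n, 200)), index=labels.index,
            columns=[f"p{j}" for j in range(200)],
        )
        matrix.iloc[:30, :5] += 2.0
        plain = subtype_specific_proteins(matrix, labels)
        bh = subtype_specific_proteins(matrix, labels, correction="bh")
        assert len(bh[1]["increased"]) <= len(plain[1]["increased"])


class TestOverlapCoefficient:
    def test_subset_gives_one(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b", "c", "d"}) == 1.0

    def test_disjoint_gives_zero(self):
        assert overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_enumerated_example(self):
        # |{p2,p3}| / min(3, 4) = 2/3
        value = overlap_coefficient({"p1", "p2", "p3"}, {"p2", "p3", "p4", "p5"})
        assert value == pytest.approx(2.0 / 3.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})

    @given(
        a=st.sets(st.integers(0, 9), min_size=1),
        b=st.sets(st.integers(0, 9), min_size=1),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        v = overlap_coefficient(a, b)
        assert v == overlap_coefficient(b, a)
        assert 0.0 <= v <= 1.0
        if a <= b or b <= a:
            assert v == 1.0


class TestCelltypeSpecificity:
    def test_dominant_neuron(self):
        row = pd.Series([0.6, 0.1, 0.1, 0.1, 0.1], index=profiles.pd.Index(
            ["neuron", "astrocyte", "oligodendrocyte", "microglia", "endothelial"]))
        assert celltype_specificity(row) == "neuron"

    def test_all_below_detection(self):
        row = pd.Series([0.1] * 5)
        assert celltype_specificity(row) == NOT_DETECTED

    def test_non_specific(self):
        row = pd.Series([0.4, 0.4, 0.2, 0.0, 0.0])
        assert celltype_specificity(row) == NON_SPECIFIC

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            celltype_specificity(pd.Series([-0.1, 1.0, 0.0, 0.0, 0.0]))

    def test_detection_threshold_applies_to_raw_levels(self):
        # same shares, different scale: the rule must change at the raw
        # detection threshold, not on shares
        low = pd.Series([0.1, 0.1, 0.1, 0.1, 0.1])
        high = low * 10
        assert celltype_specificity(low) == NOT_DETECTED
        assert celltype_specificity(high) == NON_SPECIFIC

    def test_scale_invariant_above_threshold(self, rng):
        for _ in range(20):
            row = pd.Series(rng.uniform(0.25, 3.0, size=5))
            assert celltype_specificity(row) == celltype_specificity(row * 7.5)

    def test_recovers_generator_truth(self):
        from csfsubtypes.synthetic import generate_celltype_reference

        table, truth = generate_celltype_reference(100, seed=9)
        labels = table.apply(celltype_specificity, axis=1)
        assert (labels == truth).all()


class TestCompareCharacteristics:
    def test_chi_square_hand_computed(self):
        labels = pd.Series([1] * 30 + [2] * 30, index=[f"s{i}" for i in range(60)])
        sex = pd.Series(["f"] * 20 + ["m"] * 10 + ["f"] * 10 + ["m"] * 20, index=labels.index)
        report = compare_characteristics(labels, pd.DataFrame({"sex": sex}))
        # E = 15 in each cell; sum (O-E)^2/E = 4 * 25/15 = 6.667
        assert report["sex"]["kind"] == "chi2"
        assert report["sex"]["statistic"] == pytest.approx(20.0 / 3.0)

    def test_identical_groups_null(self, rng):
        labels = pd.Series([1] * 20 + [2] * 20, index=[f"s{i}" for i in range(40)])
        values = np.concatenate([rng.standard_normal(20)] * 2)
        report = compare_characteristics(labels, pd.DataFrame({"x": values}, index=labels.index))
        contrast = report["x"]["contrasts"]["1-2"]
        assert contrast["effect"] == pytest.approx(0.0, abs=1e-12)
        assert contrast["p"] == pytest.approx(1.0)

    def test_marginal_means_equal_group_means_when_balanced(self, rng):
        labels = pd.Series(np.repeat([1, 2, 3], 10), index=[f"s{i}" for i in range(30)])
        values = pd.Series(rng.standard_normal(30) + labels.to_numpy(), index=labels.index)
        report = compare_characteristics(labels, pd.DataFrame({"x": values}))
        for subtype in (1, 2, 3):
            assert report["x"]["marginal_means"][subtype] == pytest.approx(
                values[labels == subtype].mean()
            )

    def test_constant_covariate_skipped(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        report = compare_characteristics(labels, pd.DataFrame({"x": [1.0] * 4}, index=labels.index))
        assert report["x"]["kind"] == "skipped"

    def test_control_standardization_excludes_age(self, rng):
        idx = [f"s{i}" for i in range(40)]
        labels = pd.Series([1] * 20 + [2] * 20, index=idx)
        cov = pd.DataFrame(
            {"age": rng.uniform(60, 80, 40), "tau": rng.normal(300, 50, 40)}, index=idx
        )
        report = compare_characteristics(labels, cov, control_ids=idx[:10])
        ctrl = cov["tau"].iloc[:10]
        expected = ((cov["tau"] - ctrl.mean()) / ctrl.std(ddof=1)).groupby(labels).mean()
        for subtype in (1, 2):
            assert report["tau"]["marginal_means"][subtype] == pytest.approx(expected[subtype])
        # age stays on its raw scale
        assert report["age"]["marginal_means"][1] == pytest.approx(
            cov["age"][labels == 1].mean()
        )
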