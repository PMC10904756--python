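"""Validation protocol: folds, metrics, ablation, downsampling, sweep."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_recall_fscore_support

import trunkphenix as tp
from trunkphenix.evaluation import _block_factors, convert_annotations
from conftest import RAW_CONFIG, SMALL_CONFIG, oracle_block_majority, oracle_block_mean


class TestEnumerateFolds:
    @pytest.mark.parametrize("n, expected", [(12, 66), (3, 3), (5, 10)])
    def test_fold_count_is_n_choose_2(self, n, expected):
        ids = [f"v{i}" for i in range(n)]
        folds = tp.enumerate_folds(ids)
        assert len(folds) == expected
        # brute-force pair enumeration
        assert {f.test for f in folds} == set(itertools.combinations(sorted(ids), 2))

    def test_folds_partition_cohort(self):
        folds = tp.enumerate_folds(["a", "b", "c", "d"])
        for f in folds:
            assert set(f.train) | set(f.test) == {"a", "b", "c", "d"}
            assert not set(f.train) & set(f.test)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            tp.enumerate_folds(["a", "a", "b"])


class TestComputeMetrics:
    def test_diagonal_matrix_is_perfect(self):
        cm = np.diag([5, 5, 9, 4, 2])
        report = tp.compute_metrics(cm)
        assert report.accuracy == 1.0
        np.testing.assert_allclose(report.f1, 1.0)

    def test_two_class_hand_arithmetic(self):
        report = tp.compute_metrics(np.array([[8, 2], [1, 9]]), class_names=("intact", "degraded"))
        assert report.accuracy == pytest.approx(0.85)
        # class 2 ("degraded"): p = 9/11, r = 9/10, F1 = 2pr/(p+r) = 18/21
        assert report.f1[1] == pytest.approx(2 * (9 / 11) * (9 / 10) / (9 / 11 + 9 / 10))

    def test_precision_half_recall_one_gives_two_thirds(self):
        # one class with p=0.5, r=1.0 -> F1 = 2/3
        cm = np.array([[5, 0], [5, 5]])
        report = tp.compute_metrics(cm, class_names=("a", "b"))
        assert report.precision[0] == pytest.approx(0.5)
        assert report.recall[0] == pytest.approx(1.0)
        assert report.f1[0] == pytest.approx(2 / 3)

    def test_absent_class_undefined_not_zero(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[2, 2] = 10
        cm[3, 2] = 1
        report = tp.compute_metrics(cm)
        assert np.isnan(report.f1[tp.CLASS_CODES["white_rot"]])
        assert report.f1[tp.CLASS_CODES["degraded"]] == 0.0  # present but never recovered

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            tp.compute_metrics(np.zeros((5, 5), dtype=int))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=25, max_size=25))
    def test_matches_sklearn_on_random_matrices(self, flat):
        cm = np.array(flat).reshape(5, 5)
        if cm.sum() == 0:
            cm[0, 0] = 1
        report = tp.compute_metrics(cm)
        # reconstruct label vectors and use sklearn as the independent oracle
        y_true, y_pred = [], []
        for i in range(5):
            for j in range(5):
                y_true.extend([i] * cm[i, j])
                y_pred.extend([j] * cm[i, j])
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(5), zero_division=0.0)
        present = [(cm[i].sum() + cm[:, i].sum()) > 0 for i in range(5)]
        for i in range(5):
            if present[i]:
                assert report.precision[i] == pytest.approx(p[i])
                assert report.recall[i] == pytest.approx(r[i])
                assert report.f1[i] == pytest.approx(f1[i])
            else:
                assert np.isnan(report.f1[i])
        assert report.accuracy == pytest.approx(np.mean(np.array(y_true) == np.array(y_pred)))


@pytest.fixture(scope="module")
def noiseless_cv():
    import dataclasses
    from conftest import SMALL_SPEC
    spec = dataclasses.replace(SMALL_SPEC, noise_sd=0.0)
    cohort = tp.generate_cohort(4, spec, seed=6)
    anns = {r.specimen_id: tp.sample_annotations(r, n_sections=8, per_class_cap=80, seed=2)
            for r in cohort}
    result = tp.run_cross_validation(cohort, anns, feature_config=RAW_CONFIG,
                                     hyperparams=tp.Hyperparams(n_trees=15), seed=1)
    return cohort, anns, result


class TestCrossValidation:
    def test_noiseless_phantoms_classified_perfectly(self, noiseless_cv):
        _, _, result = noiseless_cv
        assert result.report.accuracy == 1.0

    def test_fold_aggregation_conserved_exactly(self, noiseless_cv):
        _, _, result = noiseless_cv
        np.testing.assert_array_equal(np.sum(result.fold_matrices, axis=0),
                                      result.global_matrix)

    def test_each_specimen_tested_n_minus_1_times(self, noiseless_cv):
        _, anns, result = noiseless_cv
        total = sum(cm.sum() for cm in result.fold_matrices)
        n = len(anns)
        assert total == (n - 1) * sum(len(a) for a in anns.values())

    def test_no_test_leakage_in_training_metadata(self, noiseless_cv):
        _, _, result = noiseless_cv
        for fold, meta in zip(result.folds, result.fold_models_meta):
            assert set(meta["specimens"]) == set(fold.train)

    def test_noisy_small_cohort_reaches_high_f1(self, small_cohort, small_annotations):
        result = tp.run_cross_validation(small_cohort, small_annotations,
                                         feature_config=SMALL_CONFIG,
                                         hyperparams=tp.Hyperparams(n_trees=25), seed=4)
        for name in tp.TISSUE_CLASSES:
            assert result.report.f1[tp.CLASS_CODES[name]] >= 0.90

    def test_single_class_specimen_rejected(self, small_cohort, small_annotations):
        anns = dict(small_annotations)
        sid = sorted(anns)[0]
        table = anns[sid].table
        anns[sid] = tp.AnnotationSet(table=table[table["class"] == "intact"])
        with pytest.raises(ValueError, match="fewer than 2"):
            tp.run_cross_validation(small_cohort, anns, feature_config=RAW_CONFIG)


@pytest.fixture(scope="module")
def ablation_table(small_cohort, small_annotations):
    return tp.ablate_modalities(small_cohort, small_annotations,
                                feature_config=RAW_CONFIG,
                                hyperparams=tp.Hyperparams(n_trees=15), seed=2)


class TestAblation:
    def test_fifteen_subsets(self, ablation_table):
        assert len(ablation_table) == 15
        assert len(set(ablation_table["modalities"])) == 15

    def test_f1_values_in_unit_interval(self, ablation_table):
        cols = [f"f1_{n}" for n in tp.TISSUE_CLASSES]
        values = ablation_table[cols].to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_xray_alone_detects_white_rot_when_mri_is_blind(self):
        """White rot separable only in X-ray: {Xray} rivals {T1w, Xray}."""
        import dataclasses
        from conftest import SMALL_SPEC
        model = tp.default_signal_model()
        mean = model.mean.copy()
        for m in ("T1w", "T2w", "PDw"):
            mean.loc["white_rot", m] = mean.loc["degraded", m] * 0.995
        blind = tp.SignalModel(mean=mean, sd=model.sd)
        cohort = tp.generate_cohort(4, SMALL_SPEC, seed=12, model=blind)
        anns = {r.specimen_id: tp.sample_annotations(r, n_sections=10, per_class_cap=120, seed=3)
                for r in cohort}
        table = tp.ablate_modalities(cohort, anns, feature_config=SMALL_CONFIG,
                                     hyperparams=tp.Hyperparams(n_trees=25), seed=5)
        table = table.set_index("modalities")
        xray = table.loc["Xray", "f1_white_rot"]
        both = table.loc["T1w+Xray", "f1_white_rot"]
        assert xray == pytest.approx(both, abs=0.03)


class TestDownsampling:
    def test_factor_one_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 6, 6))
        out, spacing = tp.downsample_intensity(v, (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(out, v)
        assert spacing == (1.0, 1.0, 1.0)

    def test_constant_volume_stays_constant(self):
        v = np.full((7, 7, 7), 3.25)
        out, _ = tp.downsample_intensity(v, 3.0, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out, 3.25)

    def test_2x2x2_block_mean(self):
        v = np.arange(8, dtype=float).reshape(2, 2, 2)
        out, _ = tp.downsample_intensity(v, 2.0, (1.0, 1.0, 1.0))
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(3.5)

    def test_finer_target_rejected(self):
        with pytest.raises(ValueError):
            tp.downsample_intensity(np.zeros((4, 4, 4)), 0.5, (1.0, 1.0, 1.0))

    def test_majority_vote_block(self):
        labels = np.zeros((2, 2, 2), dtype=np.uint8)
        labels.ravel()[:3] = 3          # {0 x 5, 3 x 3} -> 0 wins
        out, _ = tp.downsample_labels(labels, 2.0, (1.0, 1.0, 1.0))
        assert out[0, 0, 0] == 0
        labels.ravel()[:5] = 3          # majority 3
        out, _ = tp.downsample_labels(labels, 2.0, (1.0, 1.0, 1.0))
        assert out[0, 0, 0] == 3

    def test_tie_breaks_to_lower_code(self):
        labels = np.array([1, 1, 4, 4], dtype=np.uint8).reshape(1, 1, 4)
        out, _ = tp.downsample_labels(labels, (1.0, 1.0, 4.0), (1.0, 1.0, 1.0))
        assert out[0, 0, 0] == 1

    def test_random_volume_matches_block_oracles(self):
        rng = np.random.default_rng(42)
        labels = rng.integers(0, 5, size=(12, 12, 12)).astype(np.uint8)
        intensity = rng.normal(size=(12, 12, 12))
        for target in (2.0, 3.0, 5.0):
            factors = _block_factors(target, (1.0, 1.0, 1.0))
            got_l, _ = tp.downsample_labels(labels, target, (1.0, 1.0, 1.0))
            np.testing.assert_array_equal(got_l, oracle_block_majority(labels, factors))
            got_i, _ = tp.downsample_intensity(intensity, target, (1.0, 1.0, 1.0))
            np.testing.assert_allclose(got_i, oracle_block_mean(intensity, factors), atol=1e-12)

    def test_rounded_factor_treats_near_native_as_identity(self):
        # 0.7 mm requested on a 0.68 mm grid is the native resolution
        assert _block_factors(0.7, (0.68, 0.68, 0.60)) == (1, 1, 1)


class TestAnnotationConversion:
    def test_blocks_merge_with_majority_label(self):
        table = pd.DataFrame({
            "specimen": ["s"] * 5,
            "x": [0, 1, 0, 4, 5], "y": [0, 0, 1, 0, 1], "z": [0, 0, 0, 0, 0],
            "class": ["intact", "intact", "degraded", "white_rot", "white_rot"],
        })
        converted = tp.convert_annotations(tp.AnnotationSet(table=table), (2, 2, 2))
        out = converted.table.set_index(["x", "y", "z"])["class"]
        assert out.loc[(0, 0, 0)] == "intact"      # 2 intact vs 1 degraded
        assert out.loc[(2, 0, 0)] == "white_rot"

    def test_block_label_read_from_coarse_volume_when_given(self):
        table = pd.DataFrame({"specimen": ["s"], "x": [0], "y": [0], "z": [0],
                              "class": ["white_rot"]})
        coarse = np.full((1, 1, 1), tp.CLASS_CODES["intact"], dtype=np.uint8)
        converted = tp.convert_annotations(tp.AnnotationSet(table=table), (2, 2, 2), coarse)
        assert converted.table["class"].iloc[0] == "intact"


class TestResolutionSweep:
    def test_native_entry_reproduces_plain_cv(self, small_cohort, small_annotations):
        plain = tp.run_cross_validation(small_cohort, small_annotations,
                                        feature_config=RAW_CONFIG,
                                        hyperparams=tp.Hyperparams(n_trees=15), seed=3)
        sweep = tp.resolution_sweep(small_cohort, small_annotations,
                                    spacings=[0.7, 3.0], feature_config=RAW_CONFIG,
                                    hyperparams=tp.Hyperparams(n_trees=15), seed=3)
        native = sweep.reports[0.7]
        np.testing.assert_array_equal(native.global_matrix, plain.global_matrix)
        coarse = sweep.reports[3.0]
        assert coarse.global_matrix.sum() < plain.global_matrix.sum()

    def test_non_ascending_spacings_rejected(self, small_cohort, small_annotations):
        with pytest.raises(ValueError):
            tp.resolution_sweep(small_cohort, small_annotations, spacings=[5.0, 2.0])
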