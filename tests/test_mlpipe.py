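import numpy as np
import pytest

from boneeis import (
    ClassifierSpec,
    FitOptions,
    InvalidArgumentError,
    SplitSpec,
    evaluate,
    predict,
    split,
    train,
)
from boneeis.pipeline import PipelineConfig, run_pipeline

CLASSES = (0, 20, 40, 60, 80, 100)
KINDS = ("logistic", "v_svm", "neural_network", "random_forest")

#: Reduced fit effort for pipeline-level tests; the spectra are
#: near-noiseless and start from a good heuristic guess.
FAST_FITS = FitOptions(n_restarts=2, max_iterations=800)


@pytest.fixture(scope="module")
def fast_pipeline_results():
    cfg = PipelineConfig(master_seed=7, fit_options=FAST_FITS)
    return run_pipeline(cfg)


class TestSplit:
    def test_default_design_70_train_21_test(self, default_dataset):
        spec = SplitSpec(seed=3)
        tr, te = split(default_dataset.labels, spec)
        assert len(tr) == 70 and len(te) == 21
        assert not set(tr) & set(te)
        labels = default_dataset.labels
        for lab, n_tr, n_te in zip(CLASSES, spec.train_per_class, spec.test_per_class):
            assert int((labels[tr] == lab).sum()) == n_tr
            assert int((labels[te] == lab).sum()) == n_te

    def test_seeds_change_membership_not_counts(self, default_dataset):
        tr1, te1 = split(default_dataset.labels, SplitSpec(seed=1))
        tr2, te2 = split(default_dataset.labels, SplitSpec(seed=2))
        assert len(tr1) == len(tr2) and len(te1) == len(te2)
        assert set(tr1) != set(tr2)

    def test_insufficient_class_rejected(self):
        labels = np.repeat(CLASSES, 12)
        spec = SplitSpec(train_per_class=(20,) * 6, test_per_class=(0,) * 6)
        with pytest.raises(InvalidArgumentError):
            split(labels, spec)


class TestTrainPredict:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_toy_training_accuracy(self, kind):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-1, 0.05, 10), rng.normal(1, 0.05, 10)])
        y = np.array([0] * 10 + [1] * 10)
        model = train(ClassifierSpec(kind=kind, seed=0), x[:, None], y)
        assert (predict(model, x[:, None]) == y).all()

    @pytest.mark.parametrize("kind", KINDS)
    def test_deterministic_given_spec_data_seed(self, kind):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 3))
        y = rng.integers(0, 3, 40)
        y[:3] = [0, 1, 2]  # ensure all classes present
        preds = [
            predict(train(ClassifierSpec(kind=kind, seed=5), x, y), x)
            for _ in range(2)
        ]
        assert np.array_equal(preds[0], preds[1])

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            train(ClassifierSpec(kind="logistic"), np.ones((5, 2)), np.zeros(5))

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ClassifierSpec(kind="svm")


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat(CLASSES, 2)
        rep = evaluate(y, y, CLASSES)
        assert rep.accuracy == 1.0 and rep.precision == 1.0
        assert np.array_equal(rep.confusion, np.diag([2] * 6))

    def test_hand_computed_three_class_confusion(self):
        # confusion [[2,1,0],[0,3,0],[1,0,2]] by construction
        actual = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        pred = [0, 0, 1, 1, 1, 1, 0, 2, 2]
        rep = evaluate(pred, actual, (0, 1, 2))
        assert np.array_equal(rep.confusion, [[2, 1, 0], [0, 3, 0], [1, 0, 2]])
        assert rep.accuracy == pytest.approx(7 / 9)
        assert rep.per_class[0.0]["precision"] == pytest.approx(2 / 3)
        assert rep.per_class[1.0]["precision"] == pytest.approx(3 / 4)
        assert rep.per_class[2.0]["precision"] == pytest.approx(1.0)
        assert rep.precision == pytest.approx((3 * (2 / 3) + 3 * (3 / 4) + 3 * 1) / 9)

    def test_constant_prediction_on_balanced_truth(self):
        actual = np.repeat(CLASSES, 2)
        rep = evaluate(np.zeros(12), actual, CLASSES)
        assert rep.accuracy == pytest.approx(1 / 6)

    def test_bookkeeping_trace_over_total(self):
        rng = np.random.default_rng(17)
        actual = rng.choice(CLASSES, 60)
        pred = rng.choice(CLASSES, 60)
        rep = evaluate(pred, actual, CLASSES)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum()
        )
        assert np.array_equal(
            rep.confusion.sum(axis=1),
            [int((actual == c).sum()) for c in CLASSES],
        )

    def test_contract_violations(self):
        with pytest.raises(InvalidArgumentError):
            evaluate([0, 1], [0], (0, 1))
        with pytest.raises(InvalidArgumentError):
            evaluate([0, 5], [0, 1], (0, 1))


class TestPipelineBehaviour:
    def test_all_classifiers_beat_chance(self, fast_pipeline_results):
        for mode in ("impedance_only", "combined"):
            for kind in KINDS:
                assert fast_pipeline_results[mode].reports[kind].accuracy > 1 / 6

    def test_combined_features_do_not_hurt_vsvm(self):
        """Adding fitted circuit parameters should not degrade nu-SVM
        accuracy (median over 5 master seeds)."""
        diffs = []
        for seed in range(5):
            cfg = PipelineConfig(
                master_seed=seed,
                fit_options=FAST_FITS,
                classifier_kinds=("v_svm",),
            )
            res = run_pipeline(cfg)
            diffs.append(
                res["combined"].reports["v_svm"].accuracy
                - res["impedance_only"].reports["v_svm"].accuracy
            )
        assert np.median(diffs) >= 0

    def test_master_seed_reproduces_whole_run(self):
        cfg = PipelineConfig(
            master_seed=3,
            fit_options=FAST_FITS,
            classifier_kinds=("v_svm",),
            feature_modes=("impedance_only",),
        )
        r1 = run_pipeline(cfg)
        r2 = run_pipeline(cfg)
        assert np.array_equal(
            r1["impedance_only"].reports["v_svm"].confusion,
            r2["impedance_only"].reports["v_svm"].confusion,
        )
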