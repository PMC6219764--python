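"""Training schedule semantics, network mechanics, view filtering, and
null-signal sanity of the small CNN."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from siteshift import stats
from siteshift.modeling import (
    ClassifierSpec,
    PlateauSchedule,
    TrainSchedule,
    TrainedClassifier,
    train_classifier,
    view_filter,
)
from siteshift.nn import SmallCAMNet
from siteshift.synthetic import GeneratorConfig, SiteProfile, generate_study_set
from siteshift.cohorts import split_by_patient
from siteshift.experiments import PNEUMONIA
from siteshift.modeling import multilabel_targets


class TestPlateauSchedule:
    def test_documented_loss_sequence(self):
        # improvement is relative to the best loss so far
        policy = PlateauSchedule(TrainSchedule())
        lrs, stops = [], []
        for loss in [1.0, 0.9, 0.95, 0.94, 0.93]:
            lr, _, stop = policy.step(loss)
            lrs.append(lr)
            stops.append(stop)
        # decays after epochs 3, 4 and 5; stops after epoch 5
        assert lrs == pytest.approx([0.01, 0.01, 0.001, 0.0001, 1e-05])
        assert stops == [False, False, False, False, True]

    def test_improvement_resets_stagnation(self):
        policy = PlateauSchedule(TrainSchedule())
        for loss in [1.0, 1.1, 1.2, 0.5, 0.6, 0.7]:
            _, _, stop = policy.step(loss)
        assert not stop  # two stagnant epochs since the reset at 0.5
        _, _, stop = policy.step(0.8)
        assert stop

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_reference_step_through(self, losses):
        schedule = TrainSchedule()
        policy = PlateauSchedule(schedule)
        # independent reference: lr = initial / factor^(number of decays)
        best = np.inf
        stagnant = 0
        decays = 0
        for loss in losses:
            lr, improved, stop = policy.step(loss)
            if loss < best:
                best = loss
                stagnant = 0
            else:
                stagnant += 1
                decays += 1
            assert improved == (stagnant == 0)
            assert lr == pytest.approx(
                schedule.initial_lr / schedule.lr_decay_factor ** decays
            )
            assert stop == (stagnant >= schedule.patience_stop)
            if stop:
                break

    def test_patience_validation(self):
        with pytest.raises(ValueError):
            TrainSchedule(patience_decay=3, patience_stop=1)


class TestNetworkMechanics:
    def test_identical_images_identical_outputs(self):
        net = SmallCAMNet(n_outputs=3, task="multiclass", seed=0)
        img = np.random.default_rng(0).random((64, 64)).astype(np.float32)
        batch = np.stack([img, img, img])
        probs = net.predict_proba(batch)
        np.testing.assert_allclose(probs[0], probs[1])
        np.testing.assert_allclose(probs[0], probs[2])

    def test_multiclass_rows_sum_to_one(self):
        net = SmallCAMNet(n_outputs=4, task="multiclass", seed=1)
        x = np.random.default_rng(1).random((5, 64, 64))
        np.testing.assert_allclose(net.predict_proba(x).sum(axis=1), 1.0, atol=1e-6)

    def test_multilabel_probabilities_bounded(self):
        net = SmallCAMNet(n_outputs=9, task="multilabel", seed=2)
        p = net.predict_proba(np.random.default_rng(2).random((4, 64, 64)))
        assert (p >= 0).all() and (p <= 1).all()

    def test_batch_vs_single_image_consistent(self):
        net = SmallCAMNet(n_outputs=2, task="multiclass", seed=3)
        x = np.random.default_rng(3).random((7, 64, 64)).astype(np.float32)
        batched = net.predict_logits(x, batch_size=7)
        single = np.stack([net.predict_logits(xi[None])[0] for xi in x])
        np.testing.assert_allclose(batched, single, atol=1e-5)

    def test_zero_image_zero_feature_map_at_init(self):
        net = SmallCAMNet(n_outputs=2, seed=4)
        fmap = net.final_feature_map(np.zeros((64, 64)))
        np.testing.assert_array_equal(fmap, 0.0)

    def test_input_size_mismatch_rejected(self):
        net = SmallCAMNet(n_outputs=2, seed=5)
        with pytest.raises(ValueError, match="64x64"):
            net.predict_proba(np.zeros((32, 32)))


def _tiny_training_set(n=220, seed=0, effect=0.25):
    config = GeneratorConfig(
        patients_per_site=n, studies_per_patient_mean=1.0,
        lateral_fraction=0.0, effect_size=effect, seed=seed,
    )
    records = generate_study_set(
        config, [SiteProfile(site_id="s", prevalence=0.4)]
    )
    x = np.stack([r.image for r in records])
    y = multilabel_targets(records)
    return x, y


class TestTrainClassifier:
    def test_empty_sets_rejected(self):
        spec = ClassifierSpec()
        with pytest.raises(ValueError):
            train_classifier(np.zeros((0, 64, 64)), np.zeros((0, 9)),
                             np.zeros((2, 64, 64)), np.zeros((2, 9)),
                             spec, TrainSchedule())

    def test_shuffled_labels_chance_auc(self):
        x, y = _tiny_training_set(n=240, seed=6)
        rng = np.random.default_rng(6)
        y_shuffled = y[rng.permutation(len(y))]
        model = train_classifier(
            x[:160], y_shuffled[:160], x[160:200], y_shuffled[160:200],
            ClassifierSpec(), TrainSchedule(max_epochs=6, seed=6),
        )
        scores = model.predict_proba(x[200:])[:, PNEUMONIA]
        labels = y_shuffled[200:, PNEUMONIA]
        est = stats.auc(stats.ScoredSet(scores, labels))
        assert abs(est.auc - 0.5) <= 0.25  # chance-level, wide band at n=40

    def test_training_log_and_best_params_kept(self):
        x, y = _tiny_training_set(n=150, seed=7)
        model = train_classifier(
            x[:100], y[:100], x[100:], y[100:],
            ClassifierSpec(), TrainSchedule(max_epochs=8, seed=7),
        )
        losses = [row["tune_loss"] for row in model.log]
        assert len(losses) <= 8
        # retained parameters reproduce the best tune loss
        assert model.net.tune_loss(x[100:], y[100:]) == pytest.approx(
            min(losses), abs=1e-6
        )

    def test_deterministic_given_seed(self):
        x, y = _tiny_training_set(n=100, seed=8)
        kwargs = dict(spec=ClassifierSpec(), schedule=TrainSchedule(max_epochs=3, seed=8))
        m1 = train_classifier(x[:70], y[:70], x[70:], y[70:], **kwargs)
        m2 = train_classifier(x[:70], y[:70], x[70:], y[70:], **kwargs)
        np.testing.assert_array_equal(
            m1.predict_proba(x[:10]), m2.predict_proba(x[:10])
        )

    def test_save_load_roundtrip(self, tmp_path):
        x, y = _tiny_training_set(n=80, seed=9)
        model = train_classifier(
            x[:50], y[:50], x[50:], y[50:],
            ClassifierSpec(), TrainSchedule(max_epochs=2, seed=9),
        )
        model.save(tmp_path / "ckpt")
        loaded = TrainedClassifier.load(tmp_path / "ckpt")
        np.testing.assert_allclose(
            model.predict_proba(x[:8]), loaded.predict_proba(x[:8]), atol=1e-7
        )
        assert loaded.log == model.log


class TestExtractFinalFeatures:
    def test_grid_shape_and_pooling_identity(self):
        x, y = _tiny_training_set(n=90, seed=10)
        model = train_classifier(
            x[:60], y[:60], x[60:], y[60:],
            ClassifierSpec(), TrainSchedule(max_epochs=2, seed=10),
        )
        features, heads = model.extract_final_features(x[0])
        assert features.grid == 8  # 64-pixel input, three poolings
        assert features.grid ** 2 == 64
        assert len(heads) == 9
        from siteshift.interpret import subregion_scores

        scores = subregion_scores(features, heads)
        logits = model.predict_logits(x[0][None])[0]
        np.testing.assert_allclose(
            scores.y.mean(axis=(1, 2)), logits, atol=1e-5
        )

    def test_batch_input_rejected(self):
        net = SmallCAMNet(n_outputs=2, seed=0)
        model = TrainedClassifier(net=net, spec=ClassifierSpec(task="multiclass", n_outputs=2),
                                  schedule=TrainSchedule())
        with pytest.raises(ValueError, match="single"):
            model.extract_final_features(np.zeros((2, 64, 64)))


class TestViewFilter:
    def test_distinct_silhouettes_high_accuracy(self):
        config = GeneratorConfig(
            patients_per_site=160, lateral_fraction=0.45, seed=12,
        )
        records = generate_study_set(
            config, [SiteProfile(site_id="s", prevalence=0.1)]
        )
        kept, accuracy = view_filter(
            records, labeled_sizes=(200, 100, 102),
            schedule=TrainSchedule(max_epochs=6, seed=12),
        )
        assert accuracy >= 0.98
        true_frontal = {r.study_id for r in records if r.view == "frontal"}
        kept_ids = {r.study_id for r in kept}
        agreement = len(kept_ids & true_frontal) / len(kept_ids)
        assert agreement >= 0.95

    def test_all_frontal_passthrough(self):
        config = GeneratorConfig(patients_per_site=20, lateral_fraction=0.0, seed=13)
        records = generate_study_set(config, [SiteProfile(site_id="s", prevalence=0.1)])
        kept, accuracy = view_filter(records)
        assert kept == records
        assert accuracy is None


class TestNullSignal:
    def test_zero_effect_size_gives_chance_auc(self):
        # two sites of 500 single-study images, no disease signal in either:
        # a trained CNN cannot separate pneumonia
        config = GeneratorConfig(
            patients_per_site=500, studies_per_patient_mean=1.0,
            lateral_fraction=0.0, effect_size=0.0, seed=1,
        )
        profiles = [
            SiteProfile(site_id="train_site", prevalence=0.3),
            SiteProfile(site_id="test_site", prevalence=0.3),
        ]
        records = generate_study_set(config, profiles)
        train = [r for r in records if r.site_id == "train_site"]
        test = [r for r in records if r.site_id == "test_site"]
        assignment = split_by_patient(train, fractions=(0.8, 0.2, 0.0), seed=1)
        tr = assignment.subset(train, "train")
        tu = assignment.subset(train, "tune")
        model = train_classifier(
            np.stack([r.image for r in tr]), multilabel_targets(tr),
            np.stack([r.image for r in tu]), multilabel_targets(tu),
            ClassifierSpec(), TrainSchedule(max_epochs=6, seed=1),
        )
        scores = model.predict_proba(np.stack([r.image for r in test]))[:, PNEUMONIA]
        labels = np.array([r.labels["pneumonia"] for r in test])
        est = stats.auc(stats.ScoredSet(scores, labels))
        assert abs(est.auc - 0.5) <= 0.05
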