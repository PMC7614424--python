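"""Training protocol, pretext pre-training and pipeline contract tests.

Heavier end-to-end learning behaviour (pretext recovery, pipeline
ordering) lives in the acceptance suite; here the contracts are exercised
on very small cohorts and short schedules.
"""

import numpy as np
import pandas as pd
import pytest

from petqc import (
    BackboneSpec,
    FreezePolicy,
    HeadSpec,
    UnavailableResourceError,
    build_backbone,
    make_cohort,
)
from petqc.training import (
    LabelledPatches,
    TrainConfig,
    cohort_patches,
    pretext_pretrain,
    pretext_target,
    run_pipeline,
    train,
)

SPEC = BackboneSpec(base_width=2, input_size=32)


def _toy_patches(rng, n, patients, target=lambda i: 0.7):
    x = rng.random((n, 3, 32, 32)).astype(np.float32)
    y = np.array([[target(i)] for i in range(n)], dtype=np.float32)
    pids = np.array([patients[i % len(patients)] for i in range(n)])
    return LabelledPatches(x=x, y=y, patient_ids=pids, fractions=np.full(n, 0.5))


class TestTrain:
    def test_constant_target_converges_near_zero(self, rng):
        model = build_backbone(SPEC, HeadSpec(kind="dose"), seed=0)
        tr = _toy_patches(rng, 40, ["A"])
        va = _toy_patches(rng, 10, ["B"])
        result = train(model, tr, va, TrainConfig(learning_rate=1e-3, max_epochs=30, seed=0))
        preds = result.model.predict(va.x)
        assert np.mean(np.abs(preds - 0.7)) < 0.05

    def test_history_and_checkpoint_selection_contract(self, rng):
        model = build_backbone(SPEC, HeadSpec(kind="dose"), seed=1)
        tr = _toy_patches(rng, 20, ["A"])
        va = _toy_patches(rng, 8, ["B"])
        cfg = TrainConfig(max_epochs=7, seed=1)
        result = train(model, tr, va, cfg)
        assert len(result.history) <= cfg.max_epochs
        assert result.best_epoch == int(result.history["val_loss"].idxmin())
        assert result.best_val_loss == result.history["val_loss"].min()

    def test_deterministic_given_seed(self, rng):
        losses = []
        for _ in range(2):
            model = build_backbone(SPEC, HeadSpec(kind="dose"), seed=2)
            tr = _toy_patches(np.random.default_rng(5), 20, ["A"], target=lambda i: i / 40)
            va = _toy_patches(np.random.default_rng(6), 8, ["B"], target=lambda i: i / 16)
            result = train(model, tr, va, TrainConfig(max_epochs=4, seed=3))
            losses.append(result.history["val_loss"].to_numpy())
        np.testing.assert_array_equal(losses[0], losses[1])

    def test_empty_sets_rejected(self, rng):
        model = build_backbone(SPEC, HeadSpec(kind="dose"), seed=0)
        empty = LabelledPatches(
            x=np.zeros((0, 3, 32, 32), dtype=np.float32),
            y=np.zeros((0, 1), dtype=np.float32),
            patient_ids=np.array([], dtype=str),
            fractions=np.array([]),
        )
        with pytest.raises(ValueError):
            train(model, empty, _toy_patches(rng, 4, ["B"]), TrainConfig())

    def test_overlapping_patients_rejected(self, rng):
        model = build_backbone(SPEC, HeadSpec(kind="dose"), seed=0)
        tr = _toy_patches(rng, 10, ["A", "B"])
        va = _toy_patches(rng, 4, ["B"])
        with pytest.raises(ValueError, match="split violation"):
            train(model, tr, va, TrainConfig())

    def test_divergent_learning_rate_aborts_with_diagnostic(self, rng):
        model = build_backbone(SPEC, HeadSpec(kind="dose"), seed=0)
        tr = _toy_patches(rng, 10, ["A"], target=lambda i: 1e4)
        va = _toy_patches(rng, 4, ["B"], target=lambda i: 1e4)
        with pytest.raises(RuntimeError, match="loss"):
            train(model, tr, va, TrainConfig(learning_rate=1e12, max_epochs=3))


class TestCohortPatches:
    def test_targets_and_provenance(self):
        cohort = make_cohort(2, 3, seed=4, shape=(48, 48, 40))
        data = cohort_patches(cohort, per_plane=4, size=32, seed=0, target="dose")
        assert len(data) == 2 * 3 * 12
        assert data.y.shape == (len(data), 1)
        # dose target equals fraction * full_counts / weight for each patch
        rec = {r.patient_id: r for r in cohort}
        for i in range(0, len(data), 13):
            r = rec[str(data.patient_ids[i])]
            expected = pretext_target(data.fractions[i], r.full_counts, r.weight_kg)
            assert data.y[i, 0] == pytest.approx(expected, rel=1e-5)

    def test_clinical_targets_are_score_triples(self):
        cohort = make_cohort(1, 3, seed=4, shape=(48, 48, 40))
        data = cohort_patches(cohort, per_plane=3, size=32, seed=0, target="clinical")
        assert data.y.shape[1] == 3
        scores = {df.fraction: df.scores for df in cohort[0].fractions}
        for i in range(len(data)):
            s = scores[float(data.fractions[i])]
            np.testing.assert_allclose(data.y[i], [s.gqr, s.pr, s.dc], atol=1e-6)


@pytest.fixture(scope="module")
def mini_pretext_cohort():
    return make_cohort(3, fractions_per_patient=7, seed=21, shape=(48, 48, 40), id_prefix="PTX")


class TestPretext:
    def test_val_patient_must_be_held_out(self, mini_pretext_cohort):
        with pytest.raises(ValueError, match="validation patient"):
            pretext_pretrain(
                mini_pretext_cohort, TrainConfig(max_epochs=1),
                val_patient=mini_pretext_cohort[0], spec=SPEC, per_plane=2,
            )

    def test_single_fraction_cohort_converges_to_constant(self):
        # one shared fraction, equal weights and counts: every target coincides
        cohort = make_cohort(3, fractions_per_patient=7, seed=30, shape=(48, 48, 40))
        for rec in cohort:
            rec.fractions = [df for df in rec.fractions if df.fraction == 0.25]
            rec.weight_kg = 75.0
            rec.full_counts = 200_000_000
        result = pretext_pretrain(
            cohort[:-1], TrainConfig(learning_rate=1e-3, max_epochs=10, seed=0),
            val_patient=cohort[-1], spec=SPEC, per_plane=3,
        )
        assert result.val_mae < 0.1

    def test_prediction_count_matches_val_patches(self, mini_pretext_cohort):
        result = pretext_pretrain(
            mini_pretext_cohort[:-1], TrainConfig(max_epochs=2, seed=1),
            val_patient=mini_pretext_cohort[-1], spec=SPEC, per_plane=2,
        )
        n_val = len(mini_pretext_cohort[-1].fractions) * 2 * 3
        preds = result.trained.model.predict(
            cohort_patches([mini_pretext_cohort[-1]], 2, 32, seed=9, target="dose").x
        )
        assert preds.shape == (n_val, 1)

    def test_target_scaling_modes(self, mini_pretext_cohort):
        for mode in ("log-minmax", "minmax"):
            res = pretext_pretrain(
                mini_pretext_cohort[:-1], TrainConfig(max_epochs=1, seed=0),
                val_patient=mini_pretext_cohort[-1], spec=SPEC, per_plane=2,
                target_scale=mode,
            )
            assert np.isfinite(res.val_mae)
        with pytest.raises(ValueError):
            pretext_pretrain(
                mini_pretext_cohort[:-1], TrainConfig(max_epochs=1),
                val_patient=mini_pretext_cohort[-1], spec=SPEC, per_plane=2,
                target_scale="robust",
            )


@pytest.fixture(scope="module")
def mini_clinical():
    cohort = make_cohort(5, fractions_per_patient=3, seed=22, shape=(48, 48, 40), id_prefix="CLN")
    return cohort[:3], cohort[3:4], cohort[4:]


class TestPipelines:
    def test_pipeline_c_conv_weights_fixed(self, mini_pretext_cohort, mini_clinical):
        tr, va, te = mini_clinical
        result = run_pipeline(
            "c", tr, va, te, pretext_cohort=mini_pretext_cohort,
            config=TrainConfig(max_epochs=3, seed=0), spec=SPEC, per_plane=3,
        )
        pretext_conv = result.pretext.trained.model.conv_params()
        final_conv = result.trained.model.conv_params()
        for key in pretext_conv:
            np.testing.assert_array_equal(pretext_conv[key], final_conv[key])

    def test_pipeline_a_trains_all_blocks(self, mini_clinical):
        tr, va, te = mini_clinical
        result = run_pipeline(
            "a", tr, va, te, config=TrainConfig(max_epochs=2, seed=0), spec=SPEC, per_plane=3,
        )
        assert result.trained.model.n_trainable_params == result.trained.model.n_params
        assert set(result.predictions["metric"]) == {"GQR", "PR", "DC"}
        assert result.predictions["predicted"].between(0, 3).all()

    def test_pipeline_b_without_weights_fails_explicitly(self, mini_clinical):
        tr, va, te = mini_clinical
        with pytest.raises(UnavailableResourceError):
            run_pipeline("b", tr, va, te, config=TrainConfig(max_epochs=1), spec=SPEC, per_plane=2)

    def test_empty_training_cohort_rejected(self, mini_clinical):
        _, va, te = mini_clinical
        with pytest.raises(ValueError):
            run_pipeline("a", [], va, te, config=TrainConfig(max_epochs=1), spec=SPEC)

    def test_patient_overlap_between_pretext_and_clinical_rejected(
        self, mini_pretext_cohort, mini_clinical
    ):
        tr, va, te = mini_clinical
        overlapping = mini_pretext_cohort + [tr[0]]
        with pytest.raises(ValueError, match="split violation"):
            run_pipeline(
                "c", tr, va, te, pretext_cohort=overlapping,
                config=TrainConfig(max_epochs=1), spec=SPEC, per_plane=2,
            )

    def test_predictions_are_image_level(self, mini_clinical):
        tr, va, te = mini_clinical
        result = run_pipeline(
            "a", tr, va, te, config=TrainConfig(max_epochs=1, seed=0), spec=SPEC, per_plane=3,
        )
        n_images = sum(len(r.fractions) for r in te)
        assert len(result.predictions) == n_images * 3  # one row per image and metric
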