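"""Phantom generator, count thinning and score-model tests."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from petqc import (
    AnatomyParams,
    ClinicalScores,
    ScoreModelParams,
    assign_scores,
    generate_phantom,
    load_cohort,
    make_cohort,
    normalize_volume,
    save_cohort,
    simulate_dose_fraction,
)
from petqc.synthetic_data import FRACTIONS, _quantise_half_up


class TestPhantom:
    def test_background_is_majority_zero(self):
        vol = generate_phantom(seed=1, shape=(64, 64, 48)).voxels
        assert np.mean(vol == 0) > 0.30

    def test_uptake_ordering_cortex_white_ventricle(self):
        anatomy = AnatomyParams(texture_amplitude=0.0)
        vol = generate_phantom(seed=2, shape=(64, 64, 48), anatomy=anatomy).voxels
        values = set(np.unique(vol)) - {0.0}
        assert values == {
            anatomy.cortex_uptake,
            anatomy.white_uptake,
            anatomy.ventricle_uptake,
        }

    def test_equal_uptakes_give_constant_head(self, flat_anatomy):
        vol = generate_phantom(seed=3, shape=(64, 64, 48), anatomy=flat_anatomy).voxels
        inside = vol[vol > 0]
        assert inside.size > 0
        assert np.allclose(inside, inside[0])

    def test_deterministic_given_seed(self):
        a = generate_phantom(seed=9, shape=(48, 48, 40)).voxels
        b = generate_phantom(seed=9, shape=(48, 48, 40)).voxels
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(shape=(16, 64, 48)),
            dict(shape=(64, 64)),
            dict(anatomy=AnatomyParams(white_uptake=-0.1)),
            dict(anatomy=AnatomyParams(cortex_uptake=0.0)),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_phantom(seed=0, **{"shape": (64, 64, 48), **kwargs})


class TestDoseThinning:
    def test_mean_total_counts_conserved(self, default_phantom):
        """Monte-Carlo: mean total over repeats within 3 SE of f * N."""
        full, frac, reps = 1_000_000, 1.0, 100
        totals = np.array(
            [
                simulate_dose_fraction(default_phantom, full, frac, seed=s).sum()
                for s in range(reps)
            ]
        )
        se = totals.std(ddof=1) / np.sqrt(reps)
        assert abs(totals.mean() - frac * full) < 3 * se

    def test_relative_noise_larger_at_low_fraction(self, default_phantom):
        """Per-voxel CoV over repeats is strictly larger at 0.5% than 100%."""
        brain = default_phantom.voxels > 0
        cov = {}
        for frac in (0.005, 1.0):
            stack = np.stack(
                [
                    simulate_dose_fraction(default_phantom, 10**6, frac, seed=1000 + r)
                    for r in range(50)
                ]
            )
            mean = stack.mean(axis=0)[brain]
            sd = stack.std(axis=0)[brain]
            ok = mean > 0
            cov[frac] = float(np.median(sd[ok] / mean[ok]))
        assert cov[0.005] > cov[1.0]

    def test_invalid_fraction_and_empty_activity_rejected(self, default_phantom):
        with pytest.raises(ValueError):
            simulate_dose_fraction(default_phantom, 1000, 0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_dose_fraction(default_phantom, 1000, 1.5, seed=0)
        with pytest.raises(ValueError):
            simulate_dose_fraction(np.zeros((32, 32, 32)), 1000, 0.5, seed=0)


class TestNormalize:
    def test_constant_volume_maps_to_ones(self):
        out = normalize_volume(np.full((4, 4, 4), 7.0))
        np.testing.assert_allclose(out, 1.0)

    def test_scaling_by_max(self, rng):
        vol = rng.uniform(0, 250, (8, 8, 8))
        vol.flat[0] = 250.0
        np.testing.assert_allclose(normalize_volume(vol), vol / 250.0)
        assert normalize_volume(vol).max() == 1.0

    def test_idempotent(self, rng):
        vol = rng.uniform(0, 5, (6, 6, 6))
        once = normalize_volume(vol)
        np.testing.assert_array_equal(normalize_volume(once), once)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_volume(np.zeros((4, 4, 4)))


class TestScoreModel:
    def test_scores_on_half_grid_and_clipped(self):
        for seed in range(50):
            s = assign_scores(fraction=1.0, weight_kg=70, seed=seed)
            for v in s.as_dict().values():
                assert 0.0 <= v <= 3.0
                assert v * 2 == round(v * 2)

    def test_clipping_at_top_of_scale(self):
        params = ScoreModelParams(
            noise_sd={"gqr": 0.0, "pr": 0.0, "dc": 0.0},
            slopes={"gqr": 5.0, "pr": 2.0, "dc": 1.5},
            intercepts={"gqr": 0.0, "pr": 0.0, "dc": 0.0},
        )
        s = assign_scores(1.0, 75.0, params=params, seed=0)
        assert s.gqr == 3.0

    def test_halfway_values_round_up(self):
        assert _quantise_half_up(1.25, 0.5) == 1.5
        assert _quantise_half_up(1.24, 0.5) == 1.0
        assert _quantise_half_up(2.75, 0.5) == 3.0

    def test_score_dose_association_strongest_for_gqr(self):
        """Spearman(score, log fraction) positive for all, highest for GQR."""
        rng = np.random.default_rng(0)
        rows = {m: [] for m in ("gqr", "pr", "dc")}
        fracs = []
        for i in range(200):
            frac = FRACTIONS[i % len(FRACTIONS)]
            s = assign_scores(frac, 75.0, seed=int(rng.integers(2**31)))
            fracs.append(np.log10(frac))
            for m, v in s.as_dict().items():
                rows[m].append(v)
        rho = {m: spearmanr(fracs, v).statistic for m, v in rows.items()}
        assert all(r > 0 for r in rho.values())
        assert rho["gqr"] == max(rho.values())

    def test_gqr_slope_noise_ratio_enforced(self):
        with pytest.raises(ValueError):
            ScoreModelParams(noise_sd={"gqr": 2.0, "pr": 0.1, "dc": 0.1})

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            assign_scores(0.0, 75.0)

    def test_clinical_scores_validate_grid(self):
        with pytest.raises(ValueError):
            ClinicalScores(gqr=1.3, pr=1.0, dc=1.0)
        with pytest.raises(ValueError):
            ClinicalScores(gqr=3.5, pr=1.0, dc=1.0)


class TestCohort:
    def test_seven_patients_three_fractions_is_21_volumes(self, tiny_cohort):
        cohort = make_cohort(7, fractions_per_patient=3, seed=1, shape=(48, 48, 40))
        assert sum(len(r.fractions) for r in cohort) == 21
        for rec in cohort:
            assert len(rec.fractions) == 3
            assert 45 <= rec.weight_kg <= 120
            for df in rec.fractions:
                assert df.fraction in FRACTIONS
                assert 0.0 <= df.volume.min() and df.volume.max() <= 1.0

    def test_single_patient_cohort_valid(self):
        cohort = make_cohort(1, fractions_per_patient=3, seed=2, shape=(48, 48, 40))
        assert len(cohort) == 1

    def test_cohort_deterministic(self):
        a = make_cohort(2, 3, seed=11, shape=(48, 48, 40))
        b = make_cohort(2, 3, seed=11, shape=(48, 48, 40))
        for ra, rb in zip(a, b):
            assert ra.weight_kg == rb.weight_kg
            for fa, fb in zip(ra.fractions, rb.fractions):
                assert fa.scores == fb.scores
                np.testing.assert_array_equal(fa.volume, fb.volume)

    def test_patients_are_not_identical(self, tiny_cohort):
        v0 = tiny_cohort[0].fractions[0].volume
        v1 = tiny_cohort[1].fractions[0].volume
        assert not np.array_equal(v0, v1)

    def test_seven_fraction_patients_cover_all_levels(self):
        cohort = make_cohort(1, fractions_per_patient=7, seed=3, shape=(48, 48, 40))
        assert tuple(df.fraction for df in cohort[0].fractions) == FRACTIONS

    def test_roundtrip_nifti_manifest(self, tiny_cohort, tmp_path):
        manifest = save_cohort(tiny_cohort, tmp_path)
        loaded = load_cohort(manifest)
        assert [r.patient_id for r in loaded] == [r.patient_id for r in tiny_cohort]
        for ra, rb in zip(tiny_cohort, loaded):
            for fa, fb in zip(ra.fractions, rb.fractions):
                assert fa.scores == fb.scores
                np.testing.assert_allclose(fa.volume, fb.volume, atol=1e-6)
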