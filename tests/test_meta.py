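"""Meta-analysis layer: normalisation, averaging, shifts, calibration."""

import dataclasses

import numpy as np
import pytest

from samtox import (
    DoseResponseDataset,
    GeneratorConfig,
    LL5Params,
    StressCapacityDistribution,
    StudyPair,
    average_curves,
    calibrate_shape,
    compute_env_mortality,
    effect_mortality,
    fit_study_pair,
    generate_meta_dataset,
    lc,
    ll5_survival,
    model_r2,
    normalize_curve,
    observed_shift,
    observed_shifts,
    overall_prediction,
)
from samtox.errors import CalibrationError, InputError
from samtox.meta import predicted_shifts_refit


class TestEnvMortality:
    @pytest.mark.parametrize(
        "env, ctrl, expected",
        [(0.9, 1.0, 0.10), (0.85, 0.85, 0.0), (0.72, 0.9, 0.20)],
    )
    def test_abbott_correction(self, env, ctrl, expected):
        assert compute_env_mortality(env, ctrl) == pytest.approx(expected, abs=1e-12)

    def test_clamped_and_validated(self):
        assert compute_env_mortality(0.95, 0.9) == 0.0  # better than control
        with pytest.raises(InputError):
            compute_env_mortality(0.9, 0.0)


class TestNormalizeCurve:
    def test_endpoint_effects(self, asymmetric_curve):
        nc = normalize_curve(asymmetric_curve)
        assert nc.mortality(0.0) == pytest.approx(0.01, abs=1e-9)
        assert nc.mortality(1.0) == pytest.approx(0.99, abs=1e-9)

    def test_monotone(self, asymmetric_curve):
        nc = normalize_curve(asymmetric_curve)
        grid = np.linspace(0, 1, 40)
        assert np.all(np.diff(nc.survival(grid)) <= 1e-12)

    def test_symmetric_curve_centres_lc50(self, symmetric_curve):
        # for f = 1 the curve is log-symmetric, so the LC50 sits exactly
        # halfway between log LC1 and log LC99
        nc = normalize_curve(symmetric_curve)
        assert nc.mortality(0.5) == pytest.approx(0.5, abs=1e-9)


class TestAverageCurves:
    def test_identical_curves_zero_se(self, asymmetric_curve):
        curves = [normalize_curve(asymmetric_curve)] * 3
        avg = average_curves(curves)
        np.testing.assert_allclose(avg.se_survival, 0.0, atol=1e-12)
        expected = [curves[0].survival(u) for u in avg.levels]
        np.testing.assert_allclose(avg.median_survival, expected, atol=1e-12)

    def test_median_of_three_known_curves(self):
        curves = [normalize_curve(LL5Params(1.0, 0.0, 1.0, 10.0, f)) for f in (0.5, 1.0, 2.0)]
        avg = average_curves(curves)
        for j, u in enumerate(avg.levels):
            vals = sorted(c.survival(u) for c in curves)
            assert avg.median_survival[j] == pytest.approx(vals[1], abs=1e-12)

    def test_ten_equidistant_levels(self, asymmetric_curve, symmetric_curve):
        avg = average_curves([normalize_curve(asymmetric_curve), normalize_curve(symmetric_curve)])
        np.testing.assert_allclose(avg.levels, np.linspace(0, 1, 10), atol=1e-15)

    def test_band_brackets_median_at_levels(self, asymmetric_curve, symmetric_curve):
        avg = average_curves([normalize_curve(asymmetric_curve), normalize_curve(symmetric_curve)])
        up = ll5_survival(avg.upper_params, np.clip(avg.levels[1:], 1e-9, None))
        lo = ll5_survival(avg.lower_params, np.clip(avg.levels[1:], 1e-9, None))
        med = ll5_survival(avg.median_params, avg.levels[1:])
        assert np.all(up >= med - 0.02)
        assert np.all(lo <= med + 0.02)

    def test_needs_two_curves(self, asymmetric_curve):
        with pytest.raises(InputError):
            average_curves([normalize_curve(asymmetric_curve)])


def _pair_from_curves(tox_curve, comb_curve, m_env, n_points=9, study_id="T1"):
    grid = np.exp(np.linspace(np.log(lc(tox_curve, 1)), np.log(lc(tox_curve, 99)), n_points))
    tox = DoseResponseDataset(grid, ll5_survival(tox_curve, grid), tox_curve.d)
    comb = DoseResponseDataset(grid, ll5_survival(comb_curve, grid) * (1 - m_env),
                               comb_curve.d * (1 - m_env))
    return StudyPair(study_id=study_id, tox_arm=tox, combined_arm=comb, m_env=m_env)


class TestObservedShift:
    def test_identical_arms_no_shift(self, symmetric_curve):
        pair = _pair_from_curves(symmetric_curve, symmetric_curve, 0.0)
        rec = observed_shift(pair, 50.0, interpolate=None)
        assert rec.shift == pytest.approx(1.0, rel=1e-6)

    def test_constructed_tenfold_displacement(self, symmetric_curve):
        # the combined arm responds at 10x lower concentrations
        shifted = dataclasses.replace(symmetric_curve, e=symmetric_curve.e / 10.0)
        pair = _pair_from_curves(symmetric_curve, shifted, 0.0)
        rec = observed_shift(pair, 50.0, interpolate=None)
        assert rec.shift == pytest.approx(10.0, rel=1e-3)
        assert rec.lcx / rec.lcx_star == rec.shift

    def test_sam_truth_matches_predicted_readout(self):
        # noise-free SAM-generated pair: the observed shift equals the
        # SAM-predicted shift read off through the same fitting pipeline
        cfg = GeneratorConfig(seed=0, n_studies=1, noise="none", true_shape=3.2,
                              env_mortality_range=(0.2, 0.2))
        (pair,), _ = generate_meta_dataset(cfg)
        fitted = fit_study_pair(pair, interpolate=None)
        dist = StressCapacityDistribution(3.2, 3.2)
        for x in (10.0, 50.0):
            rec = observed_shift(pair, x, interpolate=None)
            table = predicted_shifts_refit(dist, fitted, pair.combined_arm.concentrations,
                                           (x,), True, None)
            assert rec.shift == pytest.approx(table[x][2], rel=1e-4)
            assert rec.shift > 1.0


class TestModelR2:
    def test_perfect_prediction(self):
        obs = [1.2, 3.0, 8.0, 20.0]
        assert model_r2(obs, obs) == pytest.approx(1.0, abs=1e-12)

    def test_mean_prediction_is_zero(self):
        obs = np.array([1.0, 10.0, 100.0])
        mean_pred = np.full(3, 10.0 ** np.mean(np.log10(obs)))
        assert model_r2(obs, mean_pred) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # log10 obs = [0, 1, 2, 3], log10 pred = [0, 1, 1, 3]
        # SS_res = 1, SS_tot = 5 -> R^2 = 0.8
        obs = [1.0, 10.0, 100.0, 1000.0]
        pred = [1.0, 10.0, 10.0, 1000.0]
        assert model_r2(obs, pred) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(InputError):
            model_r2([2.0, 2.0], [1.0, 3.0])

    def test_relabelling_invariance(self, rng):
        obs = rng.uniform(1, 50, size=8)
        pred = rng.uniform(1, 50, size=8)
        perm = rng.permutation(8)
        assert model_r2(obs, pred) == pytest.approx(model_r2(obs[perm], pred[perm]), abs=1e-12)


class TestCalibrateShape:
    def test_noise_free_recovery(self):
        cfg = GeneratorConfig(seed=3, n_studies=1, noise="none", true_shape=5.0)
        pairs, _ = generate_meta_dataset(cfg)
        result = calibrate_shape(pairs, interpolate=None)
        assert result.shape == pytest.approx(5.0, abs=0.05)

    def test_all_zero_env_mortality_raises(self, symmetric_curve):
        pair = _pair_from_curves(symmetric_curve, symmetric_curve, 0.0)
        with pytest.raises(CalibrationError):
            calibrate_shape([pair])

    def test_invariance_to_study_order_and_units(self):
        cfg = GeneratorConfig(seed=4, n_studies=2, noise="none", true_shape=3.2)
        pairs, _ = generate_meta_dataset(cfg)
        base = calibrate_shape(pairs, interpolate=None).shape
        reordered = calibrate_shape(pairs[::-1], interpolate=None).shape
        assert reordered == pytest.approx(base, abs=1e-6)
        # rescale one study's concentration units by 1000
        p = pairs[0]
        rescaled_pair = StudyPair(
            study_id=p.study_id,
            tox_arm=dataclasses.replace(p.tox_arm,
                                        concentrations=p.tox_arm.concentrations * 1e3),
            combined_arm=dataclasses.replace(p.combined_arm,
                                             concentrations=p.combined_arm.concentrations * 1e3),
            m_env=p.m_env,
        )
        rescaled = calibrate_shape([rescaled_pair, pairs[1]], interpolate=None).shape
        assert rescaled == pytest.approx(base, abs=1e-3)


@pytest.fixture(scope="module")
def avg_and_table():
    cfg = GeneratorConfig(seed=1, n_studies=10, true_shape=3.2)
    pairs, _ = generate_meta_dataset(cfg)
    fitted = [fit_study_pair(p, interpolate=None) for p in pairs]
    avg = average_curves([normalize_curve(f.tox_params) for f in fitted])
    dist = StressCapacityDistribution(3.2, 3.2)
    return avg, overall_prediction(avg, dist)


class TestOverallPrediction:
    def test_effect_addition_never_shifts(self, avg_and_table):
        _, table = avg_and_table
        ea = table[table.model == "ea"]
        np.testing.assert_allclose(ea["shift"], 1.0, atol=1e-12)

    def test_model_ordering(self, avg_and_table):
        # SAM >= CA >= EA on the right-skewed average curve; all models
        # converge to shift 1 as env stress vanishes, so the 1% env level
        # is compared with 1% relative slack
        _, table = avg_and_table
        wide = table.pivot_table(index=["env_mortality", "x"], columns="model",
                                 values="shift")
        strict = wide[wide.index.get_level_values("env_mortality") >= 0.02]
        corner = wide[wide.index.get_level_values("env_mortality") < 0.02]
        assert np.all(strict["sam"] >= strict["ca"] - 1e-9)
        assert np.all(corner["sam"] >= corner["ca"] * 0.99)
        assert np.all(wide["ca"] >= wide["ea"] - 1e-9)

    def test_low_effect_shift_exceeds_high_effect_shift(self, avg_and_table):
        _, table = avg_and_table
        sam = table[table.model == "sam"].pivot_table(
            index="env_mortality", columns="x", values="shift")
        assert np.all(sam[10.0] >= sam[50.0] - 1e-9)

    def test_uncertainty_band_is_a_sensible_envelope(self, avg_and_table):
        # the SE-band curves give a sensitivity envelope around the median
        # shift; band shifts are valid shifts (>= 1) and the median-curve
        # shift lies within the envelope up to a small fitting slack (the
        # band fits are independent curve fits, not pointwise bounds)
        _, table = avg_and_table
        ok = table[table.reachable]
        assert np.all(ok["shift_lower"] <= ok["shift_upper"] + 1e-12)
        assert np.all(ok["shift_lower"] >= 1.0 - 1e-9)
        assert np.all(ok["shift"] >= ok["shift_lower"] * 0.95)
        assert np.all(ok["shift"] <= ok["shift_upper"] * 1.05)
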