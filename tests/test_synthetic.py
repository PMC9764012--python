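"""Protocols, population simulation and kymograph rendering."""

import numpy as np
import pytest

import capkinetics as ck
from capkinetics.synthetic import (GasChallengeProtocol, OpticsConfig,
                                   PopulationSpec, make_protocol,
                                   population_to_frame, render_sti,
                                   simulate_population)


class TestProtocols:
    def test_low_oxygen_challenge_segments(self):
        p = make_protocol("O2_7to2")
        assert p.segments == ((60.0, 7.0, 5.0), (120.0, 2.0, 5.0))
        assert p.duration == 180.0

    def test_combined_challenge_segments(self):
        p = make_protocol("combined")
        assert p.segments == ((60.0, 7.0, 5.0), (60.0, 2.0, 5.0),
                              (120.0, 2.0, 10.0))
        assert p.duration == 240.0

    def test_co2_challenges_hold_oxygen_at_7(self):
        for name in ("CO2_5to0", "CO2_0to5", "CO2_5to10", "CO2_10to5"):
            p = make_protocol(name)
            assert all(o2 == 7.0 for _, o2, _ in p.segments)
            assert p.duration == 180.0

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError, match="unknown protocol"):
            make_protocol("O2_50to50")

    def test_degenerate_identity_protocol_valid(self):
        p = make_protocol("O2_7to7", segments=[(60, 7, 5), (120, 7, 5)])
        assert p.gas_at(30) == p.gas_at(150) == (7.0, 5.0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            make_protocol("bad", segments=[(60, 120, 5)])
        with pytest.raises(ValueError):
            make_protocol("bad", segments=[(0, 7, 5)])

    def test_yaml_round_trip(self, tmp_path):
        p = make_protocol("combined")
        path = tmp_path / "p.yaml"
        p.to_yaml(path)
        assert GasChallengeProtocol.from_yaml(path) == p


def _kin(y0_v=116.5, tau_v=35.5):
    return {
        "velocity": ck.MonoExpParams(0.0, 60.0, y0_v, tau_v),
        "lineal_density": ck.MonoExpParams(0.0, 64.7, 13.5, 26.9),
        "so2": ck.MonoExpParams(0.0, 62.3, -27.8, 1.4),
    }


class TestSimulatePopulation:
    def test_null_response_is_constant(self):
        spec = PopulationSpec(n_capillaries=3)
        kin = {m: ck.MonoExpParams(0.0, 60.0, 0.0, 10.0)
               for m in ("velocity", "lineal_density", "so2")}
        pop = simulate_population(make_protocol("O2_7to2"), spec, kin, seed=1)
        for s in pop:
            for m in ("velocity", "lineal_density", "so2"):
                arr = getattr(s, m)
                np.testing.assert_allclose(arr, arr[0])

    def test_noiseless_single_capillary_matches_closed_form(self):
        spec = PopulationSpec(
            n_capillaries=1,
            baseline={"velocity": (228.5, 0.0), "lineal_density": (49.4, 0.0),
                      "so2": (69.7, 0.0)})
        pop = simulate_population(make_protocol("O2_7to2"), spec, _kin(), seed=0)
        v180 = pop[0].velocity[-1]
        assert v180 == pytest.approx(228.5 + 116.5 * (1 - np.exp(-120 / 35.5)),
                                     rel=1e-12)

    def test_population_baseline_mean_within_sampling_error(self):
        mu, sd, n = 228.5, 60.0, 10_000
        spec = PopulationSpec(
            n_capillaries=n,
            baseline={"velocity": (mu, sd), "lineal_density": (49.4, 0.0),
                      "so2": (69.7, 0.0)})
        kin = {m: None for m in ("velocity", "lineal_density", "so2")}
        pop = simulate_population(make_protocol("O2_7to2"), spec, kin, seed=5)
        sample = np.array([s.velocity[0] for s in pop])
        # truncation at 0 is negligible at mu/sd ~ 3.8
        assert abs(sample.mean() - mu) < 3 * sd / np.sqrt(n)

    def test_supply_rate_identity_holds_with_noise(self):
        spec = PopulationSpec(
            n_capillaries=5,
            noise_sd={"velocity": 20.0, "lineal_density": 5.0, "so2": 2.0})
        pop = simulate_population(make_protocol("O2_7to2"), spec, _kin(), seed=2)
        for s in pop:
            np.testing.assert_allclose(
                s.supply_rate, s.velocity * s.lineal_density / 1000.0,
                rtol=1e-9)

    def test_noiseless_population_mean_equals_model_curve(self):
        spec = PopulationSpec(
            n_capillaries=4,
            baseline={"velocity": (228.5, 0.0), "lineal_density": (49.4, 0.0),
                      "so2": (69.7, 0.0)})
        pop = simulate_population(make_protocol("O2_7to2"), spec, _kin(), seed=3)
        df = population_to_frame(pop)
        means = df.groupby("t")["velocity"].mean()
        t = means.index.to_numpy(float)
        model = ck.eval_mono(t, ck.MonoExpParams(228.5, 60.0, 116.5, 35.5))
        np.testing.assert_allclose(means.to_numpy(), model, rtol=1e-9)

    def test_reproducible_under_fixed_seed(self):
        spec = PopulationSpec(n_capillaries=3,
                              noise_sd={"velocity": 10.0, "lineal_density": 1.0,
                                        "so2": 1.0})
        a = simulate_population(make_protocol("O2_7to2"), spec, _kin(), seed=9)
        b = simulate_population(make_protocol("O2_7to2"), spec, _kin(), seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.velocity, sb.velocity)
            np.testing.assert_array_equal(sa.so2, sb.so2)

    def test_out_of_bounds_response_clipped_with_warning(self):
        spec = PopulationSpec(
            n_capillaries=2,
            baseline={"velocity": (228.5, 0.0), "lineal_density": (49.4, 0.0),
                      "so2": (20.0, 0.0)})
        kin = _kin()  # SO2 amplitude -27.8 from baseline 20 crosses zero
        with pytest.warns(UserWarning, match="clipped"):
            pop = simulate_population(make_protocol("O2_7to2"), spec, kin, seed=1)
        assert np.all(pop[0].so2 >= 0.0)

    def test_delay_outside_protocol_rejected(self):
        spec = PopulationSpec(n_capillaries=1)
        kin = _kin()
        kin["velocity"] = ck.MonoExpParams(0.0, 500.0, 10.0, 5.0)
        with pytest.raises(ValueError, match="delay"):
            simulate_population(make_protocol("O2_7to2"), spec, kin, seed=0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_capillaries=0)
        with pytest.raises(ValueError):
            PopulationSpec(baseline={"velocity": (100.0, -1.0),
                                     "lineal_density": (50, 1),
                                     "so2": (70, 1)})


class TestRenderSti:
    def test_empty_capillary_renders_background(self, optics, constant_series):
        s = constant_series(v=300.0, ld=0.0)
        a, b = render_sti(s, optics, seed=1)
        np.testing.assert_array_equal(a.data, optics.i0)
        np.testing.assert_array_equal(b.data, optics.i0)

    def test_isosbestic_image_invariant_to_so2(self, optics, constant_series):
        a0, b0 = render_sti(constant_series(so2=0.0), optics, seed=4)
        a1, b1 = render_sti(constant_series(so2=100.0), optics, seed=4)
        np.testing.assert_array_equal(a0.data, a1.data)  # 420 nm bit-identical
        assert np.any(b0.data != b1.data)  # 438 nm differs inside streaks

    def test_deterministic_under_fixed_seed(self, optics, constant_series):
        s = constant_series()
        a0, _ = render_sti(s, optics, seed=8)
        a1, _ = render_sti(s, optics, seed=8)
        np.testing.assert_array_equal(a0.data, a1.data)

    def test_streak_slope_matches_velocity(self, optics, constant_series):
        # independent oracle: frame-to-frame cross-correlation lag of the
        # absorbance profile, sub-pixel refined, converted to um/s
        v_true = 300.0
        a, _ = render_sti(constant_series(v=v_true, ld=40.0, T=2), optics, seed=2)
        absorb = optics.i0 - a.data
        nr = absorb.shape[0]
        lags = []
        for k in range(absorb.shape[1] - 1):
            x = absorb[:, k] - absorb[:, k].mean()
            y = absorb[:, k + 1] - absorb[:, k + 1].mean()
            xc = np.correlate(y, x, mode="full")
            i = int(np.argmax(xc))
            if 0 < i < xc.size - 1:  # parabolic sub-pixel refinement
                denom = xc[i - 1] - 2 * xc[i] + xc[i + 1]
                frac = 0.5 * (xc[i - 1] - xc[i + 1]) / denom if denom else 0.0
            else:
                frac = 0.0
            lags.append(i + frac - (nr - 1))
        v_est = np.mean(lags) * a.um_per_px * optics.fps
        assert v_est == pytest.approx(v_true,
                                      abs=optics.um_per_px * optics.fps / 2)
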