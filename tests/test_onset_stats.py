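"""Population means, Dunnett-adjusted onset detection, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import capkinetics as ck
from capkinetics.onset_stats import (_max_abs_t_sf_mc, aggregate_means,
                                     dunnett_vs_baseline, find_onset_and_peak,
                                     max_abs_t_sf, percent_change)
from capkinetics.synthetic import PopulationSpec, make_protocol, \
    population_to_frame, simulate_population


def _pop_df(values, t):
    """Long frame from a capillaries x seconds array (velocity column)."""
    n, T = values.shape
    return pd.DataFrame({
        "capillary_id": np.repeat(np.arange(n), T),
        "t": np.tile(t, n),
        "velocity": values.ravel(),
    })


class TestAggregateMeans:
    def test_mean_sd_n(self):
        t = np.array([10.0])
        df = _pop_df(np.array([[1.0], [2.0], [3.0]]), t)
        out = aggregate_means(df, measures=("velocity",))
        row = out.iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(1.0)
        assert row["n"] == 3
        assert row["sem"] == pytest.approx(1.0 / math.sqrt(3))

    def test_available_case_counts(self):
        t = np.array([10.0])
        df = _pop_df(np.array([[1.0], [np.nan], [3.0]]), t)
        out = aggregate_means(df, measures=("velocity",))
        assert out.iloc[0]["n"] == 2
        assert out.iloc[0]["mean"] == 2.0

    def test_noiseless_population_reproduces_model(self):
        spec = PopulationSpec(
            n_capillaries=3,
            baseline={"velocity": (228.5, 0.0), "lineal_density": (49.4, 0.0),
                      "so2": (69.7, 0.0)})
        kin = {"velocity": ck.MonoExpParams(0.0, 60.0, 116.5, 35.5),
               "lineal_density": None, "so2": None}
        pop = simulate_population(make_protocol("O2_7to2"), spec, kin, seed=0)
        out = aggregate_means(population_to_frame(pop), measures=("velocity",))
        model = ck.eval_mono(out["t"].to_numpy(float),
                             ck.MonoExpParams(228.5, 60.0, 116.5, 35.5))
        np.testing.assert_allclose(out["mean"].to_numpy(), model, rtol=1e-9)


class TestFamilyAdjustment:
    def test_single_comparison_reduces_to_paired_t(self):
        sf = max_abs_t_sf([2.0], k=1, nu=30, rho=1 / 11)
        assert sf[0] == pytest.approx(2 * stats.t.sf(2.0, 30), abs=5e-4)

    def test_quadrature_matches_scipy_multivariate_t(self):
        # independent oracle: sample the equicorrelated mvt via scipy
        k, nu, rho, c = 3, 25, 1 / 11, 2.5
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        mvt = stats.multivariate_t(loc=np.zeros(k), shape=cov, df=nu, seed=5)
        draws = mvt.rvs(200_000)
        ref = np.mean(np.abs(draws).max(axis=1) >= c)
        assert max_abs_t_sf([c], k, nu, rho)[0] == pytest.approx(ref, abs=0.005)

    def test_monte_carlo_path_matches_quadrature(self):
        k, nu, rho = 60, 40, 1 / 11
        tv = [2.0, 3.0, 3.5]
        quad = max_abs_t_sf(tv, k, nu, rho)
        mc = _max_abs_t_sf_mc(tv, k, nu, rho, n_draws=100_000, seed=2)
        np.testing.assert_allclose(mc, quad, atol=0.01)

    def test_adjusted_p_monotone_in_family_size(self):
        p1 = max_abs_t_sf([2.5], 1, 50, 1 / 11)[0]
        p120 = max_abs_t_sf([2.5], 120, 50, 1 / 11)[0]
        assert p120 > p1


class TestDunnett:
    def test_null_identity_no_significance(self):
        # post seconds identically equal to each capillary's baseline values
        rng = np.random.default_rng(0)
        t = np.arange(51, 81.0)
        base = rng.normal(100, 10, size=(20, 10))
        vals = np.concatenate([base, np.repeat(base.mean(axis=1)[:, None],
                                               20, axis=1)], axis=1)
        out = dunnett_vs_baseline(vals, t)
        assert not (out["p_adj"] < 0.05).any()

    def test_missing_seconds_dropped_per_comparison(self):
        rng = np.random.default_rng(1)
        t = np.arange(51, 75.0)
        vals = rng.normal(0, 1, size=(30, t.size))
        vals[:5, 12] = np.nan
        out = dunnett_vs_baseline(vals, t)
        assert out.loc[out["t"] == t[12], "n"].item() == 25

    def test_insufficient_pairs_give_missing_p(self):
        t = np.arange(51, 70.0)
        vals = np.random.default_rng(2).normal(size=(4, t.size))
        vals[1:, 15] = np.nan
        out = dunnett_vs_baseline(vals, t)
        assert np.isnan(out.loc[out["t"] == t[15], "p_adj"].item())

    def test_step_detected_quickly_at_scale(self):
        # 2-SD step at t=61 across many capillaries: onset within seconds
        rng = np.random.default_rng(3)
        t = np.arange(51, 181.0)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            vals = rng.normal(0, 1, size=(300, t.size))
            vals[:, t > 60] += 2.0
            out = dunnett_vs_baseline(vals, t)
            first = out.loc[out["p_adj"] < 0.05, "t"]
            if not first.empty and first.iloc[0] <= 65:
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestOnsetAndPeak:
    def _means(self, t, mean):
        return pd.DataFrame({"measure": "velocity", "t": t, "mean": mean,
                             "sd": np.ones_like(t), "sem": np.ones_like(t),
                             "n": 10})

    def test_first_crossing_time(self):
        t = np.arange(61, 70.0)
        p = np.array([0.2, 0.04, 0.03, 0.5, 0.01, 0.2, 0.3, 0.4, 0.5])
        dn = pd.DataFrame({"t": t, "diff": 1.0, "stat": 1.0, "p_adj": p,
                           "n": 10})
        means = self._means(np.arange(51, 70.0), np.arange(51, 70.0))
        s = find_onset_and_peak(means, dn)
        assert s.first_sig_time == 62.0

    def test_monotone_rise_peaks_at_boundary(self):
        t = np.arange(51, 181.0)
        means = self._means(t, t.copy())  # rising to the end
        dn = pd.DataFrame({"t": t[t > 60], "diff": 1.0, "stat": 5.0,
                           "p_adj": 0.001, "n": 10})
        s = find_onset_and_peak(means, dn)
        assert s.peak_time == 180.0
        assert s.direction == 1

    def test_all_na_when_nothing_significant(self):
        t = np.arange(51, 181.0)
        means = self._means(t, np.full(t.size, 60.8))
        dn = pd.DataFrame({"t": t[t > 60], "diff": 0.0, "stat": 0.1,
                           "p_adj": 0.9, "n": 10})
        s = find_onset_and_peak(means, dn)
        assert math.isnan(s.first_sig_time) and math.isnan(s.peak_time)
        assert math.isnan(s.peak_p)
        # baseline is still reported, mirroring published NA rows
        assert s.baseline_mean == pytest.approx(60.8)

    def test_nadir_direction(self):
        t = np.arange(51, 181.0)
        mean = np.where(t > 60, 50.0, 100.0)
        means = self._means(t, mean.astype(float))
        dn = pd.DataFrame({"t": t[t > 60], "diff": -50.0, "stat": -9.0,
                           "p_adj": 0.001, "n": 10})
        s = find_onset_and_peak(means, dn)
        assert s.direction == -1
        assert s.peak_mean == pytest.approx(50.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_affine_invariance_of_onset_time(self, scale, shift):
        t = np.arange(51, 101.0)
        rng = np.random.default_rng(4)
        vals = rng.normal(10, 1, size=(40, t.size))
        vals[:, t > 70] += 3.0
        out0 = dunnett_vs_baseline(vals, t, baseline_window=(51, 60))
        out1 = dunnett_vs_baseline(vals * scale + shift, t,
                                   baseline_window=(51, 60))
        np.testing.assert_allclose(out0["p_adj"], out1["p_adj"], atol=1e-9)


class TestPercentChange:
    def test_reference_values(self):
        assert percent_change(100.0, 100.0) == 0.0
        assert percent_change(100.0, 50.0) == -50.0
        # low-oxygen velocity peak vs baseline, arithmetic definition
        assert percent_change(228.5, 353.2) == pytest.approx(54.57, abs=0.01)

    def test_zero_baseline_undefined(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 10.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(b=st.floats(0.1, 1e4), e=st.floats(-1e4, 1e4),
           s=st.floats(0.1, 100))
    def test_invariant_under_positive_scaling(self, b, e, s):
        assert percent_change(b * s, e * s) == pytest.approx(
            percent_change(b, e), rel=1e-9, abs=1e-9)
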