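"""Dwell-time collection, exponential-decay fitting, area fractions, model
selection and photobleaching correction, with survival and maximum-
likelihood oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from cbhkin import dwelltime, presets, simulate
from cbhkin.dwelltime import (
    ILL_SEPARATED,
    DwellDataset,
    ExpDecayFit,
    bleach_correct,
    collect_dwells,
    component_fractions,
    fit_exponential,
    rate_to_time_constant,
    select_decay_model,
    time_constant_to_rate,
)
from cbhkin.errors import EmptyDatasetError, InvalidParameterError
from cbhkin.models import ImagingConditions


def events_from_dwells(dwells, duration=1e9):
    n = len(dwells)
    return pd.DataFrame(
        {
            "fibril_id": ["f0"] * n,
            "molecule_id": [f"m{i}" for i in range(n)],
            "t_bind": np.zeros(n),
            "t_end": np.asarray(dwells, dtype=float),
            "end_cause": ["dissociation"] * n,
            "mode": ["unknown"] * n,
        }
    )


def exact_dataset(amplitudes, rates, dt=0.2, n_bins=200):
    """Noise-free histogram generated directly from the decay model."""
    edges = np.arange(dt, (n_bins + 2) * dt, dt)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros_like(centers)
    for a, k in zip(amplitudes, rates):
        counts += a * np.exp(-k * centers)
    dwells = np.repeat(centers, 3)  # only used for initialization
    return DwellDataset(
        dwells=dwells, frame_interval=dt, bin_edges=edges, counts=counts,
        n_censored=0, min_frames=1,
    )


class TestCollect:
    def test_direct_subtraction_and_binning(self):
        cond = ImagingConditions(frame_rate=5.0, duration=400.0)
        ev = events_from_dwells([2.05])
        ev.loc[0, "t_bind"], ev.loc[0, "t_end"] = 1.0, 3.0
        data = collect_dwells(ev, cond)
        assert data.dwells[0] == pytest.approx(2.0)
        idx = np.searchsorted(data.bin_edges, 2.0, side="right") - 1
        assert data.bin_edges[idx] == pytest.approx(2.0)
        assert data.counts[idx] == 1

    def test_movie_end_events_excluded_but_counted(self):
        cond = ImagingConditions(frame_rate=5.0, duration=400.0)
        ev = events_from_dwells([1.0, 2.0, 3.0])
        ev.loc[2, "end_cause"] = "movie_end"
        data = collect_dwells(ev, cond)
        assert data.n == 2
        assert data.n_censored == 1

    def test_min_frames_retention_matches_survival(self):
        # discard events shorter than 2 frames: retained fraction should be
        # exp(-koff * 2 * dt) (exponential survival oracle)
        rng = np.random.default_rng(51)
        koff, dt = 0.5, 0.2
        dwells = rng.exponential(1 / koff, 10_000)
        cond = ImagingConditions(frame_rate=5.0, duration=1e9)
        data = collect_dwells(events_from_dwells(dwells), cond, min_frames=2)
        retained = data.n / len(dwells)
        expected = math.exp(-koff * 2 * dt)
        se = math.sqrt(expected * (1 - expected) / len(dwells))
        assert abs(retained - expected) < 3 * se

    def test_empty_after_filtering(self):
        cond = ImagingConditions(frame_rate=5.0, duration=400.0)
        ev = events_from_dwells([0.05])
        with pytest.raises(EmptyDatasetError):
            collect_dwells(ev, cond, min_frames=1)


class TestFit:
    def test_exact_single_exponential(self):
        data = exact_dataset([100.0], [0.5])
        fit = fit_exponential(data, 1)
        assert fit.rates[0] == pytest.approx(0.5, rel=1e-6)

    def test_exact_double_exponential(self):
        # amplitudes chosen so area fractions are 81/19 at rates 1.7/0.13
        a_fast, a_slow = 0.81 * 1.7, 0.19 * 0.13
        data = exact_dataset([a_fast * 1000, a_slow * 1000], [1.7, 0.13])
        fit = fit_exponential(data, 2)
        assert fit.k_fast == pytest.approx(1.7, rel=1e-4)
        assert fit.k_slow == pytest.approx(0.13, rel=1e-4)
        assert fit.frac_fast == pytest.approx(0.81, rel=1e-3)

    def test_stochastic_recovery_of_slow_rate(self, intact_truth, intact_events, dwell_movie):
        data = collect_dwells(intact_events, dwell_movie)
        fit = fit_exponential(data, 2)
        assert fit.k_slow == pytest.approx(intact_truth.koff_slow, rel=0.10)
        assert fit.k_fast == pytest.approx(intact_truth.koff_fast, rel=0.15)

    def test_ls_agrees_with_mle_oracle(self):
        # maximum likelihood on the truncated mixture is an independent
        # estimator; the histogram fit should agree within 5%
        rng = np.random.default_rng(52)
        n = 100_000
        fast = rng.random(n) < 0.33
        dwells = np.where(
            fast, rng.exponential(1 / 0.85, n), rng.exponential(1 / 0.086, n)
        )
        cond = ImagingConditions(frame_rate=5.0, duration=1e9)
        data = collect_dwells(events_from_dwells(dwells), cond)
        fit = fit_exponential(data, 2)

        t0 = data.min_frames * data.frame_interval
        obs = data.dwells

        def nll(p):
            w = 1 / (1 + math.exp(-p[0]))
            kf, ks = math.exp(p[1]), math.exp(p[2])
            norm = w * math.exp(-kf * t0) + (1 - w) * math.exp(-ks * t0)
            dens = w * kf * np.exp(-kf * obs) + (1 - w) * ks * np.exp(-ks * obs)
            return -np.log(dens / norm).sum()

        res = minimize(nll, [0.0, 0.0, math.log(0.1)], method="Nelder-Mead")
        kf_mle, ks_mle = sorted(np.exp(res.x[1:]), reverse=True)
        assert fit.k_fast == pytest.approx(kf_mle, rel=0.05)
        assert fit.k_slow == pytest.approx(ks_mle, rel=0.05)

    def test_censoring_bias_is_bounded(self, intact_truth):
        # quadrupling the movie length changes the slow rate by < 5%
        field = simulate.make_fibril_field(10, 5.0, 0.0, {1: 1.0}, seed=0)
        rates = []
        for duration in (400.0, 1600.0):
            cond = presets.binding_movie(
                bleach_rate=0.0, enzyme_conc=5e-9, duration=duration
            )
            events = simulate.simulate_binding(intact_truth, field, cond, seed=53)
            fit = fit_exponential(collect_dwells(events, cond), 2)
            rates.append(fit.k_slow)
        assert rates[0] == pytest.approx(rates[1], rel=0.05)


class TestFractions:
    def test_closed_form_areas(self):
        fit = ExpDecayFit(
            n_components=2, amplitudes=(10.0, 5.0), rates=(1.0, 0.25),
            fractions=(1 / 3, 2 / 3), r_squared=1.0, n_events=10,
        )
        assert component_fractions(fit) == pytest.approx((1 / 3, 2 / 3))

    def test_single_component_fraction_is_one(self):
        fit = ExpDecayFit(
            n_components=1, amplitudes=(10.0,), rates=(0.5,),
            fractions=(1.0,), r_squared=1.0, n_events=10,
        )
        assert component_fractions(fit) == (1.0,)

    def test_area_ratio_33_67(self):
        # amplitudes proportional to f*k give back the mixture weights
        c = 1000.0
        fit = ExpDecayFit(
            n_components=2, amplitudes=(0.33 * 0.85 * c, 0.67 * 0.086 * c),
            rates=(0.85, 0.086), fractions=(0.33, 0.67),
            r_squared=1.0, n_events=10,
        )
        assert component_fractions(fit) == pytest.approx((0.33, 0.67))

    @given(
        a=st.tuples(
            st.floats(0.1, 1e3), st.floats(0.1, 1e3)
        ),
        k=st.tuples(st.floats(1.0, 10.0), st.floats(0.01, 0.4)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_always_sum_to_one(self, a, k):
        fit = ExpDecayFit(
            n_components=2, amplitudes=a, rates=k,
            fractions=dwelltime._area_fractions(a, k),
            r_squared=1.0, n_events=10,
        )
        assert sum(component_fractions(fit)) == pytest.approx(1.0, abs=1e-9)


class TestModelSelection:
    def _fit(self, n, r2, warnings=()):
        if n == 1:
            return ExpDecayFit(1, (10.0,), (0.5,), (1.0,), r2, 100)
        return ExpDecayFit(
            2, (10.0, 2.0), (1.0, 0.1), dwelltime._area_fractions((10, 2), (1, 0.1)),
            r2, 100, warnings=tuple(warnings),
        )

    def test_strict_improvement_prefers_double(self):
        assert select_decay_model(self._fit(1, 0.90), self._fit(2, 0.98)).n_components == 2

    def test_tie_goes_to_double(self):
        assert select_decay_model(self._fit(1, 0.95), self._fit(2, 0.95)).n_components == 2

    def test_worse_double_rejected(self):
        assert select_decay_model(self._fit(1, 0.98), self._fit(2, 0.90)).n_components == 1

    def test_ill_separated_double_rejected(self):
        chosen = select_decay_model(
            self._fit(1, 0.95), self._fit(2, 0.95, warnings=(ILL_SEPARATED,))
        )
        assert chosen.n_components == 1

    def test_single_mode_truth_selects_single(self):
        # with one-component truth, the double model should rarely win
        rng = np.random.default_rng(54)
        cond = ImagingConditions(frame_rate=5.0, duration=1e9)
        single_wins = 0
        n_seeds = 100
        for _ in range(n_seeds):
            dwells = rng.exponential(1 / 0.3, 2000)
            data = collect_dwells(events_from_dwells(dwells), cond)
            fit1 = fit_exponential(data, 1)
            try:
                fit2 = fit_exponential(data, 2)
            except Exception:
                single_wins += 1
                continue
            if select_decay_model(fit1, fit2).n_components == 1:
                single_wins += 1
        assert single_wins >= 0.95 * n_seeds


class TestBleachCorrection:
    def test_subtraction(self):
        fit = ExpDecayFit(1, (10.0,), (0.139,), (1.0,), 0.99, 100)
        corrected = bleach_correct(fit, 0.053)
        assert corrected.rates[0] == pytest.approx(0.086)
        assert corrected.bleach_corrected

    def test_zero_rate_is_identity(self):
        fit = ExpDecayFit(1, (10.0,), (0.139,), (1.0,), 0.99, 100)
        assert bleach_correct(fit, 0.0) is fit

    def test_unreliable_correction_flagged(self):
        fit = ExpDecayFit(1, (10.0,), (0.05,), (1.0,), 0.99, 100)
        corrected = bleach_correct(fit, 0.06)
        assert dwelltime.UNRELIABLE_BLEACH in corrected.warnings

    def test_competing_risk_recovery(self):
        # single-mode koff 0.2 with bleaching at 0.053: the corrected rate
        # recovers the true dissociation rate within 10%
        truth = presets.intact_truth(
            frac_fast=0.0, frac_slow=1.0, koff_fast=2.0, koff_slow=0.2
        )
        field = simulate.make_fibril_field(1, 5.0, 0.0, {1: 1.0}, seed=0)
        cond = ImagingConditions(
            frame_rate=5.0, duration=5e4, bleach_rate=0.053, enzyme_conc=1e-10
        )
        events = simulate.simulate_binding(truth, field, cond, seed=55)
        data = collect_dwells(events, cond)
        assert data.n >= 10_000
        fit = fit_exponential(data, 1)
        corrected = bleach_correct(fit, 0.053)
        assert corrected.rates[0] == pytest.approx(0.2, rel=0.10)


class TestRateConversions:
    def test_bleach_rate_to_time_constant(self):
        assert rate_to_time_constant(0.053) == pytest.approx(18.9, abs=0.05)
        assert time_constant_to_rate(18.9) == pytest.approx(0.053, abs=5e-4)

    def test_non_positive_rejected(self):
        with pytest.raises(InvalidParameterError):
            rate_to_time_constant(0.0)
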