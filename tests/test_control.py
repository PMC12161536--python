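"""Force-response calibration, recruitment selection, spike-train emission."""

import numpy as np
import pytest
from scipy.signal import resample_poly

from semgsim.anatomy import Anatomy
from semgsim.config import desk_config
from semgsim.control import (
    ForceMatrix,
    MRef,
    RecruitmentPlan,
    ReferenceForce,
    build_mref,
    generate_spike_trains,
    prepare_reference_force,
    select_recruitment,
)
from semgsim.fiber import TwitchParams, fiber_force_profile


def _toy_anatomy(n_mu=2, fib_per_mu=2):
    n = n_mu * fib_per_mu
    path = np.array([[0.0, 0, 0], [0, 0, 150.0]])
    return Anatomy(
        paths=np.tile(path, (n, 1, 1)),
        ftype=np.zeros(n, dtype=int),
        r=np.full(n, 20.0),
        sigma_ic=np.full(n, 0.35),
        thr=np.full(n, 1e-9),  # every impulse innervates
        f_base=np.linspace(50, 80, n),
        tau_up=np.full(n, 30.0),
        tau_down=np.full(n, 40.0),
        cv=np.full(n, 4.0),
        nmj_arc_mm=np.full(n, 60.0),
        nmj_pos=np.zeros((n, 3)),
        mu_of_fiber=np.repeat(np.arange(n_mu), fib_per_mu),
        mu_sizes=np.full(n_mu, fib_per_mu),
        section_area_mm2=100.0,
        seed=0,
    )


class TestBuildMref:
    def test_toy_matrix_matches_twitch_superposition_oracle(self):
        cfg = desk_config(rate_step=17.0)  # rates 8, 25, 42
        anat = _toy_anatomy()
        fm, mref = build_mref(anat, cfg)
        ctl = cfg.control
        fs = cfg.fs
        n_samples = int(ctl.calib_duration_s * fs)
        w0 = int((ctl.calib_duration_s - ctl.calib_window_s) * fs)
        for j, rate in enumerate(fm.rates):
            # with vanishing thresholds each impulse innervates one sample
            # after the spike; oracle superposes sampled twitches directly
            spikes = np.round(
                np.arange(0, ctl.calib_duration_s, 1 / rate) * fs
            ).astype(int)
            innerv = (spikes + 1) / fs
            for mu in range(anat.n_mu):
                expect = 0.0
                for f in np.flatnonzero(anat.mu_of_fiber == mu):
                    tw = TwitchParams(
                        anat.f_base[f], anat.tau_up[f], anat.tau_down[f],
                        2 * anat.r[f],
                    )
                    prof = fiber_force_profile(innerv, tw, fs, n_samples)
                    expect += prof[w0:].mean()
                assert fm.values[mu, j] == pytest.approx(expect, rel=2e-3)

    def test_cumulative_rows_are_monotone(self, small_mref):
        _, mref = small_mref
        assert np.all(np.diff(mref.cumulative, axis=0) >= -1e-9)

    def test_mu_order_is_ascending_in_size(self, small_anatomy, small_mref):
        _, mref = small_mref
        sizes = small_anatomy.mu_sizes[mref.mu_order]
        assert np.all(np.diff(sizes) >= 0)

    def test_empty_rate_grid_rejected(self):
        with pytest.raises(ValueError):
            ForceMatrix(values=np.zeros((2, 0)), rates=np.empty(0))


def _toy_mref():
    cumulative = np.array(
        [[10.0, 20.0, 30.0], [40.0, 60.0, 80.0], [70.0, 100.0, 130.0]]
    )
    return MRef(
        cumulative=cumulative,
        rates=np.array([8.0, 25.0, 42.0]),
        mu_order=np.arange(3),
    )


def _exhaustive_select(f, mref, window=0.01):
    """Brute-force oracle over all (n, m)."""
    M = mref.cumulative
    N, R = M.shape
    best, best_d = None, np.inf
    for n in range(1, N + 1):
        for m in range(R):
            if (1 - window) * f < M[n - 1, m] < (1 + window) * f:
                d = abs(n / N - (m + 1) / R) / np.sqrt(2)
                if d < best_d:
                    best, best_d = (n, m), d
    return best


class TestSelection:
    def test_zero_demand_recruits_nothing(self):
        mref = _toy_mref()
        ref = ReferenceForce(samples=np.zeros(10), fs=2000.0)
        plan = select_recruitment(ref, mref)
        assert (plan.n == 0).all()

    def test_saturation_above_model_maximum(self):
        mref = _toy_mref()
        ref = ReferenceForce(samples=np.array([1e9]), fs=2000.0)
        plan = select_recruitment(ref, mref)
        assert plan.n[0] == 3 and plan.m_idx[0] == 2

    def test_matches_exhaustive_search(self):
        mref = _toy_mref()
        # demands with 1- and 2-candidate windows
        for f in (10.05, 59.9, 99.8, 130.2, 40.2, 70.2):
            ref = ReferenceForce(samples=np.array([f]), fs=2000.0)
            plan = select_recruitment(ref, mref)
            oracle = _exhaustive_select(f, mref)
            if oracle is not None:
                assert (plan.n[0], plan.m_idx[0]) == oracle

    def test_empty_window_falls_back_to_nearest_force(self):
        mref = _toy_mref()
        ref = ReferenceForce(samples=np.array([33.0]), fs=2000.0)
        plan = select_recruitment(ref, mref)
        assert _exhaustive_select(33.0, mref) is None
        idx = np.argmin(np.abs(mref.cumulative - 33.0))
        assert (plan.n[0] - 1) * 3 + plan.m_idx[0] == idx

    def test_monotone_on_ramp(self, small_mref):
        _, mref = small_mref
        f = np.linspace(0, mref.model_mvc, 400)
        ref = ReferenceForce(samples=f, fs=2000.0)
        plan = select_recruitment(ref, mref)
        # recruited force is non-decreasing along a monotone demand ramp
        sel = np.where(
            plan.n > 0,
            mref.cumulative[np.clip(plan.n - 1, 0, None), plan.m_idx],
            0.0,
        )
        violations = np.diff(sel) < -0.01 * mref.model_mvc
        assert not violations.any()


class TestSpikeTrains:
    def _plan(self, n, m_idx, m_hz, std, samples, fs=2000.0):
        return RecruitmentPlan(
            n=np.full(samples, n, dtype=int),
            m_idx=np.full(samples, m_idx, dtype=int),
            m_hz=np.full(samples, m_hz),
            rate_std_hz=np.full(samples, std),
            fs=fs,
        )

    def test_zero_std_fires_at_exact_rate(self):
        mref = _toy_mref()
        plan = self._plan(2, 1, 25.0, 0.0, 4000)
        spikes = generate_spike_trains(plan, mref, seed=0)
        assert len(spikes[2]) == 0  # third unit not recruited
        for mu in (0, 1):
            isi = np.diff(spikes[mu])
            assert np.allclose(isi, 1 / 25.0, atol=1e-12)

    def test_constant_isi_between_plan_changes(self):
        mref = _toy_mref()
        plan = self._plan(3, 2, 30.0, 5.0, 6000)
        spikes = generate_spike_trains(plan, mref, seed=4)
        for s in spikes:
            if len(s) > 2:
                assert np.ptp(np.diff(s)) < 1e-12

    def test_assigned_rate_spread_matches_clamped_gaussian(self):
        # Monte-Carlo: sample std of assigned rates at full recruitment
        # approximates the 10 Hz draw std (clamp-adjusted oracle)
        mref = _toy_mref()
        rates = []
        for seed in range(600):
            plan = self._plan(3, 1, 25.0, 10.0, 2000)
            spikes = generate_spike_trains(plan, mref, seed=seed)
            for s in spikes:
                if len(s) > 1:
                    rates.append(1.0 / np.diff(s)[0])
        rng = np.random.default_rng(0)
        oracle = np.clip(rng.normal(25.0, 10.0, 100_000), 8.0, 42.0)
        assert np.std(rates) == pytest.approx(np.std(oracle), rel=0.1)

    def test_henneman_ordering(self, small_mref):
        # a unit never fires while a smaller unit is silent
        _, mref = small_mref
        n_mu = mref.n_mu
        plan = self._plan(max(n_mu // 2, 1), 1, 20.0, 0.0, 2000)
        spikes = generate_spike_trains(plan, mref, seed=1)
        active = {mu for mu in range(n_mu) if len(spikes[mu])}
        expected = set(mref.mu_order[: max(n_mu // 2, 1)].tolist())
        assert active == expected


class TestReferencePreparation:
    def test_resampling_length(self):
        ref = prepare_reference_force(np.ones(100), 100.0, 1.0, 5.0, 2000.0)
        assert len(ref.samples) == 2000

    def test_constant_profile_scaling_identity(self):
        ref = prepare_reference_force(
            np.full(200, 3.0), 100.0, 3.0, 7.5, 2000.0
        )
        mid = ref.samples[500:-500]
        assert np.allclose(mid, 7.5, rtol=2e-3)

    def test_round_trip_resampling(self):
        rng = np.random.default_rng(1)
        from scipy.signal import windows

        raw = np.convolve(
            rng.normal(size=400), windows.hann(41) / 20.5, mode="same"
        )
        ref = prepare_reference_force(raw, 100.0, 2.0, 2.0, 2000.0)
        back = resample_poly(ref.samples, 1, 20)
        core = slice(40, -40)
        assert np.allclose(back[core], raw[core], atol=0.05 * np.abs(raw).max())

    def test_non_positive_mvc_rejected(self):
        with pytest.raises(ValueError):
            prepare_reference_force(np.ones(10), 100.0, 0.0, 1.0, 2000.0)
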