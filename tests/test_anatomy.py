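"""Fiber paths, motor-unit dispersion/assignment, typing, parameter sampling."""

import numpy as np
import pytest

from semgsim.anatomy import (
    CrossSectionStack,
    FiberTypeTargets,
    assign_fiber_types,
    assign_mus_to_positions,
    build_fiber_paths,
    disperse_motor_unit,
    make_mu_layout,
    MotorUnitLayout,
    sample_fiber_parameters,
)
from semgsim.config import desk_config


def _reference_pairing(pa, pb):
    """Independent recursive implementation of the bisection pairing."""
    out = {}

    def rec(ia, ib):
        if len(ia) == 1:
            out[ia[0]] = ib[0]
            return
        ext = pa[ia].max(axis=0) - pa[ia].min(axis=0)
        ax = 0 if ext[0] >= ext[1] else 1

        def srt(p, idx):
            return sorted(idx, key=lambda i: (p[i, ax], p[i, 1 - ax], i))

        sa, sb = srt(pa, ia), srt(pb, ib)
        h = (len(ia) + 1) // 2
        rec(sa[:h], sb[:h])
        rec(sa[h:], sb[h:])

    rec(list(range(len(pa))), list(range(len(pb))))
    return out


class TestFiberPaths:
    def test_square_layers_pairing_is_bijection(self):
        sq = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        stack = CrossSectionStack(
            layers=[sq, sq.copy()], z_positions=np.array([0.0, 10.0])
        )
        paths = build_fiber_paths(stack)
        assert paths.shape == (4, 2, 3)
        # every endpoint used exactly once and matches exhaustive recursion
        ref = _reference_pairing(sq, sq)
        ends = {tuple(p[1, :2]) for p in paths}
        assert len(ends) == 4
        for i, p in enumerate(paths):
            assert np.allclose(p[1, :2], sq[ref[i]])

    @pytest.mark.parametrize("n", [8, 13, 32, 64])
    def test_random_layers_match_exhaustive_recursion(self, n, rng):
        pa = rng.uniform(-10, 10, (n, 2))
        pb = rng.uniform(-10, 10, (n, 2))
        stack = CrossSectionStack(
            layers=[pa, pb], z_positions=np.array([0.0, 5.0])
        )
        paths = build_fiber_paths(stack)
        ref = _reference_pairing(pa, pb)
        for i in range(n):
            assert np.allclose(paths[i, 1, :2], pb[ref[i]])
        # bijection: each target point used once
        used = {ref[i] for i in range(n)}
        assert len(used) == n

    def test_seven_layers_give_seven_waypoints(self, rng):
        layers = [rng.uniform(0, 5, (12, 2)) for _ in range(7)]
        stack = CrossSectionStack(layers=layers, z_positions=np.arange(7.0))
        assert build_fiber_paths(stack).shape == (12, 7, 3)

    def test_single_point_layers(self):
        layers = [np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]])]
        stack = CrossSectionStack(layers=layers, z_positions=np.array([0.0, 9.0]))
        paths = build_fiber_paths(stack)
        assert np.allclose(paths[0], [[1, 2, 0], [3, 4, 9]])

    def test_unequal_point_counts_rejected(self):
        with pytest.raises(ValueError):
            CrossSectionStack(
                layers=[np.zeros((3, 2)), np.zeros((4, 2))],
                z_positions=np.array([0.0, 1.0]),
            )


class TestDispersion:
    def test_zero_variance_limit(self, rng):
        off = disperse_motor_unit(1.0, 1e-12, 50, rng)
        assert np.abs(off).max() < 1e-9

    def test_linear_scaling_in_radius(self):
        a = disperse_motor_unit(1.0, 0.3, 100, np.random.default_rng(7))
        b = disperse_motor_unit(2.0, 0.3, 100, np.random.default_rng(7))
        assert np.allclose(b, 2 * a)

    def test_sample_std_matches_lambda(self, rng):
        off = disperse_motor_unit(1.0, 0.3, 10000, rng)
        assert off.std(axis=0) == pytest.approx([0.3, 0.3], rel=0.05)

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            disperse_motor_unit(-1.0, 0.3, 5, rng)
        with pytest.raises(ValueError):
            disperse_motor_unit(1.0, 0.0, 5, rng)


class TestAssignment:
    def test_counts_conserved_single_mu(self, rng):
        pts = rng.uniform(0, 10, (20, 2))
        layout = MotorUnitLayout(
            mu_sizes=np.array([20]),
            r_disp=np.array([0.2]),
            lambda_disp=np.array([0.3]),
        )
        mu = assign_mus_to_positions(layout, pts, 100.0, rng)
        assert (mu == 0).all()

    def test_each_point_gets_exactly_one_fiber(self, rng):
        pts = rng.uniform(0, 10, (60, 2))
        layout = MotorUnitLayout(
            mu_sizes=np.array([25, 35]),
            r_disp=np.array([0.1, 0.3]),
            lambda_disp=np.array([0.3, 0.4]),
        )
        mu = assign_mus_to_positions(layout, pts, 100.0, rng)
        assert (mu >= 0).all()
        assert np.bincount(mu).tolist() == [25, 35]

    def test_two_clusters_split_between_tight_mus(self):
        # two well-separated clusters, tight dispersion: each unit should
        # claim predominantly one cluster (checked over the assignment)
        rng = np.random.default_rng(5)
        c1 = rng.normal(0, 0.4, (6, 2))
        c2 = rng.normal(50, 0.4, (6, 2)) + [50, 0]
        pts = np.vstack([c1, c2])
        layout = MotorUnitLayout(
            mu_sizes=np.array([6, 6]),
            r_disp=np.array([0.0004, 0.0004]),
            lambda_disp=np.array([0.2, 0.2]),
        )
        mu = assign_mus_to_positions(layout, pts, 100.0, rng)
        first = mu[:6]
        assert (first == first[0]).sum() >= 5  # one unit dominates cluster 1
        assert (mu[6:] == (1 - first[0])).sum() >= 5


class TestFiberTypes:
    def _layout(self, rng, n_mu=12, size=40):
        sizes = rng.integers(size // 2, size * 2, n_mu)
        mu_of = np.repeat(np.arange(n_mu), sizes)
        return mu_of, sizes

    def test_all_type_one_target(self, rng):
        mu_of, sizes = self._layout(rng)
        ft = assign_fiber_types(
            mu_of, sizes, FiberTypeTargets(100, 0, 0), rng, tol_pct=0.0
        )
        assert (ft == 0).all()

    def test_realized_percentages_within_tolerance(self, rng):
        mu_of, sizes = self._layout(rng, n_mu=20, size=60)
        ft = assign_fiber_types(mu_of, sizes, FiberTypeTargets(50, 28, 22), rng)
        pct = np.bincount(ft, minlength=3) / len(ft) * 100
        assert np.abs(pct - [50, 28, 22]).max() <= 1.0

    def test_slow_fibers_sit_in_smaller_units(self):
        # statistical check over seeds of the slow-to-fast size tendency
        diffs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mu_of, sizes = self._layout(rng, n_mu=25, size=50)
            ft = assign_fiber_types(
                mu_of, sizes, FiberTypeTargets(40, 30, 30), rng
            )
            s = sizes[mu_of]
            diffs.append(s[ft == 2].mean() - s[ft == 0].mean())
        assert np.mean(diffs) > 0
        assert sum(d >= 0 for d in diffs) >= 4

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            FiberTypeTargets(60, 30, 20)


class TestParameterSampling:
    def _paths(self, n, rng):
        base = np.stack(
            [np.zeros(3), np.zeros(3), np.array([0.0, 75.0, 150.0])], axis=1
        )
        paths = np.tile(base, (n, 1, 1))
        paths[:, :, 0] += rng.uniform(-5, 5, n)[:, None]
        return paths

    def test_cv_hits_range_endpoints_and_is_monotone(self, rng):
        cfg = desk_config()
        n = 500
        ft = rng.integers(0, 3, n)
        out = sample_fiber_parameters(ft, self._paths(n, rng), cfg, rng)
        prod = out["r"] * out["sigma_ic"]
        assert out["cv"][np.argmin(prod)] == pytest.approx(3.0)
        assert out["cv"][np.argmax(prod)] == pytest.approx(5.0)
        order = np.argsort(prod)
        assert np.all(np.diff(out["cv"][order]) >= -1e-12)

    def test_constant_population_maps_to_midpoint(self, rng):
        from dataclasses import replace

        from semgsim.config import FiberTypeParams, GaussianSpec

        cfg = desk_config()
        zero_std = {
            t: FiberTypeParams(
                **{
                    k: GaussianSpec(getattr(p, k).avg, 1e-300)
                    for k in (
                        "r",
                        "sigma_ic",
                        "thr",
                        "f_base",
                        "tau_up",
                        "tau_down",
                    )
                }
            )
            for t, p in cfg.fiber_params.items()
        }
        cfg = replace(cfg, fiber_params=zero_std)
        ft = np.zeros(20, dtype=int)
        out = sample_fiber_parameters(ft, self._paths(20, rng), cfg, rng)
        assert np.allclose(out["cv"], 4.0)

    def test_type_one_radius_statistics(self, rng):
        cfg = desk_config()
        n = 10000
        ft = np.zeros(n, dtype=int)
        out = sample_fiber_parameters(ft, self._paths(n, rng), cfg, rng)
        assert out["r"].mean() == pytest.approx(20.0, rel=0.03)
        assert out["r"].std() == pytest.approx(5.0, rel=0.08)
        assert (out["r"] > 0).all()

    def test_nmj_lies_on_polyline_at_fraction(self, rng):
        cfg = desk_config()
        n = 50
        paths = self._paths(n, rng)
        out = sample_fiber_parameters(
            rng.integers(0, 3, n), paths, cfg, rng
        )
        # junction z equals top minus fraction of length (z-monotone paths)
        z_expect = 150.0 - out["nmj_frac"] * 150.0
        assert np.allclose(out["nmj_pos"][:, 2], z_expect, atol=1e-9)

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_fiber_parameters(
                np.empty(0, dtype=int), np.empty((0, 3, 3)), desk_config(), rng
            )


class TestLayout:
    def test_sizes_sum_to_fiber_count(self, rng):
        cfg = desk_config(n_fib=999, n_mu=13)
        layout = make_mu_layout(cfg, 999, rng)
        assert layout.mu_sizes.sum() == 999
        assert (layout.mu_sizes >= 1).all()

    def test_dispersion_means_scale_with_size(self, rng):
        cfg = desk_config(n_fib=5000, n_mu=40)
        layout = make_mu_layout(cfg, 5000, rng)
        big = layout.mu_sizes >= np.median(layout.mu_sizes)
        assert layout.r_disp[big].mean() > layout.r_disp[~big].mean()
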