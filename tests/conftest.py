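"""Shared fixtures: a desk-scale phantom pipeline reused across test modules.

Everything is generated programmatically; the heavy artifacts (lead field,
calibration matrix, one simulated contraction) are session-scoped so the
suite solves them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from semgsim.anatomy import FiberTypeTargets, build_anatomy
from semgsim.config import desk_config
from semgsim.control import build_mref, prepare_reference_force
from semgsim.engine import compute_fiber_templates, simulate_contraction
from semgsim.synthetic import (
    ForceProfileSpec,
    PhantomSpec,
    make_force_profile,
    make_phantom,
)
from semgsim.volume import place_electrodes, solve_lead_field


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(n_fib=600, n_slices=3)


@pytest.fixture(scope="session")
def small_cfg():
    return desk_config(n_fib=600, n_mu=15, rate_step=2.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec, seed=11)


@pytest.fixture(scope="session")
def small_anatomy(small_phantom, small_spec, small_cfg):
    _, stack = small_phantom
    return build_anatomy(
        stack,
        small_cfg,
        FiberTypeTargets(50, 28, 22),
        seed=1,
        section_area_mm2=small_spec.biceps_area_mm2,
    )


@pytest.fixture(scope="session")
def small_leadfield(small_phantom, small_cfg):
    grid, _ = small_phantom
    electrodes = place_electrodes(grid, small_cfg.electrodes)
    return solve_lead_field(grid, electrodes)


@pytest.fixture(scope="session")
def small_mref(small_anatomy, small_cfg):
    return build_mref(small_anatomy, small_cfg)


@pytest.fixture(scope="session")
def iso_ref(small_mref, small_cfg):
    _, mref = small_mref
    raw = make_force_profile(
        ForceProfileSpec(task="isometric", level_pct_mvc=10, rep_duration_s=3),
        mvc=1.0,
    )
    return prepare_reference_force(raw, 100.0, 1.0, mref.model_mvc, small_cfg.fs)


@pytest.fixture(scope="session")
def small_templates(small_anatomy, small_leadfield, small_cfg):
    return compute_fiber_templates(small_anatomy, small_leadfield, small_cfg)


@pytest.fixture(scope="session")
def sim_result(small_anatomy, small_mref, small_leadfield, iso_ref, small_cfg, small_templates):
    _, mref = small_mref
    return simulate_contraction(
        small_anatomy,
        mref,
        small_leadfield,
        iso_ref,
        small_cfg,
        seed=3,
        templates=small_templates,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
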