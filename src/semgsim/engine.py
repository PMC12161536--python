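"""End-to-end contraction simulation.

Pipeline: reference force -> per-sample recruitment plan -> per-unit spike
trains -> fiber innervations (acetylcholine triggering) -> traveling
tripole pole trains -> lead-field superposition -> monopolar and bipolar
surface EMG, plus twitch-summed muscle force.

Because the geometry is static during a contraction, each fiber's single
innervation produces the same electrode waveform every time; the engine
therefore propagates each fiber's pole train once, superposes it through
the lead field into a per-fiber, per-electrode template, and accumulates
time-shifted copies at the innervation instants.  By linearity of the
volume conductor this is exactly the pole-by-pole sum, at a fraction of
the cost.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import h5py
import numpy as np

from .anatomy import Anatomy
from .config import SimConfig
from .control import (
    MRef,
    RecruitmentPlan,
    ReferenceForce,
    generate_spike_trains,
    select_recruitment,
)
from .fiber import (
    RosenfalckParams,
    TwitchParams,
    propagate_poles,
    tripole_decompose,
    twitch_kernel,
)
from .motoneuron import AChParams, trigger_innervations
from .volume import LeadField, superpose_potentials

__all__ = [
    "SimResult",
    "compute_fiber_templates",
    "simulate_contraction",
    "write_result",
    "read_result",
]


@dataclass
class SimResult:
    """Simulated multichannel sEMG and force on one clock.

    ``semg_monopolar`` is (n_channels, n_samples); ``semg_bipolar`` is
    (n_pairs, n_samples), each row the difference of its two monopolar
    parents; ``force`` is (n_samples,) in model force units.
    """

    semg_monopolar: np.ndarray
    semg_bipolar: np.ndarray
    force: np.ndarray
    fs: float
    seed: int
    config_hash: str = ""
    anatomy_hash: str = ""
    plan: RecruitmentPlan | None = None
    innervation_counts: np.ndarray | None = None


def anatomy_hash(anatomy: Anatomy) -> str:
    md = hashlib.md5()
    for arr in (anatomy.paths, anatomy.r, anatomy.thr, anatomy.mu_of_fiber):
        md.update(np.ascontiguousarray(arr).tobytes())
    return md.hexdigest()[:16]


def config_hash(cfg: SimConfig) -> str:
    from dataclasses import asdict

    return hashlib.md5(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def compute_fiber_templates(
    anatomy: Anatomy,
    lead: LeadField,
    cfg: SimConfig,
    fiber_ids: Sequence[int] | None = None,
) -> List[np.ndarray]:
    """Single-innervation electrode waveform of each fiber.

    Returns, per fiber, an (n_electrodes, n_steps) template: the mirrored
    tripole pair propagated from the junction to the tendons and projected
    through the lead field.  Indexed like ``fiber_ids`` (default: all).
    """
    if fiber_ids is None:
        fiber_ids = range(anatomy.n_fib)
    ros = RosenfalckParams.from_config(cfg.membrane)
    templates = []
    for f in fiber_ids:
        tri = tripole_decompose(
            ros, float(anatomy.sigma_ic[f]), float(anatomy.r[f])
        )
        train = propagate_poles(
            anatomy.paths[f],
            float(anatomy.nmj_arc_mm[f]),
            float(anatomy.cv[f]),
            tri,
            cfg.fs,
            ramp_length_mm=cfg.ramp_length_mm,
            alpha=cfg.membrane.alpha,
        )
        templates.append(superpose_potentials(lead, train))
    return templates


def _accumulate(out: np.ndarray, idx: np.ndarray, kernel: np.ndarray) -> None:
    """Add ``kernel`` (2D channels x k or 1D) at each sample index."""
    n = out.shape[-1]
    k = kernel.shape[-1]
    for i in idx:
        if i >= n:
            continue
        m = min(k, n - i)
        out[..., i : i + m] += kernel[..., :m]


def simulate_contraction(
    anatomy: Anatomy,
    mref: MRef,
    lead: LeadField,
    ref: ReferenceForce,
    cfg: SimConfig,
    seed: int,
    templates: List[np.ndarray] | None = None,
    mu_subset: Sequence[int] | None = None,
) -> SimResult:
    """Run a full contraction against a reference force profile.

    All upstream artifacts must share the configuration clock
    (``ref.fs == cfg.fs``); precomputed ``templates`` (from
    :func:`compute_fiber_templates`) are accepted to amortise repeated runs
    on the same anatomy and lead field.  ``mu_subset`` restricts the output
    to the contributions of the listed motor units while keeping the plan,
    spike trains and innervations of the full model — by linearity the
    results of complementary subsets sum to the full run.
    """
    if abs(ref.fs - cfg.fs) > 1e-9:
        raise ValueError("reference force clock does not match the simulation")
    n_samples = len(ref.samples)
    plan = select_recruitment(
        ref, mref, rate_std_max_hz=cfg.control.rate_std_max_hz
    )
    spikes = generate_spike_trains(plan, mref, seed)
    spike_samples = [np.round(s * cfg.fs).astype(np.int64) for s in spikes]
    ach = AChParams.from_config(cfg.ach)
    innervations = trigger_innervations(
        spike_samples,
        anatomy.mu_of_fiber,
        anatomy.thr * cfg.ach.threshold_scale,
        ach,
        cfg.fs,
        n_samples,
    )
    keep_mu = (
        None if mu_subset is None else np.isin(anatomy.mu_of_fiber, mu_subset)
    )
    if keep_mu is not None:
        innervations = [
            ev if keep_mu[f] else np.empty(0, dtype=np.int64)
            for f, ev in enumerate(innervations)
        ]
    if templates is None:
        active = [f for f in range(anatomy.n_fib) if len(innervations[f])]
        tmpl_map = dict(
            zip(active, compute_fiber_templates(anatomy, lead, cfg, active))
        )
    else:
        tmpl_map = {f: templates[f] for f in range(anatomy.n_fib)}
    n_elec = lead.electrodes.n_electrodes
    semg = np.zeros((n_elec, n_samples))
    force = np.zeros(n_samples)
    counts = np.zeros(anatomy.n_fib, dtype=np.int64)
    for f, ev in enumerate(innervations):
        if len(ev) == 0:
            continue
        counts[f] = len(ev)
        _accumulate(semg, ev, tmpl_map[f])
        tw = twitch_kernel(
            TwitchParams(
                f_base=float(anatomy.f_base[f]),
                tau_up=float(anatomy.tau_up[f]),
                tau_down=float(anatomy.tau_down[f]),
                d_um=2.0 * float(anatomy.r[f]),
            ),
            cfg.fs,
        )
        _accumulate(force, ev, tw)
    pairs = lead.electrodes.bipolar_pairs
    semg_bi = np.stack([semg[a] - semg[b] for a, b in pairs]) if pairs else (
        np.zeros((0, n_samples))
    )
    return SimResult(
        semg_monopolar=semg,
        semg_bipolar=semg_bi,
        force=force,
        fs=cfg.fs,
        seed=seed,
        config_hash=config_hash(cfg),
        anatomy_hash=anatomy_hash(anatomy),
        plan=plan,
        innervation_counts=counts,
    )


def write_result(res: SimResult, path: str | Path, csv_dir: str | Path | None = None) -> None:
    """Persist a result to HDF5 (lossless) and optionally per-channel CSV."""
    try:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("semg_mono", data=res.semg_monopolar)
            h5.create_dataset("semg_bi", data=res.semg_bipolar)
            h5.create_dataset("force", data=res.force)
            h5.attrs["fs"] = res.fs
            h5.attrs["seed"] = res.seed
            h5.attrs["config_hash"] = res.config_hash
            h5.attrs["anatomy_hash"] = res.anatomy_hash
    except OSError as exc:
        raise OSError(f"failed writing result to {path}: {exc}") from exc
    if csv_dir is not None:
        csv_dir = Path(csv_dir)
        csv_dir.mkdir(parents=True, exist_ok=True)
        t = np.arange(res.semg_monopolar.shape[1]) / res.fs
        np.savetxt(
            csv_dir / "semg_mono.csv",
            np.column_stack([t, res.semg_monopolar.T]),
            delimiter=",",
            header="t_s,"
            + ",".join(f"ch{i}" for i in range(len(res.semg_monopolar))),
            comments="",
        )
        np.savetxt(
            csv_dir / "force.csv",
            np.column_stack([t, res.force]),
            delimiter=",",
            header="t_s,force",
            comments="",
        )


def read_result(path: str | Path) -> SimResult:
    with h5py.File(path, "r") as h5:
        return SimResult(
            semg_monopolar=h5["semg_mono"][...],
            semg_bipolar=h5["semg_bi"][...],
            force=h5["force"][...],
            fs=float(h5.attrs["fs"]),
            seed=int(h5.attrs["seed"]),
            config_hash=str(h5.attrs["config_hash"]),
            anatomy_hash=str(h5.attrs["anatomy_hash"]),
        )
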