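"""Simulation configuration.

All tunable physiological and numerical parameters live here, grouped the way
the model is organised: membrane electrophysiology, acetylcholine kinetics,
per-type muscle-fiber property distributions, motor-unit pool statistics,
tissue conductivities, electrode layout and the motor-control rate grid.

Defaults reproduce the biceps-brachii parameterisation used throughout the
package documentation.  Configurations round-trip through YAML
(:func:`load_config` / :func:`save_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, Tuple

import yaml

__all__ = [
    "GaussianSpec",
    "FiberTypeParams",
    "AChConfig",
    "MotorUnitConfig",
    "MembraneConfig",
    "TissueConfig",
    "ElectrodeConfig",
    "ControlConfig",
    "SimConfig",
    "FIBER_TYPES",
    "TISSUE_LABELS",
    "default_config",
    "desk_config",
    "load_config",
    "save_config",
]

#: Categorical fiber types, ordered slow to fast.
FIBER_TYPES = ("I", "IIa", "IIx")

#: Voxel tissue codes used in label grids.
TISSUE_LABELS = {
    "air": 0,
    "fat_skin": 1,
    "muscle": 2,
    "cortical_bone": 3,
    "cancellous_bone": 4,
}


@dataclass(frozen=True)
class GaussianSpec:
    """Mean/std pair for a Gaussian-distributed parameter."""

    avg: float
    std: float

    def as_tuple(self) -> Tuple[float, float]:
        return (self.avg, self.std)


@dataclass(frozen=True)
class FiberTypeParams:
    """Per-type muscle-fiber property distributions.

    Units: ``r`` in um, ``sigma_ic`` in S/m, ``thr`` in mM, ``f_base`` in mN,
    ``tau_up``/``tau_down`` in ms.
    """

    r: GaussianSpec
    sigma_ic: GaussianSpec
    thr: GaussianSpec
    f_base: GaussianSpec
    tau_up: GaussianSpec
    tau_down: GaussianSpec


@dataclass(frozen=True)
class AChConfig:
    """Acetylcholine release kinetics (single-impulse profile).

    ``am`` is the maximum released concentration (mM); ``kr`` and ``kd`` are
    the release and degradation rates.  ``units`` selects how the printed
    rate constants are interpreted: ``"per_s"`` (verbatim, s^-1) or
    ``"per_ms"`` (ms^-1, i.e. 1000x faster kinetics).  ``threshold_scale``
    multiplies every fiber's innervation threshold before comparison with the
    summed cleft concentration; 1.0 keeps thresholds verbatim.
    """

    am: float = 1.0
    kr: float = 0.45
    kd: float = 30.0
    units: str = "per_s"
    threshold_scale: float = 1.0

    @property
    def kr_per_s(self) -> float:
        return self.kr * (1000.0 if self.units == "per_ms" else 1.0)

    @property
    def kd_per_s(self) -> float:
        return self.kd * (1000.0 if self.units == "per_ms" else 1.0)


@dataclass(frozen=True)
class MotorUnitConfig:
    """Motor-unit pool statistics.

    ``size`` and ``number`` are Gaussians for fibers-per-unit and unit count.
    ``r_range`` is the dispersion radius band as a fraction of the muscle
    cross-section area; ``lambda_range`` is the dispersion std band as a
    fraction of R.  Means scale linearly with unit size across these bands.
    """

    size: GaussianSpec = GaussianSpec(300.0, 100.0)
    number: GaussianSpec = GaussianSpec(1000.0, 250.0)
    r_range: Tuple[float, float] = (0.04, 0.40)
    lambda_range: Tuple[float, float] = (0.20, 0.50)


@dataclass(frozen=True)
class MembraneConfig:
    """Membrane action-potential shape constants.

    ``a`` (mV) action-potential amplitude, ``b`` (mV) resting potential,
    ``alpha`` (mm^-1) spatial scale of the intracellular waveform, ``c``
    dimensionless amplitude constant that absorbs the unit bookkeeping
    between membrane current and recorded voltage.
    """

    a: float = 96.0
    b: float = 90.0
    alpha: float = 0.55
    c: float = 1500.0


@dataclass(frozen=True)
class TissueConfig:
    """Tissue conductivities in S/m, keyed by label name."""

    conductivity: Dict[str, float] = field(
        default_factory=lambda: {
            "air": 0.0,
            "fat_skin": 4.07e-2,
            "muscle": 0.30,
            "cortical_bone": 2.00e-2,
            "cancellous_bone": 7.56e-2,
        }
    )

    def by_label(self) -> Dict[int, float]:
        return {TISSUE_LABELS[k]: v for k, v in self.conductivity.items()}


@dataclass(frozen=True)
class ElectrodeConfig:
    """Skin electrode grid: ``m`` rings in theta x ``n`` rows in z.

    ``spacing_mm`` is the inter-electrode distance along z; the theta arc is
    chosen so the circumferential spacing matches at the casting radius.
    ``z_center_frac`` centres the grid along the z axis.
    """

    m: int = 2
    n: int = 3
    spacing_mm: float = 15.0
    z_center_frac: float = 0.30
    cast_radius_mm: float = 80.0


@dataclass(frozen=True)
class ControlConfig:
    """Motor-control strategy knobs.

    The force-response matrix is computed on ``rate_min..rate_max`` Hz in
    steps of ``rate_step``.  ``calib_duration_s`` is the steady spike train
    length used for calibration, averaged over the trailing
    ``calib_window_s``.  Assigned firing rates get a Gaussian spread up to
    ``rate_std_max_hz`` scaled by the recruited fraction.
    """

    rate_min: float = 8.0
    rate_max: float = 42.0
    rate_step: float = 1.0
    calib_duration_s: float = 2.0
    calib_window_s: float = 1.5
    rate_std_max_hz: float = 10.0


@dataclass(frozen=True)
class SimConfig:
    """Top-level configuration bundle."""

    fs: float = 2000.0
    n_fib: int = 200_000
    fiber_params: Dict[str, FiberTypeParams] = field(
        default_factory=lambda: {
            "I": FiberTypeParams(
                r=GaussianSpec(20.0, 5.0),
                sigma_ic=GaussianSpec(0.35, 0.25),
                thr=GaussianSpec(0.45, 0.15),
                f_base=GaussianSpec(65.0, 15.0),
                tau_up=GaussianSpec(37.0, 12.0),
                tau_down=GaussianSpec(50.0, 14.0),
            ),
            "IIa": FiberTypeParams(
                r=GaussianSpec(27.5, 7.5),
                sigma_ic=GaussianSpec(0.5, 0.5),
                thr=GaussianSpec(0.6, 0.2),
                f_base=GaussianSpec(75.0, 20.0),
                tau_up=GaussianSpec(15.0, 5.0),
                tau_down=GaussianSpec(20.0, 7.0),
            ),
            "IIx": FiberTypeParams(
                r=GaussianSpec(30.0, 10.0),
                sigma_ic=GaussianSpec(0.7, 0.5),
                thr=GaussianSpec(0.9, 0.3),
                f_base=GaussianSpec(100.0, 25.0),
                tau_up=GaussianSpec(7.0, 3.0),
                tau_down=GaussianSpec(10.0, 4.0),
            ),
        }
    )
    nmj_frac: GaussianSpec = GaussianSpec(0.40, 0.05)
    cv_range: Tuple[float, float] = (3.0, 5.0)
    ach: AChConfig = AChConfig()
    motor_units: MotorUnitConfig = MotorUnitConfig()
    membrane: MembraneConfig = MembraneConfig()
    tissues: TissueConfig = TissueConfig()
    electrodes: ElectrodeConfig = ElectrodeConfig()
    control: ControlConfig = ControlConfig()
    ramp_length_mm: float | None = None  # None -> tripole span (3+sqrt(3))/alpha

    @property
    def dt(self) -> float:
        return 1.0 / self.fs


def default_config() -> SimConfig:
    """Full-scale biceps configuration (~200k fibers, ~1000 motor units)."""
    return SimConfig()


def desk_config(
    n_fib: int = 2000,
    n_mu: int = 50,
    rate_step: float = 1.0,
) -> SimConfig:
    """Scaled-down configuration for desk-scale runs.

    Keeps every distribution shape of the full model but shrinks the fiber
    and motor-unit counts (preserving the relative std of the pool
    statistics) so an end-to-end contraction runs in minutes on one core.
    The acetylcholine threshold scale is set to 0.012 so the innervation
    threshold band spans the cleft-concentration band reachable between the
    minimum and maximum firing rates (see docs/methods.md).
    """
    base = default_config()
    mu = MotorUnitConfig(
        size=GaussianSpec(n_fib / n_mu, n_fib / n_mu / 3.0),
        number=GaussianSpec(float(n_mu), n_mu / 4.0),
        r_range=base.motor_units.r_range,
        lambda_range=base.motor_units.lambda_range,
    )
    return replace(
        base,
        n_fib=n_fib,
        motor_units=mu,
        ach=replace(base.ach, threshold_scale=0.012),
        control=replace(base.control, rate_step=rate_step),
    )


# ---------------------------------------------------------------------------
# YAML round-trip


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(asdict(cfg)), fh, sort_keys=False)


def _gauss(d) -> GaussianSpec:
    return GaussianSpec(float(d["avg"]), float(d["std"]))


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    fiber_params = {
        t: FiberTypeParams(**{k: _gauss(v) for k, v in p.items()})
        for t, p in d["fiber_params"].items()
    }
    return SimConfig(
        fs=float(d["fs"]),
        n_fib=int(d["n_fib"]),
        fiber_params=fiber_params,
        nmj_frac=_gauss(d["nmj_frac"]),
        cv_range=tuple(d["cv_range"]),
        ach=AChConfig(**d["ach"]),
        motor_units=MotorUnitConfig(
            size=_gauss(d["motor_units"]["size"]),
            number=_gauss(d["motor_units"]["number"]),
            r_range=tuple(d["motor_units"]["r_range"]),
            lambda_range=tuple(d["motor_units"]["lambda_range"]),
        ),
        membrane=MembraneConfig(**d["membrane"]),
        tissues=TissueConfig(conductivity=dict(d["tissues"]["conductivity"])),
        electrodes=ElectrodeConfig(**d["electrodes"]),
        control=ControlConfig(**d["control"]),
        ramp_length_mm=d.get("ramp_length_mm"),
    )
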