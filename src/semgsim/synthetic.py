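"""Synthetic study inputs: layered arm phantom and reference force tasks.

The phantom is a concentric-cylinder upper arm — cancellous bone core,
cortical bone shell, muscle annulus, fat/skin layer — on a regular voxel
grid spanning x, y in [-50, 50] mm and z in [0, 150] mm.  A configurable
angular sector of the muscle annulus stands in for the biceps and is filled
with a deterministic, evenly spread fiber cross-section at each of several
longitudinal slices.

Force profiles emulate the two laboratory tasks: sustained isometric
plateaus (smoothed trapezoids at a given %MVC) and periodic isotonic bursts
(raised-cosine bells), sampled at the dynamometer rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import CrossSectionStack
from .config import TISSUE_LABELS, TissueConfig
from .volume import VolumeGrid

__all__ = [
    "PhantomSpec",
    "ForceProfileSpec",
    "make_phantom",
    "make_force_profile",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Concentric-cylinder arm phantom geometry (mm).

    Radii must strictly increase: cancellous < cortical < muscle < skin.
    The biceps sector (``sector_center_deg`` +/- half ``sector_width_deg``,
    radial band ``biceps_r_inner..biceps_r_outer``) must lie inside the
    muscle annulus.  ``n_fib`` points fill the sector at each of
    ``n_slices`` z positions.
    """

    r_cancellous: float = 7.0
    r_cortical: float = 12.0
    r_muscle: float = 40.0
    r_skin: float = 45.0
    x_range: tuple = (-50.0, 50.0)
    y_range: tuple = (-50.0, 50.0)
    z_range: tuple = (0.0, 150.0)
    voxel_mm: float = 4.0
    sector_center_deg: float = 90.0
    sector_width_deg: float = 120.0
    biceps_r_inner: float = 15.0
    biceps_r_outer: float = 35.0
    n_fib: int = 2000
    n_slices: int = 3
    jitter_frac: float = 0.25  # per-slice point jitter, fraction of spacing

    def __post_init__(self):
        radii = (self.r_cancellous, self.r_cortical, self.r_muscle, self.r_skin)
        if not all(a < b for a, b in zip(radii, radii[1:])):
            raise ValueError("phantom radii must strictly increase")
        if not (
            self.r_cortical <= self.biceps_r_inner
            and self.biceps_r_outer <= self.r_muscle
        ):
            raise ValueError("biceps sector must lie inside the muscle annulus")

    @property
    def biceps_area_mm2(self) -> float:
        return (
            0.5
            * np.radians(self.sector_width_deg)
            * (self.biceps_r_outer**2 - self.biceps_r_inner**2)
        )


def _sector_points(spec: PhantomSpec, n: int, rng: np.random.Generator):
    """Evenly spread points over the annular sector (sunflower layout with
    optional jitter).  Area-uniform in radius, golden-angle in theta."""
    i = np.arange(n) + 0.5
    r2 = spec.biceps_r_inner**2 + (i / n) * (
        spec.biceps_r_outer**2 - spec.biceps_r_inner**2
    )
    r = np.sqrt(r2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    w = np.radians(spec.sector_width_deg)
    th0 = np.radians(spec.sector_center_deg) - w / 2
    th = th0 + np.mod(i * golden, w)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    if spec.jitter_frac > 0:
        spacing = np.sqrt(spec.biceps_area_mm2 / n)
        pts = pts + rng.normal(0.0, spec.jitter_frac * spacing, pts.shape)
    return pts


def make_phantom(
    spec: PhantomSpec,
    tissues: TissueConfig | None = None,
    seed: int = 0,
) -> tuple[VolumeGrid, CrossSectionStack]:
    """Build the label grid and the biceps fiber cross-section stack.

    Voxel labels come from the radius of each voxel centre; the stack holds
    ``n_fib`` points per slice at evenly spaced z positions, deterministic
    given the spec and seed.
    """
    if tissues is None:
        tissues = TissueConfig()
    vx = spec.voxel_mm
    x = np.arange(spec.x_range[0], spec.x_range[1] + vx / 2, vx)
    y = np.arange(spec.y_range[0], spec.y_range[1] + vx / 2, vx)
    z = np.arange(spec.z_range[0], spec.z_range[1] + vx / 2, vx)
    cx = 0.5 * (x[:-1] + x[1:])
    cy = 0.5 * (y[:-1] + y[1:])
    rr = np.hypot(cx[:, None], cy[None, :])
    section = np.full(rr.shape, TISSUE_LABELS["air"], dtype=np.int8)
    section[rr <= spec.r_skin] = TISSUE_LABELS["fat_skin"]
    section[rr <= spec.r_muscle] = TISSUE_LABELS["muscle"]
    section[rr <= spec.r_cortical] = TISSUE_LABELS["cortical_bone"]
    section[rr <= spec.r_cancellous] = TISSUE_LABELS["cancellous_bone"]
    labels = np.repeat(section[:, :, None], len(z) - 1, axis=2)
    grid = VolumeGrid.from_tissue_config(x, y, z, labels, tissues)

    rng = np.random.default_rng(seed)
    zs = np.linspace(spec.z_range[0], spec.z_range[1], spec.n_slices)
    layers = [_sector_points(spec, spec.n_fib, rng) for _ in zs]
    stack = CrossSectionStack(layers=layers, z_positions=zs)
    return grid, stack


@dataclass(frozen=True)
class ForceProfileSpec:
    """Reference-force task description.

    ``task`` is ``"isometric"`` (smoothed trapezoid plateaus) or
    ``"isotonic"`` (raised-cosine bursts); ``level_pct_mvc`` in (0, 100].
    Durations in seconds, ``rate_hz`` is the recording rate of the raw
    series (dynamometer-style).
    """

    task: str = "isometric"
    level_pct_mvc: float = 10.0
    reps: int = 1
    rep_duration_s: float = 5.0
    rest_duration_s: float = 2.0
    rate_hz: float = 100.0
    ramp_s: float = 0.5

    def __post_init__(self):
        if self.task not in ("isometric", "isotonic"):
            raise ValueError("task must be isometric or isotonic")
        if not (0.0 <= self.level_pct_mvc <= 100.0):
            raise ValueError("level must be within [0, 100] %MVC")
        if min(self.rep_duration_s, self.rest_duration_s) < 0:
            raise ValueError("durations must be non-negative")


def make_force_profile(spec: ForceProfileSpec, mvc: float) -> np.ndarray:
    """Raw force series (same units as ``mvc``) at ``spec.rate_hz``.

    Isometric reps ramp up over ``ramp_s``, hold ``level_pct_mvc`` of mvc
    for the rep duration, and ramp down; isotonic reps are raised-cosine
    bells peaking at the level.  Reps are separated by zero-force rest.
    """
    fs = spec.rate_hz
    peak = spec.level_pct_mvc / 100.0 * mvc
    rest = np.zeros(int(round(spec.rest_duration_s * fs)))
    if spec.task == "isometric":
        n_ramp = max(int(round(spec.ramp_s * fs)), 1)
        n_hold = int(round(spec.rep_duration_s * fs))
        up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_ramp)))
        rep = np.concatenate([up, np.ones(n_hold), up[::-1]]) * peak
    else:
        n_rep = max(int(round(spec.rep_duration_s * fs)), 2)
        rep = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_rep) / n_rep)) * peak
    parts = []
    for k in range(spec.reps):
        parts.append(rep)
        if k < spec.reps - 1:
            parts.append(rest)
    return np.concatenate(parts) if parts else np.zeros(0)
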