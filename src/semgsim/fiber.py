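"""Per-fiber electrophysiology and mechanics.

The intracellular action potential along the membrane follows Rosenfalck's
analytic waveform ``Vm(z) = A (alpha z)^3 exp(-alpha z) - B``.  The
transmembrane current is proportional to its second spatial derivative and
is triphasic; it is collapsed onto three balanced point charges (a tripole)
located at the charge centroid of each current lobe.  On innervation a pair
of mirrored tripoles travels from the neuromuscular junction toward each
tendon along the fiber's 3D polyline at the fiber's conduction velocity,
with linear amplitude ramps in a generation region around the junction and
an extinction region ending at each tendon.

Mechanics: a single innervation produces a twitch
``F(t) = F_base (1 - exp(-t/tau_up)) d^2 exp(-t/tau_down)`` and a fiber's
force profile is the linear superposition of twitches at its innervation
instants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import MembraneConfig

__all__ = [
    "RosenfalckParams",
    "Tripole",
    "PoleTrain",
    "TwitchParams",
    "rosenfalck_vm",
    "tripole_decompose",
    "propagate_poles",
    "single_twitch_force",
    "fiber_force_profile",
    "twitch_kernel",
    "twitch_cumulative",
    "arc_lengths",
    "point_at_arc",
]

# Zero crossings of the second derivative of u^3 exp(-u): u (u^2 - 6u + 6)
_U1 = 3.0 - math.sqrt(3.0)
_U2 = 3.0 + math.sqrt(3.0)


@dataclass(frozen=True)
class RosenfalckParams:
    """Membrane waveform constants.

    ``a`` (mV), ``b`` (mV), ``alpha`` (mm^-1), ``c`` dimensionless.
    """

    a: float = 96.0
    b: float = 90.0
    alpha: float = 0.55
    c: float = 1500.0

    def __post_init__(self):
        if min(self.a, self.b, self.alpha, self.c) <= 0:
            raise ValueError("Rosenfalck parameters must be positive")

    @classmethod
    def from_config(cls, m: MembraneConfig) -> "RosenfalckParams":
        return cls(a=m.a, b=m.b, alpha=m.alpha, c=m.c)

    @property
    def span_mm(self) -> float:
        """Distance between the outer zero crossings of the current wave."""
        return _U2 / self.alpha


def rosenfalck_vm(z, p: RosenfalckParams):
    """Membrane voltage (mV) at distance ``z`` (mm) behind the wavefront.

    Raises for negative ``z``; propagation handles direction symmetry, the
    waveform itself is one-sided.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative")
    u = p.alpha * z
    return p.a * u**3 * np.exp(-u) - p.b


def _lobe_charge_centroid(a: float, b: float) -> tuple[float, float]:
    """Charge and centroid of one lobe of g''(u) for g(u) = u^3 exp(-u).

    Uses the closed-form antiderivatives g'(u) = (3u^2 - u^3) e^-u and
    int u g'' du = u g'(u) - g(u); the upper bound may be ``inf``.
    """

    def gp(u):
        return (3 * u * u - u**3) * math.exp(-u) if math.isfinite(u) else 0.0

    def ug_minus_g(u):
        if not math.isfinite(u):
            return 0.0
        return u * gp(u) - u**3 * math.exp(-u)

    q = gp(b) - gp(a)
    m1 = ug_minus_g(b) - ug_minus_g(a)
    return q, m1 / q


@dataclass(frozen=True)
class Tripole:
    """Three balanced point charges trailing the depolarisation wavefront.

    ``charges`` sum to zero (enforced on the middle pole); ``offsets_mm``
    are distances behind the wavefront, strictly increasing.
    """

    charges: np.ndarray
    offsets_mm: np.ndarray

    def __post_init__(self):
        if abs(float(np.sum(self.charges))) > 1e-9 * float(
            np.max(np.abs(self.charges))
        ):
            raise ValueError("tripole charges must balance to zero")
        if not np.all(np.diff(self.offsets_mm) > 0):
            raise ValueError("tripole offsets must be strictly increasing")


def tripole_decompose(
    p: RosenfalckParams, sigma_ic: float, r_um: float
) -> Tripole:
    """Collapse the triphasic membrane current into three point charges.

    The current is ``C sigma_ic pi r^2 Vm''(z)``; its sign lobes are bounded
    by the analytic zero crossings ``alpha z = 0, 3 - sqrt(3), 3 + sqrt(3)``.
    Each lobe is integrated to a point charge at its charge centroid.  The
    middle charge is set to minus the sum of the outer two, so the net
    charge is exactly zero regardless of rounding.
    """
    if sigma_ic <= 0 or r_um <= 0:
        raise ValueError("sigma_ic and r must be positive")
    lobes = [
        _lobe_charge_centroid(0.0, _U1),
        _lobe_charge_centroid(_U1, _U2),
        _lobe_charge_centroid(_U2, math.inf),
    ]
    scale = p.c * sigma_ic * math.pi * r_um**2 * p.a * p.alpha
    q = np.array([lobe[0] for lobe in lobes]) * scale
    q[1] = -(q[0] + q[2])
    offsets = np.array([lobe[1] for lobe in lobes]) / p.alpha
    return Tripole(charges=q, offsets_mm=offsets)


# ---------------------------------------------------------------------------
# Polyline geometry helpers


def arc_lengths(path: np.ndarray) -> np.ndarray:
    """Cumulative arc length (mm) at each waypoint of an (n, 3) polyline."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_at_arc(path: np.ndarray, s, cum: np.ndarray | None = None):
    """3D point(s) at arc position(s) ``s`` along the polyline."""
    if cum is None:
        cum = arc_lengths(path)
    s = np.clip(np.asarray(s, dtype=float), 0.0, cum[-1])
    return np.stack(
        [np.interp(s, cum, path[:, k]) for k in range(3)], axis=-1
    )


@dataclass
class PoleTrain:
    """Active point sources of one innervation, sampled on the clock.

    ``positions[t]`` is an (n_poles, 3) array in mm and ``amplitudes[t]``
    the matching signed charges after ramp scaling, for sample offsets
    ``t = 0, 1, ...`` relative to the innervation sample.  Two mirrored
    tripoles are pooled per timestep.
    """

    fs: float
    positions: list = field(default_factory=list)
    amplitudes: list = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.positions)

    def to_records(self):
        """Flatten to (t_index, x, y, z, amplitude) rows for debug dumps."""
        rows = []
        for t, (pos, amp) in enumerate(zip(self.positions, self.amplitudes)):
            for p, a in zip(pos, amp):
                rows.append((t, p[0], p[1], p[2], a))
        return np.array(rows) if rows else np.empty((0, 5))


def propagate_poles(
    path: np.ndarray,
    nmj_arc_mm: float,
    cv_m_s: float,
    tripole: Tripole,
    fs: float,
    ramp_length_mm: float | None = None,
    alpha: float = 0.55,
) -> PoleTrain:
    """Travel a mirrored tripole pair from the junction to both tendons.

    Every sample the wavefronts advance ``cv * dt`` in arc length along the
    polyline, one toward each tendon.  All three charges of a tripole are
    jointly scaled by a linear generation ramp over ``ramp_length_mm`` from
    the junction and a linear extinction ramp over the same distance before
    the tendon; a train ends when its wavefront reaches the tendon.  The
    default ramp length is the tripole span ``(3 + sqrt 3)/alpha``.

    ``nmj_arc_mm`` is the junction's arc-length position on the polyline; it
    must lie within the polyline (a geometry error otherwise).
    """
    cum = arc_lengths(path)
    total = cum[-1]
    if not (0.0 <= nmj_arc_mm <= total):
        raise ValueError("neuromuscular junction is not on the fiber polyline")
    if ramp_length_mm is None:
        ramp_length_mm = _U2 / alpha
    dt = 1.0 / fs
    step_mm = cv_m_s * 1000.0 * dt
    train = PoleTrain(fs=fs)
    # distances from NMJ to the two tendons (positive and negative arc sense)
    d_up = total - nmj_arc_mm
    d_down = nmj_arc_mm
    n_steps = int(math.ceil(max(d_up, d_down) / step_mm)) + 1
    offs = tripole.offsets_mm
    q = tripole.charges
    for k in range(n_steps):
        front = k * step_mm
        pos_list = []
        amp_list = []
        for direction, d_tendon in ((+1, d_up), (-1, d_down)):
            if front > d_tendon:
                continue  # this train's wavefront has reached its tendon
            ramp = min(
                1.0,
                front / ramp_length_mm,
                (d_tendon - front) / ramp_length_mm,
            )
            ramp = max(ramp, 0.0)
            # poles trail the wavefront; until they emerge they sit clamped
            # at the junction so the tripole stays balanced at every step
            pole_d = np.clip(front - offs, 0.0, d_tendon)
            s = nmj_arc_mm + direction * pole_d
            pos_list.append(point_at_arc(path, s, cum))
            amp_list.append(q * ramp)
        if pos_list:
            train.positions.append(np.vstack(pos_list))
            train.amplitudes.append(np.concatenate(amp_list))
        else:
            train.positions.append(np.empty((0, 3)))
            train.amplitudes.append(np.empty(0))
    return train


# ---------------------------------------------------------------------------
# Twitch force


@dataclass(frozen=True)
class TwitchParams:
    """Single-twitch parameters: ``f_base`` mN, ``tau_up``/``tau_down`` ms,
    ``d_um`` fiber diameter in um."""

    f_base: float
    tau_up: float
    tau_down: float
    d_um: float

    def __post_init__(self):
        if min(self.f_base, self.tau_up, self.tau_down, self.d_um) <= 0:
            raise ValueError("twitch parameters must be positive")


def single_twitch_force(t_ms, p: TwitchParams):
    """Twitch force at ``t_ms`` after innervation; exactly 0 for ``t < 0``.

    ``F_base (1 - exp(-t/tau_up)) d^2 exp(-t/tau_down)``, in model force
    units of mN * um^2 (the diameter factor is kept verbatim).
    """
    t = np.asarray(t_ms, dtype=float)
    growth = 1.0 - np.exp(-np.clip(t, 0.0, None) / p.tau_up)
    decay = np.exp(-np.clip(t, 0.0, None) / p.tau_down)
    return np.where(t < 0, 0.0, p.f_base * growth * p.d_um**2 * decay)


def twitch_kernel(p: TwitchParams, fs: float, tail: float = 8.0) -> np.ndarray:
    """Sampled twitch waveform, truncated ``tail`` decay constants out."""
    dur_ms = tail * p.tau_down + p.tau_up
    n = max(int(round(dur_ms / 1000.0 * fs)), 2)
    t_ms = np.arange(n) / fs * 1000.0
    return single_twitch_force(t_ms, p)


def twitch_cumulative(t_ms, p: TwitchParams):
    """Closed-form integral of the twitch from 0 to ``t_ms`` (per ms).

    Used for window-averaged forces without sampling the profile.
    """
    t = np.clip(np.asarray(t_ms, dtype=float), 0.0, None)
    tau_c = 1.0 / (1.0 / p.tau_up + 1.0 / p.tau_down)
    amp = p.f_base * p.d_um**2
    return amp * (
        p.tau_down * (1.0 - np.exp(-t / p.tau_down))
        - tau_c * (1.0 - np.exp(-t / tau_c))
    )


def fiber_force_profile(
    impulse_times_s: Sequence[float],
    p: TwitchParams,
    fs: float,
    n_samples: int,
) -> np.ndarray:
    """Superpose twitches at the given innervation instants.

    Impulse times are snapped to the nearest sample of ``fs``.  Returns the
    force series over ``n_samples`` samples.
    """
    out = np.zeros(n_samples)
    if len(impulse_times_s) == 0:
        return out
    kernel = twitch_kernel(p, fs)
    idx = np.round(np.asarray(impulse_times_s, dtype=float) * fs).astype(int)
    for i in idx:
        if i >= n_samples or i < 0:
            continue
        m = min(len(kernel), n_samples - i)
        out[i : i + m] += kernel[:m]
    return out
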