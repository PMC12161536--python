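"""Motor-neuron behaviour: acetylcholine release and fiber triggering.

Each motor-neuron impulse releases acetylcholine into the junction cleft
with profile ``ACh(t) = Am (1 - exp(-kr (t - tp))) exp(-kd (t - tp))``;
profiles of successive impulses sum linearly.  A fiber innervates when the
summed cleft concentration at its junction reaches the fiber's threshold,
upon which reuptake zeroes that fiber's local trace: further innervations
require fresh releases.  This makes the innervation rate of a fiber a
graded function of the neuron firing rate and the fiber's threshold, so
fast (high-threshold) fibers only participate at high rates.

The profile difference-of-exponentials form admits an exact two-state
recursion per sample, which :func:`trigger_innervations` exploits to run
thousands of fibers in one vectorised sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .config import AChConfig

__all__ = [
    "AChParams",
    "MotorNeuron",
    "ach_profile",
    "ach_peak_time",
    "transmit_and_trigger",
    "trigger_innervations",
    "mu_aggregate",
]


@dataclass(frozen=True)
class AChParams:
    """Release kinetics: ``am`` mM, ``kr``/``kd`` in s^-1."""

    am: float = 1.0
    kr: float = 0.45
    kd: float = 30.0

    def __post_init__(self):
        if min(self.am, self.kr, self.kd) <= 0:
            raise ValueError("ACh parameters must be positive")

    @classmethod
    def from_config(cls, c: AChConfig) -> "AChParams":
        return cls(am=c.am, kr=c.kr_per_s, kd=c.kd_per_s)


def ach_profile(t_s, tp_s: float, p: AChParams):
    """Single-impulse cleft concentration (mM); 0 before the impulse."""
    t = np.asarray(t_s, dtype=float) - tp_s
    tpos = np.clip(t, 0.0, None)
    prof = p.am * (1.0 - np.exp(-p.kr * tpos)) * np.exp(-p.kd * tpos)
    return np.where(t < 0, 0.0, prof)


def ach_peak_time(p: AChParams) -> float:
    """Time after the impulse at which the single-impulse profile peaks."""
    return float(np.log((p.kr + p.kd) / p.kd) / p.kr)


@dataclass
class MotorNeuron:
    """A motor neuron: member fibers, release kinetics and its spike train."""

    mu_id: int
    fiber_ids: np.ndarray
    ach: AChParams
    spike_train: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if len(self.fiber_ids) == 0:
            raise ValueError("a motor neuron must own at least one fiber")
        if np.any(np.diff(self.spike_train) < 0):
            raise ValueError("spike train must be sorted")


def trigger_innervations(
    spike_samples: Sequence[np.ndarray],
    lane_of_fiber: np.ndarray,
    thr: np.ndarray,
    p: AChParams,
    fs: float,
    n_samples: int,
) -> List[np.ndarray]:
    """Vectorised threshold triggering with per-fiber reuptake.

    ``spike_samples[l]`` holds the impulse sample indices of lane ``l`` (a
    lane is one spike train; several fibers may listen to the same lane via
    ``lane_of_fiber``).  The summed trace ``Am (1 - e^-kr tau) e^-kd tau``
    is maintained per fiber as the difference of two exponential states
    advanced sample by sample; an innervation is recorded at the first
    sample where a fiber's trace reaches ``thr`` and that fiber's states
    reset to zero (reuptake).  Returns per-fiber arrays of innervation
    sample indices.
    """
    n_fib = len(thr)
    n_lanes = len(spike_samples)
    imp = np.zeros((n_samples, n_lanes), dtype=np.float32)
    for l, ss in enumerate(spike_samples):
        ss = np.asarray(ss, dtype=np.int64)
        ss = ss[(ss >= 0) & (ss < n_samples)]
        np.add.at(imp, (ss, np.full(len(ss), l)), 1.0)
    d1 = np.exp(-p.kd / fs)
    d2 = np.exp(-(p.kr + p.kd) / fs)
    s1 = np.zeros(n_fib)
    s2 = np.zeros(n_fib)
    active = imp.any(axis=1)
    events_t: list = []
    events_f: list = []
    lane_of_fiber = np.asarray(lane_of_fiber)
    quiet = 0  # samples since both states decayed to negligible
    for t in range(n_samples):
        if active[t]:
            add = p.am * imp[t][lane_of_fiber]
            s1 = s1 * d1 + add
            s2 = s2 * d2 + add
            quiet = 0
        else:
            s1 *= d1
            s2 *= d2
            quiet += 1
            if quiet > 64 and float(s1.max(initial=0.0)) < 1e-12:
                continue  # silent stretch, trace negligible everywhere
        trace = s1 - s2
        crossed = trace >= thr
        if crossed.any():
            idx = np.flatnonzero(crossed)
            events_t.append(np.full(len(idx), t, dtype=np.int64))
            events_f.append(idx)
            s1[idx] = 0.0
            s2[idx] = 0.0
    out: List[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(n_fib)]
    if events_t:
        all_t = np.concatenate(events_t)
        all_f = np.concatenate(events_f)
        order = np.lexsort((all_t, all_f))
        all_t, all_f = all_t[order], all_f[order]
        bounds = np.searchsorted(all_f, np.arange(n_fib + 1))
        for f in range(n_fib):
            out[f] = all_t[bounds[f] : bounds[f + 1]]
    return out


def transmit_and_trigger(
    neuron: MotorNeuron,
    thr: np.ndarray,
    fs: float,
    n_samples: int,
    threshold_scale: float = 1.0,
) -> List[np.ndarray]:
    """Innervation sample indices for each fiber of one motor neuron.

    ``thr`` holds the member fibers' thresholds in the order of
    ``neuron.fiber_ids``; ``threshold_scale`` globally rescales them before
    comparison with the cleft trace (1.0 = thresholds verbatim).
    """
    spikes = np.round(neuron.spike_train * fs).astype(np.int64)
    lanes = np.zeros(len(thr), dtype=np.int64)
    return trigger_innervations(
        [spikes], lanes, np.asarray(thr) * threshold_scale, neuron.ach, fs, n_samples
    )


def mu_aggregate(
    fiber_voltages: Sequence[np.ndarray] | None,
    fiber_forces: Sequence[np.ndarray] | None,
):
    """Sum member-fiber voltage and force series into motor-unit series.

    Voltages are (n_channels, n_samples) per fiber; forces are
    (n_samples,).  Series must share one clock (equal shapes), otherwise an
    alignment error is raised.  Either argument may be None.
    """

    def _sum(series):
        if series is None or len(series) == 0:
            return None
        shapes = {s.shape for s in series}
        if len(shapes) != 1:
            raise ValueError("fiber series are not aligned on the same clock")
        out = np.zeros_like(series[0])
        for s in series:
            out += s
        return out

    return _sum(fiber_voltages), _sum(fiber_forces)
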