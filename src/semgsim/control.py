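"""Motor-control strategy: recruitment from a reference force profile.

Calibration first builds an N x M force-response matrix (N motor units, M
firing rates from 8 to 42 Hz): each entry is the window-averaged force a
unit produces under a steady periodic spike train at that rate, with the
fiber-level acetylcholine triggering in the loop (so high rates recruit
more of a unit's fibers).  Sorting units ascending by size and cumulating
rows yields the recruitment reference matrix ``M_ref`` whose entry (n, m)
is the force of the n smallest units at rate m — the size principle made
into a lookup table.

At run time every reference-force sample picks the (n, m) pair whose
``M_ref`` entry lies within +/-1% of the demanded force, preferring the
candidate closest to the diagonal from (0, 0) to (N_max, M_max) in
normalised index space; spike trains then fire the selected units
periodically with Gaussian rate jitter that grows with the recruited
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List

import numpy as np
from scipy.signal import resample_poly

from .anatomy import Anatomy
from .config import SimConfig
from .fiber import TwitchParams, twitch_cumulative
from .motoneuron import AChParams, trigger_innervations

__all__ = [
    "ForceMatrix",
    "MRef",
    "RecruitmentPlan",
    "ReferenceForce",
    "build_mref",
    "select_recruitment",
    "generate_spike_trains",
    "prepare_reference_force",
    "load_reference_csv",
    "save_reference_csv",
]


@dataclass
class ForceMatrix:
    """Per-unit window-averaged force (rows) per firing rate (columns)."""

    values: np.ndarray  # (n_mu, n_rates), model force units
    rates: np.ndarray  # Hz, strictly increasing

    def __post_init__(self):
        if len(self.rates) == 0:
            raise ValueError("empty firing-rate grid")
        if not np.all(np.diff(self.rates) > 0):
            raise ValueError("rate grid must be strictly increasing")


@dataclass
class MRef:
    """Cumulative force matrix under size-principle ordering.

    ``cumulative[n, m]`` is the summed average force of the ``n + 1``
    smallest units at rate index ``m``; ``mu_order`` lists unit ids
    ascending by size.
    """

    cumulative: np.ndarray
    rates: np.ndarray
    mu_order: np.ndarray

    @property
    def n_mu(self) -> int:
        return self.cumulative.shape[0]

    @property
    def model_mvc(self) -> float:
        """Maximum producible force: all units at the top rate."""
        return float(self.cumulative[-1, -1])


@dataclass
class RecruitmentPlan:
    """Per-sample recruitment: unit count, mean rate and rate spread."""

    n: np.ndarray  # recruited unit count per sample
    m_idx: np.ndarray  # rate-grid index per sample (-1 where n == 0)
    m_hz: np.ndarray  # mean firing rate per sample (0 where n == 0)
    rate_std_hz: np.ndarray
    fs: float

    def to_csv(self, path: str | Path) -> None:
        t = np.arange(len(self.n)) / self.fs
        np.savetxt(
            path,
            np.column_stack([t, self.n, self.m_hz, self.rate_std_hz]),
            delimiter=",",
            header="t_s,n_recruited,rate_hz,rate_std_hz",
            comments="",
        )


@dataclass
class ReferenceForce:
    """Reference force series on the simulation clock.

    ``samples`` in model force units at ``fs``; provenance keeps the raw
    rate and the two MVC values used for normalisation.
    """

    samples: np.ndarray
    fs: float
    raw_rate_hz: float | None = None
    participant_mvc: float | None = None
    model_mvc: float | None = None


# ---------------------------------------------------------------------------


def build_mref(
    anatomy: Anatomy, cfg: SimConfig
) -> tuple[ForceMatrix, MRef]:
    """Calibrate the per-unit force response over the firing-rate grid.

    Every (fiber, rate) pair is run as one lane of the vectorised
    triggering sweep under a steady periodic train of
    ``cfg.control.calib_duration_s``; forces are averaged over the trailing
    ``calib_window_s`` using the closed-form twitch integral, then summed
    per unit.
    """
    ctl = cfg.control
    rates = np.arange(ctl.rate_min, ctl.rate_max + 1e-9, ctl.rate_step)
    if len(rates) == 0:
        raise ValueError("empty firing-rate grid")
    fs = cfg.fs
    n_samples = int(round(ctl.calib_duration_s * fs))
    t1 = ctl.calib_duration_s
    t0 = t1 - ctl.calib_window_s
    spike_lanes = [
        np.round(np.arange(0.0, ctl.calib_duration_s, 1.0 / rho) * fs).astype(int)
        for rho in rates
    ]
    n_fib, n_rates = anatomy.n_fib, len(rates)
    # virtual fiber (f, j) listens to rate lane j
    lane_of_virtual = np.tile(np.arange(n_rates), n_fib)
    thr_virtual = np.repeat(anatomy.thr, n_rates) * cfg.ach.threshold_scale
    ach = AChParams.from_config(cfg.ach)
    innervations = trigger_innervations(
        spike_lanes, lane_of_virtual, thr_virtual, ach, fs, n_samples
    )
    values = np.zeros((anatomy.n_mu, n_rates))
    for f in range(n_fib):
        p = TwitchParams(
            f_base=float(anatomy.f_base[f]),
            tau_up=float(anatomy.tau_up[f]),
            tau_down=float(anatomy.tau_down[f]),
            d_um=2.0 * float(anatomy.r[f]),
        )
        mu = int(anatomy.mu_of_fiber[f])
        for j in range(n_rates):
            ev = innervations[f * n_rates + j]
            if len(ev) == 0:
                continue
            ti = ev / fs
            avg = (
                twitch_cumulative((t1 - ti) * 1000.0, p)
                - twitch_cumulative((t0 - ti) * 1000.0, p)
            ).sum() / ((t1 - t0) * 1000.0)
            values[mu, j] += avg
    fm = ForceMatrix(values=values, rates=rates)
    order = np.lexsort((np.arange(anatomy.n_mu), anatomy.mu_sizes))
    cumulative = np.cumsum(values[order], axis=0)
    return fm, MRef(cumulative=cumulative, rates=rates, mu_order=order)


def select_recruitment(
    ref: ReferenceForce,
    mref: MRef,
    window: float = 0.01,
    rate_std_max_hz: float = 10.0,
) -> RecruitmentPlan:
    """Choose (n, m) per sample so ``M_ref[n, m]`` tracks the reference.

    Candidates satisfy ``(1 - window) f < M_ref < (1 + window) f``; the one
    nearest the normalised diagonal from (0, 0) to (N_max, M_max) wins.
    Zero demand recruits nothing; demand above the model maximum saturates
    at (N_max, M_max); an empty candidate window falls back to the entry
    nearest in force.
    """
    M = mref.cumulative
    if M.size == 0:
        raise ValueError("empty M_ref")
    n_mu, n_rates = M.shape
    flat = M.ravel()
    nn, mm = np.meshgrid(
        np.arange(1, n_mu + 1), np.arange(1, n_rates + 1), indexing="ij"
    )
    diag_dist = (np.abs(nn / n_mu - mm / n_rates) / np.sqrt(2.0)).ravel()
    f = np.asarray(ref.samples, dtype=float)
    n_out = np.zeros(len(f), dtype=np.int64)
    m_out = np.full(len(f), -1, dtype=np.int64)
    mvc = mref.model_mvc
    chunk = 2048
    # selection depends only on the demanded force value: cache per value
    for lo in range(0, len(f), chunk):
        fc = f[lo : lo + chunk]
        pos = fc > 0
        sat = fc >= mvc
        inside = pos & ~sat
        if inside.any():
            fi = fc[inside]
            within = (flat[None, :] > (1 - window) * fi[:, None]) & (
                flat[None, :] < (1 + window) * fi[:, None]
            )
            score = np.where(within, diag_dist[None, :], np.inf)
            best = np.argmin(score, axis=1)
            empty = ~within.any(axis=1)
            if empty.any():
                best[empty] = np.argmin(
                    np.abs(flat[None, :] - fi[empty, None]), axis=1
                )
            sel_n = best // n_rates + 1
            sel_m = best % n_rates
            tmp_n = n_out[lo : lo + chunk]
            tmp_m = m_out[lo : lo + chunk]
            tmp_n[inside] = sel_n
            tmp_m[inside] = sel_m
        if sat.any():
            n_out[lo : lo + chunk][sat] = n_mu
            m_out[lo : lo + chunk][sat] = n_rates - 1
    m_hz = np.where(m_out >= 0, mref.rates[np.clip(m_out, 0, None)], 0.0)
    rate_std = rate_std_max_hz * n_out / n_mu
    return RecruitmentPlan(
        n=n_out, m_idx=m_out, m_hz=m_hz, rate_std_hz=rate_std, fs=ref.fs
    )


def generate_spike_trains(
    plan: RecruitmentPlan,
    mref: MRef,
    seed: int,
    rate_bounds: tuple[float, float] | None = None,
) -> List[np.ndarray]:
    """Emit per-unit spike times realising the recruitment plan.

    Units activate in size order (``mref.mu_order``).  Whenever the plan's
    (n, m) selection changes, every active unit draws a fresh rate from
    ``N(m_hz, rate_std)`` clamped to the rate grid; spikes are periodic at
    the assigned rate, newly recruited units start with a uniform random
    phase, continuing units keep their phase.  De-recruited units stop.
    Returns spike-time arrays indexed by original unit id.
    """
    rng = np.random.default_rng(seed)
    if rate_bounds is None:
        rate_bounds = (float(mref.rates[0]), float(mref.rates[-1]))
    n_mu = mref.n_mu
    fs = plan.fs
    # segment boundaries where the (n, m) selection changes
    change = np.flatnonzero(
        (np.diff(plan.n) != 0) | (np.diff(plan.m_idx) != 0)
    )
    seg_starts = np.concatenate([[0], change + 1])
    seg_ends = np.concatenate([change + 1, [len(plan.n)]])
    spikes: List[list] = [[] for _ in range(n_mu)]
    cur_rate = np.zeros(n_mu)
    next_spike = np.full(n_mu, np.inf)
    active = np.zeros(n_mu, dtype=bool)
    for s0, s1 in zip(seg_starts, seg_ends):
        n_rec = int(plan.n[s0])
        m_hz = float(plan.m_hz[s0])
        std = float(plan.rate_std_hz[s0])
        t0, t1 = s0 / fs, s1 / fs
        now_active = np.zeros(n_mu, dtype=bool)
        now_active[: n_rec] = True  # ranks in size order
        if n_rec > 0:
            draw = rng.normal(m_hz, std, size=n_rec) if std > 0 else np.full(
                n_rec, m_hz
            )
            draw = np.clip(draw, rate_bounds[0], rate_bounds[1])
        for rank in range(n_mu):
            if now_active[rank]:
                rho = float(draw[rank])
                if not active[rank]:
                    next_spike[rank] = t0 + rng.uniform(0.0, 1.0 / rho)
                cur_rate[rank] = rho
                while next_spike[rank] < t1:
                    spikes[rank].append(next_spike[rank])
                    next_spike[rank] += 1.0 / cur_rate[rank]
            elif active[rank]:
                next_spike[rank] = np.inf
        active = now_active
    out = [np.empty(0) for _ in range(n_mu)]
    for rank, ss in enumerate(spikes):
        out[int(mref.mu_order[rank])] = np.asarray(ss)
    return out


def prepare_reference_force(
    raw: np.ndarray,
    raw_rate_hz: float,
    participant_mvc: float,
    model_mvc: float,
    fs: float,
) -> ReferenceForce:
    """Resample a raw force recording to ``fs`` and rescale to model units.

    Band-limited polyphase resampling; the series is divided by the
    participant's maximum voluntary contraction and multiplied by the
    model's (``M_ref`` at full recruitment and top rate).
    """
    if participant_mvc <= 0 or model_mvc <= 0:
        raise ValueError("MVC values must be positive")
    from fractions import Fraction

    frac = Fraction(fs / raw_rate_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    resampled = resample_poly(
        np.asarray(raw, dtype=float), up, down, padtype="line"
    )
    samples = resampled / participant_mvc * model_mvc
    return ReferenceForce(
        samples=samples,
        fs=fs,
        raw_rate_hz=raw_rate_hz,
        participant_mvc=participant_mvc,
        model_mvc=model_mvc,
    )


def save_reference_csv(
    path: str | Path, raw: np.ndarray, rate_hz: float, mvc: float
) -> None:
    t = np.arange(len(raw)) / rate_hz
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={rate_hz}\n# mvc={mvc}\n")
        fh.write("time_s,force\n")
        for ti, fi in zip(t, raw):
            fh.write(f"{ti:.6f},{fi:.9g}\n")


def load_reference_csv(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Returns (raw samples, rate_hz, mvc) from a headered delimited file."""
    rate = mvc = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                if k == "rate_hz":
                    rate = float(v)
                elif k == "mvc":
                    mvc = float(v)
            elif line and not line[0].isalpha():
                rows.append(float(line.split(",")[1]))
    if rate is None or mvc is None:
        raise ValueError("reference file must declare rate_hz and mvc")
    return np.asarray(rows), rate, mvc
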