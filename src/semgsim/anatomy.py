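"""Muscle geometry and population building.

Builds everything the simulation needs to know about the muscle before any
contraction: per-fiber 3D paths threaded through stacked cross-sections,
motor-unit membership with spatially dispersed territories, slow/fast fiber
type labels, and per-fiber electrical and mechanical parameters sampled from
type-specific Gaussian distributions.

The path construction follows a recursive bisection pairing: consecutive
cross-sections are split into two equal-count halves along their larger
extent, recursively, until single points remain, which are then paired.
This yields a bijection between consecutive layers that keeps neighbouring
fibers geometrically coherent without solving an assignment problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import FIBER_TYPES, SimConfig
from .fiber import arc_lengths, point_at_arc

__all__ = [
    "CrossSectionStack",
    "MuscleFiber",
    "MotorUnitLayout",
    "FiberTypeTargets",
    "Anatomy",
    "build_fiber_paths",
    "disperse_motor_unit",
    "make_mu_layout",
    "assign_mus_to_positions",
    "assign_fiber_types",
    "sample_fiber_parameters",
    "build_anatomy",
]


@dataclass
class CrossSectionStack:
    """Ordered 2D point sets, one per longitudinal slice.

    ``layers[k]`` is an (n_fib, 2) array of x, y coordinates in mm at axial
    position ``z_positions[k]``.  Every layer must hold the same number of
    points and the z positions must strictly increase.
    """

    layers: Sequence[np.ndarray]
    z_positions: np.ndarray

    def __post_init__(self):
        counts = {len(l) for l in self.layers}
        if len(counts) != 1:
            raise ValueError("all layers must have the same point count")
        if not np.all(np.diff(self.z_positions) > 0):
            raise ValueError("z_positions must be strictly increasing")

    @property
    def n_fib(self) -> int:
        return len(self.layers[0])

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class MuscleFiber:
    """One muscle fiber: type, electrical, mechanical and geometric state."""

    ftype: str
    r: float  # um
    sigma_ic: float  # S/m
    thr: float  # mM
    f_base: float  # mN
    tau_up: float  # ms
    tau_down: float  # ms
    cv: float  # m/s
    fib_pos: np.ndarray  # (n_layers, 3) mm
    nmj_pos: np.ndarray  # (3,) mm
    nmj_arc_mm: float
    mu_id: int

    @property
    def d(self) -> float:
        return 2.0 * self.r


@dataclass
class MotorUnitLayout:
    """Motor-unit sizes, dispersion parameters and fiber membership."""

    mu_sizes: np.ndarray  # fibers per MU
    r_disp: np.ndarray  # per-MU dispersion radius, fraction of section area
    lambda_disp: np.ndarray  # per-MU dispersion std, fraction of R
    fiber_ids: list = field(default_factory=list)  # per-MU fiber indices

    @property
    def n_mu(self) -> int:
        return len(self.mu_sizes)


@dataclass(frozen=True)
class FiberTypeTargets:
    """Target fiber-type percentages (must sum to 100)."""

    pct_i: float
    pct_iia: float
    pct_iix: float

    def __post_init__(self):
        vals = (self.pct_i, self.pct_iia, self.pct_iix)
        if any(v < 0 for v in vals) or abs(sum(vals) - 100.0) > 1e-9:
            raise ValueError("percentages must be non-negative and sum to 100")

    def as_array(self) -> np.ndarray:
        return np.array([self.pct_i, self.pct_iia, self.pct_iix])


# ---------------------------------------------------------------------------
# Fiber paths


def _pair_layers(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Bijection from points of layer a to points of layer b.

    Recursive bisection: split both subsets into ceil/floor halves along the
    larger bounding-box extent of the layer-a subset (ties split along x,
    i.e. a vertical dividing line); the larger half sits on the lower-
    coordinate side.  Returns ``out`` with ``out[i] = j`` pairing a-point i
    with b-point j.
    """
    if len(pa) != len(pb):
        raise ValueError("layers must have equal point counts")
    out = np.empty(len(pa), dtype=np.int64)

    def order(p: np.ndarray, idx: np.ndarray, ax: int) -> np.ndarray:
        key = np.lexsort((idx, p[idx, 1 - ax], p[idx, ax]))
        return idx[key]

    stack = [(np.arange(len(pa)), np.arange(len(pb)))]
    while stack:
        ia, ib = stack.pop()
        if len(ia) == 1:
            out[ia[0]] = ib[0]
            continue
        ext = pa[ia].max(axis=0) - pa[ia].min(axis=0)
        ax = 0 if ext[0] >= ext[1] else 1
        sa = order(pa, ia, ax)
        sb = order(pb, ib, ax)
        h = (len(ia) + 1) // 2
        stack.append((sa[:h], sb[:h]))
        stack.append((sa[h:], sb[h:]))
    return out


def build_fiber_paths(stack: CrossSectionStack) -> np.ndarray:
    """Thread one polyline per fiber through all layers.

    Returns an (n_fib, n_layers, 3) array; fiber ``i`` starts at point ``i``
    of the first layer and follows the recursive-bisection bijections
    through the stack.
    """
    n_fib, n_layers = stack.n_fib, stack.n_layers
    paths = np.empty((n_fib, n_layers, 3))
    current = np.arange(n_fib)
    for k in range(n_layers):
        pts = stack.layers[k]
        paths[:, k, :2] = pts[current]
        paths[:, k, 2] = stack.z_positions[k]
        if k + 1 < n_layers:
            mapping = _pair_layers(stack.layers[k], stack.layers[k + 1])
            current = mapping[current]
    return paths


# ---------------------------------------------------------------------------
# Motor-unit layout and spatial assignment


def disperse_motor_unit(
    r: float, lam: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` 2D fiber offsets as ``R * N(0, lambda)`` per axis."""
    if r <= 0 or lam <= 0:
        raise ValueError("R and lambda must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return r * rng.normal(0.0, lam, size=(n, 2))


def make_mu_layout(cfg: SimConfig, n_fib: int, rng: np.random.Generator) -> MotorUnitLayout:
    """Draw motor-unit count and sizes, then adjust the total to ``n_fib``.

    Sizes and count come from the configured Gaussians; the fiber total is
    corrected one fiber at a time on uniformly random units, never letting a
    unit drop below one fiber.  Dispersion radius and std means scale
    linearly with unit size across the configured bands (smallest unit gets
    the smallest mean); each unit's values are drawn with a 10% relative
    std and clipped to the band.
    """
    mu_cfg = cfg.motor_units
    n_mu = max(1, int(round(rng.normal(*mu_cfg.number.as_tuple()))))
    sizes = np.maximum(
        1, np.round(rng.normal(*mu_cfg.size.as_tuple(), size=n_mu)).astype(int)
    )
    diff = n_fib - int(sizes.sum())
    while diff != 0:
        k = rng.integers(n_mu)
        if diff > 0:
            sizes[k] += 1
            diff -= 1
        elif sizes[k] > 1:
            sizes[k] -= 1
            diff += 1
    rank = (sizes - sizes.min()) / max(sizes.max() - sizes.min(), 1)
    r_lo, r_hi = mu_cfg.r_range
    l_lo, l_hi = mu_cfg.lambda_range
    r_mean = r_lo + rank * (r_hi - r_lo)
    l_mean = l_lo + rank * (l_hi - l_lo)
    r_disp = np.clip(rng.normal(r_mean, 0.1 * r_mean), r_lo, r_hi)
    lam_disp = np.clip(rng.normal(l_mean, 0.1 * l_mean), l_lo, l_hi)
    return MotorUnitLayout(mu_sizes=sizes, r_disp=r_disp, lambda_disp=lam_disp)


def assign_mus_to_positions(
    layout: MotorUnitLayout,
    section_points: np.ndarray,
    section_area_mm2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Match every cross-section point to a motor unit.

    Units are visited in random order.  Each unit's dispersed fiber cloud
    (offsets ``R * N(0, lambda)``, with R converted from an area fraction to
    the radius of a disc covering that fraction of the section) is
    re-centred on a randomly chosen unassigned point, then every dispersed
    fiber greedily claims the nearest still-unassigned point.  Terminates
    with a perfect matching by construction.  Returns ``mu_of_point``.
    """
    n_pts = len(section_points)
    if int(layout.mu_sizes.sum()) != n_pts:
        raise ValueError("total fibers must equal the number of section points")
    mu_of_point = np.full(n_pts, -1, dtype=np.int64)
    unassigned = np.ones(n_pts, dtype=bool)
    for mu in rng.permutation(layout.n_mu):
        size = int(layout.mu_sizes[mu])
        r_mm = np.sqrt(layout.r_disp[mu] * section_area_mm2 / np.pi)
        offsets = disperse_motor_unit(
            r_mm, float(layout.lambda_disp[mu]), size, rng
        )
        free = np.flatnonzero(unassigned)
        center = section_points[free[rng.integers(len(free))]]
        targets = center + offsets
        tree = cKDTree(section_points[free])
        taken = np.zeros(len(free), dtype=bool)
        k_query = min(32, len(free))
        for t in targets:
            dd, ii = tree.query(t, k=k_query)
            ii = np.atleast_1d(ii)
            chosen = -1
            for j in ii:
                if not taken[j]:
                    chosen = j
                    break
            if chosen < 0:  # all near neighbours taken: brute force
                rem = np.flatnonzero(~taken)
                d2 = np.sum((section_points[free[rem]] - t) ** 2, axis=1)
                chosen = rem[np.argmin(d2)]
            taken[chosen] = True
            mu_of_point[free[chosen]] = mu
        unassigned[free[taken]] = False
    return mu_of_point


# ---------------------------------------------------------------------------
# Fiber types


def assign_fiber_types(
    mu_of_fiber: np.ndarray,
    mu_sizes: np.ndarray,
    targets: FiberTypeTargets,
    rng: np.random.Generator,
    tol_pct: float = 1.0,
    std: float | None = None,
    max_iter: int = 1_000_000,
) -> np.ndarray:
    """Iteratively convert fibers until type percentages match the targets.

    Starts from a uniform random assignment.  Three Gaussians with a shared
    std and means evenly spaced over the motor-unit size range steer the
    conversions: the lowest-mean Gaussian samples sizes for conversion to
    type I, the middle to IIa, the highest to IIx, so slow fibers
    concentrate in small units and fast fibers in large ones while any unit
    may contain any type.  Converts one fiber per iteration; raises with the
    achieved percentages if the tolerance is not met within ``max_iter``.
    """
    n = len(mu_of_fiber)
    sizes = mu_sizes[mu_of_fiber].astype(float)
    lo, hi = float(mu_sizes.min()), float(mu_sizes.max())
    means = np.linspace(lo, hi, 3)
    if std is None:
        std = max((hi - lo) / 6.0, 1e-9)
    ftype = rng.integers(0, 3, size=n)
    target_counts = targets.as_array() / 100.0 * n
    for _ in range(max_iter):
        counts = np.bincount(ftype, minlength=3).astype(float)
        deficit = target_counts - counts
        if np.all(np.abs(deficit) / n * 100.0 <= tol_pct):
            return ftype
        t = int(np.argmax(deficit))
        donors = np.flatnonzero((ftype != t) & (deficit[ftype] < 0))
        if len(donors) == 0:
            donors = np.flatnonzero(ftype != t)
        x = rng.normal(means[t], std)
        pick = donors[np.argmin(np.abs(sizes[donors] - x))]
        ftype[pick] = t
    achieved = np.bincount(ftype, minlength=3) / n * 100.0
    raise RuntimeError(
        f"fiber-type assignment did not converge; achieved {achieved}"
    )


# ---------------------------------------------------------------------------
# Parameter sampling


def _trunc_normal(
    avg: float, std: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Positive-truncated Gaussian: redraw negatives (<=100 rounds), then
    clamp stragglers to avg/10."""
    x = rng.normal(avg, std, size)
    for _ in range(100):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(avg, std, int(bad.sum()))
    x[x <= 0] = avg / 10.0
    return x


@dataclass
class Anatomy:
    """The full muscle population in array form.

    One row per fiber across all arrays; ``paths`` is (n_fib, n_layers, 3)
    in mm.  ``section_area_mm2`` is the muscle cross-section area used for
    dispersion scaling and ``seed`` the generator seed that built it.
    """

    paths: np.ndarray
    ftype: np.ndarray  # int codes into FIBER_TYPES
    r: np.ndarray
    sigma_ic: np.ndarray
    thr: np.ndarray
    f_base: np.ndarray
    tau_up: np.ndarray
    tau_down: np.ndarray
    cv: np.ndarray
    nmj_arc_mm: np.ndarray
    nmj_pos: np.ndarray  # (n_fib, 3)
    mu_of_fiber: np.ndarray
    mu_sizes: np.ndarray
    section_area_mm2: float
    seed: int

    @property
    def n_fib(self) -> int:
        return len(self.r)

    @property
    def n_mu(self) -> int:
        return len(self.mu_sizes)

    def fiber(self, i: int) -> MuscleFiber:
        return MuscleFiber(
            ftype=FIBER_TYPES[self.ftype[i]],
            r=float(self.r[i]),
            sigma_ic=float(self.sigma_ic[i]),
            thr=float(self.thr[i]),
            f_base=float(self.f_base[i]),
            tau_up=float(self.tau_up[i]),
            tau_down=float(self.tau_down[i]),
            cv=float(self.cv[i]),
            fib_pos=self.paths[i],
            nmj_pos=self.nmj_pos[i],
            nmj_arc_mm=float(self.nmj_arc_mm[i]),
            mu_id=int(self.mu_of_fiber[i]),
        )

    def mu_fiber_ids(self, mu: int) -> np.ndarray:
        return np.flatnonzero(self.mu_of_fiber == mu)


def sample_fiber_parameters(
    ftype: np.ndarray,
    paths: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Sample per-fiber electrical/mechanical parameters given the types.

    Conduction velocity maps the population's ``r * sigma_ic`` products
    affinely onto the configured range (a constant population maps to the
    midpoint).  The neuromuscular junction sits where each fiber's polyline
    crosses the z-plane at a Gaussian length fraction measured from the
    upper (high-z) tendon.
    """
    n = len(ftype)
    if n == 0:
        raise ValueError("empty fiber population")
    out = {
        k: np.empty(n)
        for k in ("r", "sigma_ic", "thr", "f_base", "tau_up", "tau_down")
    }
    for code, tname in enumerate(FIBER_TYPES):
        idx = np.flatnonzero(ftype == code)
        if len(idx) == 0:
            continue
        p = cfg.fiber_params[tname]
        for k in out:
            spec = getattr(p, k)
            out[k][idx] = _trunc_normal(spec.avg, spec.std, len(idx), rng)
    prod = out["r"] * out["sigma_ic"]
    lo, hi = float(prod.min()), float(prod.max())
    cv_lo, cv_hi = cfg.cv_range
    if hi - lo < 1e-15:
        cv = np.full(n, 0.5 * (cv_lo + cv_hi))
    else:
        cv = cv_lo + (prod - lo) / (hi - lo) * (cv_hi - cv_lo)
    out["cv"] = cv

    frac = np.clip(
        rng.normal(*cfg.nmj_frac.as_tuple(), size=n), 0.05, 0.95
    )
    nmj_arc = np.empty(n)
    nmj_pos = np.empty((n, 3))
    for i in range(n):
        path = paths[i]
        cum = arc_lengths(path)
        z = path[:, 2]
        z_target = z[-1] - frac[i] * (z[-1] - z[0])
        s = float(np.interp(z_target, z, cum))
        nmj_arc[i] = s
        nmj_pos[i] = point_at_arc(path, s, cum)
    out["nmj_arc_mm"] = nmj_arc
    out["nmj_pos"] = nmj_pos
    out["nmj_frac"] = frac
    return out


def build_anatomy(
    stack: CrossSectionStack,
    cfg: SimConfig,
    targets: FiberTypeTargets,
    seed: int,
    section_area_mm2: float | None = None,
) -> Anatomy:
    """Run the full anatomy pipeline from a cross-section stack.

    Paths -> motor-unit layout -> spatial assignment -> fiber types ->
    parameter sampling, all driven by one seeded generator.
    """
    rng = np.random.default_rng(seed)
    paths = build_fiber_paths(stack)
    n_fib = stack.n_fib
    first = stack.layers[0]
    if section_area_mm2 is None:
        # convex-hull-free estimate: bounding-box area of the section
        ext = first.max(axis=0) - first.min(axis=0)
        section_area_mm2 = float(ext[0] * ext[1])
    layout = make_mu_layout(cfg, n_fib, rng)
    mu_of_fiber = assign_mus_to_positions(
        layout, first, section_area_mm2, rng
    )
    layout.fiber_ids = [
        np.flatnonzero(mu_of_fiber == m) for m in range(layout.n_mu)
    ]
    ftype = assign_fiber_types(mu_of_fiber, layout.mu_sizes, targets, rng)
    params = sample_fiber_parameters(ftype, paths, cfg, rng)
    return Anatomy(
        paths=paths,
        ftype=ftype,
        r=params["r"],
        sigma_ic=params["sigma_ic"],
        thr=params["thr"],
        f_base=params["f_base"],
        tau_up=params["tau_up"],
        tau_down=params["tau_down"],
        cv=params["cv"],
        nmj_arc_mm=params["nmj_arc_mm"],
        nmj_pos=params["nmj_pos"],
        mu_of_fiber=mu_of_fiber,
        mu_sizes=layout.mu_sizes,
        section_area_mm2=section_area_mm2,
        seed=seed,
    )
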