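"""Volume-conduction environment: voxel tissue grid and FEM lead field.

The tissue volume is a regular voxel grid with per-voxel labels (air,
fat/skin, muscle, cortical and cancellous bone).  For each electrode a
scalar lead field ``h_elec(l)`` — the voltage at the electrode per unit
point source at ``l`` — is obtained by reciprocity: unit current is
injected at the electrode node and the quasi-static conduction equation
``div(sigma grad V) = 0`` is solved with trilinear hexahedral finite
elements, no-flux (natural) conditions on the skin–air interface and
grounded (V = 0) truncation planes at both ends of the z axis.  A pole of
charge q at position l then contributes ``q * h_elec(l)`` to the electrode,
and contributions of all active poles superpose linearly.

Geometry is in mm; the assembly converts to metres so conductivities in
S/m give h in volts per ampere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .config import TISSUE_LABELS, ElectrodeConfig, TissueConfig
from .fiber import PoleTrain

__all__ = [
    "VolumeGrid",
    "ElectrodeArray",
    "LeadField",
    "place_electrodes",
    "solve_lead_field",
    "solve_unit_current",
    "superpose_potentials",
]

AIR = TISSUE_LABELS["air"]


@dataclass
class VolumeGrid:
    """Regular voxel tissue grid.

    ``x, y, z`` are strictly increasing node coordinate vectors (mm);
    ``labels`` has shape (nx-1, ny-1, nz-1) with one tissue code per voxel;
    ``conductivity`` maps label code to sigma in S/m (air must be 0 and is
    excluded from the solve domain).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    labels: np.ndarray
    conductivity: Dict[int, float]

    def __post_init__(self):
        for ax in (self.x, self.y, self.z):
            if not np.all(np.diff(ax) > 0):
                raise ValueError("grid axes must be strictly increasing")
        expect = (len(self.x) - 1, len(self.y) - 1, len(self.z) - 1)
        if self.labels.shape != expect:
            raise ValueError("labels must be one voxel per grid cell")
        for lab in np.unique(self.labels):
            if int(lab) not in self.conductivity:
                raise ValueError(f"no conductivity for label {lab}")
        if self.conductivity.get(AIR, 0.0) != 0.0:
            raise ValueError("air conductivity must be zero")

    @classmethod
    def from_tissue_config(cls, x, y, z, labels, tissues: TissueConfig):
        return cls(x=x, y=y, z=z, labels=labels, conductivity=tissues.by_label())

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Voxel label at each 3D point; air outside the grid."""
        pts = np.atleast_2d(points)
        out = np.full(len(pts), AIR, dtype=self.labels.dtype)
        idx = []
        inside = np.ones(len(pts), dtype=bool)
        for d, ax in enumerate((self.x, self.y, self.z)):
            i = np.searchsorted(ax, pts[:, d], side="right") - 1
            inside &= (i >= 0) & (i <= len(ax) - 2) & (pts[:, d] <= ax[-1])
            idx.append(np.clip(i, 0, len(ax) - 2))
        out[inside] = self.labels[idx[0][inside], idx[1][inside], idx[2][inside]]
        return out


@dataclass
class ElectrodeArray:
    """Skin electrodes: positions (n, 3) mm plus grid/montage bookkeeping."""

    positions: np.ndarray
    grid_shape: tuple  # (m, n): theta columns x z rows
    bipolar_pairs: list = field(default_factory=list)  # (i, j) index pairs

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)


@lru_cache(maxsize=8)
def _hex_stiffness(hx: float, hy: float, hz: float) -> np.ndarray:
    """8x8 trilinear hexahedral stiffness for unit conductivity.

    Local node order: index = di + 2*dj + 4*dk.  2x2x2 Gauss quadrature
    (exact for trilinear gradients on a box).
    """
    g = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    corners = np.array(
        [[di, dj, dk] for dk in (0, 1) for dj in (0, 1) for di in (0, 1)]
    )
    # reorder to index = di + 2*dj + 4*dk
    order = np.argsort(corners[:, 0] + 2 * corners[:, 1] + 4 * corners[:, 2])
    corners = corners[order]
    signs = 2 * corners - 1  # -1/+1 per axis
    K = np.zeros((8, 8))
    h = np.array([hx, hy, hz])
    vol = hx * hy * hz / 8.0  # jacobian of [-1,1]^3 -> box
    for gx in g:
        for gy in g:
            for gz in g:
                xi = np.array([gx, gy, gz])
                grad = np.empty((8, 3))
                for a in range(8):
                    s = signs[a]
                    for d in range(3):
                        others = [0.5 * (1 + s[e] * xi[e]) for e in range(3) if e != d]
                        grad[a, d] = 0.5 * s[d] * others[0] * others[1] * (2.0 / h[d])
                K += vol * grad @ grad.T
    return K


def _node_ids(nx: int, ny: int, nz: int, i, j, k):
    return (i * ny + j) * nz + k


def _assemble(grid: VolumeGrid):
    """Global stiffness, active-node set and Dirichlet mask."""
    nx, ny, nz = len(grid.x), len(grid.y), len(grid.z)
    hx = float(grid.x[1] - grid.x[0]) * 1e-3  # mm -> m
    hy = float(grid.y[1] - grid.y[0]) * 1e-3
    hz = float(grid.z[1] - grid.z[0]) * 1e-3
    if not (
        np.allclose(np.diff(grid.x), grid.x[1] - grid.x[0])
        and np.allclose(np.diff(grid.y), grid.y[1] - grid.y[0])
        and np.allclose(np.diff(grid.z), grid.z[1] - grid.z[0])
    ):
        raise ValueError("FEM assembly requires a uniform grid")
    Kref = _hex_stiffness(hx, hy, hz)
    sigma_lut = np.zeros(int(grid.labels.max()) + 1)
    for lab, s in grid.conductivity.items():
        if lab <= grid.labels.max():
            sigma_lut[lab] = s
    ci, cj, ck = np.nonzero(grid.labels != AIR)
    sig = sigma_lut[grid.labels[ci, cj, ck]]
    keep = sig > 0
    ci, cj, ck, sig = ci[keep], cj[keep], ck[keep], sig[keep]
    corners = np.array(
        [(di, dj, dk) for dk in (0, 1) for dj in (0, 1) for di in (0, 1)]
    )
    order = np.argsort(corners[:, 0] + 2 * corners[:, 1] + 4 * corners[:, 2])
    corners = corners[order]
    cell_nodes = np.stack(
        [
            _node_ids(nx, ny, nz, ci + di, cj + dj, ck + dk)
            for di, dj, dk in corners
        ],
        axis=1,
    )  # (ncell, 8)
    rows = np.repeat(cell_nodes, 8, axis=1).ravel()
    cols = np.tile(cell_nodes, (1, 8)).ravel()
    vals = (sig[:, None] * Kref.ravel()[None, :]).ravel()
    n_nodes = nx * ny * nz
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
    active = np.zeros(n_nodes, dtype=bool)
    active[np.unique(cell_nodes)] = True
    kk = np.arange(n_nodes) % nz
    dirichlet = active & ((kk == 0) | (kk == nz - 1))
    return K, active, dirichlet


def solve_unit_current(
    grid: VolumeGrid,
    inject_nodes: Sequence[tuple],
    rtol: float = 1e-8,
) -> np.ndarray:
    """Lead fields for unit current injected at the given (i, j, k) nodes.

    Returns an array of shape (n_inject, nx, ny, nz); entries are 0 on the
    grounded z-planes and at nodes outside the conductive domain.  Direct
    sparse factorisation for small systems, conjugate gradients otherwise.
    """
    nx, ny, nz = len(grid.x), len(grid.y), len(grid.z)
    K, active, dirichlet = _assemble(grid)
    free = active & ~dirichlet
    if not dirichlet.any():
        raise ValueError("no grounded nodes: the system is singular")
    free_idx = np.flatnonzero(free)
    pos_of = -np.ones(nx * ny * nz, dtype=np.int64)
    pos_of[free_idx] = np.arange(len(free_idx))
    Kff = K[free_idx][:, free_idx].tocsc()
    n_free = len(free_idx)
    rhs_list = []
    for (i, j, k) in inject_nodes:
        nid = _node_ids(nx, ny, nz, i, j, k)
        p = pos_of[nid]
        if p < 0:
            raise ValueError(
                f"injection node {(i, j, k)} is grounded or outside the domain"
            )
        b = np.zeros(n_free)
        b[p] = 1.0
        rhs_list.append(b)
    out = np.zeros((len(inject_nodes), nx * ny * nz))
    if n_free <= 50_000:
        lu = spla.splu(Kff)
        sols = [lu.solve(b) for b in rhs_list]
    else:
        inv_diag = 1.0 / Kff.diagonal()
        M = spla.LinearOperator((n_free, n_free), lambda v: inv_diag * v)
        sols = []
        for b in rhs_list:
            xsol, info = spla.cg(Kff, b, rtol=rtol, maxiter=20_000, M=M)
            if info != 0:
                raise RuntimeError(
                    f"lead-field CG did not converge (info={info})"
                )
            sols.append(xsol)
    for e, xsol in enumerate(sols):
        out[e, free_idx] = xsol
    return out.reshape(len(inject_nodes), nx, ny, nz)


@dataclass
class LeadField:
    """Per-electrode lead fields on the grid nodes (V per unit source)."""

    h: np.ndarray  # (n_elec, nx, ny, nz)
    grid: VolumeGrid
    electrodes: ElectrodeArray

    def __post_init__(self):
        self._interp = [
            RegularGridInterpolator(
                (self.grid.x, self.grid.y, self.grid.z),
                self.h[e],
                bounds_error=False,
                fill_value=0.0,
            )
            for e in range(len(self.h))
        ]

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear h at the given (n, 3) points; shape (n_elec, n)."""
        pts = np.atleast_2d(points)
        return np.stack([itp(pts) for itp in self._interp])


def _section_centroid(grid: VolumeGrid, z_mm: float) -> np.ndarray:
    """Centroid of the non-air tissue in the slice nearest ``z_mm``."""
    k = int(np.clip(np.searchsorted(grid.z, z_mm) - 1, 0, len(grid.z) - 2))
    sl = grid.labels[:, :, k]
    ii, jj = np.nonzero(sl != AIR)
    if len(ii) == 0:
        raise ValueError("slice contains no tissue")
    xc = 0.5 * (grid.x[ii] + grid.x[ii + 1]).mean()
    yc = 0.5 * (grid.y[jj] + grid.y[jj + 1]).mean()
    return np.array([xc, yc, z_mm])


def place_electrodes(
    grid: VolumeGrid,
    cfg: ElectrodeConfig,
    theta_center_deg: float = 90.0,
    theta_spacing_deg: float | None = None,
) -> ElectrodeArray:
    """Cast an M x N cylindrical electrode grid onto the skin surface.

    Electrodes start on a cylinder of ``cfg.cast_radius_mm`` (must exceed
    the body's radial extent), evenly spaced: N rows along z separated by
    ``cfg.spacing_mm`` and centred at ``cfg.z_center_frac`` of the z axis,
    M theta columns around ``theta_center_deg``.  Each electrode's segment
    toward the slice centroid is marched through the voxel grid; the
    electrode snaps to its first intersection with tissue.  The default
    theta spacing subtends ``cfg.spacing_mm`` of arc at the skin.

    Bipolar montage: neighbouring z rows within each theta column.
    """
    zmin, zmax = float(grid.z[0]), float(grid.z[-1])
    z_center = zmin + cfg.z_center_frac * (zmax - zmin)
    z_rows = z_center + (np.arange(cfg.n) - (cfg.n - 1) / 2) * cfg.spacing_mm
    # estimate skin radius from tissue extent for the default theta spacing
    any_tissue = (grid.labels != AIR).any(axis=2)
    ii, jj = np.nonzero(any_tissue)
    xc_all = 0.5 * (grid.x[ii] + grid.x[ii + 1])
    yc_all = 0.5 * (grid.y[jj] + grid.y[jj + 1])
    r_skin = float(np.hypot(xc_all, yc_all).max())
    if cfg.cast_radius_mm <= r_skin:
        raise ValueError("cast radius must exceed the body's radial extent")
    if theta_spacing_deg is None:
        theta_spacing_deg = np.degrees(cfg.spacing_mm / r_skin)
    th = np.radians(
        theta_center_deg
        + (np.arange(cfg.m) - (cfg.m - 1) / 2) * theta_spacing_deg
    )
    step = 0.25 * min(
        grid.x[1] - grid.x[0], grid.y[1] - grid.y[0], grid.z[1] - grid.z[0]
    )
    positions = []
    for col, theta in enumerate(th):
        for row, ze in enumerate(z_rows):
            start = np.array(
                [
                    cfg.cast_radius_mm * np.cos(theta),
                    cfg.cast_radius_mm * np.sin(theta),
                    ze,
                ]
            )
            target = _section_centroid(grid, ze)
            seg = target - start
            length = np.linalg.norm(seg)
            n_steps = int(np.ceil(length / step))
            ts = np.linspace(0.0, 1.0, n_steps + 1)
            pts = start[None, :] + ts[:, None] * seg[None, :]
            labs = grid.label_at(pts)
            hit = np.flatnonzero(labs != AIR)
            if len(hit) == 0:
                raise ValueError(
                    f"electrode ray (col {col}, row {row}) misses the body"
                )
            lo, hi = ts[hit[0] - 1] if hit[0] > 0 else 0.0, ts[hit[0]]
            for _ in range(30):  # bisect to the tissue surface
                mid = 0.5 * (lo + hi)
                if grid.label_at(start + mid * seg)[0] != AIR:
                    hi = mid
                else:
                    lo = mid
            positions.append(start + hi * seg)
    positions = np.array(positions)
    pairs = []
    for col in range(cfg.m):
        for row in range(cfg.n - 1):
            a = col * cfg.n + row
            pairs.append((a, a + 1))
    return ElectrodeArray(
        positions=positions, grid_shape=(cfg.m, cfg.n), bipolar_pairs=pairs
    )


def solve_lead_field(grid: VolumeGrid, electrodes: ElectrodeArray) -> LeadField:
    """FEM lead field for every electrode (reciprocal unit injection).

    Each electrode position is snapped to the nearest non-grounded node of
    the conductive domain before injection.
    """
    nodes = []
    for pos in electrodes.positions:
        ijk = tuple(
            int(np.clip(np.argmin(np.abs(ax - c)), 1, len(ax) - 2))
            for ax, c in zip((grid.x, grid.y, grid.z), pos)
        )
        nodes.append(ijk)
    h = solve_unit_current(grid, nodes)
    return LeadField(h=h, grid=grid, electrodes=electrodes)


def superpose_potentials(lead: LeadField, train: PoleTrain) -> np.ndarray:
    """Electrode voltages of one pole train: (n_elec, n_steps).

    Per sample, each electrode sees the charge-weighted sum of its lead
    field interpolated at the active pole positions.
    """
    n_elec = lead.electrodes.n_electrodes
    n_steps = train.n_steps
    out = np.zeros((n_elec, n_steps))
    if n_steps == 0:
        return out
    all_pos = [p for p in train.positions if len(p)]
    if not all_pos:
        return out
    pos = np.concatenate(all_pos)
    amps = np.concatenate([a for a in train.amplitudes if len(a)])
    steps = np.concatenate(
        [
            np.full(len(p), t, dtype=np.int64)
            for t, p in enumerate(train.positions)
            if len(p)
        ]
    )
    hvals = lead.sample(pos)  # (n_elec, n_poles)
    for e in range(n_elec):
        np.add.at(out[e], steps, amps * hvals[e])
    return out
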