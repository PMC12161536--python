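"""HDF5 persistence for anatomy bundles, lead fields and phantoms."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .anatomy import Anatomy, CrossSectionStack
from .volume import ElectrodeArray, LeadField, VolumeGrid

__all__ = [
    "save_anatomy",
    "load_anatomy",
    "save_leadfield",
    "load_leadfield",
    "save_phantom",
    "load_phantom",
]

_ANATOMY_ARRAYS = (
    "paths",
    "ftype",
    "r",
    "sigma_ic",
    "thr",
    "f_base",
    "tau_up",
    "tau_down",
    "cv",
    "nmj_arc_mm",
    "nmj_pos",
    "mu_of_fiber",
    "mu_sizes",
)


def save_anatomy(anatomy: Anatomy, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        for name in _ANATOMY_ARRAYS:
            h5.create_dataset(name, data=getattr(anatomy, name))
        h5.attrs["section_area_mm2"] = anatomy.section_area_mm2
        h5.attrs["seed"] = anatomy.seed


def load_anatomy(path: str | Path) -> Anatomy:
    with h5py.File(path, "r") as h5:
        arrays = {name: h5[name][...] for name in _ANATOMY_ARRAYS}
        return Anatomy(
            **arrays,
            section_area_mm2=float(h5.attrs["section_area_mm2"]),
            seed=int(h5.attrs["seed"]),
        )


def save_phantom(
    grid: VolumeGrid, stack: CrossSectionStack, path: str | Path
) -> None:
    with h5py.File(path, "w") as h5:
        g = h5.create_group("grid")
        for name in ("x", "y", "z", "labels"):
            g.create_dataset(name, data=getattr(grid, name))
        labs = sorted(grid.conductivity)
        g.create_dataset("cond_labels", data=np.array(labs))
        g.create_dataset(
            "cond_values", data=np.array([grid.conductivity[l] for l in labs])
        )
        s = h5.create_group("stack")
        s.create_dataset("z_positions", data=stack.z_positions)
        s.create_dataset("layers", data=np.stack(stack.layers))


def load_phantom(path: str | Path) -> tuple[VolumeGrid, CrossSectionStack]:
    with h5py.File(path, "r") as h5:
        g = h5["grid"]
        cond = dict(
            zip(
                (int(v) for v in g["cond_labels"][...]),
                (float(v) for v in g["cond_values"][...]),
            )
        )
        grid = VolumeGrid(
            x=g["x"][...],
            y=g["y"][...],
            z=g["z"][...],
            labels=g["labels"][...],
            conductivity=cond,
        )
        s = h5["stack"]
        stack = CrossSectionStack(
            layers=list(s["layers"][...]), z_positions=s["z_positions"][...]
        )
    return grid, stack


def save_leadfield(lead: LeadField, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("h", data=lead.h)
        h5.create_dataset("positions", data=lead.electrodes.positions)
        h5.create_dataset(
            "bipolar_pairs", data=np.array(lead.electrodes.bipolar_pairs)
        )
        h5.attrs["grid_shape"] = lead.electrodes.grid_shape
        g = h5.create_group("grid")
        for name in ("x", "y", "z", "labels"):
            g.create_dataset(name, data=getattr(lead.grid, name))
        labs = sorted(lead.grid.conductivity)
        g.create_dataset("cond_labels", data=np.array(labs))
        g.create_dataset(
            "cond_values",
            data=np.array([lead.grid.conductivity[l] for l in labs]),
        )


def load_leadfield(path: str | Path) -> LeadField:
    with h5py.File(path, "r") as h5:
        g = h5["grid"]
        cond = dict(
            zip(
                (int(v) for v in g["cond_labels"][...]),
                (float(v) for v in g["cond_values"][...]),
            )
        )
        grid = VolumeGrid(
            x=g["x"][...],
            y=g["y"][...],
            z=g["z"][...],
            labels=g["labels"][...],
            conductivity=cond,
        )
        electrodes = ElectrodeArray(
            positions=h5["positions"][...],
            grid_shape=tuple(int(v) for v in h5.attrs["grid_shape"]),
            bipolar_pairs=[tuple(p) for p in h5["bipolar_pairs"][...]],
        )
        return LeadField(h=h5["h"][...], grid=grid, electrodes=electrodes)
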