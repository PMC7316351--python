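"""File dialects: localization tables, frame stacks, camera maps, TCF grids.

Native localization table columns:
``frame, channel, x_nm, y_nm, photons, background, crlb_x_nm, crlb_y_nm,
n_merged``.  Unknown columns are preserved on round trips.  A
ThunderSTORM-style CSV dialect is translated on read (``x [nm]`` → ``x_nm``,
``uncertainty [nm]`` → both crlb columns, …).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .localize import LOC_COLUMNS
from .simulate import CameraModel

__all__ = [
    "read_localization_table", "write_localization_table",
    "read_frames", "write_frames", "read_camera", "write_camera",
    "write_tcf_grid", "read_tcf_grid", "write_scene",
]

MANDATORY = ["frame", "x_nm", "y_nm", "photons", "crlb_x_nm", "crlb_y_nm"]

THUNDERSTORM_MAP = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "intensity [photon]": "photons",
    "offset [photon]": "background",
    "bkgstd [photon]": "bkgstd_photon",
    "uncertainty [nm]": "uncertainty_nm",
    "uncertainty_xy [nm]": "uncertainty_nm",
    "sigma [nm]": "sigma_nm",
    "id": "id",
}


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANDATORY if c not in table.columns]
    if missing:
        raise ValueError(f"localization table is missing mandatory columns: {missing}")
    if "channel" not in table.columns:
        table = table.assign(channel=1)
    if "background" not in table.columns:
        table = table.assign(background=0.0)
    if "n_merged" not in table.columns:
        table = table.assign(n_merged=1)
    return table


def read_localization_table(path, dialect: str = "auto") -> pd.DataFrame:
    """Read a localization table (native CSV, native HDF5, thunderstorm CSV)."""
    path = Path(path)
    if dialect == "auto":
        if path.suffix in (".h5", ".hdf5"):
            dialect = "hdf5"
        else:
            head = pd.read_csv(path, nrows=0)
            dialect = "thunderstorm" if any("[nm]" in c for c in head.columns) \
                else "csv"
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            g = f["localizations"]
            tab = pd.DataFrame({k: g[k][()] for k in g})
            for c in tab.columns:
                if tab[c].dtype == object or tab[c].dtype.kind == "S":
                    tab[c] = tab[c].astype(str)
        return _validate(tab)
    tab = pd.read_csv(path)
    if dialect == "thunderstorm":
        tab = tab.rename(columns={k: v for k, v in THUNDERSTORM_MAP.items()
                                  if k in tab.columns})
        if "uncertainty_nm" in tab.columns and "crlb_x_nm" not in tab.columns:
            tab["crlb_x_nm"] = tab["uncertainty_nm"]
            tab["crlb_y_nm"] = tab["uncertainty_nm"]
    return _validate(tab)


def write_localization_table(table: pd.DataFrame, path) -> None:
    """Write the native dialect; format chosen by extension (.csv or .h5)."""
    path = Path(path)
    table = _validate(table.copy())
    ordered = [c for c in LOC_COLUMNS if c in table.columns] + \
        [c for c in table.columns if c not in LOC_COLUMNS]
    table = table[ordered]
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            g = f.create_group("localizations")
            for c in table.columns:
                col = table[c].to_numpy()
                if col.dtype == object:
                    col = col.astype("S")
                g.create_dataset(c, data=col)
    else:
        table.to_csv(path, index=False)


def write_frames(frames: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(frames, np.float32),
                     photometric="minisblack")


def read_frames(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_camera(camera: CameraModel, path) -> None:
    """Camera calibration as an HDF5 group (offset/gain/read-noise maps)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("camera")
        g.attrs["pixel_size_nm"] = camera.pixel_size_nm
        g.attrs["n_frames"] = camera.n_frames
        g.create_dataset("offset", data=camera.offset_map)
        g.create_dataset("gain", data=camera.gain_map)
        g.create_dataset("readnoise_var", data=camera.readnoise_var_map)


def read_camera(path) -> CameraModel:
    with h5py.File(path, "r") as f:
        g = f["camera"]
        return CameraModel(
            pixel_size_nm=float(g.attrs["pixel_size_nm"]),
            offset_map=g["offset"][()], gain_map=g["gain"][()],
            readnoise_var_map=g["readnoise_var"][()],
            n_frames=int(g.attrs["n_frames"]),
        )


def write_scene(scene_table: pd.DataFrame, params: dict, path_csv) -> None:
    """Scene registry as CSV plus a JSON parameter sidecar."""
    path_csv = Path(path_csv)
    scene_table.to_csv(path_csv, index=False)
    with open(path_csv.with_suffix(".json"), "w") as f:
        json.dump(params, f, indent=2)


def write_tcf_grid(grid, path_h5, path_csv=None) -> None:
    """TCFGrid to HDF5 (all arrays) and optionally f_angular to flat CSV."""
    with h5py.File(path_h5, "w") as f:
        g = f.create_group("tcf")
        g.attrs["ntheta"] = grid.ntheta
        g.attrs["boundary_mode"] = grid.boundary_mode
        g.attrs["n_visited"] = grid.n_visited
        g.attrs["mean_densities"] = list(grid.mean_densities)
        for name in ("r1_edges", "r2_edges", "f_values", "pair_counts",
                     "g12", "g12_counts"):
            g.create_dataset(name, data=getattr(grid, name))
        for name in ("f_angular", "r3_edges", "c3_values", "c3_mask"):
            v = getattr(grid, name)
            if v is not None:
                g.create_dataset(name, data=v)
        if grid.r3_convention:
            g.attrs["r3_convention"] = grid.r3_convention
    if path_csv is not None and grid.f_angular is not None:
        r1c = 0.5 * (grid.r1_edges[:-1] + grid.r1_edges[1:])
        r2c = 0.5 * (grid.r2_edges[:-1] + grid.r2_edges[1:])
        r3c = 0.5 * (grid.r3_edges[:-1] + grid.r3_edges[1:])
        A, B, R = grid.f_angular.shape
        ii, jj, kk = np.meshgrid(range(A), range(B), range(R), indexing="ij")
        pd.DataFrame({
            "r1_nm": r1c[ii.ravel()], "r2_nm": r2c[jj.ravel()],
            "r3_nm": r3c[kk.ravel()], "f": grid.f_angular.ravel(),
        }).dropna(subset=["f"]).to_csv(path_csv, index=False)


def read_tcf_grid(path_h5):
    from .correlate import TCFGrid

    with h5py.File(path_h5, "r") as f:
        g = f["tcf"]
        grid = TCFGrid(
            r1_edges=g["r1_edges"][()], r2_edges=g["r2_edges"][()],
            ntheta=int(g.attrs["ntheta"]), f_values=g["f_values"][()],
            pair_counts=g["pair_counts"][()], g12=g["g12"][()],
            g12_counts=g["g12_counts"][()],
            mean_densities=tuple(g.attrs["mean_densities"]),
            boundary_mode=str(g.attrs["boundary_mode"]),
            n_visited=int(g.attrs["n_visited"]),
        )
        for name in ("f_angular", "r3_edges", "c3_values", "c3_mask"):
            if name in g:
                setattr(grid, name, g[name][()])
        if "r3_convention" in g.attrs:
            grid.r3_convention = str(g.attrs["r3_convention"])
    return grid
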