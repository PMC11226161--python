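"""HDF5 / TIFF archives for simulated scans and reconstructions.

Scan archive layout::

    /frames            (n_angles, ny_det, nx_det)  int64 photon counts
    /flats             (n_flats, ny_det, nx_det)   int64
    /angles            (n_angles,)                  radians
    /truth/left        (n_angles, ny, nx)           radians, optional
    /truth/right       (n_angles, ny, nx)           radians, optional
    /meta              group with geometry/scan attributes
                       (every imaging-geometry quantity by name)

Reconstruction archive layout::

    /phases/{left,right}     (n_angles, ny, nx)    retrieved phase, radians
    /volumes/{left,right,fused}  (ny, nx, nx)      delta
    /report                  JSON string attribute

Datasets are written with ``track_times=False`` so that re-running a
simulation with the same config and seed produces a byte-identical file.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .optics import ImagingGeometry
from .scene import CompoundFrame, SimulatedScan

__all__ = [
    "write_scan",
    "read_scan",
    "write_reconstruction",
    "read_reconstruction",
    "write_tiff_preview",
]

_GEOMETRY_ATTRS = (
    "z01",
    "z12",
    "z02",
    "detector_pixel",
    "d_img",
    "magnification",
    "effective_pixel",
    "fov",
    "z_eff",
    "fresnel_number",
    "wavelength",
)


def _dset(group: h5py.Group, name: str, data: np.ndarray) -> h5py.Dataset:
    return group.create_dataset(name, data=data, track_times=False)


def write_scan(path: str, scan: SimulatedScan) -> None:
    """Write a simulated scan (frames, flats, angles, truth, metadata)."""
    with h5py.File(path, "w", track_order=True) as f:
        _dset(f, "frames", np.stack([fr.counts for fr in scan.frames]))
        if scan.flats:
            _dset(f, "flats", np.stack(scan.flats))
        _dset(f, "angles", scan.angles)
        truth = f.create_group("truth")
        _dset(truth, "left", np.stack([p.phi for p in scan.truth_left]))
        _dset(truth, "right", np.stack([p.phi for p in scan.truth_right]))
        meta = f.create_group("meta")
        for name in _GEOMETRY_ATTRS:
            meta.attrs[name] = getattr(scan.geometry, name)
        meta.attrs["alpha"] = scan.alpha
        meta.attrs["n_angles"] = len(scan.angles)
        meta.attrs["n_flats"] = len(scan.flats)
        if scan.seed is not None:
            meta.attrs["seed"] = scan.seed
        fr0 = scan.frames[0]
        meta.attrs["left_window"] = fr0.left_window
        meta.attrs["right_window"] = fr0.right_window
        meta.attrs["d_img_px"] = fr0.d_img_px
        if scan.phantom is not None:
            meta.attrs["phantom"] = scan.phantom.description


def read_scan(path: str) -> dict:
    """Read a scan archive into a plain dict (arrays + metadata)."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        out["frames"] = f["frames"][...]
        out["flats"] = f["flats"][...] if "flats" in f else np.empty((0,))
        out["angles"] = f["angles"][...]
        if "truth" in f:
            out["truth_left"] = f["truth/left"][...]
            out["truth_right"] = f["truth/right"][...]
        meta = dict(f["meta"].attrs)
        out["meta"] = meta
        geo_kwargs = {name: float(meta[name]) for name in _GEOMETRY_ATTRS}
        out["geometry"] = ImagingGeometry(**geo_kwargs)
        out["left_window"] = tuple(int(v) for v in meta["left_window"])
        out["right_window"] = tuple(int(v) for v in meta["right_window"])
        out["d_img_px"] = int(meta["d_img_px"])
        out["alpha"] = float(meta["alpha"])
    return out


def compound_frames_from_archive(archive: dict) -> list[CompoundFrame]:
    return [
        CompoundFrame(
            counts=frame,
            left_window=archive["left_window"],
            right_window=archive["right_window"],
            d_img_px=archive["d_img_px"],
        )
        for frame in archive["frames"]
    ]


def write_reconstruction(
    path: str,
    phases: dict[str, np.ndarray],
    volumes: dict[str, np.ndarray],
    report: dict,
) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        gp = f.create_group("phases")
        for name, arr in phases.items():
            _dset(gp, name, arr)
        gv = f.create_group("volumes")
        for name, arr in volumes.items():
            _dset(gv, name, arr)
        f.attrs["report"] = json.dumps(report, default=_json_default)


def read_reconstruction(path: str) -> tuple[dict, dict, dict]:
    with h5py.File(path, "r") as f:
        phases = {k: f["phases"][k][...] for k in f["phases"]}
        volumes = {k: f["volumes"][k][...] for k in f["volumes"]}
        report = json.loads(f.attrs["report"])
    return phases, volumes, report


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_residuals_csv(path: str, residuals: dict[str, list[float]]) -> None:
    """Per-projection final data residuals, one column per beam."""
    import csv

    keys = list(residuals)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["projection"] + keys)
        for i, row in enumerate(zip(*(residuals[k] for k in keys))):
            writer.writerow([i] + [f"{v:.8e}" for v in row])


def write_tiff_preview(path: str, image: np.ndarray) -> None:
    """32-bit float TIFF preview of a frame or slice."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
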