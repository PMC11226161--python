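"""End-to-end orchestration: configuration, simulation and reconstruction.

The pipeline mirrors a beamline workflow.  Simulation produces a scan
archive (compound frames + empty-beam flats + ground truth); the
reconstruction chain is

1. PCA flat-field model from the flats, per-frame dynamic correction;
2. split of each compound frame into Gaussian-faded left/right holograms;
3. iterative phase retrieval per hologram and beam;
4. reprojection alignment, filtered back-projection of the left, right
   and fused projection stacks;
5. a report with data residuals, ring metrics and, when ground truth is
   present, phase and volume errors.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from . import io as hio
from .flatfield import border_ring_mask, correct_frame, fit_flatfield, split_compound
from .optics import ImagingGeometry, derive_geometry, wavelength_from_energy
from .propagation import HologramFrame
from .retrieval import RetrievalConfig, retrieve_phase
from .scene import make_hair_phantom, make_illumination, simulate_scan
from .tomo import ProjectionStack, align_stack, fbp_reconstruct, fuse_stacks, ring_metric

logger = logging.getLogger("holoduo")

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_simulate",
    "run_retrieve",
    "run_reconstruct",
]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (lengths in metres internally)."""

    energy_kev: float = 11.0
    z01: float = 50.29e-3
    z12: float = 20.735
    detector_pixel: float = 55e-6
    d_img: float = 18.0e-3
    fzp: dict = dc_field(default_factory=dict)
    # scan
    n_angles: int = 16
    n_flats: int = 24
    alpha: float = 1.22e-3
    seed: int = 1
    # phantom
    phantom_n_voxels: int = 64
    hair_diameter: float = 4e-6
    n_elements: int = 8
    element_diameter: float = 300e-9
    element_length: float | None = None
    delta_value: float = 1e-6
    # illumination / detector
    detector_shape: tuple[int, int] = (192, 512)
    n_components: int = 5
    defect_density: float = 2e-4
    flux: float = 500.0
    exposure: float = 2.0
    # processing
    pca_components: int = 10
    fit_border_fraction: float = 0.1
    fade_plateau: float = 0.8
    fade_sigma: float = 10.0
    retrieval: RetrievalConfig = dc_field(default_factory=RetrievalConfig)
    tomo_filter: str = "shepp-logan"
    align_rounds: int = 2

    def geometry(self, sub_pixels: int | None = None) -> ImagingGeometry:
        wavelength = wavelength_from_energy(self.energy_kev)
        n = sub_pixels if sub_pixels is not None else self.phantom_n_voxels
        geo = derive_geometry(
            z01=self.z01,
            z12=self.z12,
            detector_pixel=self.detector_pixel,
            wavelength=wavelength,
            d_img=self.d_img,
            fov=0.0,
        )
        fov = n * geo.effective_pixel
        return derive_geometry(
            z01=self.z01,
            z12=self.z12,
            detector_pixel=self.detector_pixel,
            wavelength=wavelength,
            d_img=self.d_img,
            fov=fov,
        )


_UNIT_SUFFIXES = {"_m": 1.0, "_mm": 1e-3, "_um": 1e-6, "_nm": 1e-9, "_mrad": 1e-3}


def _scaled(mapping: dict, key: str, default: float) -> float:
    """Read ``key`` with an explicit unit suffix (``key_mm`` etc.)."""
    for suffix, scale in _UNIT_SUFFIXES.items():
        if key + suffix in mapping:
            return float(mapping[key + suffix]) * scale
    if key in mapping:
        return float(mapping[key])
    return default


def load_config(path_or_dict: str | dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or a parsed dict."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    geo = raw.get("geometry", {})
    cfg.energy_kev = float(geo.get("energy_keV", geo.get("energy_kev", cfg.energy_kev)))
    cfg.z01 = _scaled(geo, "z01", cfg.z01)
    cfg.z12 = _scaled(geo, "z12", cfg.z12)
    cfg.detector_pixel = _scaled(geo, "px", cfg.detector_pixel)
    cfg.d_img = _scaled(geo, "d_img", cfg.d_img)
    cfg.fzp = dict(geo.get("fzp", {}))
    scan = raw.get("scan", {})
    cfg.n_angles = int(scan.get("n_angles", cfg.n_angles))
    cfg.n_flats = int(scan.get("n_flats", cfg.n_flats))
    cfg.alpha = _scaled(scan, "alpha", cfg.alpha)
    cfg.seed = int(scan.get("seed", cfg.seed))
    ph = raw.get("phantom", {})
    cfg.phantom_n_voxels = int(ph.get("n_voxels", cfg.phantom_n_voxels))
    cfg.hair_diameter = _scaled(ph, "hair_diameter", cfg.hair_diameter)
    cfg.n_elements = int(ph.get("n_elements", cfg.n_elements))
    cfg.element_diameter = _scaled(ph, "element_diameter", cfg.element_diameter)
    if any(("element_length" + s) in ph for s in ("", "_m", "_mm", "_um", "_nm")):
        cfg.element_length = _scaled(ph, "element_length", 0.0)
    cfg.delta_value = float(ph.get("delta", cfg.delta_value))
    ill = raw.get("illumination", {})
    cfg.n_components = int(ill.get("n_components", cfg.n_components))
    cfg.defect_density = float(ill.get("defect_density", cfg.defect_density))
    cfg.flux = float(ill.get("flux", cfg.flux))
    cfg.exposure = float(ill.get("exposure", cfg.exposure))
    det = raw.get("detector", {})
    if "shape" in det:
        cfg.detector_shape = tuple(int(v) for v in det["shape"])
    proc = raw.get("processing", {})
    cfg.pca_components = int(proc.get("pca_components", cfg.pca_components))
    cfg.fit_border_fraction = float(
        proc.get("fit_border_fraction", cfg.fit_border_fraction)
    )
    cfg.fade_plateau = float(proc.get("fade_plateau", cfg.fade_plateau))
    cfg.fade_sigma = float(proc.get("fade_sigma", cfg.fade_sigma))
    ret = raw.get("retrieval", {})
    if ret:
        cfg.retrieval = RetrievalConfig(
            **{k: v for k, v in ret.items() if k in RetrievalConfig.__dataclass_fields__}
        )
    tomo = raw.get("tomo", {})
    cfg.tomo_filter = str(tomo.get("filter", cfg.tomo_filter))
    cfg.align_rounds = int(tomo.get("align_rounds", cfg.align_rounds))
    return cfg


def run_simulate(config: PipelineConfig, out_path: str) -> None:
    """Simulate a full dual-beam scan and write the archive.

    Deterministic: rerunning with an identical config produces a
    byte-identical HDF5 file.
    """
    t0 = time.time()
    geo = config.geometry()
    phantom = make_hair_phantom(
        n_voxels=config.phantom_n_voxels,
        voxel_size=geo.effective_pixel,
        hair_diameter=config.hair_diameter,
        n_elements=config.n_elements,
        element_diameter=config.element_diameter,
        element_length=config.element_length,
        delta_value=config.delta_value,
        seed=config.seed,
    )
    illum = make_illumination(
        config.detector_shape,
        n_components=config.n_components,
        defect_density=config.defect_density,
        flux=config.flux,
        exposure=config.exposure,
        seed=config.seed + 1,
    )
    scan = simulate_scan(
        phantom,
        geo,
        illum,
        n_angles=config.n_angles,
        alpha=config.alpha,
        seed=config.seed,
        n_flats=config.n_flats,
    )
    hio.write_scan(out_path, scan)
    logger.info("simulated %d frames + %d flats in %.1f s -> %s",
                config.n_angles, config.n_flats, time.time() - t0, out_path)


def _retrieve_stack(
    holograms: list[HologramFrame],
    angles: np.ndarray,
    geometry: ImagingGeometry,
    config: PipelineConfig,
    label: str,
) -> tuple[ProjectionStack, list[float]]:
    phases = []
    residuals = []
    for holo in holograms:
        holo.pixel_size = geometry.effective_pixel
        holo.fresnel_number = geometry.fresnel_number
        pm, diag = retrieve_phase(holo, geometry, config.retrieval)
        phases.append(pm.phi)
        residuals.append(float(diag["residuals"][-1]))
    stack = ProjectionStack(
        phases=np.stack(phases),
        angles=angles,
        pixel_size=geometry.effective_pixel,
        wavelength=geometry.wavelength,
        beam_label=label,
    )
    return stack, residuals


def _correct_and_split(
    config: PipelineConfig, archive: dict
) -> tuple[list[HologramFrame], list[HologramFrame]]:
    """Dynamic flat-field correction and faded splitting of every frame."""
    frames = archive["frames"]
    flats = archive["flats"]
    if flats.size:
        n_comp = min(config.pca_components, len(flats) - 1)
        model = fit_flatfield(flats, n_comp)
    else:
        logger.warning("no flats in archive: falling back to mean-flat division")
        model = fit_flatfield(np.stack([np.ones(frames[0].shape)] * 2), 0)
    fit_region = border_ring_mask(frames[0].shape, config.fit_border_fraction)
    holos_left, holos_right = [], []
    for frame in frames:
        corrected = correct_frame(frame, model, fit_region)
        left, right = split_compound(
            corrected.intensity,
            archive["left_window"],
            archive["right_window"],
            plateau_fraction=config.fade_plateau,
            mask_sigma=config.fade_sigma,
        )
        holos_left.append(left)
        holos_right.append(right)
    return holos_left, holos_right


def run_retrieve(config: PipelineConfig, archive_path: str, out_path: str) -> dict:
    """Flat-field correct, split and phase-retrieve a scan archive.

    Writes the retrieved phase stacks (no tomography) plus a
    per-projection residual CSV next to the output file.
    """
    t0 = time.time()
    archive = hio.read_scan(archive_path)
    geo = archive["geometry"]
    angles = archive["angles"]
    holos_left, holos_right = _correct_and_split(config, archive)
    stack_left, res_left = _retrieve_stack(holos_left, angles, geo, config, "left")
    stack_right, res_right = _retrieve_stack(holos_right, angles, geo, config, "right")
    report = {
        "retrieval_residuals": {"left": res_left, "right": res_right},
        "total_s": time.time() - t0,
    }
    if "truth_left" in archive:
        report["phase_nrmse"] = {
            "left": _stack_nrmse(stack_left.phases, archive["truth_left"]),
            "right": _stack_nrmse(stack_right.phases, archive["truth_right"]),
        }
    hio.write_reconstruction(
        out_path,
        phases={"left": stack_left.phases, "right": stack_right.phases},
        volumes={},
        report=report,
    )
    hio.write_residuals_csv(
        out_path + ".residuals.csv", report["retrieval_residuals"]
    )
    return report


def run_reconstruct(
    config: PipelineConfig, archive_path: str, out_path: str
) -> dict:
    """Run the full reconstruction chain on a scan archive.

    Returns the report dict (also stored in the output archive).
    """
    t0 = time.time()
    archive = hio.read_scan(archive_path)
    geo = archive["geometry"]
    angles = archive["angles"]
    report: dict = {"stages": {}}

    holos_left, holos_right = _correct_and_split(config, archive)
    report["stages"]["flatfield_s"] = time.time() - t0

    t1 = time.time()
    stack_left, res_left = _retrieve_stack(holos_left, angles, geo, config, "left")
    stack_right, res_right = _retrieve_stack(holos_right, angles, geo, config, "right")
    report["retrieval_residuals"] = {"left": res_left, "right": res_right}
    report["stages"]["retrieval_s"] = time.time() - t1

    t2 = time.time()
    if len(angles) >= 8 and config.align_rounds > 0:
        stack_left = align_stack(stack_left, n_rounds=config.align_rounds)
        stack_right = align_stack(stack_right, n_rounds=config.align_rounds)
        report["reprojection_errors"] = {
            "left": stack_left.meta.get("reprojection_errors"),
            "right": stack_right.meta.get("reprojection_errors"),
        }
    fused = fuse_stacks(stack_left, stack_right, archive["alpha"])
    vol_left = fbp_reconstruct(stack_left, config.tomo_filter)
    vol_right = fbp_reconstruct(stack_right, config.tomo_filter)
    vol_fused = fbp_reconstruct(fused, config.tomo_filter)
    report["ring_metric"] = {
        "left": ring_metric(vol_left),
        "right": ring_metric(vol_right),
        "fused": ring_metric(vol_fused),
    }
    report["stages"]["tomo_s"] = time.time() - t2

    if "truth_left" in archive:
        report["phase_nrmse"] = {
            "left": _stack_nrmse(stack_left.phases, archive["truth_left"]),
            "right": _stack_nrmse(stack_right.phases, archive["truth_right"]),
        }
    report["total_s"] = time.time() - t0

    hio.write_reconstruction(
        out_path,
        phases={"left": stack_left.phases, "right": stack_right.phases},
        volumes={
            "left": vol_left.delta_recon,
            "right": vol_right.delta_recon,
            "fused": vol_fused.delta_recon,
        },
        report=report,
    )
    hio.write_residuals_csv(
        out_path + ".residuals.csv", report["retrieval_residuals"]
    )
    logger.info("reconstruction finished in %.1f s -> %s", report["total_s"], out_path)
    return report


def _stack_nrmse(retrieved: np.ndarray, truth: np.ndarray) -> float:
    mask = np.abs(truth) > 1e-6
    if not mask.any():
        return float("nan")
    return float(
        np.sqrt(np.mean((retrieved[mask] - truth[mask]) ** 2))
        / np.sqrt(np.mean(truth[mask] ** 2))
    )
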