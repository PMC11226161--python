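"""Seeded synthetic benchmarks for phase retrieval and dual-beam fusion.

These benches define the package's reference test conditions: hair-like
phantoms imaged at the experiment geometry (Fresnel number 3.1e-3), an
object occupying the central half of the hologram frame so that its
fringe field is essentially contained in the detector window, and —
for the noisy variant — Poisson statistics at a stated photon budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import ImagingGeometry
from .presets import experiment_geometry
from .propagation import HologramFrame, PhaseMap, forward_hologram
from .retrieval import RetrievalConfig, retrieve_phase
from .scene import make_hair_phantom, project_phase

__all__ = ["BenchCase", "make_bench_case", "retrieval_nrmse", "retrieval_benchmark"]


@dataclass
class BenchCase:
    """One phantom projection embedded in a hologram frame, with truth."""

    phase: PhaseMap
    hologram: HologramFrame
    truth_mask: np.ndarray
    geometry: ImagingGeometry


def make_bench_case(
    seed: int,
    frame_px: int = 128,
    phantom_px: int = 64,
    geometry: ImagingGeometry | None = None,
    noise_photons: float | None = None,
    noise_seed_offset: int = 1000,
) -> BenchCase:
    """Build the standard retrieval bench case for one seed.

    A hair phantom (4 µm shaft, 300 nm hairlets, scaled down with the
    grid) on a ``phantom_px`` grid is projected at a seed-dependent angle
    and embedded centrally in a ``frame_px`` frame; the noiseless
    hologram is optionally replaced by a Poisson realisation at
    ``noise_photons`` photons per pixel.
    """
    geo = geometry or experiment_geometry()
    scale = phantom_px / 64.0
    phantom = make_hair_phantom(
        phantom_px,
        geo.effective_pixel,
        hair_diameter=4e-6 * scale,
        n_elements=8,
        element_diameter=300e-9,
        element_length=1.4e-6 * scale,
        delta_value=1e-6,
        seed=seed,
    )
    pm = project_phase(phantom, 0.3 + 0.1 * seed, geo.wavelength)
    phi = np.zeros((frame_px, frame_px))
    o = (frame_px - phantom_px) // 2
    phi[o : o + phantom_px, o : o + phantom_px] = pm.phi
    phase = PhaseMap(phi=phi, pixel_size=geo.effective_pixel)
    holo = forward_hologram(phase, geo)
    if noise_photons is not None:
        rng = np.random.default_rng(noise_seed_offset + seed)
        noisy = rng.poisson(noise_photons * holo.intensity) / noise_photons
        holo = HologramFrame(noisy, holo.pixel_size, holo.fresnel_number)
    return BenchCase(
        phase=phase, hologram=holo, truth_mask=np.abs(phi) > 1e-6, geometry=geo
    )


def retrieval_nrmse(case: BenchCase, config: RetrievalConfig | None = None) -> float:
    """Retrieve the phase of a bench case; NRMSE inside the true support."""
    rec, _ = retrieve_phase(case.hologram, case.geometry, config)
    m = case.truth_mask
    return float(
        np.sqrt(np.mean((rec.phi[m] - case.phase.phi[m]) ** 2))
        / np.sqrt(np.mean(case.phase.phi[m] ** 2))
    )


def retrieval_benchmark(
    seeds: range | list[int],
    noise_photons: float | None = None,
    config: RetrievalConfig | None = None,
    frame_px: int = 128,
) -> np.ndarray:
    """NRMSE over a set of seeded phantoms (noiseless or Poisson)."""
    return np.array(
        [
            retrieval_nrmse(
                make_bench_case(s, frame_px=frame_px, noise_photons=noise_photons),
                config,
            )
            for s in seeds
        ]
    )


def ring_fusion_bench(
    seed: int = 7,
    n: int = 128,
    n_angles: int = 220,
    offset_strength: float = 1.0,
    alpha: float = 1.22e-3,
) -> dict:
    """Seeded dual-beam ring-artifact bench.

    A smooth random object is projected at the left/right beam angles;
    each beam's sinogram carries its own fixed per-detector-column offset
    (the ring-artifact source), drawn independently per beam and
    normalised to equal RMS.  Returns the ring metric of the left, right
    and fused reconstructions.  Because detector-fixed errors differ
    between the beams, the fused stack averages them down; the object is
    scaled so its angular structure dominates the total variance while
    the rings dominate the radial profile, which is the regime where the
    ring metric resolves the averaging.
    """
    import warnings

    from scipy import ndimage

    from .optics import wavelength_from_energy
    from .tomo import ProjectionStack, fbp_reconstruct, fuse_stacks, radon_forward, ring_metric

    lam = wavelength_from_energy(11.0)
    vox = 133e-9
    rng_obj = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng_obj.standard_normal((n, n)), 2.0)
    yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2
    truth = base * (np.hypot(yy, xx) < n / 2 - 4)
    angles = np.arange(n_angles) * np.pi / n_angles
    sino_l = radon_forward(truth, angles)
    sino_r = radon_forward(truth, angles + alpha)
    rng_det = np.random.default_rng(seed + 100)
    scale = np.abs(sino_l).mean()

    def column_offsets() -> np.ndarray:
        g = ndimage.gaussian_filter(rng_det.standard_normal(n), 2.0)
        return offset_strength * scale * g / np.sqrt(np.mean(g**2))

    def stack(sino, offs, ang, label):
        phases = -(2 * np.pi / lam) * (sino + offs[:, None]).T[:, None, :] * vox
        return ProjectionStack(
            phases=phases, angles=ang, pixel_size=vox, wavelength=lam, beam_label=label
        )

    left = stack(sino_l, column_offsets(), angles, "left")
    right = stack(sino_r, column_offsets(), angles + alpha, "right")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_left = ring_metric(fbp_reconstruct(left))
        m_right = ring_metric(fbp_reconstruct(right))
        fused = fuse_stacks(left, right, alpha, register=False)
        m_fused = ring_metric(fbp_reconstruct(fused))
    return {"left": m_left, "right": m_right, "fused": m_fused}
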