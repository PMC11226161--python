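"""Synthetic beamline scenes: phantom, illumination, and compound frames.

Everything a holotomography beamline would deliver is generated here so the
full processing chain can be exercised without experimental data:

* a 3D phantom mimicking a spider attachment hair — a 5–15 µm shaft
  carrying 100–300 nm hairlets, a standard weakly absorbing test object
  for nanoscale phase contrast;
* projected phase maps ``phi = -(2*pi/lambda) * integral(delta dl)`` over
  0–180 deg;
* an illumination model with low-rank flat-field dynamics, dark
  zone-plate-imperfection spots, detector chip-gap stripes, and Poisson
  counting noise at a configurable photon flux;
* compound two-beam detector frames: the same object seen by both beams
  at angles differing by the beam separation angle ``alpha``, imaged onto
  two disjoint windows of one detector.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import ImagingGeometry
from .propagation import PhaseMap, forward_hologram

__all__ = [
    "PhantomVolume",
    "IlluminationModel",
    "CompoundFrame",
    "SimulatedScan",
    "make_hair_phantom",
    "project_phase",
    "make_illumination",
    "sample_flat",
    "render_compound_frame",
    "simulate_scan",
]


@dataclass
class PhantomVolume:
    """3D grid of the refractive-index decrement ``delta`` (>= 0).

    Array layout is ``(y, x, z)``: ``y`` is the (vertical) rotation axis,
    the beam propagates along ``z``, and projections are ``(y, x)`` maps.
    """

    delta: np.ndarray
    voxel_size: float
    description: str = ""

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 3:
            raise ValueError("phantom must be 3D")
        if np.any(self.delta < 0):
            raise ValueError("delta must be non-negative")


@dataclass
class IlluminationModel:
    """Low-rank dynamic flat field plus static detector/optic defects.

    A sampled flat is ``(mean_flat + sum_k a_k * components[k]) * response``
    where the coefficients ``a_k`` are drawn per frame with scales
    ``component_scales`` and ``response`` carries the static dark
    imperfection spots and chip-gap stripes.  ``flux * exposure`` sets the
    Poisson scale in photons per pixel.
    """

    mean_flat: np.ndarray
    components: list[np.ndarray]
    component_scales: np.ndarray
    response: np.ndarray
    defect_spots: list[tuple[tuple[float, float], float, float]]
    chip_gap_rows: list[int]
    chip_gap_cols: list[int]
    flux: float = 500.0
    exposure: float = 2.0

    @property
    def photons_per_pixel(self) -> float:
        return self.flux * self.exposure

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean_flat.shape


@dataclass
class CompoundFrame:
    """Integer photon counts of one dual-beam exposure.

    ``left_window`` / ``right_window`` are ``(y0, y1, x0, x1)`` pixel
    rectangles of the two sub-holograms, disjoint by construction and
    separated horizontally by ``d_img_px`` pixels (center to center).
    """

    counts: np.ndarray
    left_window: tuple[int, int, int, int]
    right_window: tuple[int, int, int, int]
    d_img_px: int

    def __post_init__(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        ly0, ly1, lx0, lx1 = self.left_window
        ry0, ry1, rx0, rx1 = self.right_window
        if not (lx1 <= rx0 or rx1 <= lx0):
            raise ValueError("sub-hologram windows overlap on the detector")

    def window_view(self, side: str) -> np.ndarray:
        y0, y1, x0, x1 = self.left_window if side == "left" else self.right_window
        return self.counts[y0:y1, x0:x1]


@dataclass
class SimulatedScan:
    """A full synthetic tomographic acquisition with ground truth."""

    frames: list[CompoundFrame]
    flats: list[np.ndarray]
    angles: np.ndarray
    alpha: float
    truth_left: list[PhaseMap]
    truth_right: list[PhaseMap]
    illumination: IlluminationModel
    geometry: ImagingGeometry
    phantom: PhantomVolume | None = None
    seed: int | None = None


def _segment_mask(
    shape: tuple[int, int, int],
    p0: np.ndarray,
    p1: np.ndarray,
    radius_vox: float,
) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Boolean mask of a capsule (cylinder with round caps) between two
    points, evaluated only on its bounding box for speed."""
    lo = np.floor(np.minimum(p0, p1) - radius_vox - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius_vox + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    if np.any(hi <= lo):
        empty = (slice(0, 0),) * 3
        return np.zeros((0, 0, 0), bool), empty
    grids = np.meshgrid(
        *[np.arange(lo[i], hi[i], dtype=float) for i in range(3)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        dist2 = np.sum((pts - p0) ** 2, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = np.sum((pts - proj) ** 2, axis=-1)
    box = tuple(slice(lo[i], hi[i]) for i in range(3))
    return dist2 <= radius_vox**2, box


def make_hair_phantom(
    n_voxels: int,
    voxel_size: float,
    hair_diameter: float = 8e-6,
    n_elements: int = 40,
    element_diameter: float = 266e-9,
    delta_value: float = 1e-6,
    seed: int = 0,
    tilt: float = 0.06,
    element_length: float | None = None,
) -> PhantomVolume:
    """Spider-attachment-hair phantom: a tilted shaft with radial hairlets.

    Parameters
    ----------
    n_voxels : side length of the cubic grid.
    voxel_size : voxel pitch in metres (the effective pixel of the scan).
    hair_diameter : shaft diameter (typically 5–15 µm).
    n_elements : number of hairlets placed pseudo-randomly from ``seed``.
    element_diameter : hairlet diameter (100–300 nm); must be at least
        two voxels to be resolvable.
    delta_value : constant refractive-index decrement inside the material.
    tilt : shaft tilt (dimensionless slope of the axis per vertical voxel).
    element_length : hairlet length; default ``6 * element_diameter``.
    """
    if element_diameter < 2 * voxel_size:
        raise ValueError(
            "element_diameter must be >= 2 voxels to be resolvable "
            f"({element_diameter} < {2 * voxel_size})"
        )
    rng = np.random.default_rng(seed)
    n = int(n_voxels)
    shape = (n, n, n)
    R = hair_diameter / 2.0 / voxel_size
    if element_length is None:
        element_length = 6.0 * element_diameter
    L = element_length / voxel_size
    r_el = element_diameter / 2.0 / voxel_size

    margin = R + (L if n_elements > 0 else 0.0) + 2
    c = (n - 1) / 2.0
    if margin >= n / 2.0:
        raise ValueError(
            "phantom exceeds the grid: shaft radius + hairlet length "
            f"({margin:.1f} vox) does not fit in {n} voxels"
        )

    y = np.arange(n, dtype=float)
    x = np.arange(n, dtype=float)
    z = np.arange(n, dtype=float)
    # tilted shaft: axis runs along y with linear drift in x and z
    xc = c + tilt * (y - c)
    zc = c - 0.5 * tilt * (y - c)
    dist2 = (x[None, :, None] - xc[:, None, None]) ** 2 + (
        z[None, None, :] - zc[:, None, None]
    ) ** 2
    delta = np.zeros(shape)
    delta[dist2 <= R**2] = delta_value
    delta[:2] = 0.0  # cap the shaft: support strictly inside the grid
    delta[-2:] = 0.0

    for _ in range(n_elements):
        yi = rng.uniform(margin, n - 1 - margin)
        az = rng.uniform(0.0, 2 * np.pi)
        pitch = rng.uniform(-0.3, 0.3)  # slight out-of-plane slope
        direction = np.array([pitch, np.cos(az), np.sin(az)])
        direction /= np.linalg.norm(direction)
        x0 = c + tilt * (yi - c)
        z0 = c - 0.5 * tilt * (yi - c)
        start = np.array([yi, x0, z0]) + direction * (R - r_el)
        end = start + direction * L
        mask, box = _segment_mask(shape, start, end, max(r_el, 1.0))
        if mask.size:
            delta[box][mask] = delta_value

    occupied = delta > 0
    if occupied.size and (
        occupied[0].any()
        or occupied[-1].any()
        or occupied[:, 0].any()
        or occupied[:, -1].any()
        or occupied[:, :, 0].any()
        or occupied[:, :, -1].any()
    ):
        raise ValueError("phantom support touches the grid border")
    desc = (
        f"hair phantom: n={n}, voxel={voxel_size:.3e} m, shaft {hair_diameter:.2e} m, "
        f"{n_elements} elements of {element_diameter:.2e} m, delta={delta_value:.2e}, "
        f"seed={seed}"
    )
    return PhantomVolume(delta=delta, voxel_size=voxel_size, description=desc)


def rotate_volume(delta: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a ``(y, x, z)`` volume about the vertical y axis by ``angle``
    radians (trilinear resampling, grid size preserved)."""
    if angle == 0.0:
        return delta
    return ndimage.rotate(
        delta,
        np.degrees(angle),
        axes=(1, 2),
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )


def project_phase(phantom: PhantomVolume, angle: float, wavelength: float) -> PhaseMap:
    """Projected phase at tomographic angle ``angle`` (radians).

    The volume is rotated about the vertical axis and summed along the
    beam axis: ``phi = -(2*pi/lambda) * sum(delta) * voxel`` — always
    non-positive for ``delta >= 0``.
    """
    rotated = rotate_volume(phantom.delta, angle)
    thickness = rotated.sum(axis=2) * phantom.voxel_size
    phi = -(2.0 * np.pi / wavelength) * thickness
    return PhaseMap(phi=np.minimum(phi, 0.0), pixel_size=phantom.voxel_size)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    return f - f.mean()


def make_illumination(
    shape: tuple[int, int],
    n_components: int = 5,
    defect_density: float = 2e-4,
    flux: float = 500.0,
    exposure: float = 2.0,
    seed: int = 0,
    chip_size: int = 256,
    gap_gain: float = 1.5,
    component_scale: float = 0.05,
    envelope: float = 0.15,
) -> IlluminationModel:
    """Random-but-seeded illumination with low-rank flat-field structure.

    ``n_components`` orthonormal smooth fields model the beam drift seen
    in empty-beam series; dark spots (surface density ``defect_density``
    per pixel) model zone-plate imperfections; rows/columns at multiples
    of ``chip_size`` get gain ``gap_gain`` to model the detector's
    interpolated chip-gap stripes.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    base = np.exp(-(((yy - cy) / (1.2 * ny)) ** 2 + ((xx - cx) / (1.2 * nx)) ** 2))
    mean_flat = 1.0 + envelope * (base / base.mean() - 1.0)

    components: list[np.ndarray] = []
    if n_components > 0:
        sigma = max(min(ny, nx) / 10.0, 2.0)
        stack = np.stack(
            [_smooth_field(rng, shape, sigma).ravel() for _ in range(n_components)]
        )
        q, _ = np.linalg.qr(stack.T)  # orthonormalise, keep smoothness
        components = [q[:, k].reshape(shape) for k in range(n_components)]
    scales = component_scale * (0.7 ** np.arange(n_components)) * np.sqrt(ny * nx)

    response = np.ones(shape)
    n_defects = rng.poisson(defect_density * ny * nx)
    defect_spots: list[tuple[tuple[float, float], float, float]] = []
    for _ in range(n_defects):
        center = (rng.uniform(0, ny - 1), rng.uniform(0, nx - 1))
        radius = rng.uniform(1.0, max(2.0, min(ny, nx) / 40.0))
        depth = rng.uniform(0.3, 0.8)
        defect_spots.append((center, radius, depth))
        d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
        response[d2 <= radius**2] *= 1.0 - depth

    chip_gap_rows = [r for r in range(chip_size, ny, chip_size)]
    chip_gap_cols = [c for c in range(chip_size, nx, chip_size)]
    for r in chip_gap_rows:
        response[r, :] *= gap_gain
    for c in chip_gap_cols:
        response[:, c] *= gap_gain

    return IlluminationModel(
        mean_flat=mean_flat,
        components=components,
        component_scales=scales,
        response=response,
        defect_spots=defect_spots,
        chip_gap_rows=chip_gap_rows,
        chip_gap_cols=chip_gap_cols,
        flux=flux,
        exposure=exposure,
    )


def sample_flat(model: IlluminationModel, rng: np.random.Generator) -> np.ndarray:
    """One realisation of the relative flat field (mean level ~ 1)."""
    flat = model.mean_flat.copy()
    for scale, comp in zip(model.component_scales, model.components):
        flat = flat + rng.normal(0.0, scale) * comp
    return np.clip(flat, 1e-3, None) * model.response


def sample_flat_counts(model: IlluminationModel, rng: np.random.Generator) -> np.ndarray:
    """One empty-beam exposure in integer photon counts."""
    lam = model.photons_per_pixel * sample_flat(model, rng)
    return rng.poisson(lam).astype(np.int64)


def _windows_for(
    detector_shape: tuple[int, int], sub_shape: tuple[int, int], d_img_px: int
) -> tuple[tuple[int, int, int, int], tuple[int, int, int, int]]:
    ny, nx = detector_shape
    sy, sx = sub_shape
    y0 = (ny - sy) // 2
    cxl = nx // 2 - d_img_px // 2
    cxr = cxl + d_img_px
    lx0 = cxl - sx // 2
    rx0 = cxr - sx // 2
    left = (y0, y0 + sy, lx0, lx0 + sx)
    right = (y0, y0 + sy, rx0, rx0 + sx)
    if left[3] > right[2]:
        raise ValueError(
            f"sub-hologram windows overlap: separation {d_img_px} px < width {sx} px"
        )
    if left[2] < 0 or right[3] > nx or y0 < 0 or y0 + sy > ny:
        raise ValueError("sub-hologram windows exceed the detector")
    return left, right


def render_compound_frame(
    phase_left: PhaseMap,
    phase_right: PhaseMap,
    geometry: ImagingGeometry,
    illum: IlluminationModel,
    seed: int | np.random.Generator = 0,
) -> CompoundFrame:
    """One dual-beam exposure: two holograms on one noisy detector frame.

    Each side is ``flat x |P(exp(i*phi), z_eff)|^2`` sampled with Poisson
    statistics at ``flux * exposure`` photons per pixel; the two windows
    are separated by ``d_img_px = round(d_img / px)`` detector pixels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_img_px = int(round(geometry.d_img / geometry.detector_pixel))
    left, right = _windows_for(illum.shape, phase_left.phi.shape, d_img_px)
    flat = sample_flat(illum, rng)
    expectation = illum.photons_per_pixel * flat
    for window, phase in ((left, phase_left), (right, phase_right)):
        holo = forward_hologram(phase, geometry).intensity
        y0, y1, x0, x1 = window
        expectation[y0:y1, x0:x1] *= holo
    counts = rng.poisson(expectation).astype(np.int64)
    return CompoundFrame(
        counts=counts, left_window=left, right_window=right, d_img_px=d_img_px
    )


def simulate_scan(
    phantom: PhantomVolume,
    geometry: ImagingGeometry,
    illum: IlluminationModel,
    n_angles: int,
    alpha: float,
    seed: int = 0,
    n_flats: int = 120,
) -> SimulatedScan:
    """Full tomographic acquisition: ``n_angles`` compound frames over
    0–180 deg plus ``n_flats`` empty-beam frames, with ground truth.

    Angles are ``theta_i = i * pi / n_angles`` (endpoint exclusive); the
    left beam sees the object at ``theta_i``, the right beam at
    ``theta_i + alpha``.  ``alpha`` is applied as a rotation offset of the
    phantom — at mrad scale the geometric difference across the FOV is
    sub-voxel, so a tilted propagation axis is not modelled.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    rng = np.random.default_rng(seed)
    angles = np.arange(n_angles) * np.pi / n_angles
    frames: list[CompoundFrame] = []
    truth_left: list[PhaseMap] = []
    truth_right: list[PhaseMap] = []
    for theta in angles:
        pl = project_phase(phantom, theta, geometry.wavelength)
        pr = project_phase(phantom, theta + alpha, geometry.wavelength)
        frames.append(render_compound_frame(pl, pr, geometry, illum, rng))
        truth_left.append(pl)
        truth_right.append(pr)
    flats = [sample_flat_counts(illum, rng) for _ in range(n_flats)]
    return SimulatedScan(
        frames=frames,
        flats=flats,
        angles=angles,
        alpha=alpha,
        truth_left=truth_left,
        truth_right=truth_right,
        illumination=illum,
        geometry=geometry,
        phantom=phantom,
        seed=seed if isinstance(seed, int) else None,
    )
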