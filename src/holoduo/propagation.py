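"""Scalar Fresnel free-space propagation and the near-field hologram forward model.

The propagator is the angular-spectrum / transfer-function method: a
wavefield sampled on a regular grid is multiplied in Fourier space by the
paraxial free-space kernel

    H(f) = exp(-i * pi * lambda * z * |f|^2),

with periodic boundary conditions.  H is unimodular, so the propagator is
unitary: total power is conserved exactly and ``propagate(z)`` followed by
``propagate(-z)`` is the identity.  The cone-beam (divergent) geometry of
the instrument is mapped onto this parallel-beam picture by the Fresnel
scaling theorem: simulate on the effective-pixel grid ``dx = px/M`` at the
effective distance ``z_eff = z01*z12/z02``.

In the weak-phase limit a pure phase object ``psi = exp(i*phi)`` produces
the classic phase contrast-transfer function: ``I_hat(f) - delta(f) ≈
2*sin(pi*lambda*z*|f|^2) * phi_hat(f)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import ImagingGeometry

__all__ = [
    "ComplexWavefield",
    "PhaseMap",
    "HologramFrame",
    "fresnel_transfer_function",
    "fresnel_propagate",
    "forward_hologram",
    "sampling_check",
    "SamplingReport",
    "pad_to_fresnel_grid",
]


@dataclass
class ComplexWavefield:
    """2D complex amplitude on a regular grid of pitch ``pixel_size`` (m)."""

    values: np.ndarray
    pixel_size: float
    wavelength: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("wavefield must be 2D")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be positive")

    @property
    def power(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass
class PhaseMap:
    """Projected phase shift of the object in radians (``phi <= 0`` for a
    refractive-index decrement ``delta > 0``)."""

    phi: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValueError("phase map must be 2D")


@dataclass
class HologramFrame:
    """Flat-field-normalised near-field intensity (empty beam == 1)."""

    intensity: np.ndarray
    pixel_size: float
    fresnel_number: float = float("nan")
    bad_pixel_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram must be 2D")


def fresnel_transfer_function(
    shape: tuple[int, int], pixel_size: float, wavelength: float, distance: float
) -> np.ndarray:
    """Paraxial free-space Fourier multiplier exp(-i*pi*lambda*z*|f|^2)."""
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.fftfreq(shape[1], d=pixel_size)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return np.exp(-1j * np.pi * wavelength * distance * f2)


def fresnel_propagate(field: ComplexWavefield, distance: float) -> ComplexWavefield:
    """Propagate a wavefield by ``distance`` metres (negative = backward).

    Transfer-function propagator with periodic boundaries; exactly
    unitary, so ``propagate(z)`` then ``propagate(-z)`` recovers the
    input to round-off.
    """
    if distance == 0:
        return ComplexWavefield(field.values.copy(), field.pixel_size, field.wavelength)
    kernel = fresnel_transfer_function(
        field.values.shape, field.pixel_size, field.wavelength, distance
    )
    out = np.fft.ifft2(np.fft.fft2(field.values) * kernel)
    return ComplexWavefield(out, field.pixel_size, field.wavelength)


def pad_to_fresnel_grid(
    array: np.ndarray, fill: complex = 1.0, min_pad_fraction: float = 0.25
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Embed ``array`` centrally in a power-of-two grid at least
    ``(1 + min_pad_fraction)`` times larger, filled with ``fill``.

    Returns the padded array and the slices that recover the original
    region.  Padding with the empty-beam value suppresses wrap-around
    artifacts of the periodic propagator.
    """
    ny, nx = array.shape
    target = 1
    need = int(np.ceil(max(ny, nx) * (1.0 + min_pad_fraction)))
    while target < need:
        target *= 2
    out = np.full((target, target), fill, dtype=array.dtype)
    oy = (target - ny) // 2
    ox = (target - nx) // 2
    window = (slice(oy, oy + ny), slice(ox, ox + nx))
    out[window] = array
    return out, window


def forward_hologram(
    phase: PhaseMap,
    geometry: ImagingGeometry,
    pad: bool = True,
) -> HologramFrame:
    """Near-field hologram of a pure phase object.

    ``I = |P(exp(i*phi), z_eff)|^2`` on the effective-pixel grid.  The
    object is a pure phase screen (absorption zero); the field is padded
    with the unit empty-beam value before propagation (>= 25%) and
    cropped back, so border wrap-around stays outside the frame.
    """
    z_eff = getattr(geometry, "z_eff", None)
    if z_eff is None or not np.isfinite(z_eff):
        raise ValueError("geometry must provide a finite effective distance z_eff")
    psi = np.exp(1j * phase.phi)
    if pad:
        padded, window = pad_to_fresnel_grid(psi.astype(complex))
    else:
        padded, window = psi.astype(complex), (slice(None), slice(None))
    out = fresnel_propagate(
        ComplexWavefield(padded, geometry.effective_pixel, geometry.wavelength), z_eff
    )
    intensity = np.abs(out.values[window]) ** 2
    return HologramFrame(
        intensity=intensity,
        pixel_size=geometry.effective_pixel,
        fresnel_number=geometry.fresnel_number,
    )


@dataclass(frozen=True)
class SamplingReport:
    """Outcome of the alias-safety check for the transfer-function propagator."""

    ok: bool
    z_max: float
    z_requested: float
    message: str


def sampling_check(geometry: ImagingGeometry, grid_n: int) -> SamplingReport:
    """Alias-safety of the periodic propagator on an ``grid_n``-wide grid.

    The Fourier-multiplier kernel is adequately sampled when the
    propagation distance satisfies ``z <= N * dx**2 / lambda`` (the
    kernel phase changes by < pi between adjacent frequency samples).
    """
    z_max = grid_n * geometry.effective_pixel**2 / geometry.wavelength
    z = abs(geometry.z_eff)
    ok = z <= z_max
    msg = (
        f"z_eff = {z * 1e3:.2f} mm vs N*dx^2/lambda = {z_max * 1e3:.2f} mm: "
        + ("alias-safe" if ok else "UNDERSAMPLED transfer function — enlarge the grid")
    )
    return SamplingReport(ok=ok, z_max=z_max, z_requested=z, message=msg)
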