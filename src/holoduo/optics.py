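"""Dual-beam zone-plate optics and imaging-geometry calculators.

Pure functions and frozen dataclasses describing the divergent-beam
holography geometry: a dual Fresnel zone plate (dFZP) — two half zone
plates with laterally offset centers — focuses the beam into two foci;
the beams cross in the sample plane a distance ``z01`` behind the focus
and separate again to a distance ``d_img`` on the detector, ``z12``
further downstream.  All lengths are metres internally; helpers that
accept config dictionaries handle the mm/µm/nm suffixes.

The geometric relations are elementary similar-triangle identities:

* ``d_FZP = d_img * z01 / z12`` — zone-plate center separation that
  makes the two beams overlap in the sample plane,
* ``z01 = z02 * dx / px`` — defocus distance realising a target
  effective pixel ``dx`` with detector pixel ``px`` (``M = px/dx``),
* ``M = z02 / z01``, ``dx = px / M``, ``z_eff = z01*z12/z02`` (Fresnel
  scaling theorem), ``F = dx**2 / (lambda * z_eff)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HC_KEV_M",
    "BeamSpec",
    "ZonePlateDesign",
    "ImagingGeometry",
    "SamplingPlan",
    "GeometryConfigurationError",
    "wavelength_from_energy",
    "focal_length",
    "fzp_center_separation",
    "overlap_distance",
    "derive_geometry",
    "crowther_projections",
    "crowther_general",
    "beam_angle_at_detector",
]

#: hc in keV*m (12.3984198 keV*Angstrom), the conversion behind every lambda.
HC_KEV_M = 1.23984198e-9


class GeometryConfigurationError(ValueError):
    """Raised when a geometry is internally inconsistent (e.g. the two
    sub-holograms would overlap on the detector)."""


def _check_positive(**values: float) -> None:
    for name, value in values.items():
        if not (value > 0 and math.isfinite(value)):
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in metres for a photon energy in keV."""
    _check_positive(energy_kev=energy_kev)
    return HC_KEV_M / energy_kev


def focal_length(diameter: float, outer_zone_width: float, wavelength: float) -> float:
    """First-order focal length of a thin Fresnel zone plate.

    ``f = D * dr_n / lambda`` with parent diameter ``D`` and outermost
    zone width ``dr_n``, all in metres.
    """
    _check_positive(
        diameter=diameter, outer_zone_width=outer_zone_width, wavelength=wavelength
    )
    return diameter * outer_zone_width / wavelength


def fzp_center_separation(d_img: float, z01: float, z12: float) -> float:
    """Zone-plate center separation from the image separation at the detector.

    Similar triangles: the two foci sit ``d_FZP`` apart, the beams cross in
    the sample plane ``z01`` downstream and separate to ``d_img`` after a
    further ``z12``; hence ``d_FZP = d_img * z01 / z12``.
    ``d_img = 0`` (coincident zone plates) is allowed and returns 0.
    """
    if d_img < 0:
        raise ValueError(f"d_img must be non-negative, got {d_img!r}")
    _check_positive(z01=z01, z12=z12)
    return d_img * z01 / z12


def overlap_distance(target_pixel: float, detector_pixel: float, z02: float) -> float:
    """Defocus distance ``z01`` that realises a target effective pixel size.

    ``z01 = z02 * dx / px`` — equivalently ``z01 = z02 / M`` with the
    magnification ``M = px / dx``.  Demagnification (``dx >= px``) is not
    supported, except for the exact unit-magnification limit ``dx == px``.
    """
    _check_positive(target_pixel=target_pixel, detector_pixel=detector_pixel, z02=z02)
    if target_pixel > detector_pixel:
        raise ValueError(
            "target effective pixel must not exceed the detector pixel "
            f"(magnification < 1 unsupported): {target_pixel} > {detector_pixel}"
        )
    return z02 * target_pixel / detector_pixel


def beam_angle_at_detector(d_img: float, z12: float) -> float:
    """Operational beam-separation angle ``d_img / z12`` in radians.

    This is the chief-ray separation rate between sample plane and
    detector — a convention, documented as such; it is the angle by which
    the two simultaneously recorded projections differ.
    """
    if d_img < 0:
        raise ValueError(f"d_img must be non-negative, got {d_img!r}")
    _check_positive(z12=z12)
    return d_img / z12


def crowther_projections(n_pix: int) -> int:
    """Minimum projection count over 180 deg for an ``n_pix``-wide image.

    Crowther criterion at a resolution of two pixels: ``n_proj =
    pi * n_pix / 2``, rounded up (a projection count is an integer and
    the criterion is a lower bound).  The angular step is
    ``pi / n_proj`` radians.
    """
    if n_pix < 1:
        raise ValueError(f"n_pix must be >= 1, got {n_pix!r}")
    return math.ceil(math.pi * n_pix / 2)


def crowther_general(object_size: float, resolution: float) -> int:
    """Crowther criterion ``n_proj = pi * D / d`` (rounded up) for an
    object of size ``D`` imaged at resolution ``d``."""
    _check_positive(object_size=object_size, resolution=resolution)
    if resolution > object_size:
        raise ValueError(
            f"resolution d={resolution} must not exceed object size D={object_size}"
        )
    return math.ceil(math.pi * object_size / resolution)


@dataclass(frozen=True)
class BeamSpec:
    """Monochromatic beam: photon energy (keV) and wavelength (m)."""

    energy: float
    wavelength: float

    def __post_init__(self) -> None:
        _check_positive(energy=self.energy, wavelength=self.wavelength)

    @classmethod
    def from_energy(cls, energy_kev: float) -> "BeamSpec":
        return cls(energy=energy_kev, wavelength=wavelength_from_energy(energy_kev))


@dataclass(frozen=True)
class ZonePlateDesign:
    """Dual Fresnel zone plate design parameters, all lengths in metres.

    ``center_separation`` is the distance between the centers of the two
    parent zone plates; ``gap`` the physical gap between the written
    halves; ``central_stop_width`` the tungsten stop between them.
    """

    parent_diameter: float
    outer_zone_width: float
    focal_length: float
    center_separation: float = 0.0
    gap: float = 0.0
    central_stop_width: float = 0.0

    def __post_init__(self) -> None:
        _check_positive(
            parent_diameter=self.parent_diameter,
            outer_zone_width=self.outer_zone_width,
            focal_length=self.focal_length,
        )
        for name in ("center_separation", "gap", "central_stop_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_beam(
        cls,
        parent_diameter: float,
        outer_zone_width: float,
        beam: BeamSpec,
        **kwargs: float,
    ) -> "ZonePlateDesign":
        f = focal_length(parent_diameter, outer_zone_width, beam.wavelength)
        return cls(parent_diameter, outer_zone_width, f, **kwargs)

    def validate_focal_length(self, beam: BeamSpec, rtol: float = 0.01) -> None:
        """Check the stored focal length against ``D*dr_n/lambda``."""
        f = focal_length(self.parent_diameter, self.outer_zone_width, beam.wavelength)
        if abs(f - self.focal_length) > rtol * f:
            raise GeometryConfigurationError(
                f"focal length {self.focal_length} inconsistent with "
                f"D*dr_n/lambda = {f} (rtol={rtol})"
            )


@dataclass(frozen=True)
class ImagingGeometry:
    """Complete cone-beam holography geometry (all lengths in metres).

    ``z01``: focus-to-sample (defocus) distance; ``z12``: sample-to-
    detector; ``z02 = z01 + z12``; ``magnification = z02/z01``;
    ``effective_pixel = detector_pixel / M``; ``z_eff = z01*z12/z02`` is
    the parallel-beam equivalent propagation distance (Fresnel scaling
    theorem) and ``fresnel_number = dx**2/(lambda*z_eff)`` the per-pixel
    Fresnel number of the hologram.
    """

    z01: float
    z12: float
    z02: float
    detector_pixel: float
    d_img: float
    magnification: float
    effective_pixel: float
    fov: float
    z_eff: float
    fresnel_number: float
    wavelength: float


def derive_geometry(
    z01: float,
    z12: float,
    detector_pixel: float,
    wavelength: float,
    d_img: float = 0.0,
    fov: float = 0.0,
) -> ImagingGeometry:
    """Fill in every derived geometry quantity from the free parameters.

    Raises :class:`GeometryConfigurationError` when the two magnified
    sub-images of the configured field of view would overlap on the
    detector (``d_img < fov * M``); ``d_img = 0`` or ``fov = 0`` skips
    the check (single-beam or unconstrained use).
    """
    _check_positive(z01=z01, z12=z12, detector_pixel=detector_pixel, wavelength=wavelength)
    z02 = z01 + z12
    magnification = z02 / z01
    effective_pixel = detector_pixel / magnification
    z_eff = z01 * z12 / z02
    fresnel_number = effective_pixel**2 / (wavelength * z_eff)
    if d_img > 0 and fov > 0 and d_img < fov * magnification:
        raise GeometryConfigurationError(
            f"sub-images overlap on the detector: d_img = {d_img * 1e3:.2f} mm "
            f"< FOV * M = {fov * magnification * 1e3:.2f} mm"
        )
    return ImagingGeometry(
        z01=z01,
        z12=z12,
        z02=z02,
        detector_pixel=detector_pixel,
        d_img=d_img,
        magnification=magnification,
        effective_pixel=effective_pixel,
        fov=fov,
        z_eff=z_eff,
        fresnel_number=fresnel_number,
        wavelength=wavelength,
    )


@dataclass(frozen=True)
class SamplingPlan:
    """Tomographic angular sampling for a dual-beam scan.

    ``n_proj`` is the Crowther minimum over 180 deg for ``n_pix``-wide
    sub-images, ``delta_theta = pi/n_proj`` the step, and ``alpha`` the
    fixed angle between the two simultaneously recorded beams.
    """

    n_pix: int
    n_proj: int
    delta_theta: float
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @classmethod
    def for_detector(cls, n_pix: int, alpha: float = 0.0) -> "SamplingPlan":
        n_proj = crowther_projections(n_pix)
        return cls(n_pix=n_pix, n_proj=n_proj, delta_theta=math.pi / n_proj, alpha=alpha)
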