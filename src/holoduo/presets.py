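"""Reference configurations of the dual-beam holotomography instrument.

Two parameter sets are shipped: the *design* configuration of the dual
zone-plate optics (target field of view 50 µm, effective pixel 197 nm)
and the *experiment* configuration actually aligned at the beamline
(shorter defocus, higher magnification, effective pixel 133 nm).  All
lengths in metres.
"""

from __future__ import annotations

from .optics import (
    BeamSpec,
    ImagingGeometry,
    ZonePlateDesign,
    derive_geometry,
)

__all__ = [
    "ENERGY_KEV",
    "DETECTOR_SHAPE",
    "DETECTOR_PIXEL",
    "DESIGN",
    "EXPERIMENT",
    "ZONE_PLATE",
    "reference_beam",
    "reference_zone_plate",
    "design_geometry",
    "experiment_geometry",
]

ENERGY_KEV = 11.0
DETECTOR_PIXEL = 55e-6
#: photon-counting detector: 12 chips of 256 x 256 px on a 2 x 6 grid; the
#: covered chip gaps are resolved into extra (interpolated) pixel rows/cols,
#: giving 516 x 1556 px = 28.38 mm x 85.57 mm.
DETECTOR_SHAPE = (516, 1556)

ZONE_PLATE = {
    "parent_diameter": 418e-6,
    "outer_zone_width": 61.4e-9,
    "center_separation": 62e-6,
    "gap": 162.3e-6,
    "central_stop_width": 100e-6,
}

DESIGN = {
    "z01": 71.66e-3,
    "z12": 19.928,
    "d_img": 17.3e-3,
    "fov": 50e-6,
}

EXPERIMENT = {
    "z01": 50.29e-3,
    "z12": 20.735,
    "d_img": 18.0e-3,
    "fov": 29.3e-6,  # 220 px of the detector actually used
}

#: measured angle between the two beams (rad); the design value differs
#: slightly (1.14 mrad)
ALPHA_MEASURED = 1.22e-3
ALPHA_DESIGN = 1.14e-3

#: typical dose: mean photon flux per pixel and exposure per projection
FLUX_PHOTONS_PER_PX_S = 500.0
EXPOSURE_S = 2.0

#: scan protocol: compound frames over 0-180 deg and empty-beam frames
N_ANGLES_FULL = 900
N_FLATS_FULL = 120


def reference_beam() -> BeamSpec:
    return BeamSpec.from_energy(ENERGY_KEV)


def reference_zone_plate() -> ZonePlateDesign:
    return ZonePlateDesign.from_beam(
        ZONE_PLATE["parent_diameter"],
        ZONE_PLATE["outer_zone_width"],
        reference_beam(),
        center_separation=ZONE_PLATE["center_separation"],
        gap=ZONE_PLATE["gap"],
        central_stop_width=ZONE_PLATE["central_stop_width"],
    )


def _geometry(params: dict) -> ImagingGeometry:
    return derive_geometry(
        z01=params["z01"],
        z12=params["z12"],
        detector_pixel=DETECTOR_PIXEL,
        wavelength=reference_beam().wavelength,
        d_img=params["d_img"],
        fov=params["fov"],
    )


def design_geometry() -> ImagingGeometry:
    """Geometry the dual zone plate was designed for (197 nm pixel)."""
    return _geometry(DESIGN)


def experiment_geometry() -> ImagingGeometry:
    """Geometry as aligned in the experiment (133 nm pixel)."""
    return _geometry(EXPERIMENT)
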