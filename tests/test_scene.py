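"""Synthetic scene generators: phantom geometry, projections, illumination."""

import numpy as np
import pytest

from holoduo.optics import wavelength_from_energy
from holoduo.scene import (
    CompoundFrame,
    make_hair_phantom,
    make_illumination,
    project_phase,
    render_compound_frame,
    sample_flat,
    sample_flat_counts,
    simulate_scan,
)

LAM = wavelength_from_energy(11.0)
VOX = 133e-9


def test_plain_cylinder_projection_matches_analytic_chord():
    """Axial ray through a plain shaft: phi = -(2 pi/lambda) * delta * chord."""
    ph = make_hair_phantom(
        64, VOX, hair_diameter=4e-6, n_elements=0, element_diameter=300e-9,
        delta_value=1e-6, seed=0, tilt=0.0,
    )
    pm = project_phase(ph, 0.0, LAM)
    # center column, away from the vertical caps
    center = pm.phi[32, 32]
    expected = -(2 * np.pi / LAM) * 1e-6 * 4e-6
    assert center == pytest.approx(expected, rel=0.05)
    assert np.all(pm.phi <= 0)


def test_empty_phantom_projects_to_zero():
    ph = make_hair_phantom(
        32, VOX, hair_diameter=2e-6, n_elements=0, element_diameter=300e-9,
        delta_value=0.0, seed=0,
    )
    pm = project_phase(ph, 0.7, LAM)
    assert np.all(pm.phi == 0.0)


def test_phantom_generation_is_deterministic():
    kwargs = dict(
        n_voxels=48, voxel_size=VOX, hair_diameter=3e-6, n_elements=10,
        element_diameter=300e-9, element_length=0.8e-6, delta_value=1e-6, seed=7,
    )
    a = make_hair_phantom(**kwargs)
    b = make_hair_phantom(**kwargs)
    assert np.array_equal(a.delta, b.delta)
    c = make_hair_phantom(**{**kwargs, "seed": 8})
    assert not np.array_equal(a.delta, c.delta)


def test_phantom_rejects_oversized_shaft():
    with pytest.raises(ValueError):
        make_hair_phantom(
            32, VOX, hair_diameter=8e-6, n_elements=0, element_diameter=300e-9,
            delta_value=1e-6, seed=0,
        )


def test_phantom_rejects_unresolvable_elements():
    with pytest.raises(ValueError):
        make_hair_phantom(
            64, VOX, hair_diameter=4e-6, n_elements=2, element_diameter=100e-9,
            delta_value=1e-6, seed=0,
        )


def test_projection_mass_is_conserved_across_angles():
    """Radon invariant: the summed projection is angle-independent."""
    ph = make_hair_phantom(
        48, VOX, hair_diameter=3e-6, n_elements=6, element_diameter=300e-9,
        element_length=0.8e-6, delta_value=1e-6, seed=3,
    )
    masses = [
        project_phase(ph, theta, LAM).phi.sum()
        for theta in np.linspace(0, np.pi, 8, endpoint=False)
    ]
    assert np.ptp(masses) <= 5e-3 * abs(np.mean(masses))


def test_zero_angle_projection_equals_direct_sum():
    ph = make_hair_phantom(
        48, VOX, hair_diameter=3e-6, n_elements=6, element_diameter=300e-9,
        element_length=0.8e-6, delta_value=1e-6, seed=3,
    )
    pm = project_phase(ph, 0.0, LAM)
    direct = -(2 * np.pi / LAM) * ph.delta.sum(axis=2) * VOX
    assert np.allclose(pm.phi, np.minimum(direct, 0.0))


def test_constant_illumination_limit():
    model = make_illumination(
        (48, 48), n_components=0, defect_density=0.0, seed=0, envelope=0.0
    )
    rng = np.random.default_rng(0)
    flat = sample_flat(model, rng)
    assert np.allclose(flat, 1.0)


def test_illumination_is_seed_reproducible():
    a = make_illumination((48, 48), seed=5)
    b = make_illumination((48, 48), seed=5)
    assert np.array_equal(a.mean_flat, b.mean_flat)
    assert np.array_equal(a.response, b.response)
    ra, rb = np.random.default_rng(2), np.random.default_rng(2)
    assert np.array_equal(sample_flat_counts(a, ra), sample_flat_counts(b, rb))


def test_flat_stack_has_configured_numerical_rank():
    """120 flats from a rank-5 drift model: singular values 6+ vanish."""
    model = make_illumination(
        (48, 48), n_components=5, defect_density=0.0, seed=1, envelope=0.1
    )
    rng = np.random.default_rng(0)
    stack = np.stack([sample_flat(model, rng) for _ in range(120)])
    centered = (stack - stack.mean(axis=0)).reshape(120, -1)
    s = np.linalg.svd(centered, compute_uv=False)
    assert s[5] < 1e-8 * s[0]
    assert s[4] > 1e-6 * s[0]


def test_poisson_noise_statistics():
    """Variance/mean of Poisson counts near 1 for a flat exposure."""
    model = make_illumination(
        (128, 128), n_components=0, defect_density=0.0, seed=0, envelope=0.0,
        flux=500.0, exposure=2.0,
    )
    counts = sample_flat_counts(model, np.random.default_rng(11))
    ratio = counts.var() / counts.mean()
    assert 0.9 <= ratio <= 1.1
    assert counts.mean() == pytest.approx(1000.0, rel=0.02)


def _small_geometry(d_img_px=80):
    from holoduo.optics import derive_geometry

    return derive_geometry(
        z01=50.29e-3,
        z12=20.735,
        detector_pixel=55e-6,
        wavelength=LAM,
        d_img=d_img_px * 55e-6,
    )


def test_compound_frame_layout_and_separation():
    geo = _small_geometry(80)
    ph = make_hair_phantom(
        32, geo.effective_pixel, hair_diameter=2e-6, n_elements=0,
        element_diameter=300e-9, delta_value=1e-6, seed=0,
    )
    pl = project_phase(ph, 0.0, LAM)
    pr = project_phase(ph, 1.22e-3, LAM)
    illum = make_illumination((64, 192), n_components=2, defect_density=0.0, seed=2)
    frame = render_compound_frame(pl, pr, geo, illum, seed=0)
    assert frame.d_img_px == 80
    ly0, ly1, lx0, lx1 = frame.left_window
    ry0, ry1, rx0, rx1 = frame.right_window
    assert lx1 <= rx0  # disjoint
    assert (rx0 + rx1) // 2 - (lx0 + lx1) // 2 == 80
    assert frame.counts.dtype.kind == "i" and frame.counts.min() >= 0


def test_paper_scale_image_separation_in_pixels():
    geo = _small_geometry()
    # 18 mm at 55 um pixels -> 327 px
    from holoduo.optics import derive_geometry

    geo18 = derive_geometry(
        z01=50.29e-3, z12=20.735, detector_pixel=55e-6, wavelength=LAM, d_img=18.0e-3
    )
    assert int(round(geo18.d_img / geo18.detector_pixel)) == 327


def test_compound_frame_rejects_overlapping_windows():
    geo = _small_geometry(20)  # separation smaller than the 32 px window
    ph = make_hair_phantom(
        32, geo.effective_pixel, hair_diameter=2e-6, n_elements=0,
        element_diameter=300e-9, delta_value=1e-6, seed=0,
    )
    pl = project_phase(ph, 0.0, LAM)
    illum = make_illumination((64, 192), n_components=0, defect_density=0.0, seed=2)
    with pytest.raises(ValueError):
        render_compound_frame(pl, pl, geo, illum, seed=0)


def test_simulate_scan_single_angle():
    geo = _small_geometry(80)
    ph = make_hair_phantom(
        32, geo.effective_pixel, hair_diameter=2e-6, n_elements=0,
        element_diameter=300e-9, delta_value=1e-6, seed=0,
    )
    illum = make_illumination((64, 192), n_components=2, defect_density=0.0, seed=2)
    scan = simulate_scan(ph, geo, illum, n_angles=1, alpha=1.22e-3, seed=0, n_flats=3)
    assert len(scan.frames) == 1
    assert len(scan.truth_left) == len(scan.truth_right) == 1
    assert len(scan.flats) == 3
    assert scan.angles[0] == 0.0


def test_simulate_scan_is_deterministic():
    geo = _small_geometry(80)
    ph = make_hair_phantom(
        32, geo.effective_pixel, hair_diameter=2e-6, n_elements=2,
        element_diameter=300e-9, element_length=0.5e-6, delta_value=1e-6, seed=0,
    )
    illum = make_illumination((64, 192), n_components=2, defect_density=1e-4, seed=2)
    a = simulate_scan(ph, geo, illum, n_angles=2, alpha=1.22e-3, seed=9, n_flats=2)
    b = simulate_scan(ph, geo, illum, n_angles=2, alpha=1.22e-3, seed=9, n_flats=2)
    for fa, fb in zip(a.frames, b.frames):
        assert np.array_equal(fa.counts, fb.counts)
    for xa, xb in zip(a.flats, b.flats):
        assert np.array_equal(xa, xb)
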