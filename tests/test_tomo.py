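"""Tomography: adjointness, FBP accuracy, alignment, fusion, ring metric."""

import numpy as np
import pytest
from scipy import ndimage

from holoduo.optics import wavelength_from_energy
from holoduo.scene import make_hair_phantom, project_phase
from holoduo.tomo import (
    ProjectionStack,
    TomoVolume,
    align_stack,
    fbp_reconstruct,
    forward_project_volume,
    fuse_stacks,
    radon_adjoint,
    radon_forward,
    ring_metric,
)

LAM = wavelength_from_energy(11.0)
VOX = 133e-9


def _phase_stack(phantom, angles, shifts=None, label="left"):
    phases = np.stack([project_phase(phantom, t, LAM).phi for t in angles])
    return ProjectionStack(
        phases=phases,
        angles=np.asarray(angles),
        pixel_size=phantom.voxel_size,
        wavelength=LAM,
        shifts=shifts,
        beam_label=label,
    )


def test_projector_backprojector_are_adjoint(rng):
    angles = rng.uniform(0, np.pi, 7)
    x = rng.standard_normal((64, 64))
    y = rng.standard_normal((64, 7))
    lhs = np.sum(radon_forward(x, angles) * y)
    rhs = np.sum(x * radon_adjoint(y, angles))
    assert abs(lhs - rhs) <= 1e-6 * abs(lhs)


def test_zero_sinogram_reconstructs_zero_volume():
    angles = np.linspace(0, np.pi, 32, endpoint=False)
    stack = ProjectionStack(
        phases=np.zeros((32, 4, 32)), angles=angles, pixel_size=VOX, wavelength=LAM
    )
    with pytest.warns(UserWarning):  # below Crowther minimum
        vol = fbp_reconstruct(stack)
    assert np.allclose(vol.delta_recon, 0.0)


def test_single_projection_is_rejected():
    stack = ProjectionStack(
        phases=np.zeros((1, 4, 32)), angles=np.array([0.0]), pixel_size=VOX,
        wavelength=LAM,
    )
    with pytest.raises(ValueError):
        fbp_reconstruct(stack)


def test_disc_phantom_radius_and_value():
    """Analytic disc sinogram: radius within 1 voxel, interior delta within 5%."""
    n, R, delta = 64, 14.0, 1e-6
    angles = np.linspace(0, np.pi, 120, endpoint=False)
    s = np.arange(n) - (n - 1) / 2
    chord = 2.0 * np.sqrt(np.clip(R**2 - s**2, 0.0, None))  # pixels
    phases = np.broadcast_to(
        -(2 * np.pi / LAM) * delta * chord * VOX, (len(angles), 1, n)
    ).copy()
    stack = ProjectionStack(
        phases=np.repeat(phases, 3, axis=1), angles=angles, pixel_size=VOX,
        wavelength=LAM,
    )
    vol = fbp_reconstruct(stack)
    slc = vol.delta_recon[1]
    yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2
    rr = np.hypot(yy, xx)
    interior = rr < R - 2
    assert slc[interior].mean() == pytest.approx(delta, rel=0.05)
    # measured radius from the half-maximum contour
    above = slc > delta / 2
    measured_r = np.sqrt(above.sum() / np.pi)
    assert abs(measured_r - R) <= 1.0


def test_hair_phantom_closure_through_fbp():
    """Project-then-reconstruct returns the interior delta to within 10%."""
    ph = make_hair_phantom(
        64, VOX, hair_diameter=3e-6, n_elements=6, element_diameter=300e-9,
        delta_value=1e-6, seed=1,
    )
    angles = np.arange(360) * np.pi / 360
    vol = fbp_reconstruct(_phase_stack(ph, angles))
    interior = ndimage.binary_erosion(ph.delta > 0, iterations=1)
    err = np.sqrt(np.mean((vol.delta_recon[interior] - ph.delta[interior]) ** 2))
    assert err / np.sqrt(np.mean(ph.delta[interior] ** 2)) <= 0.1


def test_fbp_matches_algebraic_oracle(rng):
    """FBP vs conjugate-gradient normal equations on the adjoint pair."""
    n = 64
    yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2
    truth = np.exp(-((yy - 6) ** 2 + (xx + 4) ** 2) / 40.0) + 0.5 * np.exp(
        -((yy + 8) ** 2 + xx**2) / 30.0
    )
    truth[np.hypot(yy, xx) > 22] = 0.0
    angles = np.linspace(0, np.pi, 100, endpoint=False)
    sino = radon_forward(truth, angles)

    # CG on R^T R x = R^T b
    b = radon_adjoint(sino, angles)
    x = np.zeros_like(truth)
    r = b.copy()
    p = r.copy()
    rs = np.sum(r * r)
    for _ in range(50):
        Ap = radon_adjoint(radon_forward(p, angles), angles)
        alpha = rs / np.sum(p * Ap)
        x += alpha * p
        r -= alpha * Ap
        rs_new = np.sum(r * r)
        p = r + (rs_new / rs) * p
        rs = rs_new

    phases = -(2 * np.pi / LAM) * sino.T[:, None, :] * VOX
    stack = ProjectionStack(
        phases=phases, angles=angles, pixel_size=VOX, wavelength=LAM
    )
    fbp = fbp_reconstruct(stack).delta_recon[0]
    circle = np.hypot(yy, xx) < 26
    diff = np.sqrt(np.mean((fbp[circle] - x[circle]) ** 2))
    assert diff / np.sqrt(np.mean(x[circle] ** 2)) <= 0.1


def test_forward_projection_consistency():
    """Volume reprojection reproduces the originating phase maps."""
    ph = make_hair_phantom(
        48, VOX, hair_diameter=3e-6, n_elements=0, element_diameter=300e-9,
        delta_value=1e-6, seed=0,
    )
    theta = 0.4
    pm = project_phase(ph, theta, LAM)
    reproj = forward_project_volume(ph.delta, theta)
    assert np.allclose(-(2 * np.pi / LAM) * reproj * VOX, pm.phi, atol=1e-8)


def test_alignment_of_unshifted_stack_is_identity():
    ph = make_hair_phantom(
        48, VOX, hair_diameter=3e-6, n_elements=4, element_diameter=300e-9,
        element_length=0.8e-6, delta_value=1e-6, seed=2,
    )
    angles = np.linspace(0, np.pi, 48, endpoint=False)
    with np.errstate(all="ignore"):
        aligned = align_stack(_phase_stack(ph, angles), n_rounds=1, upsample=10)
    assert np.max(np.abs(aligned.shifts)) <= 0.1


def test_alignment_recovers_known_shifts():
    """Seeded +-3 px jitter recovered to <= 0.5 px RMS in 3 rounds."""
    rng = np.random.default_rng(0)
    ph = make_hair_phantom(
        48, VOX, hair_diameter=3e-6, n_elements=4, element_diameter=300e-9,
        element_length=0.8e-6, delta_value=1e-6, seed=2,
    )
    angles = np.linspace(0, np.pi, 60, endpoint=False)
    clean = _phase_stack(ph, angles)
    true_shifts = rng.uniform(-3, 3, size=(len(angles), 2))
    jittered = np.stack(
        [
            ndimage.shift(p, s, order=1, mode="nearest")
            for p, s in zip(clean.phases, true_shifts)
        ]
    )
    stack = ProjectionStack(
        phases=jittered, angles=angles, pixel_size=VOX, wavelength=LAM
    )
    aligned = align_stack(stack, n_rounds=3, upsample=20)
    # a common offset of all projections is unobservable (object position)
    residual = aligned.shifts - true_shifts
    residual -= residual.mean(axis=0)
    rms = np.sqrt(np.mean(residual**2))
    assert rms <= 0.5
    errors = aligned.meta["reprojection_errors"]
    assert errors[-1] <= errors[0] + 1e-12


def test_fuse_identical_stacks_at_zero_alpha():
    ph = make_hair_phantom(
        48, VOX, hair_diameter=3e-6, n_elements=4, element_diameter=300e-9,
        element_length=0.8e-6, delta_value=1e-6, seed=2,
    )
    angles = np.linspace(0, np.pi, 60, endpoint=False)
    stack = _phase_stack(ph, angles)
    fused = fuse_stacks(stack, stack, alpha=0.0, register=False)
    assert len(fused.angles) == 2 * len(angles)
    v1 = fbp_reconstruct(stack).delta_recon
    v2 = fbp_reconstruct(fused).delta_recon
    assert np.max(np.abs(v1 - v2)) <= 1e-10 * max(np.max(np.abs(v1)), 1e-30)


def test_fused_angles_alternate_spacing():
    alpha = 1.22e-3
    angles = np.arange(10) * np.pi / 10
    phases = np.zeros((10, 2, 8))
    left = ProjectionStack(phases=phases, angles=angles, pixel_size=VOX, wavelength=LAM)
    right = ProjectionStack(
        phases=phases, angles=angles + alpha, pixel_size=VOX, wavelength=LAM,
        beam_label="right",
    )
    fused = fuse_stacks(left, right, alpha, register=False)
    spacing = np.diff(fused.angles)
    assert np.allclose(spacing[::2], alpha, rtol=1e-9)
    assert np.allclose(spacing[1::2], np.pi / 10 - alpha, rtol=1e-9)
    assert np.all(spacing > 0)


def test_fuse_rejects_mismatched_lengths():
    a = ProjectionStack(
        phases=np.zeros((4, 2, 8)), angles=np.arange(4.0), pixel_size=VOX,
        wavelength=LAM,
    )
    b = ProjectionStack(
        phases=np.zeros((5, 2, 8)), angles=np.arange(5.0), pixel_size=VOX,
        wavelength=LAM,
    )
    with pytest.raises(ValueError):
        fuse_stacks(a, b, 1e-3)


def test_ring_metric_detects_concentric_rings(rng):
    n = 128
    base = ndimage.gaussian_filter(rng.standard_normal((n, n)), 2.0)
    base -= base.mean()
    clean = ring_metric(base)
    yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2
    rr = np.hypot(yy, xx)
    rings = 0.05 * np.ptp(base) * np.sin(rr * 0.8)
    ringed = ring_metric(base + rings)
    assert clean <= 0.05
    assert ringed > 2 * clean


def test_ring_metric_is_rotation_invariant(rng):
    n = 65
    base = ndimage.gaussian_filter(rng.standard_normal((n, n)), 4.0)
    m0 = ring_metric(base)
    m90 = ring_metric(np.rot90(base))
    assert m90 == pytest.approx(m0, rel=0.05, abs=5e-3)


def test_dual_beam_fusion_reduces_ring_artifacts():
    """Distinct per-beam detector-column errors average down after fusion."""
    from holoduo.bench import ring_fusion_bench

    metrics = ring_fusion_bench(seed=7)
    assert metrics["fused"] <= min(metrics["left"], metrics["right"])


def test_central_slice_helper():
    vol = TomoVolume(delta_recon=np.arange(27.0).reshape(3, 3, 3), voxel_size=VOX)
    assert np.array_equal(vol.central_slice(), vol.delta_recon[1])
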