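"""Independent oracles shared by the propagation tests.

All three are derived without the FFT propagator under test: a
closed-form Gaussian-mixture solution of the Fresnel integral, a direct
1D Fresnel-integral quadrature for axis-invariant (cylinder) objects,
and the analytic weak-phase contrast-transfer-function prediction.
"""

import numpy as np
from scipy import ndimage

from holoduo.propagation import ComplexWavefield, fresnel_propagate


def gaussian_mixture_field(r2, wavelength, z, w, eps, n_terms=40):
    """Fresnel propagation of exp(i*eps*exp(-r^2/w^2)) in closed form."""

    def gauss_prop(wn):
        q = 1 + 1j * wavelength * z / (np.pi * wn**2)
        return (1 / q) * np.exp(-r2 / (wn**2 * q))

    out = np.ones(r2.shape, complex)
    term = 1.0
    for n in range(1, n_terms):
        term = term * (1j * eps) / n
        out = out + term * gauss_prop(w / np.sqrt(n))
        if abs(term) < 1e-18:
            break
    return out


def gaussian_oracle_rms(geo, n=256, w_px=10.0, eps=0.5):
    """RMS intensity error of the FFT propagator vs the closed form."""
    dx = geo.effective_pixel
    c = (n - 1) / 2
    x = (np.arange(n) - c) * dx
    X, Y = np.meshgrid(x, x, indexing="ij")
    r2 = X**2 + Y**2
    w = w_px * dx
    psi0 = np.exp(1j * eps * np.exp(-r2 / w**2))
    out = fresnel_propagate(ComplexWavefield(psi0, dx, geo.wavelength), geo.z_eff)
    truth = gaussian_mixture_field(r2, geo.wavelength, geo.z_eff, w, eps)
    crop = slice(n // 2 - 32, n // 2 + 32)
    diff = np.abs(out.values[crop, crop]) ** 2 - np.abs(truth[crop, crop]) ** 2
    return float(np.sqrt(np.mean(diff**2)))


def cylinder_quadrature_rms(geo, n=256, r_px=15.0, amplitude=0.35, sigma_px=2.0):
    """RMS intensity error vs direct 1D Fresnel quadrature (smooth cylinder)."""
    lam, dx, z = geo.wavelength, geo.effective_pixel, geo.z_eff
    c = (n - 1) / 2
    x = (np.arange(n) - c) * dx
    R, sig = r_px * dx, sigma_px * dx

    fine = np.linspace(-n / 2 * dx, n / 2 * dx, 2**17 + 1)
    chord = np.where(
        np.abs(fine) < R, -amplitude * np.sqrt(np.clip(1 - (fine / R) ** 2, 0, 1)), 0.0
    )
    df = fine[1] - fine[0]
    half = int(6 * sig / df)
    kernel = np.exp(-0.5 * ((np.arange(-half, half + 1) * df) / sig) ** 2)
    phi_fine = np.convolve(chord, kernel / kernel.sum(), mode="same")
    phi = np.interp(x, fine, phi_fine)

    psi = np.exp(1j * np.broadcast_to(phi[None, :], (n, n)))
    line = np.abs(fresnel_propagate(ComplexWavefield(psi, dx, lam), z).values[n // 2]) ** 2

    pert = np.exp(1j * phi_fine) - 1
    nz = np.abs(pert) > 1e-14
    fs, ps = fine[nz], pert[nz]
    k = np.pi / (lam * z)
    pref = np.sqrt(1 / (1j * lam * z))
    oracle = np.ones(n, complex)
    for i, xv in enumerate(x):
        oracle[i] += pref * np.trapezoid(ps * np.exp(1j * k * (xv - fs) ** 2), fs)
    crop = slice(n // 2 - 32, n // 2 + 32)
    diff = (line - np.abs(oracle) ** 2)[crop]
    return float(np.sqrt(np.mean(diff**2)))


def ctf_relative_error(geo, rng, n=128, eps=1e-3):
    """Relative error of (I-1)/eps against 2*sin(chi)*g_hat in Fourier space."""
    g = ndimage.gaussian_filter(rng.standard_normal((n, n)), 4.0)
    g -= g.mean()
    field = ComplexWavefield(np.exp(1j * eps * g), geo.effective_pixel, geo.wavelength)
    intensity = np.abs(fresnel_propagate(field, geo.z_eff).values) ** 2
    measured = np.fft.fft2((intensity - 1.0) / eps)
    f = np.fft.fftfreq(n, d=geo.effective_pixel)
    chi = np.pi * geo.wavelength * geo.z_eff * (f[:, None] ** 2 + f[None, :] ** 2)
    predicted = 2.0 * np.sin(chi) * np.fft.fft2(g)
    return float(np.linalg.norm(measured - predicted) / np.linalg.norm(predicted))
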