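"""Dynamic flat-field correction by principal component analysis.

The illumination of a zone-plate holography setup drifts from frame to
frame, so dividing by a static mean flat leaves residual structure.  The
dynamic scheme fits, per frame, the best flat in the affine span of a PCA
basis extracted from a series of empty-beam images: the mean flat plus a
linear combination of the leading principal components.  The coefficients
are solved by least squares on a region where the sample is absent
(default: a border ring), so the object does not bias the fit.

A compound dual-beam frame carries both sub-holograms; after correction
the two windows are cropped and blended toward the unit empty-beam level
with a Gaussian-fading mask so that the noisy border regions do not leak
into phase retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .propagation import HologramFrame
from .scene import CompoundFrame

__all__ = [
    "FlatFieldModel",
    "FadeMask",
    "fit_flatfield",
    "synthesize_flat",
    "correct_frame",
    "border_ring_mask",
    "make_fade_mask",
    "split_compound",
]


@dataclass
class FlatFieldModel:
    """Mean flat plus an orthonormal PCA basis of flat-field variation."""

    mean_flat: np.ndarray
    components: np.ndarray  # (k, ny, nx), orthonormal over pixels
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean_flat.shape


def fit_flatfield(flats: list[np.ndarray] | np.ndarray, n_components: int) -> FlatFieldModel:
    """PCA of an empty-beam series.

    Components are the top right-singular vectors of the mean-subtracted
    stack, ordered by singular value; they are orthonormal over pixels.
    ``n_components`` must be smaller than the number of flats.
    """
    stack = np.asarray(flats, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need at least 2 flat frames")
    n_flats, ny, nx = stack.shape
    if not (0 <= n_components < n_flats):
        raise ValueError(
            f"n_components must satisfy 0 <= k < n_flats ({n_components} vs {n_flats})"
        )
    mean_flat = stack.mean(axis=0)
    centered = (stack - mean_flat).reshape(n_flats, -1)
    # SVD of the (small) Gram side: n_flats << n_pixels
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # drop (numerically) zero-variance directions: their singular vectors
    # are arbitrary and would let the per-frame fit absorb sample signal
    tol = 1e-10 * max(float(np.linalg.norm(mean_flat)), 1.0)
    keep = min(n_components, int(np.sum(s > tol)))
    components = vt[:keep].reshape(keep, ny, nx)
    return FlatFieldModel(
        mean_flat=mean_flat,
        components=components,
        singular_values=s[:keep].copy(),
    )


def border_ring_mask(shape: tuple[int, int], fraction: float = 0.1) -> np.ndarray:
    """Boolean mask of a border ring of the given width fraction."""
    ny, nx = shape
    w = max(1, int(round(fraction * min(ny, nx))))
    mask = np.zeros(shape, dtype=bool)
    mask[:w, :] = mask[-w:, :] = True
    mask[:, :w] = mask[:, -w:] = True
    return mask


def synthesize_flat(
    frame: np.ndarray,
    model: FlatFieldModel,
    fit_region: np.ndarray | None = None,
) -> np.ndarray:
    """Best-fitting flat for ``frame`` in the span of the PCA model.

    Solves ``min_c || (frame - mean_flat) - sum_k c_k comp_k ||`` over the
    pixels of ``fit_region`` (default: whole frame) and returns
    ``mean_flat + sum_k c_k comp_k``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != model.shape:
        raise ValueError(f"frame shape {frame.shape} != model shape {model.shape}")
    if fit_region is None:
        fit_region = np.ones(model.shape, dtype=bool)
    fit_region = np.asarray(fit_region, dtype=bool)
    if not fit_region.any():
        raise ValueError("fit_region is empty")
    if model.n_components == 0:
        return model.mean_flat.copy()
    residual = (frame - model.mean_flat)[fit_region]
    basis = model.components.reshape(model.n_components, -1)[:, fit_region.ravel()].T
    coeffs, *_ = np.linalg.lstsq(basis, residual, rcond=None)
    return model.mean_flat + np.tensordot(coeffs, model.components, axes=1)


def correct_frame(
    frame: np.ndarray,
    model: FlatFieldModel,
    fit_region: np.ndarray | None = None,
) -> HologramFrame:
    """Divide a frame by its synthesised per-frame flat.

    Pixels where the synthesised flat is non-positive are set to the unit
    empty-beam level and reported in ``bad_pixel_mask``.
    """
    flat = synthesize_flat(frame, model, fit_region)
    bad = flat <= 0
    safe = np.where(bad, 1.0, flat)
    corrected = np.where(bad, 1.0, np.asarray(frame, float) / safe)
    return HologramFrame(
        intensity=corrected,
        pixel_size=float("nan"),
        bad_pixel_mask=bad if bad.any() else None,
    )


@dataclass
class FadeMask:
    """Gaussian-fading window weights: 1 on an interior plateau, smoothly
    decreasing toward 0 at the frame border."""

    weights: np.ndarray
    plateau_fraction: float
    sigma: float


def make_fade_mask(
    shape: tuple[int, int], plateau_fraction: float = 0.8, sigma: float = 10.0
) -> FadeMask:
    """Separable Gaussian-fade mask.

    Each axis gets a profile that is 1 over the central
    ``plateau_fraction`` of the axis and decays as a Gaussian of width
    ``sigma`` pixels outside it; the 2D weights are the outer product.
    ``sigma -> 0`` with a full plateau degenerates to a plain crop.
    """

    def profile(n: int) -> np.ndarray:
        half_plateau = plateau_fraction * n / 2.0
        d = np.abs(np.arange(n) - (n - 1) / 2.0) - half_plateau
        d = np.clip(d, 0.0, None)
        if sigma <= 0:
            return (d == 0).astype(float)
        return np.exp(-0.5 * (d / sigma) ** 2)

    weights = np.outer(profile(shape[0]), profile(shape[1]))
    return FadeMask(weights=weights, plateau_fraction=plateau_fraction, sigma=sigma)


def split_compound(
    frame: CompoundFrame | np.ndarray,
    left_window: tuple[int, int, int, int] | None = None,
    right_window: tuple[int, int, int, int] | None = None,
    plateau_fraction: float = 0.8,
    mask_sigma: float = 10.0,
    pixel_size: float = float("nan"),
    fresnel_number: float = float("nan"),
) -> tuple[HologramFrame, HologramFrame]:
    """Split a (corrected) compound frame into faded left/right holograms.

    Accepts either a :class:`~holoduo.scene.CompoundFrame` or a plain 2D
    array with explicit windows.  Each window is cropped and blended
    toward the empty-beam level: ``I' = w*I + (1 - w)*1`` with the
    Gaussian fade weights ``w`` (plateau pixels are returned untouched).
    """
    if isinstance(frame, CompoundFrame):
        data = frame.counts.astype(float)
        left_window = frame.left_window
        right_window = frame.right_window
    else:
        data = np.asarray(frame, dtype=float)
        if left_window is None or right_window is None:
            raise ValueError("windows must be given for a plain array")
    ly0, ly1, lx0, lx1 = left_window
    ry0, ry1, rx0, rx1 = right_window
    if not (lx1 <= rx0 or rx1 <= lx0):
        raise ValueError("sub-hologram windows overlap")
    out = []
    for y0, y1, x0, x1 in (left_window, right_window):
        crop = data[y0:y1, x0:x1]
        mask = make_fade_mask(crop.shape, plateau_fraction, mask_sigma)
        faded = mask.weights * crop + (1.0 - mask.weights)
        out.append(
            HologramFrame(
                intensity=faded, pixel_size=pixel_size, fresnel_number=fresnel_number
            )
        )
    return out[0], out[1]
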