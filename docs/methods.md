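# Methods

This note documents the models, numerical choices and limitations behind
`holoduo`. It is written for users who want to judge what the synthetic
benchmarks do and do not demonstrate about real dual-beam holotomography
data.

## Imaging model

The instrument is a divergent-beam (cone-beam) near-field holography
setup: a dual Fresnel zone plate focuses a monochromatic 11 keV beam
(λ = hc/E with hc = 12.3984 keV·Å) into two foci separated by
`d_FZP = 62 µm`; the beams cross in the sample plane a defocus distance
`z01` downstream of the foci and diverge to an image separation `d_img`
on the detector, `z12` further on. Two geometric identities fix the
design: `d_FZP = d_img·z01/z12` (similar triangles through the sample
plane) and `z01 = z02·Δx/px` (choice of effective pixel
`Δx = px/M`, `M = z02/z01`). All geometry functions are pure, operate in
metres, and are validated against the instrument's nominal design
(M = 280×, Δx = 197 nm) and experimental (M = 413×, Δx = 133 nm,
F = 3.1×10⁻³) configurations to a 5×10⁻³ relative tolerance that absorbs
the rounding of those nominal values. Two documented inconsistencies in
the reference parameter set are *not* resolved by the code: the design beam angle
(1.14 mrad) is not reproduced by any combination of the nominal values we tried
(`d_img/z12` gives 0.868 mrad; `beam_angle_at_detector` implements this
convention and is documented as such), and the design Fresnel number
4.9×10⁻³ is consistent with a 70.66 mm defocus while the nominal
design defocus is 71.66 mm; the tabulated distances are treated as
canonical.

By the Fresnel scaling theorem the cone-beam measurement equals a
parallel-beam hologram on the `Δx` grid at the effective distance
`z_eff = z01·z12/z02`; all wave optics run in this effective geometry.

## Propagator

Free-space propagation is the angular-spectrum/transfer-function method:
multiplication by `exp(−iπλz|f|²)` in Fourier space, with periodic
boundaries. The kernel is unimodular, so propagation is exactly unitary
and invertible. Fields are padded with the unit empty-beam value to a
power-of-two grid at least 25% larger before forming holograms, which
keeps wrap-around at the frame border. The alias-safety criterion
`z ≤ N·Δx²/λ` is exposed as `sampling_check`. The propagator is verified
against two independent oracles: a closed-form Gaussian-mixture solution
(a Gaussian-phase object expanded into analytically propagating
Gaussians; agreement ≤ 10⁻⁶ RMS in intensity) and a direct 1D
Fresnel-integral quadrature for axis-invariant smooth cylinders
(≤ 10⁻⁵ RMS), plus the weak-phase contrast-transfer-function limit
`Î(f) − δ(f) → 2 sin(πλz_eff|f|²)·φ̂(f)`.

## Synthetic scenes

The phantom emulates a spider attachment hair: a tilted cylindrical
shaft (default 4–8 µm diameter, δ = 10⁻⁶ inside the material) carrying
radial hairlets of 100–300 nm diameter, placed pseudo-randomly from a
seed; the support is kept strictly inside the grid (the shaft is capped
two voxels from the vertical borders). Projections are computed by
trilinear rotation of the volume about the vertical axis and summation
along the beam axis, `φ = −(2π/λ)∫δ dl ≤ 0`; the Radon mass invariant
holds to discretisation error. The beam-separation angle α is applied as
a rotation offset of the phantom, not as a tilted propagation axis — at
1.22 mrad the geometric difference across the field of view is
sub-voxel.

Illumination is modelled as `(mean + Σₖ aₖ·cₖ)·response`: a smooth mean
flat, `n_components` orthonormalised smooth random fields with
geometrically decaying coefficient scales (the low-rank drift a PCA of
empty-beam series recovers exactly), and a static response carrying dark
zone-plate-imperfection spots and detector chip-gap stripes (gain 1.5 at
multiples of the 256 px chip pitch). Photon counting is ideal Poisson at
`flux·exposure` photons per pixel (default 500 s⁻¹ × 2 s). Not modelled:
charge sharing, saturation, partial coherence of the source (the ~231 nm
focal spot), vibrations, and any beam structure finer than the low-rank
model — benchmarks passing on these scenes therefore demonstrate
algorithmic correctness, not robustness to every beamline nonideality.

Default desk-scale scans use 24–360 angles and 16–120 flats on reduced
detector areas; the full protocol (900 compound frames over 0–180°,
120 flats, full 516×1556 detector) is available behind the CLI `--full`
flag.

## Flat-field correction

The PCA model keeps the top right-singular vectors of the mean-subtracted
flat stack; numerically zero-variance directions are dropped so that a
degenerate (constant) stack reduces to mean division rather than fitting
sample signal into arbitrary basis vectors. Per-frame coefficients are
solved by least squares on a border ring (default 10% of the frame
width) where the sample is absent; full-frame fitting is available. The
corrected compound frame is split into the two sub-holograms and blended
toward the unit empty-beam level with a separable Gaussian fade (plateau
80% of the window, σ = 10 px); plateau pixels are bit-identical to the
crop.

## Phase retrieval

Single-distance retrieval is alternating projections between the object
constraints — unit modulus (zero absorption), phase clipped to
`[−∞, 0]`, zero outside the active support — and the detector-plane data
constraint, which replaces the propagated modulus by √I on the measured
window. The self-refining support thresholds |φ| at 0.03 rad, erodes
with the diameter-3 disc (to remove stray-pixel clusters) and dilates
with the diameter-10 disc; it activates at iteration 70 and is refreshed
every 5 iterations; the full schedule is 850 iterations. Structuring
elements are discrete discs `{(i,j): i²+j² ≤ (d/2)²}` — d = 3 yields the
full 3×3 square, d = 10 an 11×11 radius-5 disc — and the morphology is
verified against an exhaustive set-based oracle over all 2¹⁶ 4×4
patterns, so the element can be swapped and re-verified at will.

One numerical choice matters and is specific to this package: the
treatment of the *unmeasured padding region* at the detector plane.
Leaving it fully free is exactly consistent with fringes that spill past
the detector crop (best noiseless accuracy), but the weakly transferred
low-spatial-frequency modes of the single-distance problem — CTF
`sin(πλz f²) → 0` as `f → 0` — then absorb measurement noise almost
unchecked, and Poisson noise inflates the retrieved phase depth.
Clamping the padding to the empty-beam amplitude suppresses that but
biases the noiseless solution through the spill truncation. The default
`padding_prior = 0.05` relaxes the padding amplitude toward 1 at 5% per
iteration, balancing the two regimes; on the reference bench (ten seeded
hair phantoms embedded in 128² frames at F = 3.1×10⁻³) the retrieval
reaches NRMSE ≈ 0.043 of the true phase noiseless and ≈ 0.11 at 1000
photons/px. Setting `padding_prior = 0` or `1` recovers the two extremes.
The relaxation parameter mixes successive object-plane phases
(Krasnoselskii averaging) and defaults to 1 (plain error reduction);
whether the support refresh reads the masked or unmasked iterate is a
config switch (`refine_from_masked`, default unmasked).

The bench embeds 64³ phantoms centrally in 128² frames so the fringe
field is essentially contained in the detector window. When the object
fills the whole frame (as a real hair crossing the field of view does),
the measurement itself truncates the fringe field and the achievable
NRMSE floor rises to ≈ 0.13 for every solver variant we tried; the
desk-scale pipeline demo is in this regime, and its reported phase error
should be read accordingly.

## Tomography

The projector/backprojector pair is a bilinear gather (rotate-and-sum
sampling, identical to the phantom projection convention, rotation
center at the array center `(n−1)/2`) and its exact transpose
(adjointness ≤ 10⁻⁶ relative, in practice ~10⁻¹⁵). Filtered
back-projection uses the band-limited ramp filter in the Kak–Slaney
real-space construction with Shepp–Logan (ramp×sinc) apodisation and a
pixel-driven linear-interpolation backprojector sharing the same center;
it is contract-tested against an analytic disc (interior δ within 5%,
radius within 1 voxel) and a 50-iteration conjugate-gradient solution of
the normal equations (≤ 10% NRMSE). Reconstruction output is converted
to δ per voxel via `δ-line-integral = −φλ/(2π)`.

Reprojection alignment loops reconstruct → forward-project → register
each measured projection to its reprojection by sub-pixel
cross-correlation; shifts beyond 25% of the frame are clamped as
outliers. A common offset of all shifts is unobservable (it moves the
object, not the consistency), so shift-recovery accuracy is assessed
after removing the mean; seeded ±3 px jitter is recovered to ≤ 0.5 px
RMS in 3 rounds.

Dual-beam fusion merges the stacks at `θᵢ` and `θᵢ + α` (one global
cross-beam shift estimated on the closest-angle pair) into a sorted
2N-projection stack; exact angle ties (α = 0) are allowed and both
duplicates simply contribute. Because detector-fixed response errors
differ between the two beams, fusion averages them: the reconstruction
error variance from per-beam fixed sinogram offsets halves, verified
directly.

The ring metric polar-resamples the central slice about the rotation
axis and reports the variance over radius of the angular-mean profile
relative to the total variance — the fraction of slice variance
explained by purely radial (ring-like) structure, in [0, 1]. Two
properties of this metric constrain its use. It is a *purity ratio*:
when rings dominate both the radial profile and the total variance it is
invariant under averaging (two pure-ring fields average to another
pure-ring field), and when rings are much weaker than the object its
differences are cross-covariance noise. The seeded fusion bench
(`bench.ring_fusion_bench`) therefore sets the detector offsets so the
object dominates total variance while rings dominate the radial
profile — the regime where the averaging claim is resolvable — and the
inequality `fused ≤ min(left, right)` is a typical-case property of that
seeded bench (it held on 6 of 8 random seeds during design; the shipped
bench uses a mid-margin seed). It is *not* asserted for centered
cylindrical objects, whose own radial symmetry saturates the metric.

The convolutional-network denoising step that can follow dual-beam
acquisition is out of scope; `export_training_pairs` writes the aligned
left/right volumes to HDF5 in a documented layout so external tools can
train on them.

## Problem sizes

Default test/bench sizes are chosen for a single CPU: 128² holograms and
850-iteration retrieval (~4 s per phantom), 48³–128³ tomographic
benches, 24–64-angle pipeline demos. The same code paths accept
paper-scale inputs (900 angles, 516×1556 frames) unchanged.

## Determinism

Every stochastic generator takes an explicit seed and is bit-reproducible;
simulation archives rerun byte-identically (HDF5 timestamps disabled).
Phase retrieval is deterministic given the hologram and initial guess.
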