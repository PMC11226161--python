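# holoduo

Simulation and reconstruction for **dual-beam X-ray near-field
holotomography**: a nanotomography configuration in which a dual Fresnel
zone plate (dFZP) — two half zone plates with laterally offset centers —
splits the beam into two foci, so that every detector exposure records
*two* holographic projections of the sample, viewed from angles that
differ by the small beam-separation angle α (≈ 1.2 mrad).

The package is aimed at beamline scientists and method developers who
want to design such a setup, generate realistic synthetic scans, and run
the complete processing chain without beamtime:

1. **Optics/geometry design** — zone-plate focal length `f = D·Δr_n/λ`,
   the similar-triangle relations `d_FZP = d_img·z01/z12` (center
   separation of the two zone plates from the image separation on the
   detector) and `z01 = z02·Δx/px` (defocus distance for a target
   effective pixel), magnification `M = z02/z01`, effective propagation
   distance `z_eff = z01·z12/z02` (Fresnel scaling theorem), Fresnel
   number `F = Δx²/(λ·z_eff)`, and the Crowther sampling criterion
   `n_proj = π·D/d` (= `π·n_pix/2` at two-pixel resolution).
2. **Wave propagation** — a unitary angular-spectrum Fresnel propagator
   (`H(f) = exp(−iπλz|f|²)`) and the single-distance hologram forward
   model `I = |P(e^{iφ}, z_eff)|²` for pure phase objects.
3. **Synthetic scenes** — a spider-attachment-hair phantom (5–15 µm
   shaft with 100–300 nm hairlets, a standard weakly absorbing test
   object), a low-rank drifting flat field with zone-plate imperfection
   spots and detector chip-gap stripes, and Poisson counting noise at a
   configurable photon flux (default 500 photons px⁻¹ s⁻¹ × 2 s).
4. **Dynamic flat-field correction** — per-frame best-fit flat from a
   PCA basis of empty-beam images, then Gaussian-faded splitting of the
   compound frame into the two sub-holograms.
5. **Phase retrieval** — iterative alternating projections with the
   measured modulus as data constraint, phase restricted to `[−∞, 0]`,
   zero absorption, and a *self-refining support* (threshold 0.03 rad,
   erosion diameter 3 px, dilation diameter 10 px, active from iteration
   70, refreshed every 5; 850 iterations).
6. **Tomography** — iterative reprojection alignment, filtered
   back-projection with a Shepp–Logan filter, fusion of the two beams'
   stacks into a single tomogram (which averages down detector-fixed
   ring artifacts), and a quantitative ring-artifact metric.

## Worked example

The geometry calculators reproduce the instrument's nominal design and
as-aligned experimental parameters from first principles:

```sh
$ holoduo geometry report
Beam: 11 keV (lambda = 1.1271e-10 m)
Zone plate: D = 418 um, dr_n = 61.4 nm, f = 227.7 mm, d_FZP = 62 um

[design]
  magnification                279.091
  effective_pixel_nm           197.068
  fzp_center_separation_um     62.2099
  ...
[experiment]
  magnification                413.309
  effective_pixel_nm           133.072
  fresnel_number               0.00313165
  crowther_n_proj              346
  crowther_step_deg            0.520231
  ...
```

Reading: at the experimental defocus `z01 = 50.29 mm` the cone-beam
geometry magnifies 413×, giving a 133 nm effective pixel and a hologram
Fresnel number of 3.1×10⁻³; the 62 µm zone-plate center separation makes
the two beams overlap in the sample plane while their images sit 17.3 mm
apart on the detector; 220 used detector pixels need 346 projections
(0.52° steps) by the Crowther criterion, so the 900-frame dual-beam scan
(= 1800 projections) is fully sampled.

An end-to-end desk-scale simulation and reconstruction:

```sh
$ holoduo simulate  --config examples/demo.yaml --out scan.h5
$ holoduo reconstruct --config examples/demo.yaml --in scan.h5 --out recon.h5
```

writes an HDF5 archive with the retrieved phase stacks
(`/phases/{left,right}`), the three tomograms
(`/volumes/{left,right,fused}`) and a JSON report with per-projection
data residuals, ring metrics and (for synthetic scans) the phase error
against ground truth.  The retrieval self-check

```sh
$ holoduo bench --seed 1 --n-phantoms 2
noiseless retrieval NRMSE: [0.0407, 0.0414]
poisson(1000) retrieval NRMSE: [0.1108, 0.1139]
```

retrieves seeded hair phantoms at the experimental Fresnel number and
reports the phase error inside the true support: ≈ 4% of the phase
signal without noise, ≈ 11% at 1000 photons per pixel.

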