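# Desk-scale dual-beam holotomography demo.
# Experimental distances; reduced frame counts, detector area and
# retrieval schedule so the full chain runs in about a minute.
geometry:
  energy_keV: 11.0
  z01_mm: 50.29
  z12_mm: 20735.0
  px_um: 55.0
  d_img_mm: 4.4          # 80 px window separation on the reduced detector
  fzp:
    diameter_um: 418.0
    outer_zone_nm: 61.4
    gap_um: 162.3
    central_stop_um: 100.0

scan:
  n_angles: 24
  n_flats: 16
  alpha_mrad: 1.22
  seed: 1

phantom:
  n_voxels: 32
  hair_diameter_um: 2.0
  n_elements: 2
  element_diameter_nm: 300
  element_length_um: 0.5
  delta: 1.0e-6

detector:
  shape: [64, 192]

illumination:
  n_components: 5
  defect_density: 2.0e-4
  flux: 500.0
  exposure: 2.0

processing:
  pca_components: 5

retrieval:
  n_iterations: 200
  support_start_iter: 70
  support_refresh: 5

tomo:
  filter: shepp-logan
  align_rounds: 1
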