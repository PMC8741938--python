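# Demo cohort: two groups of 10 slides x 500 cells with an injected
# ellipticity-atypia (EP SD) effect in the LN-positive group.  Per-slide
# jitter of the aspect-ratio SD models inter-patient heterogeneity so the
# groups overlap and logistic effect sizes stay finite.
min_cells: 500
outcome: ln_status
dichotomize: true
variables: [sc_mean, sc_sd, sn_mean, sn_sd, ep_mean, ep_sd, ncr_mean, ncr_sd]
heatmap:
  scale_factor: 16
  sigma: 2.0
  blend_alpha: 0.5
froc:
  n_tumor_images: 3
  n_benign_images: 3
  sensitivity: 0.9
  fp_per_image: 3.0
groups:
  - name: ln_neg
    n_slides: 10
    cells_per_slide: 500
    image_shape: [2000, 2000]
    dist:
      cell_area_mean: 2000
      cell_area_sd: 400
      aspect_ratio_mean: 0.85
      aspect_ratio_sd: 0.060
      ncr_mean: 0.25
      ncr_sd: 0.05
      nucleus_eccentricity: 0.6
    slide_jitter:
      aspect_ratio_sd: 0.012
    covariates:
      site: colorectum
      lesion_type: primary
      ln_status: 0
      t_stage: 2
  - name: ln_pos
    n_slides: 10
    cells_per_slide: 500
    image_shape: [2000, 2000]
    dist:
      cell_area_mean: 2000
      cell_area_sd: 400
      aspect_ratio_mean: 0.85
      aspect_ratio_sd: 0.085
      ncr_mean: 0.25
      ncr_sd: 0.05
      nucleus_eccentricity: 0.6
    slide_jitter:
      aspect_ratio_sd: 0.012
    covariates:
      site: colorectum
      lesion_type: primary
      ln_status: 1
      t_stage: 3
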