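profile: high_quality
seed: 0
fou_width: 10.0
vessel:
  radius: 7
  scale_with_width: true
  threshold_rule: fixed
  fixed_threshold: 15.0
  prefilter_sigma: 1.0
  inpaint_iterations: 100
de:
  population: 30
  generations: 100
  F: 0.5
  CR: 0.9
localize:
  k: 2
  roi_fraction: 0.25
  min_component_frac: 0.0005
level_set:
  time_step: 1.0
  iterations: 300
  smoothing: 2
  sigma: 2.0
  balloon: 1.0
  tolerance: 0.001
  alpha: 100.0
  threshold: auto
cup:
  min_spot: 50
  area_floor: 3000.0
  scale_area_floor: true
  reference_width: 2376
  closing_radius: 3
  bridge_radius: 6
  enhance_percentiles:
  - 1.0
  - 99.0
  hough_radius_rel:
  - 0.15
  - 0.6
  de_population: 30
  de_generations: 100
  area_test_after_hough: false
evaluate:
  cdr_threshold: 0.075
  analyses:
  - hcdr
  - vcdr
  - final
  thresholds: {}
simulate:
  profile: small
  n_images: 20
  noise_sigma: 8.0
  n_vessels: 4
  grader:
    n_graders: 6
    area_jitter_cv: 0.05
    centroid_jitter_sd: 2.0
    cdr_jitter_sd: 0.03
    outlier_rate: 0.0
    outlier_scale: 10.0
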