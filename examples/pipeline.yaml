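# Two-condition ERP experiment: simulate, image, smooth, test.
stages:
  - stage: simulate
    out: dataset
    n_trials: {face: 12, scrambled: 12}
    n_channels: 32
    dt_ms: 4.0
    epoch_ms: [-100.0, 400.0]
    effects:
      - centers: [[0.3, 0.2], [-0.2, 0.25]]   # dipolar +/- pair on the layout
        center_signs: [1.0, -1.0]
        spread: 0.35
        amplitude: 2.5
        latency_ms: 170.0
        temporal_fwhm_ms: 60.0
        condition_weights: {face: 1.0, scrambled: 0.3}
    noise: {sd: 1.0, spatial_corr_length: 0.3, ar_coef: 0.3}
  - stage: convert
    dataset: dataset
    out: images
    n_pixels: 32
  - stage: smooth
    fwhm: [8.0, 8.0, 8.0]       # mm x mm x ms
  - stage: glm
    design: two-sample
    contrast: t
    alpha: 0.05
    out: results.tsv
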