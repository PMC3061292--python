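# topostat

Sensor-level statistical mapping for M/EEG: convert epoched multichannel
recordings into NIfTI summary-statistic images, fit mass-univariate
general linear models across subjects or trials, and control the
family-wise error rate over the whole sensor-time (or time-frequency)
search space with random field theory.

## Who this is for

Electrophysiologists who want topologically-corrected inference on
scalp data — "where and when does condition A differ from condition B?"
— without pre-selecting channels or windows, and methodologists who
need a self-contained, simulation-validated implementation of the
scalp-map → image → GLM → RFT pipeline with every stage testable
against synthetic ground truth.

## What it computes

**Images.** Each time frame of each trial is interpolated from the 2D
sensor layout onto a pixel grid (Delaunay triangulation + barycentric
linear interpolation, 64×64 pixels by default); stacking frames over
peristimulus time gives a 3D space × space × time image per trial (or
per condition for averaged data). Bad channels are either interpolated
over or removed, in which case the resulting holes (NaN) propagate
through smoothing and statistics. Planar gradiometer pairs combine as
√((g₁²+g₂²)/2). Morlet wavelet power (w(t,f) ∝ e^{i2πft}e^{−t²/2σ_t²},
σ_t = n_cycles/2πf) reduces to 2D time-frequency images (average over
channels) or band-average power waveforms (average over frequencies).

**GLM.** Voxelwise least squares Y = Xβ + ε with one-sample,
two-sample and paired designs; t = c'β̂ / √(σ̂² c'(X'X)⁻c) and the
equivalent F for multi-row contrasts.

**RFT correction.** The corrected peak p-value is the expected Euler
characteristic of the excursion set,

    P(max Z ≥ u) ≈ Σ_d R_d ρ_d(u),

with resel counts R_d estimated from the variance of first differences
of the standardized residuals (FWHM_j = √(4ln2/λ_j)) and EC densities
ρ_d for Gaussian, t and F fields. Reported p-values are
min(RFT, Bonferroni), so validity survives low smoothness. Cluster
extents get the standard Gaussian-field approximation
P(extent ≥ k) = exp(−βk^{2/D}). Gaussian-weighted time-window and
Morlet energy contrasts (evoked / induced / per-trial) summarize
time-frequency windows of interest; a single time point uses an 8 ms
FWHM Gaussian window.

Rigid coregistration (fiducial Procrustes fit with reflection guard,
plus three-phase iterative-closest-point refinement against a surface)
and icosphere generation (2562-vertex canonical head surfaces at
subdivision level 4) round out the toolkit.

## Worked example

Simulate a 32-channel, two-condition experiment (12 trials each) with a
dipolar ±
pattern peaking at 170 ms in the "face" condition, export per-trial
images, smooth by 8 mm × 8 mm × 8 ms, and test face vs scrambled:

```sh
topostat run --config examples/pipeline.yaml --workdir work --seed 42
head -3 work/results.tsv
```

prints (columns abridged):

```
peak_x   peak_y    peak_z  stat     p_peak_corrected  cluster_k  p_cluster_corrected  significant
51.1793  17.2111   164     6.51398  0.0486348         317        2.20373e-05          True
57.6296  -7.48853  164     6.41089  0.0587599         317        2.20373e-05          False
```

The most significant peak sits at 164 ms — the injected effect peaked
at 170 ms — with corrected peak p = 0.049 and a 317-voxel cluster at
cluster-level corrected p = 2.2 × 10⁻⁵: the effect survives whole-image
correction at α = 0.05 without any channel or window pre-selection.
`peak_x/peak_y` are in nominal layout mm (unit head disc ≙ 100 mm),
`peak_z` in peristimulus ms. The same stages are available as the
subcommands `simulate`, `convert`, `smooth`, `tf`, `contrast`, `glm`,
`coreg` and `report`, and as library functions.

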