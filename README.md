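# ptcmap

Vertex-wise population tuning-curve (pTC) mapping for 1-D sweep fMRI
paradigms: a Gaussian forward model of neural tuning, two-pass fitting with
participant-level double-gamma HRF estimation, empirical-null FDR
thresholding, map-level gradient/correlation statistics, and coverage
permutation tests — together with a synthetic-data generator that produces
BOLD cohorts with known ground truth for end-to-end validation.

## What it does

Two mapping paradigms are modelled on a shared normalized axis `u ∈ [0, 1]`
(`u = 0` = top of the mapped space):

- **spatial**: a horizontal bar (height 0.11, step 0.055 per 2 TRs) sweeping
  the vertical meridian (±5 d.v.a. around fixation);
- **face**: a sampling window (height 1/9, step 1/18) traversing a face
  from hairline to chin.

A canonical run is 202 volumes at TR = 1 s (10 dummies + six 32-s trials:
down, up, blank, up, down, blank). Per-vertex series are DCT band-passed
(drop the two lowest non-constant components, cut above 0.26 Hz), z-scored,
and averaged over runs. Fitting searches μ ∈ [−0.2, 1.2] step 0.005 and
σ = 2^x, x ∈ [−5.6, 1] step 0.05, maximizing the squared Pearson
correlation between the observed series and band-passed, HRF-convolved
model predictions; pass 1 uses a canonical HRF, the participant HRF is then
fitted on vertices with R² > 0.2, and pass 2 refits tuning under that HRF.
Downstream analyses include R² > 0.3 thresholding with an empirical-null
FDR upper bound, posterior–anterior axis projection with per-hemisphere
Fisher-z group t tests, a fixed-peak mixture-of-Gaussians alternative with
BIC comparison, split-condition permutation tests, and UVF/LVF coverage
curves with a label-shuffle permutation test.

## CLI

```bash
ptcmap demo --out results/demo --seed 0 --n-vertices 500   # full synthetic run
ptcmap simulate --out sim --n-vertices 200 --seed 1        # cohort TSVs
ptcmap fit --series sim/series_spatial.tsv --kind spatial --out fits.tsv
ptcmap null --out null_r2.tsv --n-series 5000              # empirical null
ptcmap analyze --pairs results/demo/vertex_pairs.tsv --out report.json
ptcmap coverage --pairs results/demo/vertex_pairs.tsv --out coverage.tsv
```

All interchange is TSV/JSON; GIFTI ingestion is available through
`ptcmap.io_cli.read_gifti_series` (requires nibabel).

## Layout

| module | contents |
| --- | --- |
| `ptcmap.stimulus_design` | run designs, aperture matrices, d.v.a. conversion |
| `ptcmap.preprocessing` | DCT band-pass, z-scoring, run averaging |
| `ptcmap.hrf_model` | double-gamma kernel, convolution, pooled HRF fit |
| `ptcmap.tuning_fit` | prediction grids, coarse/fine/two-pass fits, MoG, BIC |
| `ptcmap.fdr_threshold` | empirical-null FDR bound, R² thresholding |
| `ptcmap.map_analysis` | axis projection, map correlations, group t tests, split comparisons |
| `ptcmap.coverage_analysis` | coverage curves and label-shuffle permutation test |
| `ptcmap.synthetic_data` | ground-truth cohorts, BOLD simulation, null series, SNR calibration |
| `ptcmap.io_cli` | config, table I/O, pipeline driver, CLI |
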