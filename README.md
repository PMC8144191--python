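# azquant

Quantitative image analysis for protein phase-separation and synaptic
active-zone experiments: segmentation and fusion/fission dynamics of
liquid condensates, FRAP recovery kinetics, STED side-view synapse line
profiles, confocal synaptic ROI intensities, and the assumption-gated
statistics used to compare experimental groups. A synthetic-data module
generates images and traces with exact ground truth, so every measurement
stage is verifiable end to end without access to raw microscopy data.

The package is aimed at cell biologists and microscopists quantifying
liquid–liquid phase separation (spherical condensates > 1 µm that fuse and
exchange molecules with the cytosol) and presynaptic nanoscale
organisation (protein peaks measured along axes perpendicular to
active-zone markers in STED images).

## Core quantities

- **Condensates** — objects above an automatic threshold with equivalent
  diameter 2√(A/π) ≥ 1 µm; "droplet-positive" additionally requires
  sphericity (aspect ratio AR ≤ 1.5). Fusion is two droplets merging into
  a product that stays stable ≥ 30 s; after fusion the aspect ratio
  relaxes as **AR(t) = AR∞ + (AR₀ − AR∞)·exp(−t/τ)**, fitted by least
  squares.
- **FRAP** — traces normalised to one or two pre-bleach frames;
  per-bleach segments report the recovered fraction, the mobile fraction,
  and **t½ of maximum recovery** (first time the trace reaches halfway
  from the bleach floor to the segment maximum, interpolated between
  frames). A second bleach of the same structure recovers toward its own
  pre-bleach level — the mobile pool stays fully mobile.
- **STED side views** — a 1 µm × 250 nm profile perpendicular to the
  elongated active-zone/PSD marker at the vesicle-cloud edge, sampled at
  22.5 nm/px; after a five-pixel rolled average, the protein peak is the
  maximum within ±100 nm of the marker peak. Marker densities are
  segmented with a 0.04–0.4 µm² size filter; PMA effects are percent of
  the per-culture −PMA mean.
- **Confocal synapses** — 1.4 µm rolling-average background subtraction,
  puncta ROIs from the vesicle-marker channel, per-ROI protein means,
  per-culture control normalisation, and Pearson colocalization.
- **Statistics** — Shapiro/Levene gating into t-test/ANOVA or
  Mann–Whitney/Kruskal–Wallis, with Tukey–Kramer or Holm-corrected post
  hocs; all tests two-sided.

## Worked example

The numbered scripts under `analysis/` run each stage on simulated data
and write tables under `results/`. For the condensate movie:

```sh
python analysis/01_simulate_droplets.py
python analysis/02_condensate_dynamics.py
```

prints

```
Simulated 50 frames at 100.0 nm/px, 1 Hz.
Planted fusion at frame 6: AR relaxes from 2.00 toward 1.00 with tau = 7.41 s.
Condensates per frame: 2-3
Confirmed fusion at t = 6 s (product stable 43 s).
Relaxation fit: AR(t) = 1.00 + 0.98*exp(-t/7.54 s), rss = 0.0147
```

Two 1.4-µm droplets fuse at t = 6 s; the product passes the 30-s
stability rule and its aspect-ratio decay, measured from the segmented
ellipses of the noisy movie, returns the planted relaxation time (7.54 s
fitted vs 7.41 s planted) and asymptote. The remaining drivers follow the
same pattern — `03_frap_recovery.py` reports t½ of maximum recovery and
the near-complete second-bleach recovery, `04_sted_sideview.py` the peak
localization and the planted 130% PMA effect, `05_confocal_cohort.py` the
planted 0.65× knockout ratio, and `06_group_stats.py` the gated test
report:

```
first bleach: t_1/2 max recovery = 17.1 +/- 0.3 s, recovered fraction = 0.45 (n = 30 traces)
second bleach: t_1/2 max recovery = 17.3 +/- 0.2 s, recovered fraction = 1.04 (n = 30 traces)
Recovered normalized KO mean = 0.654 +/- 0.005 (n = 15 images, 3 cultures).
Selected test: t-test; omnibus p = 5.42e-27
```

## Library layout

| module | contents |
| --- | --- |
| `azquant.synth` | ground-truth generators: droplet movies, FRAP traces, side-view synapses, confocal punctum fields |
| `azquant.condensates` | segmentation, droplet-positive classification, tracking, fusion/fission confirmation, relaxation fit |
| `azquant.frap` | normalisation, bleach segmentation, recovery metrics, exponential cross-check |
| `azquant.sted` | side-view qualification, profile extraction, rolled-average smoothing, windowed peak measurement, density segmentation, PMA normalisation |
| `azquant.confocal` | background subtraction, ROI definition, ROI means, control normalisation, Pearson colocalization |
| `azquant.stats` | test selection, Holm adjustment, omnibus + post hoc reports, chi-square ratio test |
| `azquant.io` / `azquant.pipeline` | calibrated TIFF I/O, seeded end-to-end pipeline runner |
| `azquant.validation` | the closed-loop generator→analysis→truth studies |

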