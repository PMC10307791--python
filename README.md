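# condquant

Quantification pipeline for biomolecular-condensate microscopy. It packages,
as tested and reusable code, the measurements used to characterise
liquid–liquid phase separation (LLPS) of bacterial cell-division regulators
in vitro and in vivo:

- **Separation factor** — the percentage of total image fluorescence inside
  segmented condensates, `SF = 100 · Σ I(condensates) / Σ I(image)`, read
  from maximum-intensity projections of confocal z-stacks. It measures how
  much protein has partitioned into the dense phase.
- **Client enrichment** — partitioning of a client protein (e.g. the
  tubulin homolog FtsZ) into condensates formed by a scaffold protein:
  `E = ⟨I_client inside⟩ / ⟨I_client outside⟩`, corrected by subtracting the
  raw enrichment of a no-client bleedthrough control, measured on the
  best-focus slice (maximal intensity STDEV). A labeling-ratio helper
  quantifies how unequal degrees of dye labeling alone would inflate one
  client's enrichment over another's (19 vs 0.5 dyes/protein → 38-fold).
- **Coefficient of variation (CV)** — `σ/μ` of the image, a filament
  bundling/heterogeneity metric: concentrating fixed fluorescence into
  fewer, brighter structures raises the CV.
- **FRAP analysis** — double normalization (background-corrected bleached
  ROI over background-corrected whole-cell signal, which exactly cancels
  acquisition photobleaching), single-exponential recovery fitting
  `y = y₀ + A·e^(−x/t)` and `t½ = t·ln 2`.
- **Per-cell cluster accounting** — background-corrected cluster, cytoplasm
  and total intensities and *fluorescence concentrations* (intensity/area),
  the cluster-over-cytoplasm enrichment factor, cluster-axis vs cell-length
  scaling regressions, mother→daughter conservation across division
  (distinguishing cluster *fission* from *disintegration*), cluster
  counting, and constriction–cluster colocalization.
- **GTPase rates** — NADH-coupled assay: after subtracting a no-enzyme
  control, the A340 slope converts via Beer–Lambert
  (`rate = −slope/(ε·l)`, ε₃₄₀ = 6220 M⁻¹cm⁻¹, l = 0.248 cm) into the GTP
  hydrolysis rate (1:1 coupling).

Because raw microscopy data of this kind are rarely deposited, the package
ships a first-class synthetic-data module (`condquant.simulate`) that
generates every input class with known, exported ground truth — two-phase
condensate scenes (Gaussian PSF, Poisson + read noise, channel
bleedthrough), filament scenes with a tunable bundling parameter, FRAP
acquisitions with photobleaching, division time-lapses, snapshot cell
populations and plate-reader traces — so every estimator is validated
end-to-end against hidden truth.

Intended users: microscopists and biophysicists quantifying in vitro phase
separation assays and in vivo condensate behaviour, who want deterministic,
scriptable statistics instead of interactive image-analysis sessions.

## Worked example

```python
from condquant import image, simulate

# separation factor under realistic acquisition (PSF blur + camera noise)
cfg = simulate.SceneConfig(seed=42)          # 128x128 px, 207.6 nm/px
scene = simulate.generate_condensate_scene(cfg)
proj = image.max_intensity_projection(scene.scene, channel="scaffold")
labels = image.segment_condensates(proj)
bg = image.estimate_background(proj, labels > 0, min_pixels=10)
condensates = image.screen_condensates(labels, proj, bg)
sf = image.separation_factor(proj, condensates)
print(f"condensates retained: {condensates.n_objects}")
print(f"separation factor:    {sf.separation_factor:.1f}%")
```

prints

```
condensates retained: 7
separation factor:    25.7%  (ground truth 24.1%)
```

seven condensates survive the screening filters (≥ 9 px, mean intensity
≥ background + 3·STDEV) and 25.7% of the image fluorescence sits in the
dense phase, 1.6 percentage points from the generator's hidden truth —
the residual is the PSF halo counted into the masks. Enrichment of a
client partitioned 5:1 into the condensates, with a 10% bleedthrough
control (same scene, no client):

```
bleedthrough control raw enrichment: 1.82
client raw enrichment:               5.47
corrected enrichment:                3.65
within-condensate CV:                0.096
```

The corrected value matches the analytic expectation for these scene
parameters (3.64): raw enrichment mixes true partitioning with
bleedthrough, and the control subtraction removes the latter.

A CLI mirrors the library (`condquant simulate|quantify|frap|cellcycle|
gtpase|report`); every run writes a `manifest.json` with input hashes,
parameters, package version and seed, sufficient to reproduce it.

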