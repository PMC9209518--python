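# chromodyn

Quantitative image-analysis pipeline for studying the material state of
pericentromeric heterochromatin in mouse embryonic stem cells (ESCs).
Chromocenters — the DAPI-bright nuclear bodies formed by clustered major
satellite repeats (MSR) — behave like dynamic, liquid-like condensates:
they fuse, split, and exchange molecules on the timescale of seconds to
minutes, and noncoding MSR transcripts modulate those properties.
`chromodyn` implements the measurements by which that behaviour is
quantified, together with a synthetic-data generator that produces every
pipeline input with known ground truth, so each estimator can be validated
by parameter recovery.

The toolkit is for microscopists and computational biologists who need:

* **FRAP kinetics** (`chromodyn.frap`) — background/control-ROI correction,
  normalization to the pre-bleach level, one-phase association fitting
  `Y = Y0 + (Plateau − Y0)(1 − e^{−Kx})`, half-time `t½ = ln2/K`, mobile
  fraction `Fm = (Plateau − first post-bleach)/(pre-bleach − first
  post-bleach)`.
* **Chromocenter tracking** (`chromodyn.tracking`) — watershed spot
  detection, Hungarian frame-to-frame linking with gap closing, calling of
  coalescence (two tracks merge) and cleavage (a track branches) events,
  per-cell event-engagement fractions, and time-averaged MSD fits
  `MSD(τ) = 4 D_app τ^α` plus a directed-diffusion velocity fit.
* **Nuclear morphometry** (`chromodyn.structure`) — nucleus/chromocenter
  segmentation with one constant threshold per batch, mid-section area and
  major-axis measurements at each focus' optimal focal plane, pixelwise
  Pearson colocalization, linescans, quartile binning against a control.
* **RNA-FISH localization** (`chromodyn.rnafoci`) — focus detection and the
  overlap-rule classifier: *within* (>50% overlap with one chromocenter),
  *periphery* (<50% with exactly one), *between* (<50% with at least two).
* **Droplet assays** (`chromodyn.droplets`) — per-well droplet detection and
  the critical concentration: the minimum protein concentration of a
  dilution series at which droplets form.
* **FLIM** (`chromodyn.flim`) — two-level heterochromatin/euchromatin masks,
  Poisson maximum-likelihood monoexponential lifetime fitting of pooled
  TCSPC histograms (shorter SiR-DNA lifetime = more compact chromatin).
* **Synthetic data** (`chromodyn.synthgen`) — every input above, generated
  from named presets (`chromodyn.presets`) that encode the experimental
  conditions, with truth sidecars.

## Worked example

Generate 45 noisy FRAP traces per condition for an HP1α reporter, fit each,
and compare conditions:

```python
import numpy as np
from chromodyn import frap, presets, synthgen

fits, labels = [], []
for name in ("hp1a_ctrl", "hp1a_msr"):
    preset = presets.frap_preset(name)
    for seed in range(1, 46):
        trace, _ = synthgen.make_frap_trace(preset, seed, noise_sd=0.02)
        fits.append(frap.analyze_trace(trace))
        labels.append(name)

summary = frap.summarize_condition(fits, labels)
print(summary[summary.quantity == "t_half_s"]
      [["condition", "n", "median", "sem", "p_mannwhitney"]])
```

```
   condition   n     median       sem  p_mannwhitney
0  hp1a_ctrl  45   8.017949  0.086240   3.852547e-26
1   hp1a_msr  45  12.912440  0.200093   3.852547e-26
```

The control condition recovers half its fluorescence in ~8 s versus ~13 s
after MSR-transcript depletion, and the rank test on the 45-vs-45 half-time
samples is decisive — depleting the RNA makes chromocenter-bound HP1α
markedly less mobile.

The same pattern holds for the other assays, e.g. tracking
(`synthgen.make_timelapse` → `tracking.link_tracks` →
`tracking.event_engagement`) yields a median of ~45% of chromocenters
engaging in fusion/fission events per 20-minute movie under control
conditions versus ~25% after depletion.

A thin CLI mirrors the library (`chromodyn synth frap|timelapse|nuclei|
plate|flim`, `chromodyn frap fit`, `chromodyn track`, `chromodyn struct`,
`chromodyn rnafoci`, `chromodyn droplets`, `chromodyn flim`).

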