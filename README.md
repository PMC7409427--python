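# octachoroid

Analysis pipeline for visualizing **deep choroidal vasculature** with
swept-source OCT angiography (SS-OCTA) and measuring **choroidal vascular
density (CVD)**, exercised entirely on synthetic choroid phantoms with known
ground truth.

Beneath the choriocapillaris, choroidal vessels appear in OCTA decorrelation
images as *dark* stripes on bright stroma (fringe washout, attenuation and
threshold masking render fast-flow lumens signal-free), mirroring the dark
vessel lumens of en-face structural OCT. This package implements the full
measurement chain built on that observation:

- **Slab geometry** — single-pixel en-face slabs referenced to Bruch
  membrane (BM), quantized to the device's 2.6 µm axial grid. Nominal depths
  50, 100, …, 550 µm map to actual depths 49.4, 98.8, …, 551.2 µm; a
  percentile series samples 12.5–87.5 % of the subfoveal choroidal thickness
  (SCT).
- **Binarization** — Otsu's method from the 256-bin histogram (threshold
  minimizes intra-class variance; black = intensity ≤ threshold = vessel
  lumen).
- **Comparison** — similarity between binarized OCTA and en-face OCT images
  (`100 · matched pixels / total pixels`), four-colour comparison maps
  (white/black/green/red), an automated vessel-display rule, per-depth
  profiles and optimal-depth selection.
- **Quantification** — CVD = percentage of black pixels in the binarized
  OCTA slab, measured by default at 98.8 µm beneath BM.
- **QC** — exclusion of eyes with image score < 50, named artefacts
  (banding, blink, vessel doubling, stretching, out of window, crisscross)
  or ≥ 2 wide motion artefacts.
- **Statistics** — Lilliefors normality screen, Pearson correlation, OLS of
  CVD on age, axial length and SCT (slope reported per 100 µm of SCT),
  two-group ANOVA (raw or from published summary statistics), SCT-adjusted
  ANCOVA, demographic control matching.
- **Phantoms** — synthetic eyes with straight-tube vessels, a granular
  choriocapillaris band, exponential depth attenuation and Gaussian noise,
  whose per-slab lumen fraction is controlled to a configured target; plus a
  cohort generator with realistic SCT distributions (healthy ≈ 333 ± 94 µm,
  CSC ≈ 547 ± 118 µm), a CVD–SCT slope and a group effect for central serous
  chorioretinopathy (CSC) eyes.

## Worked example

```python
import numpy as np
from octachoroid import (PhantomConfig, generate_slab_pair, measure_cvd,
                         binarize, similarity, quantize_depth)

# one synthetic eye: SCT 350 um, 56.5% target lumen fraction at ~100 um
depth = quantize_depth(100, 2.6)                     # -> 98.8 um on the grid
cfg = PhantomConfig(sct=350, lumen_fraction_by_depth={depth: 0.565}, seed=42)
octa, enface_oct = generate_slab_pair(cfg, depth)

res = measure_cvd(octa, depth=depth, eye_id="demo")
sim = similarity(binarize(octa), binarize(enface_oct))
print(f"slab depth: {depth} um beneath BM")
print(f"Otsu threshold: {res.threshold_used}")
print(f"CVD: {res.cvd:.1f}% (target 56.5%)")
print(f"OCTA vs en-face OCT similarity: {sim:.1f}%")
```

prints

```
slab depth: 98.8 um beneath BM
Otsu threshold: 54
CVD: 56.3% (target 56.5%)
OCTA vs en-face OCT similarity: 100.0%
```

The measured CVD recovers the configured lumen fraction to a few tenths of
a percentage point: the Otsu threshold (54) falls between the attenuated
lumen and stroma grey levels, so the binarized mask reproduces the phantom's
vessel ground truth. At this depth the OCTA and en-face OCT modalities carry
the same anatomy with independent noise, hence the near-perfect similarity;
in the granular choriocapillaris band and beyond ~3 attenuation lengths the
similarity collapses toward 50 % and the display rule rejects the slab.

A full synthetic-cohort run (phantoms → QC → both depth series → profiles →
CVD → statistics) is available from the command line:

```bash
octachoroid run --config examples/cohort.yaml --out-dir out/
```

which writes the roster, exclusion log, per-depth profile tables, CVD table,
comparison maps and a statistics report (`report.json`), all deterministic
given the seed.

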