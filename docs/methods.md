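# Methods

## Model and coordinate conventions

All depths are micrometres beneath Bruch membrane (BM), positive downward,
0 = BM. The device grid samples the axial direction every 2.6 µm; a
*single-pixel slab* at depth *d* is the one voxel per A-scan at exactly
BM + *d* (no axial averaging). Nominal depths are snapped to the nearest
grid multiple, ties rounding to the deeper slab; the 50–550 µm fixed series
therefore lands at 49.4, 98.8, 150.8, 200.2, 249.6, 299.0, 351.0, 400.4,
449.8, 499.2 and 551.2 µm. "Nearest" was chosen for the percentile series
too ("as close as possible" admits no other reading consistent with the
fixed series). The en-face grid is 300 × 300 pixels over a 3.0 × 3.0 mm
macular field (10 µm/pixel), configurable for fast tests.

An eye contributes to a per-depth aggregate only while the slab is still
choroid: eligibility is `actual_depth ≤ SCT`. This rule is an inference —
per-depth cohort sizes must shrink as slabs pass the chorioscleral
interface — and is the only defensible automated choice.

## Binarization

Otsu's threshold is computed from the 256-bin histogram by maximizing the
between-class variance over every split t ∈ 0…254, black = intensity ≤ t.
Conventions pinned by tests because they change results on synthetic
two-level images: the *smallest* threshold wins ties (on a clean bimodal
image every threshold in the inter-mode gap ties, so the threshold reported
is the upper edge of the dark mode); constant images are degenerate and
produce an all-white mask; non-8-bit inputs are linearly rescaled to 0–255
first. The implementation is checked against exhaustive intra-class-variance
minimization (always equal) and against scikit-image's Otsu (within the
boundary bin on tie-free images).

## Vessel-display rule

Whether an OCTA slab "displays choroidal vessels" is, in clinical practice,
a judgement made by human image readers. Reproducibility requires an
operational definition, so
the package uses an explicit three-criterion rule on the binarized pair:

1. OCTA black fraction within 10–90 % (rejects empty and saturated slabs);
2. OCTA-vs-en-face-OCT similarity ≥ 70 % (rejects noise-dominated slabs,
   where independently noisy modalities agree on ≈ 50 % of pixels);
3. median 8-connected black-component area ≥ 20 px at 300 × 300 scale
   (scaled by image area; rejects choriocapillaris granularity and noise
   speckle, accepts stripes).

All three cutoffs are configuration (`DisplayCriteria`). Defaults were set
so that, on phantoms, the granular band fails, mid-depth stripe slabs pass,
and slabs beyond ≈ 3 attenuation lengths fail. The optimal depth maximizes
(display fraction, mean similarity) lexicographically, ties to the shallower
depth. Per-depth summaries use the sample SD (n − 1), undefined for
single-eye rows.

## Phantom generator

The phantom reproduces the features the measurement chain depends on, and
nothing else:

- **Vessels** are straight tubes with random in-plane orientation; no
  branching or curvature. Only the per-slab lumen fraction and stripe-like
  morphology matter downstream. Tube diameters interpolate from a shallow
  range (30–60 µm, medium Sattler-type vessels) to a deep range (60–120 µm,
  large Haller-type vessels). Seed points use minimum-spacing (Poisson-disk
  style) rejection so tubes do not pile up.
- **Lumen-fraction control.** Tubes are added greedily, each centred near
  the keyed depth with the largest remaining target deficit, until every
  keyed slab is within 0.005 of its target; the final gap is closed with
  minimum-diameter tubes, so realized fractions sit well inside the ±0.05
  contract (empirically within ±0.5 points at 300²).
- **Signal model.** Lumen voxels are dark (grey 30) and stroma bright
  (200) in both modalities before attenuation; the top 10 µm of the OCTA
  volume is a high-frequency granular bright band (the choriocapillaris
  decorrelation pattern); intensities decay as
  `floor + (value − floor)·exp(−z/L)` with attenuation length L = 100 µm
  and floor 20; voxels deeper than the SCT hold floor signal only; i.i.d.
  Gaussian noise (SD 8 grey levels) is added independently per modality and
  clipped to 0–255. With these defaults the stripe contrast crosses the
  noise floor at ≈ 2.5–3 L, which is what makes the display rule's depth
  profile rise and fall. Speckle, optical PSF (the ~8 µm optical axial
  resolution is not modelled; 2.6 µm is the sampling step), curvature,
  projection artefacts and shadowing are deliberately absent — so passing
  tests certify the measurement chain, not the device physics.
- **BM flattening.** Phantoms are generated pre-flattened
  (`bm_depth_map = 0`); a linear `bm_tilt` option shifts anatomy down a
  per-pixel number of pages to exercise the BM-referenced extraction.
- The fast path `generate_slab_pair` renders a single en-face plane from
  the *same* tube set (and random stream) as the full-volume path; the two
  paths produce identical lumen masks, which is tested.

## Cohort generator

Per-eye metadata mirror a screening cohort: healthy SCT ~ N(333, 94²) µm
truncated above 150, CSC SCT ~ N(547, 118²) truncated above 200; ages, sexes
and axial lengths from matching marginals. The generator-side CVD model at
the measurement depth (98.8 µm) is

    CVD% = 56.5 + 3.9·(SCT − 333)/100 + 8.2·[CSC] + ε,  ε ~ N(0, 8²),

clamped to [5, 95] and stored as the eye's target lumen fraction. Baseline,
slope, effect and noise are arguments; the defaults are the study
conditions. `match_sct=True` draws CSC SCT from the healthy distribution,
giving an SCT-matched case-control design in which the group effect is an
*adjusted* effect by construction — this is the scenario used for the
ANCOVA power study, because with the shifted CSC SCT distribution the
group–covariate collinearity (VIF ≈ 2) makes the adjusted effect only
partially identifiable at n = 22 + 22 (power ≈ 0.64 rather than ≈ 0.9).
The type-I calibration keeps the confounded design, where the ANCOVA's job
is precisely to remove the SCT-driven difference; its rejection rate is
0.049 over 1000 replicates.

A configurable fraction of eyes receives an artefact flag, a sub-50 image
score, or a wide-motion-artefact count, to exercise the QC stage, whose
rules are: exclude iff score < 50, or any named artefact, or ≥ 2 wide motion
artefacts; one reason logged per eye in that priority order.

## Statistics

- Pearson correlation and the two-group F test come from scipy; the
  summary-statistics ANOVA reconstructs between/within sums of squares
  exactly (for two groups) and is tested to agree with the raw-data ANOVA
  to 10 significant figures and with F = t².
- The CVD regression is OLS on age, axial length and SCT; only the SCT
  coefficient (and its CI) is rescaled to per-100-µm units. A constant
  response short-circuits to zero slopes with p = 1.
- ANCOVA assumes a common slope (`cvd ~ group + sct`); the group effect is
  the extra-sum-of-squares F test against `cvd ~ sct`; adjusted means are
  evaluated at the grand-mean SCT. A group × SCT interaction is screened
  and reported as a warning only.
- Normality screening is the Lilliefors variant of Kolmogorov–Smirnov
  (reference Normal with estimated mean/SD, statsmodels' table p-values);
  it is advisory and gates nothing.
- Control matching is greedy nearest-neighbour, exact on sex, distance
  |Δage|/12.3 + |ΔAL|/1.18 (cohort-scale SDs), without replacement. The
  two-eyes-per-subject correlation present in real cohorts is ignored
  (eyes treated as independent), replicating common practice; a
  mixed-effects treatment is out of scope.

## Problem sizes and determinism

Every stochastic component takes a seed and is bit-reproducible. The test
and acceptance suites use: 300 × 300 grids for the 20-eye CVD-recovery
study; 96–128 px grids for depth sweeps (4 eyes × ~180 depths) and for the
replicated regression study (100 cohorts × 91 eyes through the
slab-render + Otsu path); 200 replicates for the ANCOVA calibration and
power studies (generator-side CVD — those suites test the statistical
layer, not the imaging). Monte-Carlo acceptance bands are ±3 binomial SEs
around the nominal rate.

## Known limitations

- The phantom's optimal depth lands just below the granular band (~20–30
  µm) rather than at 100 µm: with a 10 µm granular band and monotone
  attenuation, the shallowest stripe slab is the cleanest. Real choroids
  put unresolvable capillary signal well below 10 µm and the inner-vessel
  anatomy differs; the pipeline's selection logic is validated against a
  brute-force sweep, not against the anatomical depth. (When vessels are
  keyed only near 100 µm — the cohort default — the profile does peak at
  100 µm.)
- Binary rasterization has no partial-volume edge effects, so Otsu recovery
  of the lumen fraction is a few tenths of a point accurate — tighter than
  real scans would allow.
- Artefact flags are metadata inputs, as they are assigned by human image
  readers in practice; no artefact detection from pixels is attempted.
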