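# Methods

## Scope and model

The package turns two kinds of raw recordings into phenotypes:

1. **Backlit well-plate images** of larvae (one per well of a 30-well plate)
   → calibrated surface areas with technical-replicate CV%.
2. **Per-vial video of adult flies** in a rack submerged in a water bath →
   endpoint traits of three thermal assays: chill-coma recovery
   (static low: coma induction at 0 °C for 2 h, then recovery at a benign
   temperature), heat knockdown (static high, e.g. 46.5 °C), and critical
   thermal maximum (dynamic ramp, 0.2 °C min⁻¹).

Both pipelines assume a *static scene with a single dark subject per
arena on a bright, stable backlight*: segmentation is absolute-difference
thresholding against an empty-arena reference image, and a subject is the
largest connected component (8-connectivity) whose centroid lies in the
arena. No pose, identity, or multi-animal reasoning is attempted.

## Size estimation

* Area = foreground pixel count / (px/mm)². The conversion is exactly
  quadratic in the calibration scale, and estimates are invariant to
  translation/rotation of the larva inside its well (checked to ≤ 2%,
  the rasterisation jitter of an ellipse at the default scale).
* The difference threshold is taken from config; the automatic default is
  Otsu's threshold on the difference image, chosen because it is
  deterministic and parameter-free. A constant difference image (frame ==
  reference) short-circuits to an empty mask.
* Frames in which a larva goes undetected are **dropped** from that larva's
  acquisition mean, not treated as zero area — a zero would bias the mean
  downward; the count of used frames is reported instead.
* CV% uses the sample standard deviation (n−1), the usual convention at
  n = 3 technical replicates.

## Tracking and signals

* Body-centre distance steps are Euclidean distances in mm/10 (cm). Across a
  detection gap the step is **zero, never interpolated**: interpolation would
  fabricate movement near coma, exactly where the traits are read. Gap counts
  are reported.
* The activity signal is the fraction of arena pixels whose intensity changed
  by more than a per-pixel threshold between consecutive frames. Commercial
  trackers expose a proprietary activity channel; any monotone motion-energy
  proxy has the same first/last non-zero semantics, which is all that trait
  extraction uses.
* Zone: *upper* iff the centroid is strictly above the vial's middle line in
  image coordinates; a centroid exactly on the line counts as lower, so a
  "cross" requires strictly entering the upper half.
* Timestamps are frame_index / frame_rate (0-based).

## Binning and noise filtering

* Distance and activity are summed into half-open bins [k·w, (k+1)·w),
  w = 15 s, anchored at the recording start; a final partial bin is kept and
  flagged. Pre-filter bin sums conserve raw totals exactly up to float
  summation order (tested at 1e-9 relative).
* The background-noise profile is the **maximum** binned distance and
  activity over all individuals in an analyst-declared quiescent window of a
  static high-temperature recording (after all real activity has ceased).
  As a guard against a mis-declared window, the window's mean activity must
  not exceed a ceiling (default: the mean activity of the whole recording).
* The filter subtracts the profile maxima from every bin of every assay and
  clips at zero. Zone flags are untouched — the filter corrects motion
  signals, not positions. A zero profile is the identity; the filter is
  monotone (larger maxima ⇒ pointwise smaller output) and never increases
  total distance.
* Filtering operates on the binned values (the quantities analysed
  downstream); a raw-sample path would change what "maximum noise" means and
  is not provided.
* One profile per assay batch is the default; per-camera-side profiles can be
  had by calling `quantify_noise` on subsets.

## Trait extraction

* Trait timestamps are the **bin start** — deterministic and conservative
  (never later than the event).
* Exclusions (never moved / never crossed) are in-band records with a reason
  code, not dropped rows, so exclusion counts per treatment are reproducible.
* Truncation: if the recording ends at a cutoff before the true assay end,
  last movement is non-evaluable for everyone (movement could always recur
  later), while last middle cross is kept for individuals whose event
  precedes the cutoff and marked non-evaluable for the rest.
* Manual annotations are ingested as given and never recomputed: a human
  observer scores appendage movements and whole-body crosses that a centroid
  signal cannot replicate. The package compares the two channels; it does not
  emulate the observer.

## Temperature mapping

* The ramp model is OLS of logger temperature on time, optionally windowed to
  the assay span. r² for a constant-temperature trace is defined as 0 (with a
  warning) to avoid 0/0. Extrapolation beyond the last reading is permitted
  and logged, since knockdown can postdate the final reading.

## Statistics

* Parametric-assumption screening replaces visual inspection with
  deterministic surrogates: QQ correlation ≥ 0.975 per variable for
  normality, the IQR criterion (outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]) for
  extreme outliers, a Breusch–Pagan test (p > 0.05) for homoscedasticity and
  a quadratic lack-of-fit term (p > 0.05) for linearity. Routing
  (Pearson vs Spearman) is a pure function of these flags; both coefficients
  are always reported. Quartiles use linear interpolation between order
  statistics — the convention is pinned because outlier sets depend on it.
* Wilcoxon signed-rank: zero differences are dropped (count reported), tied
  absolute differences get averaged ranks; the null is the exact
  sign-assignment distribution (dynamic programming over doubled ranks,
  equivalent to full 2ⁿ enumeration) for n ≤ 25 and a tie-corrected normal
  approximation with continuity correction beyond.
* Two-way ANOVA (treatment × method, interaction) uses Type II sums of
  squares by default for the unbalanced designs that exclusions create; the
  type is configurable and recorded in every table. Empty design cells raise
  an error naming the cell. Trait times and distances are ln(x+1)-transformed
  upstream to handle zeros.

## Synthetic fixtures

The generator defines the desk-scale study conditions:

* **Cohorts**: 60 flies per assay (3 acclimation treatments × 20), the
  design of the emulated protocol. Acclimation shifts schedule means —
  chill-coma recovery at 600/900/1800 s, heat knockdown at 500/700/1000 s,
  ramp knockdown at 43.5/44.5/45.5 °C (sd 120 s / 100 s / 0.4 °C) — so
  treatment effects exist for the ANOVA stages to find. A fixed number of
  agents per treatment is scheduled never to move or never to cross,
  providing known exclusions.
* **Trajectories** are generated at sample level (default 5 Hz — 75 samples
  per 15-s bin; the recording hardware's 25 fps is configurable but
  needless for desk-scale tests) as a reflected bounded random walk in the
  lower half of the vial, with scheduled 1-s excursions into the upper half
  at cross times. Construction guarantees zero activity and distance outside
  the active window and strictly positive activity inside it, so ground
  truth is read off the realised frames. Tracks can optionally be rasterised
  to backlit frames (sub-pixel disk centres) to exercise the tracking module
  itself.
* **Recording durations** are 3600 s (recovery), 1800 s (static high) and
  6600 s (ramp to ~49 °C) — long enough to contain every scheduled event
  plus a quiescent tail. Static-high knockdowns are clipped to precede the
  final 300 s plus margin, so the tail is a valid quiescent window by
  construction, as the filtering method presumes.
* **Noise injection** adds bubble events (distance + activity spikes) and
  lighting flicker (fixed-amplitude activity blips) with a minimum spacing of
  one bin width between events of a kind, so injected per-bin totals are
  bounded — the bounded-background regime a max-subtraction filter is
  designed for, and the regime in which the recovery guarantees are stated.
  The magnitude model is a stand-in for real artifacts, not a measurement of
  them: real recordings may contain unbounded disturbances the filter cannot
  remove, so passing tests bound behaviour only under bounded noise.
* **Larvae** are uniform-intensity ellipses (backlit silhouettes are
  effectively binary) with mass–area allometry area = 10 + 0.5·mass +
  N(0, 14.6) mm² over log-normal masses (median ≈ 100 mg), which realises a
  strong-but-imperfect correlation (r ≈ 0.8) typical of image-based size
  proxies; the realised coefficient is recorded for exact closure checks.
  Replicate weighings use 0.2% relative error (precision balance), so the
  manual CV sits well below the image-based CV.
* Every generator is bit-reproducible under a fixed seed.

What the fixtures do **not** emulate: optical distortion, shadows and
reflections at the water surface, fly-shaped posture changes, overlapping
subjects, drift in the backlight, or heavy-tailed disturbance magnitudes.
Passing tests therefore demonstrate the correctness of the computational
pipeline under its stated assumptions, not field performance on arbitrary
recordings.

## Numerical choices

* Bin anchoring at t = 0 with half-open intervals; partial last bin kept.
* On-line centroids classify as lower (tie-break stated above).
* IQR quartiles: linear interpolation (NumPy default).
* Exact Wilcoxon p-values: two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
* Ramp r² clipped to [0, 1]; degenerate fits defined as r² = 0.
* Problem sizes in the test and acceptance runs (60 flies per assay at 5 Hz,
  150 larvae over 5 plates, single-frame plate acquisitions) were chosen as
  the smallest sizes at which the sampling error of the measured rates is
  far below the acceptance margins.

## Known limitations

* The activity proxy is not numerically comparable to any commercial
  tracker's channel; only its zero/non-zero semantics are.
* The filter removes only noise bounded by the quiescent-window maxima;
  a single artifact larger than anything in the window survives filtering
  and can corrupt a first/last-movement trait.
* Manual middle-cross semantics ("any part of the body") are coarser than
  the centroid criterion; systematic manual-vs-automated offsets in cross
  times are expected and are exactly what the method-effect ANOVA term
  measures.
* The two-way ANOVA assumes independent individuals; vial position and
  camera side are not modelled as random effects.
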