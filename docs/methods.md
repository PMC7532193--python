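# Methods

## Signal path and its assumptions

The pipeline assumes a mono bruit recording whose amplitude is modulated by
the heartbeat and whose diagnostic content lies in the 20–707 Hz band. All
analysis happens at 8000 S/s; higher-rate input is decimated with
`scipy.signal.resample_poly` (rational polyphase, Kaiser-window FIR cut at
the target Nyquist, delay-compensated and therefore effectively zero-phase).
We deliberately cut at the Nyquist rather than below it: the analysed region
ends at 707 Hz either way, and a lower cutoff would shave the upper passband
for no benefit. 44 100 → 8000 uses the exact 80/441 ratio.

PCM scaling divides by 32768 (symmetric full scale). No gain normalization
is applied anywhere: the spectral features are ratios and are exactly
invariant under any positive gain, so recording level never matters
(property-tested).

## Segmentation

The envelope is a moving RMS over 50 ms — long against the ≥20 Hz carrier,
short against the ~1 Hz beat. Cut points are local envelope minima found by
`scipy.signal.find_peaks` on the negated envelope with

* `distance` = 0.3 s (a 200 bpm physiological ceiling; among minima closer
  than this the deepest wins, matching find_peaks' priority rule), and
* `prominence` = 10% of the envelope's dynamic range (suppresses jitter
  minima; a flat envelope — range below 1e-9 of its level — yields no cuts).

Segments partition the signal exactly; partial first/last cycles are kept.
All three knobs (`envelope_window_s`, `min_cycle_s`, `prominence_frac`) are
exposed, since no principled universal values exist — the defaults were
chosen once for the 60–90 bpm regime and verified on modulated-noise
constructions with known burst periods.

## Spectral features

Each segment is fixed to 8192 samples (zero-padding or truncation; no
window by default — the windowing choice demonstrably does not move class
decisions, which the suite asserts by comparing rectangular against Hann
LOPO predictions, <5% disagreement). The magnitude spectrum is normalized
by its sum over all 8192 bins — including the mirrored half, so the 16 band
features sum to at most ~0.5; only ratios matter downstream.

Third-octave bands use exact base-2 edges f_c·2^(±1/6) (nominal center 31
has exact center 31.5). Integer bin borders take f_dt = round(lower edge),
and each band runs to the next band's f_dt − 1, so the 16 bands tile
18–706 Hz with no gap or overlap; the independently rounded upper edge of a
band can disagree with this tiling by one bin, and the tiling wins because
downstream sums must neither drop nor double-count bins.

Six time-domain descriptors (duration, RMS, peak, crest factor,
zero-crossing rate, envelope min/max ratio) are computed per segment but
prefixed `aux_` in output and excluded from the default model, which
uses only the eight selected bands.

## Feature selection

`CorrelationRanker` correlates each feature with the ordinal severity code
(A=1…F=6) — the classes are ordered disease states, so ordinal coding is the
natural choice over one-vs-rest. `ForwardSearchRanker` and
`JoinedPairsRanker` are wrappers scored by macro F over pooled
cross-validated predictions of the target classifier; Joined-Pairs evaluates
every unordered pair and scores a feature by the best pair containing it, so
jointly-informative but individually-weak features surface.

`PCARanker` standardizes, then scores each feature by Σ_k EVR_k·|loading|
over the leading components covering (by default) half the variance. The
coverage default matters: over components covering ~all the variance the
orthonormality of the loading matrix makes this score nearly equal for all
features — it then favours features whose variance is spread diffusely over
many small components (typically correlated noise) rather than features
concentrated in the leading structure. Half-coverage keeps exactly the
components that carry the dominant between-class structure. The parameter is
exposed for users who want the permissive variant.

Cross-validation: stratified shuffled 10-fold (vector-level) or
leave-one-patient-out (`LeaveOneGroupOut` on patient id). Vector-level
10-fold places cycles of the same patient in both train and test, so an
instance-based classifier partly memorizes patient identity; LOPO is the
honest estimate for new patients. The package treats the 10-fold/LOPO
accuracy gap as a first-class quantity (see acceptance script).

## Classification

`DistanceWeightedKNN` (k = 7, Manhattan) weights each of the k nearest
training vectors by 1/d. Zero-distance neighbours take all the mass, split
equally — an exact spectral match should dominate. Ties at the k-th distance
resolve by training-set order (stable argsort); probability ties resolve
toward the more severe class, the conservative choice for a screening tool.
The classifier is cross-checked in the tests against sklearn's
distance-weighted k-NN on generic data. Baselines: RBF SVM (C = 10,
γ = 1/n_features, standardized inputs) and a 100-tree seeded random forest.

Quality indicators read a row-percentage confusion matrix as counts over
equally sized classes: recall = diagonal/100, precision = diagonal over
column sum, macro accuracy = mean recall. This equal-class-weight convention
is the one that exactly reproduces the published per-class indicator tables
of the 38-patient clinical study (macro accuracies 0.81/0.78/0.74 for
k-NN/SVM/RF), which the suite asserts value-by-value at two decimals with
half-up rounding. Recording-level aggregation reports, per class, the
fraction of cycles whose argmax it is.

## Synthetic cohort generator

The generator emulates the statistical structure of the clinical cohort, not
hemodynamics:

* **Cohort structure** — 38 patients in classes 3/5/7/10/9/4 (A…F), two
  30-s recordings per patient by default, yielding ≈2 650 heart-cycle
  vectors — matching the scale of the study corpus (2 670 vectors).
* **Class templates** — each class distributes spectral-magnitude mass over
  the 16 bands: 60% as a Gaussian bump (σ = 1 band slot) over the eight
  discriminative bands, centred progressively higher with severity (patent →
  low bands, failed → 280–700 Hz), 40% as a class-independent ambient floor
  over the other eight. Profiles are specified in |X|-mass with
  class-invariant total and converted to energy weights via w = q²/width, so
  the sum-normalization denominator stays class-neutral and the ambient
  bands carry no artificial class signal.
* **Calibration** — rectangular-window truncation smears 1/Δf magnitude
  tails across band borders, deforming realized profiles band-locally. A
  one-time probe with a flat profile (fixed internal seed) measures each
  band's realized response; template construction divides it out.
* **Heartbeat** — raised-cosine pulse train, 0.35 duty cycle, 60–90 bpm
  drawn per recording, on a 0.05 diastolic floor (an AVF bruit is
  continuous with systolic accentuation).
* **Patient idiosyncrasy** — per-patient log-normal gain per band
  (sd 0.3 on log energy), drawn once per patient. This is the mechanism
  that makes vector-level 10-fold CV optimistic relative to LOPO; with the
  effect switched off the two schemes agree.
* **Noise-floor jitter** — per-recording independent log-normal gain per
  band: sd 0.25 on the bruit bands, sd 0.5 on the ambient bands (between
  sessions the ambient floor and probe coupling vary far more than the
  vascular signal).
* **Determinism** — every stream derives from (global seed, CRC-32 of
  patient id, recording index), so cohorts are bit-reproducible in any
  generation order.

What the generator does **not** model: real bruits' cycle-to-cycle spectral
variation within a heartbeat (systole/diastole differences), respiration,
probe repositioning drift within a session, arrhythmia, ambient transients,
and any physiological coupling between heart rate and class. Passing the
synthetic end-to-end checks therefore demonstrates that the pipeline
recovers planted class structure of realistic magnitude under realistic
nuisance variation — not clinical performance; the published
confusion-matrix tables are reproduced at the indicator level only, since
the patient recordings are not public.

## Problem sizes and numerical choices

The test suite and acceptance script size the simulations for a laptop-class
run: the default cohort (76 × 30 s recordings, ≈2 860 vectors) for the
classification and optimism checks, and a one-recording-per-patient 15-s
cohort (≈700 vectors) for the wrapper selection methods, whose cost is
quadratic-ish in features × folds. The full suite runs in under a minute;
the acceptance script in about half a minute.

Degenerate inputs: all-zero spectra raise and the segment is dropped
(logged); a recording shorter than one refractory interval returns a single
segment (logged); an empty feature table from a recording is an empty frame,
not an error. Rounding for report tables is decimal half-up (0.805 → 0.81),
matching how the published tables were rounded; internal values keep full
precision.
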