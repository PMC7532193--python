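# phonoavf

Grading arteriovenous-fistula (AVF) condition from the sound it makes.

An AVF — the surgical artery–vein connection giving hemodialysis patients
vascular access — emits an audible bruit as blood flows through it. As
stenosis (narrowing) progresses, turbulence changes the bruit's spectrum:
the energy shifts from the low bands into a high-pitched 280–700 Hz range.
`phonoavf` implements a phono-angiography pipeline that turns a 30-second
bruit recording into one of six severity grades, A ("patent") … F
("failed"), with per-class probabilities — the software core of a low-cost
bedside screening device for dialysis units, where Doppler ultrasound is too
expensive for routine monitoring.

## The method

1. **Ingestion** — mono 16-bit PCM WAV, decimated to the 8 kS/s working rate
   with polyphase anti-aliased resampling (supports 44.1/48 kS/s sound cards).
2. **Heart-cycle segmentation** — the recording is cut at the local minima of
   its moving-RMS envelope (50 ms window, 0.3 s refractory spacing), one
   segment per heartbeat.
3. **Spectral features** — each cycle is zero-padded/truncated to 8192
   samples (rectangular window) and transformed; the FFT magnitude is
   sum-normalized,

       X_N[i] = X[i] / Σ_n X[n],

   and the feature for the third-octave band with nominal center *f* is the
   normalized energy

       T_f = Σ_{n = f_dt}^{f_gt} X_N[n],

   over the band's integer bin range (16 bands, centers 20 … 630 Hz, exact
   base-2 edges f·2^(±1/6)). Normalization makes every T_f invariant to
   recording gain.
4. **Feature selection** — four rankers (feature–class correlation, greedy
   forward search, Joined-Pairs, PCA loadings) under either stratified
   10-fold CV or leave-one-patient-out (LOPO) CV. The default model uses the
   eight bands `T_63 T_80 T_100 T_125 T_315 T_400 T_500 T_630` — the
   60–140 Hz and 280–700 Hz ranges where the discriminant energy lives.
5. **Classification** — k-nearest-neighbours with the Manhattan metric and
   distance-weighted (1/d) voting, k = 7, plus RBF-SVM and random-forest
   baselines. Per-recording output aggregates the per-cycle decisions into a
   six-bar probability chart; quality is reported as a row-percentage 6×6
   confusion matrix with per-class precision/recall/F-score and macro
   accuracy (mean per-class recall).

Because no public corpus of labelled AVF bruits exists, the package ships a
first-class synthetic generator: class-dependent third-octave spectral
profiles, heartbeat amplitude modulation, per-patient spectral
idiosyncrasies and per-recording noise-floor jitter, mirroring the clinical
study structure of 38 patients in classes 3/5/7/10/9/4 (A…F). See
`docs/methods.md` for the signal model and its limitations.

## Worked example

```bash
phonoavf simulate --out cohort --seed 1 --recordings-per-patient 1 --duration 15
# wrote 38 recordings for 38 patients to cohort
phonoavf extract --manifest cohort/manifest.csv --out features.csv
# wrote 708 feature vectors to features.csv
phonoavf train --features features.csv --out model.json
# stored k-NN model (708 training vectors, k=7) at model.json
phonoavf analyze --wav cohort/P016_r0.wav --model model.json
#   A                                            0.0%
#   B                                            0.0%
#   C                                            0.0%
#   D ######################################## 100.0%
#   E                                            0.0%
#   F                                            0.0%
# assigned class: D
```

Every bar is the fraction of heart cycles whose most probable class is the
one shown (patient P016 is a planted class-D case; noisy cycles would show
as lateral bars next to the dominant one). Honest per-patient evaluation
uses LOPO, so no patient contributes to both train and test:

```bash
phonoavf evaluate --features features.csv --cv lopo --out eval.json
# "acc": 0.97, "recall": [0.84, 0.99, 1.0, 1.0, 0.99, 1.0], ...
```

The same pipeline is available as a library of sklearn-style estimators
(`DistanceWeightedKNN`, `CorrelationRanker`, `ForwardSearchRanker`,
`JoinedPairsRanker`, `PCARanker`, `BruitFeatureExtractor`) composing with
sklearn model selection; the CLI is a thin wrapper over them.

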