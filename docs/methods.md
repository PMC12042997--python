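# Methods

This note documents the models, conventions, and numerical choices behind
`cheechlab`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data do and do not emulate.

## Cohort model

Participants are generated from a multivariate-normal predictor model:
five z-scaled predictor scores (Flanker, Stroop, and Trail-Making RT
interference; reading-span letter-recall accuracy; TFS-LF interaural-phase
threshold) drawn with a fixed 5×5 correlation matrix, and a standardized
N1-difference outcome

    y = Xβ + ε,  ε ~ N(0, σ²),

mapped to µV by an affine transform with cohort mean −0.254 µV and SD
0.340 µV.  Defaults:

* correlation matrix `DEFAULT_PREDICTOR_CORR` (moderate correlations,
  strongest between TMT and TFS, r = 0.52);
* β = (0.047, 0.598, −0.094, 0.649, −0.359).  The third coefficient is a
  deliberate choice between two candidate values: the commonly quoted
  −0.009 is inconsistent with its own reported t statistic
  (−0.518 × SE 0.182 = −0.094) and with the dominance-weight sum, since
  only β_TMT = −0.094 makes βᵀRβ = 0.583 equal both Σ GDW and the
  unadjusted R² implied by adjusted R² = 0.467 at n = 24, p = 5.  Both
  values are selectable (`CohortSpec.betas`,
  `simulate.BETA_TMT_AS_PRINTED`).
* residual SD = √(1 − 0.583), so the population R² of the standardized
  model is 0.583.

Native-unit predictor scores are affine images of the z-scores with
plausible center/scale constants (e.g., Stroop 150 ± 80 ms, reading span
0.80 ± 0.12); these are conventions chosen once for realism, not estimates
of any real cohort, and nothing downstream depends on them (all inference
is z-standardized).

`z_<name>` columns are empirically standardized per cohort (mean exactly
0, SD exactly 1), matching the analysis convention that all variables are
z-scored before regression.

## Speech proxy and chirped-speech synthesis

The generator renders voiced speech as glottal-pulse trains: impulses
exciting a 500 Hz resonance with 4 ms decay, spaced 1/F0 with 2%
multiplicative jitter, amplitude-modulated at 30 Hz (depth 0.5) to give the
track the 20–40 Hz envelope energy on which voiced-epoch detection keys.
Pulse times are recorded exactly, which is all the chirp scheduler needs;
no attempt is made at naturalistic speech synthesis, formant structure, or
pitch modulation of a second talker (the generator simply renders a second
track at a different F0).

Voiced-epoch detection band-limits to 20–1,000 Hz (4th-order zero-phase
Butterworth), takes the analytic-signal envelope, band-passes it 20–40 Hz
(2nd-order zero-phase), and takes the analytic magnitude again.  The
magnitude step replaces plain rectification deliberately: a rectified
band-passed signal crosses zero every half-cycle (~16 ms at 30 Hz), so no
supra-threshold run could ever satisfy the 50 ms minimum-duration rule;
the analytic magnitude is the smooth nonnegative modulation strength the
rule needs.  Consequence: the envelope filter's ~50 ms impulse response
sets the temporal resolution — detected boundaries are accurate to roughly
one envelope period (tests allow 50 ms), and bursts shorter than ~50 ms
smear rather than vanish.

Chirp scheduling is greedy per voiced epoch: the first pulse gets a chirp
flagged `is_first`; later pulses get chirps only if ≥ 18.2 ms after the
previous chirp and ≥ 48 ms after the epoch's first chirp (skipped pulses
do not reset either window, and the 48 ms gap is measured from the first
chirp's onset only).  The chirp waveform is a 5 ms cosine-gated
logarithmic frequency sweep spanning its band, unit peak, scaled by a
configurable chirp-to-speech ratio — the published stimulus's exact chirp
acoustics are proprietary, so this waveform is this package's convention.
By default every onset carries all three chirp bands simultaneously (one
composite chirp); cyclic band rotation is available.  Band splitting uses
4th-order zero-phase Butterworth filters at the printed edges; the 28%
voicing threshold is taken against the full-band track RMS.

## Task generation

Inter-switch intervals are uniform on [5, 7] s ("6 ± 1 s" read as a
uniform family), normalized to total exactly 450 s by iterative
rescale-and-clip, so the 75 intervals average exactly 6 s.  Switch k sits
at the cumulative sum of the first k + 1 intervals; the final switch
coincides with the block end (the degenerate one-switch-in-6-s case puts
the switch at 6 s).  Directions alternate from a seeded starting side.

Twenty-five switches (never the same switch twice) receive target color
words at lags of 0.125, 0.25, 0.5, 1, 2 s — five per lag class, balanced
13/12 between left→right and right→left switches, with the direction
receiving the extra word randomized per seed.  Masker color words must not
fall in (switch − 0.5 s, switch + 0.1 s); the "−0.5 and 0.1 ms" printed
elsewhere is treated as seconds, since a sub-millisecond window would be
meaningless at speech timescales.

Spatial rendering uses complementary equal-power raised-cosine gains
(g_L² + g_R² = 1 throughout) swapping sides over 35 ms from each switch
onset; spatialization is plain stereo panning, not HRTF filtering, but the
fixed timing offsets of a real rig (spatialization delay 1.973 ms,
earphone tube 1 ms, trigger-channel 1 ms, chirp-onset 0.541 ms) are
preserved in event alignment so real-data timing semantics survive.
Event alignment is greedy nearest-neighbor within a 5 ms tolerance (no
tolerance is prescribed anywhere; 5 ms separates jitter from the ~20 ms
event spacing), with expected events authoritative.

## Behavioral scoring

* Hits: a target word is scoreable unless any masker word lies within
  ±2 s; a hit is ≥ 1 press in the half-open window (onset, onset + 2 s];
  presses are consumed in time order and each credits at most one word
  (earliest still-unhit eligible) — for equal-length windows this greedy
  rule attains the maximum assignment, which the tests verify
  exhaustively.
* Interference scores: median RT differences (incongruent − congruent,
  Part C − Part W, TMT-B − TMT-A); Flanker medians use correct trials
  only.
* Reading span: strict position matching of recalled letters (blanks
  allowed), averaged over the three 3-letter and three 4-letter trials
  only; longer lists are deliberately ignored.
* Staircase: φ starts at 180°, ÷k after two successive correct, ×k after
  one incorrect, k = 1.25³ → 1.25² → 1.25 by turn-point count (the factor
  changes on the trial after a reversal); stop at 8 reversals or 60
  trials; threshold = geometric mean of the last six reversal φ values
  (fewer than six reversals is flagged, not fatal).  The stopping rule is
  this package's default — the procedure's published description fixes
  the step rule, not the run length.

### Staircase bias and the simulated observer

The two-down/one-up rule converges asymptotically where p² = 0.5
(p ≈ 70.7%).  Finite 8-reversal runs are biased in opposite directions
depending on the observer: when the psychometric width σ (log-IPD units)
is smaller than the final step ln 1.25 ≈ 0.22, grid quantization and lucky
sub-threshold guess streaks (a 2AFC observer still guesses at p = 0.5
below threshold) pull the tracked level down (~68.5% at σ = 0.2); when σ
is much larger, overshoot pulls it up (~73% at σ = 0.6).  The default
observer (threshold 20°, σ = 0.3, lapse 0.02) operates at step/σ ≈ 0.74 —
inside the range where up-down tracking theory applies — and tracks
70.3 ± 0.5%, consistent with the nominal 71%.  Simulations across this σ
range are how that default was established.

## EEG simulation and ERP extraction

The evoked kernel is a causal negative Gaussian component (peak 135 ms,
width 25 ms, support [0, 500) ms) scaled per condition;
`EvokedKernel.with_window_means` solves for amplitudes that give requested
[110, 160) ms window means, so ground truth is exact by construction.
Noise is additive: 1/f background (FFT-shaped, RMS-calibrated), optional
60 Hz sinusoids on chosen channels, optional 300 ms biphasic frontal blink
transients (present only to exercise rejection — there is no ICA; the
blink/heart cleaning stage of a real pipeline is a pluggable no-op here,
since that decomposition is external machinery, not part of this chain's
logic).  The synthetic montage is a reduced 16-channel 10–20 layout that
retains every contracted channel (Fz, Cz, earlobes A1/A2, mastoids M1/M2,
frontal sites); real 64+-channel recordings enter through the EDF/BDF
reader.

Filter contracts are zero-phase (forward–backward) Butterworth designs of
the printed order and edges: 2nd-order 0.1 Hz high-pass after DC removal;
8th-order 0.5–40 Hz band-pass; polyphase resampling to 512 Hz.  Tests
check realized attenuation against the analytic |H|² response.  Zero-phase
application makes the chain noncausal, so a causal kernel acquires a small
precursor that the baseline window absorbs; the chain applies one common
near-unity gain to the N1 window mean (measured ≈ 1.003), which is why
noise-free end-to-end recovery is exact without filters and proportional
(ratio-exact across participants) with them.

Line-noise detection averages 1 s periodograms (1 Hz bins) and computes
neighbor-corrected power c(f) = p(f) − mean{p(f ± 2), p(f ± 3)}; a channel
is flagged when c at 60 Hz or any of its first four harmonics exceeds
8 SD of c over all other frequencies.  Cleaning fits and subtracts
sine/cosine pairs at the offending frequencies in 4 s Hann-weighted
windows (50% overlap-add), re-detecting and iterating at most five times;
unflagged channels pass through bit-identical.

Epochs are [−50, +500) ms around first-chirp events (half-open windows,
0-based samples, seconds internally), baselined to the [−50, 0) ms mean.
Two-step rejection: (1) any |sample| > 300 µV; (2) per-epoch per-channel
peak-to-peak amplitudes z-scored across surviving epochs, rejecting epochs
with any single-channel z > 6 or mean-across-channel z > 2.  The
peak-to-peak statistic is this package's concrete reading of a "6 SD /
2 SD" rule whose original statistic is toolbox-internal; it is
oracle-tested against an independent reimplementation, zero-variance
channels yield z = 0, and kept + rejected always equals the input count
with every rejection logging its rule.  N1 is the arithmetic mean of Fz
samples with latency in [110, 160) ms of the per-condition average; the
difference score is target − masker (negative = stronger N1 to the
attended talker), and the per-story/half-split variant feeds the ICC.

## Inference layer

OLS fits (coefficients, SEs, t, two-sided p) are computed via statsmodels
on z-scored variables (intercept exactly 0); VIF_j = 1/(1 − R²_j) and
Cook's distance (flag at D > 0.5) come from the standard influence
formulas.  Dominance analysis enumerates all 2^p subsets (p ≤ 15),
averages each predictor's incremental R² within subset sizes and then
across sizes; the GDW vector sums to the full-model R² as an arithmetic
identity, individual weights may be negative under suppression, and the
size-conditional table is returned alongside.  LOOCV refits n models
explicitly (the PRESS identity e_i/(1 − h_ii) serves as the independent
check, never the implementation).  Reliability: Cronbach's α and KR20 in
closed form; ICC defaults to two-way random, single-measure *consistency*
(ICC(C,1)) on story-wise N1 differences, with absolute agreement
(ICC(A,1)) selectable — the consistency form is the default because the
two stories play symmetric roles and mean story offsets are not of
interest.

## Orchestration scale

`run_pipeline` executes cohort → stimulus → task → EEG → ERP → behavior →
inference with all randomness derived from one seed, emitting
regression-shaped tables, a manifest of content digests (byte-identical
across reruns of the same config), and TSV/JSON artifacts.  Default
simulation sizes are desk-scale choices — 24 participants, 60
epochs/condition at 2 kHz, 30 s demo stories — sufficient to exercise
every code path and verify the identities above; they are not powered
study replicas, and configs scale them up freely.

## Known limitations

* The speech proxy has pulse trains and envelope modulation but no
  phonetic content; behavioral simulation of listeners (hits, RTs) is
  illustrative rather than a perceptual model.
* Spatialization is panning; HRTF cues and their release-from-masking
  effects are out of scope.
* Bad-channel interpolation is inverse-distance weighting on 2-D layout
  coordinates, a deliberately simple stand-in for spherical splines, and
  flags affected channels in metadata.
* The line-noise cleaner assumes stationary-ish sinusoidal interference
  within 4 s windows; heavily amplitude-modulated line noise would leave
  residue (the iteration cap then reports a non-clean state rather than
  looping).
* Passing tests demonstrate correctness of the algorithms on data whose
  generative structure is known; they cannot certify performance on real
  EEG with non-Gaussian artifacts, drifting impedances, or event-code
  corruption beyond the jitter/insertion/drop model used here.
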