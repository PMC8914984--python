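# Methods

This note documents the signal model, the numerical choices, and the design
decisions behind `emgfatigue`, in the order the pipeline runs.

## Signal model and conditioning

The input is a uniformly sampled single-channel sEMG amplitude stream with a
known sampling rate (default 2000 Hz; anything above 800 Hz is accepted,
since surface EMG carries little energy above ~400 Hz).  Conditioning is:

1. DC-offset removal (mean subtraction).
2. Band-pass 25–350 Hz, Butterworth, design order 2.
3. Band-stop 47–53 Hz, Butterworth, design order 2, to remove 50 Hz mains.

All filters are applied **zero-phase** (forward–backward, `sosfiltfilt` with
its standard even-reflection padding) by default.  Zero-phase application is
the standard choice for offline EMG work and, more importantly here,
preserves envelope timing across sub-bands, so the low- and high-band IMA
series stay aligned in time.  The stated orders are prototype design orders;
forward–backward application doubles the effective roll-off.  A causal
single-pass mode (`zero_phase=False`, CLI `--causal`) is provided for
real-time-like use; its group delay shifts detected onsets slightly late.

## Segmentation

Rectangular windows of 3 s with 1.5 s overlap (hop 1.5 s).  Windows are
half-open sample ranges with start indices `round(i*hop*fs)`; a trailing
stretch shorter than one window is dropped because every feature normalises
by the fixed window length N, and no taper is applied ("rectangular" is read
literally: the spectral estimator is the raw single-window periodogram).

## Features

- **IEMG** — sum of absolute amplitudes over the window; rises with
  sustained contraction and progressing fatigue.
- **Power spectrum** — one-sided periodogram `P_k = |X_k|^2`, bins
  `0..floor(N/2)`, no averaging.
- **MNF** — power-weighted mean frequency, DC bin excluded (the offset was
  removed upstream and the defining sum starts at the first nonzero bin).
- **MDF** — exact equal-power splitting rarely holds on discrete bins, so
  MDF is defined as the smallest bin frequency at which cumulative power
  reaches half the total (documented tie-break; for a symmetric two-tone
  spectrum this returns the lower tone).

MNF/MDF are diagnostics: in the reference study their first-segment values
cluster near 75–85 Hz, motivating 80 Hz as the split between low- and
high-frequency components.  The packaged `table3_spectral_frequencies.csv`
fixture carries those per-muscle values.

## The double-step classifier

**Gate.**  `IEMG_initial` is fixed to the first window for the whole session
and the comparison is strict (`IEMG_current > IEMG_initial`).  The gate is
evaluated independently per window (no latching), and the first window is
non-fatigue by construction — it cannot strictly exceed itself.  When the
gate fails, no sub-band analysis is performed for that window.

**Sub-band step.**  The gated window is filtered by two fourth-order
Butterworth band-passes, 25–79 Hz (LFSS) and 80–350 Hz (HFSS), with the same
zero-phase convention as conditioning.  The boundary is kept at 79/80 Hz
exactly as specified, with no guard band, although the two roll-offs overlap
near 80 Hz.  Sub-band filtering happens per segment (each window is filtered
independently), matching the per-window loop of the reference algorithm.

**IMA and index.**  IMA is the mean magnitude of the window's full two-sided
length-N DFT, `(1/N) Σ |X_n|` — the literal reading of the defining sums.
One-sided variants differ only by a constant factor and are not exposed.
`Fatigue_Index = IMA(LFSS) − IMA(HFSS)`; the window is labelled fatigue iff
the gate passed and the index is ≥ 0 (the boundary value 0 counts as
fatigue).  Because both IEMG and IMA are positively homogeneous, the label
sequence is invariant under positive amplitude rescaling of the recording.

**Report counter and onset.**  The per-session report records, per window:
index, start time, IEMG, gate state, sub-band IMAs, index and label.  Onset
is defined as the start time of the first fatigue-labelled window.  The
reference study reports session-level times without fixing an alignment
convention, so this convention is stated rather than inferred.

A note on the L1 spectral measure: IMA sums magnitudes over *all* N bins, so
it also collects broadband mass (e.g. the small per-window filter-transient
splatter of the per-segment sub-band filtering, or a broadband noise floor).
That mass is common-mode between consecutive windows of a stationary signal
but not exactly equal between the two sub-bands; comparisons against
analytic filter gains are therefore made at tone bins (where they are
exact), and the synthetic generator calibrates its carriers through the full
measurement chain (below).

## Evaluation machinery

- Sample size: `N = 4 z² ρ(1−ρ)/D²`, returned raw and rounded up
  (z = 1.96, ρ = 0.89, D = 0.2 gives 37.6 → 38).
- Confusion accounting uses only the last two windows of each muscle's
  session: final-window fatigue → TP (non-fatigue → FN); penultimate-window
  non-fatigue → TN (fatigue → FP).  Earlier windows contribute no counts.
  On the packaged 75-muscle table this yields 70/72/3/5 and accuracy 94.7%.
- IEMG trend: OLS slope against window index (unit spacing).
- Paired two-tailed t-test on per-muscle IEMG slopes between conditions
  (df = n−1).  On the packaged slope table all 75 fatigue-minus-rest
  differences are positive and the recomputed p-value is far below 0.05;
  it is reported as a diagnostic, not asserted against any printed value,
  since the tabulated slopes are heavily rounded.
- One table discrepancy is preserved as printed: the five muscles whose
  final index stayed negative are subjects 8, 12, 16 (left), 25 and 32
  (right) in the index table, while the running text lists subject 22; the
  fixtures follow the tables.

## Synthetic sEMG generator

The generator exists so the full pipeline is exercisable and testable with
known ground truth.  It emulates exactly the features the classifier
senses — band power balance and overall amplitude — and nothing else.

Model: `x(t) = amp(t)·[w_h(t)·c_H(t) + w_l(t)·c_L(t)] + noise_floor·n_0(t)`
with `amp(t) = amp0·(1 + amp_growth·t)`.  In fatigue mode the band weights
follow linear trajectories crossing at `crossover_s`; the crossover is the
designed onset (the instant low-band content matches high-band content,
which is precisely the index's zero).  Defaults: fs 2000 Hz, 80 s, crossover
50 s, `w_h0 = 1.0`, `w_l0 = 0.3`, `amp_growth = 0.005`/s (a ~40% amplitude
rise over the session, driving a clearly positive IEMG slope while keeping
the high-band IMA monotone decreasing), `noise_floor = 0.02`.  Non-fatigue
mode uses constant weights and flat amplitude.

**Carriers.**  The default carrier per band is a dense random-phase
multisine on a 2/3-Hz grid (period 1.5 s, equal to the hop).  Two properties
follow: every tone is exactly bin-centred for the 3-s analysis DFT, and
every analysis window starts on a period boundary and therefore sees the
identical carrier waveform.  Per-window sub-band IMA is then essentially
deterministic given the weights, while the waveform remains Gaussian-like in
time by the central limit theorem.  A band-limited Gaussian-noise carrier is
available (`carrier="gaussian"`), but its per-window IMA fluctuates with
relative SD ≈ 0.52/√(bins in band) (≈ 4% for the 54-Hz low band), which
alone smears first-crossing onset detection by 1–2 s — more than the ±1.5 s
(one hop) recovery target — so it is not the default.

**Calibration.**  Raw carriers are calibrated through the classifier's own
measurement chain.  First, per-band scales make one unit of band weight one
unit of *net* measured sub-band IMA, solving the 2×2 gain/leakage system
(each carrier's IMA is measured in both sub-bands).  Second, a balance step
equalises the two measured sub-band IMAs on a static equal-weight mixture at
the crossover-time amplitude with the noise floor present: the noise floor
adds Rice-bias mass preferentially to the wider high band, and without this
step the measured index zero lands 1–2 s after the weight crossover.  After
calibration the designed crossover is the expected index zero as measured.

**Relaxed-muscle mode** emulates a near-silent recording (biceps with the
elbow extended): amplitude 5% of the equivalent active mixture's RMS, equal
mean band weights whose balance drifts slowly and symmetrically (low-passed
noise, 0.25 Hz corner, depth 0.6, total power held constant across the
drift), plus a brief settling transient — elevated amplitude decaying with a
1.5-s time constant, emulating residual activation while the limb drops into
the relaxed posture.  The balance drift makes the step-2-only index
fluctuate in sign (false positives, as observed on real relaxed muscles);
the settling transient elevates the first-window IEMG baseline so the
activity gate reliably rejects every later window and the full two-step
classifier reports no fatigue.  Without some such opening transient a
strictly stationary recording would pass the strict gate in roughly half its
windows by chance, and the gate-necessity contrast could not be demonstrated.

**What the generator does not model:** motor-unit recruitment and firing
statistics, electrode/skin artefacts, nonstationary bursts, movement
artefacts, inter-subject variability.  Passing tests on synthetic data show
the pipeline implements the stated mathematics and recovers designed band
crossovers; they do not certify detection performance on real recordings.

## Numerical choices and degenerate inputs

- Filters are designed as second-order sections; records shorter than 3× the
  filter startup length are rejected rather than silently padded.
- An all-zero window yields a degenerate spectrum; MNF/MDF raise rather than
  return a value.
- Report files store floats with 17 significant digits so CSV/JSON reports
  round-trip bit-for-bit.
- The simulation-based checks use 80-s sessions at 2000 Hz and 20 seeds for
  onset recovery (5 seeds for the non-fatigue and relaxed diagnostics),
  problem sizes at which each session classifies in well under a second.
- "Flat IEMG trend" in non-fatigue mode is asserted as a relative bound
  (|slope| below 0.1% of the mean per-window IEMG): with 50% window overlap,
  adjacent-window noise is correlated and a naive OLS standard error
  understates slope variability.

## Known limitations

- Single channel only; no multi-muscle fusion.
- The 79/80 Hz boundary is fixed, not per-subject adapted.
- The IEMG gate compares against the first window only; a session that
  begins mid-contraction at maximal effort would gate later windows off.
- Causal mode shifts onsets by the filters' group delay; the zero-phase
  default is not realisable in strict real time.
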