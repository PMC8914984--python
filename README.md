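# emgfatigue

Objective detection of muscle fatigue from a single-channel surface EMG
(sEMG) recording, using a **double-step binary classifier**:

1. **Activity gate (time domain).** Per 3-s window *i*, the integrated EMG
   `IEMG_i = Σ_n |EMG_n|` must strictly exceed the first window's baseline
   `IEMG_initial` — sustained contraction drives the IEMG upward, and a
   quiescent muscle must never reach the spectral step.
2. **Fatigue index (frequency domain).** The gated window is band-split with
   fourth-order Butterworth band-passes into a low-frequency sub-signal
   (LFSS, 25–79 Hz) and a high-frequency sub-signal (HFSS, 80–350 Hz).  For
   each sub-signal the *instantaneous mean amplitude* is the mean magnitude
   of its length-N DFT, `IMA = (1/N) Σ_n |X_n|`, and

   ```
   Fatigue_Index = IMA(LFSS) − IMA(HFSS),   fatigue ⇔ Fatigue_Index ≥ 0
   ```

   As fatigue progresses, sEMG spectral mass migrates from the high band into
   the low band, so the index crosses from negative to non-negative; the
   crossing time is the detected fatigue onset.

The package is aimed at biomedical-signal researchers and engineers who want
a tested, scriptable reference implementation of this classifier: the
conditioning chain (DC removal, 25–350 Hz band-pass, 47–53 Hz power-line
band-stop, all zero-phase Butterworth), overlapping rectangular segmentation
(3 s / 1.5 s), spectral features (MNF/MDF), the per-segment fatigue report
counter, study-level evaluation (sample size, confusion metrics, IEMG slope
trends, paired t-test), and a synthetic sEMG generator so the whole pipeline
runs and is testable without recordings.  The per-muscle reference tables of
the middle-deltoid study this implements (75 muscles; segment labels,
first/last fatigue indices, IEMG slopes, first-segment MNF/MDF) ship as CSV
fixtures under `emgfatigue.datasets`.

## Worked example

Generate a synthetic 80-s fatigue session whose low/high-band content is
designed to cross at 50 s, then classify it:

```sh
$ emgfatigue simulate --mode fatigue --seed 7 --duration 80 --crossover 50 --out session.csv
wrote session.csv (80 s at 2000 Hz) and session.csv.truth.json

$ emgfatigue classify session.csv --out session.report.csv
fatigue onset at 51 s (18/52 segments labelled fatigue)
report written to session.report.csv

$ head -3 session.report.csv
segment_index,t_start_s,iemg,gate_passed,ima_lfss,ima_hfss,fatigue_index,label
1,0,254.54624212224229,False,,,,non-fatigue
2,1.5,259.44171929711041,True,0.46082621895416104,1.2303767890497357,-0.7695505700955747,non-fatigue
```

The detected onset (51 s, the start of the first fatigue-labelled window)
recovers the designed 50-s crossover to within one hop (1.5 s).  Early
windows show the expected strongly negative index (high band dominant); the
first window defines the IEMG baseline and is non-fatigue by construction.

Evaluating the packaged 75-muscle reference label table reproduces the
study-level accounting:

```sh
$ emgfatigue evaluate "$(python -c 'from emgfatigue.datasets import segment_labels_path; print(segment_labels_path())')"
{
 "n_muscles": 75,
 "tp": 70,
 "tn": 72,
 "fp": 3,
 "fn": 5,
 "sensitivity": 0.9333333333333333,
 "specificity": 0.96,
 "ppv": 0.958904109589041,
 "accuracy": 0.9466666666666667
}
```

i.e. 70 true positives, 72 true negatives, 3 false positives, 5 false
negatives over the last two windows of each session; sensitivity 93.3%,
specificity 96%, positive predictive value 95.9%, accuracy 94.7%.

The same pipeline is available as a library — `read_signal`,
`run_classifier`, `simulate`, `confusion_from_labels`, `metrics` — see
`docs/methods.md` for the model details and design choices.

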