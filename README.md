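# beatboost

Heartbeat classification for ambulatory ECG under the AAMI five-class
taxonomy — **N** (non-ectopic), **S** (supraventricular ectopic),
**V** (ventricular ectopic), **F** (fusion), **Q** (unknown/paced) —
built around *attributable* features (features a cardiologist can read)
and an AdaBoost ensemble of random forests that copes with the extreme
class imbalance of real Holter recordings.

The package is aimed at biomedical-signal-processing practitioners who
want a fully testable, offline-reproducible version of this pipeline:
every stage, from wave delineation to the boosted classifier, can be
exercised against a synthetic ECG generator that carries exact ground
truth, without downloading any clinical database.

## The method

1. **Preprocessing.** The ECG is analyzed with the continuous wavelet
   transform `W(a, b) = a^(-1/2) ∫ f(t) ψ((t−b)/a) dt`; a multiscale
   Mexican-hat detector locates R peaks, a multilevel db6 decomposition
   removes baseline wander and high-frequency noise, and wave
   boundaries (P/QRS/T onsets and offsets) are delineated from the
   smoothed derivative around each R peak.
2. **Attributable feature sets.** Per beat, five sets:
   **A** 235 single-lead morphology samples (90 before the R peak, 144
   after); **B** 470 dual-lead morphology samples; **C** seven interval
   features (P, QRS, T durations, PR segment, ST-T, QT, RR), each a
   fiducial difference divided by the 360 Hz sampling rate; **D** the
   QRS area (baseline-corrected integral over the QRS complex);
   **E** db6 wavelet coefficients of the beat window. Any of the 16
   studied combinations can be assembled.
3. **Classifier.** AdaBoost over random forests: per round *m*, a
   balanced weighted bootstrap (minority classes kept in full) trains a
   forest `G_m`; its weighted error `e_m = Σ_j w_j [G_m(x_j) ≠ y_j]`
   yields the learner weight `α_m = ½ ln((1−e_m)/e_m)`; sample weights
   are multiplied by `exp(∓α_m)` (down-weighting correct beats) and
   renormalized. Rounds with `e_m > 0.5` are reset and resampled. The
   final label is the α-weighted vote `argmax_k Σ_m α_m [G_m(x) = k]`.
4. **Evaluation.** 5×5 confusion matrix and per-class
   `Se = TP/(TP+FN)`, `Sp = TN/(TN+FP)`, `+p = TP/(TP+FP)`,
   `Acc = (TP+TN)/total`, plus overall accuracy.

## Worked example

```bash
beatboost run --n-beats 1000 --rounds 5 --trees 30 --seed 42
```

generates a 1,000-beat two-lead synthetic record (class mix matching
the imbalance of a standard arrhythmia database: ~83% N, ~2.5% S,
~6.6% V, ~0.7% F, ~7.3% Q), denoises it, delineates every beat,
extracts feature sets B+C+D+E, trains 5 boosting rounds of 30-tree
forests on a stratified 90% split and prints the held-out report:

```
true    n   s   v   f   q   TP  TN  FP  FN  Se      Sp      +p      Acc
N       83  0   0   0   0   83  17  0   0   100.00  100.00  100.00  100.00
S       0   2   0   0   0   2   98  0   0   100.00  100.00  100.00  100.00
V       0   0   7   0   0   7   93  0   0   100.00  100.00  100.00  100.00
F       0   0   0   1   0   1   99  0   0   100.00  100.00  100.00  100.00
Q       0   0   0   0   7   7   93  0   0   100.00  100.00  100.00  100.00
overall accuracy (%)    100.00
```

Each row is one true class: the left block is the prediction count
matrix, then the one-vs-rest counts, then sensitivity, specificity,
positive predictivity and per-class accuracy in percent. On this
synthetic mix the full feature combination separates the classes
essentially perfectly; single-feature runs do not — the attributable
sets can be compared directly:

```bash
beatboost sweep-sets --n-beats 1000 --rounds 5 --trees 30 --seed 42 --combos D,C,BC,BCDE
combination  accuracy_pct
          D          80.0
          C          98.0
         BC         100.0
       BCDE         100.0
```

QRS area alone (set D) resolves only 80% of held-out beats; adding
intervals and morphology closes the gap. `beatboost sweep-trees`
sweeps the forest size over 20–90 trees the same way, and
`beatboost synth` writes WFDB records (`.hea`/`.dat`/`.atr`) with a
ground-truth fiducial CSV for use by other tools.

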