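# somnoscore

Automated sleep-stage scoring from polysomnography, with the statistics
needed to validate a scorer against human experts.

Sleep studies are scored manually: an expert assigns one of five AASM
stages — W (wake), N1, N2, N3 (non-REM depths), R (REM) — to every
30-second epoch of a night's EEG/EOG/EMG recording. Automated scorers must
be validated against those experts, and the field's standard report is a
stage confusion matrix, Cohen's κ, and per-stage specific agreement with
bootstrap confidence intervals. `somnoscore` provides all of the pieces:

* **psg_io** — EDF polysomnogram reading/writing (mixed per-channel rates,
  mastoid derivations formed from raw electrodes when needed) and
  plain-text hypnogram files.
* **features** — per-epoch vectors: multitaper band-power fractions
  (delta/theta/alpha/beta, normalized by epoch total power,
  contralaterally averaged over the frontal/central/occipital pairs),
  slow/fast band ratios, line length, kurtosis — each computed over 29
  two-second sub-epochs per epoch and summarized by p95/min/mean/SD —
  plus EOG slow-band energy and chin-EMG energy (116 named columns).
* **stager** — three compact sequence classifiers (`conv`, `recurrent`,
  `conv_recurrent`) with subject-level splits, κ-based model selection, and
  an optional N1-continuity smoother.
* **agreement** — confusion matrices, Cohen's κ with the Landis–Koch
  interpretation scale, Cicchetti–Feinstein specific agreement
  (PA = 2a/(2a+b+c), NA = 2d/(2d+b+c), OA = (a+d)/n per stage), and
  subject-resampled bootstrap CIs (median, 2.5/97.5 percentiles, R = 1000).
* **simulate** — seed-reproducible synthetic polysomnography: sticky-Markov
  hypnograms with a prescribed stationary stage mix, nine-channel signals
  with stage-correct spectral signatures (occipital alpha in W, spindles
  and K-complexes in N2, frontal delta in N3, REM atonia...), and noisy
  "second scorers" driven by a confusion model.

See `docs/methods.md` for the models, defaults, and the limits of what the
synthetic test bed demonstrates.

## Worked example

Evaluate a noisy scorer against ground truth — here the "scorer" resamples
each true stage through a fixed confusion model, so every statistic has a
known expectation:

```python
import numpy as np
from somnoscore import simulate as sim, agreement as A

rows = np.array([                    # P(observed | true), percent per row
    [94.0, 2.4, 2.2, 0.1, 1.3],
    [2.8, 83.9, 10.9, 0.1, 2.3],
    [1.1, 3.5, 89.0, 3.7, 2.7],
    [0.14, 0.21, 7.1, 92.0, 0.55],
    [1.2, 2.1, 3.6, 0.1, 93.0],
])
noise = sim.ScorerNoiseModel.from_row_percentages(rows)
pairs = []
for i in range(20):                  # 20 synthetic full nights
    truth = sim.generate_hypnogram(sim.DEFAULT_STAGE_PROPORTIONS, 960, seed=i)
    scored = sim.corrupt_hypnogram(truth, noise, seed=1000 + i)
    pairs.append((truth, scored))
report = A.bootstrap_agreement(pairs, R=1000, seed=0)
print(f"kappa = {report.kappa:.3f} ({report.kappa_label})")
for stage, row in report.per_stage.items():
    med, lo, hi = row["PA"]
    print(f"{stage:>3} PA {med:5.1f}% (95% CI {lo:.1f}-{hi:.1f})")
```

prints

```
kappa = 0.855 (almost perfect)
  W PA  93.7% (95% CI 92.6-94.5)
 N1 PA  83.2% (95% CI 81.7-84.4)
 N2 PA  91.6% (95% CI 91.2-92.1)
 N3 PA  72.4% (95% CI 62.1-79.2)
  R PA  90.7% (95% CI 89.6-91.9)
```

κ ≈ 0.86 is what this confusion model implies; N1 has the lowest positive
agreement (it is the hardest stage for humans and machines alike), and N3's
wide CI reflects its scarcity (~3% of epochs), which is exactly what the
subject-level bootstrap is meant to expose.

The full pipeline — simulate a cohort, extract features, train all three
classifier variants, select the best by validation κ, score the held-out
subjects and bootstrap the agreement — runs from the command line:

```sh
somnoscore all --subjects 30 --epochs 120 --seed 7 --out-dir run/
# -> run/evaluation.json, run/model_best.json, run/overlay.png, resolved_config.yaml
```

Every output directory contains the resolved configuration; re-running from
it reproduces the outputs byte-identically.

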