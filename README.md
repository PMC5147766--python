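# circadia

Circadian rhythmicity analysis for time-course data: a Fisher-g-style
spectral screen with permutation-calibrated detection for transcriptome
time courses, together with the standard larval-zebrafish behavior metrics
(activity, sleep, waking activity, masking, vertical place preference),
chi-square periodogram period estimation, and conditioning of
bioluminescence-reporter and pineal-melatonin traces. It is aimed at
chronobiologists who need a reproducible, testable implementation of these
procedures, and ships synthetic-data generators so every pipeline can be
exercised end to end without any sequencing or tracking data.

## The statistic at the core

For a uniformly sampled series `x_0 … x_{n-1}` with sampling interval `dt`
spanning a whole number of target periods, let `P_k` be the squared DFT
magnitude of the mean-centered series at harmonic `k = 1 … n/2`, and
`k* = round(n·dt / T)` the harmonic of the target period `T` (24 hr). The
**G-factor** is

    g = P_{k*} / Σ_{k≥1} P_k  ∈ [0, 1],

the fraction of non-DC spectral power at the circadian frequency: 1 for a
pure 24-hr cosine, near 0 for noise. It is invariant to shifting and
positive rescaling of the trace.

Detection over many series (e.g. transcripts) is calibrated against a
permutation null: each series' time points are shuffled (100 times by
default) and scored, forming a null pool. For a candidate list of the top
`L` series with threshold score `g_L`, the expected number of false
detections is `FP(L) = #{null ≥ g_L} / n_permutations`, giving an estimated
true-positive rate `1 − FP(L)/L`. The detected list is the longest one whose
estimated true-positive rate still meets the nominal level (90%, i.e. a 10%
false-detection rate).

Group differences in rhythmicity are tested by the two-sample
Kolmogorov–Smirnov statistic on G-factor distributions.

## Worked example

```python
import numpy as np
from circadia import make_expression_matrix, detect_circadian

# 1,000 transcripts on the 12-point, 4-hr, two-cycle constant-dark design:
# 100 cosine-rhythmic at snr 2 with random phases, 900 pure noise
matrix, truth = make_expression_matrix(n_rhythmic=100, n_null=900, snr=2.0, seed=0)

result = detect_circadian(matrix, tpr_target=0.9, n_permutations=100, seed=0)
planted = {g for g, t in zip(matrix.genes, truth) if t}
n_true = sum(g in planted for g in result.detected)
print(f"selected {len(result.detected)} transcripts, "
      f"{100 * n_true / len(result.detected):.1f}% truly rhythmic")
```

prints

```
selected 81 transcripts, 91.4% truly rhythmic
```

i.e. the calibration chose a list of 81 transcripts whose realized
true-positive rate (91.4%) meets the nominal 90% level for this seed.

The `analysis/` directory holds four numbered drivers that run the three
study workflows on synthetic data (`01_simulate.py` generates every input;
`02_transcriptome_screen.py`, `03_behavior_rhythms.py` and
`04_reporter_assays.py` analyze them), writing tables under `results/`.
A `circadia` CLI exposes the same workflows (`simulate`, `transcriptome`,
`rhythm`, `behavior`, `reporter`, `compare`).

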