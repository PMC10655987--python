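# precoss

Online syllable recognition by hierarchical predictive coding with
**oscillating prediction-error precisions**.

Speech arrives as a continuous signal, yet listeners parse it into discrete
syllables on the fly. One influential proposal is that the brain inverts a
generative model of the speech signal — continuously reconciling top-down
predictions with bottom-up prediction errors — and that cortical rhythms
set the tempo of this exchange: theta (~5 Hz) tracks the syllabic envelope,
low gamma (~40 Hz) indexes position within a syllable, and beta (~20–30 Hz)
carries top-down signals that gate how much weight bottom-up evidence
receives from moment to moment.

This package implements a working model of that idea and the apparatus to
study it:

- a **generative model** whose top level holds syllable evidence
  accumulators (ω, perfect integrators read out through a softmax), an
  8-unit gamma sequence (a stable heteroclinic channel realized as cyclic
  Lotka–Volterra winnerless competition, calibrated to 40 unit activations/s
  at rest — one full cycle per ~200 ms syllable), and a theta module (a
  canonical theta neuron tracking the stimulus envelope, free-running at
  5 Hz); the bottom level is a 6-channel spectral state that relaxes toward
  the column of the currently predicted spectrotemporal template;
- **oscillating precisions**: a harmonic pair of hidden states
  (p₁, p₂), stepped at the 1 kHz sampling rate with angular increment
  k₁ = 2πΨ/1000, drives the log-precision of the syllable- and gamma-level
  causal errors as affine functions of p₂. The five configurations are

  | variant | log V_ω | log V_γ |
  |---|---|---|
  | stationary | 2.5 | 1.5 |
  | identity | 2.5 + 2·p₂ | 1.5 |
  | timing | 5 | 1.5 + 4·p₂ |
  | full-antiphase | 2.5 + 2·p₂ | 1.5 − 4·p₂ |
  | full-samephase | 2.5 + 2·p₂ | 1.5 + 4·p₂ |

  with hidden-state precisions W_ω = e³, W_γ = W_p = e⁵ throughout;
- **inversion** by precision-weighted gradient flow on squared prediction
  errors, recording the full recognition trace (beliefs, errors, precision
  traces, reset mask, gamma-derived segmentation markers);
- **metrics**: overlap (time-weighted identity + duration agreement),
  entropy-weighted overlap, longest-common-subsequence ratio, sensory
  integration efficacy, and a duration-normalized categorical
  log-likelihood feeding a BIC (penalty 0.5·N_sent·ln N_p with 19
  parameters for oscillating variants, 17 for the stationary baseline);
- a **synthetic corpus generator** (seeded 6×8 spectrotemporal templates,
  Gamma-distributed syllable durations with 200 ms mean, rendered 1 kHz
  spectrograms plus a slow amplitude envelope peaking at syllable onsets),
  so the whole pipeline runs without any external data;
- an **experiments layer**: variant × frequency sweeps (2–60 Hz), 10 000-rep
  percentile bootstrap CIs, paired Wilcoxon tests with Bonferroni 0.05/8,
  Friedman tests with corrected post-hoc comparisons, and a two-factor
  ANOVA.

## Worked example

Generate a tiny corpus and recognize its first sentence with the
full-antiphase variant at a 20 Hz precision modulation:

```bash
precoss corpus make --n-sentences 3 --n-syllables 5 --seed 42 --out demo.h5
precoss run --corpus demo.h5 --variant full_antiphase --psi 20 --sentence 0
```

```
 start_ms  end_ms  winner_id  mean_softmax
        0     184          1      0.109867
      184     384          1      0.102896
      384     583          7      0.105139
      583     784          4      0.101780
      784     984          5      0.111294
      984    1008          2      0.100135
overlap=0.6220 ent_overlap=0.0002 lcs=0.6000 integration=0.00002 loglik=-11.29 status=ok
```

The true sequence here is (1, 9, 7, 7, 5) with onsets at 0, 228, 352, 687
and 781 ms. Each row is one gamma-defined window (bounded by peaks of the
last gamma unit); `winner_id` is the syllable with the highest mean softmax
belief in that window. The model finds syllables 1, 7 and 5 in roughly the
right places and misses the short 94 ms syllable 9, so 62% of the
sentence's duration is labelled with the correct syllable (`overlap`), and
the winner sequence shares a 3-element subsequence with the 5-element truth
(`lcs` = 0.6). The near-zero `ent_overlap` reflects that beliefs stay close
to uniform over this 10-syllable inventory (softmax ≈ 0.1–0.11); it
discounts the overlap by the belief entropy. `loglik` ≤ 0 is the
duration-normalized log-probability assigned to the true syllables, the
quantity the BIC model comparison aggregates.

A full sweep and its summary:

```bash
precoss sweep --config sweep.yaml --out results.csv
precoss report --results results.csv --metric overlap
```

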