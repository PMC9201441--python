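# dibs — dynamic inter-brain synchrony for fNIRS hyperscanning

When two people talk, cooperate or brainstorm while both wear fNIRS optodes,
the coupling between their hemodynamic signals — inter-brain synchrony
(IBS) — is not constant: it switches between recurring network
configurations. `dibs` is a tested, reusable pipeline for characterising
those *dynamic IBS states* from dyadic HbO/HbR recordings, aimed at
hyperscanning researchers who want the full chain from raw-ish channel time
series to state-level statistics, plus a synthetic-cohort generator for
validating every stage against planted ground truth.

The pipeline:

1. **Preprocess** — PCA spatial filtering of systemic components, CBSI
   motion correction (`hbo' = (hbo − α·hbr)/2`, `α = sd(hbo)/sd(hbr)`), and
   trimming of the first/last 30 s of each task block (two 5-min tasks →
   480 s of task data).
2. **Wavelet coherence** — Morlet (ω₀ = 6) wavelet transform coherence
   `R²(s,t) = |S(s⁻¹W_xy)|² / (S(s⁻¹|W_x|²)·S(s⁻¹|W_y|²))` between the two
   participants' HbO ROI series, Fisher-transformed (`z = arctanh R`).
   Reciprocal cross-brain ROI pairings are averaged: 13 ROIs → 91
   combinations per dyad.
3. **Band selection** — paired t-tests (task vs rest, across dyads, per
   scale and combination, thresholded at p < 5·10⁻⁶, uncorrected) pick the
   frequency band of interest; the synthetic cohorts plant coupling at
   0.10–0.19 Hz.
4. **Sliding windows** — band-averaged z in 10-s windows stepped by 1 s over
   the concatenated task period (480 s → 471 windows of 13×13 matrices).
5. **State clustering** — two-level k-medians under Manhattan distance
   (group centroids by elbow-selected k, then centroid-seeded per-dyad
   clustering); states ordered by descending global efficiency.
6. **Metrics & inference** — occurrence rates, transition counts, weighted
   global efficiency and (harmonic-mean) characteristic path length per
   state; repeated-measures ANOVAs with partial η² and Bonferroni
   post-hocs; Pearson correlations against behaviour (fluency, 5%-rule
   originality, flexibility, and the index of cooperation
   `IOC = converge/(group fluency − converge)`).
7. **Validation** — pseudogroup permutation: re-pair participants into sham
   dyads, re-run the pipeline, and report how often sham cohorts show no
   significant effects.

See `docs/methods.md` for the models, defaults, numerical choices and known
limitations (including an honest account of which parts of the pseudogroup
logic do and do not calibrate under a true null).

## Worked example

Simulate a small cohort and run the full pipeline from the shell:

```bash
dibs all --out demo --seed 4 --config demo.yaml
```

with `demo.yaml`:

```yaml
seed: 4
sim:
  n_dyads: 4
  n_rois: 3
  session_plan: [[rest, 40], [taskA, 80], [taskB, 80], [rest, 20]]
preprocess: {trim_head: 10, trim_tail: 10}
foi: {p_threshold: 0.01}          # tiny cohort: keep the band findable
clustering: {k: 2, n_replicates: 10}
```

The run logs

```
done: k=2, FOI 0.156-0.208 Hz, 111 windows/dyad
```

and writes `demo/state_metrics.csv`, whose per-state means are

```
 state  occurrence  globE    Lp
     1       0.317  1.501  0.67
     2       0.683  0.858  1.17
```

Read: each dyad's 120 trimmed task seconds give 111 sliding windows, and
state 1 — by convention the densest state — has higher global efficiency
(1.50 vs 0.86) and shorter path length (0.67 vs 1.17) than state 2 while
occurring less often (32% vs 68% of windows). With only four dyads the
band-selection t-test has little power, so the selected band covers only
the upper part of the planted 0.10–0.19 Hz coupling band; cohort-scale
runs (see below) recover the band itself. `demo/stats.json`
holds the state ANOVAs and brain–behaviour correlations,
`demo/behavior_scores.csv` the fluency/originality/IOC table, and
`demo/provenance.json` the config hash and seed for reproduction. The same
stages are runnable individually (`dibs simulate`, `preprocess`, `ibs`,
`states`, `metrics`, `behavior`, `stats`, `permute`, `report`) and compose
through the files in `--out`.

The library surface mirrors the stages (`dibs.synthgen`, `dibs.preprocess`,
`dibs.coherence`, `dibs.ibs_dynamics`, `dibs.states`,
`dibs.network_metrics`, `dibs.behavior`, `dibs.stats_validation`,
`dibs.pipeline`), e.g.:

```python
from dibs import WaveletSpec, wavelet_coherence
spec = WaveletSpec(sampling_rate=10.0)
coh = wavelet_coherence(hbo_a, hbo_b, spec)   # R², Fisher z, COI mask
```

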