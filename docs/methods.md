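# Methods

`dibs` implements a dynamic inter-brain synchrony (dIBS) analysis for dyadic
fNIRS hyperscanning, together with a synthetic-cohort generator that makes
every stage testable against planted ground truth. This note documents the
models, the defaults and why they were chosen, the numerical choices, and
what the synthetic validation does and does not establish.

## Pipeline model

The analysis follows a fixed stage order.

**Preprocessing.** Systemic physiology (blood pressure, respiration, global
flow) contaminates all channels of an fNIRS patch coherently, so the first
`n_components_removed` spatial principal components (default 1) are projected
out of the channels × time matrix per participant and chromophore. The SVD is
uncentred: a shared offset is systemic structure too, and the degenerate
all-channels-identical case then reduces to exact rank-1 removal. Motion
artifacts move HbO and HbR in the same direction while neurovascular
coupling moves them oppositely; CBSI (correlation-based signal improvement)
exploits this with `hbo' = (hbo − α·hbr)/2`, `α = sd(hbo)/sd(hbr)`,
`hbr' = −hbo'/α`, which cancels the common mode and leaves the corrected
chromophores exactly anti-correlated (α is retained per channel for audit;
all downstream synchrony analysis uses HbO only). Finally the first and last
30 s of each task block are dropped to keep the steady period — two 300-s
tasks yield 480 s of task data — while rest blocks are kept whole because
they are the baseline for band selection. The pipeline realises these trims
as annotation masks on the original time axis rather than by splicing the
signal: splicing puts an identical discontinuity into both participants'
series at the same instants in every dyad, and the wavelet transform turns
those synchronised transients into spurious low-frequency cross-brain
coherence confined to the task blocks — exactly the signature the band
selection looks for. Coherence is therefore computed on the continuous
recording and the trimmed task bounds are applied when task samples are
extracted for band selection and windowing (a splice-based
``trim_sessions`` remains available for callers that need physically
shortened recordings).

**Wavelet coherence.** Inter-brain synchrony between two HbO series is the
squared wavelet transform coherence with a Morlet mother (ω₀ = 6, the field
default: good time-frequency compromise, near-analytic), scales on a
geometric grid with 12 voices per octave spanning 0.01–0.7 Hz (above 0.7 Hz
cardiac pulsation dominates, below 0.01 Hz slow drift). Cross- and
auto-spectra are smoothed with the conventional operator for this mother: a
Gaussian in time with σ equal to the scale, and a 0.6-octave boxcar across
scales. Because one non-negative kernel smooths numerator and denominator,
Cauchy–Schwarz bounds R² by 1 up to round-off (the implementation asserts
this rather than silently clipping large excursions). Coherence R is
Fisher-transformed, `z = arctanh(min(R, 1−10⁻⁷))`, before any averaging; the
transform is applied to R rather than R², a convention choice that is
monotone and therefore irrelevant downstream of clustering. Cone-of-influence
points (within √2·s of a record edge) are flagged but retained; windows use
all points.

**ROI pairing.** With n ROIs per participant there are n² ordered
cross-brain pairings; the two orderings of an unordered combination (i of
participant 1 with j of participant 2, and vice versa) measure the same
relation and their z-maps are averaged, giving n(n+1)/2 combinations — 91
for 13 ROIs, of which 13 are homologous (diagonal) single maps. The table is
invariant to swapping participants.

**Frequency band of interest (FOI).** Per scale and ROI combination, a
paired t-test across dyads compares task-period mean z (first averaged
within each task block, then across blocks, so unequal block lengths carry
equal weight) against rest-period mean z. A scale qualifies when *any*
combination passes p < 5·10⁻⁶ with task > rest; the FOI is the largest
contiguous run of qualifying scales. No multiple-comparison correction is
applied — the test only locates the band, it is not an endpoint. An empty
result halts the pipeline explicitly.

**Windows.** z is averaged over the FOI scales and a 10-s window slides in
1-s steps over the two task blocks concatenated (480 s → 471 windows; the
count floor((T−w)/step)+1 is only consistent with concatenation). Each
window is a symmetric ROI × ROI matrix; its task label is the task covering
the majority of its span, ties to the earlier task.

**State clustering.** Windows are flattened to their 91-feature upper
triangles and clustered under Manhattan (L1) distance, which behaves better
than Euclidean in high-dimensional connectivity spaces. The L1-optimal
centroid is the component-wise median, so the algorithm is k-medians with
Lloyd iterations (objective asserted non-increasing; an emptied cluster is
re-seeded at the farthest point). 1,000 random-initialisation replicates
(configurable; cohort runs in this repository use 100) guard against local
minima. The cluster count is chosen by the elbow of the validity index
(mean within-cluster distance over mean between-centroid distance):
maximum curvature via the second-order difference over interior k, with two
guards — a curve whose minimum is at the smallest k has no elbow and the
minimum wins, and a flat or degenerate curve falls back to the smallest k
with a warning. Clustering is two-level: the cohort's window-by-window mean
series is clustered first, and the group centroids seed one full k-means run
per dyad. States are indexed by descending group-centroid global efficiency,
so state 1 is always the densest pattern.

**Network and temporal metrics.** A state centroid is a weighted graph on
the ROIs (edge weight = synchrony, path length = reciprocal weight, no
sparsity threshold — any threshold would be an invented constant). Global
efficiency is the mean inverse shortest-path length over ordered pairs
(unreachable pairs contribute 0); the characteristic path length is reported
as the harmonic mean of shortest-path lengths, with the arithmetic mean
alongside for audit — the two conventions differ and published magnitudes
depend on unstated toolbox settings, so these metrics are treated as
ordering references, not numeric ones. Temporal metrics per dyad and task:
occurrence rate (fraction of windows per state; sums to 1) and transition
count (adjacent unequal labels, never counted across the task boundary).

**Behaviour.** Fluency is the number of non-redundant responses (normalised
keys, per participant; dyad scores are member sums). Originality gives one
point per response produced by at most 5% of the cohort's participants —
note this is degenerate in cohorts smaller than 20, where even a unique
response exceeds 5%. Flexibility is distinct categories over fluency. The
index of cooperation scans the merged chronological dyad log: `converge`
counts responses whose category repeats the immediately preceding
substantive response ("pass" turns are skipped and do not break the chain),
and `IOC = converge/(group fluency − converge)`. Inter-rater consistency is
Cronbach's α for two raters, `2(1 − (V₁+V₂)/V_total)`.

**Inference.** One-way repeated-measures ANOVA with the classical
within-subject decomposition, partial η² = SS_cond/(SS_cond+SS_err), and
Bonferroni-multiplied paired-t post-hocs. Sphericity corrections are not
applied to the reported statistic (matching the uncorrected degrees of
freedom convention); the Greenhouse–Geisser ε is computed and returned.
Brain–behaviour couplings are Pearson correlations.

**Pseudogroup permutation.** Participants are re-paired into sham dyads
(never reproducing a real pairing; each permutation is a perfect matching),
the windowed-coherence and clustering stages are re-run per sham cohort with
the real cohort's FOI and k (re-deriving a FOI per permutation is often
ill-defined because pseudo-FOIs can be empty), and three tests are recorded
per permutation at α = 0.05: the state global-efficiency RM-ANOVA, the state
occurrence RM-ANOVA, and the originality–occurrence correlations. The
report gives the proportion of permutations with no significant effect.
Per-participant wavelet transforms are cached across permutations, and
coherence is evaluated only on FOI-adjacent scales (padded by the
scale-smoothing half-width, which leaves FOI-band values identical to a
full-grid run).

## Synthetic cohorts

The generator emulates a standard dyadic hyperscanning protocol: 10 Hz sampling, 13
ROIs per participant (prefrontal + right temporo-parietal labels), a 2-min
rest / two 5-min task / 1-min rest session plan, and a latent semi-Markov
coupling-state sequence (geometric dwells, no self-transitions, default mean
dwell 20 s; recovery studies in this repository use 45 s so that 10-s
windows resolve the dwells). During task, every ROI pair coupled in the
active state receives a shared band-limited (0.10–0.19 Hz) Gaussian process,
dyad-common with a fresh realisation per dwell, amplitude equal to the
coupling strength (dense state 0.8, sparse 0.1); during rest the amplitude
is scaled by 0.05. Optional per-session state preferences and dwell means
let a "creative" block favour the dense state and switch faster than its
control. Nuisance structure per channel: 1/f drift below 0.01 Hz, a Mayer
wave near 0.1 Hz — deliberately inside the band of interest, amplitude kept
small (0.15) as a documented confound knob — respiration near 0.3 Hz,
cardiac pulsation near 1.2 Hz with phase jitter, white noise, and Poisson
motion spikes (0.5/min, exponential decay) shared between chromophores. HbR
is `hbr_ratio` (−0.5) times clean HbO plus independent noise. All generation
is deterministic under a seed. Behaviour logs alternate speakers with
Zipf-weighted response keys (so cohort-level originality has rare/common
structure) and a convergence probability that can be tied to dense-state
occupancy, planting a brain–behaviour correlation.

One consequence of the edge-process coupling model is worth knowing: each
coupled ROI pair gets its own latent process, so an ROI coupled to many
partners carries a sum of independent processes and the *per-pair* shared
fraction of its variance — hence the observable pairwise coherence — falls
with its coupling degree. Dense states at high ROI counts therefore show
weaker per-pair coherence contrast than the same topology at few ROIs,
which lowers window-label recovery at the full 13-ROI geometry relative to
the 6-ROI recovery studies. A latent-factor (component-level) coupling
model would avoid the dilution but could not express arbitrary edge
topologies; expressiveness was preferred.

What the generator does **not** emulate: optical physics and channel
geometry, between-participant heterogeneity in SNR or physiology, speech
acoustics, non-stationary artifact regimes, and any time-locking of state
sequences across dyads. Passing recovery tests therefore show that the
pipeline recovers the model's own planted structure at realistic noise
levels — not that real recordings satisfy the model.

## Problem sizes and tolerances

Recovery suites run at 3–6 ROIs and 6–20 dyads with the full-length session
plan; these sizes were chosen for the statistical power each test needs
(the FOI threshold p < 5·10⁻⁶ presumes a cohort-scale paired t-test, so
band-recovery cohorts use 16–27 dyads), while the main acceptance run keeps
the full 13-ROI geometry at 16 dyads. Cohort-path wavelet transforms run in
single precision (coherence is insensitive at the 10⁻⁶ level; the R² ≤ 1
bound is then asserted at 10⁻³ instead of 10⁻⁶). Band-limited dwell
processes are spectrally synthesised on grids of at least 4096 samples; a
10–45 s dwell cannot be narrowband (Δf ≈ 1/T), so state-switching cohorts
inject a band that is intrinsically blurred — the leaked low-frequency
content is genuinely shared between participants and the band selection
correctly detects it. Band-recovery studies therefore use continuous
task-long coupling (one state), for which the injected band is sharp; even
then the scale-domain boxcar spreads detectable coherence by ±0.3 octave
per side, which bounds the attainable band-overlap Jaccard well below 1 and
is why recovery is scored by overlap rather than edge equality (the band's
geometric centre, by contrast, is recovered almost exactly).

## Known limitations

* **Limits of the pseudogroup logic under a true null.** On a fully
  uncoupled synthetic cohort (100 permutations), the occurrence RM-ANOVA is
  approximately calibrated (93–96% of permutations non-significant across
  runs — slightly anti-conservative), but the global-efficiency RM-ANOVA is
  significant in essentially every permutation (1–3% non-significant):
  clustering windows by similarity
  and then comparing cluster-conditional network density is circular —
  even exchangeable noise splits into ordered dense/mid/sparse states
  consistently across dyads. The omnibus F is invariant to state
  relabeling, so this is not an artifact of the efficiency-based state
  ordering; the full-k-means and labeling-only dyad variants behave
  identically. The originality-correlation test lands at 85–90%
  non-significant, which matches the ~1 − 0.95³ false-positive rate
  implied by flagging a permutation when *any* of the three states'
  correlations reaches uncorrected α = 0.05; under that reading a ≥95%
  non-significance rate is unreachable for any correctly calibrated test
  family. The corresponding acceptance tests are left failing rather than
  weakened; a permutation scheme that validates state *structure* would
  need a non-circular statistic (e.g., real-vs-sham within-cluster cost)
  and a single pre-registered correlation per permutation.
* The published globE/Lp magnitudes depend on unreported graph-toolbox
  conventions (the printed path lengths are not reciprocals of the printed
  efficiencies); both metric variants are reported and only orderings are
  asserted.
* The elbow criterion is unreliable on group-mean series when dyads' state
  sequences are not time-locked (averaging washes out state structure);
  recovery runs therefore fix k at the planted count. Elbow selection is
  validated separately on well-separated data, and on *individual* dyads'
  window series — where the planted structure survives — the per-dyad
  elbow does recover the planted state count.
* Whether the original analysis transformed R or R², and how it handled the
  cone of influence, is unstated; both choices here (R, retain-and-flag) are
  conventions and are monotone-neutral for clustering.
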