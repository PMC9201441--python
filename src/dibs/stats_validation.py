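"""Inferential layer: repeated-measures ANOVA, brain-behaviour correlations,
and the pseudogroup permutation null.

The one-way repeated-measures ANOVA uses the classical within-subject
decomposition SS_total = SS_conditions + SS_subjects + SS_error with
F = MS_conditions / MS_error on (c-1, (c-1)(n-1)) degrees of freedom and
effect size partial eta^2 = SS_cond / (SS_cond + SS_err).  Sphericity
corrections are not applied to the reported statistic (degrees of freedom are
left uncorrected), but the Greenhouse-Geisser epsilon is computed and
returned for transparency.  Post-hoc pairwise comparisons are paired t-tests
with Bonferroni-multiplied p-values capped at 1.

The pseudogroup validation re-pairs participants into sham dyads that never
actually interacted (the real pairing is excluded), re-runs the windowed
coherence -> state clustering pipeline for each sham cohort using the real
cohort's FOI and cluster count, and records whether the state effects
(global-efficiency ANOVA, occurrence ANOVA) and the originality correlation
reach significance.  Genuine interaction-driven effects should vanish in the
sham cohorts: the report's headline numbers are the proportions of
permutations with no significant effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .coherence import WaveletSpec
from .ibs_dynamics import (
    FOIBand,
    channels_to_roi,
    expanded_scale_idx,
    pair_table_from_transforms,
    participant_transforms,
    restrict_foi,
    window_ibs,
)
from .network_metrics import centroid_to_graph, global_efficiency
from .states import cluster_group_then_dyads
from .synthgen import DyadRecording

__all__ = [
    "RmAnovaResult",
    "PermutationReport",
    "rm_anova_oneway",
    "brain_behavior_correlation",
    "pseudogroup_permutation",
    "random_pseudo_matching",
]


@dataclass
class RmAnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float
    condition_means: np.ndarray
    posthoc: dict[tuple[int, int], float]
    gg_epsilon: float
    ss: dict[str, float]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"F({self.df[0]}, {self.df[1]}) = {self.F:.2f}, p = {self.p:.4g}, "
            f"partial eta^2 = {self.partial_eta_sq:.3f}"
        )


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the condition covariance."""
    k = data.shape[1]
    s = np.cov(data, rowvar=False)
    # double-center
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    lam = np.linalg.eigvalsh(s_dc)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    return float(min(1.0, lam.sum() ** 2 / ((k - 1) * (lam**2).sum())))


def rm_anova_oneway(data: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions
    matrix.

    Missing cells raise (no imputation).  Degenerate data with zero error
    variance yields F = inf (p = 0) unless the condition effect is also zero,
    in which case F = 0.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    n, c = data.shape
    if c < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed")
    gm = data.mean()
    col_means = data.mean(axis=0)
    row_means = data.mean(axis=1)
    ss_cond = n * np.sum((col_means - gm) ** 2)
    ss_subj = c * np.sum((row_means - gm) ** 2)
    ss_tot = np.sum((data - gm) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = c - 1, (c - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat = 0.0 if ms_cond == 0 else float("inf")
    else:
        f_stat = ms_cond / ms_err
    p = float(stats.f.sf(f_stat, df_cond, df_err)) if np.isfinite(f_stat) else 0.0
    denom = ss_cond + ss_err
    pes = float(ss_cond / denom) if denom > 0 else 0.0
    n_pairs = c * (c - 1) // 2
    posthoc: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(c), 2):
        if np.ptp(data[:, i] - data[:, j]) == 0:
            p_ij = 1.0 if np.allclose(data[:, i], data[:, j]) else 0.0
        else:
            p_ij = float(stats.ttest_rel(data[:, i], data[:, j]).pvalue)
        posthoc[(i, j)] = min(1.0, p_ij * n_pairs)
    return RmAnovaResult(
        F=float(f_stat),
        df=(df_cond, df_err),
        p=p,
        partial_eta_sq=pes,
        condition_means=col_means,
        posthoc=posthoc,
        gg_epsilon=_gg_epsilon(data),
        ss={"conditions": float(ss_cond), "subjects": float(ss_subj),
            "error": float(ss_err), "total": float(ss_tot)},
    )


def brain_behavior_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p between paired dyad-level vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError("need n >= 4 dyads for a meaningful correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        import warnings

        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


Participant = tuple[int, int]  # (dyad index, member 1 or 2)


def random_pseudo_matching(
    n_dyads: int, rng: np.random.Generator, max_tries: int = 10_000
) -> list[tuple[Participant, Participant]]:
    """Random perfect matching of the 2 * n_dyads participants in which no
    sham pair reproduces a real dyad pairing."""
    if n_dyads < 2:
        raise ValueError("cohort too small to avoid real pairings")
    people: list[Participant] = [(d, m) for d in range(n_dyads) for m in (1, 2)]
    for _ in range(max_tries):
        perm = rng.permutation(len(people))
        pairs = [(people[perm[i]], people[perm[i + 1]]) for i in range(0, len(people), 2)]
        if all(a[0] != b[0] for a, b in pairs):
            return pairs
    raise RuntimeError("failed to draw a pseudo matching avoiding real pairs")


@dataclass
class PermutationReport:
    n_permutations: int
    alpha: float
    records: pd.DataFrame  # columns: perm, test, p, significant
    proportions_nonsignificant: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.proportions_nonsignificant:
            self.proportions_nonsignificant = {
                test: float(1.0 - grp["significant"].mean())
                for test, grp in self.records.groupby("test")
            }


def pseudogroup_permutation(
    recordings: list[DyadRecording],
    originality: dict[Participant, float] | None,
    spec: WaveletSpec,
    foi: FOIBand,
    k: int,
    window_length: float = 10.0,
    step: float = 1.0,
    n_perm: int = 300,
    seed: int = 0,
    alpha: float = 0.05,
    n_replicates: int = 20,
    annotations: list[tuple[str, float, float]] | None = None,
) -> PermutationReport:
    """Permutation null from sham (pseudo) dyads.

    ``recordings`` must already be preprocessed.  Every permutation re-pairs
    the participants (excluding real pairings), recomputes windowed FOI-band
    coherence for each sham dyad, reruns the two-level clustering with the
    real cohort's ``k``, and tests: (1) RM-ANOVA of state global efficiency,
    (2) RM-ANOVA of state occurrence rates, and (3) Pearson correlations
    between sham-dyad originality (member sum) and each state's occurrence
    (significant if any state's p < alpha).  The third test is skipped when
    ``originality`` is None.

    Per-participant wavelet transforms are cached across permutations and the
    coherence is evaluated only on FOI-adjacent scales, which leaves FOI-band
    values identical to a full-grid run.
    """
    if foi.empty:
        raise ValueError("cannot run the permutation with an empty FOI")
    n_dyads = len(recordings)
    if 2 * n_dyads < 4:
        raise ValueError("need >= 4 participants")
    rng = np.random.default_rng(seed)
    ext_idx, inner_idx = expanded_scale_idx(foi, spec)
    restricted_foi = restrict_foi(foi, inner_idx)

    cache: dict[Participant, tuple[np.ndarray, np.ndarray]] = {}
    for d, rec in enumerate(recordings):
        series = channels_to_roi(rec)
        for m in (1, 2):
            cache[(d, m)] = participant_transforms(series[m], spec, ext_idx)

    template = recordings[0]
    ann = list(annotations if annotations is not None else template.annotations)
    rows = []
    for perm in range(n_perm):
        pairs = random_pseudo_matching(n_dyads, rng)
        window_series = []
        for pi, (a, b) in enumerate(pairs):
            wa, pa = cache[a]
            wb, pb = cache[b]
            table = pair_table_from_transforms(
                (wa, pa, wb, pb),
                spec,
                n_rois=len(template.rois),
                dyad_id=f"pseudo{pi:02d}",
                annotations=ann,
                sampling_rate=template.sampling_rate,
                scale_idx=ext_idx,
            )
            window_series.append(window_ibs(table, restricted_foi, window_length, step))
        partition = cluster_group_then_dyads(
            window_series, k=k, n_replicates=n_replicates, seed=seed + perm
        )
        globe = np.array(
            [
                [
                    global_efficiency(centroid_to_graph(partition.dyad_centroids[s.dyad_id][st]))
                    for st in range(k)
                ]
                for s in window_series
            ]
        )
        res_globe = rm_anova_oneway(globe)
        rows.append({"perm": perm, "test": "globE_anova", "p": res_globe.p,
                     "significant": res_globe.p < alpha})
        occ = np.array(
            [
                [
                    float(np.mean(partition.dyad_labels[s.dyad_id] == st))
                    for st in range(k)
                ]
                for s in window_series
            ]
        )
        res_occ = rm_anova_oneway(occ)
        rows.append({"perm": perm, "test": "occurrence_anova", "p": res_occ.p,
                     "significant": res_occ.p < alpha})
        if originality is not None:
            orig = np.array([originality[a] + originality[b] for a, b in pairs])
            p_min = 1.0
            for st in range(k):
                _, p_r = brain_behavior_correlation(occ[:, st], orig)
                if np.isfinite(p_r):
                    p_min = min(p_min, p_r)
            rows.append({"perm": perm, "test": "originality_correlation", "p": p_min,
                         "significant": p_min < alpha})
    return PermutationReport(
        n_permutations=n_perm, alpha=alpha, records=pd.DataFrame(rows)
    )
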