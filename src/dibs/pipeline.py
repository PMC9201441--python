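"""End-to-end pipeline orchestration.

Stage order follows the analysis design: preprocess -> wavelet coherence ->
ROI pairing / FOI selection -> sliding windows -> state clustering -> state &
network metrics -> behavioural scoring & inferential statistics -> optional
pseudogroup permutation.  Every run writes tidy CSV/JSON artifacts with a
provenance record (config hash, seed, package version) and is idempotent
under an identical configuration.

Two passes are made over the coherence computation: a full-scale-grid pass
whose period-averaged profiles drive FOI selection, and a band-restricted
pass that produces the windowed series.  The restriction pads the FOI by the
scale-smoothing half-width, so band values match the full-grid computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import ResponseLog, compute_ioc, score_fluency, score_originality
from .coherence import WaveletSpec
from .ibs_dynamics import (
    EmptyFOIError,
    FOIBand,
    IBSWindowSeries,
    expanded_scale_idx,
    period_profiles,
    restrict_foi,
    roi_pair_coherence,
    select_foi_from_profiles,
    window_ibs,
)
from .io import PipelineConfig, config_hash
from .network_metrics import state_metrics_frame
from .preprocess import PreprocessConfig, preprocess_recording, trim_annotations
from .states import StatePartition, cluster_group_then_dyads
from .stats_validation import (
    PermutationReport,
    brain_behavior_correlation,
    pseudogroup_permutation,
    rm_anova_oneway,
)
from .synthgen import DyadRecording, SimConfig, default_state_topologies, generate_cohort

__all__ = ["PipelineResult", "sim_config_from_section", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    config: PipelineConfig
    recordings: list[DyadRecording]
    foi: FOIBand
    window_series: list[IBSWindowSeries]
    partition: StatePartition
    metrics: pd.DataFrame
    behavior: pd.DataFrame | None = None
    anova_results: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    permutation: PermutationReport | None = None


def sim_config_from_section(cfg: PipelineConfig) -> SimConfig:
    s = cfg.sim
    coupling = default_state_topologies(
        s.n_states, s.n_rois, strong=s.coupling_strong, weak=s.coupling_weak
    )
    kwargs = dict(
        sampling_rate=s.sampling_rate,
        n_rois=s.n_rois,
        n_states=s.n_states,
        state_dwell_mean=s.state_dwell_mean,
        coupling_band=tuple(s.coupling_band),
        coupling_strength=coupling,
        rest_coupling_scale=s.rest_coupling_scale,
        motion_rate=s.motion_rate,
        hbr_ratio=s.hbr_ratio,
        seed=cfg.seed,
    )
    if s.session_plan is not None:
        kwargs["session_plan"] = tuple((str(a), float(b)) for a, b in s.session_plan)
    return SimConfig(**kwargs)


def wavelet_spec_from_config(cfg: PipelineConfig, sampling_rate: float) -> WaveletSpec:
    return WaveletSpec(
        sampling_rate=sampling_rate,
        omega0=cfg.wavelet.omega0,
        voices_per_octave=cfg.wavelet.voices_per_octave,
        freq_min=cfg.wavelet.freq_min,
        freq_max=cfg.wavelet.freq_max,
    )


def _behavior_frame(
    logs: list[tuple[ResponseLog, ResponseLog]], recordings: list[DyadRecording]
) -> pd.DataFrame:
    """Cohort behaviour scores: fluency, originality, flexibility, IOC."""
    aut_keys: list[set[str]] = []
    for aut, _ in logs:
        for sp in (1, 2):
            aut_keys.append(set(aut.participant_keys(sp)))
    orig = score_originality(aut_keys)
    rows = []
    for d, (aut, oct_log) in enumerate(logs):
        flu = score_fluency(aut)
        try:
            converge, ioc = compute_ioc(aut)
        except ZeroDivisionError:
            # degenerate tiny log (every response converged); score as missing
            converge, ioc = len(aut.substantive()) - 1, float("nan")
        flu_oct = score_fluency(oct_log)
        rows.append(
            {
                "dyad": recordings[d].dyad_id,
                "aut_fluency": flu[1] + flu[2],
                "aut_originality": orig[2 * d] + orig[2 * d + 1],
                "oct_fluency": flu_oct[1] + flu_oct[2],
                "converge": converge,
                "ioc": ioc,
                "originality_p1": orig[2 * d],
                "originality_p2": orig[2 * d + 1],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    recordings: list[DyadRecording] | None = None,
    behavior_logs: list[tuple[ResponseLog, ResponseLog]] | None = None,
    out_dir: str | Path | None = None,
    run_permutation: bool = False,
) -> PipelineResult:
    """Execute the full analysis; simulate a cohort when no data is given.

    Raises :class:`EmptyFOIError` when no frequency band shows task > rest
    synchrony — there is nothing meaningful to window in that case.
    """
    if recordings is None:
        sim_cfg = sim_config_from_section(config)
        recordings, behavior_logs = generate_cohort(sim_cfg, config.sim.n_dyads, seed=config.seed)

    pp_cfg = PreprocessConfig(
        n_components_removed=config.preprocess.n_components_removed,
        trim_head=config.preprocess.trim_head,
        trim_tail=config.preprocess.trim_tail,
        cbsi_enabled=config.preprocess.cbsi_enabled,
    )
    # spatial filter + CBSI; trims become annotation masks so the coherence
    # below runs on a continuous signal (see preprocess.trim_annotations)
    pre = [preprocess_recording(r, pp_cfg, splice=False) for r in recordings]
    trimmed_ann = trim_annotations(pre[0].annotations, pp_cfg)
    spec = wavelet_spec_from_config(config, pre[0].sampling_rate)

    # pass 1: full scale grid, reduced straight to period profiles (keeping
    # every dyad's full scale x time table in memory would not scale)
    task_profiles, rest_profiles = [], []
    for r in pre:
        table = roi_pair_coherence(r, spec, annotations=trimmed_ann)
        tp, rp = period_profiles(table)
        task_profiles.append(tp)
        rest_profiles.append(rp)
        del table
    foi = select_foi_from_profiles(
        np.stack(task_profiles), np.stack(rest_profiles), spec.frequencies,
        p_threshold=config.foi.p_threshold,
    )
    if foi.empty:
        raise EmptyFOIError(
            "no scale shows significantly higher task-period synchrony than rest; "
            "halting before windowing"
        )
    # pass 2: recompute on FOI-adjacent scales only (identical band values)
    ext_idx, inner_idx = expanded_scale_idx(foi, spec)
    foi_restricted = restrict_foi(foi, inner_idx)
    window_series = []
    for r in pre:
        table = roi_pair_coherence(r, spec, scale_idx=ext_idx, annotations=trimmed_ann)
        window_series.append(
            window_ibs(table, foi_restricted, config.window.length, config.window.step)
        )
        del table

    k_range = (config.clustering.k_min, config.clustering.k_max)
    partition = cluster_group_then_dyads(
        window_series,
        k=config.clustering.k,
        k_range=k_range,
        n_replicates=config.clustering.n_replicates,
        seed=config.seed,
    )
    metrics = state_metrics_frame(partition)

    anova_results: dict = {}
    g = metrics.groupby(["dyad", "state"], sort=True)[["globE", "Lp", "occurrence"]].mean()
    globe_mat = g["globE"].unstack().to_numpy()
    lp_mat = g["Lp"].unstack().to_numpy()
    if np.isfinite(globe_mat).all() and globe_mat.shape[0] >= 3:
        anova_results["globE_states"] = rm_anova_oneway(globe_mat)
        anova_results["Lp_states"] = rm_anova_oneway(lp_mat)
    occ_all = g["occurrence"].unstack().to_numpy()
    if occ_all.shape[0] >= 3:
        anova_results["occurrence_states"] = rm_anova_oneway(occ_all)
    tasks = sorted(metrics["task"].unique())
    if len(tasks) == 2:
        for s in range(1, partition.k + 1):
            sub = metrics[metrics["state"] == s].pivot(
                index="dyad", columns="task", values="occurrence"
            )[tasks]
            if sub.shape[0] >= 3:
                anova_results[f"occurrence_task_state{s}"] = rm_anova_oneway(sub.to_numpy())
        trans = metrics.drop_duplicates(["dyad", "task"]).pivot(
            index="dyad", columns="task", values="transitions"
        )[tasks]
        if trans.shape[0] >= 3:
            anova_results["transitions_task"] = rm_anova_oneway(trans.to_numpy())

    behavior_df = None
    correlations: dict = {}
    if behavior_logs:
        behavior_df = _behavior_frame(behavior_logs, recordings)
        occ_state1 = (
            metrics[metrics["state"] == 1].groupby("dyad", sort=True)["occurrence"].mean()
        )
        beh = behavior_df.set_index("dyad").loc[occ_state1.index]
        if len(occ_state1) >= 4:
            correlations["state1_originality"] = brain_behavior_correlation(
                occ_state1.to_numpy(), beh["aut_originality"].to_numpy()
            )
            ioc_vals = beh["ioc"].to_numpy()
            finite = np.isfinite(ioc_vals)
            if finite.sum() >= 4:
                correlations["state1_ioc"] = brain_behavior_correlation(
                    occ_state1.to_numpy()[finite], ioc_vals[finite]
                )

    permutation = None
    if run_permutation:
        originality = None
        if behavior_df is not None:
            originality = {}
            for d in range(len(recordings)):
                originality[(d, 1)] = float(behavior_df["originality_p1"].iloc[d])
                originality[(d, 2)] = float(behavior_df["originality_p2"].iloc[d])
        permutation = pseudogroup_permutation(
            pre,
            originality,
            spec,
            foi,
            k=partition.k,
            window_length=config.window.length,
            step=config.window.step,
            n_perm=config.stats.n_permutations,
            seed=config.seed,
            alpha=config.stats.alpha,
            n_replicates=config.stats.permutation_replicates,
            annotations=trimmed_ann,
        )

    result = PipelineResult(
        config=config,
        recordings=recordings,
        foi=foi,
        window_series=window_series,
        partition=partition,
        metrics=metrics,
        behavior=behavior_df,
        anova_results=anova_results,
        correlations=correlations,
        permutation=permutation,
    )
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "state_metrics.csv", index=False)
    if result.behavior is not None:
        result.behavior.to_csv(out / "behavior_scores.csv", index=False)
    labels_rows = []
    for dyad_id, labels in result.partition.dyad_labels.items():
        for w, (lab, task) in enumerate(zip(labels, result.partition.task_labels)):
            labels_rows.append({"dyad": dyad_id, "window": w, "task": task, "state": int(lab) + 1})
    pd.DataFrame(labels_rows).to_csv(out / "state_labels.csv", index=False)
    np.save(out / "group_centroids.npy", result.partition.group_centroids)
    with open(out / "foi.json", "w") as f:
        json.dump(result.foi.to_dict(), f, indent=2)
    if result.partition.validity_curve:
        pd.DataFrame(
            sorted(result.partition.validity_curve.items()), columns=["k", "validity_index"]
        ).to_csv(out / "validity_curve.csv", index=False)
    stats_payload = {
        name: {
            "F": r.F,
            "df": list(r.df),
            "p": r.p,
            "partial_eta_sq": r.partial_eta_sq,
            "condition_means": [float(v) for v in r.condition_means],
            "gg_epsilon": r.gg_epsilon,
        }
        for name, r in result.anova_results.items()
    }
    stats_payload["correlations"] = {
        name: {"r": rv, "p": pv} for name, (rv, pv) in result.correlations.items()
    }
    with open(out / "stats.json", "w") as f:
        json.dump(stats_payload, f, indent=2)
    if result.permutation is not None:
        result.permutation.records.to_csv(out / "permutation_report.csv", index=False)
        with open(out / "permutation_summary.json", "w") as f:
            json.dump(
                {
                    "n_permutations": result.permutation.n_permutations,
                    "alpha": result.permutation.alpha,
                    "proportions_nonsignificant": result.permutation.proportions_nonsignificant,
                },
                f,
                indent=2,
            )
    with open(out / "provenance.json", "w") as f:
        json.dump(
            {
                "config_hash": config_hash(result.config),
                "seed": result.config.seed,
                "version": __version__,
                "k": result.partition.k,
                "n_dyads": len(result.recordings),
            },
            f,
            indent=2,
        )
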