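"""ROI-level inter-brain synchrony: pair tables, FOI selection, windowing.

A dyad's IBS is computed between every ordered cross-participant ROI pairing
(participant 1's ROI i against participant 2's ROI j).  Because the pairing
IFG(1)-AG(2) and AG(1)-IFG(2) measure the same unordered combination, their
Fisher-z coherence maps are averaged, reducing n^2 ordered pairings to
n(n+1)/2 unordered combinations (91 for 13 ROIs; the n homologous i-i
pairings sit on the diagonal and are single maps).

The frequency band of interest (FOI) is selected empirically: per scale and
ROI combination, a paired t-test across dyads compares task-period against
rest-period mean synchrony over 0.01-0.7 Hz; scales where any combination is
significantly task > rest (default p < 5e-6, uncorrected — the test only
picks the band, it is not an endpoint) form the band, taking the largest
contiguous run.

Windowing averages z-coherence over the FOI scales and slides a window
(default 10 s, 1 s step) over the concatenated task period, yielding one
symmetric ROI x ROI matrix per window: 480 s of task data gives 471 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coherence import (
    WaveletSpec,
    coherence_from_transforms,
    cwt_morlet,
    fisher_z,
    smoothed_autopower,
)
from .synthgen import DyadRecording

__all__ = [
    "ROIPairTable",
    "FOIBand",
    "IBSWindowSeries",
    "EmptyFOIError",
    "channels_to_roi",
    "participant_transforms",
    "build_roi_pair_table",
    "roi_pair_coherence",
    "select_foi",
    "window_ibs",
    "n_pair_combinations",
]


class EmptyFOIError(RuntimeError):
    """No scale shows significantly higher task-period synchrony than rest."""


def n_pair_combinations(n_rois: int) -> int:
    """Unordered cross-brain ROI combinations, diagonal included."""
    return n_rois * (n_rois + 1) // 2


def pair_index(n_rois: int) -> list[tuple[int, int]]:
    """Upper-triangle (i <= j) pair ordering used throughout."""
    return [(i, j) for i in range(n_rois) for j in range(i, n_rois)]


@dataclass
class ROIPairTable:
    """Fisher-z coherence per unordered ROI combination for one dyad.

    ``z`` has shape (n_pairs, n_scales, n_times) in upper-triangle pair order;
    stored as float32 (91 x ~75 x ~7800 doubles would be needlessly large).
    """

    dyad_id: str
    n_rois: int
    z: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    annotations: list[tuple[str, float, float]]
    sampling_rate: float
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            self.pairs = pair_index(self.n_rois)
        if self.z.shape[0] != n_pair_combinations(self.n_rois):
            raise ValueError(
                f"expected {n_pair_combinations(self.n_rois)} pair entries, got {self.z.shape[0]}"
            )

    @property
    def n_pairs(self) -> int:
        return self.z.shape[0]


@dataclass
class FOIBand:
    """Selected frequency band of interest with its supporting statistics."""

    f_lo: float
    f_hi: float
    scale_idx: np.ndarray  # indices into the spec's scale grid
    t_stats: np.ndarray  # (n_pairs, n_scales)
    p_values: np.ndarray
    p_threshold: float
    n_dyads: int

    @property
    def empty(self) -> bool:
        return self.scale_idx.size == 0

    def to_dict(self) -> dict:
        return {
            "f_lo": self.f_lo,
            "f_hi": self.f_hi,
            "n_scales": int(self.scale_idx.size),
            "scale_idx": [int(s) for s in self.scale_idx],
            "p_threshold": self.p_threshold,
            "n_dyads": self.n_dyads,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FOIBand":
        return cls(
            f_lo=float(payload["f_lo"]),
            f_hi=float(payload["f_hi"]),
            scale_idx=np.asarray(payload["scale_idx"], dtype=int),
            t_stats=np.array([]),
            p_values=np.array([]),
            p_threshold=float(payload["p_threshold"]),
            n_dyads=int(payload["n_dyads"]),
        )


@dataclass
class IBSWindowSeries:
    """Chronological stack of symmetric windowed IBS matrices for one dyad."""

    dyad_id: str
    windows: np.ndarray  # (n_windows, n_rois, n_rois)
    window_starts: np.ndarray  # s, on the concatenated task time axis
    task_labels: list[str]  # per window
    window_length: float
    step: float
    rois: list[str] | None = None

    def __post_init__(self) -> None:
        if self.windows.ndim != 3 or self.windows.shape[1] != self.windows.shape[2]:
            raise ValueError("windows must be (n_windows, n_rois, n_rois)")
        if not np.allclose(self.windows, np.swapaxes(self.windows, 1, 2), atol=1e-9):
            raise ValueError("window matrices must be symmetric")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def channels_to_roi(recording: DyadRecording) -> dict[int, np.ndarray]:
    """Average member channels into ROI series, per participant.

    Returns participant -> (n_rois, n_samples) in ``recording.rois`` order.
    """
    ch_idx: dict[str, list[int]] = {r: [] for r in recording.rois}
    for ci, ch in enumerate(recording.channels):
        ch_idx[recording.channel_roi[ch]].append(ci)
    empty = [r for r, idxs in ch_idx.items() if not idxs]
    if empty:
        raise ValueError(f"ROIs without any channel: {empty}")
    out = {}
    for p in (1, 2):
        out[p] = np.stack([recording.hbo[p][ch_idx[r]].mean(axis=0) for r in recording.rois])
    return out


def participant_transforms(
    roi_series: np.ndarray, spec: WaveletSpec, scale_idx: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI Morlet CWT and smoothed auto-power for one participant.

    ``scale_idx`` restricts the retained scales (the CWT is still computed on
    the full grid, so smoothing across scales sees its neighbours); used to
    keep cohort-scale permutation runs affordable.  Returns ``(W, P)`` with
    shapes (n_rois, n_scales_kept, n_times).
    """
    scales = None if scale_idx is None else spec.scales[scale_idx]
    ws, ps = [], []
    for x in roi_series:
        w = cwt_morlet(x, spec)
        if scale_idx is not None:
            w = w[scale_idx]
        # single precision: cohort-scale runs are FFT-bound and coherence is
        # insensitive at the 1e-6 level; auto-power is smoothed on the same
        # (possibly restricted) grid as the cross-spectra so numerator and
        # denominator share one kernel
        w = w.astype(np.complex64)
        p = smoothed_autopower(w, spec, scales=scales)
        ws.append(w)
        ps.append(p)
    return np.stack(ws), np.stack(ps)


def build_roi_pair_table(
    z_ordered: np.ndarray,
    n_rois: int,
    dyad_id: str = "",
    frequencies: np.ndarray | None = None,
    times: np.ndarray | None = None,
    annotations: list | None = None,
    sampling_rate: float = 1.0,
) -> ROIPairTable:
    """Reduce ordered cross-participant pairings to the unordered table.

    ``z_ordered`` is (n_rois, n_rois, ...) with entry [i, j] the z-coherence
    of participant 1's ROI i against participant 2's ROI j.  Off-diagonal
    combinations average the two reciprocal orderings; the result is invariant
    to swapping participants (transposing the first two axes).
    """
    z_ordered = np.asarray(z_ordered)
    if z_ordered.shape[:2] != (n_rois, n_rois):
        raise ValueError("z_ordered must be (n_rois, n_rois, ...)")
    if np.isnan(z_ordered).any():
        bad = np.argwhere(np.isnan(z_ordered).reshape(n_rois, n_rois, -1).any(axis=2))
        raise ValueError(f"missing ordered pairings: {[tuple(b) for b in bad[:5]]}")
    rows = []
    for i, j in pair_index(n_rois):
        if i == j:
            rows.append(z_ordered[i, i])
        else:
            rows.append(0.5 * (z_ordered[i, j] + z_ordered[j, i]))
    return ROIPairTable(
        dyad_id=dyad_id,
        n_rois=n_rois,
        z=np.stack(rows).astype(np.float32),
        frequencies=frequencies if frequencies is not None else np.array([]),
        times=times if times is not None else np.array([]),
        annotations=annotations or [],
        sampling_rate=sampling_rate,
    )


def pair_table_from_transforms(
    transforms: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    spec: WaveletSpec,
    n_rois: int,
    dyad_id: str,
    annotations: list[tuple[str, float, float]],
    sampling_rate: float,
    scale_idx: np.ndarray | None = None,
) -> ROIPairTable:
    """Pair table from precomputed per-participant transforms ``(W1, P1, W2,
    P2)`` (see :func:`participant_transforms`); the pseudogroup permutation
    caches these and only redoes the cross-spectrum smoothing per pairing."""
    w1, p1, w2, p2 = transforms
    n_scales, n_times = w1.shape[1], w1.shape[2]
    freqs = spec.frequencies if scale_idx is None else spec.frequencies[scale_idx]
    scales = spec.scales if scale_idx is None else spec.scales[scale_idx]
    z = np.empty((n_pair_combinations(n_rois), n_scales, n_times), dtype=np.float32)
    for k, (i, j) in enumerate(pair_index(n_rois)):
        r2_ij = coherence_from_transforms(w1[i], w2[j], p1[i], p2[j], spec, scales=scales)
        z_ij = fisher_z(np.sqrt(r2_ij))
        if i == j:
            z[k] = z_ij
        else:
            r2_ji = coherence_from_transforms(w1[j], w2[i], p1[j], p2[i], spec, scales=scales)
            z[k] = 0.5 * (z_ij + fisher_z(np.sqrt(r2_ji)))
    return ROIPairTable(
        dyad_id=dyad_id,
        n_rois=n_rois,
        z=z,
        frequencies=freqs,
        times=np.arange(n_times) / sampling_rate,
        annotations=list(annotations),
        sampling_rate=sampling_rate,
    )


def roi_pair_coherence(
    recording: DyadRecording,
    spec: WaveletSpec,
    scale_idx: np.ndarray | None = None,
    annotations: list[tuple[str, float, float]] | None = None,
) -> ROIPairTable:
    """Wavelet-coherence pair table for one dyad's HbO ROI series.

    ``annotations`` overrides the recording's session bounds — the pipeline
    passes trimmed task bounds here while keeping the signal continuous.
    """
    series = channels_to_roi(recording)
    w1, p1 = participant_transforms(series[1], spec, scale_idx)
    w2, p2 = participant_transforms(series[2], spec, scale_idx)
    return pair_table_from_transforms(
        (w1, p1, w2, p2),
        spec,
        n_rois=len(recording.rois),
        dyad_id=recording.dyad_id,
        annotations=list(annotations if annotations is not None else recording.annotations),
        sampling_rate=recording.sampling_rate,
        scale_idx=scale_idx,
    )


def _period_mean(table: ROIPairTable, annotations: list[tuple[str, float, float]]) -> np.ndarray:
    """Mean z over each period's time samples, then across periods.

    Averaging per period first (rather than pooling samples) weights a short
    and a long block equally, preventing duration bias.
    """
    fs = table.sampling_rate
    means = []
    for _, a, b in annotations:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        means.append(table.z[:, :, i0:i1].mean(axis=2))
    return np.mean(means, axis=0)


def period_profiles(table: ROIPairTable) -> tuple[np.ndarray, np.ndarray]:
    """(task, rest) mean-z profiles, each (n_pairs, n_scales), for one dyad.

    These small reductions are all FOI selection needs, so cohort loops can
    discard the full scale x time table straight after computing them.
    """
    task_ann = [a for a in table.annotations if a[0].startswith("task")]
    rest_ann = [a for a in table.annotations if not a[0].startswith("task")]
    if not task_ann or not rest_ann:
        raise ValueError(f"dyad {table.dyad_id}: need both task and rest periods")
    return _period_mean(table, task_ann), _period_mean(table, rest_ann)


def select_foi_from_profiles(
    task_arr: np.ndarray,
    rest_arr: np.ndarray,
    frequencies: np.ndarray,
    p_threshold: float = 5e-6,
    n_dyads: int | None = None,
) -> FOIBand:
    """FOI selection from stacked (n_dyads, n_pairs, n_scales) profiles."""
    n_dyads = task_arr.shape[0] if n_dyads is None else n_dyads
    if n_dyads < 3:
        raise ValueError("FOI selection needs >= 3 dyads")
    t_stat, p_val = stats.ttest_rel(
        np.asarray(task_arr, dtype=np.float64), np.asarray(rest_arr, dtype=np.float64), axis=0
    )
    sig_scale = ((p_val < p_threshold) & (t_stat > 0)).any(axis=0)
    in_range = (frequencies >= 0.01) & (frequencies <= 0.7)
    sig_scale = sig_scale & in_range
    runs = _contiguous_runs(sig_scale)
    if not runs:
        return FOIBand(np.nan, np.nan, np.array([], dtype=int), t_stat, p_val,
                       p_threshold, n_dyads)
    best = max(runs, key=len)
    idx = np.asarray(best, dtype=int)
    f = frequencies[idx]
    return FOIBand(float(f.min()), float(f.max()), idx, t_stat, p_val, p_threshold, n_dyads)


def select_foi(tables: list[ROIPairTable], p_threshold: float = 5e-6) -> FOIBand:
    """Data-driven FOI: scales where task synchrony beats rest across dyads.

    Per scale and ROI combination, a paired t-test across dyads compares the
    task-period mean against the rest-period mean (each dyad's task value is
    first averaged across its task blocks).  A scale qualifies when any
    combination passes ``p_threshold`` one-signed (t > 0, task > rest); the
    FOI is the largest contiguous run of qualifying scales.  No
    multiple-comparison correction is applied: the test only locates the
    band, it is not an endpoint.  An all-empty result is returned as an
    ``empty`` FOIBand; downstream windowing raises :class:`EmptyFOIError`.
    """
    profiles = [period_profiles(t) for t in tables]
    task_arr = np.stack([p[0] for p in profiles])
    rest_arr = np.stack([p[1] for p in profiles])
    return select_foi_from_profiles(
        task_arr, rest_arr, tables[0].frequencies, p_threshold, n_dyads=len(tables)
    )


def expanded_scale_idx(foi: FOIBand, spec: WaveletSpec) -> tuple[np.ndarray, np.ndarray]:
    """FOI scale indices padded by the scale-smoothing half-width.

    Coherence computed on the padded grid matches the full-grid values on the
    inner (FOI) scales exactly, because the scale boxcar never reaches past
    the padding.  Returns ``(extended_idx, positions_of_foi_within_extended)``.
    """
    margin = spec.scale_boxcar_size // 2 + 1
    lo = max(0, int(foi.scale_idx.min()) - margin)
    hi = min(spec.scales.size, int(foi.scale_idx.max()) + margin + 1)
    ext = np.arange(lo, hi)
    inner = np.array([np.flatnonzero(ext == s)[0] for s in foi.scale_idx])
    return ext, inner


def restrict_foi(foi: FOIBand, inner_idx: np.ndarray) -> FOIBand:
    """Re-index a FOI onto the extended-scale axis of a restricted table."""
    return FOIBand(
        f_lo=foi.f_lo, f_hi=foi.f_hi, scale_idx=np.asarray(inner_idx, dtype=int),
        t_stats=foi.t_stats, p_values=foi.p_values,
        p_threshold=foi.p_threshold, n_dyads=foi.n_dyads,
    )


def _contiguous_runs(mask: np.ndarray) -> list[list[int]]:
    runs, cur = [], []
    for i, m in enumerate(mask):
        if m:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def band_series(table: ROIPairTable, foi: FOIBand) -> np.ndarray:
    """FOI-averaged z time series per pair, task samples only, concatenated.

    Shape (n_pairs, n_task_samples); the time axis stitches the task blocks
    together in chronological order.
    """
    if foi.empty:
        raise EmptyFOIError("cannot window an empty FOI")
    fs = table.sampling_rate
    segs, labels = [], []
    for label, a, b in table.annotations:
        if not label.startswith("task"):
            continue
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        segs.append(table.z[:, foi.scale_idx, i0:i1].mean(axis=1))
        labels.append((label, i1 - i0))
    return np.concatenate(segs, axis=1)


def _task_sample_labels(table: ROIPairTable) -> list[str]:
    fs = table.sampling_rate
    out: list[str] = []
    for label, a, b in table.annotations:
        if label.startswith("task"):
            out.extend([label] * (int(round(b * fs)) - int(round(a * fs))))
    return out


def window_ibs(
    table: ROIPairTable,
    foi: FOIBand,
    window_length: float = 10.0,
    step: float = 1.0,
) -> IBSWindowSeries:
    """Sliding-window IBS matrices over the concatenated task period.

    Window count follows ``floor((T - window_length)/step) + 1`` (480 s with a
    10 s window and 1 s step gives 471).  Each window's task label is the task
    covering the majority of its span, ties resolved to the earlier task.
    """
    series = band_series(table, foi)  # (n_pairs, T_task)
    sample_labels = _task_sample_labels(table)
    fs = table.sampling_rate
    n_task = series.shape[1]
    w = int(round(window_length * fs))
    s = int(round(step * fs))
    if w > n_task:
        raise ValueError(
            f"window ({window_length:.0f} s) longer than task data ({n_task / fs:.0f} s)"
        )
    starts = np.arange(0, n_task - w + 1, s)
    n_rois = table.n_rois
    iu = np.array(table.pairs)
    windows = np.empty((starts.size, n_rois, n_rois))
    task_labels: list[str] = []
    task_order = []
    for lab in sample_labels:
        if lab not in task_order:
            task_order.append(lab)
    for wi, st in enumerate(starts):
        vals = series[:, st : st + w].mean(axis=1)
        m = np.zeros((n_rois, n_rois))
        m[iu[:, 0], iu[:, 1]] = vals
        m[iu[:, 1], iu[:, 0]] = vals
        windows[wi] = m
        span = sample_labels[st : st + w]
        counts = {lab: span.count(lab) for lab in task_order}
        best = max(counts.values())
        task_labels.append(next(lab for lab in task_order if counts[lab] == best))
    return IBSWindowSeries(
        dyad_id=table.dyad_id,
        windows=windows,
        window_starts=starts / fs,
        task_labels=task_labels,
        window_length=window_length,
        step=step,
        rois=None,
    )
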