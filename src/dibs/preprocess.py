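"""Preprocessing chain for dyadic fNIRS recordings.

Three steps, applied in a fixed order:

1. PCA spatial filter — remove the leading principal component(s) shared
   across channels, which capture systemic physiology (blood pressure,
   respiration, global blood-flow changes) rather than local activity.
2. CBSI — correlation-based signal improvement.  HbO and HbR are expected to
   be anti-correlated; motion artifacts move both the same way.  With
   ``alpha = sd(HbO)/sd(HbR)``, the corrected signals

       hbo' = (hbo - alpha * hbr) / 2,     hbr' = -hbo' / alpha

   are exactly anti-correlated and the common-mode artifact cancels.
3. Session trimming — drop the first and last 30 s of every task block to
   keep only the steady period (two 300-s tasks with 30/30 trims leave 480 s
   of task data).  Rest blocks are kept whole, as they serve as the baseline
   in frequency-band selection.

All three operations are pure functions of their input arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .synthgen import DyadRecording

__all__ = [
    "PreprocessConfig",
    "CBSIResult",
    "pca_spatial_filter",
    "cbsi_correct",
    "apply_cbsi",
    "trim_sessions",
    "trim_annotations",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    n_components_removed: int = 1
    trim_head: float = 30.0
    trim_tail: float = 30.0
    cbsi_enabled: bool = True

    def __post_init__(self) -> None:
        if self.trim_head < 0 or self.trim_tail < 0:
            raise ValueError("trims must be non-negative")
        if self.n_components_removed < 0:
            raise ValueError("n_components_removed must be >= 0")


class CBSIResult(NamedTuple):
    hbo: np.ndarray
    hbr: np.ndarray
    alpha: float


def _remove_components(x: np.ndarray, n_components: int) -> np.ndarray:
    """Project the top ``n_components`` spatial principal components out of a
    channels x time matrix (uncentred SVD, so a shared offset counts as
    structure too)."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    keep = s.copy()
    keep[:n_components] = 0.0
    return u @ (keep[:, None] * vt)


def pca_spatial_filter(recording: DyadRecording, n_components: int | None = None,
                       config: PreprocessConfig | None = None) -> DyadRecording:
    """Remove global (systemic) spatial components per participant and
    chromophore.

    Zero-variance channels cannot contribute to the decomposition; they are
    passed through unchanged with a warning.  Output channel variance never
    exceeds input variance.
    """
    if n_components is None:
        n_components = (config or PreprocessConfig()).n_components_removed
    n_channels = len(recording.channels)
    if n_channels < 2:
        raise ValueError("spatial filtering needs >= 2 channels")
    if n_components >= n_channels:
        raise ValueError("n_components must be smaller than the channel count")
    if n_components == 0:
        return replace(recording, hbo={p: a.copy() for p, a in recording.hbo.items()},
                       hbr={p: a.copy() for p, a in recording.hbr.items()})
    new_hbo, new_hbr = {}, {}
    for attr, store in (("hbo", new_hbo), ("hbr", new_hbr)):
        for p, x in getattr(recording, attr).items():
            x = np.asarray(x, dtype=float)
            variable = np.ptp(x, axis=1) > 0
            if not variable.all():
                dead = [recording.channels[i] for i in np.flatnonzero(~variable)]
                warnings.warn(
                    f"constant channels excluded from spatial filter: {dead}", stacklevel=2
                )
            out = x.copy()
            if variable.sum() > n_components:
                out[variable] = _remove_components(x[variable], n_components)
            store[p] = out
    prov = dict(recording.provenance)
    prov.setdefault("preprocess", []).append({"step": "pca_spatial_filter", "n_components": n_components})
    return replace(recording, hbo=new_hbo, hbr=new_hbr, provenance=prov)


def cbsi_correct(hbo: np.ndarray, hbr: np.ndarray, channel: str = "?") -> CBSIResult:
    """Correlation-based signal improvement for one channel.

    Guarantees ``corr(hbo', hbr') == -1`` by construction; ``alpha`` is
    returned for audit.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape or hbo.ndim != 1:
        raise ValueError("hbo and hbr must be equal-length 1-D series")
    sd_r = hbr.std()
    if sd_r == 0:
        raise ValueError(f"CBSI undefined: zero-variance HbR on channel {channel}")
    alpha = hbo.std() / sd_r
    hbo_c = (hbo - alpha * hbr) / 2.0
    hbr_c = -hbo_c / alpha
    return CBSIResult(hbo_c, hbr_c, float(alpha))


def apply_cbsi(recording: DyadRecording) -> DyadRecording:
    """CBSI per channel and participant.  Corrected HbR is retained for audit
    only; downstream synchrony analysis uses HbO."""
    new_hbo, new_hbr = {}, {}
    alphas: dict[str, float] = {}
    for p in (1, 2):
        ho = recording.hbo[p].copy()
        hr = recording.hbr[p].copy()
        for ci, ch in enumerate(recording.channels):
            res = cbsi_correct(ho[ci], hr[ci], channel=f"p{p}:{ch}")
            ho[ci], hr[ci] = res.hbo, res.hbr
            alphas[f"p{p}:{ch}"] = res.alpha
        new_hbo[p], new_hbr[p] = ho, hr
    prov = dict(recording.provenance)
    prov.setdefault("preprocess", []).append({"step": "cbsi", "alpha": alphas})
    return replace(recording, hbo=new_hbo, hbr=new_hbr, provenance=prov)


def trim_sessions(recording: DyadRecording, config: PreprocessConfig | None = None) -> DyadRecording:
    """Drop the head/tail of each task session; keep rest sessions whole.

    Sample intervals are half-open ``[start, start + length)``. Annotations
    (and per-second truth labels, when present) are rebuilt on the new,
    contiguous time axis.
    """
    cfg = config or PreprocessConfig()
    fs = recording.sampling_rate
    keep_slices: list[tuple[str, int, int]] = []
    for label, a, b in recording.annotations:
        if label.startswith("task"):
            if (b - a) <= cfg.trim_head + cfg.trim_tail:
                raise ValueError(
                    f"session {label!r} ({b - a:.0f} s) shorter than trims "
                    f"({cfg.trim_head:.0f}+{cfg.trim_tail:.0f} s)"
                )
            a, b = a + cfg.trim_head, b - cfg.trim_tail
        keep_slices.append((label, int(round(a * fs)), int(round(b * fs))))
    idx = np.concatenate([np.arange(i0, i1) for _, i0, i1 in keep_slices])
    new_annotations: list[tuple[str, float, float]] = []
    t = 0.0
    for label, i0, i1 in keep_slices:
        dur = (i1 - i0) / fs
        new_annotations.append((label, t, t + dur))
        t += dur
    truth = None
    if recording.truth_states is not None:
        sec_idx = np.concatenate(
            [np.arange(int(round(i0 / fs)), int(round(i1 / fs))) for _, i0, i1 in keep_slices]
        )
        truth = recording.truth_states[sec_idx]
    prov = dict(recording.provenance)
    prov.setdefault("preprocess", []).append(
        {"step": "trim_sessions", "trim_head": cfg.trim_head, "trim_tail": cfg.trim_tail}
    )
    return replace(
        recording,
        hbo={p: a[:, idx].copy() for p, a in recording.hbo.items()},
        hbr={p: a[:, idx].copy() for p, a in recording.hbr.items()},
        annotations=new_annotations,
        truth_states=truth,
        provenance=prov,
    )


def trim_annotations(
    annotations: list[tuple[str, float, float]], config: PreprocessConfig | None = None
) -> list[tuple[str, float, float]]:
    """Trimmed session bounds on the *original* time axis (no splicing).

    Computing wavelet coherence on a spliced recording synchronises the
    splice discontinuities across both participants and manufactures
    spurious low-frequency cross-brain coherence confined to the task
    blocks. The pipeline therefore keeps the signal continuous and realises
    the head/tail trims as shrunk task annotations, applied when task
    samples are extracted for band selection and windowing.
    """
    cfg = config or PreprocessConfig()
    out = []
    for label, a, b in annotations:
        if label.startswith("task"):
            if (b - a) <= cfg.trim_head + cfg.trim_tail:
                raise ValueError(
                    f"session {label!r} ({b - a:.0f} s) shorter than trims "
                    f"({cfg.trim_head:.0f}+{cfg.trim_tail:.0f} s)"
                )
            out.append((label, a + cfg.trim_head, b - cfg.trim_tail))
        else:
            out.append((label, a, b))
    return out


def preprocess_recording(recording: DyadRecording, config: PreprocessConfig | None = None,
                         splice: bool = True) -> DyadRecording:
    """Full chain in the fixed order: spatial filter -> CBSI -> trim.

    With ``splice=False`` the trim step is skipped here (the caller applies
    :func:`trim_annotations` downstream instead); see that function for why
    the coherence pipeline prefers the mask over the splice.
    """
    cfg = config or PreprocessConfig()
    rec = pca_spatial_filter(recording, cfg.n_components_removed) if cfg.n_components_removed else recording
    if cfg.cbsi_enabled:
        rec = apply_cbsi(rec)
    return trim_sessions(rec, cfg) if splice else rec
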