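"""Synthetic dyadic fNIRS recordings with planted inter-brain coupling states.

The generator emulates the structure of a hyperscanning experiment in which
two participants' HbO/HbR concentration changes are recorded over a session
plan of rest and task blocks, while a latent sequence of inter-brain coupling
states switches with exponential-like dwell times.  During task blocks, ROI
pairs flagged as coupled in the active state receive a shared band-limited
Gaussian process (dyad-common, fresh realisation per dwell), concentrated in
the 0.10-0.19 Hz coupling band so the downstream wavelet-coherence analysis
can recover both the band and the state sequence.  During rest the coupling
amplitude is scaled to near zero.

Realistic nuisance structure is layered on every channel: slow drift below
0.01 Hz, a Mayer wave near 0.1 Hz (deliberately inside the band of interest —
a confound knob), respiration near 0.3 Hz, cardiac pulsation near 1.2 Hz with
phase jitter, white noise, and Poisson motion spikes shared between
chromophores.  HbR is an anti-correlated copy of HbO (``hbr_ratio`` < 0) plus
independent noise.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sp_fft

from .behavior import Response, ResponseLog

__all__ = [
    "ROI_NAMES_13",
    "SimConfig",
    "StateSequence",
    "DyadRecording",
    "default_state_topologies",
    "generate_state_sequence",
    "generate_dyad_recording",
    "generate_behavior",
    "generate_cohort",
]

#: default 13 regions of interest: prefrontal and right temporo-parietal
#: areas typically covered by two optode patches in hyperscanning work
ROI_NAMES_13 = [
    "dlPFC-l",
    "dlPFC-r",
    "mPFC",
    "FPC",
    "IFG-l",
    "IFG-r",
    "OFC",
    "TPJ",
    "STG",
    "MTG",
    "AG",
    "SMG",
    "SOG",
]

DEFAULT_SESSION_PLAN: tuple[tuple[str, float], ...] = (
    ("rest", 120.0),
    ("taskA", 300.0),
    ("taskB", 300.0),
    ("rest", 60.0),
)

DEFAULT_NOISE_AMPLITUDES = {
    "drift": 0.5,
    "mayer": 0.15,
    "respiration": 0.2,
    "cardiac": 0.2,
    "white": 0.3,
}

#: nuisance oscillation centre frequencies, Hz
NOISE_FREQS = {"mayer": 0.1, "respiration": 0.3, "cardiac": 1.2}


def default_state_topologies(
    n_states: int, n_rois: int, strong: float = 0.8, weak: float = 0.1
) -> np.ndarray:
    """Distinct symmetric coupling topologies, densest first.

    State 0 couples every ROI pair at ``strong``; the last state couples a
    minimal ring at ``weak``; intermediate states couple progressively smaller
    leading blocks at ``strong`` with ``weak`` elsewhere.  Diagonals are zero
    (homologous self-coupling is not planted).
    """
    out = np.zeros((n_states, n_rois, n_rois))
    for s in range(n_states):
        if n_states == 1:
            frac = 1.0
        else:
            frac = 1.0 - s / (n_states - 1)
        m = max(2, int(round(frac * n_rois)))
        c = np.full((n_rois, n_rois), 0.0)
        if s == n_states - 1 and n_states > 1:
            for i in range(n_rois):
                j = (i + 1) % n_rois
                c[i, j] = c[j, i] = weak
        else:
            c[:m, :m] = strong
            c[m:, :] = c[:, m:] = weak if s > 0 else strong
        np.fill_diagonal(c, 0.0)
        out[s] = c
    return out


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic dyadic recording.

    Defaults mirror a typical dyadic hyperscanning protocol: 10 Hz sampling, 13 ROIs per
    participant, a 2-min rest / two 5-min tasks / 1-min rest session plan,
    three coupling states, and a 0.10-0.19 Hz coupling band.
    """

    sampling_rate: float = 10.0
    n_rois: int = 13
    session_plan: tuple[tuple[str, float], ...] = DEFAULT_SESSION_PLAN
    n_states: int = 3
    state_dwell_mean: float = 20.0
    coupling_band: tuple[float, float] = (0.10, 0.19)
    coupling_strength: np.ndarray | None = None  # (n_states, n_rois, n_rois)
    rest_coupling_scale: float = 0.05
    noise_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_AMPLITUDES)
    )
    motion_rate: float = 0.5  # spikes / minute
    motion_amplitude: float = 3.0
    hbr_ratio: float = -0.5
    channels_per_roi: int = 1
    roi_names: list[str] | None = None
    #: optional per-session-label state preference (weights over states) and
    #: dwell mean; lets a "creative" task block favour the dense state and
    #: switch faster than its control
    state_weights_by_session: dict[str, tuple[float, ...]] | None = None
    dwell_mean_by_session: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * NOISE_FREQS["cardiac"]:
            raise ValueError("sampling_rate must exceed twice the cardiac frequency")
        if any(d <= 0 for _, d in self.session_plan):
            raise ValueError("session durations must be positive")
        lo, hi = self.coupling_band
        if not (0.01 < lo < hi < 0.7):
            raise ValueError("coupling_band must lie inside (0.01, 0.7) Hz")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.state_dwell_mean < 1.0 / self.sampling_rate:
            raise ValueError("state_dwell_mean shorter than one sample")
        if self.coupling_strength is None:
            self.coupling_strength = default_state_topologies(self.n_states, self.n_rois)
        self.coupling_strength = np.asarray(self.coupling_strength, dtype=float)
        if self.coupling_strength.shape != (self.n_states, self.n_rois, self.n_rois):
            raise ValueError("coupling_strength must be (n_states, n_rois, n_rois)")
        if not np.allclose(self.coupling_strength, np.swapaxes(self.coupling_strength, 1, 2)):
            raise ValueError("coupling_strength matrices must be symmetric")
        if np.any(np.abs(np.diagonal(self.coupling_strength, axis1=1, axis2=2)) > 0):
            raise ValueError("coupling_strength diagonals must be zero")
        if np.any(self.coupling_strength < 0) or np.any(self.coupling_strength > 1):
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.roi_names is None:
            if self.n_rois == 13:
                self.roi_names = list(ROI_NAMES_13)
            else:
                self.roi_names = [f"ROI{i + 1:02d}" for i in range(self.n_rois)]

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.session_plan))

    @property
    def annotations(self) -> list[tuple[str, float, float]]:
        out, t = [], 0.0
        for label, dur in self.session_plan:
            out.append((label, t, t + dur))
            t += dur
        return out

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class StateSequence:
    """Per-second latent coupling-state labels with their dwell times."""

    labels: np.ndarray  # (n_seconds,) int, values in 0..n_states-1
    dwell_times: list[float]

    def __post_init__(self) -> None:
        if any(d < 1.0 for d in self.dwell_times):
            raise ValueError("dwell times must be >= 1 s")

    @property
    def n_transitions(self) -> int:
        return int(np.sum(self.labels[1:] != self.labels[:-1]))

    def segments(self) -> list[tuple[int, int, int]]:
        """(state, start_second, end_second) runs, end exclusive."""
        out = []
        lab = self.labels
        start = 0
        for i in range(1, lab.size + 1):
            if i == lab.size or lab[i] != lab[start]:
                out.append((int(lab[start]), start, i))
                start = i
        return out


@dataclass
class DyadRecording:
    """Paired multi-channel HbO/HbR series with session annotations.

    Arrays are ``(n_channels, n_samples)`` in arbitrary concentration-change
    units; both participants share the sampling rate, duration and channel
    layout.  ``truth_states`` holds the planted per-second state labels when
    the recording is synthetic.
    """

    dyad_id: str
    hbo: dict[int, np.ndarray]  # participant (1, 2) -> (C, T)
    hbr: dict[int, np.ndarray]
    channels: list[str]
    channel_roi: dict[str, str]
    rois: list[str]
    sampling_rate: float
    annotations: list[tuple[str, float, float]]
    truth_states: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {p: a.shape for p, a in self.hbo.items()}
        if len(set(shapes.values())) != 1 or set(self.hbo) != {1, 2}:
            raise ValueError("both participants must share channel x time shape")
        for p in (1, 2):
            if self.hbr[p].shape != self.hbo[p].shape:
                raise ValueError("HbO and HbR shapes differ")
        missing = [c for c in self.channels if c not in self.channel_roi]
        if missing:
            raise ValueError(f"channels without ROI assignment: {missing}")
        bad = [c for c, r in self.channel_roi.items() if r not in self.rois]
        if bad:
            raise ValueError(f"channels mapped to unknown ROIs: {bad}")
        t, tol = 0.0, 1e-9
        for label, a, b in self.annotations:
            if abs(a - t) > tol or b <= a:
                raise ValueError("annotations must tile the recording without overlap")
            t = b
        if abs(t - self.duration) > 1.0 / self.sampling_rate + tol:
            raise ValueError("annotations do not cover the full recording")

    @property
    def n_samples(self) -> int:
        return self.hbo[1].shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def task_annotations(self) -> list[tuple[str, float, float]]:
        return [a for a in self.annotations if a[0].startswith("task")]

    def rest_annotations(self) -> list[tuple[str, float, float]]:
        return [a for a in self.annotations if not a[0].startswith("task")]


def generate_state_sequence(cfg: SimConfig, rng: np.random.Generator | None = None) -> StateSequence:
    """Semi-Markov latent state sequence at 1 s resolution.

    Dwell times are geometric with mean ``state_dwell_mean`` (minimum 1 s);
    at each dwell boundary the next state is drawn uniformly among the other
    states, so there are no self-transitions.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_seconds = int(round(cfg.total_duration))
    if cfg.n_states == 1:
        return StateSequence(labels=np.zeros(n_seconds, dtype=int), dwell_times=[float(n_seconds)])
    if cfg.state_dwell_mean < 5.0:
        warnings.warn("state_dwell_mean < 5 s: dwells barely resolvable by 10 s windows", stacklevel=2)
    session_at = np.empty(n_seconds, dtype=object)
    for label, a, b in cfg.annotations:
        session_at[int(a) : int(b)] = label
    labels = np.empty(n_seconds, dtype=int)
    dwells: list[float] = []
    state = int(rng.integers(cfg.n_states))
    t = 0
    while t < n_seconds:
        here = session_at[t]
        dwell_mean = cfg.state_dwell_mean
        if cfg.dwell_mean_by_session and here in cfg.dwell_mean_by_session:
            dwell_mean = cfg.dwell_mean_by_session[here]
        d = int(rng.geometric(min(1.0, 1.0 / dwell_mean)))
        d = min(d, n_seconds - t)
        labels[t : t + d] = state
        dwells.append(float(d))
        t += d
        others = [s for s in range(cfg.n_states) if s != state]
        if cfg.state_weights_by_session and here in cfg.state_weights_by_session:
            w = np.asarray([cfg.state_weights_by_session[here][s] for s in others], dtype=float)
            w = w / w.sum()
            state = int(rng.choice(others, p=w))
        else:
            state = int(rng.choice(others))
    return StateSequence(labels=labels, dwell_times=dwells)


def _bandlimited_noise(n: int, band: tuple[float, float], fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian process with power confined to ``band``.

    Synthesised spectrally on a grid long enough (>= 4096 samples) to resolve
    the band even for short dwell segments, then truncated to ``n``.
    """
    n_synth = max(sp_fft.next_fast_len(n), 4096)
    freqs = np.fft.rfftfreq(n_synth, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        return np.zeros(n)
    spec = np.zeros(freqs.size, dtype=complex)
    spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(spec, n_synth)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x[:n]


def _drift(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Slow 1/f-weighted drift with all power below 0.01 Hz."""
    if amp == 0:
        return np.zeros(n)
    comps = np.zeros(n)
    t = np.arange(n) / fs
    for _ in range(5):
        f = rng.uniform(0.0005, 0.009)
        comps += (0.002 / f) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    sd = comps.std()
    return amp * comps / sd if sd > 0 else comps


def _oscillation(n: int, fs: float, f0: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Sinusoid at ``f0`` with per-channel frequency offset and phase jitter."""
    if amp == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    f = f0 * (1 + rng.normal(0, 0.05))
    phase_jitter = np.cumsum(rng.normal(0, 0.03, n))
    return amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi) + phase_jitter)


def _motion_spikes(n: int, fs: float, rate_per_min: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson spike train with exponential (tau = 2 s) decay, random sign."""
    out = np.zeros(n)
    if rate_per_min <= 0 or amp == 0:
        return out
    n_spikes = rng.poisson(rate_per_min * n / fs / 60.0)
    tau = 2.0 * fs
    for _ in range(n_spikes):
        i0 = int(rng.integers(n))
        sign = rng.choice([-1.0, 1.0])
        length = min(n - i0, int(5 * tau))
        out[i0 : i0 + length] += sign * amp * np.exp(-np.arange(length) / tau)
    return out


def generate_dyad_recording(
    cfg: SimConfig,
    dyad_id: str = "dyad01",
    seed: int | None = None,
    truth: StateSequence | None = None,
) -> DyadRecording:
    """Simulate one dyad's recording under ``cfg``.

    The shared coupling process for a ROI pair is injected into that pair's
    ROI signal of *both* participants (both cross-brain orderings become
    coherent); its amplitude is the state's coupling strength during task
    seconds and ``rest_coupling_scale`` times that during rest.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.sampling_rate
    n = int(round(cfg.total_duration * fs))
    if truth is None:
        truth = generate_state_sequence(cfg, rng)

    task_mask_s = np.zeros(int(round(cfg.total_duration)), dtype=bool)
    for label, a, b in cfg.annotations:
        if label.startswith("task"):
            task_mask_s[int(a) : int(b)] = True
    amp_scale_s = np.where(task_mask_s, 1.0, cfg.rest_coupling_scale)
    amp_scale = np.repeat(amp_scale_s, int(round(fs)))[:n]

    roi_sig = {1: np.zeros((cfg.n_rois, n)), 2: np.zeros((cfg.n_rois, n))}
    for state, sec0, sec1 in truth.segments():
        i0, i1 = int(sec0 * fs), int(sec1 * fs)
        c = cfg.coupling_strength[state]
        for i in range(cfg.n_rois):
            for j in range(i + 1, cfg.n_rois):
                if c[i, j] <= 0:
                    continue
                g = _bandlimited_noise(i1 - i0, cfg.coupling_band, fs, rng)
                g = g * (c[i, j] * amp_scale[i0:i1])
                for p in (1, 2):
                    roi_sig[p][i, i0:i1] += g
                    roi_sig[p][j, i0:i1] += g

    amps = cfg.noise_amplitudes
    channels = [
        f"CH{r * cfg.channels_per_roi + k + 1:02d}"
        for r in range(cfg.n_rois)
        for k in range(cfg.channels_per_roi)
    ]
    channel_roi = {
        ch: cfg.roi_names[idx // cfg.channels_per_roi] for idx, ch in enumerate(channels)
    }
    hbo, hbr = {}, {}
    for p in (1, 2):
        C = len(channels)
        hbo_p = np.empty((C, n))
        hbr_p = np.empty((C, n))
        for ci, ch in enumerate(channels):
            r = ci // cfg.channels_per_roi
            clean = (
                roi_sig[p][r]
                + _drift(n, fs, amps.get("drift", 0.0), rng)
                + _oscillation(n, fs, NOISE_FREQS["mayer"], amps.get("mayer", 0.0), rng)
                + _oscillation(n, fs, NOISE_FREQS["respiration"], amps.get("respiration", 0.0), rng)
                + _oscillation(n, fs, NOISE_FREQS["cardiac"], amps.get("cardiac", 0.0), rng)
                + amps.get("white", 0.0) * rng.standard_normal(n)
            )
            motion = _motion_spikes(n, fs, cfg.motion_rate, cfg.motion_amplitude, rng)
            hbo_p[ci] = clean + motion
            hbr_p[ci] = (
                cfg.hbr_ratio * clean
                + 0.8 * motion  # artifacts move both chromophores the same way
                + 0.5 * amps.get("white", 0.0) * rng.standard_normal(n)
            )
        hbo[p], hbr[p] = hbo_p, hbr_p

    return DyadRecording(
        dyad_id=dyad_id,
        hbo=hbo,
        hbr=hbr,
        channels=channels,
        channel_roi=channel_roi,
        rois=list(cfg.roi_names),
        sampling_rate=fs,
        annotations=cfg.annotations,
        truth_states=truth.labels.copy(),
        provenance={"seed": int(cfg.seed if seed is None else seed), "generator": "dibs.synthgen"},
    )


_VOCAB_SIZE = 400


def generate_behavior(
    cfg: SimConfig,
    truth: StateSequence | None = None,
    seed: int | None = None,
    convergence_prob: float | None = 0.35,
    n_categories: int = 8,
    mean_gap: float = 12.0,
    pass_prob: float = 0.05,
    zipf_a: float = 1.5,
) -> tuple[ResponseLog, ResponseLog]:
    """Alternating-speaker response logs for the two task blocks (AUT, OCT).

    ``convergence_prob`` is the probability that a response repeats the
    previous response's category (driving the converge count and IOC).  When
    None and ``truth`` is given, the dyad's *task-period* occupancy of the
    densest coupling state drives both cooperation and originality —
    convergence probability rises with dense occupancy, and the Zipf
    exponent of the response vocabulary falls with it (flatter distribution,
    rarer ideas) — planting the positive dense-state/behaviour correlations
    the analysis is meant to detect.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    zipf_a_eff = zipf_a
    if convergence_prob is None:
        if truth is None:
            raise ValueError("need truth states to derive convergence_prob")
        task_secs = np.concatenate(
            [
                np.arange(int(a), int(b))
                for label, a, b in cfg.annotations
                if label.startswith("task")
            ]
        )
        dense_frac = float(np.mean(truth.labels[task_secs] == 0))
        convergence_prob = float(np.clip(0.05 + 0.9 * dense_frac, 0.0, 0.95))
        zipf_a_eff = max(1.05, zipf_a - 1.2 * dense_frac)
    categories = [f"cat{idx:02d}" for idx in range(n_categories)]
    ranks = np.arange(1, _VOCAB_SIZE + 1, dtype=float)
    vocab_p = ranks**-zipf_a_eff
    vocab_p /= vocab_p.sum()

    tasks = [a for a in cfg.annotations if a[0].startswith("task")]
    logs = []
    for task_name, (label, a, b) in zip(("AUT", "OCT"), tasks):
        records: list[Response] = []
        t = float(rng.uniform(2.0, 6.0))
        speaker = int(rng.integers(1, 3))
        prev_cat: str | None = None
        while t < (b - a):
            if rng.random() < pass_prob:
                records.append(Response(speaker=speaker, t=t, key="pass", category=None, is_pass=True))
            else:
                if prev_cat is not None and rng.random() < convergence_prob:
                    cat = prev_cat
                else:
                    others = [c for c in categories if c != prev_cat]
                    cat = str(rng.choice(others))
                word = int(rng.choice(_VOCAB_SIZE, p=vocab_p))
                key = f"{label}_{cat}_idea{word:03d}"
                records.append(Response(speaker=speaker, t=t, key=key, category=cat))
                prev_cat = cat
            speaker = 3 - speaker
            t += float(rng.exponential(mean_gap)) + 0.5
        logs.append(ResponseLog(task=task_name, records=records))
    if len(logs) < 2:
        raise ValueError("session plan must contain two task blocks")
    return logs[0], logs[1]


def generate_cohort(
    cfg: SimConfig, n_dyads: int, seed: int | None = None, behavior: bool = True
) -> tuple[list[DyadRecording], list[tuple[ResponseLog, ResponseLog]]]:
    """Simulate a cohort of dyads with independent child seeds."""
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    child_seeds = root.integers(0, 2**31 - 1, size=2 * n_dyads)
    recordings, logs = [], []
    for d in range(n_dyads):
        rec_seed = int(child_seeds[2 * d])
        cfg_d = cfg.with_(seed=rec_seed)
        truth = generate_state_sequence(cfg_d)
        rec = generate_dyad_recording(cfg_d, dyad_id=f"dyad{d + 1:02d}", seed=rec_seed, truth=truth)
        recordings.append(rec)
        if behavior:
            logs.append(
                generate_behavior(cfg_d, truth=truth, seed=int(child_seeds[2 * d + 1]), convergence_prob=None)
            )
    return recordings, logs
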