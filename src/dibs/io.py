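"""File formats, probe-geometry utilities and pipeline configuration.

The canonical interchange format is a long-form CSV with one row per sample:
``dyad, participant, channel, roi, chromophore, t, value``, accompanied by an
``<stem>.annotations.csv`` sidecar (session labels and bounds) and, for
synthetic data, a ``<stem>.truth.csv`` sidecar with the per-second planted
state labels.  SNIRF output (one HDF5 file per participant, minimal v1.0
profile with processed-Hb measurement lists) is supported for ecosystem
compatibility; round-trips through either format are lossless to numerical
precision.

Configuration is a strict-schema YAML document (unknown keys rejected).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthgen import DyadRecording

__all__ = [
    "ProbeGrid",
    "channel_count",
    "write_recording_csv",
    "read_recording_csv",
    "write_recording_snirf",
    "read_recording_snirf",
    "PipelineConfig",
    "config_hash",
]


@dataclass(frozen=True)
class ProbeGrid:
    """Alternating source/detector optode lattice (checkerboard layout)."""

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")


def channel_count(grid: ProbeGrid) -> int:
    """Measurement channels of an alternating optode grid.

    Channels exist exactly between lattice-adjacent source-detector pairs:
    ``rows * (cols - 1) + cols * (rows - 1)``.  A 3x5 patch yields 22
    channels, a 4x4 patch 24.
    """
    return grid.rows * (grid.cols - 1) + grid.cols * (grid.rows - 1)


# ---------------------------------------------------------------- CSV I/O


def write_recording_csv(recording: DyadRecording, path: str | Path) -> Path:
    path = Path(path)
    fs = recording.sampling_rate
    n = recording.n_samples
    t = np.arange(n) / fs
    frames = []
    for p in (1, 2):
        for chrom, arr in (("HbO", recording.hbo[p]), ("HbR", recording.hbr[p])):
            for ci, ch in enumerate(recording.channels):
                frames.append(
                    pd.DataFrame(
                        {
                            "dyad": recording.dyad_id,
                            "participant": p,
                            "channel": ch,
                            "roi": recording.channel_roi[ch],
                            "chromophore": chrom,
                            "t": t,
                            "value": arr[ci],
                        }
                    )
                )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
    ann = pd.DataFrame(recording.annotations, columns=["label", "start", "end"])
    ann.to_csv(path.with_suffix(".annotations.csv"), index=False)
    if recording.truth_states is not None:
        pd.DataFrame(
            {"second": np.arange(recording.truth_states.size), "state": recording.truth_states}
        ).to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


REQUIRED_CSV_COLUMNS = ["dyad", "participant", "channel", "roi", "chromophore", "t", "value"]


def read_recording_csv(path: str | Path) -> DyadRecording:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed recording CSV {path.name}: missing columns {missing}")
    dyad_id = str(df["dyad"].iloc[0])
    channels = list(dict.fromkeys(df["channel"]))
    channel_roi = dict(df.drop_duplicates("channel")[["channel", "roi"]].itertuples(index=False))
    rois = list(dict.fromkeys(channel_roi[c] for c in channels))
    t_vals = np.sort(df["t"].unique())
    n = t_vals.size
    fs = float(round(1.0 / np.median(np.diff(t_vals)), 6))
    hbo, hbr = {}, {}
    for p in (1, 2):
        for chrom, store in (("HbO", hbo), ("HbR", hbr)):
            arr = np.empty((len(channels), n))
            sub = df[(df["participant"] == p) & (df["chromophore"] == chrom)]
            for ci, ch in enumerate(channels):
                vals = sub[sub["channel"] == ch].sort_values("t")["value"].to_numpy()
                if vals.size != n:
                    raise ValueError(f"channel {ch} participant {p} {chrom}: ragged series")
                arr[ci] = vals
            store[p] = arr
    ann_path = path.with_suffix(".annotations.csv")
    if ann_path.exists():
        ann_df = pd.read_csv(ann_path)
        annotations = [(str(r.label), float(r.start), float(r.end)) for r in ann_df.itertuples()]
    else:
        annotations = [("rest", 0.0, n / fs)]
    truth = None
    truth_path = path.with_suffix(".truth.csv")
    if truth_path.exists():
        truth = pd.read_csv(truth_path)["state"].to_numpy()
    return DyadRecording(
        dyad_id=dyad_id,
        hbo=hbo,
        hbr=hbr,
        channels=channels,
        channel_roi=channel_roi,
        rois=rois,
        sampling_rate=fs,
        annotations=annotations,
        truth_states=truth,
    )


# -------------------------------------------------------------- SNIRF I/O


def write_recording_snirf(recording: DyadRecording, directory: str | Path) -> list[Path]:
    """One SNIRF (HDF5) file per participant, minimal v1.0 layout.

    Processed-hemoglobin channels use dataType 99999 with dataTypeLabel
    "HbO"/"HbR"; channel names and the ROI map travel in metaDataTags.
    Binary output: only ever written at run time, never shipped.
    """
    import h5py

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    n = recording.n_samples
    t = np.arange(n) / recording.sampling_rate
    for p in (1, 2):
        path = directory / f"{recording.dyad_id}_p{p}.snirf"
        data = np.vstack([recording.hbo[p], recording.hbr[p]]).T  # time x measurement
        with h5py.File(path, "w") as f:
            f.create_dataset("formatVersion", data="1.0")
            nirs = f.create_group("nirs")
            meta = nirs.create_group("metaDataTags")
            meta.create_dataset("SubjectID", data=f"{recording.dyad_id}_p{p}")
            meta.create_dataset("MeasurementDate", data="unknown")
            meta.create_dataset("MeasurementTime", data="unknown")
            meta.create_dataset("LengthUnit", data="mm")
            meta.create_dataset("TimeUnit", data="s")
            meta.create_dataset("FrequencyUnit", data="Hz")
            meta.create_dataset("channelNames", data=json.dumps(recording.channels))
            meta.create_dataset("channelROIMap", data=json.dumps(recording.channel_roi))
            meta.create_dataset("sessionAnnotations", data=json.dumps(recording.annotations))
            d1 = nirs.create_group("data1")
            d1.create_dataset("dataTimeSeries", data=data)
            d1.create_dataset("time", data=t)
            n_ch = len(recording.channels)
            for mi in range(2 * n_ch):
                ml = d1.create_group(f"measurementList{mi + 1}")
                ml.create_dataset("sourceIndex", data=(mi % n_ch) + 1)
                ml.create_dataset("detectorIndex", data=(mi % n_ch) + 1)
                ml.create_dataset("wavelengthIndex", data=1)
                ml.create_dataset("dataType", data=99999)
                ml.create_dataset("dataTypeLabel", data="HbO" if mi < n_ch else "HbR")
                ml.create_dataset("dataTypeIndex", data=1)
        paths.append(path)
    return paths


def read_recording_snirf(dyad_id: str, directory: str | Path) -> DyadRecording:
    import h5py

    directory = Path(directory)
    hbo, hbr = {}, {}
    channels: list[str] = []
    channel_roi: dict[str, str] = {}
    annotations: list = []
    fs = None
    for p in (1, 2):
        path = directory / f"{dyad_id}_p{p}.snirf"
        with h5py.File(path, "r") as f:
            d1 = f["nirs/data1"]
            data = np.asarray(d1["dataTimeSeries"])
            t = np.asarray(d1["time"])
            meta = f["nirs/metaDataTags"]
            channels = json.loads(meta["channelNames"][()].decode())
            channel_roi = json.loads(meta["channelROIMap"][()].decode())
            annotations = [
                (str(a), float(b), float(c))
                for a, b, c in json.loads(meta["sessionAnnotations"][()].decode())
            ]
        fs = float(round(1.0 / np.median(np.diff(t)), 6))
        n_ch = len(channels)
        hbo[p] = data[:, :n_ch].T.copy()
        hbr[p] = data[:, n_ch:].T.copy()
    rois = list(dict.fromkeys(channel_roi[c] for c in channels))
    return DyadRecording(
        dyad_id=dyad_id,
        hbo=hbo,
        hbr=hbr,
        channels=channels,
        channel_roi=channel_roi,
        rois=rois,
        sampling_rate=fs,
        annotations=annotations,
    )


# ------------------------------------------------------------- config


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_dyads: int = 8
    sampling_rate: float = 10.0
    n_rois: int = 13
    n_states: int = 3
    state_dwell_mean: float = 20.0
    coupling_band: tuple[float, float] = (0.10, 0.19)
    coupling_strong: float = 0.8
    coupling_weak: float = 0.1
    rest_coupling_scale: float = 0.05
    session_plan: list[tuple[str, float]] | None = None
    motion_rate: float = 0.5
    hbr_ratio: float = -0.5


class PreprocessSection(_Strict):
    n_components_removed: int = 1
    trim_head: float = 30.0
    trim_tail: float = 30.0
    cbsi_enabled: bool = True


class WaveletSection(_Strict):
    omega0: float = 6.0
    voices_per_octave: int = 12
    freq_min: float = 0.01
    freq_max: float = 0.7


class FOISection(_Strict):
    p_threshold: float = 5e-6


class WindowSection(_Strict):
    length: float = 10.0
    step: float = 1.0


class ClusteringSection(_Strict):
    k: int | None = None
    k_min: int = 2
    k_max: int = 8
    n_replicates: int = 100


class StatsSection(_Strict):
    n_permutations: int = 300
    alpha: float = 0.05
    permutation_replicates: int = 20


class PipelineConfig(_Strict):
    """Schema-validated configuration for the end-to-end pipeline."""

    seed: int = 0
    sim: SimSection = Field(default_factory=SimSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    wavelet: WaveletSection = Field(default_factory=WaveletSection)
    foi: FOISection = Field(default_factory=FOISection)
    window: WindowSection = Field(default_factory=WindowSection)
    clustering: ClusteringSection = Field(default_factory=ClusteringSection)
    stats: StatsSection = Field(default_factory=StatsSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(self.model_dump_json()), f, sort_keys=False)


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:16]
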