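"""Seeded synthetic multichannel EEG with planted class structure.

Each record emulates a 24-channel, 250 Hz EEG recording from one subject
labeled with one of three pain strata (1=low, 2=moderate, 3=high).  Channels
carry pink-like (1/f) background noise; a configurable subset of
"discriminative" channels additionally carries a 10 Hz alpha-band sinusoid
whose amplitude grows with the class label:

    amplitude = base_alpha_amp * class * (effect_size - 1)

so at effect_size = 1 the planted component vanishes and every channel has
identical expected alpha band power, while at effect_size >= 3 the planted
channels dominate the 8-12 Hz band for every class.  Labels are assigned to
subjects by a largest-remainder quota on ``class_probs`` and shuffled by the
seed, so class marginals track the requested probabilities exactly even at
small n.  Identical seeds give bit-identical datasets.

The default channel montage is the 22 scalp electrodes plus the two earlobe
references A1/A2 used by the chronic neuropathic pain recordings this
generator stands in for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CHANNEL_NAMES_24",
    "SynthConfig",
    "EegDataset",
    "assign_labels",
    "generate_dataset",
    "segment_record",
    "write_dataset",
    "read_dataset",
]

CHANNEL_NAMES_24 = (
    "Fp1", "Fp2", "AFz", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "CPz", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "O2",
    "A1", "A2",
)

# 1-based indices of the default planted channels: AFz, C4, CPz, P7, A2
DEFAULT_DISCRIMINATIVE = (3, 12, 14, 15, 24)


class ConfigurationError(ValueError):
    """A generator configuration field is invalid."""


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic recordings."""

    n_subjects: int = 36
    n_channels: int = 24
    fs: float = 250.0
    record_seconds: float = 60.0
    class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    discriminative_channels: tuple[int, ...] = DEFAULT_DISCRIMINATIVE
    effect_size: float = 3.0
    noise_sd: float = 1.0
    alpha_freq_hz: float = 10.0
    base_alpha_amp: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_channels < 1:
            raise ConfigurationError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.record_seconds <= 0:
            raise ConfigurationError(
                f"record_seconds must be positive, got {self.record_seconds}"
            )
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.size != 3 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_probs must be 3 nonnegative values summing to 1, "
                f"got {self.class_probs}"
            )
        bad = [c for c in self.discriminative_channels
               if not 1 <= c <= self.n_channels]
        if bad:
            raise ConfigurationError(
                f"discriminative_channels {bad} outside 1..{self.n_channels}"
            )
        if self.effect_size < 1:
            raise ConfigurationError(
                f"effect_size must be >= 1, got {self.effect_size}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class EegDataset:
    """Labeled multichannel recordings sharing channel count and rate."""

    records: list[np.ndarray]          # each (n_channels, n_samples)
    labels: np.ndarray                 # per-record class in {1, 2, 3}
    subject_ids: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    config: SynthConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.records:
            n_ch = self.records[0].shape[0]
            if any(r.shape[0] != n_ch for r in self.records):
                raise ValueError("all records must share the channel count")
            if len(self.channel_names) != n_ch:
                raise ValueError(
                    f"{len(self.channel_names)} channel names for {n_ch} channels"
                )
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (1, 2, 3)).all():
            raise ValueError("labels must lie in {1, 2, 3}")

    def __len__(self) -> int:
        return len(self.records)


def assign_labels(n: int, class_probs, rng: np.random.Generator) -> np.ndarray:
    """Quota label assignment: largest-remainder counts, shuffled order."""
    probs = np.asarray(class_probs, dtype=float)
    exact = probs * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(1, probs.size + 1), counts)
    rng.shuffle(labels)
    return labels


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_dataset(config: SynthConfig | None = None) -> EegDataset:
    """One record per subject with class-scaled alpha power on planted channels."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.record_seconds * config.fs))
    t = np.arange(n_samples) / config.fs
    planted = set(config.discriminative_channels)
    if config.n_channels == 24:
        names = CHANNEL_NAMES_24
    else:
        names = tuple(f"ch{i:02d}" for i in range(1, config.n_channels + 1))

    labels = assign_labels(config.n_subjects, config.class_probs, rng)
    records = []
    for label in labels:
        rec = np.empty((config.n_channels, n_samples))
        amp = config.base_alpha_amp * label * (config.effect_size - 1.0)
        for ch in range(1, config.n_channels + 1):
            x = config.noise_sd * _pink_noise(n_samples, rng)
            if ch in planted and amp > 0:
                phase = rng.uniform(0, 2 * np.pi)
                x = x + amp * np.sin(2 * np.pi * config.alpha_freq_hz * t + phase)
            rec[ch - 1] = x
        records.append(rec)
    return EegDataset(records=records, labels=labels,
                      subject_ids=np.arange(1, config.n_subjects + 1),
                      channel_names=names, fs=config.fs, config=config)


def segment_record(record: np.ndarray, fs: float, duration_s: float) -> list[np.ndarray]:
    """Non-overlapping consecutive segments; the trailing remainder is dropped."""
    record = np.asarray(record)
    seg_len = int(round(duration_s * fs))
    n_samples = record.shape[-1]
    if seg_len <= 0:
        raise ValueError(f"segment duration must be positive, got {duration_s}")
    if seg_len > n_samples:
        raise ValueError(
            f"requested {duration_s} s ({seg_len} samples) from a record of "
            f"{n_samples} samples"
        )
    n_segments = n_samples // seg_len
    return [record[..., i * seg_len : (i + 1) * seg_len] for i in range(n_segments)]


def write_dataset(dataset: EegDataset, out_dir: str | Path) -> Path:
    """One CSV per record (rows = channels) plus a manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(dataset.records):
        name = f"record_{i:03d}.csv"
        pd.DataFrame(rec, index=list(dataset.channel_names)).to_csv(
            out_dir / name, header=False, float_format="%.17g"
        )
        rows.append({
            "record_id": name,
            "subject_id": int(dataset.subject_ids[i]),
            "label": int(dataset.labels[i]),
            "fs": dataset.fs,
        })
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> EegDataset:
    """Read a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    records, labels, subjects = [], [], []
    channel_names: tuple[str, ...] | None = None
    fs = None
    for _, row in manifest.iterrows():
        df = pd.read_csv(manifest_path.parent / row["record_id"],
                         header=None, index_col=0,
                         float_precision="round_trip")
        if channel_names is None:
            channel_names = tuple(df.index.astype(str))
        records.append(df.to_numpy(dtype=float))
        labels.append(int(row["label"]))
        subjects.append(int(row["subject_id"]))
        fs = float(row["fs"])
    return EegDataset(records=records, labels=np.asarray(labels),
                      subject_ids=np.asarray(subjects),
                      channel_names=channel_names or (), fs=fs or 0.0)


def write_dataset_edf(dataset: EegDataset, out_dir: str | Path) -> list[Path]:
    """Optional EDF export of the records (requires mne with an EDF writer)."""
    try:
        import mne
        from mne.export import export_raw
    except ImportError as exc:
        raise RuntimeError(
            "EDF export requires the optional 'mne' dependency"
        ) from exc
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    info = mne.create_info(list(dataset.channel_names), sfreq=dataset.fs,
                           ch_types="eeg")
    paths = []
    for i, rec in enumerate(dataset.records):
        raw = mne.io.RawArray(rec * 1e-6, info, verbose="error")  # uV -> V
        path = out_dir / f"record_{i:03d}.edf"
        try:
            export_raw(path, raw, fmt="edf", verbose="error")
        except (ImportError, RuntimeError, ValueError) as exc:
            raise RuntimeError(
                "EDF export needs mne's 'edfio' writer backend, which is not "
                f"installed: {exc}"
            ) from exc
        paths.append(path)
    return paths
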