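"""WAV clip I/O, dataset manifests, channel handling, balancing and splitting.

Audio is held internally as float arrays in [-1, 1], shaped
``(channels, n_samples)``.  Integer PCM files are rescaled by ``2**(bits-1)``
on read.  Dataset manifests are plain CSV files with columns
``path,label,split`` so they stay greppable and diff-able; paths are stored
relative to the manifest location.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "DatasetManifest",
    "read_wav",
    "write_wav",
    "to_mono",
    "balance_to_min_class",
    "stratified_split",
    "kfold_assign",
]

N_CLASSES = 12


class WavFormatError(ValueError):
    """Raised for missing/corrupt WAV headers or unsupported encodings."""


@dataclass
class AudioClip:
    """A labelled multi-channel waveform.

    Parameters
    ----------
    samples
        Amplitude array shaped ``(channels, n_samples)``, values in [-1, 1].
    sample_rate
        Sampling rate in Hz, > 0.
    label
        Optional class index in ``[0, 12)``.
    source_id
        Free-text provenance tag (file stem, synthesis seed, ...).
    """

    samples: np.ndarray
    sample_rate: float
    label: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, n_samples) array")
        if self.samples.shape[1] < 1:
            raise ValueError("clip must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("clip contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sample_rate


@dataclass
class DatasetManifest:
    """Records of (path, label, split) plus class names and the split seed."""

    records: pd.DataFrame
    class_names: list[str] = field(default_factory=lambda: [f"class_{i:02d}" for i in range(N_CLASSES)])
    seed: int = 0
    root: str = "."

    def __post_init__(self) -> None:
        req = {"path", "label", "split"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"manifest needs columns {sorted(req)}")
        labels = self.records["label"].to_numpy()
        if len(labels) and (labels.min() < 0 or labels.max() >= len(self.class_names)):
            raise ValueError("labels out of range for class_names")
        if self.records["path"].duplicated().any():
            raise ValueError("manifest paths must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split].reset_index(drop=True)

    def class_counts(self) -> pd.Series:
        return self.records["label"].value_counts().sort_index()

    def resolve(self, path: str) -> str:
        return os.path.normpath(os.path.join(self.root, path))

    def save(self, path: str) -> str:
        self.records.to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str, class_names: list[str] | None = None, seed: int = 0) -> "DatasetManifest":
        df = pd.read_csv(path, dtype={"path": str, "split": str})
        df["label"] = df["label"].astype(int)
        kwargs = {} if class_names is None else {"class_names": class_names}
        return cls(records=df, seed=seed, root=os.path.dirname(os.path.abspath(path)), **kwargs)


def read_wav(path: str) -> AudioClip:
    """Read a RIFF/WAVE file into an :class:`AudioClip`.

    Integer PCM is scaled to [-1, 1] by ``2**(bits-1)``; float data is taken
    as-is.  Raises :class:`WavFormatError` on corrupt headers or unsupported
    encodings.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise WavFormatError(f"cannot read {path!r}: {exc}") from exc
    if data.dtype.kind == "i":
        scale = float(2 ** (8 * data.dtype.itemsize - 1))
        samples = data.astype(np.float64) / scale
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned, offset binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise WavFormatError(f"unsupported WAV sample encoding {data.dtype}")
    if samples.ndim == 1:
        samples = samples[None, :]
    else:
        samples = samples.T  # scipy gives (n_samples, channels)
    stem = os.path.splitext(os.path.basename(path))[0]
    return AudioClip(samples=samples, sample_rate=float(rate), source_id=stem)


def write_wav(clip: AudioClip, path: str, bit_depth: str = "float32") -> str:
    """Write a clip as float32 (lossless round-trip) or pcm16 WAV."""
    if not np.all(np.isfinite(clip.samples)):
        raise ValueError("refusing to write non-finite samples")
    data = clip.samples.T  # (n_samples, channels) for scipy
    if data.shape[1] == 1:
        data = data[:, 0]
    if bit_depth == "float32":
        wavfile.write(path, int(clip.sample_rate), data.astype(np.float32))
    elif bit_depth == "pcm16":
        clipped = np.clip(data, -1.0, 32767.0 / 32768.0)
        wavfile.write(path, int(clip.sample_rate), np.round(clipped * 32768.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported bit_depth {bit_depth!r}")
    return path


def to_mono(clip: AudioClip, mode: str = "mean") -> AudioClip:
    """Collapse a multi-channel clip to one channel.

    ``mode="mean"`` averages channels (unbiased, order-invariant);
    ``mode="channel:i"`` selects channel ``i``.
    """
    if mode == "mean":
        mono = clip.samples.mean(axis=0, keepdims=True)
    elif mode.startswith("channel:"):
        idx = int(mode.split(":", 1)[1])
        if not 0 <= idx < clip.n_channels:
            raise IndexError(f"channel {idx} out of range for {clip.n_channels}-channel clip")
        mono = clip.samples[idx : idx + 1]
    else:
        raise ValueError(f"unknown mono mode {mode!r}")
    return replace(clip, samples=mono.copy())


def _require_nonempty_classes(df: pd.DataFrame, n_classes: int) -> None:
    counts = df["label"].value_counts()
    missing = [c for c in range(n_classes) if counts.get(c, 0) == 0]
    if missing:
        raise ValueError(f"classes without records: {missing}")


def balance_to_min_class(manifest: DatasetManifest, seed: int) -> DatasetManifest:
    """Downsample every class (without replacement) to the smallest class size."""
    df = manifest.records
    _require_nonempty_classes(df, len(manifest.class_names))
    n_min = int(df["label"].value_counts().min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for label in sorted(df["label"].unique()):
        idx = df.index[df["label"] == label].to_numpy()
        keep.append(rng.choice(idx, size=n_min, replace=False))
    kept = np.sort(np.concatenate(keep))
    out = df.loc[kept].reset_index(drop=True)
    return replace(manifest, records=out, seed=seed)


def stratified_split(manifest: DatasetManifest, train_fraction: float, seed: int) -> DatasetManifest:
    """Assign train/test splits with per-class proportions within one record."""
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    df = manifest.records.copy()
    _require_nonempty_classes(df, len(manifest.class_names))
    rng = np.random.default_rng(seed)
    split = np.empty(len(df), dtype=object)
    for label in sorted(df["label"].unique()):
        idx = df.index[df["label"] == label].to_numpy()
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        split[perm[:n_train]] = "train"
        split[perm[n_train:]] = "test"
    df["split"] = split
    return replace(manifest, records=df, seed=seed)


def kfold_assign(manifest: DatasetManifest, k: int, seed: int) -> DatasetManifest:
    """Stratified fold labels ``fold_0 .. fold_{k-1}``, per-class sizes within 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    df = manifest.records.copy()
    _require_nonempty_classes(df, len(manifest.class_names))
    if int(df["label"].value_counts().min()) < k:
        raise ValueError("k exceeds the smallest class size")
    rng = np.random.default_rng(seed)
    split = np.empty(len(df), dtype=object)
    for label in sorted(df["label"].unique()):
        idx = df.index[df["label"] == label].to_numpy()
        perm = rng.permutation(idx)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            split[chunk] = f"fold_{fold}"
    df["split"] = split
    return replace(manifest, records=df, seed=seed)
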