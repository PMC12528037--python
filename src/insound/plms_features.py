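"""Patch-level log-scale mel spectrogram (PLMS) extraction.

The feature turns a preprocessed mono clip into a 256x256x3 image:

1. patch framing — overlapping windows of ``Num`` base hops (50% overlap),
2. STFT with a Hamming window, power spectrum P = |X|^2,
3. triangular mel filterbank pooling, S(n,m) = sum_k P(n,k) H_m(k),
4. dB scaling against the global maximum (so the image is invariant to any
   positive gain applied to the waveform),
5. interpolation of the mel bands onto a log10-frequency axis,
6. colormapped rendering at a fixed pixel size.

Larger patch sizes lengthen the analysis window: frequency resolution
improves (bin spacing f_t / N shrinks) while the frame count drops, the
classic time-frequency trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _resize

from .audio_io import AudioClip
from .preprocess import hamming_window

__all__ = [
    "PatchConfig",
    "StftGram",
    "MelFilterbank",
    "LogMelSpectrogram",
    "SpectrogramImage",
    "frame_signal",
    "stft",
    "mel_scale",
    "inverse_mel_scale",
    "build_mel_filterbank",
    "mel_spectrum",
    "log_scale",
    "log_frequency_remap",
    "render_image",
    "extract_plms",
]

DEFAULT_NUM_FRAMES = 10
DEFAULT_BASE_HOP_MS = 10.0
DEFAULT_N_MELS = 128
DEFAULT_FLOOR_DB = -80.0
DEFAULT_RENDER_FMIN = 20.0
DEFAULT_IMAGE_SIZE = 256
DEFAULT_COLORMAP = "viridis"


class DegenerateFilterError(ValueError):
    """A mel filter has no FFT bin under its triangle; lower the band count M."""


@dataclass(frozen=True)
class PatchConfig:
    """Patch framing parameters.

    ``num_frames`` (the patch size) sets the analysis window to
    ``num_frames`` base hops; consecutive patches overlap by half a window.
    """

    num_frames: int = DEFAULT_NUM_FRAMES
    base_hop_ms: float = DEFAULT_BASE_HOP_MS
    sample_rate: float = 2500.0
    stft_window: str = "hamming"

    def __post_init__(self) -> None:
        if self.num_frames < 1:
            raise ValueError("num_frames must be >= 1")
        if self.base_hop_ms <= 0 or self.sample_rate <= 0:
            raise ValueError("base_hop_ms and sample_rate must be positive")

    @property
    def hop_samples(self) -> int:
        return int(round(self.base_hop_ms * self.sample_rate / 1000.0))

    @property
    def window_samples(self) -> int:
        return self.num_frames * self.hop_samples

    @property
    def shift_samples(self) -> int:
        return max(1, self.window_samples // 2)

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window_samples:
            raise ValueError("signal shorter than one analysis window")
        return (n_samples - self.window_samples) // self.shift_samples + 1


@dataclass
class StftGram:
    """One-sided STFT: complex spectrum X and power P = |X|^2, frames x bins."""

    X: np.ndarray
    P: np.ndarray
    n_fft: int
    bin_hz: float

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]

    @property
    def bin_freqs(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_hz


@dataclass
class MelFilterbank:
    """Triangular band-pass filters uniformly spaced on the mel axis."""

    weights: np.ndarray  # (M, bins)
    centers: np.ndarray  # Hz
    M: int
    f_min: float
    f_max: float

    def half_widths_hz(self) -> np.ndarray:
        """Hz distance from each center to the next edge (filter half-width)."""
        edges = np.concatenate(([self.f_min], self.centers, [self.f_max]))
        return np.diff(edges)[1:]

    def evaluate(self, f: float) -> np.ndarray:
        """Continuous triangular responses of all M filters at frequency f."""
        edges = np.concatenate(([self.f_min], self.centers, [self.f_max]))
        lower, center, upper = edges[:-2], edges[1:-1], edges[2:]
        up = (f - lower) / (center - lower)
        down = (upper - f) / (upper - center)
        return np.clip(np.minimum(up, down), 0.0, None)


@dataclass
class LogMelSpectrogram:
    """dB mel spectrogram normalized so the global maximum sits at 0 dB."""

    S_db: np.ndarray  # (frames, M)
    ref: float
    floor_db: float = DEFAULT_FLOOR_DB


@dataclass
class SpectrogramImage:
    """A rendered time-frequency image (time left->right, low freq at bottom)."""

    pixels: np.ndarray  # (size, size, 3) uint8
    time_range_ms: tuple[float, float]
    freq_bounds_hz: tuple[float, float]
    feature_kind: str = "plms"
    freq_axis: str = "log10"
    colormap: str = DEFAULT_COLORMAP
    meta: dict = field(default_factory=dict)

    def save(self, path: str) -> str:
        import imageio.v3 as iio

        iio.imwrite(path, self.pixels)
        return path


def frame_signal(y: np.ndarray, config: PatchConfig) -> np.ndarray:
    """Slice a mono signal into overlapping patches, frames x window_samples."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("frame_signal expects a mono 1-D signal")
    n = config.n_frames(len(y))
    shift, N = config.shift_samples, config.window_samples
    idx = shift * np.arange(n)[:, None] + np.arange(N)[None, :]
    return y[idx]


def stft(y: np.ndarray, config: PatchConfig) -> StftGram:
    """Hamming-windowed one-sided STFT over the patch framing; P = |X|^2."""
    frames = frame_signal(y, config)
    N = config.window_samples
    w = hamming_window(N)
    X = np.fft.rfft(frames * w[None, :], n=N, axis=1)
    P = np.abs(X) ** 2
    return StftGram(X=X, P=P, n_fft=N, bin_hz=config.sample_rate / N)


def mel_scale(f):
    """Perceptual frequency warp: f_mel = 2595 log10(1 + f / 700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def inverse_mel_scale(mel):
    """Exact inverse of :func:`mel_scale`."""
    mel = np.asarray(mel, dtype=np.float64)
    out = 700.0 * (10.0 ** (mel / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def build_mel_filterbank(
    M: int,
    f_min: float,
    f_max: float,
    n_fft: int,
    sample_rate: float,
) -> MelFilterbank:
    """Construct M triangular filters with centers uniform on the mel axis.

    The M + 2 edge frequencies are equally spaced between ``mel(f_min)`` and
    ``mel(f_max)``; filter m rises from edge m-1 to its center and falls to
    edge m+1, evaluated at the one-sided FFT bin frequencies.  A filter whose
    triangle covers no bin is degenerate and raises
    :class:`DegenerateFilterError` (use fewer bands).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0 <= f_min < f_max <= sample_rate / 2:
        raise ValueError("need 0 <= f_min < f_max <= sample_rate / 2")
    edges_mel = np.linspace(mel_scale(f_min), mel_scale(f_max), M + 2)
    edges_hz = inverse_mel_scale(edges_mel)
    n_bins = n_fft // 2 + 1
    fk = np.arange(n_bins) * sample_rate / n_fft
    lower, center, upper = edges_hz[:-2], edges_hz[1:-1], edges_hz[2:]
    up = (fk[None, :] - lower[:, None]) / (center - lower)[:, None]
    down = (upper[:, None] - fk[None, :]) / (upper - center)[:, None]
    weights = np.clip(np.minimum(up, down), 0.0, None)
    empty = ~weights.any(axis=1)
    if empty.any():
        bad = int(np.flatnonzero(empty)[0])
        raise DegenerateFilterError(
            f"mel filter {bad} covers no FFT bin at n_fft={n_fft}, "
            f"sample_rate={sample_rate}; lower M (currently {M})"
        )
    return MelFilterbank(weights=weights, centers=center, M=M, f_min=f_min, f_max=f_max)


def mel_spectrum(gram: StftGram, fb: MelFilterbank) -> np.ndarray:
    """Pool the power spectrum through the filterbank: S(n,m) = sum_k P H_m."""
    if gram.P.shape[1] != fb.weights.shape[1]:
        raise ValueError("filterbank bin count disagrees with the spectrogram")
    return gram.P @ fb.weights.T


def log_scale(S: np.ndarray, floor_db: float = DEFAULT_FLOOR_DB) -> LogMelSpectrogram:
    """dB against the global maximum: logS = 10 log10(S / max), clipped at floor."""
    S = np.asarray(S, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("mel energies must be non-negative")
    ref = float(S.max())
    if ref == 0.0:
        raise ValueError("silent input: all-zero mel spectrum has no reference level")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(S / ref)
    return LogMelSpectrogram(S_db=np.maximum(db, floor_db), ref=ref, floor_db=floor_db)


def log_frequency_remap(
    logmel: LogMelSpectrogram,
    fb: MelFilterbank,
    n_rows: int = DEFAULT_IMAGE_SIZE,
    f_render_min: float = DEFAULT_RENDER_FMIN,
) -> np.ndarray:
    """Interpolate mel-band values onto rows uniform in log10(f).

    Returns ``(n_rows, frames)`` with row 0 at ``f_render_min`` and the last
    row at the filterbank's ``f_max``; band values sit at their center
    frequencies and are linearly interpolated along the log axis (edge values
    extend beyond the outermost centers).
    """
    if f_render_min <= 0:
        raise ValueError("f_render_min must be positive")
    if f_render_min >= fb.f_max:
        raise ValueError("f_render_min must lie below the filterbank f_max")
    row_logf = np.linspace(np.log10(f_render_min), np.log10(fb.f_max), n_rows)
    center_logf = np.log10(fb.centers)
    out = np.empty((n_rows, logmel.S_db.shape[0]))
    for t in range(logmel.S_db.shape[0]):
        out[:, t] = np.interp(row_logf, center_logf, logmel.S_db[t])
    return out


def render_image(
    values: np.ndarray,
    colormap: str = DEFAULT_COLORMAP,
    size: int = DEFAULT_IMAGE_SIZE,
    floor_db: float = DEFAULT_FLOOR_DB,
    **meta,
) -> SpectrogramImage:
    """Render a (freq_rows, time_cols) dB array to a fixed-size RGB image.

    The dB range is mapped affinely (floor_db -> 0, 0 dB -> 1), resized with
    bilinear interpolation, colormapped to 8-bit RGB, and flipped so low
    frequency sits at the bottom of the image.  Deterministic byte-for-byte.
    """
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values cannot be rendered")
    unit = np.clip((values - floor_db) / (0.0 - floor_db), 0.0, 1.0)
    resized = _resize(unit, (size, size), order=1, mode="edge", anti_aliasing=False)
    rgb = colormaps[colormap](np.clip(resized, 0.0, 1.0), bytes=True)[..., :3]
    return SpectrogramImage(
        pixels=np.ascontiguousarray(rgb[::-1]),  # low frequency at the bottom
        time_range_ms=meta.pop("time_range_ms", (0.0, 0.0)),
        freq_bounds_hz=meta.pop("freq_bounds_hz", (0.0, 0.0)),
        feature_kind=meta.pop("feature_kind", "plms"),
        freq_axis=meta.pop("freq_axis", "log10"),
        colormap=colormap,
        meta=meta,
    )


def extract_plms(
    clip: AudioClip,
    config: PatchConfig | None = None,
    n_mels: int = DEFAULT_N_MELS,
    f_min: float = 0.0,
    f_render_min: float = DEFAULT_RENDER_FMIN,
    floor_db: float = DEFAULT_FLOOR_DB,
    colormap: str = DEFAULT_COLORMAP,
    size: int = DEFAULT_IMAGE_SIZE,
) -> SpectrogramImage:
    """Full PLMS pipeline on a preprocessed mono clip."""
    if clip.n_channels != 1:
        raise ValueError("extract_plms expects a mono clip; run preprocessing first")
    if config is None:
        config = PatchConfig(sample_rate=clip.sample_rate)
    if config.sample_rate != clip.sample_rate:
        raise ValueError("PatchConfig sample_rate disagrees with the clip")
    y = clip.samples[0]
    gram = stft(y, config)
    fb = build_mel_filterbank(n_mels, f_min, clip.sample_rate / 2.0, gram.n_fft, clip.sample_rate)
    S = mel_spectrum(gram, fb)
    logmel = log_scale(S, floor_db=floor_db)
    remapped = log_frequency_remap(logmel, fb, n_rows=size, f_render_min=f_render_min)
    return render_image(
        remapped,
        colormap=colormap,
        size=size,
        floor_db=floor_db,
        time_range_ms=(0.0, clip.duration_ms),
        freq_bounds_hz=(f_render_min, clip.sample_rate / 2.0),
        feature_kind="plms",
        freq_axis="log10",
        n_mels=n_mels,
        num_frames=config.num_frames,
    )
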