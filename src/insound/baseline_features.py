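"""Classical time-frequency baselines rendered through the shared image backend.

Four comparison representations for the PLMS feature: the plain STFT
spectrogram, a Morlet wavelet scalogram, the pseudo Wigner-Ville
distribution, and the generalized S-transform.  All are emitted as the same
256x256x3 byte-deterministic images (time left to right, frequency bottom to
top on a linear axis) so that downstream training and evaluation are
feature-agnostic.

The hyperparameters of these baselines (window lengths, scale grids, the
generalized-S kernel) are package defaults; published flowcharts of such
comparisons rarely pin them down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import hilbert

from .audio_io import AudioClip
from .plms_features import (
    DEFAULT_COLORMAP,
    DEFAULT_FLOOR_DB,
    DEFAULT_IMAGE_SIZE,
    PatchConfig,
    SpectrogramImage,
    log_scale,
    render_image,
    stft,
)
from .preprocess import hamming_window

__all__ = [
    "BaselineConfig",
    "stft_image",
    "wavelet_image",
    "wigner_ville_image",
    "s_transform_image",
    "extract_feature",
]


@dataclass(frozen=True)
class BaselineConfig:
    """Knobs for the four baselines.

    ``wvd_mode='analytic'`` computes the pseudo Wigner-Ville distribution of
    the analytic signal (cross-terms between positive and negative frequency
    images suppressed); ``'pseudo'`` works on the raw real signal and shows
    the classic midpoint interference.  The generalized S-transform uses a
    Gaussian window of frequency-dependent width sigma(f) = 1 / (gamma f^p);
    gamma = p = 1 is the standard S-transform.
    """

    wavelet_name: str = "morl"
    wvd_mode: str = "analytic"
    st_gamma: float = 1.0
    st_power: float = 1.0
    n_freq_rows: int = 128
    n_time_cols: int = 256

    def __post_init__(self) -> None:
        if self.st_gamma <= 0 or self.st_power <= 0:
            raise ValueError("st_gamma and st_power must be positive")
        if self.wvd_mode not in ("analytic", "pseudo"):
            raise ValueError("wvd_mode must be 'analytic' or 'pseudo'")


def _mono_signal(clip: AudioClip) -> np.ndarray:
    if clip.n_channels != 1:
        raise ValueError("baseline features expect a mono clip; run preprocessing first")
    return clip.samples[0]


def _db_or_floor(power: np.ndarray, floor_db: float) -> np.ndarray:
    """dB against the global max; an all-zero (silent) input maps to the floor."""
    if power.max() == 0.0:
        return np.full(power.shape, floor_db)
    return log_scale(power, floor_db=floor_db).S_db


def _finish(values_db, clip, kind, floor_db, colormap, size, f_lo, f_hi, freq_axis="linear"):
    return render_image(
        values_db,
        colormap=colormap,
        size=size,
        floor_db=floor_db,
        time_range_ms=(0.0, clip.duration_ms),
        freq_bounds_hz=(f_lo, f_hi),
        feature_kind=kind,
        freq_axis=freq_axis,
    )


def stft_image(
    clip: AudioClip,
    config: BaselineConfig | None = None,
    patch: PatchConfig | None = None,
    floor_db: float = DEFAULT_FLOOR_DB,
    colormap: str = DEFAULT_COLORMAP,
    size: int = DEFAULT_IMAGE_SIZE,
) -> SpectrogramImage:
    """Short-time Fourier power spectrogram on a linear frequency axis."""
    y = _mono_signal(clip)
    if patch is None:
        patch = PatchConfig(sample_rate=clip.sample_rate)
    gram = stft(y, patch)
    db = _db_or_floor(gram.P, floor_db)
    return _finish(db.T, clip, "stft", floor_db, colormap, size, 0.0, clip.sample_rate / 2)


def wavelet_image(
    clip: AudioClip,
    config: BaselineConfig | None = None,
    floor_db: float = DEFAULT_FLOOR_DB,
    colormap: str = DEFAULT_COLORMAP,
    size: int = DEFAULT_IMAGE_SIZE,
    f_min: float = 20.0,
) -> SpectrogramImage:
    """Continuous Morlet scalogram, scales log-spaced over [f_min, f_t/2]."""
    config = config or BaselineConfig()
    y = _mono_signal(clip)
    fs = clip.sample_rate
    freqs = np.logspace(np.log10(f_min), np.log10(fs / 2), config.n_freq_rows)
    center = pywt.scale2frequency(config.wavelet_name, 1.0)  # cycles per sample at scale 1
    scales = center * fs / freqs
    coef, _ = pywt.cwt(y, scales, config.wavelet_name, sampling_period=1.0 / fs)
    power = np.abs(coef) ** 2  # rows follow `freqs` (ascending frequency)
    step = max(1, power.shape[1] // config.n_time_cols)
    db = _db_or_floor(power[:, ::step], floor_db)
    return _finish(db, clip, "wavelet", floor_db, colormap, size, f_min, fs / 2, freq_axis="log10")


def wigner_ville_image(
    clip: AudioClip,
    config: BaselineConfig | None = None,
    floor_db: float = DEFAULT_FLOOR_DB,
    colormap: str = DEFAULT_COLORMAP,
    size: int = DEFAULT_IMAGE_SIZE,
    max_lag: int = 127,
) -> SpectrogramImage:
    """Pseudo Wigner-Ville distribution, dB of the real part's magnitude.

    The instantaneous autocorrelation x(t+tau) x*(t-tau) is windowed in lag
    by a Hamming taper (the "pseudo" smoothing) and Fourier transformed.
    Because the lag kernel advances at twice the signal frequency, FFT bin k
    of an n-point lag transform sits at f = k f_s / (2 n); with the analytic
    signal the full bin range covers 0..f_s/2.
    """
    config = config or BaselineConfig()
    y = _mono_signal(clip)
    fs = clip.sample_rate
    x = hilbert(y) if config.wvd_mode == "analytic" else y.astype(complex)
    n = len(x)
    L = int(min(max_lag, (n - 1) // 2))
    m = min(config.n_time_cols, n - 2 * L)
    # mirror-symmetric center grid so time reversal maps the image exactly
    raw = np.rint(np.linspace(L, n - 1 - L, m)).astype(int)
    centers = raw.copy()
    centers[m - 1 - np.arange(m // 2)] = n - 1 - raw[: m // 2]
    taus = np.arange(-L, L + 1)
    taper = hamming_window(2 * L + 1)
    kernel = x[centers[:, None] + taus[None, :]] * np.conj(x[centers[:, None] - taus[None, :]])
    kernel *= taper[None, :]
    nfft = 2 * L + 1
    W = np.real(np.fft.fft(np.fft.ifftshift(kernel, axes=1), n=nfft, axis=1))
    freqs = np.arange(nfft) * fs / (2.0 * nfft)
    keep = freqs <= fs / 2.0
    mag = np.abs(W[:, keep]).T  # (freq rows ascending, time cols)
    db = _db_or_floor(mag, floor_db)
    return _finish(db, clip, "wvd", floor_db, colormap, size, 0.0, float(freqs[keep][-1]))


def s_transform_image(
    clip: AudioClip,
    config: BaselineConfig | None = None,
    floor_db: float = DEFAULT_FLOOR_DB,
    colormap: str = DEFAULT_COLORMAP,
    size: int = DEFAULT_IMAGE_SIZE,
) -> SpectrogramImage:
    """Generalized S-transform with sigma(f) = 1 / (gamma f^p).

    Computed in the frequency domain: row f_n is the inverse FFT of the
    shifted spectrum X(k + n) multiplied by the Gaussian
    exp(-2 pi^2 (k df)^2 sigma(f_n)^2).  The f = 0 row carries the signal
    mean.  gamma = p = 1 reduces to the standard S-transform.
    """
    config = config or BaselineConfig()
    y = _mono_signal(clip)
    fs = clip.sample_rate
    n = len(y)
    X = np.fft.fft(y)
    df = fs / n
    half = n // 2
    rows_idx = np.unique(np.linspace(1, half, min(config.n_freq_rows, half), dtype=int))
    k = np.arange(n)
    k_shift = np.where(k <= half, k, k - n) * df  # centered frequency offsets in Hz
    S = np.empty((len(rows_idx) + 1, n), dtype=complex)
    S[0] = np.mean(y)  # f = 0 row: the localizing window degenerates, keep the mean
    for i, nn in enumerate(rows_idx):
        f = nn * df
        sigma = 1.0 / (config.st_gamma * f**config.st_power)
        gauss = np.exp(-2.0 * np.pi**2 * (k_shift**2) * sigma**2)
        S[i + 1] = np.fft.ifft(np.roll(X, -nn) * gauss)
    freqs = np.concatenate(([0.0], rows_idx * df))
    step = max(1, n // config.n_time_cols)
    mag = np.abs(S[:, ::step]) ** 2
    db = _db_or_floor(mag, floor_db)
    return _finish(db, clip, "stransform", floor_db, colormap, size, 0.0, float(freqs[-1]))


_EXTRACTORS = {
    "stft": stft_image,
    "wavelet": wavelet_image,
    "wvd": wigner_ville_image,
    "stransform": s_transform_image,
}


def extract_feature(clip: AudioClip, feature: str, **kwargs) -> SpectrogramImage:
    """Dispatch to PLMS or one of the baselines by feature name."""
    if feature == "plms":
        from .plms_features import extract_plms

        return extract_plms(clip, **kwargs)
    try:
        fn = _EXTRACTORS[feature]
    except KeyError:
        raise ValueError(f"unknown feature {feature!r}; choose plms|stft|wavelet|wvd|stransform")
    return fn(clip, **kwargs)
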