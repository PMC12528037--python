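"""Adaptive preprocessing: FIR low-pass filtering and anti-aliased downsampling.

The pipeline reduces a 16 kHz multi-channel clip to a low-rate mono signal
while preserving the low-frequency band where the energy of insect sound
lives.  Filtering uses the window design method: an ideal sinc impulse
response truncated by a Hamming taper, giving exactly linear phase.
Downsampling evaluates a Hamming-windowed finite-support sinc kernel at
fractional sample positions after an anti-alias low-pass at half the target
rate (the Nyquist requirement f_t >= 2 f_max).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .audio_io import AudioClip, to_mono

__all__ = [
    "FIRFilter",
    "ResampleSpec",
    "antialias_cutoff_hz",
    "design_lowpass_fir",
    "apply_fir",
    "resample",
    "preprocess_clip",
]

DEFAULT_FIR_ORDER = 100
DEFAULT_KERNEL_HALFWIDTH = 64


def hamming_window(length: int) -> np.ndarray:
    """w[n] = 0.54 - 0.46 cos(2 pi n / (N-1)), n = 0..N-1.

    Built from one half and mirrored so the window (and any filter designed
    from it) is symmetric to the last bit.
    """
    if length == 1:
        return np.ones(1)
    half = (length + 1) // 2
    n = np.arange(half)
    w = np.empty(length)
    w[:half] = 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (length - 1))
    w[length - half :] = w[:half][::-1]
    return w


@dataclass(frozen=True)
class FIRFilter:
    """Linear-phase low-pass taps designed by the Hamming window method."""

    coefficients: np.ndarray
    order: int
    cutoff_hz: float
    sample_rate: float
    design_window: str = "hamming"

    @property
    def group_delay(self) -> int:
        return self.order // 2

    def magnitude_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """|H(f)| evaluated by direct DFT of the taps at arbitrary frequencies."""
        f = np.atleast_1d(np.asarray(freqs_hz, dtype=float)) / self.sample_rate
        n = np.arange(self.order + 1)
        return np.abs(np.exp(-2j * np.pi * np.outer(f, n)) @ self.coefficients)


@dataclass(frozen=True)
class ResampleSpec:
    """Windowed-sinc downsampling parameters (ratio R = f_t / f_s)."""

    source_rate: float
    target_rate: float
    kernel_halfwidth: int = DEFAULT_KERNEL_HALFWIDTH
    kernel_window: str = "hamming"
    antialias_order: int = DEFAULT_FIR_ORDER

    def __post_init__(self) -> None:
        if self.target_rate <= 0 or self.source_rate <= 0:
            raise ValueError("rates must be positive")
        if self.target_rate > self.source_rate:
            raise ValueError("upsampling is unsupported; target rate must not exceed source rate")
        if self.kernel_halfwidth < 1:
            raise ValueError("kernel_halfwidth must be >= 1")

    @property
    def ratio(self) -> float:
        return self.target_rate / self.source_rate


HAMMING_TRANSITION_FACTOR = 3.3  # approximate transition width: 3.3 f_s / taps


def antialias_cutoff_hz(source_rate: float, target_rate: float, order: int) -> float:
    """Design cutoff for the pre-decimation low-pass.

    The filter's stopband edge — not its -6 dB point — must sit at the new
    Nyquist frequency ``target_rate / 2``, otherwise half the transition band
    folds back on decimation.  The design cutoff is therefore shaded down by
    half the Hamming transition width (clamped so at least half the target
    band survives for very short filters).
    """
    delta = HAMMING_TRANSITION_FACTOR * source_rate / (order + 1)
    return max(target_rate / 2.0 - delta / 2.0, target_rate / 4.0)


def design_lowpass_fir(cutoff_hz: float, sample_rate: float, order: int = DEFAULT_FIR_ORDER) -> FIRFilter:
    """Design a type-I linear-phase low-pass FIR by the window method.

    Taps are ``h[k] = h_ideal(k - order/2) * w[k]`` over ``order + 1`` points,
    where ``h_ideal(n) = sin(2 pi f_n n) / (pi n)`` with the normalized cutoff
    ``f_n = cutoff_hz / sample_rate`` (limit value ``2 f_n`` at n = 0) and
    ``w`` the Hamming window.  Taps are rescaled to unit DC gain so a constant
    signal passes unchanged.
    """
    if not 0 < cutoff_hz < sample_rate / 2:
        raise ValueError("cutoff must lie strictly between 0 and the Nyquist frequency")
    if order < 2 or order % 2 != 0:
        raise ValueError("order must be an even integer >= 2 (type-I linear phase)")
    fn = cutoff_hz / sample_rate
    n = np.arange(order + 1) - order // 2
    h_ideal = np.empty(order + 1)
    nz = n != 0
    h_ideal[nz] = np.sin(2.0 * np.pi * fn * n[nz]) / (np.pi * n[nz])
    h_ideal[~nz] = 2.0 * fn
    taps = h_ideal * hamming_window(order + 1)
    taps /= taps.sum()  # unit DC gain
    return FIRFilter(coefficients=taps, order=order, cutoff_hz=cutoff_hz, sample_rate=sample_rate)


def apply_fir(clip: AudioClip, filt: FIRFilter) -> AudioClip:
    """Convolve every channel with the filter, compensating the group delay.

    Output has the same length as the input; edges see zero-extension.
    """
    taps = filt.coefficients
    if len(taps) > clip.n_samples:
        raise ValueError("filter longer than the signal")
    d = filt.group_delay
    out = np.empty_like(clip.samples)
    for c in range(clip.n_channels):
        full = np.convolve(clip.samples[c], taps, mode="full")
        out[c] = full[d : d + clip.n_samples]
    return replace(clip, samples=out)


def _sinc_kernel_rows(t: np.ndarray, halfwidth: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer tap positions and windowed-sinc weights for fractional times t."""
    base = np.floor(t).astype(int)
    offsets = np.arange(-halfwidth + 1, halfwidth + 1)
    k = base[:, None] + offsets[None, :]
    d = t[:, None] - k  # in (-halfwidth, halfwidth]
    # Hamming taper over the kernel support [-hw, hw]
    w = 0.54 + 0.46 * np.cos(np.pi * d / halfwidth)
    return k, np.sinc(d) * w


def resample(clip: AudioClip, target_rate: float, spec: ResampleSpec | None = None) -> AudioClip:
    """Anti-aliased windowed-sinc downsampling to ``target_rate``.

    An anti-alias FIR at cutoff ``target_rate / 2`` is applied first, then
    ``y'(n) = sum_k x(k) sinc(n/R - k) w(k)`` is evaluated with a
    Hamming-windowed finite-support sinc kernel.  Output length is
    ``floor(n_samples * f_t / f_s)``; the identity path (equal rates) bypasses
    both stages.
    """
    if spec is None:
        spec = ResampleSpec(source_rate=clip.sample_rate, target_rate=target_rate)
    if spec.source_rate != clip.sample_rate:
        raise ValueError("spec.source_rate disagrees with the clip's sample rate")
    if target_rate != spec.target_rate:
        raise ValueError("spec.target_rate disagrees with target_rate")
    if target_rate == clip.sample_rate:
        return replace(clip, samples=clip.samples.copy())

    cutoff = antialias_cutoff_hz(clip.sample_rate, target_rate, spec.antialias_order)
    filt = design_lowpass_fir(cutoff, clip.sample_rate, spec.antialias_order)
    filtered = apply_fir(clip, filt)

    ratio = spec.ratio
    n_out = int(np.floor(clip.n_samples * ratio))
    t = np.arange(n_out) / ratio
    hw = spec.kernel_halfwidth
    k, weights = _sinc_kernel_rows(t, hw)
    padded = np.pad(filtered.samples, ((0, 0), (hw, hw)))  # zero-extension at edges
    idx = np.clip(k + hw, 0, padded.shape[1] - 1)
    oob = (k < -hw) | (k >= clip.n_samples + hw)
    w = np.where(oob, 0.0, weights)
    out = np.einsum("ctk,tk->ct", padded[:, idx], w, optimize=True)
    return replace(clip, samples=out, sample_rate=float(target_rate))


def sinc_resample_bruteforce(
    x: np.ndarray, ratio: float, n_out: int, halfwidth: int | None = None
) -> np.ndarray:
    """Direct all-k evaluation of the sinc interpolation sum.

    Independent reference for the fast gather-based kernel: every input sample
    contributes ``x(k) sinc(n/R - k) w(n/R - k)`` to every output sample, with
    the Hamming taper ``w`` zero outside ``|n/R - k| <= halfwidth``.  Passing
    ``halfwidth=None`` drops the taper entirely (the ideal band-limited
    interpolator, useful for amplitude checks).  O(n_out * len(x)); only usable
    on small instances.
    """
    k = np.arange(len(x))
    t = np.arange(n_out) / ratio
    d = t[:, None] - k[None, :]
    kernel = np.sinc(d)
    if halfwidth is not None:
        taper = 0.54 + 0.46 * np.cos(np.pi * d / halfwidth)
        kernel = kernel * np.where(np.abs(d) <= halfwidth, taper, 0.0)
    return kernel @ x


def preprocess_clip(
    clip: AudioClip,
    target_rate: float,
    order: int = DEFAULT_FIR_ORDER,
    mono_mode: str = "mean",
    kernel_halfwidth: int = DEFAULT_KERNEL_HALFWIDTH,
) -> AudioClip:
    """Full preprocessing: mono mixdown, low-pass at f_t/2, downsample to f_t."""
    mono = to_mono(clip, mode=mono_mode)
    if target_rate == mono.sample_rate:
        return mono
    spec = ResampleSpec(
        source_rate=mono.sample_rate,
        target_rate=target_rate,
        kernel_halfwidth=kernel_halfwidth,
        antialias_order=order,
    )
    return resample(mono, target_rate, spec)
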