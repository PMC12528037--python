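"""Seeded generator of a 12-class insect-like sound corpus.

Clips mimic the reference recording format — four channels, 2500 ms at
16 kHz — with class-specific acoustic signatures built from the ingredients
of real insect sound: a harmonic stack at a fundamental (wingbeat or
stridulation pitch), slow amplitude modulation (wingbeat envelope), optional
pulse-train gating (stridulation bursts), and broadband noise at a
class-specific signal-to-noise ratio.  Fundamentals and harmonics stay below
1250 Hz so the whole discriminative band survives downsampling to 2500 Hz,
matching the low-frequency concentration of the insects the pipeline
targets.  Class loudness spans more than 30 dB, from very loud to nearly
inaudible.

What this corpus does NOT emulate: real wing-kinematic waveforms, room or
enclosure acoustics, microphone-array geometry (channels differ only by gain
and sub-millisecond delay), or non-stationary behavioral sequences.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .audio_io import AudioClip, DatasetManifest, write_wav

__all__ = [
    "SpeciesSpec",
    "SyntheticCorpusConfig",
    "default_species_bank",
    "synthesize_clip",
    "generate_corpus",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Acoustic signature of one synthetic class."""

    name: str
    f0_hz: float
    n_harmonics: int
    am_rate_hz: float
    pulse_rate_hz: float = 0.0
    pulse_duty: float = 0.5
    snr_db: float = 20.0
    gain_db: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.f0_hz <= 1250.0:
            raise ValueError("fundamental must lie in (0, 1250] Hz")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Corpus-level layout; defaults match the reference clip format."""

    n_per_class: int = 40
    duration_ms: float = 2500.0
    sample_rate: float = 16000.0
    channels: int = 4
    seed: int = 0


def default_species_bank() -> list[SpeciesSpec]:
    """Twelve classes with pairwise-distinct (f0, AM, pulse) signatures.

    Loudness spans 33 dB; every fundamental (and every synthesized harmonic)
    sits below 1250 Hz.
    """
    return [
        SpeciesSpec("buzzer_loud", 150.0, 6, 8.0, 0.0, 0.5, 30.0, 0.0),
        SpeciesSpec("whiner_faint", 320.0, 3, 25.0, 0.0, 0.5, 12.0, -30.0),
        SpeciesSpec("gnat_soft", 220.0, 4, 14.0, 0.0, 0.5, 18.0, -12.0),
        SpeciesSpec("tapper_slow", 90.0, 5, 0.0, 6.0, 0.3, 20.0, -6.0),
        SpeciesSpec("hover_fast", 400.0, 3, 30.0, 0.0, 0.5, 24.0, -9.0),
        SpeciesSpec("rasper_low", 110.0, 8, 5.0, 2.0, 0.5, 22.0, -15.0),
        SpeciesSpec("aphid_thin", 480.0, 2, 18.0, 0.0, 0.5, 10.0, -27.0),
        SpeciesSpec("chirper_mid", 140.0, 7, 11.0, 4.0, 0.4, 20.0, -18.0),
        SpeciesSpec("shield_burst", 190.0, 6, 7.0, 8.0, 0.25, 25.0, -3.0),
        SpeciesSpec("drummer_high", 260.0, 4, 21.0, 0.0, 0.5, 16.0, -21.0),
        SpeciesSpec("whitefly_trill", 600.0, 2, 40.0, 0.0, 0.5, 14.0, -24.0),
        SpeciesSpec("moth_pulse", 70.0, 4, 9.0, 12.0, 0.5, 18.0, -33.0),
    ]


MAX_HARMONIC_HZ = 1200.0  # keep all partials inside the 2500 Hz pipeline band
AM_DEPTH = 0.8
F0_JITTER = 0.03
PEAK_LEVEL = 0.9
MAX_DELAY_MS = 1.0


def synthesize_clip(
    spec: SpeciesSpec,
    config: SyntheticCorpusConfig | None = None,
    seed: int = 0,
    label: int | None = None,
    include_noise: bool = True,
) -> AudioClip:
    """Render one seeded clip of a species.

    The mono source is a 1/h-weighted harmonic stack at a jittered
    fundamental, amplitude-modulated, optionally gated by a pulse train, plus
    white noise at ``snr_db``.  Channels share the source with per-channel
    gains in [0.7, 1] and integer-sample delays up to 1 ms; the mix is
    peak-normalized to 0.9 before the class gain is applied.
    """
    config = config or SyntheticCorpusConfig()
    rng = np.random.default_rng(seed)
    n = int(round(config.duration_ms * config.sample_rate / 1000.0))
    t = np.arange(n) / config.sample_rate

    f0 = spec.f0_hz * (1.0 + rng.uniform(-F0_JITTER, F0_JITTER))
    sig = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        fh = f0 * h
        if fh > MAX_HARMONIC_HZ:
            break
        sig += np.sin(2.0 * np.pi * fh * t + rng.uniform(0, 2 * np.pi)) / h
    if spec.am_rate_hz > 0:
        env = 1.0 - AM_DEPTH + AM_DEPTH * 0.5 * (
            1.0 + np.sin(2.0 * np.pi * spec.am_rate_hz * t + rng.uniform(0, 2 * np.pi))
        )
        sig *= env
    if spec.pulse_rate_hz > 0:
        phase = (t * spec.pulse_rate_hz + rng.uniform(0, 1)) % 1.0
        sig *= np.where(phase < spec.pulse_duty, 1.0, 0.0)
    if include_noise:
        sig_rms = np.sqrt(np.mean(sig**2)) or 1.0
        noise_rms = sig_rms * 10.0 ** (-spec.snr_db / 20.0)
        sig = sig + rng.normal(0.0, noise_rms, n)

    max_delay = int(round(MAX_DELAY_MS * config.sample_rate / 1000.0))
    channels = np.empty((config.channels, n))
    for c in range(config.channels):
        gain = rng.uniform(0.7, 1.0)
        delay = int(rng.integers(0, max_delay + 1))
        channels[c] = gain * np.roll(sig, delay)

    peak = np.abs(channels).max() or 1.0
    channels *= PEAK_LEVEL / peak
    channels *= 10.0 ** (spec.gain_db / 20.0)
    return AudioClip(
        samples=channels,
        sample_rate=config.sample_rate,
        label=label,
        source_id=f"{spec.name}_seed{seed}",
    )


def _clip_seed(master_seed: int, label: int, index: int) -> int:
    # deterministic per-clip seed below 2**31
    return int(np.random.SeedSequence((master_seed, label, index)).generate_state(1)[0] % (2**31))


def generate_corpus(config: SyntheticCorpusConfig, out_dir: str) -> DatasetManifest:
    """Write n_per_class x 12 WAV clips plus a CSV manifest and spec-bank JSON.

    Balanced by construction; file bytes are identical for identical seeds.
    """
    bank = default_species_bank()
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for label, spec in enumerate(bank):
        for i in range(config.n_per_class):
            clip = synthesize_clip(spec, config, seed=_clip_seed(config.seed, label, i), label=label)
            fname = f"{label:02d}_{spec.name}_{i:03d}.wav"
            write_wav(clip, os.path.join(out_dir, fname), bit_depth="float32")
            rows.append({"path": fname, "label": label, "split": "train"})
    with open(os.path.join(out_dir, "species_bank.json"), "w") as fh:
        json.dump([asdict(s) for s in bank], fh, indent=2)
    manifest = DatasetManifest(
        records=pd.DataFrame(rows),
        class_names=[s.name for s in bank],
        seed=config.seed,
        root=out_dir,
    )
    manifest.save(os.path.join(out_dir, "manifest.csv"))
    return manifest
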