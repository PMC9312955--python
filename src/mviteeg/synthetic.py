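"""Synthetic labelled EEG with a controllable preictal spectral signature.

Interictal activity is modelled as per-channel pink (1/f) noise with a
per-subject gain, the canonical EEG-like background.  Preictal clips share the
identical background realisation and add a signature on top:

* a band-limited oscillation in ``sig_band`` whose envelope ramps linearly
  from zero at clip start to ``snr * RMS(background)`` at clip end, emulating
  power building up towards seizure onset, and
* Poisson-timed 70-ms biphasic transient bursts (spike-like events).

With ``snr = 0`` the signature vanishes entirely, so matched preictal and
interictal clips are bit-identical — the null condition for the pipeline.
Every random stream is derived by seeding per (subject, clip, channel, role),
so regeneration is reproducible clip-by-clip.

This generator reproduces the one statistical premise the classifier relies
on — preictal segments carry more power than interictal ones in the same
time-frequency scales — and nothing else about real seizure dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ConfigError
from .io import EEGClip

#: baseline background RMS in microvolts before per-subject gain
_BASE_RMS_UV = 10.0
#: pink-noise spectral floor (Hz): below this 1/sqrt(f) shaping is clamped
_PINK_FLOOR_HZ = 0.1
#: burst kernel duration (s): one positive then one negative half-sine lobe
_BURST_DUR_S = 0.070
#: burst amplitude as a multiple of the background RMS
_BURST_AMP_RMS = 3.0
#: per-subject gain range, log-uniform (inter-subject shift for LOSO)
_GAIN_RANGE = (0.7, 1.4)

_ROLE_GAIN = 0
_ROLE_BACKGROUND = 1
_ROLE_SIGNATURE = 2


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for one synthetic dataset.

    snr is the preictal signature amplitude at clip end, as a multiple of the
    background RMS; sig_band is the (f_lo, f_hi) band of the preictal
    oscillation in Hz; burst_rate is in bursts per minute.
    """

    n_subjects: int = 4
    clips_per_class: int = 10
    n_channels: int = 4
    fs: float = 100.0
    clip_len_s: float = 120.0
    snr: float = 2.0
    sig_band: tuple[float, float] = (18.0, 24.0)
    burst_rate: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.clips_per_class < 1 or self.n_channels < 1:
            raise ConfigError("n_subjects, clips_per_class, n_channels must be >= 1")
        if self.snr < 0:
            raise ConfigError(f"snr must be >= 0, got {self.snr}")
        f_lo, f_hi = self.sig_band
        if not (0 < f_lo < f_hi):
            raise ConfigError(f"sig_band must satisfy 0 < f_lo < f_hi, got {self.sig_band}")
        if self.fs <= 2 * f_hi:
            raise ConfigError(
                f"fs={self.fs} must exceed twice the signature band top {f_hi} Hz"
            )
        n = self.clip_len_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"clip_len_s * fs = {n} is not an integer sample count"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.clip_len_s * self.fs))


def _rng(cfg: SynthConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, *key)))


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS pink noise: white-noise spectrum shaped by 1/sqrt(f), f floored."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, _PINK_FLOOR_HZ))
    spec[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.sqrt(np.mean(x**2))


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS noise whose spectrum is confined to ``band`` (hard mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _burst_kernel(fs: float) -> np.ndarray:
    """Biphasic unit-peak transient: positive then negative half-sine lobe."""
    n = max(2, int(round(_BURST_DUR_S * fs)))
    half = n // 2
    lobe = np.sin(np.pi * np.arange(half) / half)
    return np.concatenate([lobe, -np.sin(np.pi * np.arange(n - half) / (n - half))])


def _signature(
    rng: np.random.Generator, cfg: SynthConfig, rms_bg: float
) -> np.ndarray:
    """Preictal add-on for one channel: ramped band oscillation + bursts."""
    n = cfg.n_samples
    osc = _band_noise(rng, n, cfg.fs, cfg.sig_band)
    ramp = np.linspace(0.0, 1.0, n, endpoint=True)
    sig = osc * ramp * (cfg.snr * rms_bg)
    kernel = _burst_kernel(cfg.fs) * (_BURST_AMP_RMS * rms_bg)
    n_bursts = rng.poisson(cfg.burst_rate * cfg.clip_len_s / 60.0)
    starts = rng.integers(0, n, size=n_bursts)
    for s in np.sort(starts):
        end = min(n, s + len(kernel))
        sig[s:end] += kernel[: end - s]
    return sig


def generate_clip_pair(cfg: SynthConfig, subject: int, clip_idx: int) -> tuple[EEGClip, EEGClip]:
    """Generate the matched (preictal, interictal) clip pair for one index.

    Both clips share the identical background realisation; the preictal member
    adds the signature (nothing at all when snr == 0)."""
    gain_rng = _rng(cfg, subject, _ROLE_GAIN)
    lo, hi = _GAIN_RANGE
    gain = float(np.exp(gain_rng.uniform(np.log(lo), np.log(hi))))
    n = cfg.n_samples
    bg = np.empty((cfg.n_channels, n))
    sig = np.zeros_like(bg)
    for c in range(cfg.n_channels):
        bg_rng = _rng(cfg, subject, clip_idx, c, _ROLE_BACKGROUND)
        bg[c] = _pink_noise(bg_rng, n, cfg.fs) * (_BASE_RMS_UV * gain)
        if cfg.snr > 0:
            sig_rng = _rng(cfg, subject, clip_idx, c, _ROLE_SIGNATURE)
            rms_bg = float(np.sqrt(np.mean(bg[c] ** 2)))
            sig[c] = _signature(sig_rng, cfg, rms_bg)
    names = [f"ch{c:02d}" for c in range(cfg.n_channels)]
    subj = f"subj{subject:02d}"
    pre = EEGClip(
        subject_id=subj,
        clip_id=f"{subj}_preictal_{clip_idx:03d}",
        label="preictal",
        fs=cfg.fs,
        channel_names=names,
        data=bg + sig if cfg.snr > 0 else bg.copy(),
        provenance="synthetic",
    )
    inter = EEGClip(
        subject_id=subj,
        clip_id=f"{subj}_interictal_{clip_idx:03d}",
        label="interictal",
        fs=cfg.fs,
        channel_names=names,
        data=bg.copy(),
        provenance="synthetic",
    )
    return pre, inter


def iter_dataset(cfg: SynthConfig) -> Iterator[EEGClip]:
    for s in range(cfg.n_subjects):
        for i in range(cfg.clips_per_class):
            pre, inter = generate_clip_pair(cfg, s, i)
            yield pre
            yield inter


def generate_dataset(cfg: SynthConfig) -> list[EEGClip]:
    """Generate ``n_subjects * 2 * clips_per_class`` labelled clips.

    Fully determined by ``cfg`` (including its seed)."""
    return list(iter_dataset(cfg))
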