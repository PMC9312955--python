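"""Segmentation and CWT scalogram generation.

A 10-min clip is split into 60 non-overlapping 10-s segments; the continuous
wavelet transform of each segment channel yields an ``h x d`` image of wavelet
power ("scalogram"), one image per channel per segment.  At 256 Hz a segment
is 2560 samples, at 400 Hz it is 4000; with the default 100 scales the raw
scalogram is 100 x 2560 / 100 x 4000.

The mother wavelet is the analytic Morlet

    psi(t) = pi^(-1/4) * exp(i*w0*t) * exp(-t^2/2),      w0 = 6,

scaled as ``psi_s(t) = s^(-1/2) psi(t/s)`` so the scale mapping to centre
frequency is ``f = w0 / (2 pi s)``.  Scales are chosen so the centre
frequencies are log-spaced on [f_min, f_max], stored in descending order
(highest frequency = top row).  The transform is a zero-padded discrete
convolution of the signal with the explicitly sampled wavelet (evaluated by
FFT, truncated at |t| <= 5 s·scale); the cone of influence is not masked.

The modelling pipeline applied after |W|^2 is, in order: optional log1p,
optional bilinear resize to (H, W), optional per-image z-scoring.  Raw
100 x 4000 images are impractical token grids, so the modelling preset
resizes to 64 x 256.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .errors import ConfigError, DataError
from .io import EEGClip

SEGMENT_LEN_S = 10.0
MORLET_OMEGA0 = 6.0
#: wavelet support truncation, in units of the scale's Gaussian width
_SUPPORT_SIGMAS = 5.0


@dataclass
class EEGSegment:
    """One 10-s multichannel chunk of a clip; inherits the clip label."""

    subject_id: str
    clip_id: str
    label: str
    segment_index: int
    fs: float
    data: np.ndarray  # (N, d) microvolts

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ScalogramConfig:
    """Scalogram generation settings.

    f_max=None means min(fs/2, 50 Hz), resolved per clip.  The post-power
    pipeline order is fixed: log1p -> resize -> z-score.
    """

    n_scales: int = 100
    f_min: float = 0.5
    f_max: float | None = None
    omega0: float = MORLET_OMEGA0
    log_power: bool = True
    resize_to: tuple[int, int] | None = None
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.n_scales < 2:
            raise ConfigError(f"n_scales must be >= 2, got {self.n_scales}")
        if self.f_min <= 0:
            raise ConfigError(f"f_min must be > 0, got {self.f_min}")
        if self.f_max is not None and self.f_max <= self.f_min:
            raise ConfigError(f"need f_min < f_max, got [{self.f_min}, {self.f_max}]")
        if self.resize_to is not None and (self.resize_to[0] < 1 or self.resize_to[1] < 1):
            raise ConfigError(f"bad resize_to {self.resize_to}")

    @classmethod
    def modeling_default(cls) -> "ScalogramConfig":
        """Preset used for transformer input: log power, 64x256, z-scored."""
        return cls(log_power=True, resize_to=(64, 256), normalize=True)

    def resolve_f_max(self, fs: float) -> float:
        f_max = min(fs / 2.0, 50.0) if self.f_max is None else self.f_max
        if f_max > fs / 2.0 + 1e-12:
            raise ConfigError(f"f_max={f_max} exceeds Nyquist {fs / 2}")
        if f_max <= self.f_min:
            raise ConfigError(f"need f_min < f_max <= fs/2; got [{self.f_min}, {f_max}]")
        return f_max


@dataclass
class ScalogramStack:
    """Per-channel scalogram images for one segment.

    images is (N, H, W); freqs_hz holds the n_scales centre frequencies in
    descending order (row 0 of the un-resized image = highest frequency)."""

    subject_id: str
    clip_id: str
    label: str
    segment_index: int
    freqs_hz: np.ndarray
    images: np.ndarray
    duration_s: float = SEGMENT_LEN_S

    @property
    def n_channels(self) -> int:
        return self.images.shape[0]


def segment_clip(clip: EEGClip, seg_len_s: float = SEGMENT_LEN_S) -> list[EEGSegment]:
    """Split a clip into contiguous non-overlapping segments.

    Returns ``floor(duration / seg_len_s)`` segments; the trailing remainder
    is dropped.  Each segment inherits the clip label."""
    d = int(round(seg_len_s * clip.fs))
    n_seg = clip.n_samples // d
    if n_seg < 1:
        raise DataError(
            f"clip {clip.clip_id} ({clip.duration_s:.1f} s) shorter than one "
            f"{seg_len_s:.0f}-s segment"
        )
    return [
        EEGSegment(
            subject_id=clip.subject_id,
            clip_id=clip.clip_id,
            label=clip.label,
            segment_index=k,
            fs=clip.fs,
            data=clip.data[:, k * d : (k + 1) * d].copy(),
        )
        for k in range(n_seg)
    ]


def center_frequencies(cfg: ScalogramConfig, fs: float) -> np.ndarray:
    """The n_scales log-spaced centre frequencies (Hz), descending."""
    f_max = cfg.resolve_f_max(fs)
    return np.geomspace(f_max, cfg.f_min, cfg.n_scales)


def morlet_wavelet(freq_hz: float, fs: float, omega0: float = MORLET_OMEGA0) -> np.ndarray:
    """Sampled analytic Morlet at the scale whose centre frequency is freq_hz.

    Includes the L2 scale normalisation s^(-1/2) and the dt integration factor,
    sampled on a symmetric grid truncated at |t| <= 5 s·scale."""
    s = omega0 / (2.0 * np.pi * freq_hz)  # scale in seconds
    half = int(np.ceil(_SUPPORT_SIGMAS * s * fs))
    t = np.arange(-half, half + 1) / fs
    psi = (np.pi**-0.25) * np.exp(1j * omega0 * t / s) * np.exp(-0.5 * (t / s) ** 2)
    return psi * (1.0 / np.sqrt(s)) * (1.0 / fs)


class MorletCWT:
    """Morlet CWT engine for a fixed (fs, signal length, config).

    Precomputes the wavelet bank and its FFTs once; `transform` then costs
    one FFT per channel plus one inverse FFT per (scale, channel).  The
    convolution is zero-padded and the output is the centred 'same' window,
    which matches a direct time-domain convolution sample for sample.
    """

    def __init__(self, cfg: ScalogramConfig, fs: float, n_samples: int):
        self.cfg = cfg
        self.fs = float(fs)
        self.n_samples = int(n_samples)
        self.freqs_hz = center_frequencies(cfg, fs)
        self._wavelets = [morlet_wavelet(f, fs, cfg.omega0) for f in self.freqs_hz]
        self._halves = [(len(w) - 1) // 2 for w in self._wavelets]
        max_len = max(len(w) for w in self._wavelets)
        self.nfft = next_fast_len(self.n_samples + max_len - 1)
        self._wavelet_ffts = [fft(w, self.nfft) for w in self._wavelets]

    def coefficients(self, signals: np.ndarray) -> np.ndarray:
        """Complex CWT coefficients, shape (n_signals, n_scales, d)."""
        signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
        if signals.shape[1] != self.n_samples:
            raise DataError(
                f"signal length {signals.shape[1]} != engine length {self.n_samples}"
            )
        if not np.all(np.isfinite(signals)):
            raise DataError("non-finite values in signal")
        xf = fft(signals, self.nfft, axis=1)
        out = np.empty((signals.shape[0], len(self.freqs_hz), self.n_samples), dtype=complex)
        for j, (wf, half) in enumerate(zip(self._wavelet_ffts, self._halves)):
            full = ifft(xf * wf[None, :], axis=1)
            out[:, j, :] = full[:, half : half + self.n_samples]
        return out

    def power(self, signals: np.ndarray) -> np.ndarray:
        """Wavelet power |W|^2, shape (n_signals, n_scales, d)."""
        coef = self.coefficients(signals)
        return (coef.real**2 + coef.imag**2)


def _resize_bilinear(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    return resize(
        img, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def _finalize(power: np.ndarray, cfg: ScalogramConfig) -> np.ndarray:
    """Apply the post-power pipeline: log1p -> resize -> z-score."""
    img = power
    if cfg.log_power:
        img = np.log1p(img)
    if cfg.resize_to is not None:
        img = _resize_bilinear(img, cfg.resize_to)
    if cfg.normalize:
        sd = img.std()
        img = (img - img.mean()) / (sd if sd > 0 else 1.0)
    return img


_ENGINE_CACHE: dict[tuple, MorletCWT] = {}


def _engine(cfg: ScalogramConfig, fs: float, n: int) -> MorletCWT:
    key = (cfg, float(fs), int(n))
    eng = _ENGINE_CACHE.get(key)
    if eng is None:
        if len(_ENGINE_CACHE) > 8:
            _ENGINE_CACHE.clear()
        eng = _ENGINE_CACHE[key] = MorletCWT(cfg, fs, n)
    return eng


def cwt_scalogram(signal: np.ndarray, fs: float, cfg: ScalogramConfig | None = None) -> np.ndarray:
    """Scalogram image of one signal: wavelet power through the cfg pipeline.

    With log_power/resize/normalize all off this is the raw ``n_scales x d``
    power matrix."""
    if cfg is None:
        cfg = ScalogramConfig()
    signal = np.asarray(signal, dtype=np.float64).ravel()
    eng = _engine(cfg, fs, len(signal))
    power = eng.power(signal[None, :])[0]
    return _finalize(power, cfg)


def segment_to_stack(seg: EEGSegment, cfg: ScalogramConfig) -> ScalogramStack:
    """All-channel scalogram stack for one segment (one image per channel)."""
    eng = _engine(cfg, seg.fs, seg.n_samples)
    power = eng.power(seg.data)
    images = np.stack([_finalize(p, cfg) for p in power])
    return ScalogramStack(
        subject_id=seg.subject_id,
        clip_id=seg.clip_id,
        label=seg.label,
        segment_index=seg.segment_index,
        freqs_hz=eng.freqs_hz.copy(),
        images=images,
        duration_s=seg.duration_s,
    )


def clip_to_scalograms(
    clip: EEGClip, cfg: ScalogramConfig | None = None, seg_len_s: float = SEGMENT_LEN_S
) -> list[ScalogramStack]:
    """Segment a clip and map every segment to its per-channel scalogram stack."""
    if cfg is None:
        cfg = ScalogramConfig()
    return [segment_to_stack(seg, cfg) for seg in segment_clip(clip, seg_len_s)]
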