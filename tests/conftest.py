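"""Shared fixtures: small synthetic datasets and a minimal EDF writer.

No EDF writer ships with the runtime environment, so the fixture below
implements just enough of the 16-bit EDF format (ASCII header + int16
little-endian data records) to feed the reader under test.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from mviteeg.synthetic import SynthConfig, generate_dataset


def write_minimal_edf(
    path: Path,
    data_uv: np.ndarray,
    fs: float,
    channel_names: list[str] | None = None,
    phys_range: float = 2000.0,
) -> Path:
    """Write a standard 16-bit EDF file holding ``data_uv`` (channels x samples, µV).

    One-second data records; amplitudes are quantised to the int16 grid that
    spans +/- ``phys_range`` µV (EDF is an integer format, so round-trips are
    exact only on that grid)."""
    n_ch, n_samp = data_uv.shape
    spr = int(round(fs))  # samples per 1-s record
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "fixture wants whole 1-s records"
    if channel_names is None:
        channel_names = [f"EEG {i:03d}" for i in range(n_ch)]

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")
        assert len(b) <= n, s
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration s
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, [pad(n, 16) for n in channel_names]),
        (80, [pad("", 80)] * n_ch),  # transducer
        (8, [pad("uV", 8)] * n_ch),
        (8, [pad(f"{-phys_range:.0f}", 8)] * n_ch),
        (8, [pad(f"{phys_range:.0f}", 8)] * n_ch),
        (8, [pad("-32768", 8)] * n_ch),
        (8, [pad("32767", 8)] * n_ch),
        (80, [pad("", 80)] * n_ch),  # prefiltering
        (8, [pad(str(spr), 8)] * n_ch),
        (32, [pad("", 32)] * n_ch),
    ]
    header += b"".join(b"".join(col) for _, col in fields)
    scale = 65535.0 / (2 * phys_range)
    digital = np.clip(np.round(data_uv * scale), -32768, 32767).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            f.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


@pytest.fixture(scope="session")
def tiny_synth_clips():
    """2 subjects x (2+2) clips, 2 channels, 20 s at 100 Hz, strong signature."""
    cfg = SynthConfig(
        n_subjects=2,
        clips_per_class=2,
        n_channels=2,
        fs=100.0,
        clip_len_s=20.0,
        snr=2.0,
        sig_band=(18.0, 24.0),
        seed=7,
    )
    return cfg, generate_dataset(cfg)
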