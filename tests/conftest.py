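"""Shared fixtures: seeded RNGs, tiny on-disk recordings, synthetic data."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from gecca_eeg import synth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_recording() -> synth.SyntheticRecording:
    """Default-condition synthetic recording shared across tests."""
    return synth.generate(synth.SynthConfig(seed=7, artifact_snr_db=-3.0))


def write_minimal_edf(
    path: Path,
    data: np.ndarray,
    fs: int,
    phys_range: float = 500.0,
) -> np.ndarray:
    """Write a minimal one-record EDF file and return the quantised signal.

    ``data`` is samples x channels with values inside ``(-phys_range,
    phys_range)``; the whole signal is stored as a single data record so the
    per-record sample count equals the record length.
    """
    n, n_ch = data.shape
    dig_min, dig_max = -32768, 32767
    phys_min, phys_max = -phys_range, phys_range
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min) / scale + dig_min).astype(np.int16)

    header_bytes = 256 + 256 * n_ch
    duration = n / fs

    def pad(s: str, width: int) -> bytes:
        return s.ljust(width)[:width].encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X", 80),
            pad("X", 80),
            pad("01.01.01", 8),
            pad("00.00.00", 8),
            pad(str(header_bytes), 8),
            pad("", 44),
            pad("1", 8),
            pad(f"{duration:g}", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(f"EEG C{i + 1}", 16) for i in range(n_ch)],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{phys_min:g}", 8)] * n_ch,
        [pad(f"{phys_max:g}", 8)] * n_ch,
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(n), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(hdr)
        for block in fields:
            fh.write(b"".join(block))
        for ch in range(n_ch):
            fh.write(struct.pack(f"<{n}h", *digital[:, ch]))
    return (digital.astype(float) - dig_min) * scale + phys_min
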