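"""Shared fixtures: synthetic GDF writer and expensive session-scoped runs."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from eegmvf import SynthParams, generate_dataset, prepare_features
from eegmvf.train_eval import TrainConfig, erd_separability_experiment


def _pad(text: str, n: int) -> bytes:
    b = text.encode("latin-1")[:n]
    return b + b" " * (n - len(b))


def write_minimal_gdf(
    path,
    data_uv: np.ndarray,
    fs: int = 250,
    events: list[tuple[int, int]] = (),
    channel_names: tuple[str, ...] = ("C3", "Cz", "C4"),
) -> None:
    """Write a minimal synthetic GDF 1.25 file (testing only).

    ``data_uv`` is (channels, samples) in microvolts with samples a
    multiple of ``fs`` (1-second records); ``events`` are (sample, code)
    pairs, e.g. code 769 = left cue, 770 = right cue.  Covers exactly the
    subset of the format the pipeline reads: float32 records plus a
    mode-1 event table.
    """
    data_uv = np.asarray(data_uv, dtype=np.float32)
    nchan, nsamp = data_uv.shape
    if nsamp % fs:
        raise ValueError("sample count must be a multiple of fs (1 s records)")
    n_records = nsamp // fs
    with open(path, "wb") as fh:
        fh.write(b"GDF 1.25")
        fh.write(_pad("X X", 80))  # patient
        fh.write(_pad("synthetic fixture", 80))  # recording id
        fh.write(_pad("2024010112000000", 16))  # start date
        fh.write(struct.pack("<q", 256 + 256 * nchan))  # header bytes
        fh.write(bytes(24))  # equipment / hospital / technician ids
        fh.write(bytes(20))  # reserved
        fh.write(struct.pack("<q", n_records))
        fh.write(struct.pack("<II", 1, 1))  # record duration 1 s
        fh.write(struct.pack("<I", nchan))
        for name in channel_names:
            fh.write(_pad(name, 16))
        for _ in range(nchan):
            fh.write(_pad("AgCl electrode", 80))
        for _ in range(nchan):
            fh.write(_pad("uV", 8))
        fh.write(struct.pack(f"<{nchan}d", *([-32768.0] * nchan)))  # phys min
        fh.write(struct.pack(f"<{nchan}d", *([32767.0] * nchan)))  # phys max
        fh.write(struct.pack(f"<{nchan}q", *([-32768] * nchan)))  # dig min
        fh.write(struct.pack(f"<{nchan}q", *([32767] * nchan)))  # dig max
        for _ in range(nchan):
            fh.write(_pad("HP:0.5Hz LP:100Hz", 80))
        fh.write(struct.pack(f"<{nchan}i", *([fs] * nchan)))  # samples/record
        fh.write(struct.pack(f"<{nchan}i", *([16] * nchan)))  # dtype = float32
        fh.write(bytes(32 * nchan))  # reserved
        # data records: per record, per channel, fs float32 samples
        for r in range(n_records):
            block = data_uv[:, r * fs : (r + 1) * fs]
            fh.write(block.astype("<f4").tobytes())
        # event table, mode 1
        fh.write(struct.pack("<B", 1))
        fh.write(struct.pack("<I", fs)[:3])  # event sample rate, 3 bytes
        fh.write(struct.pack("<I", len(events)))
        for pos, _ in events:
            fh.write(struct.pack("<I", pos + 1))  # 1-based positions
        for _, code in events:
            fh.write(struct.pack("<H", code))


@pytest.fixture(scope="session")
def gdf_writer():
    return write_minimal_gdf


@pytest.fixture(scope="session")
def cwt_cfg():
    from eegmvf import CWTConfig

    return CWTConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """20 trials with a strong ERD class signal (fast tests)."""
    return generate_dataset(10, SynthParams(erd_depth=0.9, noise_level=0.5, seed=5))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return prepare_features(small_dataset)


@pytest.fixture(scope="session")
def erd_run():
    """Scaled-down ERD training run shared by sanity and acceptance tests.

    Conditions: erd_depth 0.9, 100 trials/class, 10 epochs, random init.
    """
    return erd_separability_experiment(seed=7)


@pytest.fixture(scope="session")
def null_run():
    """Same recipe on no-signal data (erd_depth 0): chance-level control."""
    return erd_separability_experiment(seed=7, erd_depth=0.0, n_test_per_class=100)
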