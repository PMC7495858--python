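"""Shared fixtures and a minimal FCS writer used to build fixtures at run time."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from cytomix.types import DesignMatrix, MarkerMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mixture(rng):
    """A tiny 2-cluster, 2-marker dataset with a binary covariate."""
    n = 120
    labels = rng.integers(0, 2, n)
    mu = np.array([[0.0, 4.0], [0.0, 4.0]])
    y = mu[:, labels].T + rng.standard_normal((n, 2))
    x = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
    return MarkerMatrix(y), DesignMatrix(x), labels


def write_minimal_fcs(
    path,
    data: np.ndarray,
    names: list[str],
    datatype: str = "F",
    big_endian: bool = False,
) -> None:
    """Write a small LIST-mode FCS 3.0 file (synthetic test fixture only)."""
    data = np.asarray(data)
    n_tot, n_par = data.shape
    endian = ">" if big_endian else "<"
    np_dtype = {"F": "f4", "D": "f8", "I": "u2"}[datatype]
    payload = data.astype(np.dtype(endian + np_dtype)).tobytes()
    bits = {"F": 32, "D": 64, "I": 16}[datatype]

    kw = {
        "$MODE": "L",
        "$DATATYPE": datatype,
        "$BYTEORD": "4,3,2,1" if big_endian else "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = str(bits)
        kw[f"$P{i}R"] = "262144"
        kw[f"$P{i}E"] = "0,0"

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    text_start = 58
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1
    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}{text_end:>8d}{data_start:>8d}{data_end:>8d}".encode()
        + f"{0:>8d}{0:>8d}".encode()
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(payload)
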