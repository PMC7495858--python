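"""Minimal reader for FCS 2.0/3.0/3.1 list-mode files.

Covers the subset of the standard that cytometry exports actually use:
an ASCII header with segment offsets, a delimited TEXT segment, and an
uncompressed LIST-mode DATA segment of float32 ('F'), float64 ('D') or
unsigned-integer ('I', 16/32/64-bit) events.  Channel names come from $PnS
when present, else $PnN.  Writing FCS is out of scope.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .types import ValidationError


class FCSError(ValidationError):
    """Raised for files that are not parseable FCS."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # the standard escapes a literal delimiter by doubling it; rare in practice
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        parts = parts[: len(parts) - 1]
    keywords = {}
    for key, value in zip(parts[::2], parts[1::2]):
        keywords[key.decode("latin-1").strip().upper()] = value.decode("latin-1")
    return keywords


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Parse an FCS file into (events x channels array, channel names, keywords)."""
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise FCSError(f"{path}: too short to be an FCS file")
    version = data[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS"):
        raise FCSError(f"{path}: bad magic {version!r}, expected FCS2.0/3.0/3.1")

    def _offset(start: int) -> int:
        field = data[start : start + 8].decode("latin-1").strip()
        return int(field) if field else 0

    text_start, text_end = _offset(10), _offset(18)
    data_start, data_end = _offset(26), _offset(34)
    if text_end <= text_start:
        raise FCSError(f"{path}: invalid TEXT segment offsets")
    kw = _parse_text_segment(data[text_start : text_end + 1])

    if data_start == 0 and "$BEGINDATA" in kw:  # FCS 3.x large-file style
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        mode = kw.get("$MODE", "L").strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise FCSError(f"{path}: missing required keyword {exc}") from exc
    if mode != "L":
        raise FCSError(f"{path}: only list mode ($MODE=L) is supported, got {mode}")
    endian = "<" if byteord.startswith("1") else ">"

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"channel{i}"
        names.append(name.strip())

    raw = data[data_start : data_end + 1]
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32, 64):
            raise FCSError(f"{path}: unsupported or mixed integer widths {bits}")
        width = int(kw["$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{width}")
    else:
        raise FCSError(f"{path}: unsupported $DATATYPE {datatype!r}")

    needed = n_tot * n_par * dtype.itemsize
    if len(raw) < needed:
        raise FCSError(
            f"{path}: DATA segment holds {len(raw)} bytes, "
            f"need {needed} for {n_tot} events x {n_par} channels"
        )
    values = np.frombuffer(raw[:needed], dtype=dtype).astype(float)
    return values.reshape(n_tot, n_par), names, kw
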