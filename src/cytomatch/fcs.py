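"""Minimal FCS 3.1 reader/writer.

Covers the subset of the Flow Cytometry Standard this package needs: list-mode
(``$MODE L``) single-precision float data (``$DATATYPE F``), little-endian,
one data segment, short channel names in ``$PnN``.  Reading also accepts FCS
3.0 files written in the same layout, and double-precision (``$DATATYPE D``).

No FCS library ships in this environment, so the format is implemented here
rather than pulled in as a dependency.
"""

from __future__ import annotations

import struct

import numpy as np

from .matrix import CellMatrix

_DELIM = b"/"


def write_fcs(path, matrix: CellMatrix, extra_keywords: dict | None = None) -> None:
    """Write a CellMatrix as an FCS 3.1 file (float32, little-endian)."""
    data = np.ascontiguousarray(matrix.values, dtype="<f4")
    n_events, n_par = data.shape

    text = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(matrix.channel_names, start=1):
        text[f"$P{i}N"] = name
        text[f"$P{i}B"] = "32"
        text[f"$P{i}E"] = "0,0"
        col = data[:, i - 1]
        rng = float(col.max(initial=0.0))
        text[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)
        text[f"CYTOMATCH_P{i}KIND"] = matrix.channel_kinds[i - 1]
    for k, v in (extra_keywords or {}).items():
        text[str(k)] = str(v)

    def render(begin_data: int, end_data: int) -> bytes:
        items = dict(text)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        out = bytearray(_DELIM)
        for k, v in items.items():
            out += k.encode("ascii") + _DELIM + str(v).encode("ascii") + _DELIM
        return bytes(out)

    header_len = 58
    # Fixed-width offset fields: iterate once since rendered length can grow
    # when the data offsets gain digits.
    text_start = header_len
    begin_data = end_data = 0
    for _ in range(4):
        body = render(begin_data, end_data)
        new_begin = text_start + len(body)
        new_end = new_begin + data.nbytes - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    body = render(begin_data, end_data)
    text_end = text_start + len(body) - 1

    header = b"FCS3.1    " + (
        f"{text_start:>8d}{text_end:>8d}{begin_data:>8d}{end_data:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body)
        fh.write(data.tobytes())


def read_fcs(path) -> tuple[CellMatrix, dict]:
    """Read an FCS 3.0/3.1 file; returns (CellMatrix, text keywords)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = _parse_text(raw[text_start : text_end + 1])

    begin_data = int(text.get("$BEGINDATA") or raw[26:34])
    end_data = int(text.get("$ENDDATA") or raw[34:42])
    n_events = int(text["$TOT"])
    n_par = int(text["$PAR"])
    datatype = text.get("$DATATYPE", "F").upper()
    if text.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode ($MODE L) FCS files are supported")
    if datatype == "F":
        itemsize, code = 4, "f"
    elif datatype == "D":
        itemsize, code = 8, "d"
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    expected = n_events * n_par * itemsize
    payload = raw[begin_data : begin_data + expected]
    if len(payload) < expected:
        raise ValueError("truncated FCS data segment")
    data = np.frombuffer(payload, dtype=f"{endian}{code}").reshape(n_events, n_par)

    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    kinds = [
        text.get(f"CYTOMATCH_P{i}KIND", "protein") for i in range(1, n_par + 1)
    ]
    donor = None
    if "donor_id" in names:
        donor = data[:, names.index("donor_id")].astype(np.int64)
    return (
        CellMatrix(data.astype(float), names, kinds, donor_ids=donor),
        text,
    )


def _parse_text(segment: bytes) -> dict:
    if not segment:
        raise ValueError("empty TEXT segment")
    delim = segment[:1]
    parts = segment[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {
        parts[i].decode("ascii", "replace").strip(): parts[i + 1].decode("utf-8", "replace")
        for i in range(0, len(parts), 2)
    }
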