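"""Minimal FCS 3.0/3.1 reader and writer.

Reads list-mode float (``$DATATYPE F``/``D``) data from the primary TEXT
and DATA segments, which covers files exported by modern mass-cytometry
acquisition software. Spillover/compensation keywords are ignored: CyTOF
has minimal spillover, and inputs are assumed pre-gated. The writer emits
single-dataset FCS 3.1 files and exists mainly so round trips can be
exercised without instrument files.
"""

from __future__ import annotations

import numpy as np

_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")


def read_fcs(path: str) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file; return (events x channels matrix, channel names)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[:6].decode("ascii", "replace")
    if version not in _SUPPORTED_VERSIONS:
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = _parse_text(raw[text_start : text_end + 1])

    data_start = int(text.get("$BEGINDATA", raw[26:34] or b"0"))
    data_end = int(text.get("$ENDDATA", raw[34:42] or b"0"))
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text["$DATATYPE"].upper()
    if dtype_code not in ("F", "D"):
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r} (only F/D handled)")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    item = np.dtype(f"{endian}f4" if dtype_code == "F" else f"{endian}f8")

    names = []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}N", f"P{i}"))

    blob = raw[data_start : data_end + 1]
    need = n_par * n_tot * item.itemsize
    if len(blob) < need:
        raise ValueError("FCS data segment shorter than $PAR * $TOT events")
    data = np.frombuffer(blob[:need], dtype=item).reshape(n_tot, n_par)
    return data.astype(float), names


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise ValueError("empty FCS TEXT segment")
    delim = segment[:1]
    # Delimiter-escaping (doubled delimiters) is rare; split plainly and
    # drop empty trailing fields.
    parts = segment[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        parts = parts[:-1]
    out: dict[str, str] = {}
    for k, v in zip(parts[::2], parts[1::2]):
        out[k.decode("ascii", "replace").strip().upper()] = v.decode(
            "ascii", "replace"
        ).strip()
    return out


def write_fcs(path: str, data: np.ndarray, channel_names: list[str]) -> None:
    """Write a single-dataset FCS 3.1 file (float32 list mode)."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2:
        raise ValueError("data must be 2-D (events x channels)")
    n_tot, n_par = data.shape
    if len(channel_names) != n_par:
        raise ValueError("one channel name per column required")

    payload = data.tobytes()
    d = "/"
    kv = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        kv[f"$P{i}N"] = str(name)
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(np.ceil(float(np.abs(data).max(initial=1.0)))) + 1)

    # TEXT length depends on the data offsets it contains; iterate to a
    # fixed point (two passes always suffice at these magnitudes).
    header_len = 58
    begin_data = end_data = 0
    for _ in range(3):
        kv["$BEGINDATA"] = str(begin_data)
        kv["$ENDDATA"] = str(end_data)
        text = d + "".join(f"{k}{d}{v}{d}" for k, v in sorted(kv.items()))
        text_start = header_len
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + len(payload) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin_data:>8d}".encode()
        + f"{end_data:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(payload)
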