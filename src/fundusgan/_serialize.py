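"""Deterministic single-file checkpoint container.

Layout: magic, 8-byte little-endian header length, a sorted-key JSON
header describing metadata and array table, then raw array bytes.  The
byte stream is a pure function of its contents (no timestamps), so
save -> load -> save reproduces the file exactly — which the resume
tests rely on.
"""

from __future__ import annotations

import json
import os

import numpy as np

_MAGIC = b"FGCKPT01"
FORMAT_VERSION = 1


def save_container(path, meta: dict, arrays: dict[str, np.ndarray]) -> None:
    names = sorted(arrays)
    table = {}
    offset = 0
    blobs = []
    for name in names:
        arr = np.ascontiguousarray(arrays[name])
        raw = arr.tobytes()
        table[name] = {
            "dtype": arr.dtype.str,
            "shape": list(arr.shape),
            "offset": offset,
            "nbytes": len(raw),
        }
        offset += len(raw)
        blobs.append(raw)
    header = json.dumps(
        {"format_version": FORMAT_VERSION, "meta": meta, "arrays": table},
        sort_keys=True,
        separators=(",", ":"),
    ).encode()
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        for raw in blobs:
            fh.write(raw)


def load_container(path) -> tuple[dict, dict[str, np.ndarray]]:
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < len(_MAGIC) + 8 or data[: len(_MAGIC)] != _MAGIC:
        raise IOError(f"not a fundusgan checkpoint: {path!r}")
    hlen = int.from_bytes(data[len(_MAGIC) : len(_MAGIC) + 8], "little")
    start = len(_MAGIC) + 8
    if len(data) < start + hlen:
        raise IOError(f"truncated checkpoint header: {path!r}")
    header = json.loads(data[start : start + hlen].decode())
    if header.get("format_version") != FORMAT_VERSION:
        raise IOError(
            f"incompatible checkpoint version {header.get('format_version')!r} in {path!r};"
            f" this build reads version {FORMAT_VERSION}"
        )
    body = data[start + hlen :]
    arrays = {}
    for name, rec in header["arrays"].items():
        end = rec["offset"] + rec["nbytes"]
        if end > len(body):
            raise IOError(f"truncated checkpoint payload: {path!r}")
        arrays[name] = np.frombuffer(
            body[rec["offset"] : end], dtype=np.dtype(rec["dtype"])
        ).reshape(rec["shape"]).copy()
    return header["meta"], arrays
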