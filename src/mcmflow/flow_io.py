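"""Event-level flow cytometry I/O.

Per-cell measurements live in an :class:`EventTable`: a plain pandas frame of
linear (untransformed) channel intensities under semantic names, plus sample
metadata.  Raw values are kept linear throughout because the downstream rate
analysis histograms raw exported intensities; display-scale transforms are a
plotting concern only.

Supported formats: CSV event tables (read/write; metadata as ``# key: value``
header comments) and list-mode FCS 3.0/3.1 with float data (read/write).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = ["EventTable", "ChannelMap", "read_events", "write_events"]

SEMANTIC_CHANNELS = ("fsc_a", "ssc_a", "dna_a", "dna_h", "edu", "mcm")


@dataclass
class EventTable:
    """Per-cell multichannel measurements plus sample metadata.

    ``data`` columns are semantic channel names; extra channels (cdt1, oct4,
    cdx2, ...) are allowed by name.  ``metadata`` must carry a non-empty
    ``sample_id``.
    """

    data: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("sample_id", "unnamed")
        self.metadata.setdefault("is_negative_control", False)
        if not self.metadata["sample_id"]:
            raise ValueError("sample_id metadata must be non-empty")
        numeric = self.data.select_dtypes(include=np.number)
        if len(numeric) and not np.isfinite(numeric.to_numpy(dtype=float)).all():
            raise ValueError("event intensities must all be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def require(self, *channels: str) -> None:
        missing = [c for c in channels if c not in self.data.columns]
        if missing:
            raise KeyError(f"event table lacks channel(s): {', '.join(missing)}")

    def channel(self, name: str) -> np.ndarray:
        self.require(name)
        return self.data[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class ChannelMap:
    """Instrument-label -> semantic-channel mapping (e.g. ``FL5-A -> mcm``)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        targets = list(self.mapping.values())
        if len(set(targets)) != len(targets):
            raise ValueError("channel map must be injective on semantic channels")
        if "dna_a" not in targets:
            raise ValueError("channel map must provide dna_a")

    @classmethod
    def identity(cls) -> "ChannelMap":
        return cls({c: c for c in SEMANTIC_CHANNELS})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChannelMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [src for src in self.mapping if src not in df.columns]
        if missing:
            raise KeyError(
                f"input lacks mapped channel label(s): {', '.join(missing)}"
            )
        out = df[list(self.mapping)].rename(columns=dict(self.mapping))
        return out


# ---------------------------------------------------------------------------
# CSV

def _write_csv(table: EventTable, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        for key in sorted(table.metadata):
            fh.write(f"# {key}: {table.metadata[key]!r}\n")
        table.data.to_csv(fh, index=False)


def _read_csv(path: Path) -> tuple[pd.DataFrame, dict[str, Any]]:
    metadata: dict[str, Any] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].partition(":")
            try:
                import ast

                metadata[key.strip()] = ast.literal_eval(value.strip())
            except (ValueError, SyntaxError):
                metadata[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=skip)
    return df, metadata


# ---------------------------------------------------------------------------
# Minimal list-mode FCS 3.1 (float32 data, little-endian)

def _write_fcs(table: EventTable, path: Path) -> None:
    df = table.data
    n_par, n_evt = len(df.columns), len(df)
    data = df.to_numpy(dtype="<f4").tobytes()

    text_keys: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_evt),
    }
    for i, col in enumerate(df.columns, start=1):
        text_keys[f"$P{i}N"] = str(col)
        text_keys[f"$P{i}B"] = "32"
        text_keys[f"$P{i}E"] = "0,0"
        col_max = float(df[col].max()) if n_evt else 1.0
        text_keys[f"$P{i}R"] = str(int(max(col_max, 1.0)) + 1)
    text_keys["#SAMPLE_ID"] = str(table.metadata.get("sample_id", ""))

    def render(begin_data: int, end_data: int) -> bytes:
        keys = dict(text_keys)
        keys["$BEGINDATA"] = str(begin_data)
        keys["$ENDDATA"] = str(end_data)
        body = "/" + "/".join(f"{k}/{v}" for k, v in keys.items()) + "/"
        return body.encode("ascii")

    header_len = 58
    # iterate: text length depends on the offsets it encodes
    begin_text = header_len
    text = render(0, 0)
    for _ in range(3):
        begin_data = begin_text + len(text)
        end_data = begin_data + len(data) - 1 if data else begin_data
        text = render(begin_data, end_data)
    begin_data = begin_text + len(text)
    end_data = begin_data + len(data) - 1 if data else begin_data
    end_text = begin_text + len(text) - 1

    header = b"FCS3.1    " + (
        f"{begin_text:8d}{end_text:8d}"
        + f"{begin_data if begin_data <= 99999999 else 0:8d}"
        + f"{end_data if end_data <= 99999999 else 0:8d}"
        + f"{0:8d}{0:8d}"
    ).encode("ascii")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def _read_fcs(path: Path) -> tuple[pd.DataFrame, dict[str, Any]]:
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(f"{path}: not an FCS 3.0/3.1 file")
    begin_text = int(raw[10:18])
    end_text = int(raw[18:26])
    text = raw[begin_text : end_text + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    keys = {parts[i]: parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    n_par = int(keys["$PAR"])
    n_evt = int(keys["$TOT"])
    begin_data = int(keys.get("$BEGINDATA") or raw[26:34])
    datatype = keys.get("$DATATYPE", "F")
    byteord = keys.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        fmt, width = "f", 4
    elif datatype == "D":
        fmt, width = "d", 8
    else:
        raise ValueError(f"unsupported FCS $DATATYPE {datatype!r} (float data only)")
    count = n_par * n_evt
    values = struct.unpack(f"{endian}{count}{fmt}", raw[begin_data : begin_data + count * width])
    names = [keys.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    df = pd.DataFrame(np.asarray(values, dtype=float).reshape(n_evt, n_par), columns=names)
    meta = {k: v for k, v in keys.items() if not k.startswith("$P")}
    if "#SAMPLE_ID" in keys and keys["#SAMPLE_ID"]:
        meta["sample_id"] = keys["#SAMPLE_ID"]
    return df, meta


# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "fcs" if path.suffix.lower() == ".fcs" else "csv"


def read_events(
    path: str | Path,
    channel_map: ChannelMap | None = None,
    format: str | None = None,
    **metadata: Any,
) -> EventTable:
    """Read an event table from CSV or FCS.

    ``channel_map`` renames instrument labels to semantic channels; omit it
    when the file already uses semantic names.  No intensity transformation
    is applied.  Extra keyword arguments override/extend sample metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df, meta = _read_csv(path)
    elif fmt == "fcs":
        df, meta = _read_fcs(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'fcs'")
    if channel_map is not None:
        df = channel_map.apply(df)
    meta.setdefault("sample_id", path.stem)
    meta.update(metadata)
    return EventTable(df, metadata=meta)


def write_events(table: EventTable, path: str | Path, format: str | None = None) -> Path:
    """Write an event table (deterministic column order as stored).

    CSV carries metadata as leading ``#`` comments; an empty table writes a
    header-only file.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(table, path)
    elif fmt == "fcs":
        _write_fcs(table, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'fcs'")
    return path
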