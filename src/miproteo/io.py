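"""Readers/writers for the plain-text formats used by the pipeline.

GCT v1.2 for expression matrices, GMT for gene sets (with optional
``;u`` / ``;d`` direction suffixes on members for PTM signatures),
SEG-style TSV for copy-number segments, and plain TSV manifests.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .matrix import QuantMatrix


# ---------------------------------------------------------------- GCT v1.2

def write_gct(m: QuantMatrix, path: str | Path, description: str | None = None) -> None:
    """Write a QuantMatrix as a GCT v1.2 file (level stored in Description)."""
    df = m.data
    desc = description if description is not None else m.level
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = pd.DataFrame(
            {"Name": df.index, "Description": desc},
        ).join(df.reset_index(drop=True))
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_gct(path: str | Path, level: str = "protein") -> QuantMatrix:
    """Read a GCT v1.2 file into a QuantMatrix."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2",):
            raise ValueError(f"unsupported GCT version line {version!r}")
        nrow, ncol = (int(x) for x in fh.readline().split()[:2])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != nrow or body.shape[1] - 2 != ncol:
        raise ValueError(
            f"GCT dimension line ({nrow}x{ncol}) does not match body {body.shape}"
        )
    data = body.set_index("Name").drop(columns=["Description"])
    data.index.name = None
    return QuantMatrix(data, level)


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [f for f in fields[2:] if f]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def parse_directed_members(members: list[str]) -> dict[str, int]:
    """Split ``KEY;u`` / ``KEY;d`` suffixes into {identifier: +1/-1}.

    Members without a suffix count as up (+1).
    """
    out: dict[str, int] = {}
    for m in members:
        if m.endswith(";u"):
            out[m[:-2]] = +1
        elif m.endswith(";d"):
            out[m[:-2]] = -1
        else:
            out[m] = +1
    return out


# ---------------------------------------------------------------- SEG / TSV

SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG-style TSV (sample, chrom, start, end, log2_ratio).

    Coordinates on disk are 1-based inclusive; internally they become
    0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    out = segments[SEG_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def gct_roundtrip_string(m: QuantMatrix) -> str:
    """Serialize a QuantMatrix to a GCT string (used for determinism checks)."""
    buf = _io.StringIO()
    buf.write("#1.2\n")
    buf.write(f"{m.data.shape[0]}\t{m.data.shape[1]}\n")
    out = pd.DataFrame({"Name": m.data.index, "Description": m.level}).join(
        m.data.reset_index(drop=True)
    )
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    return buf.getvalue()
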