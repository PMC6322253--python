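"""Readers and writers for the flat formats the pipeline consumes and emits.

All coordinate conversions live here: allc tables are 1-based (position of
the cytosine itself), BED6 is 0-based half-open, GFF3 is 1-based inclusive.
Everything downstream works on 0-based half-open intervals and keeps allc
positions 1-based in the ``pos`` column (converting with ``pos - 1`` only at
the point of interval assignment).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "n"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class AllcValidationError(ValueError):
    """An allc-style row violates the count/strand/position invariants."""


def read_allc(path: str | Path) -> pd.DataFrame:
    """Read an allc-style TSV (chrom, 1-based pos, strand, context, mc, n).

    The table is headerless, as written by methylpy-compatible pipelines.
    Rows violating ``0 <= mc <= n``, ``pos >= 1`` or with an unknown strand
    symbol raise :class:`AllcValidationError` naming the first bad line.
    An empty file yields an empty, correctly-typed frame.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=ALLC_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str},
        )
    except pd.errors.EmptyDataError:
        return _empty_allc()
    for col in ("pos", "mc", "n"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise AllcValidationError(
                f"{path}: line {bad.idxmax() + 1}: non-numeric {col!r}"
            )
        df[col] = vals.astype(int)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise AllcValidationError(
            f"{path}: line {line}: unknown strand {df['strand'].iloc[line - 1]!r}"
        )
    bad = (df["mc"] < 0) | (df["mc"] > df["n"]) | (df["n"] < 0)
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise AllcValidationError(
            f"{path}: line {line}: mc={df['mc'].iloc[line - 1]} exceeds "
            f"n={df['n'].iloc[line - 1]} (or negative count)"
        )
    bad = df["pos"] < 1
    if bad.any():
        raise AllcValidationError(f"{path}: line {int(bad.idxmax()) + 1}: pos < 1")
    return df


def _empty_allc() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=int),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "mc": pd.Series(dtype=int),
            "n": pd.Series(dtype=int),
        }
    )


def write_allc(df: pd.DataFrame, path: str | Path) -> None:
    df[ALLC_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read BED6 into (chrom, start, end, name, score, strand), 0-based half-open."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BED6_COLUMNS,
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "score" not in out:
        out["score"] = 0
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def read_te_gff3(path: str | Path) -> pd.DataFrame:
    """Read a RepeatMasker-style TE GFF3 into (chrom, start, end, strand, family).

    Coordinates are converted from GFF3 1-based inclusive to 0-based
    half-open. The family is taken from the ``Family`` (or ``Target``/``Name``)
    attribute of column 9.
    """
    rows = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: malformed GFF3 line: {raw!r}")
            attrs = dict(_GFF_ATTR.findall(f[8]))
            family = attrs.get("Family") or attrs.get("Name") or attrs.get("Target")
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "family": family,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "family"])


def write_te_gff3(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in df.iterrows():
            fh.write(
                f"{r['chrom']}\trepeatmasker\tdispersed_repeat\t{r['start'] + 1}\t"
                f"{r['end']}\t.\t{r.get('strand', '+')}\t.\tFamily={r['family']}\n"
            )


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x libraries count matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def merge_intervals(starts, ends):
    """Merge overlapping or bookended half-open intervals; returns sorted arrays."""
    import numpy as np

    starts = np.asarray(starts)
    ends = np.asarray(ends)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)
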