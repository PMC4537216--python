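"""Readers and writers for the pipeline's plain-text table formats.

Counts travel as long-format TSV (gene, time_h, replicate, count), operon
layouts as a BED-like TSV, gene sets as standard GMT.  All files are
tab-separated UTF-8 with a header row (GMT excepted, per its convention).
Writers use a fixed float format so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .operons import OPERON_COLUMNS, validate_operon_table
from .preprocess import ProfileMatrix

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_operons_tsv",
    "read_operons_tsv",
    "write_gmt",
    "read_gmt",
    "write_table",
]

FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic CSV/TSV writer (separator chosen by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".bed") else ","
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FORMAT)


def write_counts_tsv(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write a ProfileMatrix as long-format TSV (gene, time_h, replicate, count)."""
    g, t, r = matrix.counts.shape
    genes = np.repeat(matrix.genes, t * r)
    times = np.tile(np.repeat(matrix.times, r), g)
    reps = np.tile(np.arange(1, r + 1), g * t)
    df = pd.DataFrame(
        {
            "gene": genes,
            "time_h": times,
            "replicate": reps,
            "count": matrix.counts.reshape(-1).astype(np.int64),
        }
    )
    write_table(df, path)


def read_counts_tsv(path: str | Path, meta: pd.DataFrame | None = None) -> ProfileMatrix:
    """Read long-format counts back into a gene x time x replicate matrix.

    Every gene must cover the full time x replicate grid; non-integer
    count entries are rejected with the offending cell named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "time_h", "replicate", "count"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path.name}: missing column(s) {sorted(missing)}")
    bad = df["count"] != np.floor(df["count"])
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"{path.name}: non-integer count for gene {row['gene']} at "
            f"time {row['time_h']} replicate {int(row['replicate'])}"
        )
    if (df["count"] < 0).any():
        row = df[df["count"] < 0].iloc[0]
        raise ValueError(f"{path.name}: negative count for gene {row['gene']}")
    times = np.sort(df["time_h"].unique())
    reps = np.sort(df["replicate"].unique())
    genes = list(dict.fromkeys(df["gene"]))  # keep first-appearance order
    wide = df.pivot_table(
        index="gene", columns=["time_h", "replicate"], values="count", aggfunc="first"
    )
    if wide.isna().any().any():
        gene = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"{path.name}: gene {gene} is missing grid entries")
    wide = wide.loc[genes]
    counts = wide.to_numpy().reshape(len(genes), times.size, reps.size)
    m = meta.loc[genes] if meta is not None else None
    return ProfileMatrix(counts, genes, times, m)


def write_operons_tsv(operons: pd.DataFrame, path: str | Path) -> None:
    write_table(operons[list(OPERON_COLUMNS)], path)


def read_operons_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_operon_table(df)


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    """Write gene sets in GMT format: name, description, member genes."""
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name in gene_sets:
            members = list(gene_sets[name])
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file; malformed or empty sets raise with the line number."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{Path(path).name}: line {lineno}: GMT needs name, "
                    "description and at least one member gene"
                )
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{Path(path).name}: line {lineno}: set {name!r} is empty")
            sets[name] = members
    return sets
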