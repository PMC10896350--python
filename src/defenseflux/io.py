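"""Tabular and sequence I/O for the pipeline's plain-text interchange formats.

All tables are tab-separated UTF-8 without quoting. Presence/absence tables
have genome IDs in the first column and trait IDs in the header row, with
strictly binary 0/1 cells. Spacer FASTA headers follow
``genome_id|locus|index``. Gene coordinates are BED-like, 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_presence_absence",
    "write_presence_absence",
    "read_gene_coords",
    "write_gene_coords",
    "read_spacer_fasta",
    "write_spacer_fasta",
    "read_ani_table",
]

COORD_COLUMNS = ["genome", "replicon", "start", "end", "strand", "og_id"]


def read_presence_absence(path: str | Path) -> pd.DataFrame:
    """Read a genomes x traits binary TSV (first column genome ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = df.astype(np.int8)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in presence/absence table") from exc
    if values.isna().any().any():
        raise ValueError(f"{path}: missing entries in presence/absence table")
    if not values.isin([0, 1]).all().all():
        raise ValueError(f"{path}: presence/absence values must be 0/1")
    values.index = values.index.astype(str)
    values.index.name = "genome"
    return values


def write_presence_absence(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.astype(int)
    out.index.name = "genome"
    out.to_csv(path, sep="\t")


def read_gene_coords(path: str | Path) -> pd.DataFrame:
    """Read BED-like gene coordinates (genome, replicon, start, end, strand, og_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"start": np.int64, "end": np.int64})
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing coordinate columns {missing}")
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: invalid 0-based half-open intervals")
    return df[COORD_COLUMNS]


def write_gene_coords(coords: pd.DataFrame, path: str | Path) -> None:
    coords[COORD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spacer_fasta(path: str | Path) -> dict[str, list[str]]:
    """Read spacers keyed by genome from FASTA with ``genome|locus|index`` headers."""
    arrays: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome = rec.id.split("|", 1)[0]
        arrays.setdefault(genome, []).append(str(rec.seq).upper())
    return arrays


def write_spacer_fasta(
    arrays: Mapping[str, list[str]], path: str | Path, locus: str = "c1"
) -> None:
    records = []
    for genome in sorted(arrays):
        for i, seq in enumerate(arrays[genome]):
            records.append(
                SeqRecord(Seq(seq), id=f"{genome}|{locus}|{i}", description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_ani_table(path: str | Path) -> pd.DataFrame:
    """Read a pairwise ANI TSV with columns genome_a, genome_b, ani.

    Values may be fractions in [0, 1] or percentages in [0, 100]; percentages
    are detected (any value > 1.5) and rescaled to fractions.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    df = df.rename(columns=dict(zip(cols, ["genome_a", "genome_b", "ani"])))
    df["ani"] = df["ani"].astype(float)
    if (df["ani"] > 1.5).any():
        df["ani"] = df["ani"] / 100.0
    if ((df["ani"] < 0) | (df["ani"] > 1)).any():
        raise ValueError(f"{path}: ANI values outside [0, 1] after scale detection")
    return df
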