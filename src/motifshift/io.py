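"""Readers and writers for the formats the pipeline consumes and emits.

BED (0-based half-open), FASTA, JASPAR-format PFM text, and the TSV tables
(tab-separated, header row, UTF-8, '.' decimal) used between stages.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .motifs import PFMotif

BED_COLUMNS = ["chrom", "start", "end", "name"]


def read_bed(path) -> pd.DataFrame:
    """BED3+ intervals as a DataFrame (chrom, start, end[, name]).

    Coordinates are 0-based half-open; malformed lines raise with their line
    number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            rows.append((fields[0], start, end, name))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA as an id -> sequence mapping; duplicate ids raise."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA id: {record.id}")
        out[record.id] = str(record.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_jaspar_pfm(path) -> list[PFMotif]:
    """JASPAR-format PFM text ('>' id/name header, four bracketed count rows
    A,C,G,T) parsed into PFMotif objects."""
    with open(path) as fh:
        content = fh.read()
    if not content.strip():
        return []
    out = []
    from io import StringIO
    try:
        parsed = bio_motifs.parse(StringIO(content), "jaspar")
    except Exception as exc:
        raise ValueError(f"{path}: not valid JASPAR PFM text ({exc})") from exc
    n_headers = sum(1 for line in content.splitlines() if line.startswith(">"))
    if len(parsed) != n_headers:
        raise ValueError(
            f"{path}: parsed {len(parsed)} motifs from {n_headers} records; "
            "malformed count rows")
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PFMotif(m.matrix_id or m.name, m.name or m.matrix_id, counts))
    return out


def write_jaspar_pfm(pfms: Iterable[PFMotif], path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.name}\n")
            for b, row in zip("ACGT", pfm.counts):
                cells = " ".join(f"{v:10.2f}" for v in row)
                fh.write(f"{b} [{cells} ]\n")


def read_counts_tsv(path) -> pd.DataFrame:
    """Per-peak two-condition counts: peak_id<TAB>count_wt<TAB>count_ko."""
    df = pd.read_csv(path, sep="\t")
    required = {"peak_id", "count_wt", "count_ko"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if (df[["count_wt", "count_ko"]] < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_gene_counts_tsv(counts_path, condition_path) -> tuple[pd.DataFrame, pd.Series]:
    """Gene count matrix (genes x samples) plus a sample->condition map."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond = pd.read_csv(condition_path, sep="\t", index_col=0)["condition"]
    missing = set(counts.columns) - set(cond.index)
    if missing:
        raise ValueError(f"samples without condition labels: {sorted(missing)}")
    return counts, cond.reindex(counts.columns)


def read_genes_tsv(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
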