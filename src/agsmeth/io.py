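"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython/pyfaidx, interval files are BED (0-based,
half-open), methylation calls travel as a per-cytosine TSV with columns
chrom, pos0, strand, context, meth_count, total_count.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

CYTOSINE_COLS = ["chrom", "pos0", "strand", "context", "meth_count", "total_count"]


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    for ext in (".fai",):
        p = Path(str(path) + ext)
        if p.exists():
            p.unlink()
    return seqs


def write_bed(df: pd.DataFrame, path: str | os.PathLike, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [c for c in ("name", "score", "strand") if c in df.columns])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_cytosine_tsv(records: pd.DataFrame, path: str | os.PathLike) -> None:
    records[CYTOSINE_COLS].to_csv(path, sep="\t", index=False)


def read_cytosine_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CYTOSINE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"cytosine table missing columns: {sorted(missing)}")
    return df


def write_bedgraph(df: pd.DataFrame, value_col: str, path: str | os.PathLike) -> None:
    df[["chrom", "start", "end", value_col]].to_csv(path, sep="\t", header=False, index=False)
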