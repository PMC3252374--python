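"""Readers and writers for the plain-text formats used throughout the package.

FASTA goes through Biopython; BED6 and TSV tables through pandas. All
functions raise ``IOError`` subclasses annotated with the offending path so
pipeline errors point at a file, not a traceback interior.
"""

from __future__ import annotations

import os
from typing import Dict, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence dict."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise OSError(f"cannot read FASTA {path!s}: {exc}") from exc
    return {rec.id: str(rec.seq).upper() for rec in records}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    try:
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
            writer.write_file(records)
    except OSError as exc:
        raise OSError(f"cannot write FASTA {path!s}: {exc}") from exc


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 6-column BED file. An empty file yields an empty frame."""
    try:
        if os.path.getsize(path) == 0:
            return pd.DataFrame(columns=BED6_COLUMNS)
        frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                            names=BED6_COLUMNS, dtype={"chrom": str, "name": str, "strand": str})
    except OSError as exc:
        raise OSError(f"cannot read BED {path!s}: {exc}") from exc
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    return frame


def write_bed6(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    try:
        frame.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    except OSError as exc:
        raise OSError(f"cannot write BED {path!s}: {exc}") from exc


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise OSError(f"cannot read table {path!s}: {exc}") from exc


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    try:
        frame.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write table {path!s}: {exc}") from exc
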