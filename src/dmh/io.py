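"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; BED4 for interval tracks (0-based half-open); TSV
via pandas for probes, scans, matrices and reports; GMT for gene sets.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4 file into columns chrom/start/end/name."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "start": int, "end": int, "name": str},
    )
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    if "name" in intervals.columns:
        cols.append("name")
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")
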