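"""Readers and writers for the pipeline's interchange formats.

Tables travel as TSV with a header row and fixed float precision (6
significant digits), sequences as FASTA with a sidecar 3' UTR interval TSV
(0-based half-open coordinates), gene sets as GMT, and configuration,
manifests and ground truth as sorted-key JSON.  All writers are
deterministic: identical in-memory objects produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Catalog",
    "write_tsv",
    "read_tsv",
    "write_fasta",
    "read_fasta_with_intervals",
    "write_intervals",
    "write_gmt",
    "read_gmt",
    "write_json",
    "read_json",
    "sha256_of",
]

FLOAT_FORMAT = "%.6g"


@dataclass
class Catalog:
    """Transcript sequences with annotated 3' UTR intervals."""

    sequences: dict[str, str]
    utr_intervals: dict[str, tuple[int, int]]
    unusable: list[str] = field(default_factory=list)  # empty-UTR genes


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_intervals(utr_intervals: dict[str, tuple[int, int]], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g, s, e) for g, (s, e) in utr_intervals.items()],
        columns=["gene_id", "utr_start", "utr_end"],
    )
    write_tsv(df, path)


def read_fasta_with_intervals(fasta_path: str | Path, interval_path: str | Path) -> Catalog:
    """Load and validate a catalog: FASTA transcripts + UTR interval TSV.

    Errors on duplicate ids, interval genes missing from the FASTA, and
    out-of-bounds intervals; genes with an empty UTR are kept but flagged
    unusable for site classification.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    intervals_df = read_tsv(interval_path)
    utr: dict[str, tuple[int, int]] = {}
    unusable: list[str] = []
    for row in intervals_df.itertuples(index=False):
        gene, start, end = row.gene_id, int(row.utr_start), int(row.utr_end)
        if gene in utr:
            raise ValueError(f"duplicate interval for {gene!r}")
        if gene not in sequences:
            raise ValueError(f"interval gene {gene!r} absent from FASTA")
        if not (0 <= start <= end <= len(sequences[gene])):
            raise ValueError(
                f"{gene}: interval [{start},{end}) out of bounds for length {len(sequences[gene])}"
            )
        utr[gene] = (start, end)
        if start == end:
            unusable.append(gene)
    missing = sorted(set(sequences) - set(utr))
    if missing:
        raise ValueError(f"FASTA genes without intervals: {missing[:5]}")
    return Catalog(sequences=sequences, utr_intervals=utr, unusable=unusable)


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(gene_sets[name])
            fh.write(f"{name}\tna\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
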