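"""miRNA seed-site scanning and target/no-site classification.

A miRNA represses transcripts carrying a short sequence in their 3' UTR that
is complementary to the miRNA "seed" (nucleotides 2-7 from the 5' end).  The
canonical site variants, from strongest to weakest, are:

* 8mer     -- reverse complement of miRNA nt 2-8, followed by an A
* 7mer-m8  -- reverse complement of miRNA nt 2-8
* 7mer-A1  -- reverse complement of miRNA nt 2-7, followed by an A
* 6mer     -- reverse complement of miRNA nt 2-7

All site strings are given in the DNA alphabet (U -> T) and matched on the
mRNA sense strand.  A gene is a *site* gene for a miRNA when its 3' UTR holds
at least one 7- or 8-nt site; it is a *no-site* gene when the whole transcript
holds no 7/8-nt site and the 3' UTR holds no 6mer; anything in between is
excluded from target/control comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "Mirna",
    "SiteMatch",
    "SiteClassification",
    "TargetSets",
    "site_strings",
    "scan_sites",
    "classify_gene",
    "classify_catalog",
    "build_target_sets",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_RNA_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class Mirna:
    """A mature miRNA, sequence 5'->3' in the RNA alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if set(seq) - _RNA_ALPHABET:
            raise ValueError(f"{self.name}: non-RNA characters in sequence")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SiteMatch:
    gene_id: str
    site_type: str  # one of SITE_TYPES
    position: int  # 0-based offset of the match start in the searched sequence
    region: str  # "3UTR" or "other"


@dataclass
class SiteClassification:
    gene_id: str
    mirna: str
    label: str  # site | no_site | excluded
    matches: list[SiteMatch] = field(default_factory=list)


@dataclass
class TargetSets:
    """Cross-controlled target/control design for a miRNA pair."""

    targets: dict[str, list[str]]
    controls: dict[str, list[str]]


def _rc_dna(rna: str) -> str:
    """Reverse complement of an RNA fragment, written as sense-strand DNA."""
    return str(Seq(rna.replace("U", "T")).reverse_complement())


def site_strings(mirna: Mirna) -> dict[str, str]:
    """The four canonical seed-match strings for a miRNA (DNA alphabet)."""
    seq = mirna.sequence
    if len(seq) < 8:
        raise ValueError(f"{mirna.name}: miRNA must be at least 8 nt")
    seed7 = seq[1:8]  # nt 2-8, 1-based
    seed6 = seq[1:7]  # nt 2-7
    m8 = _rc_dna(seed7)
    a1_core = _rc_dna(seed6)
    return {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": a1_core + "A",
        "6mer": a1_core,
    }


def _find_all(seq: str, sub: str) -> list[int]:
    """All (possibly overlapping) occurrence offsets of ``sub`` in ``seq``."""
    out = []
    i = seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out


def raw_occurrences(seq: str, mirna: Mirna) -> dict[str, list[int]]:
    """All occurrences of each site string, without precedence dedup."""
    strings = site_strings(mirna)
    return {t: _find_all(seq, strings[t]) for t in SITE_TYPES}


def scan_sites(seq: str, mirna: Mirna, gene_id: str = "", utr_interval=None) -> list[SiteMatch]:
    """Scan a sense-strand DNA sequence for seed-matched sites.

    Each locus is reported once under its most specific type: an 8mer match
    subsumes the 7mer-m8 at its start and the 7mer-A1 one base in, and a 6mer
    inside any reported 7/8mer is not separately reported.  ``N`` bases never
    match.  When ``utr_interval`` (0-based half-open) is given, matches fully
    inside it are tagged region="3UTR".
    """
    seq = seq.upper()
    occ = raw_occurrences(seq, mirna)
    strings = site_strings(mirna)
    s8 = set(occ["8mer"])
    reported: list[tuple[str, int]] = [("8mer", i) for i in occ["8mer"]]
    reported += [("7mer-m8", i) for i in occ["7mer-m8"] if i not in s8]
    reported += [("7mer-A1", i) for i in occ["7mer-A1"] if (i - 1) not in s8]
    covered6 = set(occ["7mer-A1"]) | {i + 1 for i in occ["7mer-m8"]} | {i + 1 for i in s8}
    reported += [("6mer", i) for i in occ["6mer"] if i not in covered6]
    reported.sort(key=lambda ti: (ti[1], SITE_TYPES.index(ti[0])))

    def region(site_type: str, pos: int) -> str:
        if utr_interval is None:
            return "other"
        s, e = utr_interval
        return "3UTR" if s <= pos and pos + len(strings[site_type]) <= e else "other"

    return [SiteMatch(gene_id, t, i, region(t, i)) for t, i in reported]


def classify_gene(
    transcript_seq: str, utr_interval: tuple[int, int], mirna: Mirna, gene_id: str = ""
) -> SiteClassification:
    """Apply the site / no-site / excluded rules to one transcript.

    site:    >= 1 site of length >= 7 (8mer, 7mer-m8 or 7mer-A1) fully within
             the 3' UTR.
    no_site: no 7/8-nt site anywhere in the transcript AND no 6-nt seed match
             within the 3' UTR.
    excluded: everything else (e.g. a 7mer in the coding region only).
    """
    seq = transcript_seq.upper()
    start, end = utr_interval
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(f"{gene_id}: invalid UTR interval {utr_interval} for length {len(seq)}")
    occ = raw_occurrences(seq, mirna)
    strings = site_strings(mirna)

    def in_utr(pos: int, site_type: str) -> bool:
        return start <= pos and pos + len(strings[site_type]) <= end

    long_types = ("8mer", "7mer-m8", "7mer-A1")
    any_long_utr = any(in_utr(i, t) for t in long_types for i in occ[t])
    any_long_transcript = any(occ[t] for t in long_types)
    any_6mer_utr = any(in_utr(i, "6mer") for i in occ["6mer"])

    if any_long_utr:
        label = "site"
    elif not any_long_transcript and not any_6mer_utr:
        label = "no_site"
    else:
        label = "excluded"
    matches = scan_sites(seq, mirna, gene_id=gene_id, utr_interval=utr_interval)
    return SiteClassification(gene_id, mirna.name, label, matches)


def classify_catalog(
    sequences: dict[str, str], utr_intervals: dict[str, tuple[int, int]], mirna: Mirna
) -> pd.DataFrame:
    """Classify every gene in a catalog; returns the classification table.

    Columns: gene_id, mirna, label, n_8mer_utr, n_7mer_utr, n_6mer_utr,
    n_7_8mer_transcript.
    """
    rows = []
    for gene_id in sorted(sequences):
        cls = classify_gene(sequences[gene_id], utr_intervals[gene_id], mirna, gene_id=gene_id)
        utr = [m for m in cls.matches if m.region == "3UTR"]
        rows.append(
            {
                "gene_id": gene_id,
                "mirna": mirna.name,
                "label": cls.label,
                "n_8mer_utr": sum(m.site_type == "8mer" for m in utr),
                "n_7mer_utr": sum(m.site_type in ("7mer-m8", "7mer-A1") for m in utr),
                "n_6mer_utr": sum(m.site_type == "6mer" for m in utr),
                "n_7_8mer_transcript": sum(
                    m.site_type in ("8mer", "7mer-m8", "7mer-A1") for m in cls.matches
                ),
            }
        )
    return pd.DataFrame(rows)


def build_target_sets(class_a: pd.DataFrame, class_b: pd.DataFrame) -> TargetSets:
    """Cross-controlled target/control sets for two miRNAs on one gene universe.

    Targets of miRNA A are site genes for A that are no-site genes for B
    (and vice versa), so that each miRNA's targets can serve as clean no-site
    controls for the other; controls for A are all of A's no-site genes.
    """
    a = class_a.set_index("gene_id")["label"]
    b = class_b.set_index("gene_id")["label"]
    if not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        if len(common) != len(a) or len(common) != len(b):
            raise ValueError("classifications cover different gene universes")
        b = b.loc[a.index]
    name_a = str(class_a["mirna"].iloc[0])
    name_b = str(class_b["mirna"].iloc[0])
    targets = {
        name_a: sorted(a.index[(a == "site") & (b == "no_site")]),
        name_b: sorted(a.index[(b == "site") & (a == "no_site")]),
    }
    controls = {
        name_a: sorted(a.index[a == "no_site"]),
        name_b: sorted(a.index[b == "no_site"]),
    }
    for name in (name_a, name_b):
        if not targets[name]:
            raise ValueError(f"empty target set for {name}")
        if not controls[name]:
            raise ValueError(f"empty control set for {name}")
    return TargetSets(targets=targets, controls=controls)
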