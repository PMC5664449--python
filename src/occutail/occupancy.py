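"""Relative occupancy from RIP expression tables and NanoString counts.

The relative occupancy of a protein on the mRNAs of a gene is the ratio of
the gene's abundance in the immunoprecipitated (IP) fraction to its abundance
in the matched input fraction, median-centered across the retained genes so
that the typical gene has occupancy 1.  Expression tables are tidy frames
with columns ``gene_id, protein, condition, fraction, value`` (fraction is
"input" or "IP"; values are FPKM-like, >= 0).

Filtering follows the RIP analysis conventions: a gene is retained when its
expression exceeds 1 in both the input and the IP library ("plain" mode); for
miRNA transfection experiments the >1 requirement applies to the mock
libraries and every other library only needs a non-zero value
("mirna_experiment" mode).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "filter_expressed",
    "relative_occupancy",
    "occupancy_table",
    "nanostring_normalize",
    "nanostring_occupancy",
]

log = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["gene_id", "protein", "condition", "fraction", "value"]


def _pivot(expr: pd.DataFrame, protein: str) -> pd.DataFrame:
    sub = expr[expr["protein"] == protein]
    if sub.empty:
        raise KeyError(f"no libraries for protein {protein!r}")
    wide = sub.pivot_table(
        index="gene_id", columns=["condition", "fraction"], values="value", aggfunc="first"
    )
    if (wide.values < 0).any():
        raise ValueError("negative expression values")
    return wide


def _require(wide: pd.DataFrame, condition: str, fraction: str, protein: str) -> pd.Series:
    try:
        return wide[(condition, fraction)]
    except KeyError:
        raise KeyError(
            f"missing library (protein={protein!r}, condition={condition!r}, fraction={fraction!r})"
        ) from None


def filter_expressed(
    expr: pd.DataFrame,
    protein: str,
    mode: str = "plain",
    condition: str = "mock",
) -> pd.Index:
    """Return the gene ids retained by the expression filter.

    plain: value > 1 in both input and IP of ``condition``.
    mirna_experiment: value > 1 in mock input and mock IP, and value > 0 in
    every other library of the protein.
    """
    wide = _pivot(expr, protein)
    if mode == "plain":
        inp = _require(wide, condition, "input", protein)
        ip = _require(wide, condition, "IP", protein)
        keep = (inp > 1) & (ip > 1)
    elif mode == "mirna_experiment":
        inp = _require(wide, condition, "input", protein)
        ip = _require(wide, condition, "IP", protein)
        keep = (inp > 1) & (ip > 1)
        others = [c for c in wide.columns if c[0] != condition]
        if others:
            keep &= (wide[others] > 0).all(axis=1)
        keep &= wide.notna().all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = keep.fillna(False)
    return wide.index[keep]


def relative_occupancy(
    expr: pd.DataFrame, retained: pd.Index, protein: str, condition: str
) -> pd.DataFrame:
    """Median-centered IP/input occupancy for one (protein, condition).

    Returns columns gene_id, protein, condition, occupancy, ip_value,
    input_value.  The median occupancy over the retained genes is exactly 1
    after centering.
    """
    wide = _pivot(expr, protein)
    inp = _require(wide, condition, "input", protein).reindex(retained)
    ip = _require(wide, condition, "IP", protein).reindex(retained)
    if inp.isna().any() or ip.isna().any():
        missing = retained[inp.isna() | ip.isna()]
        raise ValueError(f"retained genes missing values: {list(missing[:5])}")
    if (inp <= 0).any():
        bad = retained[inp <= 0]
        raise ValueError(f"zero input for retained genes: {list(bad[:5])}")
    occ = ip / inp
    occ = occ / occ.median()
    out = pd.DataFrame(
        {
            "gene_id": retained,
            "protein": protein,
            "condition": condition,
            "occupancy": occ.to_numpy(),
            "ip_value": ip.to_numpy(),
            "input_value": inp.to_numpy(),
        }
    )
    return out.sort_values("gene_id", ignore_index=True)


def occupancy_table(
    expr: pd.DataFrame,
    mode: str = "plain",
    mock_condition: str = "mock",
) -> pd.DataFrame:
    """Occupancies for every (protein, condition) present in the table.

    In ``mirna_experiment`` mode the gene universe for each protein is the
    miRNA-experiment filter (anchored on the mock libraries), applied jointly
    to all of that protein's conditions.
    """
    frames = []
    for protein in sorted(expr["protein"].unique()):
        retained = filter_expressed(expr, protein, mode=mode, condition=mock_condition)
        conditions = sorted(expr.loc[expr["protein"] == protein, "condition"].unique())
        for condition in conditions:
            frames.append(relative_occupancy(expr, retained, protein, condition))
    return pd.concat(frames, ignore_index=True)


def nanostring_normalize(
    counts: pd.DataFrame, reference_genes: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Reference-gene geometric-mean normalization of a genes x samples table.

    The per-sample scale factor is the across-sample average of the
    reference-gene geometric means divided by the sample's own reference-gene
    geometric mean, which equalizes reference-gene geometric means across
    samples.  Returns (normalized table, factors).
    """
    missing = [g for g in reference_genes if g not in counts.index]
    if missing:
        raise ValueError(f"reference genes absent from table: {missing}")
    ref = counts.loc[list(reference_genes)]
    if (ref <= 0).any().any():
        raise ValueError("zero reference-gene count")
    gm = np.exp(np.log(ref).mean(axis=0))
    factors = gm.mean() / gm
    return counts.mul(factors, axis=1), factors


def nanostring_occupancy(ip_counts: pd.Series, input_counts: pd.Series) -> pd.Series:
    """Median-centered occupancy from normalized NanoString IP/input counts.

    Genes with zero input counts (or absent from either table) are dropped
    with a warning.
    """
    genes = ip_counts.index.intersection(input_counts.index)
    dropped = len(ip_counts.index.union(input_counts.index)) - len(genes)
    if dropped:
        log.warning("nanostring_occupancy: %d genes absent from one table, dropped", dropped)
    inp = input_counts.loc[genes]
    ip = ip_counts.loc[genes]
    zero = inp <= 0
    if zero.any():
        log.warning("nanostring_occupancy: %d genes with zero input counts, dropped", int(zero.sum()))
        inp, ip = inp[~zero], ip[~zero]
    occ = ip / inp
    return (occ / occ.median()).sort_index()
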