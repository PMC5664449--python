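"""Occupancy vs stability: correlations, trend residuals and set enrichment.

Relative occupancy of core mRNP proteins (most informatively the cytoplasmic
poly(A)-binding protein) correlates with mRNA half-life.  Genes that deviate
strongly from that trend -- less or more stable than predicted by their
occupancy -- are biologically interesting classes; this module fits the
log2-log2 trend, extracts the symmetric residual extremes, and tests
user-supplied gene sets (GMT collections) for enrichment within either
extreme using an upper-tail hypergeometric test with Benjamini-Hochberg
correction across sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_stats import (
    bh_fdr,
    box_summary,
    hypergeometric_enrichment,
    ks_two_sample,
    spearman,
)

__all__ = [
    "correlate_features",
    "residual_scan",
    "enrich_extremes",
    "class_contrast",
]

log = logging.getLogger(__name__)

MIN_PAIR_OVERLAP = 10


def correlate_features(features: dict[str, pd.Series], pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Spearman correlations between per-gene feature vectors.

    ``features`` maps a feature name (e.g. "PABP_occupancy", "half_life",
    "mean_tail", "TE") to a gene-indexed Series.  All unordered pairs are
    tested unless ``pairs`` restricts them; pairs with fewer than 10 shared
    genes are skipped with a warning.
    """
    names = sorted(features)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        sa, sb = features[a], features[b]
        genes = sa.index.intersection(sb.index).sort_values()
        if len(genes) < MIN_PAIR_OVERLAP:
            log.warning("correlate_features: %s vs %s skipped (%d shared genes)", a, b, len(genes))
            continue
        res = spearman(sa.loc[genes].to_numpy(dtype=float), sb.loc[genes].to_numpy(dtype=float))
        rows.append(
            {"feature_a": a, "feature_b": b, "rho": res.rho, "p_value": res.p_value, "n": res.n}
        )
    return pd.DataFrame(rows)


def residual_scan(
    occupancy: pd.Series,
    half_life: pd.Series,
    extreme_quantile: float = 0.1,
    fit: str = "ols",
) -> pd.DataFrame:
    """Residuals of log2 half-life regressed on log2 occupancy.

    A least-squares line (default; ``fit='rank'`` uses least squares on
    average ranks instead, a monotone-robust alternative) predicts log2
    half-life from log2 occupancy.  The genes in the lowest
    ``extreme_quantile`` of residuals are flagged ``low_tail`` (less stable
    than predicted), the highest are ``high_tail`` (more stable than
    predicted); both extremes contain exactly floor(q * n) genes, with
    boundary ties broken by gene id for determinism.

    Returns a frame with columns gene_id, log2_occupancy, log2_half_life,
    fitted, residual, extreme.
    """
    if not 0 < extreme_quantile < 0.5:
        raise ValueError("extreme_quantile must be in (0, 0.5)")
    genes = occupancy.index.intersection(half_life.index).sort_values()
    if len(genes) < 50:
        raise ValueError(f"need >= 50 shared genes, have {len(genes)}")
    occ = occupancy.loc[genes].astype(float)
    hl = half_life.loc[genes].astype(float)
    if (occ <= 0).any() or (hl <= 0).any():
        raise ValueError("occupancy and half-life must be positive for log2 transform")
    x = np.log2(occ.to_numpy())
    y = np.log2(hl.to_numpy())
    if np.ptp(x) == 0:
        raise ValueError("constant occupancy: trend fit is degenerate")
    if fit == "ols":
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
    elif fit == "rank":
        rx = sps.rankdata(x)
        slope, intercept = np.polyfit(rx, y, 1)
        fitted = slope * rx + intercept
    else:
        raise ValueError(f"unknown fit {fit!r}")
    residual = y - fitted
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "log2_occupancy": x,
            "log2_half_life": y,
            "fitted": fitted,
            "residual": residual,
        }
    )
    k = int(np.floor(extreme_quantile * len(df)))
    df["extreme"] = "none"
    order_low = df.sort_values(["residual", "gene_id"]).index
    order_high = df.sort_values(["residual", "gene_id"], ascending=[False, True]).index
    df.loc[order_low[:k], "extreme"] = "low_tail"
    df.loc[order_high[:k], "extreme"] = "high_tail"
    return df.sort_values("gene_id", ignore_index=True)


def enrich_extremes(
    records: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    direction: str = "low_tail",
    q_threshold: float = 0.001,
    p_mode: str = "upper",
) -> pd.DataFrame:
    """Hypergeometric enrichment of gene sets within a residual extreme.

    The background universe is every gene in ``records`` (all genes entering
    the residual scan); each set is intersected with the universe first.
    Returns one row per set with hits, set size, p, BH q, and a flag for
    q < ``q_threshold``, ranked by q then name.  Sets with no gene in the
    universe are skipped.
    """
    if direction not in ("low_tail", "high_tail"):
        raise ValueError(f"unknown direction {direction!r}")
    universe = set(records["gene_id"])
    if not universe:
        raise ValueError("empty record universe")
    extreme = set(records.loc[records["extreme"] == direction, "gene_id"])
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        if not members:
            log.warning("enrich_extremes: set %s has no genes in the universe, skipped", name)
            continue
        hits = len(members & extreme)
        p = hypergeometric_enrichment(hits, len(members), len(extreme), len(universe), mode=p_mode)
        rows.append({"set": name, "hits": hits, "set_size": len(members), "p_value": p})
    if not rows:
        raise ValueError("no testable gene sets")
    df = pd.DataFrame(rows)
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    df["direction"] = direction
    df["significant"] = df["q_value"] < q_threshold
    return df.sort_values(["q_value", "set"], ignore_index=True)


def class_contrast(
    features: dict[str, pd.Series], class_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Distribution summaries of each feature for each gene class vs the rest.

    For every (class, feature) pair: box summary of the class members and a
    two-tailed K-S test against all remaining genes measured for that
    feature.  Classes with fewer than 5 measured genes are still reported but
    flagged with a warning; an empty class is an error.
    """
    rows = []
    for cls_name in sorted(class_sets):
        members = set(class_sets[cls_name])
        if not members:
            raise ValueError(f"empty class {cls_name!r}")
        for feat_name in sorted(features):
            series = features[feat_name].astype(float)
            in_class = series.loc[series.index.intersection(sorted(members))]
            rest = series.loc[~series.index.isin(members)]
            if in_class.empty or rest.empty:
                continue
            if len(in_class) < 5:
                log.warning(
                    "class_contrast: class %s has only %d genes with %s", cls_name, len(in_class), feat_name
                )
            ks = ks_two_sample(in_class.to_numpy(), rest.to_numpy())
            rows.append(
                {
                    "class": cls_name,
                    "feature": feat_name,
                    **box_summary(in_class.to_numpy()),
                    "rest_median": float(rest.median()),
                    "ks_D": ks.statistic,
                    "ks_p": ks.p_value,
                }
            )
    return pd.DataFrame(rows)
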