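"""Poly(A)-tail length analytics on per-tag measurements.

Tail data arrive as one integer tail length per sequenced tag, grouped by
gene (the output of a tag-level tail-profiling protocol).  A sample is a tidy
frame with columns ``gene_id, tail_length``.  Analyses:

* per-gene mean tails, with the >= 100-tags eligibility filter;
* bound-vs-total mean-tail differences (per-gene pairing, box summaries,
  fraction of genes shorter in the bound fraction);
* metagene tail-length distributions (per-gene-normalized histograms averaged
  with equal gene weight) and window-depletion comparisons;
* site vs no-site tail-length changes under a miRNA;
* phasing profiles: normalized frequencies of all pairwise tail-length
  differences within a gene, averaged across a random gene sample, to detect
  footprint-sized periodicity;
* occupancy binned by mean tail length in footprint-sized bins (one extra
  protein footprint per bin).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_stats import (
    box_summary,
    ks_two_sample,
    mann_whitney_u,
    spearman,
)

__all__ = [
    "mean_tails",
    "tail_diff",
    "metagene_distribution",
    "window_depletion",
    "site_tail_change",
    "phasing_profile",
    "detect_phasing_peaks",
    "bin_occupancy_by_tail",
]

TAIL_COLUMNS = ["gene_id", "tail_length"]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("empty tail-tag table")
    lengths = table["tail_length"]
    if (lengths < 0).any():
        raise ValueError("negative tail lengths")
    return table


def mean_tails(table: pd.DataFrame, min_tags: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene mean tail lengths for genes with >= ``min_tags`` tags.

    Returns (stats, excluded): ``stats`` has columns gene_id, mean_tail,
    n_tags for eligible genes; ``excluded`` lists the genes below the tag
    threshold with their counts.
    """
    _check_table(table)
    grouped = table.groupby("gene_id")["tail_length"].agg(["mean", "size"])
    grouped.columns = ["mean_tail", "n_tags"]
    grouped = grouped.sort_index()
    keep = grouped["n_tags"] >= min_tags
    stats = grouped[keep].reset_index()
    excluded = grouped[~keep].reset_index()
    return stats, excluded


def tail_diff(
    bound: pd.DataFrame, total: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Per-gene bound-minus-total mean-tail differences and their summary.

    ``bound`` and ``total`` are mean-tail stats frames (gene_id, mean_tail,
    n_tags).  The summary holds the median/quartile/whisker box of the
    differences, the fraction of genes with shorter tails in the bound
    fraction, the Spearman correlation between bound and total means, and the
    paired signed-rank p-value.
    """
    b = bound.set_index("gene_id")["mean_tail"]
    t = total.set_index("gene_id")["mean_tail"]
    genes = b.index.intersection(t.index).sort_values()
    if genes.empty:
        raise ValueError("no genes shared between bound and total samples")
    diffs = (b.loc[genes] - t.loc[genes]).astype(float)
    per_gene = pd.DataFrame(
        {
            "gene_id": genes,
            "bound_mean": b.loc[genes].to_numpy(),
            "total_mean": t.loc[genes].to_numpy(),
            "difference": diffs.to_numpy(),
        }
    )
    corr = spearman(b.loc[genes].to_numpy(), t.loc[genes].to_numpy()) if len(genes) >= 3 else None
    summary = dict(box_summary(diffs.to_numpy()))
    summary["fraction_shorter"] = float((diffs < 0).mean())
    summary["spearman_rho"] = corr.rho if corr is not None else float("nan")
    summary["spearman_p"] = corr.p_value if corr is not None else float("nan")
    paired = mann_whitney_u(b.loc[genes].to_numpy(), t.loc[genes].to_numpy(), paired=True)
    summary["paired_signed_rank_p"] = paired.p_value
    return per_gene, summary


def _per_gene_histograms(
    table: pd.DataFrame, bin_width: int, max_len: int | None, min_tags: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    stats, _ = mean_tails(table, min_tags=min_tags)
    genes = list(stats["gene_id"])
    if not genes:
        raise ValueError("no genes pass the tag threshold")
    if max_len is None:
        max_len = int(table["tail_length"].max())
    edges = np.arange(0, max_len + bin_width + 1, bin_width)
    sub = table[table["gene_id"].isin(genes)]
    hists = np.zeros((len(genes), len(edges) - 1))
    for i, (gene, grp) in enumerate(sub.groupby("gene_id", sort=True)):
        h, _ = np.histogram(grp["tail_length"].to_numpy(), bins=edges)
        hists[i] = h / h.sum()
    return hists, edges, genes


def metagene_distribution(
    table: pd.DataFrame,
    bin_width: int = 1,
    min_tags: int = 100,
    max_len: int | None = None,
    per_gene_weighting: bool = True,
) -> pd.DataFrame:
    """Metagene tail-length histogram.

    Per-gene histograms are normalized to sum to 1 and averaged with equal
    gene weight (default), so deeply sequenced genes do not dominate; with
    ``per_gene_weighting=False`` the histogram is tag-weighted instead.
    Returns a frame (bin_start, frequency) summing to 1.
    """
    _check_table(table)
    hists, edges, genes = _per_gene_histograms(table, bin_width, max_len, min_tags)
    if per_gene_weighting:
        avg = hists.mean(axis=0)
    else:
        counts = table[table["gene_id"].isin(genes)].groupby("gene_id", sort=True)["tail_length"].size()
        w = counts.to_numpy(dtype=float)
        avg = (hists * (w / w.sum())[:, None]).sum(axis=0)
    return pd.DataFrame({"bin_start": edges[:-1], "frequency": avg})


def window_depletion(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    window: tuple[float, float],
    min_tags: int = 100,
) -> dict:
    """Compare, gene by gene, the fraction of tails inside a length window.

    For each gene measured in both samples, computes the fraction of its tags
    with tail length in ``[window[0], window[1])`` and runs a paired
    signed-rank test of sample A vs sample B over genes.  Used, e.g., to ask
    whether short tails (< 50 nt) are depleted in a bound fraction relative
    to total mRNA.
    """
    lo, hi = window

    def fractions(table: pd.DataFrame) -> pd.Series:
        stats, _ = mean_tails(table, min_tags=min_tags)
        keep = table[table["gene_id"].isin(stats["gene_id"])]
        inside = keep["tail_length"].ge(lo) & keep["tail_length"].lt(hi)
        return inside.groupby(keep["gene_id"]).mean()

    fa = fractions(sample_a)
    fb = fractions(sample_b)
    genes = fa.index.intersection(fb.index).sort_values()
    if genes.empty:
        raise ValueError("no genes shared between samples")
    res = mann_whitney_u(fa.loc[genes].to_numpy(), fb.loc[genes].to_numpy(), paired=True)
    return {
        "n_genes": int(len(genes)),
        "median_fraction_a": float(fa.loc[genes].median()),
        "median_fraction_b": float(fb.loc[genes].median()),
        "p_value": res.p_value,
    }


def site_tail_change(
    stats_mock: pd.DataFrame,
    stats_mirna: pd.DataFrame,
    site_genes: list[str],
    no_site_genes: list[str],
) -> dict:
    """Site vs no-site contrast of per-gene mean-tail changes under a miRNA.

    The per-gene change is mean tail (miRNA condition) minus mean tail
    (mock).  Reports the medians of both groups, the median difference and a
    two-tailed K-S test between the two change distributions.
    """
    m = stats_mock.set_index("gene_id")["mean_tail"]
    t = stats_mirna.set_index("gene_id")["mean_tail"]
    genes = m.index.intersection(t.index)
    change = (t.loc[genes] - m.loc[genes]).astype(float)
    site = change.loc[change.index.intersection(sorted(set(site_genes)))]
    no_site = change.loc[change.index.intersection(sorted(set(no_site_genes)))]
    if site.empty:
        raise ValueError("no site genes with tail measurements in both conditions")
    if no_site.empty:
        raise ValueError("no no-site genes with tail measurements in both conditions")
    ks = ks_two_sample(site.to_numpy(), no_site.to_numpy())
    return {
        "n_site": int(site.size),
        "n_no_site": int(no_site.size),
        "median_change_site": float(site.median()),
        "median_change_no_site": float(no_site.median()),
        "median_difference": float(site.median() - no_site.median()),
        "ks_D": ks.statistic,
        "ks_p": ks.p_value,
    }


def _pairwise_difference_freqs(tail_lengths: np.ndarray, max_len: int) -> np.ndarray:
    """Normalized frequency of each absolute pairwise difference (0..max_len).

    All C(n, 2) unordered distinct tag pairs contribute; pairs of equal
    lengths contribute difference 0.  Computed from the tail-length count
    vector by correlation: the number of pairs at difference d > 0 is
    sum_L c[L] * c[L+d]; at d = 0 it is sum_L C(c[L], 2).
    """
    counts = np.bincount(tail_lengths, minlength=max_len + 1).astype(float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 tags for pairwise differences")
    corr = np.correlate(counts, counts, mode="full")[len(counts) - 1 :]
    pair_counts = corr.copy()
    pair_counts[0] = (counts * (counts - 1)).sum() / 2.0
    total = n * (n - 1) / 2.0
    return pair_counts / total


def phasing_profile(
    table: pd.DataFrame,
    n_genes: int = 100,
    seed: int = 0,
    max_diff: int = 60,
    min_tags: int = 100,
) -> pd.DataFrame:
    """Per-gene and averaged pairwise tail-length difference frequencies.

    For each of ``n_genes`` genes sampled (seeded, without replacement) among
    those passing the tag threshold, every unordered pair of tags yields an
    absolute tail-length difference; the normalized frequency of each integer
    difference is recorded per gene and averaged across genes.  The output is
    restricted to differences in [0, max_diff]; frequencies are normalized
    over the full difference range first, so columns are comparable across
    genes.  Rows with gene_id ``AVERAGE`` hold the cross-gene mean.
    """
    _check_table(table)
    stats, _ = mean_tails(table, min_tags=min_tags)
    eligible = list(stats["gene_id"])
    if len(eligible) < n_genes:
        raise ValueError(f"only {len(eligible)} genes pass min_tags={min_tags}, need {n_genes}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(eligible, size=n_genes, replace=False))
    max_len = int(table["tail_length"].max())
    sub = table[table["gene_id"].isin(chosen)]
    rows = []
    freqs = np.zeros((n_genes, max_diff + 1))
    for i, gene in enumerate(chosen):
        tl = sub.loc[sub["gene_id"] == gene, "tail_length"].to_numpy()
        f = _pairwise_difference_freqs(tl, max_len)
        freqs[i] = f[: max_diff + 1]
        for d in range(max_diff + 1):
            rows.append({"gene_id": gene, "difference": d, "frequency": freqs[i, d]})
    avg = freqs.mean(axis=0)
    for d in range(max_diff + 1):
        rows.append({"gene_id": "AVERAGE", "difference": d, "frequency": avg[d]})
    return pd.DataFrame(rows)


def detect_phasing_peaks(
    avg_profile: pd.DataFrame, window: int = 5, ratio: float = 1.5, min_diff: int | None = None
) -> list[int]:
    """Differences whose average frequency exceeds ``ratio`` x the mean of
    their +-``window`` neighborhood (neighborhood excludes the point itself).

    A footprint-phased tail population produces peaks at multiples of the
    footprint; smooth unimodal difference profiles produce none.  Differences
    below ``min_diff`` (default: the neighborhood half-width) are not scored:
    the profile is intrinsically elevated near zero, where pairs of tags
    sampling the same underlying tail state concentrate, and any footprint of
    interest is far larger than that cluster.
    """
    if min_diff is None:
        min_diff = window
    avg = avg_profile[avg_profile["gene_id"] == "AVERAGE"].sort_values("difference")
    f = avg["frequency"].to_numpy()
    d = avg["difference"].to_numpy()
    peaks = []
    for i in range(len(f)):
        if d[i] < min_diff:
            continue
        lo = max(0, i - window)
        hi = min(len(f), i + window + 1)
        neighborhood = np.concatenate([f[lo:i], f[i + 1 : hi]])
        if neighborhood.size == 0:
            continue
        mean_nb = neighborhood.mean()
        if f[i] > ratio * mean_nb and f[i] > 0:
            peaks.append(int(d[i]))
    return peaks


def bin_occupancy_by_tail(
    occupancy: pd.DataFrame,
    tail_stats: pd.DataFrame,
    footprint: int = 26,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Occupancy distributions for genes binned by mean tail length.

    Bins are [0, 25), [25, 50), ... for the default 26-nt footprint -- each
    successive bin accommodates roughly one additional bound protein (bin
    width = footprint - 1 for the first boundary, then footprint-sized
    steps as in a 25/50/75 grid).  Returns (per-bin box summaries, pairwise
    Mann-Whitney bin comparisons, overall Spearman of occupancy vs mean
    tail).
    """
    occ = occupancy.set_index("gene_id")["occupancy"]
    tails = tail_stats.set_index("gene_id")["mean_tail"]
    genes = occ.index.intersection(tails.index).sort_values()
    if genes.empty:
        raise ValueError("no genes shared between occupancy and tail tables")
    occ = occ.loc[genes].astype(float)
    tails = tails.loc[genes].astype(float)
    step = footprint - 1
    max_tail = float(tails.max())
    edges = np.arange(0, max_tail + step + 1, step)
    labels = [f"[{int(edges[i])},{int(edges[i + 1])})" for i in range(len(edges) - 1)]
    bins = pd.cut(tails, bins=edges, right=False, labels=labels)
    summaries = []
    groups: dict[str, np.ndarray] = {}
    for label in labels:
        vals = occ[bins == label].to_numpy()
        if vals.size == 0:
            continue
        groups[label] = vals
        row = {"bin": label, **box_summary(vals)}
        summaries.append(row)
    pair_rows = []
    keys = list(groups)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if groups[keys[i]].size < 2 or groups[keys[j]].size < 2:
                continue
            res = mann_whitney_u(groups[keys[i]], groups[keys[j]])
            pair_rows.append(
                {"bin_a": keys[i], "bin_b": keys[j], "U": res.statistic, "p_value": res.p_value}
            )
    if len(genes) >= 3:
        corr = spearman(occ.to_numpy(), tails.to_numpy())
        overall = {"spearman_rho": corr.rho, "spearman_p": corr.p_value, "n": int(len(genes))}
    else:
        overall = {"spearman_rho": float("nan"), "spearman_p": float("nan"), "n": int(len(genes))}
    return pd.DataFrame(summaries), pd.DataFrame(pair_rows), overall
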