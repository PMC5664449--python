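"""miRNA-attributable changes in total mRNA, IP mRNA and inferred occupancy.

For each gene the log2 fold change between a miRNA transfection and the mock
control is computed separately for the input (total mRNA) and IP fractions;
the inferred occupancy change is their difference (IP change minus total
change), i.e. the change in co-immunoprecipitated mRNA normalized to the
change in overall abundance.  The miRNA-attributable effect on any of these
quantities is the median change among site-containing targets minus the
median change among no-site controls, with a two-tailed Kolmogorov-Smirnov
test between the two change distributions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .core_stats import ecdf, ks_two_sample

__all__ = [
    "EffectSummary",
    "fold_changes",
    "cdf_effect",
    "percent_change_from_log2",
    "effect_report",
    "cdf_coordinates",
]

QUANTITIES = ("total", "ip", "occupancy")

STAR_THRESHOLDS = ((0.0001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class EffectSummary:
    mirna: str
    protein: str
    quantity: str  # total | ip | occupancy
    median_log2_change_targets: float
    median_log2_change_controls: float
    attributable_median_log2: float
    percent_change: float
    ks_D: float
    ks_p: float
    n_targets: int
    n_controls: int


def fold_changes(
    expr: pd.DataFrame,
    protein: str,
    treated_condition: str,
    mock_condition: str = "mock",
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold changes (treated vs mock) for one protein.

    IP changes are computed from raw (non-input-normalized) IP values;
    the occupancy change is defined as ip - total in log2.  ``genes`` should
    be the miRNA-experiment filter output; genes with a zero value in any of
    the four libraries are dropped (the filter normally prevents this).
    Returns a frame indexed by gene_id with columns total, ip, occupancy.
    """
    sub = expr[expr["protein"] == protein]
    wide = sub.pivot_table(
        index="gene_id", columns=["condition", "fraction"], values="value", aggfunc="first"
    )
    cols = [
        (mock_condition, "input"),
        (mock_condition, "IP"),
        (treated_condition, "input"),
        (treated_condition, "IP"),
    ]
    for c in cols:
        if c not in wide.columns:
            raise KeyError(f"missing library (protein={protein!r}, condition={c[0]!r}, fraction={c[1]!r})")
    if genes is not None:
        wide = wide.reindex(genes)
    sel = wide[cols]
    ok = sel.notna().all(axis=1) & (sel > 0).all(axis=1)
    wide = wide[ok]
    total = np.log2(wide[(treated_condition, "input")] / wide[(mock_condition, "input")])
    ip = np.log2(wide[(treated_condition, "IP")] / wide[(mock_condition, "IP")])
    out = pd.DataFrame({"total": total, "ip": ip, "occupancy": ip - total})
    out.index.name = "gene_id"
    return out.sort_index()


def percent_change_from_log2(x: float) -> float:
    """Signed percent change corresponding to a log2 fold change."""
    return float((2.0 ** x - 1.0) * 100.0)


def cdf_effect(
    fcs: pd.DataFrame,
    targets: list[str],
    controls: list[str],
    quantity: str,
    mirna: str = "",
    protein: str = "",
    ks_method: str = "asymp",
) -> EffectSummary:
    """Attributable median change and K-S contrast for one quantity.

    ``targets`` and ``controls`` must be disjoint; genes absent from the
    fold-change table (dropped by the expression filter) are ignored.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}")
    t_set, c_set = set(targets), set(controls)
    if t_set & c_set:
        raise ValueError("target and control sets overlap")
    tvals = fcs.loc[fcs.index.intersection(sorted(t_set)), quantity].to_numpy()
    cvals = fcs.loc[fcs.index.intersection(sorted(c_set)), quantity].to_numpy()
    if tvals.size == 0 or cvals.size == 0:
        raise ValueError("empty target or control values after filtering")
    med_t = float(np.median(tvals))
    med_c = float(np.median(cvals))
    attributable = med_t - med_c
    ks = ks_two_sample(tvals, cvals, method=ks_method)
    return EffectSummary(
        mirna=mirna,
        protein=protein,
        quantity=quantity,
        median_log2_change_targets=med_t,
        median_log2_change_controls=med_c,
        attributable_median_log2=attributable,
        percent_change=percent_change_from_log2(attributable),
        ks_D=ks.statistic,
        ks_p=ks.p_value,
        n_targets=int(tvals.size),
        n_controls=int(cvals.size),
    )


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def effect_report(summaries: list[EffectSummary]) -> pd.DataFrame:
    """Ranked effect table with significance stars (p < 0.05 / 0.01 / 0.0001)."""
    if not summaries:
        raise ValueError("no summaries")
    rows = [asdict(s) for s in summaries]
    df = pd.DataFrame(rows)
    df["stars"] = df["ks_p"].map(significance_stars)
    return df.sort_values(
        ["ks_p", "mirna", "protein", "quantity"], ignore_index=True
    )


def cdf_coordinates(
    fcs: pd.DataFrame, gene_sets: dict[str, list[str]], quantity: str
) -> pd.DataFrame:
    """Empirical-CDF coordinates for plotting change distributions.

    Returns a long frame (set, value, cum_fraction) with right-continuous
    CDFs evaluated at the observed values.
    """
    frames = []
    for name, genes in sorted(gene_sets.items()):
        vals = fcs.loc[fcs.index.intersection(sorted(set(genes))), quantity].to_numpy()
        if vals.size == 0:
            continue
        x, f = ecdf(vals)
        frames.append(pd.DataFrame({"set": name, "value": x, "cum_fraction": f}))
    if not frames:
        raise ValueError("no genes in any set")
    return pd.concat(frames, ignore_index=True)
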