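"""Seeded synthetic-data generator for the whole pipeline, with ground truth.

The generator emulates the statistical structure of a RIP/NanoString/tail-
profiling study of mRNP composition in a miRNA-transfected cell line:

* a gene catalog with random-composition transcripts whose 3' UTRs carry
  engineered seed sites for one of two miRNAs (targets) or are scrubbed of
  seed matches to both (controls), so the intended site/no-site labels are
  recoverable by sequence classification alone;
* log-normal gene expression with gene-specific true IP enrichment
  (occupancy) per protein, miRNA effects on abundance and occupancy applied
  to cognate targets through a per-gene targeting-efficacy multiplier, and
  NanoString-style count tables with per-sample scale factors and Poisson
  noise in which four abundant reference genes permit intersample
  normalization;
* tag-level poly(A)-tail tables: per-gene discretized-gamma tail
  distributions, an exponential short-tail bias for the DDX6-bound fraction
  (strength tau, calibrated so the median bound-minus-total mean difference
  hits a configured value), a short-tail *depletion* for the PABP-bound
  fraction, optional footprint phasing (tails snapped to multiples of a
  period plus jitter), and a small bound-tail shortening of site genes under
  the cognate miRNA;
* per-gene half-lives coupled log-linearly to true PABP occupancy, with a
  designated outlier class destabilized despite high occupancy, plus random
  gene sets (GMT) for enrichment nulls.

Everything downstream consumes these tables; every assumption is a config
knob and the ground truth is retained, so parameter-recovery tests close the
loop.  A fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .sites import Mirna, site_strings

__all__ = [
    "MirnaEffect",
    "SimConfig",
    "GroundTruth",
    "SimData",
    "generate",
    "calibrate_ddx6_tau",
    "DEFAULT_MIRNAS",
]

# miR-124 and miR-155, the two transfected miRNAs the design emulates
DEFAULT_MIRNAS = (
    ("miR-124", "UAAGGCACGCGGUGAAUGCC"),
    ("miR-155", "UUAAUGCUAAUCGUGAUAGGGGU"),
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class MirnaEffect:
    """Injected log2 effects of one miRNA on its cognate targets."""

    total_log2: float
    occupancy_log2: dict[str, float]
    bound_tail_shift_nt: float = -4.0  # DDX6-bound mean-tail shift of site genes


def _default_effects() -> dict[str, MirnaEffect]:
    # magnitudes follow the miR-124 / miR-155 transfection measurements:
    # total mRNA -0.80 / -0.52 log2; AGO2 occupancy +1.66 / +1.14;
    # eIF4G -7.3% / -5.4%; PABP -11.7% / -8.4%; eIF4E null; DDX6 +43% / +27%
    return {
        "miR-124": MirnaEffect(
            total_log2=-0.80,
            occupancy_log2={
                "AGO2": 1.66,
                "DDX6": 0.516,
                "eIF4E": 0.0,
                "eIF4G": -0.109,
                "PABP": -0.180,
            },
        ),
        "miR-155": MirnaEffect(
            total_log2=-0.52,
            occupancy_log2={
                "AGO2": 1.14,
                "DDX6": 0.345,
                "eIF4E": 0.0,
                "eIF4G": -0.080,
                "PABP": -0.127,
            },
        ),
    }


@dataclass
class SimConfig:
    """All generator knobs.  Defaults are the study conditions the closed-loop
    acceptance checks assume; see docs/methods.md for the rationale of each."""

    n_genes: int = 2200
    seed: int = 0
    target_fraction: float = 0.0432  # per miRNA; ~95 targets each at 2200 genes

    # expression / occupancy
    expression_mu_sigma: tuple[float, float] = (5.0, 2.0)  # log2 FPKM-like units
    occupancy_sigma: float = 1.0  # log2 spread of true IP enrichment
    occupancy_latent_weight: float = 0.7  # shared-factor loading coupling proteins
    expression_noise_sd: float = 0.03  # per-library log2 measurement noise
    efficacy_sd: float = 0.08  # per-gene spread of the targeting-efficacy multiplier
    proteins: tuple[str, ...] = ("AGO2", "DDX6", "eIF4E", "eIF4G", "PABP")
    mirnas: tuple[tuple[str, str], ...] = DEFAULT_MIRNAS
    mirna_effects: dict[str, MirnaEffect] = field(default_factory=_default_effects)

    # sequences
    transcript_length_range: tuple[int, int] = (1500, 2500)
    utr_length_range: tuple[int, int] = (200, 800)

    # tails
    tail_mu_range: tuple[float, float] = (30.0, 150.0)
    tail_shape: float = 8.0  # gamma shape (cv ~ 0.35)
    tail_max: int = 500
    bound_fraction_bias_tau: Optional[float] = None  # None -> calibrated
    ddx6_median_shift_nt: float = -28.0  # calibration target for tau
    pabp_short_threshold: int = 50
    pabp_short_weight: float = 0.2  # sampling weight of tails below the threshold
    phasing_period: Optional[int] = None
    phasing_jitter_sd: float = 0.0
    tags_per_gene_range: tuple[int, int] = (100, 300)
    tail_occupancy_slope: float = 0.0  # nt of mean tail per log2 PABP occupancy

    # NanoString
    nanostring_scale_range: tuple[float, float] = (0.5, 2.0)
    nanostring_counts_per_unit: float = 30.0
    reference_genes: tuple[str, ...] = ("ACTB", "G6PD", "GAPDH", "RPL19")

    # stability
    halflife_intercept_log2: float = 4.0  # log2 hours at occupancy 1
    halflife_slope: float = 0.5  # log2 hours per log2 PABP occupancy
    halflife_noise_sd: float = 0.5
    te_slope: float = 0.2
    te_noise_sd: float = 0.5
    outlier_class_name: str = "MITO_RP_LIKE"
    outlier_fraction: float = 0.05
    outlier_offset_log2: float = -1.5  # destabilization despite high occupancy
    outlier_occ_boost_log2: float = 1.0
    outlier_tail_shift_nt: float = -30.0
    n_random_sets: int = 200
    random_set_size_range: tuple[int, int] = (25, 100)

    def __post_init__(self) -> None:
        if self.n_genes < len(self.reference_genes) + 10:
            raise ValueError("n_genes too small")
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must be in (0, 1)")
        if self.target_fraction * self.n_genes < 20:
            raise ValueError("target_fraction * n_genes must be >= 20")
        for name, rng_ in (
            ("transcript_length_range", self.transcript_length_range),
            ("utr_length_range", self.utr_length_range),
            ("tail_mu_range", self.tail_mu_range),
            ("tags_per_gene_range", self.tags_per_gene_range),
        ):
            lo, hi = rng_
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name}: {rng_}")
        if self.utr_length_range[0] < 8:
            raise ValueError("UTR too short to host a site")
        if self.utr_length_range[1] >= self.transcript_length_range[0]:
            raise ValueError("UTR range must fit inside the shortest transcript")

    @property
    def n_targets_per_mirna(self) -> int:
        return int(round(self.target_fraction * self.n_genes))

    @property
    def mirna_names(self) -> list[str]:
        return [name for name, _ in self.mirnas]


@dataclass
class GroundTruth:
    """Per-gene generative truth, retrievable by gene id."""

    genes: list[str]
    abundance: pd.Series  # linear FPKM-like
    occupancy: pd.DataFrame  # gene x protein, mock condition, linear
    efficacy: pd.DataFrame  # gene x miRNA targeting-efficacy multiplier (0 = non-target)
    targets: dict[str, list[str]]
    tail_mu: pd.Series  # intended mean of the total-mRNA tail distribution
    true_mean_tail: pd.DataFrame  # gene x sample, exact mean of the sampled pmf
    outlier_genes: list[str]
    insertions: dict[str, dict]  # gene -> {mirna, site_type, position}
    nanostring_scale: dict[str, dict[str, float]]  # protein -> sample -> factor
    ddx6_tau: float

    def total_effect_log2(self, mirna: str, effect: MirnaEffect) -> pd.Series:
        return effect.total_log2 * self.efficacy[mirna]

    def occupancy_effect_log2(self, mirna: str, protein: str, effect: MirnaEffect) -> pd.Series:
        return effect.occupancy_log2[protein] * self.efficacy[mirna]


@dataclass
class SimData:
    config: SimConfig
    catalog: pd.DataFrame  # gene_id, role, length, utr_start, utr_end
    sequences: dict[str, str]
    expression: pd.DataFrame  # tidy: gene_id, protein, condition, fraction, value
    nanostring: dict[str, pd.DataFrame]  # protein -> genes x "condition:fraction"
    tails: dict[str, pd.DataFrame]  # sample ("fraction_condition") -> gene_id, tail_length
    half_lives: pd.DataFrame  # gene_id, half_life_hours, translational_efficiency
    gene_sets: dict[str, list[str]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def _purge(
    seq: bytearray,
    forbidden: list[bytes],
    protected: tuple[int, int] | None,
    rng: np.random.Generator,
) -> None:
    """Mutate single bases until no forbidden substring remains.

    Bases inside the ``protected`` interval (an inserted site) are never
    touched.  Raises if a forbidden match lies entirely inside the protected
    interval or purging fails to converge.
    """
    for _ in range(10 * len(seq)):
        hit = None
        for f in forbidden:
            pos = seq.find(f)
            if pos != -1 and (hit is None or pos < hit[0]):
                hit = (pos, len(f))
        if hit is None:
            return
        pos, flen = hit
        candidates = [
            i
            for i in range(pos, pos + flen)
            if protected is None or not (protected[0] <= i < protected[1])
        ]
        if not candidates:
            raise ValueError("forbidden seed match inside a protected site insertion")
        i = candidates[len(candidates) // 2]
        old = seq[i]
        alternatives = [b for b in b"ACGT" if b != old]
        seq[i] = alternatives[int(rng.integers(0, 3))]
    raise RuntimeError("purge did not converge")


def generate_catalog(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, str], dict[str, list[str]], dict[str, dict]]:
    """Gene catalog with engineered target/control sequences.

    Targets of each miRNA receive one inserted 7/8-nt site for that miRNA in
    the 3' UTR and are scrubbed of 6-nt seed matches to the other miRNA
    anywhere in the transcript; control and reference genes are scrubbed of
    seed matches to both miRNAs, so the intended labels round-trip through
    sequence classification exactly.
    """
    n_ref = len(config.reference_genes)
    n_t = config.n_targets_per_mirna
    names = list(config.reference_genes) + [
        f"G{i:06d}" for i in range(config.n_genes - n_ref)
    ]
    roles = (
        ["reference"] * n_ref
        + [f"target:{config.mirna_names[0]}"] * n_t
        + [f"target:{config.mirna_names[1]}"] * n_t
        + ["control"] * (config.n_genes - n_ref - 2 * n_t)
    )
    mirna_objs = {name: Mirna(name, seq) for name, seq in config.mirnas}
    seeds6 = {
        name: site_strings(m)["6mer"].encode() for name, m in mirna_objs.items()
    }
    site_choices = ("8mer", "7mer-m8", "7mer-A1")

    sequences: dict[str, str] = {}
    rows = []
    targets: dict[str, list[str]] = {name: [] for name in config.mirna_names}
    insertions: dict[str, dict] = {}
    for gene, role in zip(names, roles):
        length = int(rng.integers(*config.transcript_length_range))
        utr_len = int(rng.integers(*config.utr_length_range))
        utr_start, utr_end = length - utr_len, length
        seq = _random_seq(rng, length)
        protected = None
        if role.startswith("target:"):
            mirna_name = role.split(":", 1)[1]
            other = [n for n in config.mirna_names if n != mirna_name]
            site_type = site_choices[int(rng.integers(0, 3))]
            site = site_strings(mirna_objs[mirna_name])[site_type].encode()
            if utr_end - utr_start < len(site):
                raise ValueError(f"{gene}: UTR too short to host a site")
            pos = int(rng.integers(utr_start, utr_end - len(site) + 1))
            seq[pos : pos + len(site)] = site
            protected = (pos, pos + len(site))
            _purge(seq, [seeds6[n] for n in other], protected, rng)
            targets[mirna_name].append(gene)
            insertions[gene] = {"mirna": mirna_name, "site_type": site_type, "position": pos}
        else:
            _purge(seq, list(seeds6.values()), None, rng)
        sequences[gene] = seq.decode()
        rows.append(
            {
                "gene_id": gene,
                "role": role,
                "length": length,
                "utr_start": utr_start,
                "utr_end": utr_end,
            }
        )
    catalog = pd.DataFrame(rows)
    return catalog, sequences, targets, insertions


# ---------------------------------------------------------------------------
# expression


def _truth_skeleton(
    config: SimConfig,
    catalog: pd.DataFrame,
    targets: dict[str, list[str]],
    insertions: dict[str, dict],
    rng: np.random.Generator,
) -> GroundTruth:
    genes = list(catalog["gene_id"])
    idx = pd.Index(genes, name="gene_id")
    mu, sigma = config.expression_mu_sigma
    log2_abund = rng.normal(mu, sigma, size=len(genes))
    is_ref = catalog["role"].eq("reference").to_numpy()
    log2_abund[is_ref] = rng.normal(mu + 3 * sigma, 0.1, size=is_ref.sum())
    abundance = pd.Series(2.0 ** log2_abund, index=idx)

    w = config.occupancy_latent_weight
    latent = rng.normal(size=len(genes))
    occ = {}
    for protein in config.proteins:
        indep = rng.normal(size=len(genes))
        occ[protein] = config.occupancy_sigma * (w * latent + np.sqrt(1 - w * w) * indep)
    occupancy = pd.DataFrame(occ, index=idx)

    # destabilized outlier class: high occupancy, short tails, low half-life
    eligible = [g for g in genes if g not in config.reference_genes]
    n_out = int(round(config.outlier_fraction * len(genes)))
    outliers = sorted(rng.choice(eligible, size=n_out, replace=False))
    occupancy.loc[outliers] += config.outlier_occ_boost_log2
    occupancy = 2.0 ** occupancy

    efficacy = pd.DataFrame(0.0, index=idx, columns=config.mirna_names)
    for name in config.mirna_names:
        efficacy.loc[targets[name], name] = rng.normal(
            1.0, config.efficacy_sd, size=len(targets[name])
        )

    lo, hi = config.tail_mu_range
    tail_mu = pd.Series(rng.uniform(lo, hi, size=len(genes)), index=idx)
    if config.tail_occupancy_slope:
        tail_mu = tail_mu + config.tail_occupancy_slope * np.log2(occupancy["PABP"])
    tail_mu.loc[outliers] = tail_mu.loc[outliers] + config.outlier_tail_shift_nt
    tail_mu = tail_mu.clip(lower=15.0)

    return GroundTruth(
        genes=genes,
        abundance=abundance,
        occupancy=occupancy,
        efficacy=efficacy,
        targets={k: sorted(v) for k, v in targets.items()},
        tail_mu=tail_mu,
        true_mean_tail=pd.DataFrame(index=idx),
        outlier_genes=list(outliers),
        insertions=insertions,
        nanostring_scale={},
        ddx6_tau=float("nan"),
    )


def generate_expression(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """RIP expression tables and NanoString count tables.

    Input abundance is log-normal; the IP value is input x true occupancy x
    noise.  Under a miRNA, each cognate target's input shifts by the injected
    total effect scaled by the gene's targeting efficacy, and its IP
    additionally by the protein-specific occupancy effect.  NanoString counts
    are Poisson draws of per-sample-scaled expected abundances restricted to
    the reference + target panel; reference genes are untargeted.
    """
    n = len(truth.genes)
    conditions = ["mock"] + list(config.mirna_names)
    noise_sd = config.expression_noise_sd

    rows = []
    expected: dict[tuple[str, str, str], np.ndarray] = {}
    for protein in config.proteins:
        occ = truth.occupancy[protein].to_numpy()
        for condition in conditions:
            if condition == "mock":
                total_fold = np.ones(n)
                occ_fold = np.ones(n)
            else:
                eff = config.mirna_effects[condition]
                e = truth.efficacy[condition].to_numpy()
                total_fold = 2.0 ** (eff.total_log2 * e)
                occ_fold = 2.0 ** (eff.occupancy_log2[protein] * e)
            base_input = truth.abundance.to_numpy() * total_fold
            base_ip = base_input * occ * occ_fold
            expected[(protein, condition, "input")] = base_input
            expected[(protein, condition, "IP")] = base_ip
            for fraction, base in (("input", base_input), ("IP", base_ip)):
                noise = 2.0 ** rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 1.0
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": truth.genes,
                            "protein": protein,
                            "condition": condition,
                            "fraction": fraction,
                            "value": base * noise,
                        }
                    )
                )
    expression = pd.concat(rows, ignore_index=True)

    panel = list(config.reference_genes) + sorted(
        g for glist in truth.targets.values() for g in glist
    )
    panel_idx = [truth.genes.index(g) for g in panel]
    nanostring: dict[str, pd.DataFrame] = {}
    lo, hi = config.nanostring_scale_range
    for protein in config.proteins:
        cols = {}
        scales = {}
        for condition in conditions:
            for fraction in ("input", "IP"):
                sample = f"{condition}:{fraction}"
                scale = float(rng.uniform(lo, hi))
                lam = (
                    expected[(protein, condition, fraction)][panel_idx]
                    * scale
                    * config.nanostring_counts_per_unit
                )
                cols[sample] = rng.poisson(lam)
                scales[sample] = scale
        nanostring[protein] = pd.DataFrame(cols, index=pd.Index(panel, name="gene_id"))
        truth.nanostring_scale[protein] = scales
    return expression, nanostring


# ---------------------------------------------------------------------------
# tails


def _discrete_gamma_pmf(mu: np.ndarray, shape: float, max_len: int) -> np.ndarray:
    """P(round(X) = L) for X ~ Gamma(shape, mu/shape), L = 0..max_len."""
    scale = np.asarray(mu, dtype=float)[:, None] / shape
    edges = np.arange(max_len + 1, dtype=float) + 0.5
    cdf = sps.gamma.cdf(edges[None, :], a=shape, scale=scale)
    pmf = np.diff(np.concatenate([np.zeros((len(scale), 1)), cdf], axis=1), axis=1)
    return pmf / pmf.sum(axis=1, keepdims=True)


def _apply_phasing(pmf: np.ndarray, period: int, jitter_sd: float, max_len: int) -> np.ndarray:
    """Snap the tail distribution to multiples of ``period`` and add jitter."""
    lengths = np.arange(max_len + 1)
    snapped_to = np.clip(np.round(lengths / period).astype(int) * period, 0, max_len)
    out = np.zeros_like(pmf)
    np.add.at(out.T, snapped_to, pmf.T)
    if jitter_sd > 0:
        half = int(np.ceil(4 * jitter_sd))
        offsets = np.arange(-half, half + 1)
        kernel = np.diff(sps.norm.cdf(np.concatenate([[-np.inf], offsets + 0.5]) , scale=jitter_sd))
        jittered = np.zeros_like(out)
        for off, wgt in zip(offsets, kernel):
            dest = np.clip(lengths + off, 0, max_len)
            np.add.at(jittered.T, dest, (out * wgt).T)
        out = jittered
    return out / out.sum(axis=1, keepdims=True)


def _tilt(pmf: np.ndarray, weights: np.ndarray) -> np.ndarray:
    tilted = pmf * weights[None, :]
    return tilted / tilted.sum(axis=1, keepdims=True)


def calibrate_ddx6_tau(
    config: SimConfig,
    target_shift: float | None = None,
    tail_mu: np.ndarray | None = None,
) -> float:
    """Solve for the exponential short-tail bias strength tau.

    Finds tau such that the across-gene *median* of the bound-minus-total
    mean-tail difference equals the target (default from the config, -28 nt).
    With ``tail_mu`` given (the realized per-gene tail means, as used inside
    :func:`generate`), the median is taken over those genes; otherwise a
    single pilot gene at the midpoint of the configured tail-mean range
    stands in (the per-gene shift is monotone in the gene mean, so the
    across-gene median tracks the median gene).
    """
    target = config.ddx6_median_shift_nt if target_shift is None else target_shift
    if target >= 0:
        raise ValueError("bias calibration target must be negative (short-tail bias)")
    if tail_mu is None:
        tail_mu = np.array([0.5 * (config.tail_mu_range[0] + config.tail_mu_range[1])])
    lengths = np.arange(config.tail_max + 1, dtype=float)
    pmf = _discrete_gamma_pmf(np.asarray(tail_mu, dtype=float), config.tail_shape, config.tail_max)
    base_means = pmf @ lengths

    def median_shift(tau: float) -> float:
        tilted = _tilt(pmf, np.exp(-lengths / tau))
        return float(np.median(tilted @ lengths - base_means))

    max_shift = median_shift(0.5)
    if target < max_shift:
        raise ValueError(f"target shift {target} nt exceeds attainable {max_shift:.1f} nt")
    return float(brentq(lambda t: median_shift(t) - target, 0.5, 1e7, xtol=1e-6))


def generate_tail_tags(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Tag-level tail tables for total, DDX6-bound and PABP-bound fractions.

    Per gene and sample, tag counts are drawn from ``tags_per_gene_range``
    and tail lengths from the gene's (possibly phased) discretized-gamma
    distribution, reweighted by exp(-L/tau) for DDX6-bound tags and by the
    short-tail down-weighting for PABP-bound tags.  Under a miRNA, site
    genes' DDX6-bound distributions are rebuilt from a mean shifted by the
    configured bound-tail effect.  Exact per-sample means enter the ground
    truth.
    """
    tau = config.bound_fraction_bias_tau
    if tau is None:
        tau = calibrate_ddx6_tau(config, tail_mu=truth.tail_mu.to_numpy())
    truth.ddx6_tau = float(tau)

    max_len = config.tail_max
    lengths = np.arange(max_len + 1, dtype=float)
    ddx6_w = np.exp(-lengths / tau)
    pabp_w = np.where(lengths < config.pabp_short_threshold, config.pabp_short_weight, 1.0)

    def build_pmf(mu: np.ndarray) -> np.ndarray:
        pmf = _discrete_gamma_pmf(mu, config.tail_shape, max_len)
        if config.phasing_period:
            pmf = _apply_phasing(pmf, config.phasing_period, config.phasing_jitter_sd, max_len)
        return pmf

    mu = truth.tail_mu.to_numpy()
    base_pmf = build_pmf(mu)

    def bound_mean(m: np.ndarray) -> np.ndarray:
        return _tilt(build_pmf(m), ddx6_w) @ lengths

    def solve_bound_shift(mu_sub: np.ndarray, shift: float) -> np.ndarray:
        """Pre-bias means whose *bound-fraction* mean moves by ``shift`` nt.

        The exponential short-tail bias attenuates a shift of the underlying
        mean, so the configured bound-tail effect is imposed on the tilted
        distribution directly via a few Newton steps (skipped under phasing,
        where means are quantized and the raw shift is applied instead).
        """
        if config.phasing_period:
            return np.clip(mu_sub + shift, 5.0, None)
        target = bound_mean(mu_sub) + shift
        x = np.clip(mu_sub + shift, 5.0, None)
        for _ in range(4):
            fx = bound_mean(x)
            dfx = bound_mean(x + 0.5) - bound_mean(x - 0.5)
            x = np.clip(x - (fx - target) / dfx, 5.0, None)
        return x
    conditions = ["mock"] + list(config.mirna_names)
    genes = truth.genes
    genes_arr = np.asarray(genes, dtype=object)
    n = len(genes)
    lo, hi = config.tags_per_gene_range
    samples: dict[str, pd.DataFrame] = {}
    for condition in conditions:
        pmfs = {"total": base_pmf, "PABP": _tilt(base_pmf, pabp_w)}
        ddx6_pmf = _tilt(base_pmf, ddx6_w)
        if condition != "mock":
            eff = config.mirna_effects[condition]
            site_mask = (truth.efficacy[condition] != 0).to_numpy()
            if site_mask.any() and eff.bound_tail_shift_nt:
                mu_shifted = solve_bound_shift(mu[site_mask], eff.bound_tail_shift_nt)
                ddx6_pmf = ddx6_pmf.copy()
                ddx6_pmf[site_mask] = _tilt(build_pmf(mu_shifted), ddx6_w)
        pmfs["DDX6"] = ddx6_pmf
        for fraction, pmf in pmfs.items():
            sample = f"{fraction}_{condition}"
            truth.true_mean_tail[sample] = pmf @ lengths
            n_tags = rng.integers(lo, hi + 1, size=n)
            gene_col = []
            length_col = []
            for i in range(n):
                counts = rng.multinomial(n_tags[i], pmf[i])
                tl = np.repeat(np.arange(max_len + 1), counts)
                gene_col.append(np.full(tl.size, i))
                length_col.append(tl)
            samples[sample] = pd.DataFrame(
                {
                    "gene_id": genes_arr[np.concatenate(gene_col)],
                    "tail_length": np.concatenate(length_col).astype(int),
                }
            )
    return samples


# ---------------------------------------------------------------------------
# stability


def generate_halflives(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Half-life and translational-efficiency tables coupled to PABP occupancy.

    log2 half-life = intercept + slope * log2(true PABP occupancy) + noise;
    outlier-class genes receive the configured negative offset (destabilized
    despite high occupancy).  TE follows the same form with its own slope.
    """
    log2_occ = np.log2(truth.occupancy["PABP"].to_numpy())
    noise = rng.normal(0.0, config.halflife_noise_sd, size=len(truth.genes))
    log2_hl = config.halflife_intercept_log2 + config.halflife_slope * log2_occ + noise
    out_mask = pd.Index(truth.genes).isin(truth.outlier_genes)
    log2_hl[out_mask] += config.outlier_offset_log2
    te = config.te_slope * log2_occ + rng.normal(0.0, config.te_noise_sd, size=len(truth.genes))
    return pd.DataFrame(
        {
            "gene_id": truth.genes,
            "half_life_hours": 2.0 ** log2_hl,
            "translational_efficiency": 2.0 ** te,
        }
    )


def generate_gene_sets(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, list[str]]:
    """The outlier class plus seeded random sets for enrichment nulls."""
    sets = {config.outlier_class_name: list(truth.outlier_genes)}
    lo, hi = config.random_set_size_range
    hi = min(hi, len(truth.genes) // 2)
    lo = min(lo, hi)
    for i in range(config.n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"RANDOM_{i:03d}"] = sorted(rng.choice(truth.genes, size=size, replace=False))
    return sets


def generate(config: SimConfig) -> SimData:
    """Run the full generator under the config's seed."""
    rng = np.random.default_rng(config.seed)
    catalog, sequences, targets, insertions = generate_catalog(config, rng)
    truth = _truth_skeleton(config, catalog, targets, insertions, rng)
    expression, nanostring = generate_expression(config, truth, rng)
    tails = generate_tail_tags(config, truth, rng)
    half_lives = generate_halflives(config, truth, rng)
    gene_sets = generate_gene_sets(config, truth, rng)
    return SimData(
        config=config,
        catalog=catalog,
        sequences=sequences,
        expression=expression,
        nanostring=nanostring,
        tails=tails,
        half_lives=half_lives,
        gene_sets=gene_sets,
        truth=truth,
    )


def truth_to_jsonable(truth: GroundTruth) -> dict:
    """Ground-truth dump for the JSON sidecar."""
    return {
        "genes": truth.genes,
        "abundance": truth.abundance.round(6).to_dict(),
        "occupancy": {p: truth.occupancy[p].round(6).to_dict() for p in truth.occupancy},
        "efficacy": {m: truth.efficacy[m].round(6).to_dict() for m in truth.efficacy},
        "targets": truth.targets,
        "tail_mu": truth.tail_mu.round(6).to_dict(),
        "true_mean_tail": {s: truth.true_mean_tail[s].round(6).to_dict() for s in truth.true_mean_tail},
        "outlier_genes": truth.outlier_genes,
        "insertions": truth.insertions,
        "nanostring_scale": truth.nanostring_scale,
        "ddx6_tau": truth.ddx6_tau,
    }
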