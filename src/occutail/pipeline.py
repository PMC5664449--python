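"""End-to-end pipeline: simulate -> classify -> occupancy -> effects -> tails
-> phasing -> stability, with a reproducibility manifest.

Each stage reads the interchange files written by its predecessors inside the
output directory (so stages can be re-run or skipped) and writes its own
outputs there.  All randomness flows from the seeds recorded in the manifest;
re-running with the same configuration produces a byte-identical output tree.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as oio
from . import __version__
from .effects import cdf_coordinates, cdf_effect, effect_report, fold_changes
from .occupancy import filter_expressed, occupancy_table
from .simulate import SimConfig, generate, truth_to_jsonable
from .sites import Mirna, build_target_sets, classify_catalog
from .stability import class_contrast, correlate_features, enrich_extremes, residual_scan
from .tails import (
    detect_phasing_peaks,
    mean_tails,
    metagene_distribution,
    phasing_profile,
    site_tail_change,
    tail_diff,
    window_depletion,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "classify-sites",
    "occupancy",
    "mirna-effects",
    "tails",
    "phasing",
    "stability",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, parameters and mode flags for a pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig | None = None  # built from seed when the simulate stage runs
    min_tags: int = 100
    footprint: int = 26
    metagene_bin_width: int = 1
    extreme_quantile: float = 0.1
    phasing_n_genes: int = 100
    phasing_max_diff: int = 60
    phasing_sample: str = "total_mock"
    stability_protein: str = "PABP"
    mock_condition: str = "mock"
    short_tail_window: tuple[float, float] = (0.0, 50.0)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d


def _input_path(out_dir: Path, name: str, stage: str) -> Path:
    p = out_dir / "inputs" / name
    if not p.exists():
        raise PipelineError(stage, f"missing input file {p}")
    return p


def _write_sim_inputs(sim, out_dir: Path) -> list[str]:
    inputs = out_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    oio.write_fasta(sim.sequences, inputs / "transcripts.fasta")
    oio.write_intervals(
        {r.gene_id: (r.utr_start, r.utr_end) for r in sim.catalog.itertuples(index=False)},
        inputs / "utr_intervals.tsv",
    )
    oio.write_tsv(
        pd.DataFrame(sim.config.mirnas, columns=["name", "sequence"]), inputs / "mirnas.tsv"
    )
    oio.write_tsv(sim.expression, inputs / "expression.tsv")
    for protein, table in sorted(sim.nanostring.items()):
        oio.write_tsv(table.reset_index(), inputs / f"nanostring_{protein}.tsv")
    tail_frames = [
        df.assign(sample=sample)[["gene_id", "sample", "tail_length"]]
        for sample, df in sorted(sim.tails.items())
    ]
    oio.write_tsv(pd.concat(tail_frames, ignore_index=True), inputs / "tail_tags.tsv")
    oio.write_tsv(sim.half_lives, inputs / "half_lives.tsv")
    oio.write_gmt(sim.gene_sets, inputs / "gene_sets.gmt")
    oio.write_json(truth_to_jsonable(sim.truth), inputs / "ground_truth.json")
    return sorted(p.name for p in inputs.iterdir())


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "occutail",
        "version": __version__,
        "config": config.to_jsonable(),
        "stages": {},
        "input_checksums": {},
    }

    if "simulate" in config.stages:
        sim_config = config.sim if config.sim is not None else SimConfig(seed=config.seed)
        manifest["config"]["sim"] = dataclasses.asdict(sim_config)
        sim = generate(sim_config)
        names = _write_sim_inputs(sim, out_dir)
        manifest["stages"]["simulate"] = {
            "n_genes": int(len(sim.catalog)),
            "files": names,
        }
        log.info("simulate: wrote %d input files for %d genes", len(names), len(sim.catalog))

    inputs = out_dir / "inputs"
    if inputs.exists():
        manifest["input_checksums"] = {
            p.name: oio.sha256_of(p) for p in sorted(inputs.iterdir())
        }

    if "classify-sites" in config.stages:
        _stage_classify(config, out_dir, manifest)
    if "occupancy" in config.stages:
        _stage_occupancy(config, out_dir, manifest)
    if "mirna-effects" in config.stages:
        _stage_effects(config, out_dir, manifest)
    if "tails" in config.stages:
        _stage_tails(config, out_dir, manifest)
    if "phasing" in config.stages:
        _stage_phasing(config, out_dir, manifest)
    if "stability" in config.stages:
        _stage_stability(config, out_dir, manifest)

    oio.write_json(manifest, out_dir / "manifest.json")
    return manifest


def _load_mirnas(out_dir: Path, stage: str) -> list[Mirna]:
    df = oio.read_tsv(_input_path(out_dir, "mirnas.tsv", stage))
    return [Mirna(r.name, r.sequence) for r in df.itertuples(index=False)]


def _stage_classify(config: RunConfig, out_dir: Path, manifest: dict) -> None:
    stage = "classify-sites"
    catalog = oio.read_fasta_with_intervals(
        _input_path(out_dir, "transcripts.fasta", stage),
        _input_path(out_dir, "utr_intervals.tsv", stage),
    )
    mirnas = _load_mirnas(out_dir, stage)
    usable = {g: s for g, s in catalog.sequences.items() if g not in set(catalog.unusable)}
    tables = []
    for mirna in mirnas:
        tables.append(classify_catalog(usable, catalog.utr_intervals, mirna))
    classifications = pd.concat(tables, ignore_index=True)
    oio.write_tsv(classifications, out_dir / "site_classification.tsv")
    if len(mirnas) == 2:
        sets = build_target_sets(tables[0], tables[1])
        oio.write_json({"targets": sets.targets, "controls": sets.controls}, out_dir / "target_sets.json")
        counts = {m: len(g) for m, g in sets.targets.items()}
    else:
        counts = {}
    manifest["stages"][stage] = {
        "n_genes": int(classifications["gene_id"].nunique()),
        "n_unusable": len(catalog.unusable),
        "n_targets": counts,
    }
    log.info("%s: %d genes classified", stage, classifications["gene_id"].nunique())


def _stage_occupancy(config: RunConfig, out_dir: Path, manifest: dict) -> None:
    stage = "occupancy"
    expr = oio.read_tsv(_input_path(out_dir, "expression.tsv", stage))
    n_conditions = expr["condition"].nunique()
    mode = "mirna_experiment" if n_conditions > 1 else "plain"
    try:
        occ = occupancy_table(expr, mode=mode, mock_condition=config.mock_condition)
    except (KeyError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc
    oio.write_tsv(occ, out_dir / "occupancy.tsv")
    counts = (
        occ.groupby(["protein", "condition"])["gene_id"].size().rename("n").reset_index()
    )
    manifest["stages"][stage] = {
        "mode": mode,
        "n_retained": {f"{r.protein}:{r.condition}": int(r.n) for r in counts.itertuples(index=False)},
    }


def _stage_effects(config: RunConfig, out_dir: Path, manifest: dict) -> None:
    stage = "mirna-effects"
    expr = oio.read_tsv(_input_path(out_dir, "expression.tsv", stage))
    sets = oio.read_json(out_dir / "target_sets.json")
    mirnas = [m.name for m in _load_mirnas(out_dir, stage)]
    conditions = set(expr["condition"].unique()) - {config.mock_condition}
    summaries = []
    fc_frames = []
    cdf_frames = []
    for protein in sorted(expr["protein"].unique()):
        retained = filter_expressed(
            expr, protein, mode="mirna_experiment", condition=config.mock_condition
        )
        for mirna in mirnas:
            if mirna not in conditions:
                raise PipelineError(stage, f"no libraries for condition {mirna!r}")
            fcs = fold_changes(expr, protein, mirna, config.mock_condition, genes=retained)
            fc_frames.append(
                fcs.reset_index().assign(protein=protein, mirna=mirna)
            )
            targets = sets["targets"][mirna]
            controls = sets["controls"][mirna]
            for quantity in ("total", "ip", "occupancy"):
                summaries.append(
                    cdf_effect(fcs, targets, controls, quantity, mirna=mirna, protein=protein)
                )
                coords = cdf_coordinates(
                    fcs, {"target": targets, "no_site": controls}, quantity
                )
                cdf_frames.append(coords.assign(protein=protein, mirna=mirna, quantity=quantity))
    report = effect_report(summaries)
    oio.write_tsv(report, out_dir / "effects.tsv")
    oio.write_json(report.to_dict(orient="records"), out_dir / "effects.json")
    oio.write_tsv(pd.concat(fc_frames, ignore_index=True), out_dir / "fold_changes.tsv")
    oio.write_tsv(pd.concat(cdf_frames, ignore_index=True), out_dir / "cdf_coordinates.tsv")
    manifest["stages"][stage] = {"n_summaries": len(summaries)}


def _read_tail_sample(out_dir: Path, sample: str, stage: str) -> pd.DataFrame:
    tags = oio.read_tsv(_input_path(out_dir, "tail_tags.tsv", stage))
    sub = tags[tags["sample"] == sample]
    if sub.empty:
        raise PipelineError(stage, f"no tags for sample {sample!r} in tail_tags.tsv")
    return sub[["gene_id", "tail_length"]]


def _stage_tails(config: RunConfig, out_dir: Path, manifest: dict) -> None:
    stage = "tails"
    tags = oio.read_tsv(_input_path(out_dir, "tail_tags.tsv", stage))
    samples = sorted(tags["sample"].unique())
    stats: dict[str, pd.DataFrame] = {}
    stat_frames = []
    excluded_counts = {}
    for sample in samples:
        sub = tags.loc[tags["sample"] == sample, ["gene_id", "tail_length"]]
        s, excluded = mean_tails(sub, min_tags=config.min_tags)
        stats[sample] = s
        excluded_counts[sample] = int(len(excluded))
        stat_frames.append(s.assign(sample=sample))
    oio.write_tsv(pd.concat(stat_frames, ignore_index=True), out_dir / "tail_stats.tsv")

    mock = config.mock_condition
    summaries = {}
    diff_frames = []
    for fraction in ("DDX6", "PABP"):
        bound_name = f"{fraction}_{mock}"
        total_name = f"total_{mock}"
        if bound_name in stats and total_name in stats:
            per_gene, summary = tail_diff(stats[bound_name], stats[total_name])
            diff_frames.append(per_gene.assign(comparison=f"{bound_name}_vs_{total_name}"))
            summaries[f"{bound_name}_vs_{total_name}"] = summary
    if diff_frames:
        oio.write_tsv(pd.concat(diff_frames, ignore_index=True), out_dir / "tail_diff.tsv")

    meta_frames = []
    for sample in samples:
        sub = tags.loc[tags["sample"] == sample, ["gene_id", "tail_length"]]
        hist = metagene_distribution(
            sub, bin_width=config.metagene_bin_width, min_tags=config.min_tags
        )
        meta_frames.append(hist.assign(sample=sample))
    oio.write_tsv(pd.concat(meta_frames, ignore_index=True), out_dir / "metagene.tsv")

    if f"PABP_{mock}" in samples and f"total_{mock}" in samples:
        summaries["short_tail_depletion_PABP"] = window_depletion(
            tags.loc[tags["sample"] == f"PABP_{mock}", ["gene_id", "tail_length"]],
            tags.loc[tags["sample"] == f"total_{mock}", ["gene_id", "tail_length"]],
            window=config.short_tail_window,
            min_tags=config.min_tags,
        )

    classifications_path = out_dir / "site_classification.tsv"
    if classifications_path.exists():
        cls = oio.read_tsv(classifications_path)
        for mirna in sorted(cls["mirna"].unique()):
            bound_mock, bound_mirna = f"DDX6_{mock}", f"DDX6_{mirna}"
            if bound_mock not in stats or bound_mirna not in stats:
                continue
            sub = cls[cls["mirna"] == mirna]
            site = list(sub.loc[sub["label"] == "site", "gene_id"])
            no_site = list(sub.loc[sub["label"] == "no_site", "gene_id"])
            summaries[f"site_tail_change_DDX6_{mirna}"] = site_tail_change(
                stats[bound_mock], stats[bound_mirna], site, no_site
            )
    oio.write_json(summaries, out_dir / "tail_summaries.json")
    manifest["stages"][stage] = {
        "samples": samples,
        "n_eligible": {s: int(len(stats[s])) for s in samples},
        "n_excluded": excluded_counts,
    }


def _stage_phasing(config: RunConfig, out_dir: Path, manifest: dict) -> None:
    stage = "phasing"
    sub = _read_tail_sample(out_dir, config.phasing_sample, stage)
    try:
        profile = phasing_profile(
            sub,
            n_genes=config.phasing_n_genes,
            seed=config.seed,
            max_diff=config.phasing_max_diff,
            min_tags=config.min_tags,
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    oio.write_tsv(profile, out_dir / "phasing.tsv")
    peaks = detect_phasing_peaks(profile)
    oio.write_json({"sample": config.phasing_sample, "peaks": peaks}, out_dir / "phasing_peaks.json")
    manifest["stages"][stage] = {"n_genes": config.phasing_n_genes, "n_peaks": len(peaks)}


def _stage_stability(config: RunConfig, out_dir: Path, manifest: dict) -> None:
    stage = "stability"
    occ = oio.read_tsv(out_dir / "occupancy.tsv")
    hl = oio.read_tsv(_input_path(out_dir, "half_lives.tsv", stage))
    tail_stats = oio.read_tsv(out_dir / "tail_stats.tsv")
    gene_sets = oio.read_gmt(_input_path(out_dir, "gene_sets.gmt", stage))

    mock = config.mock_condition
    protein = config.stability_protein
    occ_mock = occ[(occ["protein"] == protein) & (occ["condition"] == mock)]
    if occ_mock.empty:
        raise PipelineError(stage, f"no occupancy values for ({protein}, {mock})")
    occ_series = occ_mock.set_index("gene_id")["occupancy"]
    hl_series = hl.set_index("gene_id")["half_life_hours"]

    features: dict[str, pd.Series] = {"half_life": hl_series}
    if "translational_efficiency" in hl.columns:
        features["TE"] = hl.set_index("gene_id")["translational_efficiency"]
    total_tail = tail_stats[tail_stats["sample"] == f"total_{mock}"]
    if not total_tail.empty:
        features["mean_tail"] = total_tail.set_index("gene_id")["mean_tail"]
    for p in sorted(occ["protein"].unique()):
        s = occ[(occ["protein"] == p) & (occ["condition"] == mock)]
        features[f"{p}_occupancy"] = s.set_index("gene_id")["occupancy"]
    correlations = correlate_features(features)
    oio.write_tsv(correlations, out_dir / "correlations.tsv")

    try:
        records = residual_scan(occ_series, hl_series, extreme_quantile=config.extreme_quantile)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    oio.write_tsv(records, out_dir / "residuals.tsv")
    for direction in ("low_tail", "high_tail"):
        enr = enrich_extremes(records, gene_sets, direction=direction)
        oio.write_tsv(enr, out_dir / f"enrichment_{direction}.tsv")

    contrast_features = {
        k: features[k]
        for k in (f"{protein}_occupancy", "half_life", "mean_tail")
        if k in features
    }
    named_sets = {k: v for k, v in gene_sets.items() if not k.startswith("RANDOM_")}
    if named_sets:
        contrast = class_contrast(contrast_features, named_sets)
        oio.write_tsv(contrast, out_dir / "class_contrast.tsv")
    manifest["stages"][stage] = {
        "n_records": int(len(records)),
        "n_gene_sets": len(gene_sets),
    }
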