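# occutail

Analytics for mRNP (mRNA–protein complex) composition: RIP-seq relative
occupancy, miRNA seed-site target classification, poly(A)-tail length
distributions, and occupancy–stability residual scanning — with a seeded
synthetic-data generator that makes every analysis testable against known
ground truth.

## The problem

RNA immunoprecipitation (RIP) followed by sequencing or NanoString counting
measures which mRNAs co-purify with a protein of interest (AGO2, eIF4E,
eIF4G, PABP, DDX6, ...).  Interpreting such data requires a stack of small,
easy-to-get-wrong computations:

* **Relative occupancy.**  For each gene, occupancy = IP abundance / input
  abundance, median-centered across retained genes so the typical gene is 1.
  Genes are retained when expression exceeds 1 in both input and IP (in
  miRNA-transfection experiments: in the mock libraries, with non-zero values
  everywhere else).
* **Seed-site classification.**  A transcript is a *site* gene for a miRNA
  when its 3′ UTR carries a 7- or 8-nt seed match (8mer, 7mer-m8 or 7mer-A1 —
  reverse complements of miRNA nt 2–8 / 2–7, with or without a trailing A);
  it is a *no-site* control when the whole transcript carries no 7/8-nt site
  and the 3′ UTR no 6mer.
* **miRNA-attributable effects.**  The per-gene log2 fold change (miRNA vs
  mock) of total mRNA, IP mRNA, and inferred occupancy (IP change − total
  change); the attributable effect is median(site genes) − median(no-site
  genes), with a two-tailed Kolmogorov–Smirnov test between the two change
  distributions.
* **Tail-length analytics.**  Tag-level poly(A)-tail measurements (one
  integer length per tag) support per-gene means (≥ 100-tag filter),
  bound-vs-total differences, metagene distributions (per-gene-normalized
  histograms averaged with equal gene weight), phasing profiles (normalized
  frequencies of all pairwise within-gene tail-length differences — a
  footprint-protected tail population would show peaks at multiples of the
  ~26-nt PABP footprint), and occupancy binned by mean tail in
  footprint-sized bins.
* **Stability residuals.**  Log2 half-life regressed on log2 occupancy;
  genes in the residual extremes (less/more stable than predicted) are
  tested for gene-set enrichment (hypergeometric + Benjamini–Hochberg
  against user-supplied GMT collections).

All of this is implemented as a library (`occutail.core_stats`, `.sites`,
`.occupancy`, `.effects`, `.tails`, `.stability`), a generator
(`occutail.simulate`), and a reproducible pipeline with a CLI
(`occutail run-all`).

## The synthetic-data generator

`occutail.simulate.SimConfig` / `generate` produce every input the pipeline
consumes — transcript FASTA with engineered seed sites, expression tables
with gene-specific true occupancies and injected miRNA effects, NanoString
counts with per-sample scale factors and four abundant reference genes
(*ACTB*, *G6PD*, *GAPDH*, *RPL19*), tag-level tail tables with calibrated
bound-fraction biases, and half-lives coupled to PABP occupancy with a
destabilized outlier class — together with the full ground truth.  Fixed
seeds give byte-identical outputs, so parameter-recovery tests close the
loop.  See `docs/methods.md` for the model and every default.

## Worked example

```python
from occutail.simulate import SimConfig, generate
from occutail.occupancy import filter_expressed
from occutail.effects import cdf_effect, fold_changes
from occutail.tails import mean_tails, tail_diff

sim = generate(SimConfig(n_genes=600, seed=4, target_fraction=0.1, n_random_sets=20))

targets = sim.truth.targets["miR-124"]
controls = list(sim.catalog.loc[sim.catalog["role"] == "control", "gene_id"])
for protein in ("AGO2", "PABP", "eIF4E"):
    retained = filter_expressed(sim.expression, protein, mode="mirna_experiment")
    fcs = fold_changes(sim.expression, protein, "miR-124", genes=retained)
    s = cdf_effect(fcs, targets, controls, "occupancy", mirna="miR-124", protein=protein)
    print(f"{protein:6s} occupancy change: {s.attributable_median_log2:+.3f} log2 "
          f"({s.percent_change:+.1f}%), K-S p = {s.ks_p:.2g}")

bound, _ = mean_tails(sim.tails["DDX6_mock"], min_tags=100)
total, _ = mean_tails(sim.tails["total_mock"], min_tags=100)
_, summary = tail_diff(bound, total)
print(f"DDX6-bound vs total tails: median {summary['median']:+.1f} nt, "
      f"{summary['fraction_shorter']:.0%} of genes shorter")
```

prints

```
AGO2   occupancy change: +1.627 log2 (+208.8%), K-S p = 0
PABP   occupancy change: -0.186 log2 (-12.1%), K-S p = 2.3e-55
eIF4E  occupancy change: -0.006 log2 (-0.4%), K-S p = 0.89
DDX6-bound vs total tails: median -27.6 nt, 100% of genes shorter
```

The generator injected an AGO2 occupancy gain of +1.66 log2, a PABP loss of
−0.18 log2 (−11.7%), no eIF4E effect, and a DDX6 short-tail bias calibrated
to a −28 nt median bound-vs-total difference; the analysis recovers each
within sampling error, and the null (eIF4E) stays non-significant.

The same run end-to-end from a shell:

```bash
occutail run-all --seed 4 --out-dir runs/demo
```

writes the generated inputs plus `occupancy.tsv`, `effects.tsv`,
`tail_stats.tsv`, `tail_diff.tsv`, `metagene.tsv`, `phasing.tsv`,
`residuals.tsv`, `enrichment_*.tsv` and a `manifest.json` recording the
config, seeds, input checksums and per-stage gene counts.

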