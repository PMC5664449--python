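# Methods

This note documents the models behind `occutail`, the defaults of the
synthetic-data generator, and the numerical and design choices that were
genuinely open.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Relative occupancy

For protein *P*, condition *c* and gene *g*,

    occ(g) = IP(g) / input(g),   occ(g) <- occ(g) / median_g' occ(g')

with the median taken over the retained genes of that (protein, condition)
pair, so the post-centering median is exactly 1.  Retention: expression > 1
in both input and IP ("plain" mode); for miRNA-transfection designs, > 1 in
the mock input and mock IP and > 0 in every other library of the protein
("mirna_experiment" mode).  Centering is per (protein, condition); whether
the original analyses centered per library or jointly across conditions is
not derivable from the outputs we emulate, so per-pair centering is adopted
and exposed as the only mode.  Occupancies are relative: they order genes
within a library pair but carry no absolute stoichiometry.

NanoString counts are normalized by reference-gene geometric means: the
per-sample factor is (across-sample average of reference geometric means) /
(sample's reference geometric mean), which equalizes reference geometric
means across samples.  This is a deliberately simple stand-in for a
proprietary normalization pipeline whose exact recipe (positive controls,
background subtraction) is not public; it is exact for pure per-sample
scaling, which is what the generator injects.

## Seed-site classification

Site strings are built from the miRNA seed (nt 2–7) and extended seed
(nt 2–8): 8mer = rc(2–8)+A, 7mer-m8 = rc(2–8), 7mer-A1 = rc(2–7)+A, 6mer =
rc(2–7), all as sense-strand DNA.  "7mer site" covers both 7-nt variants;
the 6mer is the canonical nt 2–7 match only (no offset-6mer).  Matching is
exact substring search; `N` never matches; coordinates are 0-based
half-open; a site counts as "in the 3′ UTR" only when fully inside the
annotated interval.  Scanning reports each locus once under its most
specific type (8mer > 7mer-m8 = 7mer-A1 > 6mer).  Gene labels: *site* = at
least one 7/8-nt site in the UTR; *no_site* = no 7/8-nt site anywhere in the
transcript and no 6mer in the UTR (the transcript-wide exclusion is applied
to all annotated sequence); everything else *excluded*.  Cross-controlled
target sets for a miRNA pair: targets of A = site-for-A AND no-site-for-B,
controls of A = all no-site-for-A genes.

## miRNA-attributable effects

Per-gene log2 fold changes (treated vs mock) are computed separately for
input (total) and IP values — the IP change from raw, non-input-normalized
values — and the occupancy change is their difference, so
occupancy ≡ ip − total holds exactly by construction.  The attributable
effect for a quantity is median(targets) − median(controls), which cancels
any global normalization shift; percent conversions use
(2^median − 1)·100, i.e. the percent form of the median log2 change, not
the median of per-gene percent changes.  Significance is the two-tailed
two-sample Kolmogorov–Smirnov test between target and control change
distributions (asymptotic p by default; exact enumeration available for
small samples), annotated with the conventional star thresholds 0.05, 0.01
and 0.0001.

## Tail-length analytics

Tail data are one integer length (nt) per sequenced tag.  Per-gene means
require ≥ 100 tags (`min_tags`, configurable); excluded genes are reported.
Bound-vs-total comparisons pair genes across samples and summarize the
differences with median, quartiles and Tukey 1.5·IQR whiskers, the fraction
of genes shorter in the bound fraction, a Spearman correlation of bound vs
total means, and a Wilcoxon signed-rank p ("paired Mann–Whitney" has no
standard definition; the signed-rank test on per-gene differences is the
standard paired analogue and is what `mann_whitney_u(paired=True)` runs).

Metagene distributions average per-gene-normalized histograms with equal
gene weight, so deeply sequenced genes do not dominate; tag weighting is
available as an option.  Window-depletion comparisons (e.g. fraction of
tails < 50 nt, bound vs total) are paired signed-rank tests across genes.

Phasing profiles enumerate all C(n,2) unordered distinct tag pairs per gene
and record the normalized frequency of each absolute integer difference
(ties contribute difference 0), computed via autocorrelation of the
tail-length count vector and verified against a double-loop oracle.
Absolute (unsigned) differences are used, matching a non-negative difference
axis.  Genes are sampled without replacement (seeded) among those passing
the tag filter.  Peak detection flags differences exceeding 1.5× the mean of
their ±5-nt neighborhood; differences below the neighborhood half-width are
not scored, because the zero-difference cluster — pairs of tags sampling the
same underlying tail state, broadened by any jitter — is intrinsically
elevated and carries no footprint information, while any footprint of
interest (26 nt for PABP) lies far outside it.

Occupancy-by-tail binning uses edges 0, 25, 50, 75, ... (one additional
26-nt-footprint protein per bin), with per-bin box summaries, pairwise
Mann–Whitney comparisons and an overall Spearman correlation.

## Stability residuals and enrichment

Log2 half-life is regressed on log2 occupancy by ordinary least squares
(a rank-based fit is exposed as an option; the trend form is not derivable
from the emulated outputs, and OLS on the log–log scale is the simplest
monotone choice).  The lowest and highest `extreme_quantile` (default 10%)
of residuals are the *low_tail* (less stable than predicted) and *high_tail*
(more stable than predicted) extremes; both contain exactly floor(q·n)
genes, with boundary ties broken by gene id for determinism.  Enrichment of
a gene set within an extreme is the upper-tail hypergeometric p of the
overlap, with the background equal to all genes entering the residual scan
(not the genome), Benjamini–Hochberg correction across sets, and a reporting
flag at q < 0.001.

Because the hypergeometric test is discrete, its conservative upper-tail p
cannot be uniform under the null (its CDF steps below the diagonal between
achievable values).  Null-calibration checks therefore use Lancaster's
mid-p (`mode="mid"`: P(X > k) + ½P(X = k)), which is uniform to within half
an atom; inference always uses the conservative p.

## The synthetic-data generator

The generator emulates the statistical structure of a
RIP/NanoString/tail-profiling study in a miRNA-transfected human cell line.
Defaults define the study conditions used by the closed-loop tests:

* **Scale.** 2,200 genes; per-miRNA target fraction 0.0432 (≈ 95 targets
  each for miR-124 and miR-155, leaving ≈ 2,000 no-site controls) —
  matching a 95/94-target NanoString panel design with four abundant
  reference genes.
* **Sequences.** Random-composition transcripts of 1,500–2,500 nt with
  200–800-nt 3′ UTRs.  Each target receives one inserted 7/8-nt site for
  its miRNA at a random UTR position and is scrubbed (single-base
  mutations) of 6-nt seed matches to the other miRNA anywhere in the
  transcript; controls and reference genes are scrubbed of matches to both.
  Because every 7/8-nt site contains the 6mer, scrubbing 6mers removes all
  site variants, so the intended labels round-trip through classification
  exactly.
* **Expression.** log2 abundance ~ N(5, 2) (FPKM-like units); reference
  genes at mean +3σ.  True log2 occupancy per protein = 1.0 × (0.7·latent +
  √(1−0.7²)·independent), giving the correlated occupancies expected of
  co-binding core factors.  IP value = input × occupancy × noise.
* **miRNA effects.** Each cognate target gets a targeting-efficacy
  multiplier e_g ~ N(1, 0.08) shared across quantities; injected medians
  (log2) follow the magnitudes reported for miR-124/miR-155 transfections:
  total −0.80/−0.52; occupancy AGO2 +1.66/+1.14, eIF4G −0.109/−0.080, PABP
  −0.180/−0.127, eIF4E 0, DDX6 +0.516/+0.345.  Scaling the whole effect by
  e_g (rather than adding independent per-quantity noise) makes a zero
  injected effect an exact null — required for the eIF4E non-significance
  check — and models the biological coupling of repression strength across
  readouts.  Per-library log2 measurement noise sd is 0.03, sized so the
  median-recovery band of ±0.05 at 95 targets corresponds to ≈ 2.7 standard
  errors.
* **Tails.** Per-gene mean tail ~ U(30, 150) nt; tag lengths are a
  discretized gamma with shape 8 (CV ≈ 0.35) — the true per-gene
  distribution shape is not identifiable from the emulated outputs, and a
  positive right-skewed law matching metagene shapes qualitatively is the
  modeling convenience adopted.  DDX6-bound tags are reweighted by
  exp(−L/τ); τ is solved numerically so the across-gene median bound−total
  mean difference equals −28 nt under the realized gene means (τ ≈ 23 at
  defaults).  PABP-bound tags down-weight lengths < 50 nt by 0.2 (median
  shift ≈ +3 nt).  Under a miRNA, site genes' DDX6-bound means shift by −4
  nt, imposed on the *tilted* distribution via Newton inversion so the
  injected bound-fraction effect is exact.  Optional phasing snaps tails to
  multiples of a period plus discrete Gaussian jitter.  100–300 tags per
  gene per sample.
* **NanoString.** Counts = Poisson(scale_sample × expected × 30), scale
  factors ~ U(0.5, 2).  Poisson noise only: count data with no
  overdispersion assumption.
* **Stability.** log2 half-life (hours) = 4 + 0.5·log2(PABP occupancy) +
  N(0, 0.5); a 5% outlier class is destabilized by −1.5 log2 despite a +1
  log2 occupancy boost and −30 nt shorter tails (a mitochondrial-RP-like
  class: high occupancy, short tails, short half-life).  With these values
  ≈ 90% of the class falls below the 10% residual quantile analytically.
  Translational efficiency uses slope 0.2 with sd 0.5.
* **Gene sets.** The outlier class plus 200 random sets of 25–100 genes
  for enrichment nulls.

What the generator does **not** emulate: read-level sequencing (no FASTQ,
mapping or quantification noise beyond log-normal scatter), isoform
structure, UTR composition bias, overdispersed counts, tail-length
measurement error, cell-to-cell heterogeneity, or correlated gene programs
beyond the single occupancy latent factor.  Passing closed-loop tests
therefore demonstrates correctness of the analysis code under the stated
generative model, not robustness to every artifact of real libraries.

## Statistical conventions

Two-sided tests throughout; average ranks with tie-corrected variances;
K–S and Mann–Whitney p-values are asymptotic by default with exact
enumeration modes (tie-safe, full enumeration of label assignments) for
small samples; Spearman p uses the t approximation with an exact permutation
option for n ≤ 8; Fisher's r-to-z compares independent correlations.
Empirical CDFs are right-continuous and evaluated at observed values.

## Determinism and problem sizes

All randomness flows from explicit seeds (numpy `default_rng`); iteration
orders are fixed; TSV floats are serialized at 6 significant digits; JSON is
sorted.  Re-running any pipeline configuration reproduces byte-identical
output trees, which the test suite and acceptance script verify by file
comparison.  The closed-loop checks run at the default 2,200-gene scale
(≈ 4M tail tags across 9 samples); the determinism check uses a 400-gene
configuration and the phasing checks 150-gene configurations with 100
sampled genes per profile — sizes chosen so each check exercises the full
analysis path while the whole suite stays fast on one CPU.

## Known limitations

* The logging stream is stderr-only by default; an optional `--log-file`
  exists, but no log file is placed inside the output tree, so that output
  trees remain byte-identical across runs (log content includes run paths).
* `enrich_extremes` treats gene sets as flat lists (GMT); there is no
  ontology hierarchy, term relationships or evidence-code filtering.
* The residual scan's OLS trend is sensitive to gross outliers by design
  (the outliers are the object of study); the rank-based fit option trades
  that sensitivity for robustness.
* NanoString normalization assumes the reference genes are unregulated; a
  condition that perturbed them would bias all factors, and no diagnostic
  beyond their post-normalization equality is emitted.
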