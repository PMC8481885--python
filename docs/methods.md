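# Methods

## Screening model

Both expression and methylation matrices are screened with a two-sample
t statistic per gene, cases minus controls, so positive t means higher in
cases. Calls use strict cutoffs *P* < 0.05 and |t| > 2, with no
multiplicity correction at this stage — the screen is a filter feeding an
intersection, not an inferential endpoint.

Three statistic flavors:

* `student` (default): pooled-variance t, df = n₁+n₂−2. Self-contained and
  exact under Gaussian noise; this is what the synthetic generator's noise
  model matches.
* `welch`: unequal variances, Welch–Satterthwaite df.
* `moderated`: limma-style empirical-Bayes shrinkage of the pooled
  variance, s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d), with (d₀, s₀²) fitted by
  method of moments on log variances (trigamma inversion for d₀, digamma
  correction for s₀²; d₀ → ∞ means equal variances and full shrinkage).
  P-values use d+d₀ df. This flavor exists for parity with GEO2R-style
  microarray screens; on real probe-level GEO matrices one would also use
  the smallest-p probe-collapse rule in `matrix.collapse_duplicates`.

Features with missing cells are tested on available samples; fewer than 3
per group skips the feature with a warning. Zero variance in both groups
with equal means is reported as t = 0, p = 1 rather than NaN.

## Aberrant classes

`hyper_low` = hypermethylated ∩ downregulated, `hypo_high` =
hypomethylated ∩ upregulated, by exact gene-symbol match after uppercasing
and whitespace stripping. No alias resolution is attempted: alias maps are
database-dependent and would make results irreproducible across annotation
versions. The two classes are provably disjoint (a gene cannot be up and
down in one screen) and the container enforces this.

## Shared-miRNA hypergeometric test

For one class, the miRNA universe is the set of distinct miRNAs in the
class-restricted mRNA–miRNA sub-table (size N). For a pair, n = the
mRNA's partners, m = the lncRNA's partners **restricted to the universe**
(otherwise m ≤ N can fail and the distribution is undefined), x = shared
partners. The p-value is the hypergeometric upper tail, computed via the
survival function (log-space internally), clamped to [0, 1].

Two tails are implemented because the conventional printed form of this
test sums k = 0..x, which is P(X > x), while standard enrichment practice
is P(X ≥ x). The default is `ge` (conservative standard); `gt` reproduces
the printed form literally. Pair p-values are deliberately **not**
FDR-adjusted — only co-expression p-values are — mirroring the original
two-filter design this pipeline operationalizes.

The same core scores over-representation in `enrichment.ora`
(N = background, n = query, m = set∩background), keeping a single source
of truth. No EASE-style (x−1) adjustment is applied, so DAVID p-values
will differ slightly.

## Co-expression filter

Pearson correlation across all samples of the run (cases and controls
pooled — the ceRNA coupling hypothesis concerns co-variation, and the
group shift contributes real signal for genes that move together).
The p-value uses the t-transform t = r√((s−2)/(1−r²)), exact under
normality, then Benjamini–Hochberg step-up across all pairs in the run.
Retention is strict: PCC > 0.5 and FDR < 0.05. Zero-variance or missing
profiles drop the pair with a warning rather than failing the run.

## Network topology and ranking

Each triple contributes mRNA–miRNA and miRNA–lncRNA edges; the network
container rejects same-type or mRNA–lncRNA edges and an ID occurring in
two molecular roles, so the graph is bipartite-layered by construction
(every mRNA↔lncRNA path has even length through ≥1 miRNA). Betweenness is
reported unnormalized (raw sum of pair fractions): normalization is a
monotone rescaling and the pipeline only consumes rankings. Hub selection
uses strict degree > 10 network-wide on the supplied PPI edge list.
Biomarker rows enumerate gene→miRNA→lncRNA paths from each critical gene;
lncRNAs rank by degree, then betweenness, then name, with exact ties
flagged in the report.

## Synthetic study design

The generator emulates the statistical structure the pipeline assumes,
at the scale of a small two-cohort microarray study:

* **Expression**: per-gene baselines U(6, 10) on a log2-like intensity
  scale, Gaussian noise sd = 1.0 (microarray convention); planted DE genes
  shift case means by ±2.0. With 25+25 samples this puts planted |t|
  around 7 — comfortably detectable, as in a screen whose published hit
  counts are in the hundreds-to-thousands.
* **Methylation**: clamped-Gaussian beta values around U(0.3, 0.7)
  baselines, measurement sd 0.05, case shift ±0.2. A Beta distribution
  would bound values intrinsically; clamping was chosen for simplicity
  since the bounded-range invariant stays testable either way.
* **Intersections**: half of each DE/DM block overlaps by construction,
  giving non-trivial hyper_low/hypo_high truth sets.
* **ceRNA structure**: `planted_triples` (default 20) total
  (mRNA, miRNA, lncRNA) tuples, grouped into pairs of `shared_per_pair`
  (default 4) shared miRNAs. A pair sharing a single miRNA is statistically
  indistinguishable from background co-occurrence under any hypergeometric
  threshold, so grouping is what makes the planted signal the kind of
  signal the test detects. Planted pair expression is bivariate-Gaussian
  mixed to Pearson ρ = 0.8 in expectation (mixing on the standardized mRNA
  profile gives the exact target and a trivial oracle). Background
  interaction edges are uniform at density 0.02, giving each molecule a
  realistic handful of decoy partners and the test a non-degenerate null.
* **Curated list**: all planted miRNAs plus up to 30 decoys.

Not emulated: probe-level 450K structure, batch effects, missingness
mechanisms, non-Gaussian heavy tails, and correlated background genes.
Passing recovery tests therefore demonstrates correctness of the
machinery under its stated model, not performance on real cohorts, where
effect sizes are smaller and annotation noise dominates.

## Numerical and degenerate-input choices

* Hypergeometric tails via the survival function; never naive sums.
* BH adjustment delegated to statsmodels (`fdr_bh`); tests check it
  against an independent hand-written step-up.
* Betweenness delegated to networkx (`normalized=False`); tests check
  against brute-force all-pairs geodesic enumeration.
* All ties broken deterministically (degree desc, betweenness desc,
  lexicographic). Empty intersections, empty sub-tables and hub sets
  disjoint from the network produce empty outputs with warnings, not
  errors; invalid statistic arguments raise naming the violated
  inequality.
* Every random draw flows from one integer seed
  (`numpy.random.default_rng`); identical config + seed reproduces
  identical files.

## Problem sizes

Default study: 400 genes, 120 miRNAs, 200 lncRNAs, 25+25 samples —
a scale at which the full pipeline runs in under a second while leaving
all rates (type-I fraction, recall, false-discovery proportion)
well-estimated. Calibration checks use 2000 genes for a tighter binomial
band. The hypergeometric core is verified exhaustively for all universes
N ≤ 30; topology against brute force on 200 random graphs of ≤ 12 nodes.

## Known limitations

* Gene-symbol matching only; no probe annotation, alias or coordinate
  mapping.
* The moderated-t is a method-of-moments approximation to limma's fit and
  can differ in the tails on small studies.
* PPI hub selection consumes a pre-exported edge list; module detection
  (MCODE-style) is out of scope.
* Enrichment assumes flat gene sets (no GO DAG propagation).
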