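# Methods

## Data model and conventions

All coordinates are 0-based, half-open, for uniform interval algebra; the
CGmap reader/writer converts from/to that format's 1-based positions, and
`QuantRegion.from_one_based` accepts the 1-based inclusive coordinates
printed in figure legends. Methylation levels are fractions in [0, 1]
internally; file exports (tracks, quantifications) use percent 0–100.
Cytosines on both strands are simulated and recorded separately; symmetric
CG sites are never merged, matching per-cytosine caller output. A
cytosine's context is the trinucleotide on its own strand (CG, CHG, CHH
with H = A, T or C); cytosines too close to a sequence end for a full
trinucleotide default to CHH.

## Generative model (synthetic methylomes)

The simulator emulates a paired mutant/control WGBS study, not reads or
alignments:

* **Genome.** I.i.d. random sequence at GC = 0.36 (a typical plant nuclear
  value), tiled into 2-kb blocks assigned to compartments: `TE_like`
  (default 20%), `gene_body_CG` (30%), remainder `unmethylated`.
  Unannotated sequence falls back to `unmethylated` — a conservative
  background.
* **Baselines.** True per-cytosine methylation probabilities per
  (class, context): TE-like (0.85, 0.65, 0.10) — dense CG/CHG with low
  CHH, as in plant heterochromatin; gene-body (0.60, 0, 0) — CG-only by
  definition; unmethylated (0, 0, 0).
* **Counts.** Coverage n ~ Poisson(mean_coverage), independent across
  sites — the simplest model consistent with a stated *average* coverage
  (default 30). Observed methylated reads m ~ Binomial(n, p + (1−p)(1−c)):
  incomplete bisulfite conversion (c, default 0.975) inflates apparent
  methylation of unmethylated cytosines. Mean observed methylation of a
  p = 0 site is exactly 1 − c, which is what the conversion estimator
  inverts.
* **Planted effects.** Requests are placed on a 100-bp grid (so planted
  regions coincide with calling bins) inside compartments of a chosen
  class, requiring ≥ 4 context cytosines per 100 bp so planted regions are
  eligible for calling by construction, and never overlapping each other.
  A request affecting every mutant is bookkept as a shared DMR; anything
  narrower is a hypervariable region with per-sample deltas (replicate-
  private natural variation). Deltas are validated against the class
  baseline so probabilities stay in [0, 1]. By default each affected
  sample receives the full requested delta; an optional jitter draws
  per-sample deltas uniformly from [δ(1−j), δ].

What the generator does *not* emulate: read-level artifacts (PCR
duplicates, mapping bias, chimeras), strand-asymmetric methylation,
spatial autocorrelation of methylation within compartments, and
overdispersion beyond binomial. Passing tests therefore demonstrate the
pipeline's statistical behavior under clean count noise, not robustness to
alignment pathology.

## DMR calling

Bin width 100 bp, tiling from 0 with the final partial bin kept. Per bin
and context, counts are pooled over cytosines with n ≥ 4 (both strands);
eligibility requires ≥ 4 such cytosines in both samples and nonzero pooled
coverage in both. The test is a two-sided Fisher exact test on the pooled
2×2 table, vectorized as an exhaustive hypergeometric enumeration with
log-factorials from `gammaln` and the standard 1 + 1e-7 relative slack on
tied outcomes; BH adjustment (via statsmodels) runs within one
(comparison × context) family, since contexts are called independently.
DMR = q ≤ 0.01 and |Δ| ≥ 0.40/0.20/0.10 (CG/CHG/CHH). The test statistic
is pluggable in principle (the calling function takes the thresholds
object and operates on aggregate tables), but Fisher + BH is the fixed,
fully specified default. Pooling counts into one table per bin was chosen
over per-cytosine testing or mean-of-ratios because it weights cytosines
by evidence and yields a single exact test per bin; "bin methylation
level" is correspondingly sum(m)/sum(n).

## Interval operations

Semantics mirror the classical BED toolchain: N-way intersection
decomposed into consecutive 100-bp windows restarting at each intersected
region's start, remainder kept (conserves covered bp); distance merging
joins intervals with gap ≤ d transitively (d = 300 default), restricted
within context unless told otherwise; the cross-context union joins
overlapping or directly adjacent (gap exactly 0) regions; annotation
overlap keeps/drops queries by ≥ 1 bp overlap with the feature union, and
the two modes partition the query set. Locus convergence merges windows
across contexts and directions under the same gap ≤ 300 bp relation; the
rule for collapsing direct-overlap windows into loci is a declared choice
(consistent with the other merges) since reasonable alternatives exist,
and locus counts are sensitive to it.

## Relaxed conserved DMRs

Master lists are per-(context × direction) unions of all per-comparison
DMR windows. The window × sample matrix stores pooled levels rounded to 3
decimals; rounding at that precision cannot flip a selection decision
whose margin exceeds 0.002. Row clustering uses average linkage on
1 − |Pearson r| (rows only; columns keep roster order); constant rows get
maximal distance 1 and a log entry. Selection is automated as a sign rule —
every mutant minus the control mean strictly carries the target direction,
no magnitude or coverage cutoff — because the analogous manual step
(highlighting concordant heatmap clusters by eye) is not reproducible; a
cluster-cut mode (keep whole flat clusters whose rows all pass the sign
rule) preserves the shape of the manual workflow. Rows incomplete in any
named sample are never selectable (conservative missing-value policy).
CG-context selections are then filtered against body-methylated genes
(≥ 1 bp overlap), which vary naturally between individuals.

## Targeted assays

Windowed quantification pools methylated/total observations per context
and also reports the count of distinct reference cytosines; clone
alignments are single-stranded, so the cytosine universe differs from
double-stranded call tables over the same window by design. Clone
filtering collapses exact-duplicate patterns and removes clones whose CHH
calls are ≥ 95% methylated in some 150-bp window (≥ 5 CHH sites) where the
across-clone CHH mean is < 20% — wholesale CHH methylation on an
unmethylated background indicates failed conversion. The exact duplicate
and non-conversion criteria are explicit parameters because no canonical
rule exists. McrBC relative methylation is 100 − 100·2^(Ct_mock −
Ct_treated); negative values (assay noise) are flagged, not clipped; no
amplification after digestion reports 100 (flagged), no amplification in
mock is undefined.

## Conversion-rate estimation

1 − sum(m)/sum(n) pooled over all contexts in caller-designated
unmethylated regions (≥ 100 covered cytosines required). Which regions
count as unmethylated (chloroplast, spike-in, known-unmethylated
compartments) is the caller's convention; the simulator's truth makes the
estimator exactly calibrated, E[m/n] = 1 − c on p = 0 sites.

## Pipeline and determinism

`run_pipeline` chains simulate → call (6 pairs × 3 contexts) → k-way
direct overlaps → loci → master lists/matrices/relaxed selection →
body-methylation filter → 300-bp per-context merge → cross-context
adjacency union, logging counts in/out at every stage into the manifest's
funnel. All randomness derives from the single config seed via
`SeedSequence`; identical (config, seed) gives identical manifests. Each
stage is a pure function of its declared inputs, so any stage can be
re-run standalone from written intermediates (the CLI exposes them as
subcommands).

## Validation problem sizes

Chosen to characterize the estimator well while keeping a full validation
run at a few minutes on one CPU:

* Fisher oracle: every 2×2 table with total ≤ 50 in the test suite
  (≈ 3·10⁵ tables, agreement < 1e-12); totals ≤ 40 in the acceptance
  script.
* Null experiment: 1-Mb genome, six comparisons, 20 seeds in the test
  suite (10 in the script). Expected false-call fractions sit far below
  the q ≤ 0.01 bound because BH on discrete Fisher p-values is
  conservative.
* Recovery experiment: 50 shared hyper-CG DMRs (Δ = 0.5) plus 12
  replicate-private regions per seed on a 1-Mb genome, pooled over 8 seeds
  (6 in the script). At 30× with ~4–8 CG sites per bin the observed Δ of a
  planted 0.5 effect is ≈ 0.49 ± 0.04, so a few percent of
  bin-comparisons land under the 0.40 cutoff; six-way sensitivity
  consequently sits near 0.91–0.93, and pooling seeds measures it with
  ≈ 1.4% standard error.
* Headline run: 600-kb genome, 30 shared CG + 15 shared CHG + 18 private
  regions, full pipeline.

## Known limitations

No biological-replicate dispersion modeling (comparisons are sample
pairs, as in the underlying design); no smoothing/HMM detection; the
Fisher test treats reads within a bin as independent Bernoulli draws;
relaxed selection's sign rule is stricter than human cluster judgment for
borderline rows and does not guarantee any particular count on real data;
BED annotation is plain intervals (no gene models).
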