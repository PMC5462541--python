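# methbin

Bin-based differential-methylation analysis for whole-genome bisulfite
sequencing (WGBS), built for paired mutant/control study designs in plants,
where cytosine methylation occurs in three sequence contexts (CG, CHG and
CHH, with H = A, T or C) laid down by distinct pathways.

`methbin` is for analysts who have per-cytosine methylation call tables
(CGmap-style output of a bisulfite mapper) for several mutant/control pairs
and need to answer: *which regions change methylation consistently in every
mutant, beyond the natural epigenetic variation seen even among siblings?*

## The method

**DMR calling.** The genome is tiled into non-overlapping 100-bp bins. For
each bin, context and sample, read counts are pooled over all cytosines
(both strands) covered by ≥ 4 reads. A bin is eligible when both samples of
a comparison have ≥ 4 such cytosines. Each eligible bin's pooled 2×2 table
(methylated/unmethylated × mutant/control) is tested with a two-sided
Fisher exact test; p-values are Benjamini–Hochberg adjusted within one
(comparison × context) family. A bin is a DMR iff

```
q ≤ 0.01   and   |Δ| ≥ 0.40 (CG), 0.20 (CHG), 0.10 (CHH)
```

where Δ = level(mutant) − level(control).

**Conservation across comparisons.** Because methylation varies naturally
between individuals, single-comparison DMRs are unreliable. Two filters are
provided:

* *direct*: the N-way genomic intersection of all per-comparison DMR sets,
  chopped back into 100-bp windows (bedops `-i` + `chop` semantics), then
  merged into loci across contexts within 300 bp;
* *relaxed*: the union ("master list") of all per-comparison DMRs is
  tabulated as a window × sample methylation matrix (3-decimal precision),
  clustered (average linkage, 1 − |Pearson r|), and windows kept when every
  mutant moves in the same direction relative to the control mean — no
  effect-size or coverage cutoff — then filtered against body-methylated
  genes, which are naturally hypervariable.

**Targeted assays.** Windowed average methylation (figure-legend style
1-based coordinates supported), clone-based Sanger bisulfite summaries with
duplicate/non-conversion filtering, and McrBC-qPCR relative methylation,
`100 − 100·2^(Ct_mock − Ct_treated)`.

**Synthetic methylomes.** A seeded generator emulates the study design:
compartmentalized genomes (TE-like heavy methylation, CG-only gene bodies,
unmethylated genes), ~30× Poisson coverage, binomial counts with
non-conversion inflation at conversion rate c (target ≥ 0.97), shared
planted DMRs, and replicate-private hypervariable regions.

## Worked example

```python
import methbin

cfg = methbin.default_run_config(genome_size=200_000, seed=1)
manifest = methbin.run_pipeline(cfg)
print(manifest["funnel"])
print(manifest["recovery"])
```

prints (seed 1):

```
{'per_comparison_dmrs_total': 188, 'direct_windows_total': 27, 'loci': 27,
 'hyper_mc_merged_regions': 30}
{'shared_recovered_by_direct': 27, 'shared_total': 30, 'direct_sensitivity': 0.9,
 'hypervariable_total': 12, 'hypervariable_in_direct': 0,
 'hypervariable_excluded_fraction': 1.0, 'hypervariable_detectable': 12,
 'hypervariable_detected_in_own_comparison': 12}
```

Reading: across the six comparisons 188 bins were called as DMRs, but only
27 windows survive the six-way direct overlap (the 30 planted shared DMRs,
minus three that fell just under the Δ ≥ 0.4 cutoff in one comparison).
All 12 replicate-private regions were detected in their own comparison's
DMR list yet correctly excluded from the conserved set — the filtering
behaves exactly as intended: single-comparison DMR lists are dominated by
effects that do not replicate.

The same stages are scriptable from the shell:

```
methbin simulate --genome-size 200000 --seed 1 --outdir run/
methbin call-dmrs run/calls_m1_r1.tsv run/calls_c1_r1.tsv \
    --chrom-sizes sizes.tsv --context CG --out-bed dmrs.bed
methbin intersect run/*.bed --window 100 --out direct.bed
methbin merge direct.bed --distance 300 --out merged.bed
```

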