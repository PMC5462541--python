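"""End-to-end orchestration: simulate -> call -> intersect -> relax -> merge.

One :class:`RunConfig` drives the whole study design: a roster of paired
mutant/control samples (by default three replicates of one mutant allele
plus three further mutant alleles, each with its own matched control —
six pairwise comparisons), the planted-effect requests, the calling
thresholds, and the merge distances.  :func:`run_pipeline` produces a
machine-readable manifest with the count funnel at every stage
(per-comparison DMRs -> k-way direct overlaps -> loci; master lists ->
relaxed sets -> body-methylation-filtered sets -> merged hyper-mC
regions) plus recovery statistics against the simulation's ground truth.
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import conserved, intervals as iv
from .dmr import DmrThresholds, aggregate, call_dmrs, dmr_set_from_table, write_dmr_bed
from .intervals import DmrSet, write_bed
from .io import CONTEXTS, estimate_conversion, global_methylation, write_calls
from .synthetic import (
    DEFAULT_BASELINES,
    DmrRequest,
    SampleProfile,
    build_reference,
    plant_dmrs,
    simulate_sample,
)

logger = logging.getLogger(__name__)

DIRECTIONS = ("hyper", "hypo")

__all__ = ["ComparisonPair", "RunConfig", "default_run_config", "run_pipeline"]


@dataclass(frozen=True)
class ComparisonPair:
    comparison_id: str
    mutant: str
    control: str


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML round-trippable."""

    chrom_lengths: dict[str, int]
    pairs: list[ComparisonPair]
    planted: list[DmrRequest] = field(default_factory=list)
    compartment_fractions: dict[str, float] = field(
        default_factory=lambda: {"TE_like": 0.2, "gene_body_CG": 0.3}
    )
    baselines: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    mean_coverage: float = 30.0
    conversion_rate: float = 0.975
    thresholds: DmrThresholds = field(default_factory=DmrThresholds)
    merge_distance: int = 300
    locus_merge_distance: int = 300
    window: int = 100
    seed: int = 0
    outdir: str | None = None
    write_call_tables: bool = False

    def __post_init__(self):
        muts = [p.mutant for p in self.pairs]
        ctls = [p.control for p in self.pairs]
        if len(set(muts)) != len(muts):
            raise ValueError("each mutant must appear in exactly one pair")
        if set(muts) & set(ctls):
            raise ValueError("a sample cannot be both mutant and control")

    @property
    def mutant_ids(self) -> list[str]:
        return [p.mutant for p in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        # a control may back several comparisons; keep first-seen order
        seen = dict.fromkeys(p.control for p in self.pairs)
        return list(seen)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["pairs"] = [dataclasses.asdict(p) for p in self.pairs]
        doc["planted"] = [dataclasses.asdict(r) for r in self.planted]
        doc["thresholds"] = {
            "delta_min": dict(self.thresholds.delta_min),
            "q_max": self.thresholds.q_max,
            "min_eligible_cytosines": self.thresholds.min_eligible_cytosines,
            "min_site_coverage": self.thresholds.min_site_coverage,
            "bin_width": self.thresholds.bin_width,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["pairs"] = [ComparisonPair(**p) for p in doc["pairs"]]
        doc["planted"] = [
            DmrRequest(**{**r, "affected": tuple(r["affected"])
                          if isinstance(r["affected"], list) else r["affected"]})
            for r in doc.get("planted", [])
        ]
        if "thresholds" in doc:
            doc["thresholds"] = DmrThresholds(**doc["thresholds"])
        if "baselines" in doc:
            doc["baselines"] = {k: tuple(v) for k, v in doc["baselines"].items()}
        return cls(**doc)


def default_run_config(
    genome_size: int = 400_000,
    seed: int = 0,
    n_shared_cg: int = 20,
    n_shared_chg: int = 10,
    n_private: int = 12,
    outdir: str | None = None,
) -> RunConfig:
    """A study-shaped default: 3 replicate comparisons of one mutant allele
    plus 3 further alleles, each with a matched control; shared planted
    DMRs in all mutants and replicate-private hypervariable regions spread
    over individual samples."""
    pairs = [
        ComparisonPair("m1_r1_vs_c1_r1", "m1_r1", "c1_r1"),
        ComparisonPair("m1_r2_vs_c1_r2", "m1_r2", "c1_r2"),
        ComparisonPair("m1_r3_vs_c1_r3", "m1_r3", "c1_r3"),
        ComparisonPair("m2_vs_c2", "m2", "c2"),
        ComparisonPair("m3_vs_c3", "m3", "c3"),
        ComparisonPair("m4_vs_c4", "m4", "c4"),
    ]
    samples = [p.mutant for p in pairs] + [p.control for p in pairs]
    planted = []
    if n_shared_cg:
        planted.append(DmrRequest(n_shared_cg, "CG", "hyper", 0.5))
    if n_shared_chg:
        planted.append(DmrRequest(n_shared_chg, "CHG", "hyper", 0.3))
    for i in range(n_private):
        planted.append(
            DmrRequest(1, "CG", "hyper", 0.5, affected=(samples[i % len(samples)],))
        )
    return RunConfig(
        chrom_lengths={"chr1": genome_size},
        pairs=pairs,
        planted=planted,
        seed=seed,
        outdir=outdir,
    )


def _derived_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence([0x9065, int(seed)]))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return (and optionally write) the manifest."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: reference + truth -------------------------------------
    ref = build_reference(
        config.chrom_lengths, seed=config.seed,
        compartment_fractions=config.compartment_fractions,
    )
    sample_ids = config.mutant_ids + config.control_ids
    seeds = _derived_seeds(config.seed, len(sample_ids))
    profiles = [
        SampleProfile(
            sid,
            "mutant" if sid in config.mutant_ids else "control",
            replicate_tag=sid.split("_")[-1] if "_" in sid else "",
            mean_coverage=config.mean_coverage,
            conversion_rate=config.conversion_rate,
            baseline_methylation=dict(config.baselines),
            seed=s,
        )
        for sid, s in zip(sample_ids, seeds)
    ]
    truth = plant_dmrs(config.planted, ref, profiles, seed=config.seed)

    # --- stage 2: simulate ------------------------------------------------
    samples = {p.sample_id: simulate_sample(ref, p, truth) for p in profiles}
    unmeth = ref.compartment_intervals("unmethylated")
    qc = {
        sid: {
            "global_methylation": {
                k: (round(v, 5) if v is not None else None)
                for k, v in global_methylation(s, config.thresholds.min_site_coverage).items()
            },
            "conversion_estimate": round(estimate_conversion(s, unmeth), 5) if unmeth else None,
        }
        for sid, s in samples.items()
    }

    # --- stage 3: per-comparison DMR calling ------------------------------
    tables: dict[tuple[str, str], "object"] = {}
    dmr_sets: dict[tuple[str, str, str], DmrSet] = {}
    per_comparison: dict[str, dict] = {}
    for pair in config.pairs:
        per_ctx = {}
        for ctx in CONTEXTS:
            agg_m = aggregate(
                samples[pair.mutant], config.chrom_lengths, ctx,
                bin_width=config.thresholds.bin_width,
                min_site_coverage=config.thresholds.min_site_coverage,
            )
            agg_c = aggregate(
                samples[pair.control], config.chrom_lengths, ctx,
                bin_width=config.thresholds.bin_width,
                min_site_coverage=config.thresholds.min_site_coverage,
            )
            table = call_dmrs(agg_m, agg_c, config.thresholds, pair.comparison_id)
            tables[(pair.comparison_id, ctx)] = table
            for direction in DIRECTIONS:
                dmr_sets[(pair.comparison_id, ctx, direction)] = dmr_set_from_table(table, direction)
            per_ctx[ctx] = {
                "eligible_bins": int(table.attrs["n_eligible_bins"]),
                "dmrs_hyper": len(dmr_sets[(pair.comparison_id, ctx, "hyper")]),
                "dmrs_hypo": len(dmr_sets[(pair.comparison_id, ctx, "hypo")]),
            }
            if outdir:
                write_dmr_bed(table, outdir / f"dmrs_{pair.comparison_id}_{ctx}.bed")
        per_comparison[pair.comparison_id] = per_ctx

    # --- stage 4: direct k-way overlaps ----------------------------------
    direct: dict[str, dict[str, dict]] = {}
    sixway_windows: list = []
    n_comp = len(config.pairs)
    for ctx in CONTEXTS:
        direct[ctx] = {}
        for direction in DIRECTIONS:
            sets = [dmr_sets[(p.comparison_id, ctx, direction)] for p in config.pairs]
            depth = iv.overlap_depth_counts(sets, window=config.window)
            if all(len(s) for s in sets):
                windows = iv.intersect_direct(sets, window=config.window)
            else:
                windows = []
            direct[ctx][direction] = {
                "depth_counts": {str(k): v for k, v in depth.items()},
                "direct_windows": len(windows),
            }
            sixway_windows.extend(windows)
            if outdir and windows:
                write_bed(windows, outdir / f"direct_{ctx}_{direction}.bed")

    # --- stage 5: loci ----------------------------------------------------
    loci = iv.converge_to_loci(sixway_windows, merge_distance=config.locus_merge_distance)
    if outdir and loci:
        write_bed([l.interval for l in loci], outdir / "direct_loci.bed")

    # --- stage 6: master lists, matrices, relaxed selection ---------------
    all_samples = [samples[s] for s in config.mutant_ids + config.control_ids]
    relaxed: dict[str, dict[str, int]] = {}
    relaxed_windows: dict[tuple[str, str], list] = {}
    body_genes = ref.compartment_intervals("gene_body_CG")
    for ctx in CONTEXTS:
        relaxed[ctx] = {}
        for direction in DIRECTIONS:
            master = conserved.build_master_list(
                [dmr_sets[(p.comparison_id, ctx, direction)] for p in config.pairs]
            )
            if not master:
                relaxed[ctx][f"master_{direction}"] = 0
                relaxed[ctx][f"relaxed_{direction}"] = 0
                relaxed[ctx][f"filtered_{direction}"] = 0
                relaxed_windows[(ctx, direction)] = []
                continue
            matrix = conserved.methylation_matrix(
                master, all_samples, ctx,
                min_site_coverage=config.thresholds.min_site_coverage,
            )
            sel = conserved.select_concordant(
                matrix, config.mutant_ids, config.control_ids, direction, mode="sign"
            )
            filt = conserved.filter_body_methylated(sel, body_genes)
            relaxed[ctx][f"master_{direction}"] = len(master)
            relaxed[ctx][f"relaxed_{direction}"] = len(sel)
            relaxed[ctx][f"filtered_{direction}"] = len(filt)
            relaxed_windows[(ctx, direction)] = filt
            if outdir:
                matrix.values.to_csv(outdir / f"matrix_{ctx}_{direction}.tsv", sep="\t")
                if filt:
                    write_bed(filt, outdir / f"relaxed_{ctx}_{direction}.bed")

    # --- stage 7: merged hyper-mC regions ---------------------------------
    merged_by_ctx = {
        ctx: iv.merge_within(relaxed_windows[(ctx, "hyper")], distance=config.merge_distance)
        for ctx in CONTEXTS
    }
    hyper_mc_merged = iv.union_across_contexts(merged_by_ctx)
    if outdir and hyper_mc_merged:
        write_bed(hyper_mc_merged, outdir / "hyper_mC_merged.bed")

    # --- stage 8: truth recovery -----------------------------------------
    recovery = _recovery_stats(truth, sixway_windows, dmr_sets, config)

    manifest = {
        "seed": config.seed,
        "genome_bp": int(sum(config.chrom_lengths.values())),
        "n_comparisons": n_comp,
        "sample_qc": qc,
        "per_comparison": per_comparison,
        "direct_overlap": direct,
        "funnel": {
            "per_comparison_dmrs_total": int(
                sum(c["dmrs_hyper"] + c["dmrs_hypo"]
                    for pc in per_comparison.values() for c in pc.values())
            ),
            "direct_windows_total": len(sixway_windows),
            "loci": len(loci),
            "hyper_mc_merged_regions": len(hyper_mc_merged),
        },
        "relaxed": relaxed,
        "truth": {
            "planted_shared": len(truth.planted_dmrs),
            "hypervariable": len(truth.hypervariable_regions),
        },
        "recovery": recovery,
    }
    if outdir:
        truth.to_bed(outdir / "truth_shared.bed", "shared")
        if truth.hypervariable_regions:
            truth.to_bed(outdir / "truth_hypervariable.bed", "hypervariable")
        ref.compartments_to_bed(outdir / "compartments.bed")
        config.to_yaml(outdir / "config.yaml")
        if config.write_call_tables:
            for sid, s in samples.items():
                write_calls(s, outdir / f"calls_{sid}.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


def _recovery_stats(truth, sixway_windows, dmr_sets, config) -> dict:
    """Sensitivity of the direct overlap on planted shared DMRs, and
    leakage of replicate-private regions into it."""
    out: dict = {}
    cov = iv._union_coverage(sixway_windows)
    shared = truth.planted_dmrs
    if shared:
        hit = sum(
            1 for d in shared
            if iv.overlap_bp(iv.GenomicInterval(d.chrom, d.start, d.end), cov) >= 1
        )
        out["shared_recovered_by_direct"] = hit
        out["shared_total"] = len(shared)
        out["direct_sensitivity"] = round(hit / len(shared), 4)
    hv = truth.hypervariable_regions
    if hv:
        leaked = sum(
            1 for h in hv
            if iv.overlap_bp(iv.GenomicInterval(h.chrom, h.start, h.end), cov) >= 1
        )
        out["hypervariable_total"] = len(hv)
        out["hypervariable_in_direct"] = leaked
        out["hypervariable_excluded_fraction"] = round(1 - leaked / len(hv), 4)
        # detection in the comparison that carries the private effect
        detected = 0
        detectable = 0
        pair_by_sample = {}
        for p in config.pairs:
            pair_by_sample[p.mutant] = (p.comparison_id, "hyper")
            pair_by_sample.setdefault(p.control, (p.comparison_id, "hypo"))
        for h in hv:
            for sid in h.deltas:
                if sid not in pair_by_sample:
                    continue
                comp, eff_dir = pair_by_sample[sid]
                # a hyper effect in a control shows up as a hypo DMR
                direction = h.direction if eff_dir == "hyper" else (
                    "hypo" if h.direction == "hyper" else "hyper"
                )
                detectable += 1
                own = dmr_sets[(comp, h.context, direction)].intervals
                c1 = iv._union_coverage(own)
                if iv.overlap_bp(iv.GenomicInterval(h.chrom, h.start, h.end), c1) >= 1:
                    detected += 1
        out["hypervariable_detectable"] = detectable
        out["hypervariable_detected_in_own_comparison"] = detected
    return out
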