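"""Seed-swept validation experiments on the synthetic methylome.

Two standing experiments characterize the DMR pipeline under the study's
generative conditions (30x coverage, 97.5% conversion, six paired
comparisons on a compartmentalized genome):

* the *null* experiment draws every sample from identical parameters and
  measures how often eligible bins are falsely called and whether anything
  survives the six-way direct overlap;
* the *recovery* experiment plants shared hyper-CG DMRs (delta 0.5) in all
  mutants plus replicate-private regions in single mutants, and measures
  six-way sensitivity for the shared set and exclusion of the private set.

Both are pure functions of their arguments, including the seed.
"""

from __future__ import annotations

import numpy as np

from .dmr import aggregate, call_dmrs, dmr_set_from_table
from .intervals import GenomicInterval, _union_coverage, intersect_direct, overlap_bp
from .io import CONTEXTS
from .pipeline import _derived_seeds, default_run_config
from .synthetic import DmrRequest, SampleProfile, build_reference, plant_dmrs, simulate_sample

__all__ = ["null_experiment", "recovery_experiment"]


def _profiles(cfg, seed):
    ids = cfg.mutant_ids + cfg.control_ids
    seeds = _derived_seeds(seed, len(ids))
    return [
        SampleProfile(
            sid, "mutant" if sid in cfg.mutant_ids else "control",
            mean_coverage=cfg.mean_coverage, conversion_rate=cfg.conversion_rate,
            baseline_methylation=dict(cfg.baselines), seed=s,
        )
        for sid, s in zip(ids, seeds)
    ]


def null_experiment(
    genome_size: int = 1_000_000,
    n_seeds: int = 20,
    seed: int = 0,
    contexts: tuple[str, ...] = CONTEXTS,
) -> dict:
    """Seed-swept pure-null run: no planted effects anywhere.

    Per seed and comparison, pools all contexts and records the fraction of
    eligible bins with q <= q_max and the fraction actually called (q AND
    delta thresholds); also counts windows surviving the six-way direct
    overlap in any context/direction.
    """
    cfg = default_run_config(genome_size=genome_size, seed=seed,
                             n_shared_cg=0, n_shared_chg=0, n_private=0)
    ref = build_reference(cfg.chrom_lengths, seed=seed,
                          compartment_fractions=cfg.compartment_fractions)
    thr = cfg.thresholds
    runs = []
    for i in range(n_seeds):
        run_seed = seed * 10_000 + i
        profiles = _profiles(cfg, run_seed)
        truth = plant_dmrs([], ref, profiles, seed=run_seed)
        samples = {p.sample_id: simulate_sample(ref, p, truth) for p in profiles}
        comp_stats = {}
        sets = {}
        for pair in cfg.pairs:
            elig = called = q_hits = 0
            for ctx in contexts:
                am = aggregate(samples[pair.mutant], cfg.chrom_lengths, ctx,
                               thr.bin_width, thr.min_site_coverage)
                ac = aggregate(samples[pair.control], cfg.chrom_lengths, ctx,
                               thr.bin_width, thr.min_site_coverage)
                t = call_dmrs(am, ac, thr, pair.comparison_id)
                elig += len(t)
                called += int(t["called"].sum())
                q_hits += int((t["q"] <= thr.q_max).sum())
                for direction in ("hyper", "hypo"):
                    sets.setdefault((ctx, direction), []).append(
                        dmr_set_from_table(t, direction)
                    )
            comp_stats[pair.comparison_id] = {
                "eligible": elig,
                "called_fraction": called / elig if elig else 0.0,
                "q_fraction": q_hits / elig if elig else 0.0,
            }
        sixway = 0
        for ss in sets.values():
            if all(len(s) for s in ss):
                sixway += len(intersect_direct(ss, window=thr.bin_width))
        runs.append({"seed": run_seed, "per_comparison": comp_stats, "sixway": sixway})
    return {
        "n_seeds": n_seeds,
        "genome_size": genome_size,
        "runs": runs,
        "max_called_fraction": max(
            c["called_fraction"] for r in runs for c in r["per_comparison"].values()
        ),
        "max_q_fraction": max(
            c["q_fraction"] for r in runs for c in r["per_comparison"].values()
        ),
        "min_eligible": min(
            c["eligible"] for r in runs for c in r["per_comparison"].values()
        ),
        "sixway_zero_fraction": sum(r["sixway"] == 0 for r in runs) / n_seeds,
    }


def recovery_experiment(
    genome_size: int = 1_000_000,
    n_seeds: int = 8,
    seed: int = 0,
    n_shared: int = 50,
    n_private_per_mutant: int = 2,
    delta: float = 0.5,
) -> dict:
    """Planted-effect run: shared hyper-CG DMRs vs replicate-private ones.

    Shared regions (delta in every mutant) should survive the six-way
    direct overlap; private regions (delta in exactly one mutant) should
    appear in that mutant's own DMR list but be excluded from the six-way
    set.  Results are pooled across seeds.
    """
    cfg = default_run_config(genome_size=genome_size, seed=seed,
                             n_shared_cg=0, n_shared_chg=0, n_private=0)
    ref = build_reference(cfg.chrom_lengths, seed=seed,
                          compartment_fractions=cfg.compartment_fractions)
    thr = cfg.thresholds
    requests = [DmrRequest(n_shared, "CG", "hyper", delta)]
    for mut in cfg.mutant_ids:
        requests.append(
            DmrRequest(n_private_per_mutant, "CG", "hyper", delta, affected=(mut,))
        )

    shared_total = shared_hit = 0
    private_total = private_leaked = private_detected = 0
    for i in range(n_seeds):
        run_seed = seed * 10_000 + i
        profiles = _profiles(cfg, run_seed)
        truth = plant_dmrs(requests, ref, profiles, seed=run_seed)
        samples = {p.sample_id: simulate_sample(ref, p, truth) for p in profiles}
        hyper_sets = {}
        for pair in cfg.pairs:
            am = aggregate(samples[pair.mutant], cfg.chrom_lengths, "CG",
                           thr.bin_width, thr.min_site_coverage)
            ac = aggregate(samples[pair.control], cfg.chrom_lengths, "CG",
                           thr.bin_width, thr.min_site_coverage)
            t = call_dmrs(am, ac, thr, pair.comparison_id)
            hyper_sets[pair.mutant] = dmr_set_from_table(t, "hyper")
        sets = list(hyper_sets.values())
        sixway = intersect_direct(sets, window=thr.bin_width) if all(
            len(s) for s in sets) else []
        cov = _union_coverage(sixway)
        for d in truth.planted_dmrs:
            shared_total += 1
            if overlap_bp(GenomicInterval(d.chrom, d.start, d.end), cov) >= 1:
                shared_hit += 1
        for h in truth.hypervariable_regions:
            (carrier,) = h.deltas
            private_total += 1
            if overlap_bp(GenomicInterval(h.chrom, h.start, h.end), cov) >= 1:
                private_leaked += 1
            own = _union_coverage(hyper_sets[carrier].intervals)
            if overlap_bp(GenomicInterval(h.chrom, h.start, h.end), own) >= 1:
                private_detected += 1
    return {
        "n_seeds": n_seeds,
        "genome_size": genome_size,
        "shared_total": shared_total,
        "shared_recovered": shared_hit,
        "sensitivity": shared_hit / shared_total if shared_total else float("nan"),
        "private_total": private_total,
        "private_leaked_into_sixway": private_leaked,
        "private_specificity": 1 - private_leaked / private_total if private_total else float("nan"),
        "private_detected_in_own_list": private_detected,
        "private_detection_rate": private_detected / private_total if private_total else float("nan"),
    }
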