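"""Bin-based DMR calling between one mutant sample and its paired control.

The genome is tiled into non-overlapping 100-bp bins.  Within each bin and
context, read counts are pooled over all cytosines (both strands) covered
by at least 4 reads.  A bin is eligible when both samples have at least 4
such cytosines; eligible bins are tested with a two-sided Fisher exact test
on the pooled 2x2 table, adjusted by Benjamini–Hochberg within the
(comparison x context) family.  A DMR is a bin with q <= 0.01 and an
absolute methylation change of at least 0.4 / 0.2 / 0.1 in the CG / CHG /
CHH context respectively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import DmrSet, GenomicInterval
from .io import CONTEXTS, MethylomeSample
from .stats import bh_adjust, fisher_exact_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "DmrThresholds",
    "Dmr",
    "bin_genome",
    "aggregate",
    "call_dmrs",
    "dmr_set_from_table",
    "write_dmr_bed",
]


@dataclass(frozen=True)
class DmrThresholds:
    """Calling thresholds; defaults are the standard binned-WGBS values."""

    delta_min: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.40, "CHG": 0.20, "CHH": 0.10}
    )
    q_max: float = 0.01
    min_eligible_cytosines: int = 4
    min_site_coverage: int = 4
    bin_width: int = 100

    def __post_init__(self):
        for ctx, d in self.delta_min.items():
            if not 0 < d <= 1:
                raise ValueError(f"delta_min[{ctx}] must be in (0, 1]")
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must be in (0, 1)")


@dataclass(frozen=True)
class Dmr:
    """One differentially methylated bin (mutant relative to control)."""

    interval: GenomicInterval
    context: str
    direction: str
    delta: float
    p_value: float
    q_value: float
    comparison_id: str


def bin_genome(chrom_lengths: Mapping[str, int], bin_width: int = 100) -> list[GenomicInterval]:
    """Tile each chromosome from 0 in half-open bins; final partial bin kept."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    out = []
    for chrom in chrom_lengths:
        L = chrom_lengths[chrom]
        for s in range(0, L, bin_width):
            out.append(GenomicInterval(chrom, s, min(s + bin_width, L)))
    return out


def aggregate(
    sample: MethylomeSample,
    chrom_lengths: Mapping[str, int],
    context: str,
    bin_width: int = 100,
    min_site_coverage: int = 4,
) -> pd.DataFrame:
    """Pool one sample's context calls into genome bins.

    Returns one row per bin (including empty bins) with columns
    ``chrom, start, end, eligible, m_sum, n_sum, level``:  ``eligible``
    counts context cytosines (both strands) with ``n >= min_site_coverage``,
    and the count sums run over exactly those cytosines.  ``level`` is NaN
    where ``n_sum == 0``.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    df = sample.calls
    sel = df[(df["context"] == context) & (df["n"] >= min_site_coverage)]
    frames = []
    for chrom, L in chrom_lengths.items():
        nbins = math.ceil(L / bin_width)
        starts = np.arange(nbins, dtype=np.int64) * bin_width
        sub = sel[sel["chrom"] == chrom]
        idx = (sub["pos"].to_numpy() // bin_width).astype(np.int64)
        elig = np.bincount(idx, minlength=nbins)
        m_sum = np.bincount(idx, weights=sub["m"].to_numpy(), minlength=nbins)
        n_sum = np.bincount(idx, weights=sub["n"].to_numpy(), minlength=nbins)
        with np.errstate(invalid="ignore"):
            level = np.where(n_sum > 0, m_sum / np.where(n_sum > 0, n_sum, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_width, L),
                    "eligible": elig.astype(np.int64),
                    "m_sum": m_sum.astype(np.int64),
                    "n_sum": n_sum.astype(np.int64),
                    "level": level,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs.update(
        context=context, bin_width=bin_width,
        min_site_coverage=min_site_coverage, sample_id=sample.sample_id,
    )
    return out


def call_dmrs(
    mutant: pd.DataFrame,
    control: pd.DataFrame,
    thresholds: DmrThresholds | None = None,
    comparison_id: str = "mutant_vs_control",
) -> pd.DataFrame:
    """Test eligible bins and flag DMRs; one context, one comparison.

    Inputs are :func:`aggregate` tables over the same tiling and context.
    Returns the eligible bins with ``delta, p, q, direction, called``; the
    BH family is exactly this set.  Raises on mismatched tilings/contexts.
    """
    thresholds = thresholds or DmrThresholds()
    ctx_m = mutant.attrs.get("context")
    ctx_c = control.attrs.get("context")
    if ctx_m != ctx_c or ctx_m not in CONTEXTS:
        raise ValueError(f"context mismatch: mutant={ctx_m!r} control={ctx_c!r}")
    if len(mutant) != len(control) or not (
        (mutant["chrom"].to_numpy() == control["chrom"].to_numpy()).all()
        and (mutant["start"].to_numpy() == control["start"].to_numpy()).all()
    ):
        raise ValueError("mutant and control aggregates use different bin tilings")

    elig = (
        (mutant["eligible"].to_numpy() >= thresholds.min_eligible_cytosines)
        & (control["eligible"].to_numpy() >= thresholds.min_eligible_cytosines)
        & (mutant["n_sum"].to_numpy() > 0)
        & (control["n_sum"].to_numpy() > 0)
    )
    mu = mutant[elig].reset_index(drop=True)
    ct = control[elig].reset_index(drop=True)

    out = pd.DataFrame(
        {
            "chrom": mu["chrom"],
            "start": mu["start"],
            "end": mu["end"],
            "eligible_mut": mu["eligible"],
            "eligible_ctl": ct["eligible"],
            "m_mut": mu["m_sum"],
            "n_mut": mu["n_sum"],
            "m_ctl": ct["m_sum"],
            "n_ctl": ct["n_sum"],
            "level_mut": mu["level"],
            "level_ctl": ct["level"],
        }
    )
    out["delta"] = out["level_mut"] - out["level_ctl"]
    if len(out):
        out["p"] = fisher_exact_two_sided(
            out["m_mut"].to_numpy(), out["n_mut"].to_numpy(),
            out["m_ctl"].to_numpy(), out["n_ctl"].to_numpy(),
        )
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p"] = np.empty(0)
        out["q"] = np.empty(0)
    out["direction"] = np.where(out["delta"] >= 0, "hyper", "hypo")
    dmin = thresholds.delta_min[ctx_m]
    out["called"] = (out["q"] <= thresholds.q_max) & (out["delta"].abs() >= dmin)
    out.attrs.update(
        context=ctx_m, comparison_id=comparison_id,
        bin_width=mutant.attrs.get("bin_width"),
        n_eligible_bins=int(elig.sum()),
    )
    logger.info(
        "call_dmrs[%s/%s]: %d eligible bins, %d DMRs (%d hyper / %d hypo)",
        comparison_id, ctx_m, int(elig.sum()), int(out["called"].sum()),
        int((out["called"] & (out["direction"] == "hyper")).sum()),
        int((out["called"] & (out["direction"] == "hypo")).sum()),
    )
    return out


def dmr_set_from_table(table: pd.DataFrame, direction: str) -> DmrSet:
    """Extract the called bins of one direction as a :class:`DmrSet`."""
    ctx = table.attrs.get("context")
    comparison = table.attrs.get("comparison_id", "comparison")
    sel = table[table["called"] & (table["direction"] == direction)]
    intervals = [
        GenomicInterval(
            r.chrom, int(r.start), int(r.end),
            name=f"{ctx}:{direction}", context=ctx, direction=direction,
            score=_q_score(r.q),
        )
        for r in sel.itertuples()
    ]
    return DmrSet(comparison, ctx, direction, intervals)


def _q_score(q: float) -> float:
    """BED score: -10*log10(q), capped at 1000."""
    if q <= 0:
        return 1000.0
    return min(1000.0, -10.0 * math.log10(q))


def write_dmr_bed(table: pd.DataFrame, path) -> int:
    """Write called bins as BED6 (name = context:direction, score = q score)."""
    ctx = table.attrs.get("context")
    sel = table[table["called"]]
    with open(path, "w") as fh:
        for r in sel.itertuples():
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{ctx}:{r.direction}\t"
                f"{_q_score(r.q):.1f}\t.\n"
            )
    return int(len(sel))
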