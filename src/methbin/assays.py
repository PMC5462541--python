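"""Locus-level methylation quantification: windowed averages on call
tables, clone-based (Sanger) bisulfite summaries, and McrBC-qPCR.

Clone-based bisulfite sequencing reads one strand of a PCR amplicon from
individual bacterial colonies, so its cytosine universe is single-stranded;
shotgun bisulfite call tables cover both strands.  McrBC digests methylated
DNA, so a later qPCR amplification (higher Ct) after digestion indicates
more methylation; relative methylation is
``100 - 100 * 2**(Ct_mock - Ct_treated)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTEXTS, MethylomeSample

logger = logging.getLogger(__name__)

__all__ = [
    "QuantRegion",
    "CloneAlignment",
    "QpcrMeasurement",
    "McrbcResult",
    "quantify_region",
    "clone_summary",
    "filter_clones",
    "mcrbc_relative_methylation",
]

# clone call codes
METH, UNMETH, AMBIG = 1, 0, -1


@dataclass(frozen=True)
class QuantRegion:
    """A named window on a target sequence (0-based half-open internally)."""

    name: str
    chrom: str
    start: int
    end: int
    contexts: tuple[str, ...] = CONTEXTS
    strand_scope: str = "both"  # both | plus_only

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region {self.name}: {self.start}-{self.end}")
        if self.strand_scope not in ("both", "plus_only"):
            raise ValueError(f"strand_scope must be both|plus_only")

    @classmethod
    def from_one_based(cls, name, chrom, start1, end1, **kw):
        """Build from 1-based inclusive coordinates as printed in figure
        legends (e.g. a promoter quantified over 282-1036)."""
        return cls(name, chrom, start1 - 1, end1, **kw)


@dataclass
class CloneAlignment:
    """Per-clone methylation calls over an amplicon's cytosines (one strand).

    ``calls`` is (clones x cytosines) with entries 1 methylated,
    0 unmethylated, -1 ambiguous; ``positions`` are 0-based amplicon
    coordinates of the reference cytosines, ``contexts`` their CG/CHG/CHH
    class on the sequenced strand.
    """

    amplicon: str
    positions: np.ndarray
    contexts: np.ndarray
    calls: np.ndarray
    clone_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.contexts = np.asarray(self.contexts, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[1] != len(self.positions):
            raise ValueError("calls must be (n_clones, n_cytosines)")
        if len(self.contexts) != len(self.positions):
            raise ValueError("contexts and positions must be parallel")
        bad = ~np.isin(self.calls, [METH, UNMETH, AMBIG])
        if bad.any():
            raise ValueError("clone calls must be 1 (meth), 0 (unmeth) or -1 (ambiguous)")
        if not self.clone_names:
            self.clone_names = [f"clone{i + 1}" for i in range(self.calls.shape[0])]

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired mock / McrBC-treated qPCR Ct values for one target.

    ``None`` marks "no amplification" in that reaction.
    """

    target: str
    ct_mock: float | None
    ct_treated: float | None

    def __post_init__(self):
        for label, v in (("mock", self.ct_mock), ("treated", self.ct_treated)):
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{self.target}: Ct_{label} must be positive and finite, or None")


@dataclass(frozen=True)
class McrbcResult:
    target: str
    percent: float | None
    flag: str | None = None  # negative | no_amplification_treated | undefined_mock


def quantify_region(
    source: MethylomeSample | CloneAlignment,
    region: QuantRegion,
    min_site_coverage: int = 1,
) -> dict[str, tuple[float | None, int]]:
    """Average percent methylation per context across a window.

    Returns ``{context: (percent or None, n_reference_cytosines)}`` —
    the parenthetical cytosine counts quoted alongside figure bar graphs.
    For call tables the value pools read counts over covered cytosines
    (both strands, or plus only under ``strand_scope='plus_only'``); for
    clone alignments it pools unambiguous clone calls, which are
    single-stranded by nature.
    """
    out: dict[str, tuple[float | None, int]] = {}
    if isinstance(source, MethylomeSample):
        df = source.calls
        sel = df[
            (df["chrom"] == region.chrom)
            & (df["pos"] >= region.start)
            & (df["pos"] < region.end)
        ]
        if region.strand_scope == "plus_only":
            sel = sel[sel["strand"] == "+"]
        for ctx in region.contexts:
            sub = sel[sel["context"] == ctx]
            n_cyt = int(len(sub))
            sub = sub[sub["n"] >= min_site_coverage]
            nsum = int(sub["n"].sum())
            pct = 100.0 * float(sub["m"].sum()) / nsum if nsum > 0 else None
            out[ctx] = (pct, n_cyt)
    elif isinstance(source, CloneAlignment):
        inside = (source.positions >= region.start) & (source.positions < region.end)
        for ctx in region.contexts:
            cols = inside & (source.contexts == ctx)
            n_cyt = int(cols.sum())
            calls = source.calls[:, cols]
            obs = calls != AMBIG
            total = int(obs.sum())
            pct = 100.0 * float((calls == METH).sum()) / total if total > 0 else None
            out[ctx] = (pct, n_cyt)
    else:
        raise TypeError(f"cannot quantify a {type(source).__name__}")
    return out


def clone_summary(clones: CloneAlignment) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cytosine percent methylation and per-clone mean methylation.

    Ambiguous calls are excluded from numerator and denominator.  The
    per-clone means expose the shape of the distribution — a uniform
    half-methylated population versus a bimodal mix of fully methylated
    and fully unmethylated epialleles looks identical in the per-cytosine
    average but very different here.
    """
    if clones.n_clones < 1:
        raise ValueError("need at least one clone")
    obs = clones.calls != AMBIG
    meth = clones.calls == METH
    with np.errstate(invalid="ignore"):
        site_pct = 100.0 * meth.sum(axis=0) / np.where(obs.sum(axis=0) > 0, obs.sum(axis=0), np.nan)
        clone_mean = meth.sum(axis=1) / np.where(obs.sum(axis=1) > 0, obs.sum(axis=1), np.nan)
    per_site = pd.DataFrame(
        {
            "pos": clones.positions,
            "context": clones.contexts,
            "n_observed": obs.sum(axis=0),
            "percent_methylated": site_pct,
        }
    )
    return per_site, clone_mean


def filter_clones(
    clones: CloneAlignment,
    dedup: bool = True,
    nonconversion_window: int = 150,
    nonconversion_chh_frac: float = 0.95,
    background_chh_max: float = 0.20,
    min_chh_sites: int = 5,
) -> tuple[CloneAlignment, list[tuple[str, str]]]:
    """Remove duplicate clones and suspected non-conversion failures.

    Exact-duplicate call patterns collapse to one representative (PCR
    siblings).  A clone is flagged as non-converted when, in some
    ``nonconversion_window``-bp window holding >= ``min_chh_sites`` CHH
    sites, at least ``nonconversion_chh_frac`` of its CHH calls are
    methylated while the across-clone CHH mean there is below
    ``background_chh_max`` — wholesale CHH methylation on an otherwise
    unmethylated stretch is chemistry, not biology.  Clones that are
    entirely ambiguous are dropped.  Returns the filtered alignment and a
    ``(clone_name, reason)`` removal log.
    """
    removed: list[tuple[str, str]] = []
    keep = np.ones(clones.n_clones, dtype=bool)

    all_ambig = (clones.calls == AMBIG).all(axis=1)
    for i in np.flatnonzero(all_ambig):
        keep[i] = False
        removed.append((clones.clone_names[i], "all_ambiguous"))

    if dedup:
        seen: dict[bytes, int] = {}
        for i in range(clones.n_clones):
            if not keep[i]:
                continue
            pat = clones.calls[i].tobytes()
            if pat in seen:
                keep[i] = False
                removed.append(
                    (clones.clone_names[i], f"duplicate_of:{clones.clone_names[seen[pat]]}")
                )
            else:
                seen[pat] = i

    chh_cols = np.flatnonzero(clones.contexts == "CHH")
    if len(chh_cols):
        chh_pos = clones.positions[chh_cols]
        chh_calls = clones.calls[:, chh_cols]
        chh_obs = chh_calls != AMBIG
        with np.errstate(invalid="ignore"):
            col_mean = (chh_calls == METH).sum(axis=0) / np.where(
                chh_obs.sum(axis=0) > 0, chh_obs.sum(axis=0), np.nan
            )
        for w_start in range(0, int(chh_pos.max()) + 1, nonconversion_window):
            in_w = (chh_pos >= w_start) & (chh_pos < w_start + nonconversion_window)
            if in_w.sum() < min_chh_sites:
                continue
            bg = np.nanmean(col_mean[in_w])
            if not np.isfinite(bg) or bg >= background_chh_max:
                continue
            for i in range(clones.n_clones):
                if not keep[i]:
                    continue
                obs_i = chh_obs[i, in_w]
                if obs_i.sum() < min_chh_sites:
                    continue
                frac = (chh_calls[i, in_w] == METH)[obs_i].mean()
                if frac >= nonconversion_chh_frac:
                    keep[i] = False
                    removed.append(
                        (clones.clone_names[i],
                         f"nonconversion:window_{w_start}_chh_frac_{frac:.2f}")
                    )

    if not keep.any():
        raise ValueError("all clones removed by filtering")
    for name, reason in removed:
        logger.info("filter_clones: removed %s (%s)", name, reason)
    kept = CloneAlignment(
        clones.amplicon,
        clones.positions,
        clones.contexts,
        clones.calls[keep],
        [n for n, k in zip(clones.clone_names, keep) if k],
    )
    return kept, removed


def mcrbc_relative_methylation(q: QpcrMeasurement) -> McrbcResult:
    """Relative methylation from a mock/McrBC-digested qPCR pair.

    ``100 - 100 * 2**(Ct_mock - Ct_treated)``: complete digestion delays
    amplification of the treated aliquot, pushing the value toward 100.
    Negative values (treated amplified earlier than mock — assay noise)
    are reported as-is with a ``negative`` flag, not clipped.  No
    amplification of the treated aliquot means complete digestion (100,
    flagged); no amplification of the mock leaves the assay undefined.
    """
    if q.ct_mock is None:
        return McrbcResult(q.target, None, "undefined_mock")
    if q.ct_treated is None:
        return McrbcResult(q.target, 100.0, "no_amplification_treated")
    value = 100.0 - 100.0 * 2.0 ** (q.ct_mock - q.ct_treated)
    flag = "negative" if value < 0 else None
    if flag:
        logger.warning("%s: negative relative methylation %.2f", q.target, value)
    return McrbcResult(q.target, value, flag)
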