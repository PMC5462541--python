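"""Relaxed (clustering-based) conserved-DMR selection.

Requiring a window to be called independently in every comparison is very
stringent; the relaxed route instead (1) unions all per-comparison DMR
windows into master lists, (2) tabulates each window's methylation level in
every sample (3-decimal precision), (3) clusters windows by average-linkage
hierarchical clustering on a 1 - |Pearson r| distance, and (4) keeps the
windows whose methylation moves in the stated direction in *every* mutant
relative to the control mean, without re-imposing effect-size or coverage
cutoffs.  Body-methylated genes — highly variable between individuals —
are filtered out of CG-context selections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .intervals import DmrSet, GenomicInterval, overlap_annotation, sort_intervals
from .io import MethylomeSample

logger = logging.getLogger(__name__)

__all__ = [
    "DmrMatrix",
    "build_master_list",
    "methylation_matrix",
    "cluster_rows",
    "select_concordant",
    "filter_body_methylated",
    "rank_by_mean_difference",
]


@dataclass
class DmrMatrix:
    """DMR-window-by-sample matrix of mean methylation levels.

    ``values`` rows are indexed ``chrom:start-end`` in genomic order and
    parallel ``windows``; entries are fractions in [0, 1] rounded to
    ``decimals`` places, NaN where a window had no covered cytosine.
    """

    values: pd.DataFrame
    windows: list[GenomicInterval]
    context: str | None = None
    direction: str | None = None
    roles: dict[str, str] = field(default_factory=dict)  # sample_id -> control|mutant

    def __post_init__(self):
        if len(self.values) != len(self.windows):
            raise ValueError("values rows and windows must be parallel")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")

    def window_by_id(self, row_id: str) -> GenomicInterval:
        return self.windows[self.values.index.get_loc(row_id)]


def _window_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def build_master_list(sets: list[DmrSet]) -> list[GenomicInterval]:
    """Union of DMR windows across comparisons, deduplicated and sorted.

    All inputs must share context and direction (one master list per
    context x direction, six in a full hyper/hypo x CG/CHG/CHH design).
    """
    if not sets:
        return []
    ctxs = {s.context for s in sets}
    dirs = {s.direction for s in sets}
    if len(ctxs) > 1 or len(dirs) > 1:
        raise ValueError(f"master list inputs mix contexts {ctxs} or directions {dirs}")
    seen = {}
    for s in sets:
        for iv in s.intervals:
            seen.setdefault(iv.key, iv)
    return sort_intervals(seen.values())


def methylation_matrix(
    dmrs: list[GenomicInterval],
    samples: list[MethylomeSample],
    context: str,
    min_site_coverage: int = 4,
    decimals: int = 3,
    roles: dict[str, str] | None = None,
) -> DmrMatrix:
    """Tabulate pooled methylation per (window, sample), rounded.

    Value = sum(m)/sum(n) over the window's context cytosines with
    ``n >= min_site_coverage`` in that sample; NaN when none are covered.
    Rows missing in every sample are dropped (logged).
    """
    dmrs = sort_intervals(dmrs)
    cols = {}
    for sample in samples:
        df = sample.calls
        sel = df[(df["context"] == context) & (df["n"] >= min_site_coverage)]
        vals = np.full(len(dmrs), np.nan)
        for chrom, grp in sel.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(grp["m"].to_numpy())])
            cn = np.concatenate([[0], np.cumsum(grp["n"].to_numpy())])
            for i, iv in enumerate(dmrs):
                if iv.chrom != chrom:
                    continue
                lo = np.searchsorted(pos, iv.start)
                hi = np.searchsorted(pos, iv.end)
                nsum = cn[hi] - cn[lo]
                if nsum > 0:
                    vals[i] = (cm[hi] - cm[lo]) / nsum
        cols[sample.sample_id] = np.round(vals, decimals)
    values = pd.DataFrame(cols, index=[_window_id(iv) for iv in dmrs])
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        logger.info("methylation_matrix: dropping %d all-missing rows", int(all_missing.sum()))
    keep = ~all_missing.to_numpy()
    windows = [iv for iv, k in zip(dmrs, keep) if k]
    roles = roles or {
        s.sample_id: ("mutant" if s.genotype_label == "mutant" else "control")
        for s in samples
    }
    return DmrMatrix(values[keep], windows, context=context, roles=roles)


def _abs_corr_distance(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - |Pearson r| distances between rows; constant rows get
    the maximal distance 1 to everything (logged)."""
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant rows assigned maximal distance", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - np.abs(r)
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return squareform(d, checks=False)


def cluster_rows(matrix: DmrMatrix, method: str = "average"):
    """Hierarchically cluster matrix rows (columns are never clustered).

    Distance is 1 - |Pearson r| between row profiles; linkage is average
    by default.  Rows with any missing value are excluded.  Returns
    ``(Z, row_ids)`` where ``Z`` is a scipy linkage matrix over the kept
    rows and ``row_ids`` lists them in dendrogram leaf order.
    """
    complete = ~matrix.values.isna().any(axis=1)
    X = matrix.values[complete].to_numpy(dtype=float)
    ids = matrix.values.index[complete.to_numpy()]
    if len(X) < 2:
        raise ValueError("clustering needs at least 2 complete rows")
    Z = linkage(_abs_corr_distance(X), method=method)
    order = leaves_list(Z)
    return Z, list(ids[order])


def select_concordant(
    matrix: DmrMatrix,
    mutant_ids: list[str],
    control_ids: list[str],
    direction: str,
    mode: str = "sign",
    n_clusters: int | None = None,
) -> list[GenomicInterval]:
    """Relaxed conserved-DMR selection.

    ``sign`` mode keeps a window iff every mutant value minus the control
    mean carries the sign of ``direction`` — concordant change in all
    mutants, with no magnitude or coverage cutoff.  ``cluster-cut`` mode
    cuts the row dendrogram into ``n_clusters`` flat clusters and keeps
    entire clusters in which every row passes the same sign rule,
    preserving the cluster-selection shape of a manual heatmap workflow.
    Rows with a missing value in any named column are never selected.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be hyper|hypo, got {direction!r}")
    missing_cols = [c for c in (*mutant_ids, *control_ids) if c not in matrix.values.columns]
    if missing_cols:
        raise ValueError(f"matrix lacks columns {missing_cols}")
    vals = matrix.values
    complete = ~vals[list(mutant_ids) + list(control_ids)].isna().any(axis=1)
    ctl_mean = vals[list(control_ids)].mean(axis=1)
    diffs = vals[list(mutant_ids)].sub(ctl_mean, axis=0)
    passes = (diffs > 0).all(axis=1) if direction == "hyper" else (diffs < 0).all(axis=1)
    passes &= complete

    if mode == "sign":
        selected = passes
    elif mode == "cluster-cut":
        Z, _ = cluster_rows(matrix)
        kept_rows = vals.index[(~vals.isna().any(axis=1)).to_numpy()]
        k = n_clusters or max(2, len(kept_rows) // 10)
        flat = fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=kept_rows)
        good_clusters = {
            c for c in np.unique(flat)
            if passes.reindex(labels.index[labels == c]).all()
        }
        selected = pd.Series(False, index=vals.index)
        in_good = labels.index[labels.isin(list(good_clusters))]
        selected[in_good] = True
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = [iv for iv, s in zip(matrix.windows, selected.to_numpy()) if s]
    if not out:
        logger.warning("select_concordant: empty selection (%s, %s)", direction, mode)
    return out


def filter_body_methylated(
    windows: list[GenomicInterval],
    body_meth_genes: list[GenomicInterval],
    contexts: tuple[str, ...] = ("CG",),
) -> list[GenomicInterval]:
    """Drop windows overlapping (>= 1 bp) a body-methylated gene.

    Applied to CG-context windows by default: gene-body CG methylation is
    naturally variable between individuals, so overlapping windows are
    unreliable evidence of a mutant effect.  Windows of other contexts (or
    with no context tag) pass through untouched.
    """
    in_scope = [w for w in windows if w.context in contexts]
    out_scope = [w for w in windows if w.context not in contexts]
    kept = overlap_annotation(in_scope, body_meth_genes, mode="not_element_of", min_overlap=1)
    logger.info(
        "filter_body_methylated: removed %d of %d in-scope windows",
        len(in_scope) - len(kept), len(in_scope),
    )
    return sort_intervals(kept + out_scope)


def rank_by_mean_difference(
    matrix: DmrMatrix,
    mutant_ids: list[str],
    control_ids: list[str],
) -> pd.DataFrame:
    """Order windows by mean(mutants) - mean(controls), largest first.

    Ties break by genomic coordinate.  Rows with a missing value in any
    named column are excluded (logged).  Returns the matrix values plus a
    ``score`` column, in rank order.
    """
    vals = matrix.values
    sub = vals[list(mutant_ids) + list(control_ids)]
    complete = ~sub.isna().any(axis=1)
    if (~complete).any():
        logger.info("rank_by_mean_difference: excluding %d incomplete rows", int((~complete).sum()))
    score = sub[list(mutant_ids)].mean(axis=1) - sub[list(control_ids)].mean(axis=1)
    coords = pd.DataFrame(
        {"chrom": [iv.chrom for iv in matrix.windows],
         "start": [iv.start for iv in matrix.windows]},
        index=vals.index,
    )
    out = vals[complete].copy()
    out["score"] = score[complete]
    out["_chrom"] = coords["chrom"][complete]
    out["_start"] = coords["start"][complete]
    out = out.sort_values(["score", "_chrom", "_start"], ascending=[False, True, True])
    return out.drop(columns=["_chrom", "_start"])
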