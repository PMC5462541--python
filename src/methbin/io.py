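"""Per-cytosine methylation call tables, browser tracks, and summary ratios.

The central container is :class:`MethylomeSample`: one sample's per-cytosine
calls as a pandas DataFrame with columns ``chrom, pos, strand, context, m, n``
(0-based positions; ``m`` methylated reads out of ``n`` total).  Two table
dialects are supported:

``methbin``
    Native tab-separated table with a header and 0-based positions.
``cgmap``
    CGmap-style headerless table (chrom, nucleotide, 1-based position,
    context, dinucleotide, level, mC, total) as emitted by common bisulfite
    callers; the nucleotide column (C/G) encodes the strand.

Readers are gzip-transparent (by file extension, via pandas).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "m", "n"]

__all__ = [
    "CytosineCall",
    "MethylomeSample",
    "CallTableError",
    "read_calls",
    "write_calls",
    "export_track",
    "global_methylation",
    "estimate_conversion",
]


class CallTableError(ValueError):
    """Malformed call-table content, reported with line numbers."""


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine's methylation evidence: m methylated of n total reads."""

    chrom: str
    pos: int
    strand: str
    context: str
    m: int
    n: int

    def __post_init__(self):
        if not 0 <= self.m <= self.n:
            raise ValueError(f"need 0 <= m <= n, got m={self.m}, n={self.n}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def level(self) -> float | None:
        return self.m / self.n if self.n else None


@dataclass
class MethylomeSample:
    """A sample's complete per-cytosine call set plus metadata.

    ``calls`` is sorted by (chrom, pos, strand) and unique on that key.
    """

    sample_id: str
    calls: pd.DataFrame
    genotype_label: str = "control"
    replicate_tag: str = ""
    provenance: str = ""

    def __post_init__(self):
        df = self.calls
        missing = [c for c in CALL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"calls table missing columns {missing}")
        df = df[CALL_COLUMNS].copy()
        if (df["m"] > df["n"]).any() or (df["m"] < 0).any():
            bad = int((df["m"] > df["n"]).sum() + (df["m"] < 0).sum())
            raise ValueError(f"{bad} calls violate 0 <= m <= n")
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) keys in calls")
        self.calls = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.calls)

    def subset(self, regions: Iterable[GenomicInterval]) -> pd.DataFrame:
        """Calls falling inside any of the given intervals."""
        df = self.calls
        mask = np.zeros(len(df), dtype=bool)
        pos = df["pos"].to_numpy()
        chroms = df["chrom"].to_numpy()
        for iv in regions:
            mask |= (chroms == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
        return df[mask]


def read_calls(
    path,
    dialect: str = "methbin",
    sample_id: str | None = None,
    genotype_label: str = "control",
    replicate_tag: str = "",
) -> MethylomeSample:
    """Read a per-cytosine call table; see module docstring for dialects."""
    sid = sample_id or str(path)
    if dialect == "methbin":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = [c for c in CALL_COLUMNS if c not in df.columns]
        if missing:
            raise CallTableError(f"{path}: missing columns {missing}")
        offset = 2  # header + 1-based file lines
    elif dialect == "cgmap":
        raw = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "nuc", "pos1", "context", "dinuc", "level", "m", "n"],
            dtype={"chrom": str, "nuc": str, "context": str},
        )
        bad_nuc = ~raw["nuc"].isin(["C", "G"])
        if bad_nuc.any():
            lines = (raw.index[bad_nuc] + 1).tolist()[:5]
            raise CallTableError(f"{path}: non-C/G nucleotide column at lines {lines}")
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["pos1"].astype(np.int64) - 1,  # 1-based on disk
                "strand": np.where(raw["nuc"] == "C", "+", "-"),
                "context": raw["context"],
                "m": raw["m"].astype(np.int64),
                "n": raw["n"].astype(np.int64),
            }
        )
        offset = 1
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        lines = (df.index[bad_ctx] + offset).tolist()[:5]
        raise CallTableError(f"{path}: unknown context token at lines {lines}")
    bad_mn = (df["m"] > df["n"]) | (df["m"] < 0) | (df["n"] < 0)
    if bad_mn.any():
        lines = (df.index[bad_mn] + offset).tolist()[:5]
        raise CallTableError(f"{path}: m > n (or negative counts) at lines {lines}")
    df["pos"] = df["pos"].astype(np.int64)
    df["m"] = df["m"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return MethylomeSample(sid, df, genotype_label=genotype_label, replicate_tag=replicate_tag)


def write_calls(sample: MethylomeSample, path, dialect: str = "methbin") -> None:
    """Write a call table; ``methbin`` round-trips losslessly."""
    df = sample.calls
    if dialect == "methbin":
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "cgmap":
        with np.errstate(invalid="ignore"):
            level = np.where(df["n"] > 0, df["m"] / df["n"].replace(0, 1), np.nan)
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "nuc": np.where(df["strand"] == "+", "C", "G"),
                "pos1": df["pos"] + 1,
                "context": df["context"],
                "dinuc": "--",
                "level": np.round(level, 6),
                "m": df["m"],
                "n": df["n"],
            }
        )
        out.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def export_track(
    sample: MethylomeSample,
    context: str,
    path,
    min_coverage: int = 4,
    fmt: str = "bedgraph",
) -> int:
    """Export a percent-methylation browser track for one context.

    Only cytosines with ``n >= min_coverage`` are emitted, as percent
    (0-100).  bedGraph is 0-based half-open; wiggle (variableStep) is
    1-based.  Returns the number of records written; an empty track is
    valid but warns.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    df = sample.calls
    sel = df[(df["context"] == context) & (df["n"] >= min_coverage)]
    pct = 100.0 * sel["m"].to_numpy() / sel["n"].to_numpy() if len(sel) else np.empty(0)
    with open(path, "w") as fh:
        name = f"{sample.sample_id}_{context}"
        if fmt == "bedgraph":
            fh.write(f'track type=bedGraph name="{name}"\n')
            for (chrom, pos), v in zip(zip(sel["chrom"], sel["pos"]), pct):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:g}\n")
        elif fmt == "wig":
            fh.write(f'track type=wiggle_0 name="{name}"\n')
            cur = None
            for (chrom, pos), v in zip(zip(sel["chrom"], sel["pos"]), pct):
                if chrom != cur:
                    fh.write(f"variableStep chrom={chrom}\n")
                    cur = chrom
                fh.write(f"{pos + 1}\t{v:g}\n")
        else:
            raise ValueError(f"unknown track format {fmt!r}")
    if len(sel) == 0:
        warnings.warn(
            f"{sample.sample_id}/{context}: no site passes coverage >= {min_coverage}; "
            "empty track written",
            stacklevel=2,
        )
    return int(len(sel))


def global_methylation(
    sample: MethylomeSample, min_coverage: int = 4
) -> dict[str, float | None]:
    """Pooled genome-wide methylation fraction per context.

    Per context: sum(m) / sum(n) over calls with ``n >= min_coverage``.
    A context with no covered reads is reported as None (undefined), not 0.
    """
    if len(sample) == 0:
        raise ValueError("empty sample")
    df = sample.calls[sample.calls["n"] >= min_coverage]
    out: dict[str, float | None] = {}
    for ctx in CONTEXTS:
        sub = df[df["context"] == ctx]
        nsum = int(sub["n"].sum())
        out[ctx] = float(sub["m"].sum()) / nsum if nsum > 0 else None
    return out


def estimate_conversion(
    sample: MethylomeSample,
    unmethylated_regions: Iterable[GenomicInterval],
    min_sites: int = 100,
    min_coverage: int = 1,
) -> float:
    """Bisulfite conversion rate from designated unmethylated regions.

    Pools all contexts over covered cytosines inside the regions and returns
    ``1 - sum(m)/sum(n)``: any apparent methylation there is attributed to
    failed conversion.  Which regions count as unmethylated is the caller's
    convention (e.g. a chloroplast, a spike-in, or known unmethylated
    compartments of a simulation).
    """
    sub = sample.subset(unmethylated_regions)
    sub = sub[sub["n"] >= min_coverage]
    if len(sub) < min_sites:
        raise ValueError(
            f"conversion estimate needs >= {min_sites} covered cytosines in the "
            f"designated regions; found {len(sub)}"
        )
    return 1.0 - float(sub["m"].sum()) / float(sub["n"].sum())
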