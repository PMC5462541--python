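"""Synthetic whole-genome bisulfite methylome generator.

Emulates the data a paired mutant/control WGBS study produces, so the DMR
pipeline can be exercised end to end without external data:

* a random reference genome partitioned into compartments with distinct
  methylation regimes — TE-like sequence heavily methylated in all three
  contexts, gene bodies methylated exclusively at CG sites, and
  unmethylated genes;
* per-sample per-cytosine read counts: coverage is Poisson with a target
  mean (~30x), and the observed methylated count is Binomial with success
  probability ``p + (1 - p) * (1 - c)`` where ``c`` is the bisulfite
  conversion rate — incomplete conversion inflates apparent methylation of
  unmethylated cytosines;
* planted effects: differentially methylated regions shared by every
  mutant, and replicate-private "hypervariable" regions that mimic the
  natural methylation variation seen even among siblings.

Both strands are simulated and recorded separately; symmetric CG sites are
not merged, matching per-cytosine caller output.  Coordinates are 0-based,
half-open.  All randomness is seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, sort_intervals, write_bed
from .io import CONTEXTS, MethylomeSample

logger = logging.getLogger(__name__)

COMPARTMENT_CLASSES = ("TE_like", "gene_body_CG", "unmethylated")

#: Default true methylation probabilities (p_CG, p_CHG, p_CHH) per class.
#: TE-like values follow typical plant heterochromatin (dense CG/CHG, low
#: but non-zero CHH); gene-body methylation is CG-only by definition.
DEFAULT_BASELINES: dict[str, tuple[float, float, float]] = {
    "TE_like": (0.85, 0.65, 0.10),
    "gene_body_CG": (0.60, 0.0, 0.0),
    "unmethylated": (0.0, 0.0, 0.0),
}

_CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS)}

__all__ = [
    "COMPARTMENT_CLASSES",
    "DEFAULT_BASELINES",
    "Compartment",
    "ReferenceModel",
    "SampleProfile",
    "PlantedDmr",
    "HypervariableRegion",
    "SyntheticTruth",
    "DmrRequest",
    "build_reference",
    "plant_dmrs",
    "simulate_sample",
    "cytosine_contexts",
]


@dataclass(frozen=True)
class Compartment:
    chrom: str
    start: int
    end: int
    cls: str

    def __post_init__(self):
        if self.cls not in COMPARTMENT_CLASSES:
            raise ValueError(f"unknown compartment class {self.cls!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid compartment {self.chrom}:{self.start}-{self.end}")


def cytosine_contexts(sequence: str):
    """Locate every cytosine on both strands and classify its context.

    Returns ``(pos, strand, context_idx)`` arrays: positions of C on the
    plus strand and G on the minus strand, with context CG / CHG / CHH
    (indices 0/1/2) read 5'->3' on the cytosine's own strand.  Cytosines too
    close to a sequence end for a full trinucleotide default to CHH.
    """
    b = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    L = len(b)
    is_c = b == ord("C")
    is_g = b == ord("G")

    pc = np.flatnonzero(is_c)
    ctx_p = np.full(len(pc), 2, dtype=np.int8)  # CHH unless shown otherwise
    nxt = pc + 1
    cg = (nxt < L) & is_g[np.minimum(nxt, L - 1)]
    ctx_p[cg] = 0
    nxt2 = pc + 2
    chg = ~cg & (nxt2 < L) & is_g[np.minimum(nxt2, L - 1)]
    ctx_p[chg] = 1

    pg = np.flatnonzero(is_g)
    ctx_m = np.full(len(pg), 2, dtype=np.int8)
    prv = pg - 1
    cg_m = (prv >= 0) & is_c[np.maximum(prv, 0)]
    ctx_m[cg_m] = 0
    prv2 = pg - 2
    chg_m = ~cg_m & (prv2 >= 0) & is_c[np.maximum(prv2, 0)]
    ctx_m[chg_m] = 1

    pos = np.concatenate([pc, pg])
    strand = np.concatenate([np.zeros(len(pc), np.int8), np.ones(len(pg), np.int8)])
    ctx = np.concatenate([ctx_p, ctx_m])
    order = np.argsort(pos, kind="stable")
    return pos[order], strand[order], ctx[order]


@dataclass
class ReferenceModel:
    """A synthetic reference genome with annotated methylation compartments."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    compartments: list[Compartment]
    _ctx_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for chrom in self.chrom_names:
            if len(self.sequences[chrom]) != self.chrom_lengths[chrom]:
                raise ValueError(f"{chrom}: sequence length != declared length")
        by_chrom: dict[str, list[Compartment]] = {}
        for cp in self.compartments:
            if cp.chrom not in self.chrom_lengths:
                raise ValueError(f"compartment on unknown chromosome {cp.chrom}")
            if cp.end > self.chrom_lengths[cp.chrom]:
                raise ValueError(f"compartment {cp} exceeds chromosome bounds")
            by_chrom.setdefault(cp.chrom, []).append(cp)
        for chrom, cps in by_chrom.items():
            cps.sort(key=lambda c: c.start)
            for a, b in zip(cps, cps[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping compartments on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    def contexts(self, chrom: str):
        """Cached (pos, strand, context_idx) arrays for one chromosome."""
        if chrom not in self._ctx_cache:
            self._ctx_cache[chrom] = cytosine_contexts(self.sequences[chrom])
        return self._ctx_cache[chrom]

    def _compartment_arrays(self, chrom: str):
        key = ("__cparr__", chrom)
        if key not in self._ctx_cache:
            cps = sorted(
                (cp for cp in self.compartments if cp.chrom == chrom),
                key=lambda c: c.start,
            )
            self._ctx_cache[key] = (
                np.array([c.start for c in cps], dtype=np.int64),
                np.array([c.end for c in cps], dtype=np.int64),
                np.array([COMPARTMENT_CLASSES.index(c.cls) for c in cps], dtype=np.int8),
            )
        return self._ctx_cache[key]

    def compartment_classes_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Class index per position (COMPARTMENT_CLASSES order).

        Positions outside every compartment fall back to 'unmethylated',
        the declared default background.
        """
        starts, ends, cls = self._compartment_arrays(chrom)
        default = COMPARTMENT_CLASSES.index("unmethylated")
        out = np.full(len(pos), default, dtype=np.int8)
        if len(starts) == 0:
            return out
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        out[inside] = cls[idx[inside]]
        return out

    def compartments_of_class(self, cls: str) -> list[Compartment]:
        return [cp for cp in self.compartments if cp.cls == cls]

    def compartment_intervals(self, cls: str | None = None) -> list[GenomicInterval]:
        return sort_intervals(
            GenomicInterval(cp.chrom, cp.start, cp.end, name=cp.cls)
            for cp in self.compartments
            if cls is None or cp.cls == cls
        )

    def context_counts(self) -> pd.DataFrame:
        """Cytosine counts per compartment class and context (both strands)."""
        rows = []
        for chrom in self.chrom_names:
            pos, _, ctx = self.contexts(chrom)
            cls = self.compartment_classes_at(chrom, pos)
            for ci, cname in enumerate(COMPARTMENT_CLASSES):
                for xi, xname in enumerate(CONTEXTS):
                    rows.append(
                        {"chrom": chrom, "class": cname, "context": xname,
                         "n_cytosines": int(((cls == ci) & (ctx == xi)).sum())}
                    )
        return pd.DataFrame(rows)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[c]), id=c, description="")
            for c in self.chrom_names
        ]
        SeqIO.write(records, path, "fasta")

    def compartments_to_bed(self, path) -> None:
        write_bed(self.compartment_intervals(), path)


def build_reference(
    chrom_lengths: Mapping[str, int],
    seed: int,
    compartment_fractions: Mapping[str, float] | None = None,
    block_size: int = 2000,
    gc_content: float = 0.36,
    compartments: Sequence[Compartment] | None = None,
) -> ReferenceModel:
    """Generate a seeded random reference with annotated compartments.

    Chromosomes are i.i.d. sequences at the given GC content.  Unless
    explicit ``compartments`` are passed, each chromosome is tiled into
    ``block_size``-bp blocks and every block is assigned a class by drawing
    from ``compartment_fractions`` (any unassigned mass is 'unmethylated').
    """
    for chrom, L in chrom_lengths.items():
        if L < 10_000:
            raise ValueError(f"{chrom}: chromosome length must be >= 10000 bp (got {L})")
    fractions = dict(compartment_fractions or {"TE_like": 0.2, "gene_body_CG": 0.3})
    unknown = set(fractions) - set(COMPARTMENT_CLASSES)
    if unknown:
        raise ValueError(f"unknown compartment classes {unknown}")
    tot = sum(fractions.values())
    if tot > 1 + 1e-9:
        raise ValueError(f"compartment fractions sum to {tot:.3f} > 1")
    fractions["unmethylated"] = fractions.get("unmethylated", 0.0) + (1.0 - tot)

    rng = np.random.default_rng(np.random.SeedSequence([0xB15, int(seed)]))
    at = (1 - gc_content) / 2
    gc = gc_content / 2
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, str] = {}
    names = list(chrom_lengths)
    for chrom in names:
        L = chrom_lengths[chrom]
        draw = rng.choice(bases, size=L, p=[at, gc, gc, at])
        seqs[chrom] = draw.tobytes().decode("ascii")

    if compartments is None:
        classes = list(fractions)
        probs = np.array([fractions[c] for c in classes])
        probs = probs / probs.sum()
        compartments = []
        for chrom in names:
            L = chrom_lengths[chrom]
            starts = np.arange(0, L, block_size)
            picks = rng.choice(len(classes), size=len(starts), p=probs)
            for s, k in zip(starts, picks):
                compartments.append(
                    Compartment(chrom, int(s), int(min(s + block_size, L)), classes[k])
                )

    ref = ReferenceModel(names, dict(chrom_lengths), seqs, list(compartments))
    logger.info(
        "build_reference: %d chromosomes, %d bp, %d compartments",
        len(names), sum(chrom_lengths.values()), len(ref.compartments),
    )
    return ref


@dataclass
class SampleProfile:
    """Generative parameters for one sequenced sample."""

    sample_id: str
    genotype_label: str  # "control" | "mutant"
    replicate_tag: str = ""
    mean_coverage: float = 30.0
    conversion_rate: float = 0.975
    baseline_methylation: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must be in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.genotype_label not in ("control", "mutant"):
            raise ValueError(f"genotype_label must be control|mutant, got {self.genotype_label!r}")
        for cls, ps in self.baseline_methylation.items():
            if cls not in COMPARTMENT_CLASSES:
                raise ValueError(f"unknown compartment class {cls!r}")
            if any(not 0.0 <= p <= 1.0 for p in ps):
                raise ValueError(f"baseline probabilities for {cls} outside [0, 1]")


@dataclass(frozen=True)
class PlantedDmr:
    chrom: str
    start: int
    end: int
    context: str
    direction: str  # hyper | hypo, mutant relative to control
    delta: float
    affected_sample_ids: tuple[str, ...]


@dataclass(frozen=True)
class HypervariableRegion:
    chrom: str
    start: int
    end: int
    context: str
    direction: str
    deltas: Mapping[str, float]  # per affected sample


@dataclass
class SyntheticTruth:
    """Ground truth for one simulation: what was planted, and where."""

    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    hypervariable_regions: list[HypervariableRegion] = field(default_factory=list)
    compartment_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )

    def shared_dmr_intervals(self, context: str | None = None) -> list[GenomicInterval]:
        return sort_intervals(
            GenomicInterval(d.chrom, d.start, d.end, context=d.context, direction=d.direction)
            for d in self.planted_dmrs
            if context is None or d.context == context
        )

    def hypervariable_intervals(self, context: str | None = None) -> list[GenomicInterval]:
        return sort_intervals(
            GenomicInterval(h.chrom, h.start, h.end, context=h.context, direction=h.direction)
            for h in self.hypervariable_regions
            if context is None or h.context == context
        )

    def to_bed(self, path, which: str = "shared") -> None:
        if which == "shared":
            write_bed(self.shared_dmr_intervals(), path)
        elif which == "hypervariable":
            write_bed(self.hypervariable_intervals(), path)
        else:
            raise ValueError(f"unknown truth subset {which!r}")

    def regions_affecting(self, sample_id: str):
        """(chrom, start, end, context_idx, signed delta) for one sample."""
        out = []
        for d in self.planted_dmrs:
            if sample_id in d.affected_sample_ids:
                sgn = 1.0 if d.direction == "hyper" else -1.0
                out.append((d.chrom, d.start, d.end, _CTX_INDEX[d.context], sgn * d.delta))
        for h in self.hypervariable_regions:
            if sample_id in h.deltas:
                sgn = 1.0 if h.direction == "hyper" else -1.0
                out.append((h.chrom, h.start, h.end, _CTX_INDEX[h.context], sgn * h.deltas[sample_id]))
        return out


@dataclass(frozen=True)
class DmrRequest:
    """A batch of regions to plant with a common effect.

    ``affected`` is a tuple of sample ids, or the sentinel ``"all_mutants"``.
    Requests affecting every mutant are recorded as shared DMRs; anything
    narrower is bookkept as hypervariable (replicate-private natural
    variation).  ``delta_jitter`` (0 disables) draws each affected sample's
    delta uniformly from ``[delta * (1 - jitter), delta]``.
    """

    count: int
    context: str
    direction: str  # hyper | hypo
    delta: float
    width: int = 100
    affected: tuple[str, ...] | str = "all_mutants"
    compartment_class: str = "unmethylated"
    delta_jitter: float = 0.0

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper|hypo, got {self.direction!r}")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must be in (0, 1]")
        if self.width <= 0 or self.count <= 0:
            raise ValueError("count and width must be positive")


def plant_dmrs(
    requests: Sequence[DmrRequest],
    ref: ReferenceModel,
    profiles: Sequence[SampleProfile],
    seed: int,
    min_context_sites: int = 4,
    align: int = 100,
) -> SyntheticTruth:
    """Place requested effect regions on the reference, without overlap.

    Candidate windows are ``align``-grid-aligned spans inside compartments
    of the requested class that contain at least ``min_context_sites``
    cytosines of the requested context (both strands) per 100 bp — so a
    planted region is eligible for bin-based calling by construction.
    Deltas are validated against the class baseline so true probabilities
    stay inside [0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([0xD318, int(seed)]))
    mutants = tuple(p.sample_id for p in profiles if p.genotype_label == "mutant")
    all_ids = {p.sample_id for p in profiles}
    baselines = profiles[0].baseline_methylation if profiles else DEFAULT_BASELINES

    truth = SyntheticTruth(compartment_params=dict(baselines))
    occupied: set[tuple[str, int]] = set()  # (chrom, grid slot)

    for req in requests:
        affected = mutants if req.affected == "all_mutants" else tuple(req.affected)
        if not affected:
            raise ValueError("request affects no samples (no mutants in roster?)")
        unknown = set(affected) - all_ids
        if unknown:
            raise ValueError(f"request names unknown samples {unknown}")
        base_p = baselines[req.compartment_class][_CTX_INDEX[req.context]]
        sgn = 1.0 if req.direction == "hyper" else -1.0
        if not 0.0 <= base_p + sgn * req.delta <= 1.0:
            raise ValueError(
                f"delta {req.delta} ({req.direction}) pushes {req.compartment_class} "
                f"{req.context} baseline {base_p} outside [0, 1]"
            )

        candidates = []
        for cp in ref.compartments_of_class(req.compartment_class):
            pos, _, ctx = ref.contexts(cp.chrom)
            ctx_pos = pos[(ctx == _CTX_INDEX[req.context]) & (pos >= cp.start) & (pos < cp.end)]
            first = -(-cp.start // align) * align
            for s in range(first, cp.end - req.width + 1, align):
                lo = np.searchsorted(ctx_pos, s)
                hi = np.searchsorted(ctx_pos, s + req.width)
                needed = min_context_sites * max(1, req.width // 100)
                if hi - lo >= needed:
                    candidates.append((cp.chrom, s))
        slots_per = -(-req.width // align)
        free = [
            c for c in candidates
            if all((c[0], c[1] + k * align) not in occupied for k in range(slots_per))
        ]
        if len(free) < req.count:
            raise ValueError(
                f"cannot place {req.count} x {req.width} bp {req.context} regions in "
                f"{req.compartment_class} compartments; only {len(free)} candidate "
                "windows remain unoccupied"
            )
        picks = rng.choice(len(free), size=req.count, replace=False)
        for i in sorted(picks):
            chrom, s = free[i]
            if any((chrom, s + k * align) in occupied for k in range(slots_per)):
                continue  # earlier pick in this batch took an overlapping slot
            for k in range(slots_per):
                occupied.add((chrom, s + k * align))
            if set(affected) == set(mutants):
                truth.planted_dmrs.append(
                    PlantedDmr(chrom, s, s + req.width, req.context, req.direction,
                               req.delta, tuple(sorted(affected)))
                )
            else:
                deltas = {}
                for sid in affected:
                    d = req.delta
                    if req.delta_jitter > 0:
                        d = float(rng.uniform(req.delta * (1 - req.delta_jitter), req.delta))
                    deltas[sid] = d
                truth.hypervariable_regions.append(
                    HypervariableRegion(chrom, s, s + req.width, req.context,
                                        req.direction, deltas)
                )
    placed = len(truth.planted_dmrs) + len(truth.hypervariable_regions)
    want = sum(r.count for r in requests)
    if placed < want:
        raise ValueError(f"placed only {placed}/{want} requested regions (grid collisions)")
    logger.info(
        "plant_dmrs: %d shared DMRs, %d hypervariable regions",
        len(truth.planted_dmrs), len(truth.hypervariable_regions),
    )
    return truth


def simulate_sample(
    ref: ReferenceModel,
    profile: SampleProfile,
    truth: SyntheticTruth | None = None,
) -> MethylomeSample:
    """Draw one sample's per-cytosine counts from the generative model.

    Per cytosine: true probability ``p`` from the compartment baseline,
    shifted by any planted region covering it that affects this sample;
    coverage ``n ~ Poisson(mean_coverage)``; observed methylated count
    ``m ~ Binomial(n, p + (1 - p) * (1 - c))``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x5E0, int(profile.seed)]))
    base = np.zeros((len(COMPARTMENT_CLASSES), len(CONTEXTS)))
    for ci, cls in enumerate(COMPARTMENT_CLASSES):
        base[ci] = profile.baseline_methylation.get(cls, DEFAULT_BASELINES[cls])
    mods = truth.regions_affecting(profile.sample_id) if truth is not None else []

    frames = []
    for chrom in ref.chrom_names:
        pos, strand, ctx = ref.contexts(chrom)
        cls = ref.compartment_classes_at(chrom, pos)
        p = base[cls, ctx]
        for (mchrom, s, e, mctx, sdelta) in mods:
            if mchrom != chrom:
                continue
            sel = (pos >= s) & (pos < e) & (ctx == mctx)
            p = np.where(sel, np.clip(p + sdelta, 0.0, 1.0), p)
        n = rng.poisson(profile.mean_coverage, size=len(pos))
        p_obs = p + (1.0 - p) * (1.0 - profile.conversion_rate)
        m = rng.binomial(n, p_obs)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "strand": np.where(strand == 0, "+", "-"),
                    "context": np.array(CONTEXTS, dtype=object)[ctx],
                    "m": m.astype(np.int64),
                    "n": n.astype(np.int64),
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    return MethylomeSample(
        profile.sample_id,
        calls,
        genotype_label=profile.genotype_label,
        replicate_tag=profile.replicate_tag,
        provenance=f"simulated: coverage={profile.mean_coverage}, c={profile.conversion_rate}, seed={profile.seed}",
    )
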