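"""Within-genome homeolog (WGD paralogon) detection.

Starting from a table of within-genome paralogous gene pairs with an
opaque homology percentage, the procedure is: (1) drop pairs below a
50% homology floor; (2) per source gene, rank its matches by homology
and keep only those within a 5% tolerance of the top-ranked match
(relative by default: >= 0.95 x top; an absolute 5-percentage-point
mode is available because either reading is defensible); (3) chain the
retained pairs along each source chromosome's gene order into blocks of
>= 2 contiguous loci pointing at one target chromosome, ignoring
singletons; (4) summarize blocks into a chromosome pairing report,
classifying pairs as largely conserved (one dominant target) or mosaic.

Tandem duplicates (source chromosome == target chromosome) are not
homeology evidence and are excluded from block building by default,
but counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .types import HomeologBlock, ParalogPair

log = logging.getLogger("synqtl")


def prune_low_homology(pairs: Sequence[ParalogPair], floor_pct: float = 50.0) -> list[ParalogPair]:
    """Remove pairs with homology strictly below the floor (a pair at
    exactly the floor is retained)."""
    if not (0 <= floor_pct <= 100):
        raise ValueError("floor_pct outside [0, 100]")
    kept = [p for p in pairs if p.homology_pct >= floor_pct]
    log.info("prune_low_homology: %d in, %d kept (floor %g%%)", len(pairs), len(kept), floor_pct)
    return kept


def rank_and_prune_tolerance(
    pairs: Sequence[ParalogPair],
    tolerance_frac: float = 0.05,
    mode: str = "relative",
) -> list[ParalogPair]:
    """Per source gene, keep only matches within the tolerance of its
    top-ranked (highest-homology) match.

    relative mode: keep pairs with homology >= (1 - tol) * top.
    absolute mode: keep pairs with homology >= top - 100 * tol points.
    The top-ranked match itself always survives.
    """
    if not (0 <= tolerance_frac <= 1):
        raise ValueError("tolerance_frac outside [0, 1]")
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be relative or absolute")
    best: dict[str, float] = {}
    for p in pairs:
        if p.homology_pct > best.get(p.gene_a, -1.0):
            best[p.gene_a] = p.homology_pct
    kept = []
    for p in pairs:
        top = best[p.gene_a]
        cutoff = (1.0 - tolerance_frac) * top if mode == "relative" else top - 100.0 * tolerance_frac
        if p.homology_pct >= cutoff:
            kept.append(p)
    log.info(
        "rank_and_prune_tolerance: %d in, %d kept (tol %g, %s)",
        len(pairs), len(kept), tolerance_frac, mode,
    )
    return kept


def build_homeolog_blocks(
    retained_pairs: Sequence[ParalogPair],
    gene_order: Mapping[str, Sequence[str]],
    min_block: int = 2,
    max_gap: int = 0,
    include_self: bool = False,
) -> list[HomeologBlock]:
    """Chain retained pairs into homeolog blocks along each source
    chromosome's gene order.

    Contiguity is over source genes carrying >= 1 retained pair; maximal
    runs of >= min_block consecutive such genes whose pairs point at one
    target chromosome become blocks, singletons are ignored.  A gene
    pairing with two targets can sit in one block per target.
    """
    pos_in_order: dict[str, dict[str, int]] = {
        chrom: {g: i for i, g in enumerate(genes)} for chrom, genes in gene_order.items()
    }
    by_source: dict[str, dict[str, list[ParalogPair]]] = {}
    n_self = 0
    for p in retained_pairs:
        if p.chrom_a == p.chrom_b and not include_self:
            n_self += 1
            continue
        if p.chrom_a not in pos_in_order or p.gene_a not in pos_in_order[p.chrom_a]:
            raise KeyError(f"gene {p.gene_a!r} (chrom {p.chrom_a!r}) missing from gene_order")
        by_source.setdefault(p.chrom_a, {}).setdefault(p.gene_a, []).append(p)
    if n_self:
        log.info("build_homeolog_blocks: %d same-chromosome (tandem) pairs excluded", n_self)

    blocks: list[HomeologBlock] = []
    for chrom in sorted(by_source):
        gene_pairs = by_source[chrom]
        # source genes with >= 1 retained pair, in chromosome order
        loci = sorted(gene_pairs, key=lambda g: pos_in_order[chrom][g])
        targets = sorted({p.chrom_b for ps in gene_pairs.values() for p in ps})
        for target in targets:
            flags = [any(p.chrom_b == target for p in gene_pairs[g]) for g in loci]
            for run in _maximal_runs(flags, max_gap):
                if len(run) < min_block:
                    continue
                members: list[ParalogPair] = []
                for i in run:
                    members.extend(
                        sorted(
                            (p for p in gene_pairs[loci[i]] if p.chrom_b == target),
                            key=lambda p: (p.pos_b, p.gene_b),
                        )
                    )
                members.sort(key=lambda p: p.pos_a)
                blocks.append(
                    HomeologBlock(
                        source_chrom=chrom,
                        target_chrom=target,
                        source_span=(min(m.pos_a for m in members), max(m.pos_a for m in members)),
                        members=tuple(members),
                    )
                )
    return blocks


def _maximal_runs(flags: Sequence[bool], max_gap: int) -> list[list[int]]:
    runs: list[list[int]] = []
    current: list[int] = []
    gap = 0
    for i, f in enumerate(flags):
        if f:
            if current and gap > max_gap:
                runs.append(current)
                current = []
            current.append(i)
            gap = 0
        else:
            gap += 1
    if current:
        runs.append(current)
    return runs


@dataclass(frozen=True)
class ChromPairing:
    source_chrom: str
    targets: tuple  # (target, member_count, bp_span) ranked
    classification: str  # 'conserved' | 'mosaic'

    @property
    def dominant_target(self) -> Optional[str]:
        return self.targets[0][0] if self.targets else None


def homeolog_pairs(
    blocks: Sequence[HomeologBlock], dominance_frac: float = 0.5
) -> list[ChromPairing]:
    """Per source chromosome, rank target chromosomes by total member
    count (ties broken by total bp span) and classify the pairing as
    'conserved' when one target holds >= dominance_frac of members,
    else 'mosaic'."""
    per_source: dict[str, dict[str, list[HomeologBlock]]] = {}
    for b in blocks:
        per_source.setdefault(b.source_chrom, {}).setdefault(b.target_chrom, []).append(b)
    out = []
    for chrom in sorted(per_source):
        stats = []
        for target, bs in per_source[chrom].items():
            members = sum(b.size for b in bs)
            span = sum(b.source_span[1] - b.source_span[0] for b in bs)
            stats.append((target, members, span))
        stats.sort(key=lambda t: (-t[1], -t[2], t[0]))
        total = sum(m for _, m, _ in stats)
        conserved = bool(stats) and stats[0][1] >= dominance_frac * total
        out.append(
            ChromPairing(
                source_chrom=chrom,
                targets=tuple(stats),
                classification="conserved" if conserved else "mosaic",
            )
        )
    return out


def detect_homeologs(
    pairs: Sequence[ParalogPair],
    gene_order: Mapping[str, Sequence[str]],
    floor_pct: float = 50.0,
    tolerance_frac: float = 0.05,
    tolerance_mode: str = "relative",
    min_block: int = 2,
    max_gap: int = 0,
    dominance_frac: float = 0.5,
) -> tuple[list[HomeologBlock], set[frozenset]]:
    """Full homeology pipeline, run symmetrically.

    Each pair is evaluated in both directions (every gene acts as source
    once); the reported chromosome pairings are the union over both
    directions of each source's dominant target.  Returns (all blocks,
    set of unordered homeolog chromosome pairs).
    """
    flipped = [
        ParalogPair(
            gene_a=p.gene_b, chrom_a=p.chrom_b, pos_a=p.pos_b,
            gene_b=p.gene_a, chrom_b=p.chrom_a, pos_b=p.pos_a,
            homology_pct=p.homology_pct,
        )
        for p in pairs
    ]
    both = list(pairs) + flipped
    kept = prune_low_homology(both, floor_pct)
    kept = rank_and_prune_tolerance(kept, tolerance_frac, tolerance_mode)
    blocks = build_homeolog_blocks(kept, gene_order, min_block=min_block, max_gap=max_gap)
    pairing = homeolog_pairs(blocks, dominance_frac)
    called = {
        frozenset((p.source_chrom, p.dominant_target))
        for p in pairing
        if p.dominant_target is not None
    }
    return blocks, called
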