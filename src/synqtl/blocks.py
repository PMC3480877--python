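"""Homology filtering and cross-species synteny-block construction.

Hits are accepted when E-value <= evalue_max and identity >= identity_min
(defaults 1e-4 and 60%).  Accepted hits are then chained along the
query's ordered marker map: per linkage group, the map-ordered sequence
of loci carrying at least one accepted hit is scanned for maximal runs
whose hits share one subject chromosome; runs of >= min_block loci
(default 2) become synteny blocks, singletons are ignored.  ``max_gap``
interposed loci hitting elsewhere may be tolerated inside a run
(default 0 = strict contiguity).  Contiguity is defined over loci that
have at least one accepted hit — loci without hits are invisible to the
run.  No within-block subject-order (collinearity) requirement is
imposed: blocks capture arm-to-chromosome affinity, not gene-order
conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .types import GenomeLayout, HomologyHit, MarkerMap, SyntenyBlock

log = logging.getLogger("synqtl")


@dataclass(frozen=True)
class FilterThresholds:
    evalue_max: float = 1e-4
    identity_min: float = 60.0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if not (0 <= self.identity_min <= 100):
            raise ValueError("identity_min outside [0, 100]")


def filter_hits(
    hits: Sequence[HomologyHit], thresholds: FilterThresholds = FilterThresholds()
) -> list[HomologyHit]:
    """Keep exactly the hits with evalue <= evalue_max and
    identity_pct >= identity_min.  An E-value of 0.0 always passes.
    A query may retain hits on several subject chromosomes (duplicated
    genes are expected in WGD genomes)."""
    accepted = [
        h
        for h in hits
        if h.evalue <= thresholds.evalue_max and h.identity_pct >= thresholds.identity_min
    ]
    log.info(
        "filter_hits: %d in, %d accepted (E<=%g, id>=%g%%)",
        len(hits),
        len(accepted),
        thresholds.evalue_max,
        thresholds.identity_min,
    )
    return accepted


def _attach_map(
    marker_map: MarkerMap, hits: Sequence[HomologyHit]
) -> dict[str, list[tuple[float, Optional[str], str, list[HomologyHit]]]]:
    """Join hits onto the map.  Returns, per group, the map-ordered list of
    loci with >= 1 hit as (position, arm, marker, hits-at-locus)."""
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    dropped = {q for q in by_query if q not in marker_map.marker_names()}
    if dropped:
        log.info("build_blocks: %d hit queries absent from map, dropped", len(dropped))
    out: dict[str, list[tuple[float, Optional[str], str, list[HomologyHit]]]] = {}
    for entry in marker_map.entries:
        locus_hits = by_query.get(entry.marker)
        if not locus_hits:
            continue
        out.setdefault(entry.group, []).append(
            (entry.position_cM, entry.arm, entry.marker, locus_hits)
        )
    return out


def _maximal_runs(flags: Sequence[bool], max_gap: int) -> list[list[int]]:
    """Maximal runs of True indices allowing up to max_gap consecutive
    False positions between True members.  Runs start and end on True."""
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


def build_blocks(
    marker_map: MarkerMap,
    accepted_hits: Sequence[HomologyHit],
    min_block: int = 2,
    max_gap: int = 0,
) -> list[SyntenyBlock]:
    """Chain accepted hits into synteny blocks along the ordered map.

    A locus hitting two subject chromosomes can belong to one block per
    subject chromosome.  Output order and content are invariant to the
    input hit order (loci follow map order; subject chromosomes are
    visited in sorted order).
    """
    if not marker_map.entries:
        raise ValueError("empty marker map")
    loci_by_group = _attach_map(marker_map, accepted_hits)
    blocks: list[SyntenyBlock] = []
    for group in marker_map.groups:
        loci = loci_by_group.get(group)
        if not loci:
            continue
        subject_chroms = sorted({h.subject_chrom for _, _, _, lh in loci for h in lh})
        for chrom in subject_chroms:
            flags = [any(h.subject_chrom == chrom for h in lh) for _, _, _, lh in loci]
            for run in _maximal_runs(flags, max_gap):
                if len(run) < min_block:
                    continue
                members: list[HomologyHit] = []
                for i in run:
                    pos, arm, marker, locus_hits = loci[i]
                    for h in sorted(
                        (h for h in locus_hits if h.subject_chrom == chrom),
                        key=lambda h: (h.subject_start, h.subject_end),
                    ):
                        members.append(
                            replace(h, query_group=group, query_pos=pos, query_arm=arm)
                        )
                qpos = [loci[i][0] for i in run]
                arms = {loci[i][1] for i in run if loci[i][1] is not None}
                blocks.append(
                    SyntenyBlock(
                        query_group=group,
                        subject_chrom=chrom,
                        query_span=(min(qpos), max(qpos)),
                        subject_span=(
                            min(m.subject_start for m in members),
                            max(m.subject_end for m in members),
                        ),
                        members=tuple(members),
                        query_arm=arms.pop() if len(arms) == 1 else None,
                    )
                )
    log.info("build_blocks: %d blocks (min_block=%d, max_gap=%d)", len(blocks), min_block, max_gap)
    return blocks


def merge_blocks(blocks: Sequence[SyntenyBlock], merge_gap: float = 0.0) -> list[SyntenyBlock]:
    """Union blocks on the same (query group, subject chromosome) whose
    query spans are separated by <= merge_gap query units.  The merge is
    transitive; member lists concatenate in query order."""
    keyed: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for b in blocks:
        keyed.setdefault((b.query_group, b.subject_chrom), []).append(b)
    merged: list[SyntenyBlock] = []
    for (group, chrom), bs in sorted(keyed.items()):
        bs = sorted(bs, key=lambda b: b.query_span)
        chain = [bs[0]]
        for b in bs[1:]:
            last = chain[-1]
            if b.query_span[0] - last.query_span[1] <= merge_gap:
                members = tuple(
                    sorted(
                        last.members + b.members,
                        key=lambda m: (m.query_pos if m.query_pos is not None else 0.0),
                    )
                )
                arms = {m.query_arm for m in members if m.query_arm is not None}
                chain[-1] = SyntenyBlock(
                    query_group=group,
                    subject_chrom=chrom,
                    query_span=(last.query_span[0], max(last.query_span[1], b.query_span[1])),
                    subject_span=(
                        min(last.subject_span[0], b.subject_span[0]),
                        max(last.subject_span[1], b.subject_span[1]),
                    ),
                    members=members,
                    query_arm=arms.pop() if len(arms) == 1 else None,
                )
            else:
                chain.append(b)
        merged.extend(chain)
    return merged


@dataclass(frozen=True)
class AffinitySummary:
    """Per linkage-group arm: which subject chromosomes carry blocks."""

    affinities: dict
    # (group, arm) -> sorted tuple of subject chromosomes

    def multiplicity(self, group: str, arm: Optional[str]) -> int:
        return len(self.affinities.get((group, arm), ()))

    def multiplicity_classes(self) -> dict:
        """Counts of arms by multiplicity class 0/1/2/>=3."""
        out = {0: 0, 1: 0, 2: 0, 3: 0}
        for chroms in self.affinities.values():
            out[min(len(chroms), 3)] += 1
        return out


def summarize_arm_affinities(
    blocks: Sequence[SyntenyBlock],
    layout: Optional[GenomeLayout] = None,
) -> AffinitySummary:
    """Distinct subject chromosomes per (query group, arm).

    Arms come from block/member labels, or from the layout's arm
    intervals when labels are missing; blocks whose arm cannot be
    resolved are counted under arm None ('unassigned') and logged.
    Arms present in the layout but carrying no block are reported with
    an empty set ('no synteny alignment').
    """
    affinities: dict[tuple[str, Optional[str]], set[str]] = {}
    if layout is not None:
        for chrom in layout.chromosomes:
            for arm in chrom.arms:
                affinities.setdefault((chrom.name, arm.label), set())
    unresolved = 0
    for b in blocks:
        arm = b.query_arm
        if arm is None and layout is not None and b.query_group in layout:
            chrom = layout.chromosome(b.query_group)
            mid = 0.5 * (b.query_span[0] + b.query_span[1])
            arm = chrom.arm_of(mid)
        if arm is None:
            unresolved += 1
        affinities.setdefault((b.query_group, arm), set()).add(b.subject_chrom)
    if unresolved:
        log.info("summarize_arm_affinities: %d blocks with unresolvable arm", unresolved)
    return AffinitySummary(
        affinities={k: tuple(sorted(v)) for k, v in sorted(affinities.items(), key=str)}
    )


def shared_marker_homology(
    map_a: MarkerMap,
    map_b: MarkerMap,
    min_block: int = 2,
    max_gap: int = 0,
) -> list[SyntenyBlock]:
    """Salmonid-vs-salmonid synteny from shared marker names.

    Markers present on both maps are treated as perfect hits (identity
    100, E 0) of map_a loci onto map_b groups (map_b linkage groups play
    the subject-chromosome role, with cM coordinates), then chained with
    ``build_blocks``.
    """
    shared = map_a.marker_names() & map_b.marker_names()
    if not shared:
        log.warning("shared_marker_homology: no shared markers between %s and %s",
                    map_a.parent_id, map_b.parent_id)
        return []
    hits = []
    for e in map_b.entries:
        if e.marker in shared:
            pos = int(round(e.position_cM * 100)) + 1  # cM -> integer coordinate, keep >= 1
            hits.append(
                HomologyHit(
                    query_id=e.marker,
                    subject_chrom=e.group,
                    subject_start=pos,
                    subject_end=pos,
                    evalue=0.0,
                    identity_pct=100.0,
                )
            )
    return build_blocks(map_a, hits, min_block=min_block, max_gap=max_gap)
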