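"""Ancestral-genome painting, candidate-gene transfer and cross-species
QTL homology.

Painting labels chromosome segments of a 3R/4R genome with the
pre-duplication (2R proto-Actinopterygian) chromosome they derive from,
using orthologue blocks against a rearrangement-poor proxy genome whose
chromosomes carry known lineage labels (A..M style).  Candidate-gene
transfer predicts which linkage group of a map-only genome carries a
gene, from the gene's position inside (or near) a synteny block of a
sequenced relative.  QTL homology tabulates cross-species pairs of
QTL-bearing linkage groups connected by shared-marker blocks or by
blocks to a common subject-chromosome interval.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

from .homeology import build_homeolog_blocks
from .types import (
    GenePrediction,
    GeneTable,
    PaintedSegment,
    ParalogPair,
    QtlHomologyRecord,
    SyntenyBlock,
)

log = logging.getLogger("synqtl")


def paint_ancestry(
    subject_gene_table: GeneTable,
    ortholog_pairs: Sequence[ParalogPair],
    lineage_of_proxy_chrom: Mapping[str, str],
    min_block: int = 2,
    max_gap: int = 0,
    chrom_lengths: Optional[Mapping[str, float]] = None,
) -> list[PaintedSegment]:
    """Paint subject chromosomes with ancestral lineage labels.

    ``ortholog_pairs`` carry the subject gene on the a-side and the proxy
    gene on the b-side.  Runs of >= min_block contiguous subject genes
    whose orthologues co-locate on one proxy chromosome become painted
    segments labelled with that proxy chromosome's lineage; everything
    else is 'unassigned'.  Segment boundaries fall at midpoints between
    adjacent genes of differing lineage, so a recovered breakpoint is
    within one gene-gap of the true one on clean data.  Per chromosome
    the segments are disjoint and tile the full extent.
    """
    proxy_chroms = {p.chrom_b for p in ortholog_pairs}
    missing = proxy_chroms - set(lineage_of_proxy_chrom)
    if missing:
        raise KeyError(f"proxy chromosomes without lineage label: {sorted(missing)}")

    by_chrom = subject_gene_table.by_chromosome()
    gene_order = {c: [r.gene for r in rows] for c, rows in by_chrom.items()}
    gene_pos = {r.gene: r.start_bp for r in subject_gene_table.rows}

    blocks = build_homeolog_blocks(
        ortholog_pairs, gene_order, min_block=min_block, max_gap=max_gap, include_self=True
    )

    # per gene, the lineage claimed by the largest containing block
    claim: dict[str, tuple[int, str]] = {}
    for b in blocks:
        lineage = lineage_of_proxy_chrom[b.target_chrom]
        for m in b.members:
            prev = claim.get(m.gene_a)
            cand = (b.size, lineage)
            if prev is None or cand > prev:
                claim[m.gene_a] = cand

    segments: list[PaintedSegment] = []
    for chrom, rows in sorted(by_chrom.items()):
        genes = [r.gene for r in rows]
        labels = [claim[g][1] if g in claim else "unassigned" for g in genes]
        # runs of one label; assigned runs shorter than min_block demote
        runs: list[tuple[str, int, int]] = []  # (label, i0, i1) inclusive
        i = 0
        while i < len(genes):
            j = i
            while j + 1 < len(genes) and labels[j + 1] == labels[i]:
                j += 1
            runs.append((labels[i], i, j))
            i = j + 1
        cleaned = []
        for label, i0, i1 in runs:
            if label != "unassigned" and (i1 - i0 + 1) < min_block:
                label = "unassigned"
            if cleaned and cleaned[-1][0] == label:
                cleaned[-1] = (label, cleaned[-1][1], i1)
            else:
                cleaned.append((label, i0, i1))
        extent_hi = float(chrom_lengths[chrom]) if chrom_lengths and chrom in chrom_lengths else float(rows[-1].start_bp)
        for k, (label, i0, i1) in enumerate(cleaned):
            lo = 1.0 if k == 0 else 0.5 * (gene_pos[genes[i0 - 1]] + gene_pos[genes[i0]])
            hi = extent_hi if k == len(cleaned) - 1 else 0.5 * (gene_pos[genes[i1]] + gene_pos[genes[i1 + 1]])
            segments.append(
                PaintedSegment(chrom=chrom, span=(lo, hi), lineage=label, support=i1 - i0 + 1)
            )
    return segments


def transfer_gene_positions(
    gene_table: GeneTable,
    blocks: Sequence[SyntenyBlock],
    flank_bp: float = 2_000_000.0,
) -> list[GenePrediction]:
    """Transfer gene positions from a sequenced genome onto linkage groups
    through synteny blocks.

    A gene inside a block's subject span yields a 'contained' prediction
    for the block's query group; a gene within flank_bp of a span edge
    yields a 'proximal' prediction with its distance.  A gene may be
    predicted on several groups (WGD duplicates are expected).
    """
    log.info("transfer_gene_positions: flank_bp=%g over %d blocks", flank_bp, len(blocks))
    predictions: list[GenePrediction] = []
    for row in gene_table.rows:
        for b in blocks:
            if b.subject_chrom != row.chromosome:
                continue
            lo, hi = b.subject_span
            if lo <= row.start_bp <= hi:
                dist = 0.0
                status = "contained"
            else:
                dist = float(lo - row.start_bp) if row.start_bp < lo else float(row.start_bp - hi)
                if dist > flank_bp:
                    continue
                status = "proximal"
            predictions.append(
                GenePrediction(
                    gene=row.gene,
                    source_chrom=row.chromosome,
                    source_pos=row.start_bp,
                    group=b.query_group,
                    arm=b.query_arm,
                    status=status,
                    distance_bp=dist,
                    block=b,
                )
            )
    return predictions


def _spans_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def cross_species_qtl_homology(
    qtl_tables: Mapping[str, Mapping[str, Sequence[str]]],
    shared_marker_blocks: Mapping[tuple[str, str], Sequence[SyntenyBlock]] | None = None,
    subject_blocks_per_species: Mapping[str, Sequence[SyntenyBlock]] | None = None,
    mode: str = "strict",
) -> list[QtlHomologyRecord]:
    """Cross-species QTL homology records.

    ``qtl_tables``: species -> {linkage group -> trait codes}.
    ``shared_marker_blocks``: (species_a, species_b) -> blocks whose
    query_group is an a-group and subject_chrom a b-group.
    ``subject_blocks_per_species``: species -> blocks of that species'
    groups against one common sequenced subject genome.

    A record is emitted for every ordered cross-species pair of
    QTL-bearing groups connected by a shared-marker block, or by blocks
    to a common subject chromosome with overlapping subject spans
    ('strict'; mode='chromosome' relaxes to chromosome-level identity).
    Evidence is symmetric: record(A,B) exists iff record(B,A) does.
    """
    if mode not in ("strict", "chromosome"):
        raise ValueError("mode must be strict or chromosome")
    shared_marker_blocks = shared_marker_blocks or {}
    subject_blocks_per_species = subject_blocks_per_species or {}

    def shared_marker_evidence(sp_a: str, g_a: str, sp_b: str, g_b: str) -> bool:
        for (x, y), blocks in shared_marker_blocks.items():
            if (x, y) == (sp_a, sp_b):
                if any(b.query_group == g_a and b.subject_chrom == g_b for b in blocks):
                    return True
            elif (x, y) == (sp_b, sp_a):
                if any(b.query_group == g_b and b.subject_chrom == g_a for b in blocks):
                    return True
        return False

    def subject_evidence(sp_a: str, g_a: str, sp_b: str, g_b: str) -> bool:
        blocks_a = [b for b in subject_blocks_per_species.get(sp_a, ()) if b.query_group == g_a]
        blocks_b = [b for b in subject_blocks_per_species.get(sp_b, ()) if b.query_group == g_b]
        for ba in blocks_a:
            for bb in blocks_b:
                if ba.subject_chrom != bb.subject_chrom:
                    continue
                if mode == "chromosome" or _spans_overlap(ba.subject_span, bb.subject_span):
                    return True
        return False

    records: list[QtlHomologyRecord] = []
    species = sorted(qtl_tables)
    for sp_a in species:
        for sp_b in species:
            if sp_a == sp_b:
                continue
            for g_a, traits_a in sorted(qtl_tables[sp_a].items()):
                for g_b, traits_b in sorted(qtl_tables[sp_b].items()):
                    evidence = []
                    if shared_marker_evidence(sp_a, g_a, sp_b, g_b):
                        evidence.append("shared_marker_block")
                    if subject_evidence(sp_a, g_a, sp_b, g_b):
                        evidence.append("shared_subject_chrom")
                    if evidence:
                        records.append(
                            QtlHomologyRecord(
                                species_a=sp_a, group_a=g_a, traits_a=tuple(traits_a),
                                species_b=sp_b, group_b=g_b, traits_b=tuple(traits_b),
                                evidence=tuple(evidence),
                            )
                        )
    return records
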