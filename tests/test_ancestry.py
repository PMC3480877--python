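"""Ancestral-lineage painting, candidate-gene transfer, QTL homology."""

import collections

import pytest

from synqtl import ancestry, blocks, sim
from synqtl.ancestry import cross_species_qtl_homology, paint_ancestry, transfer_gene_positions
from synqtl.types import GeneRow, GeneTable, HomologyHit, ParalogPair, SyntenyBlock


def _gene_table(chrom: str, n: int, spacing: int = 1000) -> GeneTable:
    return GeneTable(rows=tuple(
        GeneRow(gene=f"{chrom}.g{i}", chromosome=chrom, start_bp=(i + 1) * spacing)
        for i in range(n)
    ))


def _orth(subject_gene: str, subject_chrom: str, pos: int, proxy_chrom: str) -> ParalogPair:
    return ParalogPair(gene_a=subject_gene, chrom_a=subject_chrom, pos_a=pos,
                       gene_b=subject_gene + "_px", chrom_b=proxy_chrom, pos_b=pos,
                       homology_pct=85.0)


def test_paint_single_lineage_chromosome():
    table = _gene_table("chr1", 5)
    pairs = [_orth(r.gene, "chr1", r.start_bp, "ol7") for r in table.rows]
    segs = paint_ancestry(table, pairs, {"ol7": "J"})
    assert [(s.lineage, s.support) for s in segs] == [("J", 5)]
    assert segs[0].span == (1.0, 5000.0)


def test_paint_alternating_singletons_unassigned():
    table = _gene_table("chr1", 4)
    pairs = [_orth(r.gene, "chr1", r.start_bp, "olA" if i % 2 == 0 else "olB")
             for i, r in enumerate(table.rows)]
    segs = paint_ancestry(table, pairs, {"olA": "A", "olB": "B"})
    assert [s.lineage for s in segs] == ["unassigned"]


def test_paint_missing_lineage_label_rejected():
    table = _gene_table("chr1", 2)
    pairs = [_orth(r.gene, "chr1", r.start_bp, "olX") for r in table.rows]
    with pytest.raises(KeyError, match="olX"):
        paint_ancestry(table, pairs, {})


def test_paint_segments_tile_chromosome_disjointly():
    table = _gene_table("chr1", 10)
    # first half orthologous to lineage A, second half to lineage B
    pairs = [_orth(r.gene, "chr1", r.start_bp, "olA" if i < 5 else "olB")
             for i, r in enumerate(table.rows)]
    segs = paint_ancestry(table, pairs, {"olA": "A", "olB": "B"},
                          chrom_lengths={"chr1": 12000.0})
    assert [s.lineage for s in segs] == ["A", "B"]
    # disjoint tiling of [1, length]
    assert segs[0].span[0] == 1.0 and segs[-1].span[1] == 12000.0
    for s1, s2 in zip(segs, segs[1:]):
        assert s1.span[1] == s2.span[0]
    # breakpoint at the midpoint between genes 5 and 6 (within one gene-gap)
    assert segs[0].span[1] == pytest.approx(5500.0)


def test_paint_recovers_planted_fusion():
    """A fused chromosome in a simulated genome is painted with both
    ancestral lineages, breakpoint within one gene-gap of truth."""
    p = sim.SimGenomeParams(
        n_ancestral_chroms=4, genes_per_chrom=25, wgd_rounds=1,
        fusion_rate=3.0, fission_rate=0, translocation_rate=0, inversion_rate=0,
        retention_prob=1.0, noise_sd=0.0, decay_sd=0.0, seed=5,
    )
    s = sim.simulate_wgd_genomes(p)
    truth = s.truth.lineage_segments["3R"]
    fused = [c for c, lineages in truth.items() if len(set(lineages)) > 1]
    assert fused, "simulation should contain at least one fusion at rate 3"
    lineage_of_proxy = {c: segs[0] for c, segs in s.truth.lineage_segments["2R"].items()}
    segs = paint_ancestry(s.gene_table("3R"), s.ortholog_table("3R", "2R"), lineage_of_proxy)
    for chrom in fused:
        want = []
        for lin in truth[chrom]:
            if not want or want[-1] != lin:
                want.append(lin)
        got = [x.lineage for x in segs if x.chrom == chrom]
        assert got == want
        # breakpoint within one gene-gap: by construction boundaries sit at
        # inter-gene midpoints, so check support counts match truth runs
        runs = []
        for lin in truth[chrom]:
            if runs and runs[-1][0] == lin:
                runs[-1][1] += 1
            else:
                runs.append([lin, 1])
        assert [x.support for x in segs if x.chrom == chrom] == [r[1] for r in runs]


# ---------------------------------------------------------------------------
# gene transfer


def _block(group, chrom, s0, s1):
    h = HomologyHit("m", chrom, int(s0), int(s1), 0.0, 100.0)
    return SyntenyBlock(query_group=group, subject_chrom=chrom,
                        query_span=(0.0, 10.0), subject_span=(float(s0), float(s1)),
                        members=(h, h))


def test_transfer_contained_and_proximal():
    genes = GeneTable(rows=(
        GeneRow("inside", "I", 5_000_000),
        GeneRow("near", "I", 11_500_000),
        GeneRow("far", "I", 50_000_000),
        GeneRow("other", "II", 5_000_000),
    ))
    block = _block("AS-4", "I", 1_000_000, 10_000_000)
    preds = transfer_gene_positions(genes, [block], flank_bp=2_000_000)
    by_gene = {p.gene: p for p in preds}
    assert by_gene["inside"].status == "contained" and by_gene["inside"].distance_bp == 0
    assert by_gene["near"].status == "proximal"
    assert by_gene["near"].distance_bp == pytest.approx(1_500_000)
    assert "far" not in by_gene and "other" not in by_gene


def test_transfer_monotone_in_flank():
    genes = GeneTable(rows=(GeneRow("g", "I", 12_000_000),))
    block = _block("AS-4", "I", 1_000_000, 10_000_000)
    small = transfer_gene_positions(genes, [block], flank_bp=1_000_000)
    large = transfer_gene_positions(genes, [block], flank_bp=3_000_000)
    assert {p.gene for p in small} <= {p.gene for p in large}


def test_transfer_duplicated_gene_predicted_on_multiple_groups():
    genes = GeneTable(rows=(GeneRow("dup", "I", 5_000_000),))
    bs = [_block("AS-4", "I", 1_000_000, 10_000_000),
          _block("AS-22", "I", 4_000_000, 6_000_000)]
    preds = transfer_gene_positions(genes, bs, flank_bp=0)
    assert {p.group for p in preds} == {"AS-4", "AS-22"}


def test_transfer_recovers_planted_genes_on_simulated_4R():
    s = sim.simulate_wgd_genomes(sim.SimGenomeParams(seed=3))
    mmap, marker_genes = sim.emit_marker_map(s, "4R", density=0.3)
    bl = blocks.build_blocks(mmap, blocks.filter_hits(s.blast_hits(mmap, marker_genes, "3R")))
    gt3 = s.gene_table("3R")
    preds = transfer_gene_positions(gt3, bl)
    loc4 = {g.copy_id: c for c, genes in s.genomes["4R"].items() for g in genes}
    by_gene = collections.defaultdict(set)
    for p in preds:
        by_gene[p.gene].add(p.group)
    ok = tot = 0
    for row in gt3.rows:
        descendants = {loc4[row.gene + sfx] for sfx in ("a", "b") if row.gene + sfx in loc4}
        if not descendants:
            continue
        tot += 1
        ok += bool(by_gene.get(row.gene, set()) & descendants)
    assert ok / tot >= 0.9


# ---------------------------------------------------------------------------
# QTL homology


def test_qtl_homology_shared_marker_and_symmetry():
    qtl_tables = {
        "salmon": {"AS-4q": ["NKA", "OSMO"]},
        "charr": {"AC-20": ["OSMO"]},
    }
    shared = {("salmon", "charr"): [_block("AS-4q", "AC-20", 0, 100)]}
    records = cross_species_qtl_homology(qtl_tables, shared_marker_blocks=shared)
    assert len(records) == 2  # both directions
    keys = {(r.species_a, r.group_a, r.species_b, r.group_b) for r in records}
    assert ("salmon", "AS-4q", "charr", "AC-20") in keys
    assert ("charr", "AC-20", "salmon", "AS-4q") in keys
    assert all(r.evidence == ("shared_marker_block",) for r in records)


def test_qtl_homology_subject_overlap_strict_vs_chromosome():
    qtl_tables = {"salmon": {"AS-22": ["NKA"]}, "trout": {"RT-15p": ["G"]}}
    subject = {
        "salmon": [_block("AS-22", "GaI", 1_000, 5_000)],
        "trout": [_block("RT-15p", "GaI", 10_000, 20_000)],
    }
    strict = cross_species_qtl_homology(qtl_tables, subject_blocks_per_species=subject)
    assert strict == []  # disjoint spans on the common chromosome
    relaxed = cross_species_qtl_homology(
        qtl_tables, subject_blocks_per_species=subject, mode="chromosome"
    )
    assert len(relaxed) == 2
    assert all("shared_subject_chrom" in r.evidence for r in relaxed)


def test_qtl_homology_recovers_simulated_conserved_segment():
    """Two maps sharing a conserved marker segment on QTL-bearing groups
    yield a homology record."""
    from synqtl.blocks import shared_marker_homology
    from synqtl.types import MapEntry, MarkerMap

    common = tuple(MapEntry(f"s{i}", "AS-1", i * 4.0) for i in range(5))
    map_a = MarkerMap("salmon", "female", common)
    map_b = MarkerMap("charr", "female", tuple(
        MapEntry(e.marker, "AC-9", e.position_cM) for e in common
    ))
    shared_blocks = shared_marker_homology(map_a, map_b)
    records = cross_species_qtl_homology(
        {"salmon": {"AS-1": ["NKA"]}, "charr": {"AC-9": ["NKA"]}},
        shared_marker_blocks={("salmon", "charr"): shared_blocks},
    )
    assert len(records) == 2
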