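"""Hit filtering and synteny-block construction, checked against a
brute-force maximal-run oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synqtl import blocks
from synqtl.blocks import FilterThresholds, build_blocks, filter_hits, merge_blocks
from synqtl.types import HomologyHit, MapEntry, MarkerMap

from conftest import hit


# ---------------------------------------------------------------------------
# filter_hits


@pytest.mark.parametrize(
    "evalue,identity,accepted",
    [
        (1e-87, 78.0, True),   # strong candidate-gene hit
        (1e-21, 66.0, True),   # weaker but acceptable growth-hormone-style hit
        (1e-3, 55.0, False),   # fails both criteria
        (1e-4, 60.0, True),    # exactly on both thresholds
        (2e-4, 90.0, False),   # fails E-value only
        (1e-10, 59.9, False),  # fails identity only
        (0.0, 82.0, True),     # E printed as 0 always passes
    ],
)
def test_filter_hits_thresholds(evalue, identity, accepted):
    h = hit("q", "chr1", evalue=evalue, identity=identity)
    assert (filter_hits([h]) == [h]) is accepted


def test_duplicated_gene_retains_hits_on_two_chromosomes():
    # an NKCC1a-style locus hitting two chromosomes, both passing
    hits = [
        hit("NKCC1a", "groupXIV", start=13969000, evalue=0.0, identity=82),
        hit("NKCC1a", "groupXIII", start=19857000, evalue=0.0, identity=76),
    ]
    assert filter_hits(hits) == hits


def test_filter_hits_idempotent_and_order_independent(rng):
    hits = [
        hit(f"q{i}", "c", evalue=10.0 ** -rng.integers(0, 10), identity=float(rng.integers(40, 100)))
        for i in range(50)
    ]
    once = filter_hits(hits)
    assert filter_hits(once) == once
    shuffled = list(hits)
    rng.shuffle(shuffled)
    assert sorted(map(id, filter_hits(shuffled))) == sorted(map(id, once))


def test_filter_monotone_in_thresholds(rng):
    hits = [
        hit(f"q{i}", "c", evalue=float(10.0 ** -rng.uniform(0, 8)), identity=float(rng.uniform(40, 100)))
        for i in range(200)
    ]
    base = len(filter_hits(hits, FilterThresholds(1e-4, 60)))
    assert len(filter_hits(hits, FilterThresholds(1e-4, 70))) <= base
    assert len(filter_hits(hits, FilterThresholds(1e-6, 60))) <= base


# ---------------------------------------------------------------------------
# build_blocks vs brute-force oracle

def oracle_blocks(subjects_per_locus, min_block, max_gap):
    """Enumerate all maximal qualifying runs by brute force.

    ``subjects_per_locus``: per map-ordered locus, the set of subject
    chromosomes it hits (empty sets are loci without accepted hits and
    invisible to the run).  Returns {(chrom, member index tuple), ...}.
    """
    loci = [i for i, s in enumerate(subjects_per_locus) if s]
    chroms = sorted(set().union(*[subjects_per_locus[i] for i in loci])) if loci else []
    out = set()
    for chrom in chroms:
        flagged = [i for i in loci if chrom in subjects_per_locus[i]]
        pos_of = {i: k for k, i in enumerate(loci)}  # rank among visible loci
        for a in range(len(flagged)):
            for b in range(a, len(flagged)):
                members = [i for i in flagged if flagged[a] <= i <= flagged[b]]
                # internal gaps: runs of visible loci between consecutive members
                ok = all(
                    pos_of[members[k + 1]] - pos_of[members[k]] - 1 <= max_gap
                    for k in range(len(members) - 1)
                )
                if not ok or len(members) < min_block:
                    continue
                # maximality: cannot extend to previous/next flagged locus
                ia = flagged.index(members[0])
                ib = flagged.index(members[-1])
                if ia > 0 and pos_of[members[0]] - pos_of[flagged[ia - 1]] - 1 <= max_gap:
                    continue
                if ib < len(flagged) - 1 and pos_of[flagged[ib + 1]] - pos_of[members[-1]] - 1 <= max_gap:
                    continue
                out.add((chrom, tuple(members)))
    return out


def run_build_blocks(subjects_per_locus, min_block, max_gap):
    entries = tuple(
        MapEntry(marker=f"m{i}", group="LG1", position_cM=float(i))
        for i in range(len(subjects_per_locus))
    )
    mm = MarkerMap(parent_id="P", sex="female", entries=entries)
    hits = [
        hit(f"m{i}", chrom, start=100 * (i + 1))
        for i, subjects in enumerate(subjects_per_locus)
        for chrom in sorted(subjects)
    ]
    got = build_blocks(mm, hits, min_block=min_block, max_gap=max_gap)
    return {
        (b.subject_chrom, tuple(sorted({int(m.query_pos) for m in b.members})))
        for b in got
    }


def test_build_blocks_stated_examples():
    # [X, X, Y, X, X] strict: two X blocks, Y singleton ignored
    seq = [{"X"}, {"X"}, {"Y"}, {"X"}, {"X"}]
    assert run_build_blocks(seq, 2, 0) == {("X", (0, 1)), ("X", (3, 4))}
    # with one tolerated gap the X run bridges the Y locus
    assert run_build_blocks(seq, 2, 1) == {("X", (0, 1, 3, 4))}
    # all loci on distinct chromosomes: no blocks at all
    assert run_build_blocks([{"A"}, {"B"}, {"C"}], 2, 0) == set()


def test_build_blocks_requires_nonempty_map():
    with pytest.raises(ValueError, match="empty"):
        build_blocks(MarkerMap("P", "female", ()), [])


def test_locus_on_two_chromosomes_joins_two_blocks():
    seq = [{"X", "Y"}, {"X", "Y"}]
    assert run_build_blocks(seq, 2, 0) == {("X", (0, 1)), ("Y", (0, 1))}


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.sets(st.sampled_from(["X", "Y", "Z"]), max_size=3), min_size=1, max_size=25
    ),
    max_gap=st.integers(0, 2),
    min_block=st.integers(2, 3),
)
def test_build_blocks_matches_oracle(data, max_gap, min_block):
    expected = {
        (chrom, members)
        for chrom, members in oracle_blocks(data, min_block, max_gap)
    }
    assert run_build_blocks(data, min_block, max_gap) == expected


def test_build_blocks_invariant_to_hit_order(rng):
    seq = [set(rng.choice(["X", "Y", "Z"], size=rng.integers(0, 3), replace=False)) for _ in range(20)]
    entries = tuple(MapEntry(f"m{i}", "LG1", float(i)) for i in range(len(seq)))
    mm = MarkerMap("P", "female", entries)
    hits = [hit(f"m{i}", c, start=100 * (i + 1)) for i, s in enumerate(seq) for c in sorted(s)]
    ref = build_blocks(mm, hits)
    shuffled = list(hits)
    rng.shuffle(shuffled)
    got = build_blocks(mm, shuffled)
    key = lambda bs: [(b.query_group, b.subject_chrom, b.query_span, tuple(m.query_id for m in b.members)) for b in bs]
    assert key(got) == key(ref)


# ---------------------------------------------------------------------------
# merge_blocks


def _mkblock(group, chrom, q0, q1, n=2):
    members = tuple(
        HomologyHit(f"m{q0}_{k}", chrom, 100 + k, 200 + k, 0.0, 100.0,
                    query_group=group, query_pos=q0 + k * (q1 - q0) / max(n - 1, 1))
        for k in range(n)
    )
    from synqtl.types import SyntenyBlock

    return SyntenyBlock(query_group=group, subject_chrom=chrom,
                        query_span=(q0, q1), subject_span=(100.0, 200.0 + n), members=members)


def test_merge_blocks_interval_union():
    b1 = _mkblock("LG1", "X", 0.0, 10.0)
    b2 = _mkblock("LG1", "X", 12.0, 20.0)
    merged = merge_blocks([b1, b2], merge_gap=5.0)
    assert len(merged) == 1 and merged[0].query_span == (0.0, 20.0)
    assert merged[0].size == 4
    # too small a gap allowance: unchanged
    assert len(merge_blocks([b1, b2], merge_gap=1.0)) == 2


def test_merge_blocks_transitive():
    bs = [_mkblock("LG1", "X", 0.0, 5.0), _mkblock("LG1", "X", 7.0, 12.0), _mkblock("LG1", "X", 14.0, 20.0)]
    merged = merge_blocks(bs, merge_gap=2.0)
    assert len(merged) == 1 and merged[0].query_span == (0.0, 20.0)


def test_merge_blocks_keeps_distinct_subjects_apart():
    bs = [_mkblock("LG1", "X", 0.0, 5.0), _mkblock("LG1", "Y", 6.0, 10.0)]
    assert len(merge_blocks(bs, merge_gap=100.0)) == 2


# ---------------------------------------------------------------------------
# arm affinities & shared-marker homology


def test_arm_affinity_multiplicity(simple_map):
    hits = [
        hit("LG1m1", "VII"), hit("LG1m2", "VII"),   # p arm: block on VII
        hit("LG1m3", "I"), hit("LG1m4", "I"),       # q arm: block on I
        hit("LG1m5", "I"),
    ]
    bs = build_blocks(simple_map, hits)
    summary = blocks.summarize_arm_affinities(bs)
    assert summary.affinities[("LG1", "p")] == ("VII",)
    assert summary.affinities[("LG1", "q")] == ("I",)
    assert summary.multiplicity("LG1", "p") == 1
    assert summary.multiplicity("LG2", "p") == 0  # no synteny alignment


def test_shared_marker_homology_recovers_conserved_segment():
    common = tuple(MapEntry(f"s{i}", "A1", float(i) * 5) for i in range(4))
    map_a = MarkerMap("A", "female", common)
    map_b = MarkerMap("B", "female", tuple(
        MapEntry(e.marker, "B9", e.position_cM) for e in common
    ))
    got = blocks.shared_marker_homology(map_a, map_b)
    assert len(got) == 1
    assert got[0].size == 4
    assert got[0].subject_chrom == "B9"


def test_shared_marker_homology_singletons_and_disjoint():
    map_a = MarkerMap("A", "female", (
        MapEntry("s1", "A1", 0.0), MapEntry("x2", "A1", 5.0), MapEntry("s3", "A1", 10.0),
    ))
    map_b = MarkerMap("B", "female", (
        MapEntry("s1", "B1", 0.0), MapEntry("s3", "B2", 0.0),
    ))
    assert blocks.shared_marker_homology(map_a, map_b) == []
    map_c = MarkerMap("C", "female", (MapEntry("zz", "C1", 0.0),))
    assert blocks.shared_marker_homology(map_a, map_c) == []
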