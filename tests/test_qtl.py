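"""Trait preprocessing, QTL scans, permutation thresholds, FDR, PEV,
combined-family analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from synqtl import qtl, sim
from synqtl.qtl import (
    bh_fdr,
    combined_family_scan,
    f_to_pev,
    interval_scan,
    lilliefors_mc,
    permutation_threshold,
    preprocess_trait,
    rank_inverse_normal,
    single_marker_scan,
)


def _trait_frame(values, order=None, family=None):
    n = len(values)
    return pd.DataFrame(
        {
            "value": values,
            "order": order if order is not None else np.arange(1, n + 1),
            "family": family if family is not None else ["F1"] * n,
        },
        index=[f"p{i}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# preprocessing


def test_gaussian_trait_not_transformed(rng):
    data_rng = np.random.default_rng(0)
    tv = preprocess_trait(_trait_frame(data_rng.normal(size=300)), n_draws=2000, rng=rng)
    assert any("no transform" in s for s in tv.steps)


def test_lognormal_trait_transformed(rng):
    tv = preprocess_trait(_trait_frame(np.exp(rng.normal(size=300) * 1.5)), n_draws=2000, rng=rng)
    assert any("inverse-normal" in s for s in tv.steps)
    # transformed values are close to Gaussian quantiles
    _, p_after = lilliefors_mc(tv.values, n_draws=1000, rng=rng)
    assert p_after > 0.05


def test_lilliefors_calibration(rng):
    """Under Gaussian data the MC Lilliefors test rejects at ~5%."""
    rej = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.normal(size=60)
        _, p = lilliefors_mc(x, n_draws=400, rng=rng)
        rej += p <= 0.05
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rej / n_rep - 0.05) <= 4 * se


def test_batch_effect_removed(rng):
    n = 500
    order = rng.permutation(n) + 1
    batch = (order - 1) // 20
    effects = rng.normal(0, 2.0, size=batch.max() + 1)
    y = rng.normal(size=n) + effects[batch]
    tv = preprocess_trait(_trait_frame(y, order=order), batch_size=20, n_draws=1000, rng=rng)
    r = np.corrcoef(tv.values, effects[batch])[0, 1]
    assert abs(r) < 0.05


def test_constant_trait_rejected(rng):
    with pytest.raises(ValueError, match="zero variance"):
        preprocess_trait(_trait_frame(np.ones(20)), rng=rng)


def test_rank_inverse_normal_monotone(rng):
    x = rng.normal(size=50) ** 3
    z = rank_inverse_normal(x)
    assert np.all(np.diff(z[np.argsort(x)]) > 0)


# ---------------------------------------------------------------------------
# scans


def test_equal_means_give_zero_f():
    G = pd.DataFrame({"m": [0, 0, 1, 1]}, index=list("abcd"), dtype=float)
    y = pd.Series([1.0, 2.0, 1.0, 2.0], index=list("abcd"))
    res = single_marker_scan(G, y)
    assert res.f_stats[0] == pytest.approx(0.0)
    assert f_to_pev(res.f_stats[0], 4) == 0.0


def test_single_class_marker_skipped():
    G = pd.DataFrame({"mono": [0, 0, 0, 0], "ok": [0, 1, 0, 1]}, index=list("abcd"), dtype=float)
    y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    res = single_marker_scan(G, y)
    assert res.labels == ["ok"]


def test_perfect_separation_pev_one():
    G = pd.DataFrame({"m": [0, 0, 1, 1]}, index=list("abcd"), dtype=float)
    y = pd.Series([1.0, 1.0, 5.0, 5.0], index=list("abcd"))
    res = single_marker_scan(G, y)
    assert f_to_pev(res.f_stats[0], 4) == 1.0


def test_interval_scan_equals_single_marker_at_markers():
    mm = sim.uniform_map(n_groups=1, markers_per_group=6, length_cM=50)
    cross = sim.simulate_cross(mm, sim.SimCrossParams(
        n_progeny=150, n_families=1,
        qtl=(sim.PlantedQtl("LG1", 25.0, 0.2, parents=("F1_female",)),), seed=2))
    G = cross.genotypes["F1_female"]
    y = cross.traits.loc[G.index, "value"]
    entries = mm.group_entries("LG1")
    sm = single_marker_scan(G, y)
    iv = interval_scan(G, entries, y, step_cM=1.0)
    iv_at = dict(zip(iv.labels, iv.f_stats))
    for marker, f in zip(sm.labels, sm.f_stats):
        assert iv_at[marker] == pytest.approx(f, rel=1e-9)


def test_interval_scan_localizes_midpoint_qtl():
    """QTL planted midway between flanking markers 20 cM apart: scan max
    within 10 cM of truth in >= 80% of replicates (n=200, 20% variance)."""
    mm = sim.uniform_map(n_groups=1, markers_per_group=5, length_cM=80)  # 20 cM spacing
    ok = 0
    n_rep = 40
    for seed in range(n_rep):
        cross = sim.simulate_cross(mm, sim.SimCrossParams(
            n_progeny=200, n_families=1,
            qtl=(sim.PlantedQtl("LG1", 30.0, 0.2, parents=("F1_female",)),), seed=seed))
        G = cross.genotypes["F1_female"]
        y = cross.traits.loc[G.index, "value"]
        res = interval_scan(G, mm.group_entries("LG1"), y)
        ok += abs(res.max_position - 30.0) <= 10.0
    assert ok / n_rep >= 0.8


def test_planted_qtl_attains_scan_maximum():
    """A planted 20%-variance QTL at a marker is the scan max in >= 90%."""
    mm = sim.uniform_map(n_groups=1, markers_per_group=5, length_cM=80)
    ok = 0
    n_rep = 100
    for seed in range(n_rep):
        cross = sim.simulate_cross(mm, sim.SimCrossParams(
            n_progeny=200, n_families=1,
            qtl=(sim.PlantedQtl("LG1", 40.0, 0.2, parents=("F1_female",)),), seed=seed))
        G = cross.genotypes["F1_female"]
        y = cross.traits.loc[G.index, "value"]
        res = single_marker_scan(G, y)
        ok += res.max_label == "LG1M03"  # the marker at 40 cM
    assert ok / n_rep >= 0.9


# ---------------------------------------------------------------------------
# permutations


def test_permutation_p_definition_and_determinism(rng):
    mm = sim.uniform_map(n_groups=1, markers_per_group=4, length_cM=30)
    cross = sim.simulate_cross(mm, sim.SimCrossParams(
        n_progeny=100, n_families=1,
        qtl=(sim.PlantedQtl("LG1", 15.0, 0.5, parents=("F1_female",)),), seed=0))
    G = cross.genotypes["F1_female"]
    y = cross.traits.loc[G.index, "value"]
    p1, obs1, perm1 = permutation_threshold(G, y, 999, np.random.default_rng(7))
    p2, obs2, perm2 = permutation_threshold(G, y, 999, np.random.default_rng(7))
    assert p1 == p2 and obs1 == obs2 and np.array_equal(perm1, perm2)
    # a 50%-variance QTL beats all 999 permutations: p = 1/1000
    assert p1 == pytest.approx(0.001)


def test_permutation_requires_min_perms():
    G = pd.DataFrame({"m": [0.0, 1.0] * 10})
    with pytest.raises(ValueError):
        permutation_threshold(G, np.zeros(20), 50)


def test_permutation_null_calibration():
    """Null trait: chromosome-wide rejection rate at 0.05 within 3 SE
    over replicates (n_perm=200)."""
    mm = sim.uniform_map(n_groups=1, markers_per_group=6, length_cM=50)
    rej = 0
    n_rep = 200
    for seed in range(n_rep):
        cross = sim.simulate_cross(mm, sim.SimCrossParams(n_progeny=100, n_families=1, seed=seed))
        G = cross.genotypes["F1_female"]
        y = cross.traits.loc[G.index, "value"]
        p, _, _ = permutation_threshold(G, y, 200, np.random.default_rng(70_000 + seed),
                                        entries=mm.group_entries("LG1"))
        rej += p <= 0.05
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rej / n_rep - 0.05) <= 3 * se


# ---------------------------------------------------------------------------
# B-H FDR


def bh_oracle(pvals, alpha=0.05, gate=0.05):
    """Independent exhaustive step-up: flag all gated p <= the largest
    p(i) (sorted ascending) with p(i) <= i*alpha/m."""
    gated = [(p, i) for i, p in enumerate(pvals) if p <= gate]
    flags = [False] * len(pvals)
    if not gated:
        return flags
    m = len(gated)
    ranked = sorted(p for p, _ in gated)
    cutoff = 0.0
    for i, p in enumerate(ranked, 1):
        if p <= i * alpha / m:
            cutoff = p
    for p, i in gated:
        if cutoff and p <= cutoff:
            flags[i] = True
    return flags


def test_bh_examples():
    assert bh_fdr([0.01, 0.02, 0.04]) == [True, True, True]
    # [0.04 x3]: at i=3, 0.04 <= 0.05 -> all flagged
    assert bh_fdr([0.04, 0.04, 0.04]) == [True, True, True]
    assert bh_fdr([0.049]) == [True]
    assert bh_fdr([0.051]) == [False]  # fails the chromosome-wide gate
    assert bh_fdr([]) == []
    with pytest.raises(ValueError):
        bh_fdr([0.0, 0.5])


def test_bh_matches_oracle_exhaustive_and_sampled(rng):
    grid = np.round(np.arange(0.01, 1.001, 0.01), 2)
    # exhaustive for lengths 1 and 2
    for p in grid:
        assert bh_fdr([p]) == bh_oracle([p])
    for p1, p2 in itertools.product(grid[::4], grid[::4]):
        assert bh_fdr([p1, p2]) == bh_oracle([p1, p2])
    # sampled (with ties forced) for lengths 3..6
    for length in range(3, 7):
        for _ in range(400):
            p = list(rng.choice(grid, size=length))
            if rng.random() < 0.3:
                p[rng.integers(length)] = p[0]  # force a tie
            assert bh_fdr(p) == bh_oracle(p)


# ---------------------------------------------------------------------------
# PEV recovery


def test_pev_recovery_within_five_points():
    """Mean estimated PEV of a planted 20%-variance QTL at n=300 is within
    +-5 percentage points of truth."""
    mm = sim.uniform_map(n_groups=1, markers_per_group=6, length_cM=50)
    pevs = []
    for seed in range(60):
        cross = sim.simulate_cross(mm, sim.SimCrossParams(
            n_progeny=300, n_families=1,
            qtl=(sim.PlantedQtl("LG1", 25.0, 0.2, parents=("F1_female",)),), seed=seed))
        G = cross.genotypes["F1_female"]
        y = cross.traits.loc[G.index, "value"]
        res = single_marker_scan(G, y)
        pevs.append(f_to_pev(res.max_statistic, len(y)))
    assert abs(np.mean(pevs) - 0.20) <= 0.05


def test_pev_bias_shrinks_with_n():
    """PEV estimator consistency: |bias| decreases from n=50 to n=800."""
    mm = sim.uniform_map(n_groups=1, markers_per_group=6, length_cM=50)

    def mean_pev(n, reps=30):
        vals = []
        for seed in range(reps):
            cross = sim.simulate_cross(mm, sim.SimCrossParams(
                n_progeny=n, n_families=1,
                qtl=(sim.PlantedQtl("LG1", 25.0, 0.2, parents=("F1_female",)),), seed=seed))
            G = cross.genotypes["F1_female"]
            y = cross.traits.loc[G.index, "value"]
            res = single_marker_scan(G, y)
            vals.append(f_to_pev(res.max_statistic, len(y)))
        return np.mean(vals)

    bias = {n: abs(mean_pev(n) - 0.2) for n in (50, 200, 800)}
    assert bias[800] < bias[50]


# ---------------------------------------------------------------------------
# combined-family analysis


def _combined_cross(seed, qtl_spec=()):
    mm = sim.uniform_map(n_groups=1, markers_per_group=5, length_cM=40)
    cross = sim.simulate_cross(mm, sim.SimCrossParams(
        n_progeny=100, n_families=2, qtl=qtl_spec, family_sd=0.7, seed=seed))
    parent_geno = {p: G["LG1M03"] for p, G in cross.genotypes.items()}
    return cross, parent_geno


def test_combined_scan_null_calibration():
    rej = 0
    n_rep = 100
    for seed in range(n_rep):
        cross, parent_geno = _combined_cross(seed)
        res = combined_family_scan(parent_geno, cross.traits, "LG1M03",
                                   n_perm=200, rng=np.random.default_rng(seed))
        rej += res.joint_p <= 0.05
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rej / n_rep - 0.05) <= 3 * se


def test_combined_scan_detects_shared_qtl_and_reports_partials():
    qtl_spec = (sim.PlantedQtl("LG1", 20.0, 0.15,
                               parents=("F1_female", "F1_male")),)
    cross, parent_geno = _combined_cross(3, qtl_spec)
    res = combined_family_scan(parent_geno, cross.traits, "LG1M03",
                               n_perm=300, rng=np.random.default_rng(1))
    assert res.joint_p <= 0.05
    assert set(res.parent_partial_r2) == set(parent_geno)
    # the segregating parents explain more than the non-segregating family
    seg = np.mean([res.parent_partial_r2["F1_female"], res.parent_partial_r2["F1_male"]])
    non = np.mean([res.parent_partial_r2["F2_female"], res.parent_partial_r2["F2_male"]])
    assert seg > non


def test_combined_scan_joint_more_powerful_than_single_parent():
    """A QTL segregating in both parents of one family: the joint test
    rejects at least as often as either single-parent test at alpha 0.05."""
    qtl_spec = (sim.PlantedQtl("LG1", 20.0, 0.08,
                               parents=("F1_female", "F1_male")),)
    joint_hits = single_hits = 0
    n_rep = 60
    for seed in range(n_rep):
        cross, parent_geno = _combined_cross(seed, qtl_spec)
        rng = np.random.default_rng(90_000 + seed)
        res = combined_family_scan(parent_geno, cross.traits, "LG1M03", n_perm=200, rng=rng)
        joint_hits += res.joint_p <= 0.05
        # single-parent test (F1_female alone)
        G = cross.genotypes["F1_female"][["LG1M03"]]
        y = cross.traits.loc[G.index, "value"]
        p, _, _ = permutation_threshold(G, y, 200, np.random.default_rng(95_000 + seed))
        single_hits += p <= 0.05
    assert joint_hits >= single_hits


def test_combined_scan_delegates_when_one_parent_informative():
    cross, parent_geno = _combined_cross(5)
    # blank out all but one parent
    masked = {}
    for i, (p, g) in enumerate(sorted(parent_geno.items())):
        masked[p] = g if i == 0 else g * np.nan
    res = combined_family_scan(masked, cross.traits, "LG1M03",
                               n_perm=200, rng=np.random.default_rng(0))
    assert res.delegated == sorted(parent_geno)[0]
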