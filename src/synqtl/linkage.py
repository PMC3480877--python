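"""Two-point linkage analysis for single-parent (pseudo-testcross) data.

Each outbred parent is treated as a backcross parent: genotypes record
which of the parent's two alleles each full-sib progeny inherited (codes
0/1, NaN missing).  Because linkage phase is unknown, the recombination
fraction for a marker pair is estimated under both phase assignments and
the one with fewer recombinants kept: r_hat = min(r, k)/n capped at 0.5.
The two-point LOD is

    LOD = k*log10(2*(1-r_hat)) + r*log10(2*r_hat),   0*log10(0) := 0,

the log10 likelihood ratio against free recombination.  Markers are
grouped by single-linkage transitive closure over pairs exceeding a
sex-specific LOD threshold (defaults 4.0 female / 3.0 male), ordered by
greedy nearest-neighbour seriation with 2-opt improvement, and placed
with the Haldane map function (Kosambi available for output).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("synqtl")


@dataclass(frozen=True)
class TwoPointEstimate:
    marker_1: str
    marker_2: str
    n_informative: int
    r_hat: float
    lod: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_hat <= 0.5):
            raise ValueError("r_hat outside [0, 0.5]")


def lod_score(k: int, r: int) -> float:
    """Two-point LOD at the MLE r_hat = r/(k+r) (k non-recombinants)."""
    n = k + r
    r_hat = min(r / n, 0.5)
    lod = 0.0
    if k:
        lod += k * math.log10(2.0 * (1.0 - r_hat))
    if r:
        lod += r * math.log10(2.0 * r_hat)
    return lod


def estimate_rf_lod(genotypes: pd.DataFrame, m1: str, m2: str) -> TwoPointEstimate:
    """Two-point recombination fraction and LOD for one marker pair.

    Missing genotypes are dropped pairwise.  Phase is resolved by taking
    whichever assignment gives fewer recombinants.
    """
    g1 = genotypes[m1].to_numpy(float)
    g2 = genotypes[m2].to_numpy(float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no informative progeny for pair ({m1}, {m2})")
    mismatches = int((g1[ok] != g2[ok]).sum())
    r = min(mismatches, n - mismatches)
    k = n - r
    r_hat = min(r / n, 0.5)
    return TwoPointEstimate(marker_1=m1, marker_2=m2, n_informative=n, r_hat=r_hat, lod=lod_score(k, r))


def all_pairs(genotypes: pd.DataFrame) -> list[TwoPointEstimate]:
    markers = list(genotypes.columns)
    out = []
    for i, m1 in enumerate(markers):
        for m2 in markers[i + 1:]:
            out.append(estimate_rf_lod(genotypes, m1, m2))
    return out


def group_markers(
    markers: Sequence[str],
    estimates: Sequence[TwoPointEstimate],
    lod_threshold: float,
) -> list[list[str]]:
    """Single-linkage transitive closure over pairs with lod >= threshold.

    Unlinked markers come back as singleton groups.  The grouping is
    invariant to marker input order and relabelling; groups are returned
    largest first (ties by first member) with members sorted.
    """
    if lod_threshold <= 0:
        raise ValueError("lod_threshold must be positive")
    parent = {m: m for m in markers}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in estimates:
        if e.lod >= lod_threshold and e.marker_1 in parent and e.marker_2 in parent:
            ra, rb = find(e.marker_1), find(e.marker_2)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for m in markers:
        groups.setdefault(find(m), []).append(m)
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: (-len(g), g[0]))
    n_single = sum(1 for g in out if len(g) == 1)
    log.info("group_markers: %d groups (%d singletons) at LOD >= %g", len(out), n_single, lod_threshold)
    return out


def lod_threshold_for_sex(sex: str, lod_female: float = 4.0, lod_male: float = 3.0) -> float:
    if sex not in ("female", "male"):
        raise ValueError("sex must be female or male")
    return lod_female if sex == "female" else lod_male


def _tour_length(order: Sequence[int], d: np.ndarray) -> float:
    return float(sum(d[order[i], order[i + 1]] for i in range(len(order) - 1)))


def order_markers(
    group: Sequence[str],
    estimates: Sequence[TwoPointEstimate],
) -> list[str]:
    """Greedy nearest-neighbour seriation on r_hat with 2-opt improvement.

    Deterministic: the seed marker is the pair with smallest r_hat, ties
    broken by label; of the two equivalent orientations the one starting
    with the lexicographically smaller endpoint is returned.
    """
    group = list(group)
    if len(group) < 2:
        return group
    idx = {m: i for i, m in enumerate(group)}
    d = np.full((len(group), len(group)), 0.5)
    np.fill_diagonal(d, 0.0)
    for e in estimates:
        if e.marker_1 in idx and e.marker_2 in idx:
            d[idx[e.marker_1], idx[e.marker_2]] = e.r_hat
            d[idx[e.marker_2], idx[e.marker_1]] = e.r_hat

    # greedy path construction from the closest pair
    best_pair = min(
        ((i, j) for i in range(len(group)) for j in range(i + 1, len(group))),
        key=lambda t: (d[t], group[t[0]], group[t[1]]),
    )
    path = list(best_pair)
    remaining = [i for i in range(len(group)) if i not in path]
    remaining.sort(key=lambda i: group[i])
    while remaining:
        # append the marker closest to either end, at that end
        cand = min(remaining, key=lambda i: (min(d[i, path[0]], d[i, path[-1]]), group[i]))
        if d[cand, path[0]] < d[cand, path[-1]]:
            path.insert(0, cand)
        else:
            path.append(cand)
        remaining.remove(cand)

    # 2-opt on total adjacent r_hat
    improved = True
    while improved:
        improved = False
        for i in range(len(path) - 1):
            for j in range(i + 2, len(path) + (0 if i > 0 else -1)):
                new = path[:i + 1] + path[i + 1:j + 1][::-1] + path[j + 1:]
                if _tour_length(new, d) < _tour_length(path, d) - 1e-12:
                    path = new
                    improved = True

    ordered = [group[i] for i in path]
    if ordered[-1] < ordered[0]:
        ordered.reverse()
    return ordered


def map_distance(r_hat: float, function: str = "haldane") -> float:
    """Map distance in cM from a recombination fraction.

    Haldane (no interference, default): d = -50 ln(1 - 2r).
    Kosambi (output convenience only):  d = 25 ln((1+2r)/(1-2r)).
    """
    if not (0.0 <= r_hat < 0.5):
        raise ValueError("r_hat must lie in [0, 0.5)")
    if function == "haldane":
        return -50.0 * math.log(1.0 - 2.0 * r_hat)
    if function == "kosambi":
        return 25.0 * math.log((1.0 + 2.0 * r_hat) / (1.0 - 2.0 * r_hat))
    raise ValueError("function must be haldane or kosambi")


def recombination_fraction(d_cM: float, function: str = "haldane") -> float:
    """Inverse map function: expected recombination fraction across d cM."""
    if d_cM < 0:
        raise ValueError("distance must be >= 0")
    if function == "haldane":
        return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))
    if function == "kosambi":
        return 0.5 * math.tanh(2.0 * d_cM / 100.0)
    raise ValueError("function must be haldane or kosambi")


def build_map(
    genotypes: pd.DataFrame,
    sex: str,
    lod_female: float = 4.0,
    lod_male: float = 3.0,
    map_function: str = "haldane",
) -> pd.DataFrame:
    """End-to-end: two-point estimates -> groups -> order -> cM positions.

    Returns a tidy frame (marker, group, position_cM) consumable by the
    marker-map reader/writer.
    """
    estimates = all_pairs(genotypes)
    est_lookup = {frozenset((e.marker_1, e.marker_2)): e for e in estimates}
    threshold = lod_threshold_for_sex(sex, lod_female, lod_male)
    groups = group_markers(list(genotypes.columns), estimates, threshold)
    rows = []
    for gi, group in enumerate(groups, 1):
        ordered = order_markers(group, estimates)
        pos = 0.0
        for i, m in enumerate(ordered):
            if i > 0:
                e = est_lookup[frozenset((ordered[i - 1], m))]
                r = min(e.r_hat, 0.4999)
                pos += map_distance(r, map_function)
            rows.append({"marker": m, "group": f"LG{gi}", "position_cM": pos})
    return pd.DataFrame(rows)
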