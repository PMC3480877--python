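"""Trait preprocessing and QTL detection for outbred full-sib families.

Traits are tested for normality with a Lilliefors test (Kolmogorov-
Smirnov with estimated mean/sd, Monte-Carlo null), rank-inverse-normal
transformed when rejected, and adjusted for a sampling-order batch
effect (blood samples were processed in batches of 20) by keeping the
residuals of a batch ANOVA.  QTL scans are single-parent: a single-
marker scan (one-way F on the transmitted allele) and a Haley-Knott
style interval scan (regression of the trait on the expected allele
dose from flanking markers under Haldane recombination).  Chromosome-
wide significance comes from permutation of trait values against the
genotypes (p = (1 + #{perm max >= observed max}) / (1 + n_perm));
genome-wide status from a Benjamini-Hochberg FDR step over the
chromosome-wide p-values of QTL passing the 0.05 gate.  The QTL effect
size is reported as PEV, the model R-squared at the scan maximum.  A
combined-family single-marker analysis fits trait ~ family + per-parent
allele terms with a joint permutation test (permuting within family)
and per-parent partial R-squared.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .linkage import recombination_fraction
from .types import MapEntry, ScanResult

log = logging.getLogger("synqtl")


# ---------------------------------------------------------------------------
# Trait preprocessing


def lilliefors_mc(
    x: np.ndarray, n_draws: int = 5000, rng: Optional[np.random.Generator] = None
) -> tuple[float, float]:
    """Lilliefors normality test with a Monte-Carlo null.

    The statistic is the KS distance between the standardized sample and
    N(0,1); the null distribution accounts for the estimated mean/sd by
    re-standardizing each simulated Gaussian sample.  Returns (stat, p).
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, float)
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 observations")

    def ks_stat(v: np.ndarray) -> float:
        z = (v - v.mean()) / v.std(ddof=1)
        return stats.kstest(z, "norm").statistic

    obs = ks_stat(x)
    null = rng.standard_normal((n_draws, n))
    z = (null - null.mean(axis=1, keepdims=True)) / null.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    grid = np.arange(1, n + 1)
    cdf = stats.norm.cdf(z)
    d_plus = (grid / n - cdf).max(axis=1)
    d_minus = (cdf - (grid - 1) / n).max(axis=1)
    null_stats = np.maximum(d_plus, d_minus)
    p = (1 + int((null_stats >= obs - 1e-12).sum())) / (1 + n_draws)
    return obs, p


def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform."""
    x = np.asarray(x, float)
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


@dataclass
class TraitVector:
    """A preprocessed trait, aligned to progeny ids."""

    ids: list
    values: np.ndarray
    family: Optional[np.ndarray] = None
    order: Optional[np.ndarray] = None
    steps: list = field(default_factory=list)

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ids, name="value")


def preprocess_trait(
    trait: pd.DataFrame,
    alpha: float = 0.05,
    batch_size: int = 20,
    batch_mode: str = "categorical",
    n_draws: int = 5000,
    rng: Optional[np.random.Generator] = None,
) -> TraitVector:
    """Normality gate, optional normalization, sampling-order adjustment.

    ``trait`` has columns value / order / family indexed by progeny id.
    The Lilliefors test is applied at ``alpha``; on rejection the trait is
    rank-inverse-normal transformed.  The sampling-order effect is then
    removed by regressing on the order batch (categorical by default,
    ``batch_mode='linear'`` regresses on the raw order) and keeping the
    residuals.
    """
    rng = rng or np.random.default_rng()
    if len(trait) < 10:
        raise ValueError("need >= 10 observations")
    y = trait["value"].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("zero variance trait")
    steps = []
    stat, p = lilliefors_mc(y, n_draws=n_draws, rng=rng)
    if p <= alpha:
        y = rank_inverse_normal(y)
        steps.append(f"normality rejected (Lilliefors p={p:.4g}); inverse-normal transform applied")
    else:
        steps.append(f"normality not rejected (Lilliefors p={p:.4g}); no transform")

    order = trait["order"].to_numpy(float) if "order" in trait.columns else None
    if order is not None:
        if batch_mode == "categorical":
            batch = ((order - order.min()) // batch_size).astype(int)
            means = pd.Series(y).groupby(batch).transform("mean").to_numpy()
            y = y - means + y.mean()
            steps.append(f"sampling-order batch residuals (batch size {batch_size})")
        elif batch_mode == "linear":
            beta = np.polyfit(order, y, 1)
            y = y - np.polyval(beta, order) + y.mean()
            steps.append("sampling-order linear residuals")
        else:
            raise ValueError("batch_mode must be categorical or linear")
    for s in steps:
        log.info("preprocess_trait: %s", s)
    fam = trait["family"].to_numpy() if "family" in trait.columns else None
    return TraitVector(ids=list(trait.index), values=y, family=fam, order=order, steps=steps)


# ---------------------------------------------------------------------------
# Vectorized statistics (shared by scans and permutations)


def _f_two_group(g: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """One-way F (2 classes) of each Y column against binary g (no NaN)."""
    n = len(g)
    n1 = g.sum()
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return np.full(Y.shape[1], np.nan)
    s1 = g @ Y
    tot = Y.sum(axis=0)
    m1 = s1 / n1
    m0 = (tot - s1) / n0
    grand = tot / n
    ssb = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    sst = (Y**2).sum(axis=0) - n * grand**2
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / (n - 2))
    return np.where(ssw <= 1e-300, np.inf, f)


def _f_regression(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Simple-regression F of each Y column on x (no NaN in x)."""
    n = len(x)
    xc = x - x.mean()
    sxx = (xc**2).sum()
    if sxx == 0:
        return np.full(Y.shape[1], np.nan)
    Yc = Y - Y.mean(axis=0)
    sxy = xc @ Yc
    syy = (Yc**2).sum(axis=0)
    ssb = sxy**2 / sxx
    ssw = np.maximum(syy - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / (n - 2))
    return np.where(ssw <= 1e-300, np.inf, f)


def f_to_lod(f: float | np.ndarray, n: int) -> float | np.ndarray:
    """LOD-equivalent of a 1-df F statistic: (n/2) log10(RSS0/RSS1)."""
    r2 = f / (f + n - 2)
    return -(n / 2.0) * np.log10(1.0 - r2)


def f_to_pev(f: float, n: int) -> float:
    """Model R-squared at the scan maximum (fraction of variance)."""
    if math.isinf(f):
        return 1.0
    if math.isnan(f) or f < 0:
        return 0.0
    return f / (f + n - 2)


# ---------------------------------------------------------------------------
# Scans


def single_marker_scan(genotypes: pd.DataFrame, trait: pd.Series | np.ndarray) -> ScanResult:
    """Per-marker one-way F of the trait by transmitted allele.

    Missing genotypes are dropped per marker.  Markers with a single
    allele class are skipped (logged).
    """
    y_all = np.asarray(trait, float) if not isinstance(trait, pd.Series) else trait.loc[genotypes.index].to_numpy(float)
    positions, labels, fs, lods = [], [], [], []
    skipped = 0
    for j, marker in enumerate(genotypes.columns):
        g = genotypes[marker].to_numpy(float)
        ok = ~np.isnan(g) & ~np.isnan(y_all)
        g_ok, y_ok = g[ok], y_all[ok]
        if len(g_ok) < 3 or len(np.unique(g_ok)) < 2:
            skipped += 1
            continue
        f = float(_f_two_group(g_ok, y_ok[:, None])[0])
        positions.append(float(j))
        labels.append(marker)
        fs.append(f)
        lods.append(float(f_to_lod(f, len(g_ok))))
    if skipped:
        log.info("single_marker_scan: %d single-class markers skipped", skipped)
    return ScanResult(group="", positions=positions, labels=labels, f_stats=fs, lods=lods)


def _dose_matrix(
    genotypes: pd.DataFrame, entries: Sequence[MapEntry], step_cM: float
) -> tuple[np.ndarray, list[float], list[str]]:
    """Expected transmitted-allele dose at each grid point from flanking
    markers via Haldane probabilities.  Missing flanks are handled by
    one-sided conditioning; doubly missing gives dose 0.5."""
    markers = [e.marker for e in entries if e.marker in genotypes.columns]
    entries = [e for e in entries if e.marker in genotypes.columns]
    pos = np.array([e.position_cM for e in entries])
    G = genotypes[markers].to_numpy(float)
    n = G.shape[0]
    grid = list(np.arange(pos[0], pos[-1] + 1e-9, step_cM))
    if grid[-1] < pos[-1] - 1e-9:
        grid.append(pos[-1])
    labels = []
    D = np.empty((n, len(grid)))
    for gi, x in enumerate(grid):
        right = int(np.searchsorted(pos, x + 1e-12))
        left = right - 1
        if left < 0:
            left = 0
        if right >= len(pos):
            right = len(pos) - 1
        at_marker = abs(pos - x).min() < 1e-9
        if at_marker:
            j = int(abs(pos - x).argmin())
            labels.append(markers[j])
            gL = gR = G[:, j]
            rL = rR = 0.0
        else:
            labels.append(f"{markers[left]}@{x:.6g}cM")
            gL, gR = G[:, left], G[:, right]
            rL = recombination_fraction(x - pos[left])
            rR = recombination_fraction(pos[right] - x)
        dose = np.full(n, 0.5)
        okL, okR = ~np.isnan(gL), ~np.isnan(gR)
        # both flanks observed
        both = okL & okR
        if both.any():
            a, b = gL[both], gR[both]
            p1 = a * (1 - rL) + (1 - a) * rL  # P(x=1 | left allele)
            pb_1 = b * (1 - rR) + (1 - b) * rR  # P(right | x=1)
            pb_0 = b * rR + (1 - b) * (1 - rR)  # P(right | x=0)
            denom = p1 * pb_1 + (1 - p1) * pb_0
            dose[both] = p1 * pb_1 / denom
        onlyL = okL & ~okR
        if onlyL.any():
            a = gL[onlyL]
            dose[onlyL] = a * (1 - rL) + (1 - a) * rL
        onlyR = okR & ~okL
        if onlyR.any():
            b = gR[onlyR]
            dose[onlyR] = b * (1 - rR) + (1 - b) * rR
        D[:, gi] = dose
    return D, [float(x) for x in grid], labels


def interval_scan(
    genotypes: pd.DataFrame,
    entries: Sequence[MapEntry],
    trait: pd.Series | np.ndarray,
    step_cM: float = 1.0,
) -> ScanResult:
    """Haley-Knott interval scan along one linkage group.

    At each grid point the trait is regressed on the expected allele
    dose; at a fully informative marker the dose collapses to the
    genotype and the statistic equals the single-marker F.  Falls back
    to a single-marker scan when fewer than two markers are mapped.
    """
    group = entries[0].group if entries else ""
    mapped = [e for e in entries if e.marker in genotypes.columns]
    if len(mapped) < 2:
        log.warning("interval_scan: <2 mapped markers on %s; single-marker fallback", group)
        res = single_marker_scan(genotypes[[e.marker for e in mapped]], trait)
        res.group = group
        return res
    y = np.asarray(trait, float) if not isinstance(trait, pd.Series) else trait.loc[genotypes.index].to_numpy(float)
    D, grid, labels = _dose_matrix(genotypes, mapped, step_cM)
    n = len(y)
    fs, lods = [], []
    for gi in range(D.shape[1]):
        f = float(_f_regression(D[:, gi], y[:, None])[0])
        fs.append(f)
        lods.append(float(f_to_lod(f, n)))
    return ScanResult(group=group, positions=grid, labels=labels, f_stats=fs, lods=lods)


# ---------------------------------------------------------------------------
# Permutation thresholds


def _scan_max_matrix(
    genotypes: pd.DataFrame,
    Y: np.ndarray,
    entries: Optional[Sequence[MapEntry]] = None,
    step_cM: float = 1.0,
) -> np.ndarray:
    """Max scan statistic per Y column (vectorized over permutations)."""
    n_cols = Y.shape[1]
    maxima = np.full(n_cols, -np.inf)
    if entries is not None and len([e for e in entries if e.marker in genotypes.columns]) >= 2:
        D, _, _ = _dose_matrix(genotypes, list(entries), step_cM)
        for gi in range(D.shape[1]):
            f = _f_regression(D[:, gi], Y)
            maxima = np.fmax(maxima, np.where(np.isnan(f), -np.inf, f))
        return maxima
    for marker in genotypes.columns:
        g = genotypes[marker].to_numpy(float)
        ok = ~np.isnan(g)
        if ok.all():
            g_ok, Y_ok = g, Y
        else:
            g_ok, Y_ok = g[ok], Y[ok]
        if len(g_ok) < 3 or len(np.unique(g_ok)) < 2:
            continue
        f = _f_two_group(g_ok, Y_ok)
        maxima = np.fmax(maxima, np.where(np.isnan(f), -np.inf, f))
    return maxima


def permutation_threshold(
    genotypes: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    entries: Optional[Sequence[MapEntry]] = None,
    step_cM: float = 1.0,
) -> tuple[float, float, np.ndarray]:
    """Chromosome-wide empirical p for the observed scan maximum.

    Trait values are permuted against progeny ids; the scan maximum is
    recorded per permutation and p = (1 + #{perm max >= observed}) /
    (1 + n_perm), which can never be exactly zero.  Returns
    (p, observed max, permuted maxima).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng or np.random.default_rng()
    y = np.asarray(trait, float) if not isinstance(trait, pd.Series) else trait.loc[genotypes.index].to_numpy(float)
    observed = float(_scan_max_matrix(genotypes, y[:, None], entries, step_cM)[0])
    perms = np.empty((len(y), n_perm))
    for i in range(n_perm):
        perms[:, i] = rng.permutation(y)
    perm_max = _scan_max_matrix(genotypes, perms, entries, step_cM)
    p = (1 + int((perm_max >= observed - 1e-12).sum())) / (1 + n_perm)
    return p, observed, perm_max


# ---------------------------------------------------------------------------
# Genome-wide calls


def bh_fdr(chrom_p: Sequence[float], alpha: float = 0.05, gate: float = 0.05) -> list[bool]:
    """Genome-wide flags by Benjamini-Hochberg step-up.

    Only QTL already significant at the chromosome-wide ``gate`` enter
    the FDR step; flags are True for every gated p <= the largest p(i)
    with p(i) <= i*alpha/m (m = number gated).
    """
    p = np.asarray(list(chrom_p), float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    flags = np.zeros(p.size, bool)
    gated = p <= gate
    if gated.any():
        reject, *_ = multipletests(p[gated], alpha=alpha, method="fdr_bh")
        flags[gated] = reject
    return flags.tolist()


# ---------------------------------------------------------------------------
# Combined-family single-marker analysis


@dataclass
class CombinedScanResult:
    marker: str
    joint_f: float
    joint_p: float
    parent_partial_r2: dict
    n: int
    delegated: Optional[str] = None  # parent id when only one parent informative


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    proj = q.T @ Y
    return (Y**2).sum(axis=0) - (proj**2).sum(axis=0)


def combined_family_scan(
    parent_genotypes: Mapping[str, pd.Series],
    trait: pd.DataFrame,
    marker: str,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> CombinedScanResult:
    """Single-marker analysis with all parents from all families combined.

    Model: trait ~ family + one allele term per informative parent, each
    parent's transmitted allele centered within its family (progeny of
    other families contribute 0, keeping the design orthogonal to the
    family terms).  The joint F tests all allele terms at once; its
    empirical p permutes the trait within family.  Per-parent effects are
    reported as partial R-squared of each allele term.
    """
    rng = rng or np.random.default_rng()
    ids = list(trait.index)
    y = trait["value"].to_numpy(float)
    fam = np.asarray(trait["family"].astype(str))
    fam_levels = sorted(set(fam))
    n = len(y)

    cols = []
    names = []
    for parent, geno in sorted(parent_genotypes.items()):
        g = geno.reindex(ids).to_numpy(float)
        ok = ~np.isnan(g)
        if ok.sum() < 3 or len(np.unique(g[ok])) < 2:
            continue
        col = np.zeros(n)
        for f_level in fam_levels:
            m = ok & (fam == f_level)
            if m.sum() >= 2 and len(np.unique(g[m])) == 2:
                col[m] = g[m] - g[m].mean()
        if np.any(col != 0):
            cols.append(col)
            names.append(parent)
    if not cols:
        raise ValueError(f"marker {marker!r} informative in no parent")
    delegated = names[0] if len(cols) == 1 else None
    if delegated:
        log.info("combined_family_scan: marker %s informative in %s only; single-parent model", marker, delegated)

    X0 = np.column_stack([np.ones(n)] + [(fam == f_level).astype(float) for f_level in fam_levels[1:]])
    X1 = np.column_stack([X0] + cols)
    Y = y[:, None]
    rss0 = _rss(X0, Y)[0]
    rss1 = _rss(X1, Y)[0]
    q = len(cols)
    df_res = n - X1.shape[1]
    joint_f = ((rss0 - rss1) / q) / (rss1 / df_res) if rss1 > 0 else np.inf

    # permutation within family
    perms = np.empty((n, n_perm))
    base = np.arange(n)
    fam_idx = [np.where(fam == f_level)[0] for f_level in fam_levels]
    for i in range(n_perm):
        order = base.copy()
        for idx in fam_idx:
            order[idx] = rng.permutation(idx)
        perms[:, i] = y[order]
    rss0_p = _rss(X0, perms)
    rss1_p = _rss(X1, perms)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_f = ((rss0_p - rss1_p) / q) / (rss1_p / df_res)
    joint_p = (1 + int((perm_f >= joint_f - 1e-12).sum())) / (1 + n_perm)

    partial = {}
    for k, parent in enumerate(names):
        Xr = np.column_stack([X0] + [c for j, c in enumerate(cols) if j != k])
        rss_r = _rss(Xr, Y)[0]
        partial[parent] = float((rss_r - rss1) / rss_r) if rss_r > 0 else 0.0

    return CombinedScanResult(
        marker=marker, joint_f=float(joint_f), joint_p=joint_p,
        parent_partial_r2=partial, n=n, delegated=delegated,
    )
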