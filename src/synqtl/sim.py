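"""Synthetic data: WGD-evolved genomes and outbred full-sib crosses.

Genome side
-----------
A labelled proto (2R) genome evolves along a small species tree: one
tip keeps the 2R state (a rearrangement-poor proxy, playing medaka's
role), a second tip passes through one whole-genome duplication (the 3R
genome, playing stickleback's role), and a third passes through a
second duplication on top of that (the 4R genome, playing a salmonid's
role).  Each WGD duplicates every chromosome; each new gene copy is
retained independently with a retention probability; Poisson numbers of
fusions, fissions, terminal translocations and inversions rearrange
chromosomes on every branch.  Rearrangements operate on gene-index
boundaries so the truth bookkeeping stays exact.  Homology percentages
between surviving copies decay additively per branch (Gaussian
per-copy-per-branch decay) plus measurement noise — a deliberately
simple stand-in for sequence evolution.  The generator emits every
table the comparative modules read (gene tables, ortholog and paralogue
tables, BLAST-tabular hit files with E-values monotone in identity,
marker maps) alongside a full truth record.

Cross side
----------
Outbred full-sib families under a pseudo-testcross model: per parent,
progeny transmitted alleles follow a Markov walk along each linkage
group with Haldane recombination probabilities from adjacent cM gaps
(no interference, so closed-form checks hold).  The trait is a sum of
planted additive QTL effects (each scaled to explain its stated
fraction of total variance), a family effect, a batch effect over
sampling order (batches of 20) and Gaussian residual noise.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .linkage import recombination_fraction
from .types import GeneRow, GeneTable, HomologyHit, MapEntry, MarkerMap, ParalogPair

# ---------------------------------------------------------------------------
# Genome simulation


@dataclass(frozen=True)
class GeneCopy:
    anc: int            # ancestral gene id
    lineage: str        # ancestral chromosome (2R lineage label)
    copy_id: str
    history: tuple      # ((branch_tag, decay), ...) — shared prefix = shared evolution


@dataclass
class SimGenomeParams:
    n_ancestral_chroms: int = 6
    genes_per_chrom: int = 60
    wgd_rounds: int = 2
    fusion_rate: float = 0.0
    fission_rate: float = 0.0
    translocation_rate: float = 0.5
    inversion_rate: float = 0.5
    retention_prob: float = 0.7
    decay_mean: float = 8.0
    decay_sd: float = 2.0
    noise_sd: float = 2.0
    gene_spacing_bp: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.retention_prob <= 1):
            raise ValueError("retention_prob outside [0, 1]")
        for r in (self.fusion_rate, self.fission_rate, self.translocation_rate, self.inversion_rate):
            if r < 0:
                raise ValueError("rearrangement rates must be >= 0")
        if self.wgd_rounds < 0:
            raise ValueError("wgd_rounds must be >= 0")


Genome = dict[str, list[GeneCopy]]  # chromosome name -> ordered gene copies


@dataclass
class SimTruth:
    """Planted genome history: everything emitted is derivable from here."""

    genealogy: dict = field(default_factory=dict)
    # anc gene id -> list of (genome_id, copy_id, chrom, pos_bp, lineage)
    homeolog_pairs: dict = field(default_factory=dict)
    # genome_id -> list of [chrom_a, chrom_b] mirror pairs as named at the
    #   most recent WGD (chromosomes may later be renamed/lost by
    #   fusion/fission)
    homeolog_partners: dict = field(default_factory=dict)
    # genome_id -> list of [chrom_a, chrom_b]: content-based pairing of the
    #   emitted genome — for each chromosome, the chromosome holding the
    #   plurality of its genes' WGD-partner copies (exact bookkeeping,
    #   reflects planted translocations/fusions)
    lineage_segments: dict = field(default_factory=dict)
    # genome_id -> chrom -> per-gene lineage labels in order
    qtl: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genealogy": {str(k): v for k, v in self.genealogy.items()},
            "homeolog_pairs": {k: [sorted(p) for p in v] for k, v in self.homeolog_pairs.items()},
            "homeolog_partners": {k: [sorted(p) for p in v] for k, v in self.homeolog_partners.items()},
            "lineage_segments": self.lineage_segments,
            "qtl": self.qtl,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _ancestral_genome(params: SimGenomeParams) -> Genome:
    letters = string.ascii_uppercase
    if params.n_ancestral_chroms > len(letters):
        raise ValueError("too many ancestral chromosomes for single-letter lineages")
    genome: Genome = {}
    gid = 0
    for ci in range(params.n_ancestral_chroms):
        lineage = letters[ci]
        chrom = f"anc{ci + 1}"
        genome[chrom] = [
            GeneCopy(anc=gid + k, lineage=lineage, copy_id=f"g{gid + k:05d}.0", history=())
            for k in range(params.genes_per_chrom)
        ]
        gid += params.genes_per_chrom
    return genome


def _wgd(genome: Genome, tag: str) -> tuple[Genome, list[tuple[str, str]]]:
    """Duplicate every chromosome; returns the duplicated genome and the
    planted mirror pairs."""
    out: Genome = {}
    mirrors = []
    for chrom, genes in genome.items():
        ca, cb = f"{chrom}{tag}a", f"{chrom}{tag}b"
        # zero-cost divergence markers make the two copies' histories
        # structurally distinct from the duplication onward
        out[ca] = [GeneCopy(g.anc, g.lineage, g.copy_id + "a", g.history + ((f"{tag}a", 0.0),))
                   for g in genes]
        out[cb] = [GeneCopy(g.anc, g.lineage, g.copy_id + "b", g.history + ((f"{tag}b", 0.0),))
                   for g in genes]
        mirrors.append((ca, cb))
    return out, mirrors


def _retention(genome: Genome, prob: float, rng: np.random.Generator) -> Genome:
    out: Genome = {}
    for chrom in sorted(genome):
        kept = [g for g in genome[chrom] if rng.random() < prob]
        if kept:
            out[chrom] = kept
    return out


def _apply_decay(genome: Genome, branch: str, params: SimGenomeParams, rng: np.random.Generator) -> Genome:
    out: Genome = {}
    for chrom in sorted(genome):
        out[chrom] = [
            GeneCopy(
                g.anc, g.lineage, g.copy_id,
                g.history + ((branch, float(max(rng.normal(params.decay_mean, params.decay_sd), 0.0))),),
            )
            for g in genome[chrom]
        ]
    return out


def _rearrange(genome: Genome, params: SimGenomeParams, rng: np.random.Generator) -> Genome:
    """Poisson counts of fusions / fissions / terminal translocations /
    inversions, on gene-index boundaries."""
    genome = {c: list(g) for c, g in genome.items()}
    counter = [0]

    def fresh(base: str) -> str:
        counter[0] += 1
        return f"{base}.r{counter[0]}"

    def pick_chrom(min_genes: int = 1) -> Optional[str]:
        ok = sorted(c for c in genome if len(genome[c]) >= min_genes)
        return None if not ok else ok[rng.integers(len(ok))]

    for _ in range(rng.poisson(params.fusion_rate)):
        if len(genome) < 2:
            break
        a = pick_chrom()
        b = pick_chrom()
        while b == a:
            b = pick_chrom()
        genome[fresh(a)] = genome.pop(a) + genome.pop(b)
    for _ in range(rng.poisson(params.fission_rate)):
        c = pick_chrom(min_genes=2)
        if c is None:
            break
        genes = genome.pop(c)
        cut = int(rng.integers(1, len(genes)))
        genome[fresh(c)] = genes[:cut]
        genome[fresh(c)] = genes[cut:]
    for _ in range(rng.poisson(params.translocation_rate)):
        if len(genome) < 2:
            break
        a = pick_chrom(min_genes=2)
        b = pick_chrom(min_genes=2)
        while b == a:
            b = pick_chrom(min_genes=2)
        if a is None or b is None:
            break
        ga, gb = genome[a], genome[b]
        cut_a = int(rng.integers(1, len(ga)))
        cut_b = int(rng.integers(1, len(gb)))
        genome[a] = ga[:cut_a] + gb[cut_b:]
        genome[b] = gb[:cut_b] + ga[cut_a:]
    for _ in range(rng.poisson(params.inversion_rate)):
        c = pick_chrom(min_genes=2)
        if c is None:
            break
        genes = genome[c]
        i = int(rng.integers(0, len(genes) - 1))
        j = int(rng.integers(i + 1, len(genes) + 1))
        genome[c] = genes[:i] + genes[i:j][::-1] + genes[j:]
    return genome


def _divergence(a: GeneCopy, b: GeneCopy) -> float:
    """Summed decay on both sides since the copies' shared history ends."""
    k = 0
    for ha, hb in zip(a.history, b.history):
        if ha != hb:
            break
        k += 1
    return sum(d for _, d in a.history[k:]) + sum(d for _, d in b.history[k:])


def _identity(a: GeneCopy, b: GeneCopy, noise_sd: float, rng: np.random.Generator) -> float:
    raw = 100.0 - _divergence(a, b) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return float(min(max(raw, 0.0), 100.0))


@dataclass
class SimGenomes:
    params: SimGenomeParams
    genomes: dict            # genome_id -> Genome
    truth: SimTruth
    rng: np.random.Generator

    # -- emitted tables ------------------------------------------------

    def gene_table(self, genome_id: str) -> GeneTable:
        rows = []
        genome = self.genomes[genome_id]
        spacing = self.params.gene_spacing_bp
        for chrom in sorted(genome):
            for i, g in enumerate(genome[chrom]):
                rows.append(GeneRow(gene=g.copy_id, chromosome=chrom, start_bp=(i + 1) * spacing))
        return GeneTable(rows=tuple(rows))

    def gene_order(self, genome_id: str) -> dict[str, list[str]]:
        return {c: [g.copy_id for g in genes] for c, genes in self.genomes[genome_id].items()}

    def _copies_by_anc(self, genome_id: str) -> dict[int, list[tuple[str, int, GeneCopy]]]:
        out: dict[int, list[tuple[str, int, GeneCopy]]] = {}
        spacing = self.params.gene_spacing_bp
        for chrom in sorted(self.genomes[genome_id]):
            for i, g in enumerate(self.genomes[genome_id][chrom]):
                out.setdefault(g.anc, []).append((chrom, (i + 1) * spacing, g))
        return out

    def paralog_table(self, genome_id: str) -> list[ParalogPair]:
        """All within-genome pairs of surviving copies of one ancestral gene."""
        pairs = []
        for anc, copies in sorted(self._copies_by_anc(genome_id).items()):
            for i in range(len(copies)):
                for j in range(i + 1, len(copies)):
                    ca, pa, ga = copies[i]
                    cb, pb, gb = copies[j]
                    pairs.append(
                        ParalogPair(
                            gene_a=ga.copy_id, chrom_a=ca, pos_a=pa,
                            gene_b=gb.copy_id, chrom_b=cb, pos_b=pb,
                            homology_pct=_identity(ga, gb, self.params.noise_sd, self.rng),
                        )
                    )
        return pairs

    def ortholog_table(self, genome_a: str, genome_b: str) -> list[ParalogPair]:
        """Cross-genome pairs of surviving copies of one ancestral gene
        (a-side genome_a, b-side genome_b)."""
        by_anc_b = self._copies_by_anc(genome_b)
        pairs = []
        for anc, copies_a in sorted(self._copies_by_anc(genome_a).items()):
            for ca, pa, ga in copies_a:
                for cb, pb, gb in by_anc_b.get(anc, ()):
                    pairs.append(
                        ParalogPair(
                            gene_a=ga.copy_id, chrom_a=ca, pos_a=pa,
                            gene_b=gb.copy_id, chrom_b=cb, pos_b=pb,
                            homology_pct=_identity(ga, gb, self.params.noise_sd, self.rng),
                        )
                    )
        return pairs

    def true_homeolog_pairs(self, genome_id: str) -> set[frozenset]:
        """Content-based homeolog pairing of one genome.

        The partner of a gene copy is the copy created alongside it at
        the genome's most recent WGD (copy ids differ in the final
        duplication suffix).  Each chromosome pairs with the chromosome
        holding the plurality of its genes' surviving partners; the
        genome-level pairing is the union over chromosomes, mirroring
        how the detector reconciles directions.
        """
        genome = self.genomes[genome_id]
        location = {g.copy_id: chrom for chrom, genes in genome.items() for g in genes}
        pairs: set[frozenset] = set()
        for chrom in sorted(genome):
            counts: dict[str, int] = {}
            for g in genome[chrom]:
                flip = "b" if g.copy_id.endswith("a") else "a"
                partner = location.get(g.copy_id[:-1] + flip)
                if partner is not None and partner != chrom:
                    counts[partner] = counts.get(partner, 0) + 1
            if counts:
                best = max(sorted(counts), key=lambda c: counts[c])
                pairs.add(frozenset((chrom, best)))
        return pairs

    def blast_hits(self, marker_map: MarkerMap, marker_genes: Mapping[str, str],
                   subject_genome: str) -> list[HomologyHit]:
        """BLAST-tabular style hits of map markers onto a sequenced genome.

        ``marker_genes`` maps marker name -> gene copy_id in the mapped
        genome; each surviving ortholog of the underlying ancestral gene
        in ``subject_genome`` yields one hit.  Synthesized E-values are
        monotone decreasing in identity.
        """
        by_anc = self._copies_by_anc(subject_genome)
        # locate the marker's own copy to compute pair identity
        all_copies = {}
        for genome_id in self.genomes:
            for chrom, genes in self.genomes[genome_id].items():
                for g in genes:
                    all_copies[g.copy_id] = g
        hits = []
        for e in marker_map.entries:
            copy_id = marker_genes.get(e.marker)
            if copy_id is None:
                continue
            ga = all_copies[copy_id]
            for cb, pb, gb in by_anc.get(ga.anc, ()):
                ident = _identity(ga, gb, self.params.noise_sd, self.rng)
                evalue = 10.0 ** (-(max(ident - 55.0, 0.0)))
                hits.append(
                    HomologyHit(
                        query_id=e.marker, subject_chrom=cb,
                        subject_start=pb, subject_end=pb + 1000,
                        evalue=evalue, identity_pct=ident,
                    )
                )
        return hits


def simulate_wgd_genomes(params: SimGenomeParams) -> SimGenomes:
    """Evolve proxy (2R), 3R and 4R genomes from a labelled ancestor.

    Genome ids: '2R' (proxy tip, decay only, no rearrangements — the
    rearrangement-poor outgroup), '3R' (one WGD), '4R' (two WGDs, the
    second applied to the 3R state).
    """
    rng = np.random.default_rng(params.seed)
    truth = SimTruth()
    anc = _ancestral_genome(params)

    # proxy tip: decay only (rearrangement-poor by construction)
    proxy = _apply_decay(anc, "b_proxy", params, rng)

    genomes: dict[str, Genome] = {"2R": proxy}
    state = anc
    mirrors_by_round = {}
    ids = ["3R", "4R"]
    for round_i in range(params.wgd_rounds):
        tag = f"w{round_i + 1}"
        state, mirrors = _wgd(state, tag)
        state = _retention(state, params.retention_prob, rng)
        state = _apply_decay(state, f"b_{tag}", params, rng)
        state = _rearrange(state, params, rng)
        gid = ids[round_i] if round_i < len(ids) else f"R{round_i + 1}"
        # keep only mirror pairs whose both chromosomes still exist by name
        mirrors_by_round[gid] = [(a, b) for a, b in mirrors if a in state and b in state]
        genomes[gid] = state

    sim = SimGenomes(params=params, genomes=genomes, truth=truth, rng=rng)
    spacing = params.gene_spacing_bp
    for genome_id, genome in genomes.items():
        for chrom in sorted(genome):
            for i, g in enumerate(genome[chrom]):
                truth.genealogy.setdefault(g.anc, []).append(
                    (genome_id, g.copy_id, chrom, (i + 1) * spacing, g.lineage)
                )
        truth.lineage_segments[genome_id] = {
            chrom: [g.lineage for g in genome[chrom]] for chrom in sorted(genome)
        }
    truth.homeolog_pairs = {gid: [list(p) for p in ms] for gid, ms in mirrors_by_round.items()}
    truth.homeolog_partners = {
        gid: [sorted(p) for p in sorted(sim.true_homeolog_pairs(gid), key=sorted)]
        for gid in mirrors_by_round
    }
    return sim


def emit_marker_map(
    sim: SimGenomes,
    genome_id: str,
    density: float = 0.3,
    cM_per_Mbp: float = 1.5,
    jitter_sd: float = 0.0,
    parent_id: Optional[str] = None,
    sex: str = "female",
    rng: Optional[np.random.Generator] = None,
) -> tuple[MarkerMap, dict[str, str]]:
    """Subsample genes of one genome as mapped markers.

    Marker names derive from the ancestral gene id (``m<anc>``), so the
    same locus carries the same name on maps of different genomes; when
    several surviving copies of one ancestral gene are sampled in one
    genome (duplicated loci), the later ones (by chromosome, position)
    get a ``_2``/``_3`` suffix to keep names unique within a parent.
    Returns the map plus marker -> gene copy_id provenance.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    rng = rng or sim.rng
    entries = []
    marker_genes: dict[str, str] = {}
    genome = sim.genomes[genome_id]
    spacing = sim.params.gene_spacing_bp
    for chrom in sorted(genome):
        for i, g in enumerate(genome[chrom]):
            if rng.random() >= density:
                continue
            name = f"m{g.anc:05d}"
            k = 2
            while name in marker_genes:
                name = f"m{g.anc:05d}_{k}"
                k += 1
            marker_genes[name] = g.copy_id
            pos_cM = (i + 1) * spacing / 1e6 * cM_per_Mbp
            if jitter_sd > 0:
                pos_cM += rng.normal(0.0, jitter_sd)
            entries.append(MapEntry(marker=name, group=chrom, position_cM=max(pos_cM, 0.0)))
    group_order = {c: k for k, c in enumerate(sorted(genome))}
    entries.sort(key=lambda e: (group_order[e.group], e.position_cM, e.marker))
    return (
        MarkerMap(parent_id=parent_id or f"{genome_id}_map", sex=sex, entries=tuple(entries)),
        marker_genes,
    )


# ---------------------------------------------------------------------------
# Cross simulation


@dataclass(frozen=True)
class PlantedQtl:
    group: str
    position_cM: float
    variance_frac: float
    parents: Optional[tuple] = None  # parent ids; None = segregating in all


@dataclass
class SimCrossParams:
    n_progeny: int = 100            # per family
    n_families: int = 2
    missing_rate: float = 0.0
    qtl: tuple = ()
    family_sd: float = 0.5
    batch_sd: float = 0.3
    residual_sd: float = 1.0
    batch_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate outside [0, 1)")
        total = sum(q.variance_frac for q in self.qtl)
        if total >= 1:
            raise ValueError("QTL variance fractions must sum to < 1")


def uniform_map(
    n_groups: int = 3, markers_per_group: int = 10, length_cM: float = 90.0,
    parent_id: str = "sim", sex: str = "female",
) -> MarkerMap:
    """Evenly spaced markers, the default study map for cross simulations."""
    entries = []
    for g in range(1, n_groups + 1):
        step = length_cM / max(markers_per_group - 1, 1)
        for m in range(markers_per_group):
            entries.append(
                MapEntry(marker=f"LG{g}M{m + 1:02d}", group=f"LG{g}", position_cM=m * step)
            )
    return MarkerMap(parent_id=parent_id, sex=sex, entries=tuple(entries))


@dataclass
class SimCross:
    params: SimCrossParams
    marker_map: MarkerMap
    genotypes: dict          # parent id -> DataFrame (progeny x markers), NaN = missing
    traits: pd.DataFrame     # value / order / family indexed by progeny id
    truth: dict              # qtl genotypes, effects, family/batch draws


def _walk(positions: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Markov walk of transmitted alleles along one group (Haldane)."""
    out = np.empty((n, len(positions)), dtype=float)
    out[:, 0] = rng.integers(0, 2, size=n)
    for j in range(1, len(positions)):
        r = recombination_fraction(positions[j] - positions[j - 1])
        flip = rng.random(n) < r
        out[:, j] = np.where(flip, 1 - out[:, j - 1], out[:, j - 1])
    return out


def simulate_cross(marker_map: MarkerMap, params: SimCrossParams) -> SimCross:
    """Simulate the full multi-family pseudo-testcross design.

    QTL positions must lie within their group's map span.  Each planted
    QTL is scaled so that, marginally, it explains its stated fraction
    of the total trait variance.
    """
    rng = np.random.default_rng(params.seed)
    groups = marker_map.groups
    spans = {g: (marker_map.group_entries(g)[0].position_cM,
                 marker_map.group_entries(g)[-1].position_cM) for g in groups}
    for q in params.qtl:
        if q.group not in spans:
            raise ValueError(f"QTL group {q.group!r} not on map")
        lo, hi = spans[q.group]
        if not (lo <= q.position_cM <= hi):
            raise ValueError(f"QTL position {q.position_cM} outside map span of {q.group}")

    families = [f"F{i + 1}" for i in range(params.n_families)]
    parents = {fam: (f"{fam}_female", f"{fam}_male") for fam in families}
    all_parents = [p for fam in families for p in parents[fam]]
    progeny_ids = [f"{fam}_p{k + 1:04d}" for fam in families for k in range(params.n_progeny)]
    fam_of = np.repeat(families, params.n_progeny)
    n_total = len(progeny_ids)

    # per parent, per group: simulate walk over marker+QTL positions
    genotypes: dict[str, pd.DataFrame] = {}
    qtl_geno: dict[str, dict[int, np.ndarray]] = {p: {} for p in all_parents}
    for fam in families:
        fam_mask = fam_of == fam
        for parent in parents[fam]:
            cols: dict[str, np.ndarray] = {}
            for g in groups:
                entries = marker_map.group_entries(g)
                pos = [e.position_cM for e in entries]
                names = [e.marker for e in entries]
                qtl_here = [(qi, q) for qi, q in enumerate(params.qtl) if q.group == g]
                aug = sorted(
                    [(p_, ("M", nm)) for p_, nm in zip(pos, names)]
                    + [(q.position_cM, ("Q", qi)) for qi, q in qtl_here],
                    key=lambda t: t[0],
                )
                walk = _walk(np.array([a for a, _ in aug]), params.n_progeny, rng)
                for j, (_, (kind, key)) in enumerate(aug):
                    if kind == "M":
                        cols[key] = walk[:, j]
                    else:
                        qtl_geno[parent][key] = walk[:, j]
            G = pd.DataFrame(cols, index=[pid for pid, f in zip(progeny_ids, fam_of) if f == fam])
            G = G[[e.marker for e in marker_map.entries]]
            if params.missing_rate > 0:
                mask = rng.random(G.shape) < params.missing_rate
                G = G.mask(mask)
            genotypes[parent] = G

    # trait assembly
    total_qtl_frac = sum(q.variance_frac for q in params.qtl)
    base_var = params.family_sd**2 + params.batch_sd**2 + params.residual_sd**2
    total_var = base_var / (1.0 - total_qtl_frac) if total_qtl_frac < 1 else base_var

    y = np.zeros(n_total)
    qtl_truth = []
    for qi, q in enumerate(params.qtl):
        designated = list(q.parents) if q.parents is not None else all_parents
        term = np.zeros(n_total)
        k_per_progeny = np.zeros(n_total)
        for parent in designated:
            fam = parent.rsplit("_", 1)[0]
            m = fam_of == fam
            term[m] += qtl_geno[parent][qi][: m.sum()] - 0.5
            k_per_progeny[m] += 1
        kbar = k_per_progeny.mean()
        if kbar == 0:
            raise ValueError(f"QTL {qi} has no designated parents on the design")
        a = math.sqrt(q.variance_frac * total_var / (0.25 * kbar))
        y += a * term
        qtl_truth.append(
            {"group": q.group, "position_cM": q.position_cM,
             "variance_frac": q.variance_frac, "effect": a,
             "parents": designated}
        )

    fam_effects = {fam: rng.normal(0.0, params.family_sd) for fam in families}
    y += np.array([fam_effects[f] for f in fam_of])

    order = rng.permutation(n_total) + 1  # sampling order, 1-based
    n_batches = int(np.ceil(n_total / params.batch_size))
    batch_effects = rng.normal(0.0, params.batch_sd, size=n_batches)
    batch_idx = (order - 1) // params.batch_size
    y += batch_effects[batch_idx]
    y += rng.normal(0.0, params.residual_sd, size=n_total)

    traits = pd.DataFrame(
        {"value": y, "order": order, "family": fam_of}, index=progeny_ids
    )
    truth = {
        "qtl": qtl_truth,
        "qtl_genotypes": {p: {qi: g.tolist() for qi, g in d.items()} for p, d in qtl_geno.items()},
        "family_effects": fam_effects,
        "batch_effects": batch_effects.tolist(),
        "total_var": total_var,
    }
    return SimCross(params=params, marker_map=marker_map, genotypes=genotypes, traits=traits, truth=truth)
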