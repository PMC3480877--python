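"""Shared domain types for the comparative-synteny / QTL pipeline.

Coordinate conventions
----------------------
Genomic (sequence) positions are 1-based inclusive base pairs, matching
BLAST tabular output and gene-table conventions.  Genetic-map positions
are centimorgans stored as floats.  Inputs given in Mbp (as candidate-gene
tables often are) must be converted to bp on read (x 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class Arm:
    """A named chromosome arm spanning [start, end] in the chromosome's unit."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"arm {self.label}: end < start")


@dataclass(frozen=True)
class Chromosome:
    """One chromosome or linkage group of a genome layout.

    ``unit`` is 'bp' for sequenced genomes and 'cM' for linkage maps.
    Centromere position, if known, must lie within [0, length].
    """

    name: str
    length: float
    unit: str = "bp"
    centromere: Optional[float] = None
    arms: tuple[Arm, ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.unit not in ("bp", "cM"):
            raise ValueError(f"chromosome {self.name}: unit must be bp or cM")
        if self.centromere is not None and not (0 <= self.centromere <= self.length):
            raise ValueError(f"chromosome {self.name}: centromere outside [0, length]")
        prev_end = None
        for arm in sorted(self.arms, key=lambda a: a.start):
            if arm.start < 0 or arm.end > self.length:
                raise ValueError(f"chromosome {self.name}: arm {arm.label} outside chromosome")
            if prev_end is not None and arm.start < prev_end:
                raise ValueError(f"chromosome {self.name}: overlapping arms")
            prev_end = arm.end

    def arm_of(self, pos: float) -> Optional[str]:
        for arm in self.arms:
            if arm.start <= pos <= arm.end:
                return arm.label
        return None


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome inventory of one genome, with true (unscaled) lengths."""

    genome_id: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"chromosome {name!r} not in layout {self.genome_id!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)


@dataclass(frozen=True)
class HomologyHit:
    """One alignment of a query locus (marker or gene) to a subject chromosome.

    ``query_group``/``query_pos`` are attached by joining against a marker
    map and may be None straight after parsing a BLAST table.
    """

    query_id: str
    subject_chrom: str
    subject_start: int
    subject_end: int
    evalue: float
    identity_pct: float
    query_group: Optional[str] = None
    query_pos: Optional[float] = None
    query_arm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subject_end < self.subject_start:
            raise ValueError(f"hit {self.query_id}: subject_end < subject_start")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"hit {self.query_id}: identity_pct outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}: negative E-value")


@dataclass(frozen=True)
class MapEntry:
    marker: str
    group: str
    position_cM: float
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position_cM < 0:
            raise ValueError(f"marker {self.marker}: negative cM position")


@dataclass(frozen=True)
class MarkerMap:
    """An ordered sex-specific marker map for one outbred parent.

    Entries are sorted by (group, position); ties keep file order.  Marker
    names are unique within a parent.
    """

    parent_id: str
    sex: str
    entries: tuple[MapEntry, ...]

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        names = [e.marker for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names in map: {dupes}")
        # stable sort on position within each group
        by_group: dict[str, float] = {}
        for e in self.entries:
            prev = by_group.get(e.group)
            if prev is not None and e.position_cM < prev:
                raise ValueError(f"group {e.group} not sorted by position (marker {e.marker})")
            by_group[e.group] = e.position_cM

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.group not in seen:
                seen.append(e.group)
        return seen

    def group_entries(self, group: str) -> list[MapEntry]:
        return [e for e in self.entries if e.group == group]

    def marker_names(self) -> set[str]:
        return {e.marker for e in self.entries}

    def position_of(self, marker: str) -> MapEntry:
        for e in self.entries:
            if e.marker == marker:
                return e
        raise KeyError(marker)


def sort_map_entries(entries: Sequence[MapEntry]) -> tuple[tuple[MapEntry, ...], bool]:
    """Stable-sort entries by (group-first-appearance, position). Returns
    (sorted entries, whether the input order changed)."""
    group_order: dict[str, int] = {}
    for e in entries:
        group_order.setdefault(e.group, len(group_order))
    indexed = list(enumerate(entries))
    indexed.sort(key=lambda t: (group_order[t[1].group], t[1].position_cM, t[0]))
    out = tuple(e for _, e in indexed)
    return out, list(out) != list(entries)


@dataclass(frozen=True)
class GeneRow:
    gene: str
    chromosome: str
    start_bp: int
    end_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError(f"gene {self.gene}: start_bp must be >= 1 (1-based)")
        if self.end_bp is not None and self.end_bp < self.start_bp:
            raise ValueError(f"gene {self.gene}: end_bp < start_bp")


@dataclass(frozen=True)
class GeneTable:
    """Positions of genes on a sequenced genome (1-based bp)."""

    rows: tuple[GeneRow, ...]

    def by_chromosome(self) -> dict[str, list[GeneRow]]:
        out: dict[str, list[GeneRow]] = {}
        for r in self.rows:
            out.setdefault(r.chromosome, []).append(r)
        for rows in out.values():
            rows.sort(key=lambda r: r.start_bp)
        return out

    def position_of(self, gene: str) -> GeneRow:
        for r in self.rows:
            if r.gene == gene:
                return r
        raise KeyError(gene)


@dataclass(frozen=True)
class ParalogPair:
    """A within-genome gene pair with an opaque homology percentage —
    the substrate for homeolog (WGD paralogon) detection."""

    gene_a: str
    chrom_a: str
    pos_a: int
    gene_b: str
    chrom_b: str
    pos_b: int
    homology_pct: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair for gene {self.gene_a}")
        if not (0.0 <= self.homology_pct <= 100.0):
            raise ValueError(f"pair {self.gene_a}/{self.gene_b}: homology outside [0,100]")


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal run of >= min_block contiguous query loci whose accepted
    hits co-locate on one subject chromosome."""

    query_group: str
    subject_chrom: str
    query_span: tuple[float, float]
    subject_span: tuple[float, float]
    members: tuple[HomologyHit, ...]
    query_arm: Optional[str] = None

    @property
    def size(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("empty block")
        if any(m.subject_chrom != self.subject_chrom for m in self.members):
            raise ValueError("block members on mixed subject chromosomes")


@dataclass(frozen=True)
class HomeologBlock:
    """A run of contiguous source-chromosome genes whose retained paralogues
    all point at the same target chromosome of the same genome."""

    source_chrom: str
    target_chrom: str
    source_span: tuple[int, int]
    members: tuple[ParalogPair, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PaintedSegment:
    """A chromosome interval labelled with a 2R ancestral lineage."""

    chrom: str
    span: tuple[float, float]
    lineage: str
    support: int

    def __post_init__(self) -> None:
        if self.lineage != "unassigned" and self.support < 2:
            raise ValueError("assigned segment requires support >= 2")


@dataclass(frozen=True)
class GenePrediction:
    """Predicted linkage-group location of a candidate gene, transferred
    through a synteny block from a sequenced relative."""

    gene: str
    source_chrom: str
    source_pos: int
    group: str
    arm: Optional[str]
    status: str  # 'contained' | 'proximal'
    distance_bp: float
    block: SyntenyBlock

    def __post_init__(self) -> None:
        if self.status not in ("contained", "proximal"):
            raise ValueError("status must be contained or proximal")
        if (self.distance_bp == 0) != (self.status == "contained"):
            raise ValueError("distance 0 iff contained")


@dataclass(frozen=True)
class QtlHomologyRecord:
    """Cross-species pair of QTL-bearing linkage groups with synteny evidence."""

    species_a: str
    group_a: str
    traits_a: tuple[str, ...]
    species_b: str
    group_b: str
    traits_b: tuple[str, ...]
    evidence: tuple[str, ...]  # subset of {shared_marker_block, shared_subject_chrom}

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("record requires at least one evidence item")


@dataclass
class ScanResult:
    """Per-position QTL scan statistics along one linkage group."""

    group: str
    positions: "list[float]"
    labels: "list[str]"
    f_stats: "list[float]"
    lods: "list[float]"

    @property
    def max_statistic(self) -> float:
        return max(self.f_stats) if self.f_stats else float("nan")

    @property
    def max_index(self) -> int:
        import numpy as _np

        return int(_np.nanargmax(self.f_stats))

    @property
    def max_position(self) -> float:
        return self.positions[self.max_index]

    @property
    def max_label(self) -> str:
        return self.labels[self.max_index]


@dataclass(frozen=True)
class QtlCall:
    """One QTL call: scan maximum with its permutation p and PEV."""

    group: str
    trait: str
    parent: str
    marker_or_interval: str
    chrom_p: float
    pev: float
    genome_wide: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.chrom_p <= 1):
            raise ValueError("chrom_p must lie in (0, 1]")
        if not (0 <= self.pev <= 1):
            raise ValueError("pev must lie in [0, 1]")
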