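"""Readers and writers for every tabular format the pipeline touches.

All formats are plain text: BLAST 12-column tabular (outfmt 6) for
homology hits, TSV for marker maps / gene tables / paralogue tables /
genotypes / traits / block tables, and the Circos karyotype and links
grammars for ideogram export.  Read-then-write round trips are lossless
at full float precision (floats are serialized with ``repr``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    GeneRow,
    GeneTable,
    GenomeLayout,
    HomologyHit,
    MapEntry,
    MarkerMap,
    ParalogPair,
    SyntenyBlock,
    sort_map_entries,
)

log = logging.getLogger("synqtl")

MISSING_CODES = {"NA", "na", "", ".", "-9"}

# BLAST outfmt 6: qseqid sseqid pident length mismatch gapopen
#                 qstart qend sstart send evalue bitscore
BLAST_NCOLS = 12


class ParseError(ValueError):
    pass


def _fmt(x: float) -> str:
    """Full-precision float serialization (ints stay ints)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Parse a 12-column BLAST tabular file into homology hits.

    Comment lines starting with ``#`` are skipped.  Subject coordinates
    are normalised so start <= end (minus-strand hits arrive reversed).
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != BLAST_NCOLS:
                raise ParseError(
                    f"{path}:{lineno}: expected {BLAST_NCOLS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                sstart = int(float(fields[8]))
                send = int(float(fields[9]))
                evalue = float(fields[10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_chrom=fields[1],
                    subject_start=min(sstart, send),
                    subject_end=max(sstart, send),
                    evalue=evalue,
                    identity_pct=pident,
                )
            )
    log.info("read %d hits from %s", len(hits), path)
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits back out in the 12-column dialect (alignment-detail
    columns that the pipeline does not model are filled with 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_chrom,
                        _fmt(h.identity_pct),
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        str(h.subject_start),
                        str(h.subject_end),
                        _fmt(h.evalue),
                        "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Marker maps


def read_marker_map(
    path: str | Path, parent_id: Optional[str] = None, sex: Optional[str] = None
) -> MarkerMap:
    """Read a TSV marker map (columns: marker, group, arm, position_cM).

    Header may also carry parent/sex metadata lines (``#parent=``,
    ``#sex=``).  Entries are returned sorted within each group by
    position; an unsorted input is sorted (stably) and the permutation
    logged.  Duplicate marker names are an error listing both lines.
    """
    meta: dict[str, str] = {}
    entries: list[MapEntry] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, _, v = line.lstrip("#").partition("=")
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                required = {"marker", "group", "position_cm"}
                if not required <= set(header):
                    raise ParseError(f"{path}: header must contain {sorted(required)}")
                continue
            row = dict(zip(header, fields))
            marker = row["marker"]
            if marker in seen:
                raise ParseError(
                    f"{path}: duplicate marker {marker!r} on lines {seen[marker]} and {lineno}"
                )
            seen[marker] = lineno
            try:
                pos = float(row["position_cm"])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric position") from None
            if pos < 0:
                raise ParseError(f"{path}:{lineno}: negative cM position")
            arm = row.get("arm") or None
            if arm in ("", "NA", "."):
                arm = None
            entries.append(MapEntry(marker=marker, group=row["group"], position_cM=pos, arm=arm))
    sorted_entries, changed = sort_map_entries(entries)
    if changed:
        log.info("marker map %s was not position-sorted; sorted on read", path)
    return MarkerMap(
        parent_id=parent_id or meta.get("parent", "unknown"),
        sex=sex or meta.get("sex", "female"),
        entries=sorted_entries,
    )


def write_marker_map(mm: MarkerMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#parent={mm.parent_id}\n#sex={mm.sex}\n")
        fh.write("marker\tgroup\tarm\tposition_cM\n")
        for e in mm.entries:
            fh.write(f"{e.marker}\t{e.group}\t{e.arm or 'NA'}\t{_fmt(e.position_cM)}\n")


# ---------------------------------------------------------------------------
# Gene tables (BED-like TSV, 1-based bp starts)


def read_gene_table(path: str | Path, mbp: bool = False) -> GeneTable:
    """Read a gene-position TSV (gene, chromosome, start_bp[, end_bp]).

    With ``mbp=True`` the start column is interpreted as Mbp (as in
    candidate-gene tables) and converted to bp by x 1e6.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    rows = []
    for _, r in df.iterrows():
        start = float(r["start_bp" if "start_bp" in df.columns else "start"])
        if mbp:
            start *= 1e6
        end = None
        if "end_bp" in df.columns and not pd.isna(r["end_bp"]):
            end = int(r["end_bp"])
        rows.append(
            GeneRow(gene=str(r["gene"]), chromosome=str(r["chromosome"]), start_bp=int(round(start)), end_bp=end)
        )
    return GeneTable(rows=tuple(rows))


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchromosome\tstart_bp\tend_bp\n")
        for r in table.rows:
            fh.write(f"{r.gene}\t{r.chromosome}\t{r.start_bp}\t{r.end_bp if r.end_bp is not None else 'NA'}\n")


# ---------------------------------------------------------------------------
# Paralogue tables


def read_paralog_table(path: str | Path) -> list[ParalogPair]:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    pairs = []
    for _, r in df.iterrows():
        pairs.append(
            ParalogPair(
                gene_a=str(r["gene_a"]),
                chrom_a=str(r["chrom_a"]),
                pos_a=int(r["pos_a"]),
                gene_b=str(r["gene_b"]),
                chrom_b=str(r["chrom_b"]),
                pos_b=int(r["pos_b"]),
                homology_pct=float(r["homology_pct"]),
            )
        )
    return pairs


def write_paralog_table(pairs: Iterable[ParalogPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tchrom_a\tpos_a\tgene_b\tchrom_b\tpos_b\thomology_pct\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.chrom_a}\t{p.pos_a}\t{p.gene_b}\t{p.chrom_b}\t{p.pos_b}\t{_fmt(p.homology_pct)}\n"
            )


# ---------------------------------------------------------------------------
# Genotype / trait tables


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Progeny x marker matrix of transmitted-allele codes {0, 1, NaN};
    first column is the progeny id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=sorted(MISSING_CODES))
    bad = set(np.unique(df.values[~pd.isna(df.values)])) - {0, 1, 0.0, 1.0}
    if bad:
        raise ParseError(f"{path}: genotype codes outside {{0,1,NA}}: {sorted(bad)}")
    return df.astype(float)


def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "progeny"
    text = out.to_csv(sep="\t", na_rep="NA", float_format="%.0f")
    Path(path).write_text(text)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Trait table: progeny id, value, sampling order, family."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    for col in ("value", "order", "family"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def write_traits(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "progeny"
    Path(path).write_text(out.to_csv(sep="\t"))


# ---------------------------------------------------------------------------
# Block tables


def write_block_table(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "query_group\tquery_arm\tquery_start\tquery_end\t"
            "subject_chrom\tsubject_start\tsubject_end\tsize\tmembers\n"
        )
        for b in blocks:
            fh.write(
                "\t".join(
                    [
                        b.query_group,
                        b.query_arm or "NA",
                        _fmt(b.query_span[0]),
                        _fmt(b.query_span[1]),
                        b.subject_chrom,
                        _fmt(b.subject_span[0]),
                        _fmt(b.subject_span[1]),
                        str(b.size),
                        ",".join(m.query_id for m in b.members),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Circos export

_PALETTE = [
    "chr1", "chr2", "chr3", "chr4", "chr5", "chr6", "chr7", "chr8",
    "chr9", "chr10", "chr11", "chr12", "chr13", "chr14", "chr15",
    "chr16", "chr17", "chr18", "chr19", "chr20", "chr21", "chr22",
]

CIRCOS_UNITS = 100  # every chromosome is standardized to 100 units


def scale_position(pos: float, length: float) -> float:
    """Affine per-chromosome scaling onto the 100-unit ideogram axis."""
    return CIRCOS_UNITS * pos / length


def write_circos_karyotype(layouts: Sequence[GenomeLayout], path: str | Path) -> None:
    """Karyotype file with every chromosome standardized to 100 units."""
    lines = []
    i = 0
    for layout in layouts:
        for chrom in layout.chromosomes:
            colour = _PALETTE[i % len(_PALETTE)]
            ident = f"{layout.genome_id}.{chrom.name}"
            lines.append(f"chr - {ident} {chrom.name} 0 {CIRCOS_UNITS} {colour}")
            i += 1
    if not lines:
        log.warning("circos karyotype: no chromosomes to write")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_circos_links(
    blocks: Sequence[SyntenyBlock],
    query_layout: GenomeLayout,
    subject_layout: GenomeLayout,
    path: str | Path,
    highlight_groups: Optional[set[str]] = None,
) -> None:
    """One link line per synteny block, both end intervals rescaled to the
    100-unit system.  Blocks on groups in ``highlight_groups`` (e.g.
    QTL-bearing linkage groups) carry a colour attribute."""
    lines = []
    for b in blocks:
        if b.query_group not in query_layout:
            raise KeyError(f"block query group {b.query_group!r} not in layout")
        if b.subject_chrom not in subject_layout:
            raise KeyError(f"block subject chromosome {b.subject_chrom!r} not in layout")
        qlen = query_layout.chromosome(b.query_group).length
        slen = subject_layout.chromosome(b.subject_chrom).length
        q0, q1 = (scale_position(p, qlen) for p in b.query_span)
        s0, s1 = (scale_position(p, slen) for p in b.subject_span)
        line = (
            f"{query_layout.genome_id}.{b.query_group} {q0:.3f} {q1:.3f} "
            f"{subject_layout.genome_id}.{b.subject_chrom} {s0:.3f} {s1:.3f}"
        )
        if highlight_groups and b.query_group in highlight_groups:
            line += " color=red"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
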