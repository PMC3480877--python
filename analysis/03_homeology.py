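#!/usr/bin/env python
"""Detect homeologous (WGD-duplicated) chromosome pairs in the 3R genome
from its paralogue table: 50% homology floor, 5% rank tolerance, blocks
of >= 2 contiguous loci, symmetric pairing report; then score the calls
against the planted truth.

Reads results/genomes/, writes results/homeology/.
"""

import json
from pathlib import Path

from synqtl import homeology, io
from synqtl.config import PipelineConfig

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig()
    out = BASE / "homeology"
    out.mkdir(parents=True, exist_ok=True)
    pairs = io.read_paralog_table(BASE / "genomes" / "paralogs_3R.tsv")
    genes = io.read_gene_table(BASE / "genomes" / "genes_3R.tsv")
    gene_order = {c: [r.gene for r in rows] for c, rows in genes.by_chromosome().items()}
    hblocks, called = homeology.detect_homeologs(
        pairs, gene_order,
        floor_pct=cfg.paralog_floor_pct, tolerance_frac=cfg.tolerance_frac,
        tolerance_mode=cfg.tolerance_mode, min_block=cfg.min_block, max_gap=cfg.max_gap,
    )
    with open(out / "homeolog_pairs.tsv", "w") as fh:
        fh.write("chrom_a\tchrom_b\n")
        for a, b in sorted(tuple(sorted(p)) for p in called):
            fh.write(f"{a}\t{b}\n")
    report = homeology.homeolog_pairs(hblocks)
    with open(out / "pairing_report.tsv", "w") as fh:
        fh.write("source_chrom\tdominant_target\tclassification\ttargets\n")
        for r in report:
            targets = ";".join(f"{t}:{m}" for t, m, _ in r.targets)
            fh.write(f"{r.source_chrom}\t{r.dominant_target}\t{r.classification}\t{targets}\n")

    truth = json.loads((BASE / "genomes" / "truth.json").read_text())
    planted = {frozenset(p) for p in truth["homeolog_partners"]["3R"]}
    tp = len(called & planted)
    print(f"{len(hblocks)} homeolog blocks; {len(called)} chromosome pairs called")
    print(f"vs planted truth: precision {tp / len(called):.3f}, recall {tp / len(planted):.3f}")


if __name__ == "__main__":
    main()
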