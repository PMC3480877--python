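#!/usr/bin/env python
"""Simulate the study genomes: a 2R proxy, a 3R genome and a 4R genome
descended from a labelled proto-genome through two whole-genome
duplications, with gene loss, translocations and inversions.

Writes gene tables, the within-3R paralogue table, cross-genome ortholog
tables, a 4R marker map, marker-vs-3R homology hits (BLAST tabular) and
the full truth record under results/genomes/.
"""

import json
from pathlib import Path

from synqtl import io, sim

SEED = 2012
OUT = Path(__file__).resolve().parent.parent / "results" / "genomes"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = sim.SimGenomeParams(
        n_ancestral_chroms=6, genes_per_chrom=60,
        retention_prob=0.7, translocation_rate=0.5, inversion_rate=0.5,
        noise_sd=2.0, seed=SEED,
    )
    s = sim.simulate_wgd_genomes(params)
    for gid, genome in s.genomes.items():
        io.write_gene_table(s.gene_table(gid), OUT / f"genes_{gid}.tsv")
        print(f"{gid}: {len(genome)} chromosomes, "
              f"{sum(len(g) for g in genome.values())} gene copies")
    io.write_paralog_table(s.paralog_table("3R"), OUT / "paralogs_3R.tsv")
    io.write_paralog_table(s.ortholog_table("3R", "2R"), OUT / "orthologs_3R_2R.tsv")

    mmap, marker_genes = sim.emit_marker_map(s, "4R", density=0.3)
    io.write_marker_map(mmap, OUT / "map_4R.tsv")
    (OUT / "marker_genes.json").write_text(json.dumps(marker_genes, indent=0, sort_keys=True))
    hits = s.blast_hits(mmap, marker_genes, "3R")
    io.write_blast_tab(hits, OUT / "hits_4R_vs_3R.tsv")
    s.truth.to_json(OUT / "truth.json")
    print(f"map: {len(mmap.entries)} markers on {len(mmap.groups)} groups; "
          f"{len(hits)} homology hits vs the 3R genome")


if __name__ == "__main__":
    main()
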