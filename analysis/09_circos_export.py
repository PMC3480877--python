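#!/usr/bin/env python
"""Export the 4R-vs-3R synteny block set as Circos karyotype and links
files, every chromosome standardized to 100 units, with QTL-bearing
linkage groups highlighted.

Reads results/genomes/, results/blocks/ and results/qtl/, writes
results/circos/.
"""

from pathlib import Path

import pandas as pd

from synqtl import io
from synqtl.types import Chromosome, GenomeLayout

BASE = Path(__file__).resolve().parent.parent / "results"

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "gene_transfer_driver", Path(__file__).with_name("05_gene_transfer.py"))
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
read_block_table = _mod.read_block_table


def main() -> None:
    out = BASE / "circos"
    out.mkdir(parents=True, exist_ok=True)
    blocks = read_block_table(BASE / "blocks" / "blocks_4R_vs_3R.tsv")
    mmap = io.read_marker_map(BASE / "genomes" / "map_4R.tsv")
    genes3 = io.read_gene_table(BASE / "genomes" / "genes_3R.tsv")

    span = {g: max(e.position_cM for e in mmap.group_entries(g)) + 1.0 for g in mmap.groups}
    qlay = GenomeLayout("4R", tuple(Chromosome(g, span[g], unit="cM") for g in mmap.groups))
    lengths3 = {c: rows[-1].start_bp + 1e6 for c, rows in genes3.by_chromosome().items()}
    slay = GenomeLayout("3R", tuple(Chromosome(c, L) for c, L in sorted(lengths3.items())))

    qtl_groups: set[str] = set()
    calls_path = BASE / "qtl" / "qtl_calls.tsv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path, sep="\t")
        qtl_groups = set(calls.loc[calls["P"] <= 0.05, "group"].astype(str))

    io.write_circos_karyotype([qlay, slay], out / "karyotype.txt")
    io.write_circos_links(blocks, qlay, slay, out / "links.txt",
                          highlight_groups=qtl_groups or None)
    print(f"{len(qlay.chromosomes) + len(slay.chromosomes)} ideograms, "
          f"{len(blocks)} links ({len(qtl_groups)} QTL-bearing groups highlighted)")


if __name__ == "__main__":
    main()
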