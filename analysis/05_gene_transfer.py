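#!/usr/bin/env python
"""Transfer candidate-gene positions from the sequenced 3R genome onto
the map-only 4R genome through marker-map synteny blocks ('contained'
inside a block's subject span, 'proximal' within the 2 Mbp flank), and
score predictions against the planted gene genealogy.

Reads results/genomes/ and results/blocks/, writes results/transfer/.
"""

import collections
import json
from pathlib import Path

from synqtl import ancestry, io
from synqtl.config import PipelineConfig
from synqtl.types import HomologyHit, SyntenyBlock

BASE = Path(__file__).resolve().parent.parent / "results"


def read_block_table(path: Path) -> list[SyntenyBlock]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        h = HomologyHit("member", str(r["subject_chrom"]),
                        int(r["subject_start"]), int(r["subject_end"]), 0.0, 100.0)
        out.append(SyntenyBlock(
            query_group=str(r["query_group"]), subject_chrom=str(r["subject_chrom"]),
            query_span=(float(r["query_start"]), float(r["query_end"])),
            subject_span=(float(r["subject_start"]), float(r["subject_end"])),
            members=(h,) * int(r["size"]),
            query_arm=None if str(r["query_arm"]) == "NA" else str(r["query_arm"]),
        ))
    return out


def main() -> None:
    cfg = PipelineConfig()
    out = BASE / "transfer"
    out.mkdir(parents=True, exist_ok=True)
    genes = io.read_gene_table(BASE / "genomes" / "genes_3R.tsv")
    blocks = read_block_table(BASE / "blocks" / "blocks_4R_vs_3R.tsv")
    preds = ancestry.transfer_gene_positions(genes, blocks, flank_bp=cfg.flank_bp)
    with open(out / "gene_predictions.tsv", "w") as fh:
        fh.write("gene\tsource_chrom\tsource_pos\tpredicted_group\tstatus\tdistance_bp\n")
        for p in preds:
            fh.write(f"{p.gene}\t{p.source_chrom}\t{p.source_pos}\t{p.group}\t"
                     f"{p.status}\t{p.distance_bp:.0f}\n")

    truth = json.loads((BASE / "genomes" / "truth.json").read_text())
    loc4 = {copy_id: chrom
            for entries in truth["genealogy"].values()
            for genome_id, copy_id, chrom, *_ in entries if genome_id == "4R"}
    by_gene = collections.defaultdict(set)
    for p in preds:
        by_gene[p.gene].add(p.group)
    ok = tot = 0
    for row in genes.rows:
        descendants = {loc4[row.gene + sfx] for sfx in ("a", "b") if row.gene + sfx in loc4}
        if not descendants:
            continue
        tot += 1
        ok += bool(by_gene.get(row.gene, set()) & descendants)
    print(f"{len(preds)} predictions for {len(by_gene)} genes")
    print(f"{ok}/{tot} surviving genes predicted on a true 4R group ({ok / tot:.3f})")


if __name__ == "__main__":
    main()
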