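#!/usr/bin/env python
"""Filter 4R-marker-vs-3R homology hits at the acceptance thresholds
(E <= 1e-4, identity >= 60%) and chain them into synteny blocks of two
or more contiguous loci along the 4R marker map; summarize per-group
subject-chromosome affinities.

Reads results/genomes/, writes results/blocks/.
"""

from pathlib import Path

from synqtl import blocks, io
from synqtl.config import PipelineConfig

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = PipelineConfig()
    out = BASE / "blocks"
    out.mkdir(parents=True, exist_ok=True)
    hits = io.read_blast_tab(BASE / "genomes" / "hits_4R_vs_3R.tsv")
    accepted = blocks.filter_hits(hits, blocks.FilterThresholds(cfg.evalue_max, cfg.identity_min))
    mmap = io.read_marker_map(BASE / "genomes" / "map_4R.tsv")
    bl = blocks.build_blocks(mmap, accepted, min_block=cfg.min_block, max_gap=cfg.max_gap)
    io.write_block_table(bl, out / "blocks_4R_vs_3R.tsv")
    print(f"{len(accepted)}/{len(hits)} hits accepted; {len(bl)} synteny blocks")

    summary = blocks.summarize_arm_affinities(bl)
    classes = summary.multiplicity_classes()
    with open(out / "arm_affinities.tsv", "w") as fh:
        fh.write("group\tarm\tsubject_chromosomes\tmultiplicity\n")
        for (group, arm), chroms in summary.affinities.items():
            fh.write(f"{group}\t{arm or 'NA'}\t{','.join(chroms)}\t{len(chroms)}\n")
    print(f"affinity multiplicity classes (1/2/>=3): "
          f"{classes[1]}/{classes[2]}/{classes[3]} "
          f"({classes[0]} arms with no synteny alignment)")


if __name__ == "__main__":
    main()
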