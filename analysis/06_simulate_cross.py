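#!/usr/bin/env python
"""Simulate the mapping-panel design on the simulated 4R genome's marker
map: two outbred full-sib families (100 progeny each, four parents),
two planted QTL on distinct 4R linkage groups, a family effect, a
sampling-order batch effect (batches of 20) and Gaussian residual noise.

Reads results/genomes/map_4R.tsv, writes genotype/trait tables and
truth under results/cross/.
"""

import json
from pathlib import Path

from synqtl import io, sim

SEED = 2012
BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = BASE / "cross"
    out.mkdir(parents=True, exist_ok=True)
    mmap = io.read_marker_map(BASE / "genomes" / "map_4R.tsv")

    # plant QTL mid-span on the two best-covered linkage groups
    coverage = sorted(mmap.groups, key=lambda g: -len(mmap.group_entries(g)))
    g1, g2 = coverage[:2]

    def midpoint(group: str) -> float:
        entries = mmap.group_entries(group)
        return 0.5 * (entries[0].position_cM + entries[-1].position_cM)

    params = sim.SimCrossParams(
        n_progeny=100, n_families=2, missing_rate=0.05,
        qtl=(
            sim.PlantedQtl(g1, round(midpoint(g1), 2), 0.20, parents=("F1_female",)),
            sim.PlantedQtl(g2, round(midpoint(g2), 2), 0.10,
                           parents=("F1_female", "F1_male")),
        ),
        family_sd=0.5, batch_sd=0.3, residual_sd=1.0, seed=SEED,
    )
    cross = sim.simulate_cross(mmap, params)
    for parent, G in cross.genotypes.items():
        io.write_genotypes(G, out / f"genotypes_{parent}.tsv")
    io.write_traits(cross.traits, out / "traits.tsv")
    (out / "truth.json").write_text(json.dumps(cross.truth, default=str, indent=1))
    print(f"{len(cross.traits)} progeny in {params.n_families} families, "
          f"{len(mmap.entries)} markers on {len(mmap.groups)} groups, "
          f"{len(params.qtl)} planted QTL")
    for q in cross.truth["qtl"]:
        print(f"  QTL {q['group']}@{q['position_cM']}cM: variance fraction "
              f"{q['variance_frac']}, allele effect {q['effect']:.3f}, "
              f"segregating in {','.join(q['parents'])}")


if __name__ == "__main__":
    main()
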