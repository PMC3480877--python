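import numpy as np
import pytest

from synqtl import sim
from synqtl.types import HomologyHit, MapEntry, MarkerMap


@pytest.fixture
def simple_map() -> MarkerMap:
    """Two linkage groups, five loci each, 10 cM spacing."""
    entries = []
    for g in ("LG1", "LG2"):
        for i in range(5):
            entries.append(
                MapEntry(marker=f"{g}m{i + 1}", group=g, position_cM=10.0 * i,
                         arm="p" if i < 2 else "q")
            )
    return MarkerMap(parent_id="P1", sex="female", entries=tuple(entries))


def hit(query: str, chrom: str, start: int = 100, evalue: float = 1e-20,
        identity: float = 90.0) -> HomologyHit:
    return HomologyHit(
        query_id=query, subject_chrom=chrom, subject_start=start,
        subject_end=start + 500, evalue=evalue, identity_pct=identity,
    )


@pytest.fixture
def small_genomes() -> sim.SimGenomes:
    return sim.simulate_wgd_genomes(
        sim.SimGenomeParams(n_ancestral_chroms=3, genes_per_chrom=30, seed=42)
    )


@pytest.fixture
def clean_wgd() -> sim.SimGenomes:
    """One WGD, no rearrangement, no loss, no noise."""
    return sim.simulate_wgd_genomes(
        sim.SimGenomeParams(
            n_ancestral_chroms=3, genes_per_chrom=20, wgd_rounds=1,
            fusion_rate=0, fission_rate=0, translocation_rate=0, inversion_rate=0,
            retention_prob=1.0, noise_sd=0.0, decay_sd=0.0, seed=1,
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120824)
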