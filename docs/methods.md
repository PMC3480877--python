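# Methods

This note records the models, conventions and design choices behind
`synqtl`, in the order the pipeline runs them.

## Coordinates and formats

Genomic positions are 1-based inclusive base pairs (BLAST convention);
tables given in Mbp are converted by ×10⁶ on read. Genetic-map positions
are centimorgans as reals. Homology hits arrive as 12-column BLAST
tabular; minus-strand subject coordinates are normalised to
start ≤ end on read. An E-value printed as 0 is stored as 0.0 and passes
any threshold. All writers serialize floats at full precision, so
read–write round trips are lossless and fixed-seed pipeline runs are
byte-identical. Circos export rescales every chromosome to 100 units
(scaled = 100·pos/length), exactly mapping endpoints to 0 and 100; true
lengths are never altered internally.

## Synteny blocks

Hits are accepted when E ≤ `evalue_max` (default 10⁻⁴) **and**
identity ≥ `identity_min` (default 60%). A query may keep hits on several
subject chromosomes: duplicated loci are expected in WGD genomes, and a
locus can belong to one block per subject chromosome.

Blocks are maximal runs of contiguous hit-bearing loci along the ordered
map whose hits share one subject chromosome; runs shorter than
`min_block` (default 2) are discarded. Two readings of "contiguous" are
supported: strict adjacency (`max_gap = 0`, the default and the
conservative reading) and gapped runs tolerating up to `max_gap`
interposed loci whose hits lie elsewhere. Loci with no accepted hits are
invisible to the run in either mode. No within-block subject-order
(collinearity) requirement is imposed — blocks capture segment-to-
chromosome affinity, not gene-order conservation. Ties at equal query cM
keep file order, for determinism. Block merging
(`merge_blocks`) unions same-(group, subject) blocks whose query spans
are within `merge_gap` (default 0: no merging unless requested).

`shared_marker_homology` treats marker names present on two maps as
perfect hits (identity 100, E 0) and reuses the same run logic, with the
second map's groups in the subject role; block subject coordinates are
then on an integer-scaled cM axis.

## Homeolog detection

The paralogue table is an opaque-percentage pair list. The pipeline:
floor filter (pairs < 50% homology removed; exactly 50% retained), then
per-source-gene rank/tolerance pruning. "Within 5% of the top-ranked
match" is read as relative by default (keep homology ≥ 0.95 × top); an
absolute mode (top − 5 points) is provided because either reading is
defensible; the top match itself always survives. Same-chromosome pairs
(tandem duplicates) are excluded from block building — they are not
homeology evidence — but counted in logs. Pairs are evaluated in both
directions (each gene as source once) and the chromosome pairing report
is the union over directions of each source chromosome's dominant target
(ranked by member count, ties by span). A pairing is "conserved" when
the dominant target holds ≥ 50% of members, else "mosaic".

## Ancestry painting and gene transfer

Painting reuses the run machinery on orthologue pairs against a proxy
genome whose chromosomes carry supplied lineage labels (the pipeline
never reconstructs the ancestor itself). When overlapping blocks claim a
gene, the larger block wins; assigned runs that fall below `min_block`
after that resolution are demoted to unassigned. Segment boundaries sit
at midpoints between adjacent genes of differing lineage, so on
noise-free data a recovered breakpoint is within one gene-gap of truth;
per chromosome the segments are disjoint and tile [1, length].

Gene transfer: a gene whose position lies inside a block's subject span
yields a "contained" prediction for the block's query group; within
`flank_bp` (default 2 Mbp — an explicit, logged choice for "proximal"
calls) it yields a "proximal" prediction with its distance. Predictions
are monotone in the flank. Cross-species QTL homology connects
QTL-bearing group pairs via shared-marker blocks or via blocks to a
common subject chromosome; the default requires overlapping subject
intervals, a relaxed mode accepts chromosome-level identity. Records are
emitted in both directions, so the evidence relation is symmetric.

## Linkage

Genotypes are transmitted-allele codes per parent (pseudo-testcross).
Phase is unknown in outbred parents, so each pair is scored under both
phases and the one with fewer recombinants kept: with k non-recombinant
and r recombinant among n informative progeny (pairwise-complete
deletion), r̂ = min(r, k)/n capped at 0.5 and
LOD = k·log₁₀(2(1−r̂)) + r·log₁₀(2r̂) with 0·log₁₀0 := 0. This LOD is the
profile maximum over r ∈ [0, 0.5] (grid-checked in the tests). Grouping
is single-linkage transitive closure at sex-specific thresholds (4.0
female, 3.0 male); unlinked markers are reported as singletons. Ordering
is greedy nearest-neighbour seriation on r̂ with 2-opt improvement —
deterministic, canonicalized by reversing to the lexicographically
smaller endpoint — and is a stand-in for a full multipoint likelihood
order. Distances use Haldane (no interference) so that closed-form
checks against the simulator hold exactly; Kosambi is available as an
output convention only.

## QTL analysis

Trait preprocessing: a Lilliefors test (KS statistic with estimated
mean/sd, Monte-Carlo null of ≥ 5000 re-standardized Gaussian samples) at
α = 0.05; on rejection the trait is rank-inverse-normal transformed
(Blom). The sampling-order effect is removed by keeping residuals of a
batch ANOVA (categorical batches of 20, matching the blood-processing
protocol of sampling 20 fish between spins; a linear-in-order mode is
available). The batch model is the default because the protocol is
batchwise; all steps are logged.

Scans: the single-marker statistic is the one-way F of the trait by
transmitted allele (equal to t²). The interval scan is Haley–Knott
regression of the trait on the expected allele dose at each grid point,
computed from flanking genotypes via Haldane probabilities; missing
flanks fall back to one-sided conditioning and doubly-missing to dose
0.5. At a fully informative marker the dose collapses to the genotype
and the interval statistic equals the single-marker F exactly. The
statistic is reported both as F and as a LOD equivalent,
(n/2)·log₁₀(RSS₀/RSS₁). The interval model replaces a proprietary
multipoint likelihood package with an openly specified regression; this
is a declared substitution, not an emulation.

Chromosome-wide significance: trait values are permuted against progeny
(n_perm = 1000 by default) and p = (1 + #{perm max ≥ observed max}) /
(1 + n_perm) — the +1 correction keeps p > 0. Genome-wide status:
QTL passing the chromosome-wide 0.05 gate enter a Benjamini–Hochberg
step-up at α = 0.05 across all scans of a trait. PEV is the model R² at
the scan maximum, R² = F/(F + n − 2) for the 1-df scans.

Combined-family analysis: trait ~ family + one allele term per
informative parent, each parent's allele centered within its family
(other families' progeny contribute 0, keeping allele terms orthogonal
to family terms). The joint F tests all allele terms; its empirical p
permutes the trait **within** family, preserving the family structure
under the null. Per-parent effects are partial R² of each allele term.
When only one parent is informative the model reduces to the
single-parent path and says so. The reported `P` for a QTL call is
always the empirical permutation p, not a model-based p.

## Synthetic data

The genome generator emulates the 2R → 3R → 4R history: a labelled proto
genome (default 6 chromosomes × 60 genes, one lineage letter per
chromosome, genes at 1 Mbp spacing) evolves along three tips — a proxy
that only diverges (rearrangement-poor by construction, playing the 2R
outgroup role), a 3R tip with one WGD, and a 4R tip with a second WGD on
top of the 3R state. After each WGD every copy is retained independently
with `retention_prob` (default 0.7, i.e. 30% per-copy loss); Poisson
numbers of fusions, fissions, terminal-segment translocations and
inversions (defaults 0, 0, 0.5, 0.5 per branch) act on gene-index
boundaries so the truth bookkeeping stays exact. Homology between two
surviving copies is 100 minus the per-copy Gaussian decay (mean 8 sd 2
points per branch) summed over both histories since their divergence
point, plus measurement noise (sd 2), truncated to [0, 100]. Divergence
points are tracked structurally (zero-cost markers appended at each
WGD), so the model is exact even with zero decay variance. Synthesized
E-values are a monotone decreasing function of identity. This additive
decay is a deliberately simple stand-in for sequence evolution: it
reproduces the rank structure the homeology procedure consumes (younger
duplicates more similar than older ones) but none of the rate
heterogeneity, saturation or alignment-length effects of real data, so
passing tests demonstrate correctness of the procedures, not performance
on real divergence distributions.

Marker maps subsample genes (default density 0.3) with cM = bp × 1.5
cM/Mbp plus optional jitter. Marker names derive from the ancestral gene
id so the same locus shares a name across genomes; duplicated loci
within one genome get `_2`/`_3` suffixes, matching how duplicated
microsatellites are distinguished on real maps.

The cross generator simulates outbred full-sib families (default two
families × 100 progeny, four parents) under Haldane meiosis (a Markov
walk over marker+QTL positions; no interference, so closed-form
recombination checks hold). The trait is a sum of planted additive QTL —
each QTL's allele effect is scaled so it explains exactly its stated
fraction of total trait variance, given which parents it segregates in —
plus a family effect (sd 0.5), a batch effect over sampling order
(sd 0.3, batches of 20) and Gaussian residual (sd 1.0). Genotypes are
masked at the missing rate. The truth record keeps QTL genotypes,
realized effects and all random-effect draws.

Truth for homeolog recovery is recorded two ways: the mirror pairs named
at the WGD, and the content-based partner pairing of the emitted genome
(for each chromosome, the chromosome holding the plurality of its genes'
WGD partners). The latter is what detection is scored against, because a
large planted translocation genuinely moves a chromosome's dominant
partner.

## Problem sizes and numerical choices

Recovery and calibration studies run at: homeolog recovery — 6×60-gene
genomes, 20 replicates per loss level (0.3/0.55/0.8); painting — 4×25
genes, zero noise, fusion+translocation rate 1.5; transfer — default
genomes, marker density 0.3, 20 replicates; permutation calibration —
500 null crosses of 100 progeny × 6 markers at 200 permutations; power —
100 crosses of 200 progeny with a 20%-variance QTL; PEV — 100 crosses of
300 progeny. These sizes give Monte-Carlo error comfortably inside the
tolerances asserted (e.g. 3 SE ≈ 0.029 on the 0.05 type-I rate at 500
replicates). Permutation scans are vectorized across permutations
(group-mean and simple-regression F computed by matrix algebra), which
is what makes the calibration studies cheap.

Degenerate inputs: empty maps, constant traits, single-class markers,
r̂ ≥ 0.5 map distances, genes missing from gene order, proxy chromosomes
without lineage labels and QTL outside the map span all raise or are
skipped with a logged count, as documented per function. Seeds flow from
a single `--seed`/config value through `numpy.random.default_rng`; no
global state is used.

## Known limitations

- The homology percentage is treated as opaque; nothing in the
  E-value/identity model reflects alignment length or composition.
- Marker ordering is a heuristic (NN + 2-opt) and can return a
  locally-optimal order on noisy data; grouping and QTL results do not
  depend on within-group order beyond the interval-scan grid.
- Dominance, epistasis and selection are out of scope: QTL are additive
  only, and the combined-family model assumes homogeneous allele effects
  within a parent.
- The painting resolution is bounded by orthologue density: segments
  shorter than `min_block` genes are reported as unassigned by design.
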