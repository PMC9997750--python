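# Methods

This note documents the models and procedures implemented in symbiocensus,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Symbiont load estimation

**Model.** In a host individual sequenced shotgun-style, read depth on any
DNA species is proportional to its copy number in the extract. If a
single-copy host marker gene (elongation factor 1-alpha) has mean depth
*m̄* and a symbiont genome has median depth *d̃*, the symbiont's abundance
relative to the host genome is *a = d̃ / m̄*, and the number of symbionts
per host cell is *a / n* with *n* the host chromosome copy number
(default 2, diploid). The median is used on the symbiont side because
symbiont genomes carry repeats and mobile elements whose collapsed copies
inflate local depth; the median is insensitive to such spikes (injecting
10× depth at 5% of positions moves it by well under 1%, which the suite
checks). The mean is used on the short marker interval where robustness
matters less than efficiency.

**Cross-mapping correction.** Two near-identical strains (≥ 99% nucleotide
identity on shared genes) cannot be distinguished by read mapping on the
genes they share: each strain's track receives the other strain's reads
there, and when the shared fraction exceeds one half, the whole-genome
median lands on an inflated shared-gene position and approaches the *sum*
of the two loads. The estimator therefore restricts the median, for each
member of a configured confounded pair, to that strain's accessory genes —
families private to the strain after the 100-aa length filter, taken from
the pangenome partition rather than hard-coded, since accessory sets
depend on the annotation and comparison set in use.

**Parameters.** `ploidy` (host chromosome copies, default 2);
`presence_threshold` (load per host cell above which a symbiont is called
present, default 0.01 — far below biologically meaningful loads of ~0.1+,
but above the residual noise of cross-mapping and spurious mapping);
`include_zero_depth` (default true: the median is over the whole genome;
a covered-only mode is provided because depth-track conventions differ on
whether zero positions are recorded).

**Clustering.** Samples are grouped by agglomerative clustering of their
per-sample load vectors under Euclidean distance. Only the distance is
intrinsic to the analysis; the linkage is a convention and defaults to
complete linkage, exposed in the configuration.

## Pangenome partition

Protein families are connected components of a similarity graph
(single-linkage clustering): an all-against-all local alignment under
BLOSUM62 with affine gap penalties (open 11, extend 1), edges kept at
e-value < 10⁻³ (Karlin–Altschul statistics with the database size set to
the total residue count; λ = 0.267, K = 0.041, the standard gapped
BLOSUM62 11/1 parameters), identity ≥ 35% and mutual coverage ≥ 80%.
Connected components are computed by union-find; the test suite checks the
output against an independent graph-library connected-components oracle on
random graphs. An exact-5-mer prescreen skips pairs sharing no 5-mer; a
pair passing the 35%-identity/80%-coverage thresholds shares many 5-mers,
so the prescreen only removes pairs that could not have formed an edge.

The length filter (proteins < 100 aa removed) applies at partition time,
not clustering time, so families may be linked through short members but
are classified by their credible ones. A family is accessory to genome *g*
when all surviving members belong to *g*; shared when they span ≥ 2
genomes. Accessory families are summarized by COG category using the most
common unambiguous single-letter annotation among members; multi-letter
annotations are ambiguous and ignored; families with no usable annotation
are counted as "de novo OGs"; categories with ≤ 2 families are pooled into
"Other categories".

## ANI / AAI species delimitation

**ANI** follows the fragment recipe: genome A is cut into consecutive
1020-nt fragments; each fragment is aligned to genome B and contributes
its percent identity when it aligns at ≥ 30% identity over ≥ 70% of its
length; the one-way ANI is the mean identity over contributing fragments
and the reported ANI averages the two directions. Fragment placement is
BLAST-like: a fragment is considered alignable only if it shares an exact
20-mer with B on either strand (unseeded fragments fail, which is what
makes ANI *undefined* between unrelated genomes); seeded fragments are
placed by infix edit-distance alignment (edlib) and identity is read off
the extended CIGAR. The 20-mer seed keeps full sensitivity above ~75%
identity (expected seeds per 1020-nt fragment ≫ 1) while the chance that
two unrelated 50-kb genomes seed any fragment at all is a few percent.
All four numbers (fragment length, identity, alignable fraction, seed
size) are configuration.

**AAI** is the unweighted mean identity over reciprocal best hits between
two proteomes under the same protein aligner, with hits filtered at ≥ 30%
identity and ≥ 70% mutual coverage; it is undefined with fewer than 10
RBH pairs. The same-species call requires *every defined* metric to reach
its threshold (default 95% for both) — a strict-AND convention; because
ANI and AAI can disagree near the boundary, the raw values are always
reported alongside the call.

## Transposase contact tracing

For each transposase family spanning ≥ 2 genomes:

1. **Alignment.** Progressive multiple alignment: pairwise 3-mer distances
   → neighbor-joining guide tree (midpoint-rooted) → profile–profile
   global alignment under BLOSUM62 with affine gaps (open 11, extend 1).
   The profile dynamic program is exact for a pair of sequences (the suite
   checks pairwise alignments against an exhaustive three-state DP);
   profile columns are scored as frequency-weighted substitution scores
   with gaps contributing zero mass. Externally computed alignments can be
   supplied instead.
2. **Degradation filter.** A copy is removed when it is missing ≥ 15% of
   the consensus-span columns contiguously at either terminus *and* is
   ≥ 90% identical to its nearest neighbor over its aligned span — i.e.
   the copy is truncated (pseudogenized), not merely divergent. This is a
   codification of what is usually manual curation; both thresholds are
   configuration. Families reduced below 3 members are untestable.
3. **Trimming.** Columns with gap fraction > 0.5 or Shannon entropy
   (normalized to base 20) > 0.6 are removed; trimming is idempotent.
4. **Tree.** Poisson-corrected distances *d = −ln(1 − p)* over mutually
   ungapped columns (≥ 30 columns required per pair), neighbor joining
   with deterministic tie-breaking (lexicographically smallest label pair)
   and negative branch lengths clamped to zero with the deficit moved to
   the sister branch, plus a nonparametric bootstrap (columns resampled
   with replacement; support = % of replicates containing each internal
   bipartition). NJ is exact on additive matrices, which the suite
   verifies against a four-point-condition quartet oracle.
5. **Classification.** Per genome pair on the tree: **recent** when the
   minimum cross-genome patristic distance ≤ 0.02 substitutions/site
   (≈ 98% identity — fresh transfers leave near-identical copies on both
   sides); otherwise **ancient_sister** when each genome's members form a
   clade (singletons allowed) and the two clades are joined as sisters
   with bootstrap support ≥ 95 on the joining branch; otherwise
   **unresolved**. Support is required only on the joining branch. When
   the only realization of the joining bipartition is a terminal edge
   (two clades plus a single outgroup leaf), there is no internal joining
   branch and the weaker of the two clade supports is used instead.
   Maximum-likelihood trees computed elsewhere can be imported as Newick
   and classified unchanged, since the decision is purely topological.

The 0.02 recent threshold is a package convention (no community standard
number exists for "recent"); it is reported with every call and is far
below the ancient-divergence regime (≥ 0.2 subs/site) where sister-clade
structure appears, so the two calls cannot collide at realistic
divergences — the suite checks zero recent↔ancient confusion at 0.3
subs/site.

## Variant density summaries

Variants are summarized only where they are interpretable: samples must
have median symbiont-genome depth ≥ 30 and must not come from the
population the reference genomes were assembled from (those would show
zero divergence by construction). Kept variants are fixed (frequency = 1
within 10⁻⁹ — the caller's fraction-of-reads estimate) and outside
transposases and introns (1-based inclusive interval overlap, precedence
transposase > intron > CDS). The density is kept variants per kb of
*genome* (not of filtered territory), and type proportions are reported
over {SNP, insertion, deletion, substitution}. Because it is ambiguous
whether a cohort average should weight samples or (sample, genome) pairs,
both aggregations are reported. The frequency and feature filters
commute, and variants added inside excluded features never change a
summary — both are property-tested.

A toy pileup caller (fixed SNP where alt fraction ≥ 0.95 and depth ≥ 10)
stands in for an external caller so the filter chain can be exercised
end-to-end on synthetic data; it is not a general-purpose caller.

## Synthetic data generator

The generator emulates the statistical structure the estimators assume,
not raw reads:

- **Depth** is drawn per base as Poisson(L × m × n) for a symbiont at
  per-host-cell load L, marker mean depth m, and host ploidy n, with the
  host marker track Poisson(m). Cross-mapping is modeled explicitly: on
  genes shared by the confounded pair, each strain's track receives an
  additional independent Poisson draw at the sister strain's rate. Read
  mapping, duplicates, GC bias and mapping-quality effects are upstream
  of the implemented statistic and are not simulated — so passing
  recovery tests demonstrate estimator correctness under the Poisson
  model, not robustness to mapping artifacts.
- **Gene content**: every genome carries all core families plus a private
  accessory set; the confounded pair shares exactly the configured
  fraction of its families at ≥ 99.8% nucleotide identity (the
  cross-mapping substrate); a configured fraction of genes are emitted as
  short ghost CDS fragments (40–80 aa). Proteins are generated first and
  back-translated through random synonymous codons, so protein-level
  family structure and nucleotide-level identity are controlled
  independently.
- **TE histories** realize the two competing hypotheses: *recent* families
  place a copy in a second genome at ≤ 1 substitution from a donor copy;
  *ancient* families diverge two per-genome clades by a configured total
  of 0.3 substitutions/site (uniform substitution over 20 residues,
  multiple hits allowed, so the expected p-distance is ≈ 1 − e^(−d));
  *vertical* families stay in one genome. Degradation truncates a
  configured fraction of copies by 20–40% at one terminus.
- **Variants** are placed with known counts inside and outside excluded
  feature classes; the truth density counts fixed variants outside
  excluded features per kb.

Default study conditions: 6 samples, 4 symbionts (first two confounded at
80% sharing), 50-kb genomes with 120 gene families (30% core), marker
depth 30×, diploid host, loads drawn once per configuration from
U[0.1, 5] with 75% infection probability. These sizes keep every
recovery experiment to seconds while leaving ≥ 10⁴ positions per track
for distributional checks. All randomness flows from one root seed
through named child streams, so a fixed configuration reproduces
byte-identical outputs.

## Numerical choices and degenerate inputs

- Medians over an even number of positions are the mean of the two
  central values; region medians deduplicate overlapping intervals.
- A zero host-marker mean is an error (the sample is unusable), not a
  zero or infinite load.
- Relative abundances are normalized over *present* symbionts (so they
  sum to 1 whenever anything is present); absent symbionts report 0.
- NJ tie-breaks and family ids are lexicographic, making outputs
  invariant to input order; bootstrap replicates that fail distance
  computation (p ≥ 1 after resampling) count as not containing any
  bipartition.
- The all-vs-all aligner refuses > 5000 proteins unless overridden, since
  its cost is quadratic in proteins and in length.
- Guide trees for progressive alignment fall back to sequential joining
  when the k-mer distance matrix is degenerate (e.g. all zeros).

## Known limitations

- ANI uses edit-distance identity after exact-seed placement, not a
  tuned BLASTN; values can differ from BLAST-based implementations by
  fractions of a percent, and sensitivity decays below ~70% identity.
- The e-value proxy uses fixed Karlin–Altschul parameters without
  composition adjustment; clustering thresholds are configurable to
  compensate.
- Tree inference is distance-based (NJ), chosen because the
  classification target is topological; branch-length estimates under
  strong rate heterogeneity will be cruder than maximum-likelihood ones,
  and imported ML trees are the recommended path for publication-grade
  phylogenies.
- The toy pileup caller has no error model; it exists to exercise the
  filter chain on synthetic data.
- The generator does not simulate assembly artifacts, contamination, or
  strain mixtures within one symbiont species.
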