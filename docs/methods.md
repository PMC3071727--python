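# Methods

## The problem and the approach

A miRNA represses its targets either by destabilizing their transcripts or
by suppressing translation. The second mode is invisible to expression
arrays: the transcript sits at the same level in both conditions while the
protein drops. `earmir` implements an integration strategy for paired
tissues (here called A and B; in the motivating application, the vestibular
and cochlear sensory epithelia of the newborn mouse inner ear) that layers
three measurements — a two-color miRNA array, a transcript expression array,
and iTRAQ relative protein quantification — and asks, for every miRNA
family, whether its predicted targets are statistically over- or
under-represented in the genes down-regulated in each tissue at the
transcript level, the protein level, both, or the protein level *only*.
A family that is itself up-regulated in tissue A and whose targets are
enriched among the genes down in A behaves as the model of miRNA repression
predicts; a family whose co-expressed genes are *depleted* of its sites is
seeing anti-target selection. Regulation confined to the protein-only sets
is the signature of translational suppression.

## Stage models

**miRNA arrays.** Each biological replicate is hybridized twice with the
dye assignments exchanged. Foreground intensities are rescaled so every
labeled sample has the same mean intensity (the scaling acts per
hybridization and channel; background is untouched). A probe is *detected*
in a tissue when its technical-replicate-averaged intensity exceeds the
per-hybridization background mean by at least `k_sd = 2` background standard
deviations in at least `min_samples = 2` of the 3 biological replicates;
background mean and SD are estimated across probes within a hybridization
because per-spot background SDs are not available in generic exports. Log2
ratios are oriented A/B regardless of dye; averaging the two technical
ratios of a dye-swap pair cancels multiplicative dye bias exactly on the log
scale. A one-sample t-test (n = 3 replicate ratios against zero) and a
linear fold filter (|fold| >= 1.25, inclusive) with p < 0.05 produce the
differential calls; the test runs on dye-swap-averaged replicate ratios, not
on the six individual hybridizations. Probe calls roll up to miRNA
families: the family ratio is the mean over member probes and a family is
differentially expressed if any member is.

**Transcripts.** Quantile normalization forces every array to the common
distribution (row-wise mean of the sorted columns; ties get the average
reference quantile, which makes the transform idempotent). Rows with no
'Present' flag in any sample are removed — presence flags are consumed as
input, not computed. Per gene, a Welch (unequal-variance) two-sample t-test
compares the n = 3 vs 3 groups; the test is Welch because nothing safer can
be assumed at n = 3. Benjamini–Hochberg q-values are computed across all
filtered rows, and a call requires q < 0.1 and an anti-logged group-mean
fold of at least 1.3 (inclusive).

**Proteins.** Per MS/MS spectrum, the share r = I_A / (I_A + I_B) of tissue
A's reporter ion (114 vs 115) is converted to odds t = r/(1−r), the linear
A/B fold carried by that peptide. Peptide odds are centered so their median
is 1, removing global loading and labeling bias; the median is taken on the
log scale (identical for odd counts, geometric interpolation for even
counts) so that exchanging the channel assignment inverts every downstream
ratio exactly. The protein ratio is the median of its peptide odds —
median, not mean, to resist single outlier spectra — and only proteins with
three or more peptides are valid. Differential abundance requires a fold of
1.3 in either direction (inclusive).

**Eight gene sets.** For each tissue T: genes down in T at the transcript
level, at the protein level, at both, and at the protein level only (down
at protein with the transcript failing either the fold or the FDR
criterion). Universes differ by layer: transcript sets are tested against
all presence-filtered genes, protein sets against all valid proteins, and
the both / protein-only sets against the genes measured at both layers.
Genes are joined across platforms by upper-cased symbol — the only key the
three platforms share.

**Target enrichment (the permutation test).** Predictions form a weighted
bipartite graph: families on one side, universe genes on the other, one
edge per (family, gene) pair with weight Σ_sites max(0, −context score) —
TargetScan context scores are negative for effective sites, so more
negative means stronger predicted repression and a larger weight. Multiple
sites are collapsed into the summed weight so that the null model operates
on a simple graph; the site count is honored through the weight, an
explicit convention rather than a claim about any other implementation.
The observed statistic for family f and gene set S is
T(f, S) = Σ_{g∈S} w(f, g). The null preserves both degree sequences:
repeated random double-edge swaps — pick edges (m1,g1), (m2,g2); if the
endpoints are distinct and neither (m1,g2) nor (m2,g1) exists, rewire —
with every weight traveling on its family-side half-edge. The chain is a
symmetric random walk, so its stationary law is uniform on the reachable
component of (graph, weight placement) states. One chain serves all
families and sets of a universe simultaneously: statistics update
incrementally per accepted swap, samples are taken every |E| attempts after
a burn-in of 10·|E| attempts, and the empirical p-value is
(1 + #{T* in tail}) / (N + 1) with ties counted in the tail, so p is never
zero and never below 1/(N+1). Enrichment is tested on the graph of
conserved sites only; depletion on the graph of all (conserved +
nonconserved) sites — anti-target selection acts on all sites, while
enrichment signal concentrates in conserved ones. Default N = 10,000.
Raw p < 0.05 defines a significant cell; BH q-values across families within
each set are reported alongside.

The exact oracle (`exact_null_small`, graphs of <= 12 edges) enumerates the
chain's reachable component by breadth-first search and computes the tails
under the uniform law on it. Note the component is what the chain can
actually reach: a complete bipartite graph admits no legal swap, its null
is the single observed state, and both tails are exactly 1.

**Integration.** A family's significant cells are read against its own
expression: up in T + targets enriched in a set down in T →
`consistent_target`; up in T + targets depleted in a set down in the other
tissue (genes up in T) → `consistent_antitarget`; any other significant
cell of a differentially expressed family → `inconsistent`; significant
cells of families that are not differentially expressed are reported as
`mirna_not_de`, never suppressed. When a family has several cells the
family verdict takes the strongest supportive reading (target beats
anti-target beats inconsistent).

## The synthetic-study generator

The generator emulates the full study design with a planted ground truth:
two tissues × 3 biological replicate pools; dye-swapped miRNA
hybridizations with additive Gaussian background (mean 200, SD 30 intensity
units, truncated at 0) and a multiplicative dye bias (default 1.15);
log-normal transcript expression with P/A presence flags (5% all-absent
rows); peptide-level iTRAQ intensities (3–8 peptides per protein,
multiplicative log-normal noise, a global 114-channel loading bias of 1.2);
and a per-site prediction table with ~1–2 sites per pair, 70% conserved.
Planted families are up-regulated in tissue A (default fold 2.5) and
suppress a fraction of their targets there by a factor (1 − s) at one of
three layers: `mRNA` shifts the transcript ratio only, `protein` shifts
both layers (canonical destabilizing regulation), and `protein_only` shifts
the protein ratio only (translational suppression). Suppressed targets
always carry at least one conserved site and at least 3 peptides, so they
are observable in principle at the layer where they were planted. One RNG
stream per data layer derives from the master seed, so changing one layer's
parameters never perturbs another layer's draws.

Noise scales are design choices stated once: transcript per-sample log2 SD
0.1 and per-channel reporter log2 SD 0.1, both at the tight end of the
realistic range for pooled-replicate arrays and QTOF reporter ratios. They
are what make the generator's own planted-recovery expectations (suppression
0.3 against the 1.3-fold thresholds at n = 3) attainable: a study design
this small has no power against those thresholds at looser dispersions, and
the planted effects would sit inside the noise rather than above it.

What the generator does **not** emulate: probe-sequence effects, spatial or
print-tip artifacts, batch effects, peptide identification error, missing
values, or correlated noise between layers. Passing tests therefore show
the pipeline's statistical machinery is correct and calibrated under its
own model; they do not certify performance on real arrays or spectra.

## Numerical choices and degenerate inputs

- Folds are compared with a relative tolerance of 1e-12 at the inclusive
  boundaries so a threshold that round-trips through log2 still passes.
- In the one-sample t-test, zero sample variance is degenerate: p = 0 with
  a nonzero mean, p = 1 for an all-zero sample — both flagged.
- Foreground intensities are floored at 1 intensity unit before log ratios.
- Peptide rows with one zero channel have direction but no finite odds;
  they are flagged and excluded from normalization and aggregation. Rows
  with both channels zero are dropped.
- Tail comparisons in the permutation kernel use a tolerance of
  1e-9·(1 + |T_obs|) so that exact ties survive incremental floating-point
  updates over millions of swaps.
- An empty gene set gives T = 0 for every family and, since every null
  sample also gives 0, both tails equal 1; the result is flagged
  degenerate. A gene set equal to the universe makes T invariant, so both
  tails are 1.
- Clustering distance is 1 − Pearson correlation; a constant profile has
  undefined correlation and is assigned distance 1 to everything, flagged.
  Samples are sorted lexicographically before linkage so ties break
  deterministically.
- Chains are single-threaded by contract; determinism holds for a fixed
  seed, with child seeds derived per (universe, conservation-mode) batch.

## Scale of the shipped checks

The test suite and the acceptance script run everything at desk scale, a
deliberate choice of problem size: studies of 500 genes × 20–50 families
(~1,500–2,000 edges), permutation depth 1,000–2,000 for pipeline runs and
20,000 where the sampler is compared with exact enumeration, 20 studies for
recovery rates. These sizes keep every conclusion statistically meaningful
(binomial confidence intervals are quoted in the tests) while a full run of
the suite stays in the minutes range.

## Known limitations

- The weight convention (clip positive scores to 0, sum per pair) and the
  universe restriction (graph genes limited to the layer actually measured)
  are reasoned defaults, stated in the run manifest, not reproductions of
  any specific external tool.
- The presence-flag and prediction inputs are consumed as given; computing
  MAS5 calls from CEL files or discovering target sites is out of scope.
- Family-level miRNA direction uses "any member differentially expressed,
  sign of the mean ratio"; a family whose members disagree in sign with a
  mean of exactly zero is treated as not differentially expressed.
- The published study's overlap p-values between layers depend on a
  universe the original report does not state; the hypergeometric overlap
  test is provided, but those two numbers are not reproduction targets.
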