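# Methods

## Model

`mutclust` tests, per genomic element, the null hypothesis that the
positions of somatic single-nucleotide substitutions are driven only by
local sequence context, against the alternative of additional positional
clustering (the footprint of positive selection). The test statistic is a
kernel-smoothing-based clustering score; its null distribution is built by
Monte-Carlo re-placement of the observed mutations.

### Coordinates and sequences

Elements are sets of non-overlapping intervals on one chromosome (BED
convention, 0-based half-open), analyzed as one concatenated sequence;
mutation positions are 1-based (VCF convention). All conversions live in a
single bidirectional coordinate map per element. Smoothing, clustering and
simulation windows operate in concatenated-element coordinates, so a window
may span a segment junction (e.g. an exon boundary); k-mer contexts,
however, are always read from the genome at the mapped genomic position, so
no chimeric junction k-mers are ever fabricated. Strand is ignored
throughout: contexts are counted and mutations re-placed on the forward
strand, which keeps counting and placement in one consistent frame with no
reverse-complement bookkeeping.

### Substitution profile

The cohort profile assigns each (k-mer context, alternate allele) pair the
fraction of cohort mutations carrying that change, k = 3 (default) or 5.
Contexts containing `N` or truncated by a chromosome edge are undefined and
carry probability zero everywhere (profile counting, placement weights,
fixture generation). By default the profile is estimated from the mutations
inside the analyzed elements — the signature relevant to the analyzed
territory — switchable to all reference-validated mutations
(`profile_scope="all"`) or to a precomputed profile file. Raw change
frequencies are used; no correction for the context *abundance* of the
territory is applied, so the profile is a resampling law, not an
opportunity-normalized mutation-rate estimate.

### Smoothing and clusters

Each mutation contributes a discrete Tukey biweight kernel,
w(d) ∝ (1 − (d/(h+1))²)² for offsets |d| ≤ h = (w_smooth−1)/2, normalized
to sum 1 — smooth, compactly supported, strictly positive at the window
edge. Kernel mass outside the element is clipped, never renormalized:
renormalizing would inflate apparent density at the element boundary, and
because the simulated curves are clipped identically, the comparison is
unbiased.

Cluster identification on the curve uses these deterministic conventions:

* values are compared after rounding to 1e-10 (so plateau detection cannot
  depend on floating-point summation order);
* a plateau of equal values is one extremum, represented by its leftmost
  index;
* every local maximum with positive value seeds a raw cluster; raw cluster
  spans partition [0, L): the minimum plateau between two peaks is split at
  its midpoint (left half to the left cluster) and the outermost clusters
  run to the element edges. Partitioning makes "each mutation belongs to
  exactly one cluster" true by construction;
* merging is the transitive closure of "consecutive raw peaks within
  w_cluster of each other"; the merged peak is the member peak with the
  largest curve value, leftmost on ties;
* merged clusters with fewer than `min_cluster_mutations` (default 2)
  mutations are discarded — a singleton is recurrence in one sample only,
  which is not a clustering signal.

### Scores

Cluster score = Σ_p 100·(m_p/M)·(1/√2)^{|p−peak|} over mutated positions p
in the cluster, with m_p the mutation count at p and M the element total.
The √2 discount base and the ×100 scaling are configuration constants; the
score of a cluster is at most 100 (all of the element's mutations at the
peak), and concentrating a fixed number of mutations toward the peak always
increases it. The element score sums its surviving clusters' scores.

### Null simulation and significance

Each of N iterations independently re-places every observed mutation within
a w_sim-nt window centered on its observed position (clipped at element
edges), with candidate weights proportional to the total change probability
of each candidate's context (summed over the three alternates). A window
with zero total weight (e.g. all-`N`) leaves the mutation at its observed
position, with a counted warning. Simulated alternate alleles are not
materialized: scores depend on positions only, and integrating the
placement weights over alternates gives the identical placement law.

Each iteration is re-smoothed, re-clustered and re-scored with the observed
parameters. Element p-value: (1 + #{simulated element scores ≥ observed}) /
(N + 1) — the pseudocount form avoids p = 0 and bounds p ≥ 1/(N+1).
Cluster p-values rank each observed cluster score against the simulated
cluster scores of all iterations pooled (one well-populated null per
element). Elements whose observed mutations form no surviving cluster get
score 0 and p = 1 without simulation (the empirical formula would return 1
regardless). Benjamini–Hochberg adjustment runs once across all analyzed
elements — every element with ≥ 1 assigned mutation, not only clustered
ones, since shrinking the family to clustered elements would bias the FDR.
Elements with q below the threshold (default 1%) are called significant.

### Determinism and parallelism

Every element draws from its own RNG stream seeded by
`SeedSequence([seed, crc32(element_id)])`, consumed across that element's
iterations. Results are therefore a pure function of (inputs, config,
seed), independent of element processing order and of the worker count
(`cores > 1` uses joblib's threading backend).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w_smooth` | 11 nt | Tukey kernel width; sets the spatial scale of a "cluster" (a turn-scale neighborhood at protein resolution) |
| `w_cluster` | 11 nt | maximum peak separation merged into one cluster |
| `min_cluster_mutations` | 2 | minimum recurrence for a reportable cluster |
| `w_sim` | 31 nt | local re-placement window; large enough to erase w_smooth-scale structure, small enough to stay local |
| `k` | 3 | context size of the substitution profile (3 or 5) |
| `n_simulations` | 1000 | null iterations; p-value resolution is 1/(N+1) |
| `fdr_threshold` | 0.01 | BH q cutoff for the significance call |
| `seed` | 1234 | master seed |

N must be chosen against the BH family size: with E analyzed elements the
smallest attainable q is E/(N+1), so a 21-element demonstration needs
N ≥ 2100 to be able to call anything at 1% FDR — the packaged toy example
uses N = 2500 for this reason. At the hundreds-of-elements scale of real
cohorts, N = 1000 already resolves q ≪ 0.01.

## Synthetic data

The generator (`mutclust.synth`) emulates exactly the structures the
analysis consumes: a multi-chromosome random reference (optionally with
embedded motifs or skewed base composition), multi-segment elements, and
cohorts drawn from a stated context profile — *null* cohorts place
mutations position-wise proportional to the profile's total change
probability, i.e. the same placement law the analyzer's simulation uses,
and *planted* cohorts add single-position hotspots carrying a floor-rounded
fraction of an element's mutations. Every fixture ships a truth table.

Because generator and analyzer share the placement law, element p-values on
null fixtures are calibrated, and the test suite verifies this directly: on
200 null elements (1000 nt, 30 mutations, N = 1000, the generator's profile
passed to the analyzer) the fraction of p < 0.05 falls in [0.03, 0.07] and
the KS distance from uniform stays below 0.1. Observed values are mildly
conservative (type-I ≈ 0.03–0.04): the simulated cohorts inherit part of
the observed configuration through the window centering, which slightly
correlates null scores with the observed score. Power, under the same
sharing, is ≥ 90% for a 30% single-site hotspot among 50 mutations in a
1000-nt element at 1% FDR.

What passing these tests does **not** show: behavior under real cohort
signatures (the generator draws from arbitrary context weight tables, not
COSMIC signatures), under sample-specific mutation burdens, under clustered
mutational processes (APOBEC showers can produce genuine but selection-free
clusters), or when the estimated profile is noisy because the cohort is
small. On real data the profile is estimated from the same mutations being
tested, an approximation whose error shrinks with cohort size.

## Numerical and degenerate-input choices

* Smoothing curves are rounded to 1e-10 before extrema analysis; all
  tie-breaks (plateau representative, merged peak, report ordering) resolve
  leftmost/lexicographic.
* Mutations failing reference-allele validation, non-SNV rows, within-sample
  duplicate rows, mutations outside all elements and mutations with
  undefined context are counted in disjoint metadata counters; the test
  suite asserts the counts add back to the input row count.
* A mutation inside several overlapping elements is analyzed in each
  (element analyses are independent); it is counted once for the profile.
* Zero-mutation elements are skipped; a cohort with no in-element mutation
  is an error, as is an empty or header-only mutation table.
* Report rows sort by q, then p, then score descending, then element_id;
  floats are written at 6 significant digits; reruns with the same seed are
  byte-identical.

## Limitations

* Linear (sequence-space) clustering only: 3D-structure clusters split
  across the sequence are invisible, as is inter-element clustering.
* No functional-impact weighting, no indel/MNV modelling, no
  transcript-aware annotation, no opportunity-corrected profile.
* The cluster-level p-value pools simulated clusters of the whole element,
  so it is a per-element, not genome-wide, statement.
* Very long elements with many mutations make the element score a sum over
  many chance clusters, diluting single-hotspot contrast; the cluster-level
  p-values are the sharper readout in that regime.
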