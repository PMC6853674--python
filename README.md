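# mutclust

Detection of genomic elements whose somatic mutations **cluster along the
sequence** more than expected from the cohort's nucleotide-context
preferences — a signal of positive selection used to nominate cancer driver
genes and regulatory elements.

## The problem and the method

Across a cohort of tumors, driver mutations tend to recur at or near the
same positions (oncogenic hotspots), while passenger mutations scatter
according to local sequence context and mutational processes. Calling
clustering "significant" therefore requires a background model of where
mutations *would* fall without selection. Instead of modelling genome-wide
mutation-rate covariates, `mutclust` builds the null **locally**: each
observed mutation is re-placed within a small window centered on its
position, with per-position probabilities proportional to the cohort's
k-mer-context substitution frequencies (k = 3 or 5, forward strand). Because
the null is anchored to the observed mutations themselves, the method
applies to any region — coding or non-coding — of any genome with a
reference sequence.

For each genomic element (a named, possibly multi-segment region analyzed
as one concatenated sequence of length L):

1. **Smoothing.** Mutations are smoothed along the element with a discrete
   Tukey biweight kernel of width `w_smooth` (default 11 nt); kernel mass
   beyond the element edge is clipped.
2. **Clusters.** Local maxima of the smoothing curve seed clusters, which
   extend to the flanking minima; clusters whose peaks lie within
   `w_cluster` (default 11 nt) merge; clusters with fewer than 2 mutations
   are dropped.
3. **Scores.** A cluster with mutation counts m_p at positions p and peak
   position `peak` scores

   score = Σ_p 100 · (m_p / M) / √2^{|p − peak|}

   where M is the element's total mutation count — the percentage of the
   element's mutations at each position, geometrically discounted by the
   distance to the peak, so tight clusters outscore diffuse ones. The
   element score is the sum of its cluster scores.
4. **Significance.** N simulation iterations (default 1000) re-place every
   mutation within a `w_sim`-nt window (default 31) following the context
   probabilities, and re-run steps 1–3. The element p-value is the
   empirical rank p = (1 + #{simulated ≥ observed}) / (N + 1); cluster
   p-values rank each observed cluster against the pooled simulated cluster
   scores. Across elements, p-values are Benjamini–Hochberg adjusted and
   elements below 1% FDR are called significant.

## Worked example

The package ships a synthetic-data generator used throughout the test
suite. Here, 21 elements of 1000 nt each receive 50 context-driven
mutations; one element (`E011`) additionally carries 60% of its mutations
at a single planted position:

```python
from mutclust import ClusteringModel, SimulationConfig
from mutclust.synth import toy_spec, build_fixture

genome, elements, mutations, truth = build_fixture(toy_spec(seed=7))
model = ClusteringModel(mutations, elements, genome,
                        config=SimulationConfig(n_simulations=2500, seed=7))
results = model.fit()
print(results.summary(top=5))
```

```
Somatic mutation clustering analysis
====================================================================
elements analyzed: 21 of 21 defined
mutations assigned: 1050 (unassigned 0, reference mismatch 0)
simulations per element: 2500, k-mer context: 3, seed: 7
significant at FDR < 0.01: 1
--------------------------------------------------------------------
element_id symbol  n_mutations  n_clusters score   p_value  q_value  significant
      E011   E011           50           2 63.09 0.0003998 0.008397         True
      E006   E006           50          15 40.96    0.1176   0.8178        False
      E021   E021           50          15 40.42    0.1631   0.8178        False
      E016   E016           50          13  39.5    0.1847   0.8178        False
      E020   E020           50          13 38.75    0.1947   0.8178        False
```

The planted element is the only significant call: its hotspot concentrates
31 of 50 mutations into one cluster (score 61 of the element's 63.1), its
p-value sits at the resolution floor 1/(N+1) = 1/2501, and after BH
adjustment q = 0.0084 < 0.01. The null elements score ~40 through many
chance two-mutation clusters but are fully compatible with their own local
simulations. `results.clusters` lists each cluster with element and genomic
coordinates:

```
element_id  left  right  peak  genomic_left  genomic_right  genomic_peak  n_mutations  score   p_value
      E011   222    321   300         11773          11872         11851           31   61.0  0.000106
```

The same analysis runs from the shell on TSV/FASTA inputs:

```bash
mutclust --mutations cohort.tsv --regions elements.bed --genome ref.fa \
         --output out/ --n-simulations 1000 --seed 1234
```

writing `elements.tsv`, `clusters.tsv`, `metadata.json` and `run.log` into
`out/`. Mutation tables are tab-separated with a header
(`chromosome  position  ref  alt  sample`, 1-based positions; VCF files can
be exported to this layout with
`bcftools query -f '%CHROM\t%POS\t%REF\t%ALT\t[%SAMPLE]\n'` plus a header);
region files are BED-like (`chromosome  start  end  element_id [symbol]`,
0-based half-open, rows sharing an element_id form one multi-segment
element).

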