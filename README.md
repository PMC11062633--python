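# monomark

Analysis toolkit for studying how a chromatin protein — PARP-1 in the
motivating experiments — reads histone post-translational modifications,
from in-vitro peptide-array binding through genomic co-enrichment to
transcriptome integration. It is aimed at chromatin biologists and
bioinformaticians who have (a) a combinatorial modified-histone peptide
array probed with their protein, (b) ChIP-seq peaks and coverage tracks
for the protein and a panel of histone marks, and (c) differential-
expression tables for mutants of the protein and of a histone-modifying
enzyme, and who want the quantitative readouts connecting the three.

## What it computes

**Peptide-array binding** (`array_model`, `array_quantify`,
`binding_analysis`). Spots on a gridded array image are quantified with a
layout prior (median disk foreground, median annulus background,
clipped subtraction), max-normalized jointly across duplicate subarrays,
and summarized as:

- the single-mark binding profile: mean ± SEM over spots whose
  modification set is exactly one mark;
- duplicate reproducibility: Pearson *r* of spot-matched intensities
  between the two subarrays;
- the **specificity factor** per mark *m*,
  `S(m) = mean(spots containing m) / mean(spots lacking m)`,
  with *S* > 1 indicating preferential binding;
- **co-mark interaction effects**: for a target mark *t* and co-mark *c*,
  `R(t, c) = mean(spots with t and c) / mean(spots with t without c)`,
  tested by a two-sided permutation test on the difference of stratum
  means (exhaustively enumerated whenever the number of relabelings fits
  the permutation budget) with Benjamini–Hochberg correction across all
  tested pairs; *R* < 1 at *q* ≤ α is called inhibiting, *R* > 1 enhancing.

**Genomic co-enrichment** (`coenrichment`). Directed peak-overlap
fractions (half-open BED semantics; fraction of one set's peaks touching
≥ 1 bp of another) and Spearman correlation of the fraction-matrix rows;
log2(IP+ψ)/(input+ψ) ratio tracks on a 50 bp grid; genome-wide track
correlation at 10 kb; scaled-region (metagene) gene × bin matrices with
seeded k-means (k = 3 by default, clusters relabeled so cluster 1 is the
most enriched); and per-gene promoter / gene-body co-enrichment calls
(the conjunction of per-factor overlap flags).

**DEG integration** (`deg_integration`). DESeq2-style tables are
classified with the rule |log2FC| ≥ 1 (inclusive) at FDR < 0.05
(strict); concordance of two mutants is the Pearson *r* of paired log2
fold changes over genes significant in at least one of them; co-enriched
genes are partitioned into DE-in-both / only-mutant-A / only-mutant-B
with up/down counts and percentages.

**Synthetic data** (`synthetic_data`). Seeded generators emulate every
input with known ground truth — multiplicative-affinity array
intensities with lognormal noise and planted interaction multipliers,
film-style rasters, genomes with designed peak overlaps and shaped
coverage, correlated DE-table pairs, and correlated two-channel line
profiles — so every estimator above is testable as parameter recovery.

## Worked example

```python
import monomark as mm

layout = mm.simulate_layout(seed=1)
truth = mm.ArrayTruthModel(
    affinities={"H4K20me1": 2.0},                    # one mark binds 2x
    interactions={("H3K4me1", "H3K9me3"): 0.3},      # K9me3 inhibits K4me1 spots
    noise_cv=0.15, seed=1,
)
result, _ = mm.simulate_array(truth, layout)

print(mm.duplicate_correlation(result))
print(mm.specificity_ranking(result, top_n=3))
```

prints

```
0.8155060270947713
       mark    factor  n_with  n_without
0  H4K20me1  2.087737       3         43
1   H4K16ac  1.065349       2         44
2  H3K27me1  0.970575       4         42
```

— the duplicate subarrays correlate at *r* ≈ 0.82 under 15%
multiplicative noise, and the planted 2× mark tops the specificity
ranking with a factor close to its designed value; every other mark sits
near the neutral factor of 1. An interaction scan on a layout with fixed
strata recovers the planted inhibition:

```python
lay = mm.interaction_layout("H3K4me1", "H3K9me3", n_with=6, n_without=6)
truth = mm.ArrayTruthModel(affinities={"H3K4me1": 5.0},
                           interactions={("H3K4me1", "H3K9me3"): 0.3},
                           noise_cv=0.10, background=0.05, seed=2)
res, _ = mm.simulate_array(truth, lay)
eff = mm.interaction_effect(res, "H3K4me1", "H3K9me3", seed=3)
print(eff.effect_ratio, eff.p_value, eff.direction)
# 0.3044958075070083 0.0021645021645021645 inhibiting
```

A command-line surface mirrors the library:
`monomark array|coenrich|deg|synth --help`.

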