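# Methods

## Array model and spot quantification

A combinatorial modified-histone peptide array carries 19-mer peptides,
each with 0–4 concurrent modifications drawn from the vocabulary
{me1, me2, me3, ac, ph, cit} on residues of H2A/H2B/H3/H4, printed in
identical duplicate subarrays; blank and positive-control spots are
first-class labels excluded from all statistics. me2 and me3 of one
residue are distinct marks throughout; composite claims about
"me2/3" are reproduced by testing each state separately.

Published array experiments rarely specify the densitometry, so the
quantification scheme is the package's own: the spot center is refined
within a small search radius by maximizing mean disk intensity, the
foreground is the **median** inside `disk(spot_radius)` and the
background the **median** in the 1.5–2.5× radius annulus, and
`corrected = max(fg − bg, 0)`. Medians make the measurement robust to
film speckle and to neighbouring-spot bleed into the annulus.
Intensities must already be oriented so that larger = stronger binding
(the CLI offers `--invert` for darker-is-stronger film scans).
Saturated spots (disk touching the detector ceiling) are flagged but
kept, matching the convention of reporting strong binders rather than
censoring them. Normalization divides by the single maximum corrected
value over non-control spots of *both* subarrays, so duplicates stay on
one comparable [0, 1] scale; the all-zero case is an error rather than
a silent 0/0.

## Binding statistics

Statistics pool (spot, subarray) observations instead of pre-averaging
duplicates; because every spot contributes the same number of replicate
values, pooled stratum means equal means of per-spot means, while the
pooled form preserves within-spot variance for the SEM of the
single-mark profile. "Single-mark" means the modification set has
cardinality exactly one.

The specificity factor for mark *m* is the ratio of the mean over spots
containing *m* (any company allowed) to the mean over spots lacking
*m*, controls excluded; it is scale-invariant, so normalized and raw
intensities give identical values. Rankings break ties alphabetically
for reproducibility.

Interaction effects formalize the qualitative enhancement/inhibition
readout: `R(t, c)` is the ratio of stratum means among target-carrying
spots with vs. without the co-mark, other marks varying freely (array
strata are small; holding all other marks fixed would empty them — a
known confounding limitation). Significance is a two-sided permutation
test on the difference of stratum means, relabeling co-mark membership
at the spot level so a spot's duplicates travel together. When the
number of distinct relabelings C(n, k) does not exceed `n_perm`
(default 9999), the test **enumerates all of them** and the p-value is
exact — for two 6-spot strata that is C(12, 6) = 924 relabelings;
otherwise it samples `n_perm` relabelings with the add-one estimator.
Scans over many (target, co) pairs apply Benjamini–Hochberg across all
computed p-values, and per-pair seeds derive deterministically from the
scan seed. Direction is inhibiting/enhancing only when q ≤ α (default
0.05), else neutral.

## Genomic co-enrichment

All coordinates are 0-based half-open; abutting intervals do not
overlap. The overlap fraction of set A in B counts A-peaks touching
≥ 1 bp of the merged B intervals via a sorted sweep (searchsorted on
merged starts), validated against an all-pairs oracle. The
"correlation of peaks by fraction of overlap" heatmap is ambiguous
between reporting the fraction matrix itself and a rank correlation of
its rows; both are emitted (CLI `--stat {fractions,
spearman-of-fractions}`). With only two peak sets, the Spearman of
2-vector rows degenerates to ±1; the statistic is meaningful for panels
of several marks.

Ratio tracks are `log2((IP+ψ)/(input+ψ))` on a common 50 bp grid
(re-binning by length-weighted mean, uncovered ground counting as
zero); ψ defaults to 1 coverage unit to guard empty bins. Genome-wide
track correlation re-bins to 10 kb and drops bins where every track is
zero. Metagene (scaled-region) matrices average a fixed flank
(default 2 kb into 20 bins) and linearly rescale the body into 50
bins; minus-strand rows are reversed so all rows read TSS→TES. Flank
and bin counts are configuration, not dogma — published heatmaps rarely
state them. k-means uses seeded scikit-learn with `n_init=10`;
clusters are relabeled by descending mean signal so "cluster 1" is
always the most enriched, and rows are ordered by cluster then
descending row mean, matching descending-sorted heatmap displays.

Promoters default to ±250 bp around the strand-aware TSS ("promoter"
is used without definition in most ChIP-seq papers); the gene body is
the transcribed unit minus the promoter-proximal window, mirrored on
the minus strand. A gene is co-enriched when **every** queried peak set
overlaps it in the chosen region mode.

## DEG integration

Significance is |log2FC| ≥ 1 (inclusive — "at least 1") with
adjusted p < 0.05 (strict — "FDR < 0.05"); missing padj is never
significant. Concordance defaults to genes significant in at least one
mutant (the plotted universe of mutant-comparison scatterplots is
usually this), with `intersection_all` available. Row z-scores use the
population standard deviation; constant rows become zeros with a
warning. In the co-enriched summary, the "both mutants" partition takes
its direction from mutant A, and genes with opposite signs in the two
mutants are counted in a separate discordant column; percentages are
reported both over the whole partition and over concordant genes only,
since either denominator is defensible.

## Synthetic data: what it emulates, and what it does not

The array truth model is multiplicative: expected spot intensity is
`background + Π(base affinities) × Π(interaction multipliers)` over the
marks present, and observed intensities multiply that by independent
mean-one lognormal noise with coefficient of variation `noise_cv`
(default 0.15; film intensities are positive and heteroscedastic).
The lognormal is parameterized as `σ² = ln(1 + CV²)`, mean exactly one,
which makes the duplicate-correlation expectation closed-form:
`r = Var(E) / (Var(E) + CV²·E[E²])` — `cv_for_duplicate_correlation`
inverts this to hit a target r analytically rather than by tuning.
Background defaults to 0.05 (small against affinity scale ~1–5); at
zero background and unit co-mark affinity the recovered interaction
ratio equals the planted multiplier exactly. Interaction multipliers
compose multiplicatively when several co-marks apply — the simplest
composable choice, sufficient for testing detection, not a claim about
binding chemistry. The generator does not model antibody
cross-reactivity, film-response nonlinearity (real exposures of
0.5–2 min are nonlinear), or spatially correlated blotches; passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to those real-world artifacts.

Synthetic genomes place non-overlapping genes on chromosomes, assign
them to three enrichment groups (multipliers 1 / 0.5 / 0 — the cluster
I–III analogue), and build peak sets where each later set states its
designed overlap with the first set: the designed share of peaks is
anchored on first-set peaks, the rest rejection-sampled from
first-set-free ground (an infeasible design raises an error instead of
silently missing the target). Coverage tracks sum per-peak plateaus,
gene-linked promoter or body enrichment, and Poisson background.
Designed overlap is relative to the first set only; a full pairwise
design matrix is over-constrained in general.

DE pairs draw correlated bivariate-normal log2 fold changes for the DE
fraction (default 30%) at effect scale 3.0 — a strong-mutant scale at
which the significance threshold |lfc| ≥ 1 truncates little of the
effect distribution, so the recovered concordance tracks the designed
correlation — and near-zero effects with uniform padj for null genes.
Line profiles are bivariate normal pairs shifted +5σ so clipping never
distorts the correlation.

## Numerical choices and degenerate inputs

- Correlations on constant vectors, empty strata, zero denominators and
  all-zero arrays raise typed errors rather than returning NaN.
- Permutation p-values compare |difference| with a relative 1e-12
  tolerance so exact ties count as extreme (conservative).
- The permutation-null calibration target (fraction of p ≤ 0.05 at most
  0.08 over 200 runs) reflects the discreteness of the exact test at
  6+6 strata (granularity 2/924) plus binomial noise.
- k-means determinism relies on a fixed `random_state` plus the
  mean-signal relabeling; duplicated rows always co-cluster.
- Problem sizes in the test suite and acceptance script (200-spot
  arrays, 20 seeds per recovery estimate, 500-peak overlap designs,
  2000-gene DE tables) are chosen so each estimate's sampling error is
  comfortably inside its stated tolerance while the whole suite runs in
  well under a minute on one core.

## Known limitations

- Interaction strata let other marks vary freely; on a real commercial
  array this confounds pairs that co-print with third marks.
- The exact commercial 384-spot layout is not shipped; users supply
  their own layout TSV to analyze real membranes.
- bigWig input is out of scope; tracks enter as bedGraph (convert
  externally, e.g. `bigWigToBedGraph`).
- Peak calling, alignment, DE model fitting and GO enrichment are
  upstream of this package and are consumed, not reproduced.
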