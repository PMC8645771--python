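# Methods

This note documents the models, default parameters and numerical choices
behind `gwaspathnet`, and what the synthetic fixtures do and do not show
about real data.

## Gene-level association scores

Every SNP is tested with the Pearson 1-df chi-square on the 2×2
case/control × allele-count table, computed as n(ad−bc)²/(r₁r₂c₁c₂).
Missing genotypes are dropped per marker (complete-case per SNP). A SNP
monomorphic in the pooled sample has no defined test; it is retained with
χ² = 0, p = 1 and a `monomorphic` flag rather than dropped, so the
per-gene SNP count M stays faithful to the map. The genomic inflation
factor divides the median observed χ² by 0.4549, the 1-df null median at
the precision conventionally used for this diagnostic.

SNPs are assigned to every gene whose interval, extended by a
`flank_bp = 20 000` bp flank on each side, contains them (multi-assignment
to overlapping genes allowed). Coordinates follow each format's own
convention — BED intervals 0-based half-open, SNP/.map positions 1-based —
and strand is ignored. Genes that receive no SNP are excluded from the
score table and reported separately.

The gene statistic is min-p with the first-order-statistic gene-size
correction p_adj = 1 − (1 − p_min)^(M^λ). The adjustment is evaluated in
log space, −expm1(M^λ · log1p(−p_min)), so p_min down to ~1e−300 keeps
full relative precision; the tests verify agreement with the naive power
expression to 12 significant digits over the range where both are stable.

### Tuning λ

λ is tuned on phenotype permutations: case/control labels are shuffled
(genotypes fixed), all SNP tests and gene minima recomputed, and for every
grid value the Pearson |corr(p_adj, M)| is evaluated on the sample pooled
across permutations; the argmin wins, with ties going to the smaller λ
(the weaker correction). Defaults: grid 0.00–1.00 in steps of 0.01, 20
permutations. Pooling across permutations stabilises the correlation
estimate; the number of permutations is configurable because the estimate
sharpens roughly with the square root of the pooled sample size. Spearman
correlation and a Kolmogorov–Smirnov uniformity statistic of the corrected
p-values at λ\* are reported as diagnostics. λ is tuned once on the
observed study and held fixed for all downstream permutation nulls;
re-tuning inside every pathway permutation would multiply cost by the grid
size for no change in the null ordering of pathways.

Because the simulator draws SNPs independently (no linkage
disequilibrium), each of a gene's M SNPs is a genuinely independent test
and λ\* lands at or near 1 — the full Šidák correction — on synthetic
data. On real genotypes, LD makes the effective number of tests smaller
than M, and λ\* settles well below 1. The synthetic fixtures therefore
validate that the tuning machinery finds the value that decorrelates
p_adj from M; they cannot validate behaviour under LD, which this package
does not model (an exchangeable within-gene correlation knob
`within_gene_corr` exists for stress-testing but is off by default and is
not a realistic LD model).

Degenerate input: if every gene has the same M, corr(p_adj, M) is
undefined and tuning raises an error saying correction is unnecessary.

## Weighted pathway tests

Weights are w_j = 1 + CS_j/C̄S with C̄S the mean combined score over
scored genes; unscored genes get w = 1, so all weights are ≥ 1 and a gene
with average prior evidence counts double. If every CS is zero the weights
are undefined and the code directs the user to equal-weight mode (all
w = 1), which reproduces the unweighted analysis.

The gene statistic is r_j = −ln p_adj,j. The log base only rescales all
statistics by a constant; the ES is invariant to that (its normaliser
cancels at exponent p = 1) and the sum-statistic's permutation p is
equivariant, so the choice is free and natural log is used. p_adj = 0 is
floored at 1e−300 and flagged before the log. Genes with equal w·r are
ordered by gene id so the ranking — and hence every downstream number —
is identical across platforms.

Pathways are first intersected with the analysed gene universe; those
with an intersected size outside the closed interval [10, 380] are
removed. Both the raw and the intersected sizes are carried in the
output, since a pathway's chip coverage is informative in itself.

Permutation nulls come in two schemes:

* `phenotype` (default for production runs): case/control labels are
  permuted and the entire gene-score stage recomputed per replicate, with
  λ and the weights held fixed — a subject-level null faithful to the
  sampling process. B defaults to 5 000.
* `gene` (fast approximation): pathway membership is randomised on the
  observed ranked statistics. For the sum-statistic this is exactly
  drawing N_H statistics without replacement; for the ES it is the
  standard competitive gene-permutation null. The test suite uses this
  scheme with B ≤ 500.

Empirical p uses the add-one convention (1 + #{ES_perm > ES})/(B + 1), so
the smallest reachable p is 1/(B+1) and no pathway reports zero; strict
`>` follows the fraction as defined, with `≥` available by flag.
NES = (ES − mean)/sd uses the sample standard deviation (ddof = 1); a
numerically constant null sample leaves NES undefined (NaN) rather than
infinite. The hypergeometric test runs unweighted only — a weighted
variant has no defined null here — with significant genes defined by
p_adj < 0.05. BH step-up adjustment is applied within each
(method, weighting) column via `statsmodels.stats.multitest.multipletests`.

Pathway crosstalk reports, per pathway pair, the count and proportion of
shared significant genes binned as none / <20% / 20–70% / >70%. The
proportion's denominator is the significant-gene count of the smaller
pathway by default (union and Jaccard variants are selectable) — the
smaller-set convention makes "complete containment" read as 100%.

## Subnetwork expansion

Seeds are genes with p_adj < 0.05 whose combined score strictly exceeds
the mean of all scored genes; the median is selectable as the cutoff
(`cs_cutoff_mode`) because either central value is defensible and they
differ on skewed score distributions. The Pearson correlation between the
selection indicator and gene length is reported as a diagnostic that seed
selection is not a disguised large-gene effect.

Flow propagation: a node with flow f and d edges in the active direction
sends f/d along each edge; receivers accumulate incoming flow truncated
at 1. Seeds carry flow 1; admitted non-seed members forward their received
flow rather than re-emitting 1, which keeps the total circulating flow
bounded by the seed count. Growth admits the highest-flow candidate (ties:
higher total degree, then lexicographic id — a total order, so
decomposition is deterministic), re-propagates from the enlarged member
set, and stops after 50 admissions per direction; the outgoing and ingoing
phases are merged, so a merged subnetwork holds at most 2 × 50 + #seeds
nodes.

A single growth pass seeded everywhere can touch several disconnected
regions; the subnetwork returned is the weakly connected component of the
grown node set containing the highest-degree seed, and only that
component's seeds are consumed. Repeated growth + deletion therefore
peels off one connected subnetwork per iteration until the seed pool is
exhausted, and every seed belongs to at most one subnetwork. Edge effect
labels (activation/inhibition) are carried through to the output but do
not alter flow — they are descriptive annotations.

The saturation Z-score standardises the subnetwork's seed count r against
drawing its n nodes from the N-node network containing R seed objects:
Z = (r − nR/N)/√(n(R/N)(1−R/N)(N−n)/(N−1)). The variance term is the
exact hypergeometric variance — verified in the tests against
`scipy.stats.hypergeom` moments — so Z > 0 exactly when r exceeds the
hypergeometric mean, in agreement with the upper-tail hypergeometric
p-value reported alongside. Zero-variance corners (R = 0, R = N, n = N)
return NaN with the p-value still defined.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Gene models**: lengths log-normal (median ≈ 22 kb, σ_log = 1.0),
  genes tiled on synthetic chromosomes with gaps wider than two flanks so
  flank regions never overlap (multi-mapping is exercised by dedicated
  unit fixtures instead). SNP counts are Poisson in gene length (min 1,
  cap 500), giving the Spearman length–count correlation ≥ 0.5 that
  creates the min-p size bias before correction.
* **Genotypes**: Hardy–Weinberg minor-allele counts Binomial(2, MAF),
  MAF ~ Uniform(0.05, 0.5), identical in cases and controls for null
  SNPs. Causal SNPs shift the case allele frequency through the 2×2 odds
  identity p₁ = OR·p₀/(1 − p₀ + OR·p₀), so the allelic test's effect
  scale matches the configured odds ratio exactly. Defaults: 1 000 cases,
  1 000 controls, per-SNP OR 1.3.
* **Pathways**: 60 sets with truncated log-normal sizes in [10, 100]; 5
  planted sets receive exactly round(0.5 × size) causal genes each
  (disjoint across planted sets while the universe allows), the rest
  sample members uniformly.
* **Priors**: CS = Gamma(2, 0.5) background (mean 1) plus an additive
  shift of 2 for causal genes — non-negative scores whose group-mean
  difference equals the shift.
* **Network**: preferential attachment (2 edges per arriving node, random
  orientation, degree-proportional target choice) over 1 200 nodes
  containing all genes; 20% of edges labelled inhibition.

The default universe holds 1 000 genes. This is deliberately large
relative to the ~50 planted causal genes (≈5%): a much smaller universe
would make causal genes so common that random member sets under the
competitive gene-permutation null routinely contain several of them,
degrading the contrast between planted and background pathways — an
artifact of fixture scale, not a property of the method. Real chips carry
~15 000 genes with a far smaller causal fraction, so 5% is still a
conservative stand-in.

What the fixtures do **not** emulate: linkage disequilibrium and
haplotype structure, imputation, population stratification, genotyping
batch effects, and realistic pathway overlap topology. Passing tests
therefore demonstrate the statistical machinery (bias removal,
calibration, power against planted signal, deterministic plumbing) — not
robustness to those real-data complications.

## Problem sizes used in the tests

The behavioural contracts run at sizes chosen to make their statistical
assertions sharp while keeping the suite quick: the bias-removal check
uses 2 000 genes with SNP counts spanning 1–500 (σ_log = 1.6 lengths) and
250 + 250 subjects, 20 tuning permutations; type-I calibration uses 120
null pathways over 600 genes with B = 500 gene-scheme permutations;
planted-pathway recovery runs 20 replicate simulations at the default
design point (1 000/1 000 subjects, OR 1.3, half of each planted pathway
causal) with the weighted sum-statistic at B = 500. At B = 500 the
smallest reachable empirical p is 1/501 ≈ 0.002, comfortably below the BH
threshold for five discoveries among 60 pathways; at B ≈ 300 that floor
sits on the threshold itself, which is a resolution limit of add-one
empirical p-values worth knowing about when choosing B.

## Known limitations

* No LD modelling; gene statistics are min-p only (no combined-p variants
  such as LD-aware sums).
* No genotype QC (call-rate/HWE filtering) — inputs are assumed clean.
* The phenotype-permutation scheme recomputes every SNP test per
  replicate; at B = 5 000 on large studies this is the dominant cost, and
  the gene scheme is the practical alternative for exploration.
* The flow-expansion heuristic is greedy; it does not optimise any global
  subnetwork objective, and different node limits can split or merge
  modules.
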