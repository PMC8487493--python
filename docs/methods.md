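# Methods

This note documents the statistical models, the synthetic world the
package simulates, the numerical choices, and the limits of what a
passing test establishes.

## Count model and normalization

Raw counts `y_gs` for gene *g* in sample *s* are modeled as negative
binomial with mean `μ_gs` and gene-wise dispersion `φ_g` (so
`Var = μ + φ μ²`; `BCV = √φ` is the biological coefficient of
variation). Genes with mean unnormalized CPM below 1 across samples are
discarded before normalization (boundary inclusive: mean CPM exactly 1
is kept).

TMM factors follow the canonical doubly-trimmed weighted mean of
M-values: the reference sample is the one whose 75th-percentile count
fraction is closest to the mean of those fractions; genes zero in
either member of a pair are dropped; two-sided trims of 30% on M and 5%
on A; weights are inverse delta-method variances; factors are rescaled
to geometric mean one. The implementation agrees with edgeR's
`calcNormFactors` to machine precision on test fixtures.

Log2 CPM uses a prior count of 2 scaled by relative effective library
size: `prior_s = 2 · L_s / mean(L)` and
`log2cpm = log2((y + prior_s) / (L_s + 2 prior_s) · 10⁶)`. With this
convention log ratios of equal relative abundance are exactly zero;
note it makes log CPM only approximately invariant to overall
sequencing depth at low counts (exact at prior 0).

## Differential expression

Each comparison fits, per gene, an NB GLM with log link, one
coefficient per group (the "average log-count" parametrization) and
offsets `log L_s`. Because the design is group-wise, each coefficient
has a 1-D Newton/Fisher-scoring solve (converged at step < 1e-10, 100
iterations max, steps clipped at ±5); all-zero groups sit at the −∞
boundary and contribute zero log-likelihood. The LRT statistic is
`2(ll_full − ll_null)` clipped at zero with a χ² reference (df = number
of merged coefficients). Fixed-dispersion fits match edgeR's
`glmFit`/`glmLRT` statistics to ~1e-8 on fixtures; the reported log
fold changes are unshrunken MLEs (edgeR's table shrinks them slightly
toward zero with its own prior).

Dispersion estimation maximizes the Cox–Reid adjusted profile
likelihood `APL_g(φ) = ll_g(β̂(φ)) − ½ Σ_groups log I_k` over a log2
grid of 81 φ values spanning BCV ≈ 0.004–4, with parabolic refinement
of the grid maximum. The common value maximizes the summed APL; the
trend maximizes a locally shared APL (per-gene mean within up-to-ten
abundance deciles, linearly interpolated between bin centers as a
function of average log2 CPM); tagwise values maximize
`APL_g + G0 · sharedAPL_g` with `G0 = prior_df / df_residual` and
`prior_df = 10` by default, which shrinks gene-wise estimates toward
the trend; `prior_df = ∞` returns the trend exactly. An optional
`robust=True` winsorizes per-gene APL curves within bins (damping
outlier genes); the default is off. Parameter recovery: simulated
BCV 0.4 data (2000 genes × 16 samples) is recovered within ±0.03, the
Poisson limit estimates below 0.01, and the full filter→TMM→
dispersion→LRT pipeline holds its nominal size (type-I error within
[0.03, 0.08] at p < 0.05).

Dispersions are estimated once on the four-group design and the
tagwise values are reused by all six contrasts, with the null fit using
the same dispersion as the full fit (standard LRT practice). BH FDR is
applied within each comparison family separately; candidate-set runs
correct within the candidate family only (a flag in `run_comparisons`
switches the family). Storey q-values (π₀ from a cubic smoother of
π₀(λ) over λ ∈ {0.05, …, 0.90}, evaluated at the largest λ, clamped to
(0, 1]) are used where the module analyses call for q-values; families
smaller than 20 tests fall back to π₀ = 1 (= BH) because the smoother
is unstable there.

Sign convention: geography contrasts report positive log2FC for
overexpression in sympatry; sex contrasts report positive log2FC for
overexpression in females (the latter is this package's own
convention choice).

## Divergence trees

Per gene: expression is standardized to mean 0, sd 1 (population sd;
constant genes dropped with a warning), averaged within the four
groups, converted to the 4×4 absolute-difference matrix and summarized
by neighbor joining (Saitou–Nei). The four-taxon case is vectorized in
closed form across genes; a general NJ implementation backs the tree
type and is validated against additive matrices (exact) and
scikit-bio. Negative NJ branch lengths are clipped to zero and flagged.
Twelve randomization tests compare mean tip-length differences for the
pairs (SF,AF), (SM,AM), (SF,SM), (AF,AM) — within the candidate set,
within the non-candidate set, and the candidate-minus-non-candidate
difference — against 10,000 shuffles of the candidate labels; p is the
one-sided proportion of null ≥ observed (an `add_one` flag gives the
(r+1)/(N+1) estimator); BH over the 12 tests. The four default pairs
are this package's choice of the biologically motivated contrasts; they
are configurable.

## Ratio randomization tests

For two 0/1 significance columns A and B the statistic is
`ΣA / ΣB`; each null replicate swaps each gene's (A,B) pair
independently with probability ½. The shuffled "numbers" are the 0/1
indicators (the minimal reading of a per-gene two-column table);
shuffling is exposed per gene, so the null preserves each gene's total.
The three standard tables are: geography-DE (union of the two
within-sex comparisons) vs sex-DE (union of the two within-geography
comparisons); geography-DE in females vs males; sex-DE in sympatry vs
allopatry. Monte-Carlo p-values agree with exact enumeration within
three binomial standard errors at 10,000 replicates.

## Co-expression network

Genes are ranked by expression variance and the top fraction retained.
The ranking uses log2 CPM by default: raw-CPM variance scales with the
squared mean and effectively ranks abundance, which buries genuine
co-variation structure; a `variance_on="cpm"` switch restores the
raw-CPM ranking. Pearson correlations of log2 CPM are soft-thresholded
to `a = |r|^β` (unsigned default, signed available). `pick_soft_threshold`
selects the smallest β whose log-log degree-frequency regression
reaches R² ≥ 0.9 with negative slope; when no β qualifies (typical of
small block-structured data, which is not scale-free) it falls back to
the best-fitting β among those keeping mean connectivity ≥ 2, with a
warning. The pipeline default fixes β = 6: on desk-scale synthetic
data the automatic selection is seed-unstable, and 6 is the
canonical choice for networks of this kind.

TOM similarity is `ω_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 −
a_ij)`, diagonal 1. Modules come from average-linkage clustering of
`1 − ω` with a bottom-up "significant branch" cut: merges are replayed
in height order below the cut height (0.99); when two clusters that
each hold at least `major_size` genes merge, each side that does not
already contain a module and has at least `min_module_size` genes is
frozen as one; single-gene (chain) absorptions merely extend clusters.
`deep_split` maps to the partner-size requirement (3 → partner =
min_module_size; smaller values demand larger partners and split
less). This approximates the dynamic tree cut while being robust to
the singleton chaining average linkage produces; over-split modules
are reunited by the eigengene merging stage (dissimilarity 1 − cor <
0.3, iterated to a fixed point, merged modules take the largest
member's color name). Module recovery contracts: two well-separated
planted blocks are recovered exactly (ARI 1); planted latent-factor
modules (3 × 60 genes, loading 0.8, 16 samples) are recovered with
ARI ≥ 0.8; pure noise leaves ≥ 95% of genes grey.

Eigengenes are unit-norm first right-singular vectors of the
standardized module submatrix, oriented positively against the module
mean profile. Module–trait correlations use binary codes
(allopatric=0/sympatric=1, male=0/female=1), t-distributed p-values
(df = n − 2) and Storey q over all module × trait tests. Connectivity
statistics (degree, clustering coefficient, neighborhood connectivity)
are computed on the binary graph at |r| ≥ 0.05 and validated against
networkx; hubs maximize within-module connectivity, with a secondary
annotated hub recorded when annotations are supplied.

## Pathway concentration tests

A pathway is synaptic when "synap", "neuro" or "neura" occurs
(case-insensitive) in its name or its ancestor/child term text (that
text is an input column; no ontology service is queried). Per-module
tests use the synaptic count in the module against a
pathway-to-module shuffle holding module sizes fixed — exactly a
hypergeometric null, which the Monte-Carlo p matches within three
binomial standard errors. The overall test uses the total synaptic
count in trait-significant modules (either-trait by default;
geography-only by argument); the mean-per-significant test shuffles
the significance designation across modules; the geography-ratio test
uses `meanNSynapticGeo / meanNSynapticNonGeo` with the designation
shuffle. Ties count as ≥ throughout.

## The synthetic world

`SimulationConfig` defaults state a desk-scale version of the study
design: 17 − 1 = 16 samples in four groups (AF 5, AM 3, SF 4, SM 4),
2000 genes, lognormal library sizes with mean 2×10⁶ and CV 0.25 (a
stand-in for ~55M read pairs; depth does not change the statistics
exercised), per-gene baseline log2 abundance N(3, 2), and dispersion
`φ_g = 0.4² + 2/μ̄_g` (the BCV-vs-abundance trend; no numeric
dispersions are available for this design, so BCV 0.4 — the textbook
value for outbred animal tissue — is an assumption).

Planted effects. Geography effects are additive log2 offsets on
sympatric samples: 2% of genes shift in both sexes, 6.5% with full
magnitude (|log2FC| = 2) in females and half of it in males, 1% the
reverse, 1.5% shift by sex. The attenuated-shared parametrization is
deliberate: a pure one-group interaction effect would also create
massive sex-DE within sympatry, contradicting the design being
emulated (large female/male geography-DE asymmetry but few sex-DE
genes); expressing the full effect in the biased sex and
`cross_sex_attenuation = 0.5` of it in the other reproduces the
observed pattern structure. Modules are single latent factors
`z_s = a·trait_s + √(1−a²)·ε_s` (a = 0.75 for tied modules) entering
log2 abundance with loading 0.8; the default plants 12 modules of 35
genes (3 geography-tied, 1 sex-tied, 8 neutral) on genes free of
planted DE. Candidates (5% of genes) receive annotation text
containing a keyword from the shipped rule file; decoy annotations
(2% of non-candidates) contain a broad keyword plus its exclusion
trigger. The pathway plan gives every module 20 pathways, 12 synaptic
for geography modules and 2 otherwise.

What the generator does **not** emulate: read-level error, mapping
ambiguity, batch effects, isoform structure, correlated library
quality, and any non-NB overdispersion. A green recovery test
establishes that the pipeline can detect the stated effect structure
at the stated noise level — not that it would on arbitrary real data.

Determinism: one integer seed; per-component child generators are
spawned as `default_rng([offset, seed])` with fixed offsets, so each
output (counts, annotations, pathway table) is individually
reproducible and identical seeds give bit-identical outputs.

## Pipeline defaults and numerical choices

The end-to-end pipeline (`run_all`) uses α = 0.05 everywhere, 10,000
randomization replicates by default (integration tests scale this to
1,000–2,000, which only widens Monte-Carlo error), β = 6, a 35%
variance fraction and min module size 25 at desk scale (the study's
10% / 40 / cut 0.99 / deepsplit 3 / merge 0.3 remain the `NetworkConfig`
defaults for full-scale data). Planted pathway tables refer to planted
module labels; the pipeline maps each planted module to the detected
module holding the plurality of its genes before running the
concentration tests. Sample clustering support values are plain gene
bootstrap percentages, not approximately-unbiased multiscale p-values.
MDS is classical Torgerson scaling of root-mean-square log2
differences with negative eigenvalues clipped (warned).

## Known limitations

- The dispersion shrinkage is a documented APL + weighted-likelihood
  scheme, not a line-by-line reimplementation of edgeR's
  `estimateDisp(robust=TRUE)`; contracts are calibration and recovery,
  not numeric identity.
- The module detector approximates `cutreeDynamic`; partitions can
  differ from WGCNA's on the same data even when both satisfy the
  recovery contracts.
- Automatic β selection assumes approximate scale-freeness; on small
  block-structured data it warns and falls back (the pipeline pins
  β = 6 for this reason).
- Storey q-values fall back to BH below 20 tests.
- `ratio_statistic` is undefined when category B has no significant
  genes; the error suggests swapping categories.
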