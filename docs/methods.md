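# Methods

This note records the models the package implements, the defaults and why
they are set where they are, what the synthetic data does and does not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer from the code.

## Trait model (BLUP)

Replicated measurements follow y = μ + u_cultivar + u_rep + e with
independent Gaussian random effects. Variance components are estimated by
EM on the mixed-model equations maximizing the restricted likelihood
(iteration cap 500, relative tolerance 1e-8, components floored at 0);
non-convergence is flagged and the last iterate returned. The trait handed
to every later stage is μ + BLUP(u_cultivar) — kept on the mg/g scale, not
centred, so genotype-group impact rates downstream remain interpretable as
percentages of content. EM was chosen over a Newton-type optimizer because
the two-component problem is tiny, EM is monotone, and the zero-variance
boundary (all-identical measurements) is handled without special casing.
The grid-search REML oracle in the test suite confirms the EM fixed point
attains the restricted-likelihood optimum to 1e-4.

The K–S normality test uses estimated mean and SD without a Lilliefors
correction, matching the default behaviour of the common statistics
packages; the resulting conservatism is inherent to that convention and is
why the test's role here is descriptive, not gatekeeping.

## Single-locus association

Kinship is the centred cross-product estimator K = WW′/c with
W = dosage − 2p̂ and c = 2Σp̂(1−p̂), mean-imputing missing calls, plus 1e-6
on the diagonal for numerically safe eigendecomposition. Population
structure enters as principal-component scores (the Q-matrix role); GLM(Q)
and GLM(PCA) differ only in how many components the configuration asks for.

The mixed model y = Xβ + x_s b_s + u + e, u ~ N(0, σ²_g K) is fitted on the
spectral decomposition of K. The variance ratio δ = σ²_e/σ²_g is estimated
once on the marker-free model (REML over a log-spaced grid in 10^[−8, 8]
refined by bounded scalar minimization) and reused for every marker — the
population-parameters-previously-determined shortcut, which keeps a
4,000-marker scan near one second. Each marker is then tested by
generalized least squares on the rotated data with a 1-df F test. The F
reference (not a χ² Wald) is deliberate: as σ̂²_g → 0 the scan then reduces
*exactly* to the GLM, a limit the test suite asserts to 1e-6. PVE is the
partial R² of the marker in the (transformed) regression. Missing dosages
are mean-imputed for the mixed model because the eigen-rotation mixes
samples; the GLM path uses complete cases per marker.

LD pruning is greedy within windows of 50 SNPs sliding by 50: while any
retained pair has r² ≥ 0.2 the lower-MAF member is dropped (tie: later
position). The drop rule is fixed and documented because only
window/step/r² are conventionally specified.

The Bonferroni threshold is FWER/m with FWER defaulting to 0.01 — the
arithmetic that reproduces the printed 2.54×10⁻⁷ (−log₁₀ = 6.59) for
m = 39,327.

## Multi-locus association

One representative two-stage architecture stands in for the published
family of multi-locus models, because the funnel consumes only the set of
LOD-significant loci: stage 1 screens markers with the single-locus mixed
model at p ≤ 0.01 (capped at n/2 markers); stage 2 whitens everything with
the null-model covariance, residualizes markers on the fixed effects, and
fits all retained markers jointly with per-marker Gaussian priors whose
variances are estimated by EM empirical Bayes (cap 1000, tolerance 1e-8,
floors 1e-10). Different stage-1 strictness values act as model presets.

The LOD score of a marker is the likelihood ratio of its *shrunken* (EB)
effect against the marker-free model, evaluated at the marker-free residual
variance, divided by 2 ln 10. Two alternatives were tried and rejected
during development for inflating the null: profiling the residual variance
per marker lets the joint stage-2 overfit leak into every score, and
re-estimating the effect unshrunk by OLS undoes exactly the shrinkage that
protects chance-admitted markers. With the EB form, a pure-noise trait
yields ~0 markers at LOD ≥ 3 per 1,000-marker run while planted QTNs at
PVE 0.15 score LOD ≈ 10–50.

Significant hits within 20 kb on a chromosome chain into one locus
(single linkage; representative = best-scoring member); merging is
idempotent and order-independent. A locus becomes a QTN when every model of
at least one required set (all six single-locus, or all multi-locus
presets) has a locus within the same 20 kb distance. Gene windowing takes
every annotated gene whose span *overlaps* [QTN − 500 kb, QTN + 500 kb],
boundaries inclusive — overlap rather than containment, the permissive
reading.

## Co-expression modules

The network is unsigned: a_ij = |cor(x_i, x_j)|^β. The 70 %-zero filter
removes genes with zeros in strictly more than 70 % of samples (a gene at
exactly 70.0 % stays). Outlier samples are detected on the average-linkage
tree of Euclidean distances between expression profiles: a sample is
flagged only if it sits above the largest gap in the sorted leaf merge
heights *and* that gap exceeds 3×MAD of the tree's merge heights. A plain
"median + 3·MAD" cutoff was tried first and rejected: some sample always
joins the tree last, so that rule flags somebody on nearly every
homogeneous dataset. Flagging more than 20 % of samples requires an
explicit override, since that pattern indicates a batch problem rather
than a few bad arrays.

The soft threshold scans powers 1–20 in half-integer steps (so the
conventional 8.5 is on the grid), computing the signed scale-free fit
(log₁₀ frequency vs log₁₀ mean connectivity over 10 equal-width bins,
negated for a positive slope). Selection runs on a 3-point median filter of
the fit curve — the binned statistic is noisy in β and an isolated spike
must not decide the power — taking the smallest power reaching R² ≥ 0.85,
else the argmax. The *pipeline* nevertheless defaults to a fixed β = 8.5
(configurable, `power: null` restores automatic selection): on panels where
several modules correlate with the same trait, and therefore with each
other, the scale-free fit peaks at low powers where the unsigned TOM still
entangles those modules; fixing the conventional value, as the original
analysis did after inspecting the fit curve, is the robust choice and the
report records both the fixed and the fit-selected power.

TOM is the standard topological overlap
TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with unit diagonal,
verified against a triple-loop evaluation to 1e-12. Modules come from
average-linkage clustering of 1 − TOM with a static cut at 0.99 of the
maximum merge height — static, not dynamic, so module assignment is a
deterministic function of the input; 0.99 rather than a value closer to the
root because two distinct tight modules whose clusters merge just below the
root must stay separate, while unclustered background still splinters into
sub-minimum fragments that fall into the grey set. Branches under 5 genes
are grey. Eigengenes are first principal components of standardized module
expression, sign-fixed against the module mean profile; module–trait p uses
the t-transform of Pearson r. Hubs are the top-5 genes by weighted degree
on within-module edges with adjacency > 0.4 (ties break lexicographically).

## SNP effects

The ORF finder scans the three forward frames of the oriented mRNA for the
longest ATG-initiated, stop-terminated frame of at least 150 nt (stop codon
included; ties to the earliest start); reverse-strand search is out of
scope because inputs are already oriented transcripts. Substitutions inside
the ORF are classified by translating the affected codon(s) with the
standard genetic code; InDels are frameshift when the length difference is
not a multiple of 3, otherwise in-frame and reported as non-synonymous.

Genotype-group statistics compare the two homozygote classes by
equal-variance t-test (heterozygotes excluded by default; a pooling option
exists), with the impact rate (High − Low)/Low × 100 % always non-negative
because High is defined as the larger group mean. Raw p ≤ 0.05 without
multiple-testing correction follows the published procedure this pipeline
operationalizes; Benjamini–Hochberg is available behind a flag.

The seven dominance classes are assigned after normalizing labels so "AA"
is the favorable homozygote (larger mean). Sample means are never exactly
equal, so equality is operationalized statistically: AG = AA and AG = GG by
two-sample t-tests, AG = midpoint by a one-sample t-test of heterozygote
values against the observed midpoint, all at α = 0.05, checked outward from
the midpoint (AD first, then CD/NCD, then the strict orderings). An
exact-arithmetic mode (tolerance 1e-9) exists for analytic fixtures and is
what the exhaustiveness sweep uses: over a fine grid of heterozygote means
the classifier returns exactly one of {OD, CD, ID, AD, NID, NCD, NOD}.

## Correlation networks

Edges join gene pairs whose Pearson correlation has two-sided t-transform
p ≤ the threshold; constant-expression genes are excluded from edges but
kept as flagged nodes, and edge sets are monotone in the threshold by
construction. "Tight interaction with the enzyme panel" is operationalized
minimally as ≥ 1 surviving direct edge to a panel gene (a stricter minimum
edge count is a parameter): a candidate is *confirmed* if connected at
p ≤ 0.05 and *key* if still connected at p ≤ 10⁻⁶. The high/mid/low
comparison ranks samples by trait (ties by sample id, deterministically),
takes the top, centered-middle and bottom group_size samples (default 14),
builds each group's p ≤ 0.05 network, and reports connected-node counts,
total nodes, edges, and per-group unique genes and edges — both node
conventions, since published node counts do not state whether isolated
nodes are included.

## Synthetic data

The generator emulates the statistical structure of a ~344-cultivar core
collection measured for a root metabolite: biallelic SNPs in LD blocks,
mild two-subpopulation structure, a replicated mg/g trait with CV ≈ 0.5
(mean 0.632 mg/g), planted QTNs, and an expression matrix with planted
modules. All randomness flows through one `numpy.random.default_rng`
(PCG64) stream per entry point, so outputs are bit-identical across
platforms for a fixed seed.

Genotypes: each allele copy is a thresholded Gaussian; within an LD block
the latents share compound-symmetric correlation ld_rho (default 0.9,
block size 10). The ancestral frequency is drawn uniform(0.05, 0.5) *per
block* and shared by block mates — with independent per-SNP frequencies the
attainable r² between block mates would be capped by the frequency mismatch
no matter how strong the copula correlation. Subpopulation frequencies
diverge by a Balding–Nichols Beta draw (F_st default 0.05). SNP positions
sit on a fixed grid with a seeded jitter so variants can fall inside gene
spans. A Gaussian copula was preferred to a coalescent simulation because
it is desk-scale, needs no external machinery, and gives directly
controllable r².

Trait: g = Σ β·dosage + d·het over planted QTNs (auto-placement: two QTNs
on different chromosomes sized for PVE 0.15 each); the non-genetic variance
is split 60 % persistent sample effect, 5 % replicate effect, the rest
residual, and replicates are clipped at 0 mg/g — matching the non-negative
content scale rather than assuming log-normality. The reported trait SD and
CV of the emulated study are mutually inconsistent with its mean; the
generator targets the CV and does not attempt to match both.

Expression: each planted module is driven by a factor correlated with the
standardized trait at its target r (defaults (10, 0.85), (15, 0.5),
(20, −0.4) — one strong module mirroring the reported key-module
correlation, plus a weaker positive and a negative one); member genes load
at 0.95, deliberately tight (pairwise r ≈ 0.9) because hub selection at
adjacency > 0.4 under β ≈ 8–12 requires the near-duplicate co-expression
that transcripts of one pathway exhibit. The 15-gene key-enzyme panel rides
the strongest module's factor. Non-negativity comes from an exponential
link with scale 0.3, which distorts Pearson correlations only mildly.

Gene models are intron-less tiles, each with one planted ORF of known
frame; for any SNP inside a gene span the mRNA base at the mapped position
is overwritten with the VCF REF allele so genomic variants translate
consistently. `simulate_dataset` places the strongest module's genes
closest to the first QTN, and the end-to-end configurations tile genes at
90 % genic coverage over the whole SNP territory — without that coverage a
mid-chromosome QTN can land outside every gene and the SNP-effect stage has
nothing to test, breaking the construction the integration tests rely on.

What the generator does *not* emulate: realistic recombination maps or LD
decay (blocks are rectangular), allele-frequency spectra of real panels,
expression count noise or library-size effects (values are smooth
log-normal-like), introns/UTR structure beyond a single planted ORF, and
any genome-sequence realism. Passing tests therefore demonstrate that the
pipeline's statistics are calibrated and its plumbing correct on data with
the assumed structure — not that the biological conclusions of any
particular real dataset would be reproduced.

## Desk-scale problem sizes

Defaults are sized so the full pipeline runs in seconds-to-minutes on one
CPU: 344 samples × 4,000 SNPs (the sample size of the emulated study, with
the marker panel scaled down; paper-scale 39,327 markers is a config value
away), 600–800 genes, 3 replicates. The acceptance script uses 2,000 SNPs
over 8 chromosomes for the funnel run and 10 replicate seeds for the
calibration and recovery rates.

## Known limitations

- The multi-locus stage is one representative two-stage EB model, not a
  re-implementation of the five published optimizers; agreement with their
  numerical output is explicitly out of scope.
- P3D (shared null variance components) slightly misestimates per-marker
  variance when a marker has large effect; exact per-marker REML exists
  only in the test oracles.
- The static tree cut with a fixed height is cruder than dynamic branch
  cutting for modules of very different tightness; the cut height is a
  config knob.
- Genomic both-strand ORF search, splice-aware consequence annotation,
  fine-mapping and annotation-weighted prioritization are out of scope.
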