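# Methods

`enrichsim` is a simulation study of SNP-heritability *enrichment*
estimation: how accurately does two-component GREML recover the share of
heritability carried by an annotated SNP category, under different
assumptions about the relationship between allele frequency, linkage
disequilibrium (LD) and effect size?  Everything below is computed by the
package; the analysis drivers under `analysis/` and the tests exercise
exactly these components.

## The estimand

For a variant category F ("functional" subset) inside a panel of
N_total QC-passing SNPs, the heritability enrichment fold is

    fold = (h²_F / h²) / (N_F / N_total),

the category's share of SNP heritability divided by its share of SNPs;
fold 1 means no enrichment.  h²_F and h² come from a two-kinship mixed
model

    y = Xβ + g_F + g_R + e,   g_F ~ N(0, σ²_F G_F),  g_R ~ N(0, σ²_R G_R),
    e ~ N(0, σ²_e I),

where G_F is built from the category's SNPs and G_R from the rest of the
genome, X holds an intercept plus the leading principal components of the
all-SNP kinship, and heritabilities are variance shares
h²_c = σ²_c / (σ²_F + σ²_R + σ²_e).  Each sub-kinship is rescaled to mean
diagonal 1 before fitting so the shares are on a common scale (the
alternative — no rescaling — changes the h² scale slightly; we normalise
and say so).

## Kinship model family

All four kinship models are one family.  With dosages x_ki ∈ {0,1,2},
allele frequency p_i, heterozygosity h_i = 2p_i(1−p_i), exponent α and
optional LD weights w*_i:

    z_ki = (x_ki − 2p_i) · h_i^(α/2) · √w*_i,
    G = ZZᵀ / Σ_i w*_i h_i^(1+α).

α = 0 is the VanRaden kinship (effect variance ∝ h_i), α = −1 the classic
GCTA kinship (equal variance per SNP), intermediate α the "α-model", and
α = −0.25 with LDAK-style weights the LD-adjusted kinship (the printed
exponent 0.75 is 1 + α).  Under Hardy–Weinberg sampling E[(x−2p)²] = h,
so E[diag G] = 1 for every member.  A literal "as-printed" variant —
shared centered M with model-specific scalar denominators — is available
behind `scaling="as_printed"` for sensitivity checks; it does not reduce
to the standardized kinship at α = −1, which is why the per-SNP scaling
family is the default.

LD weights: the genome is tiled into half-open windows of a fixed kb
length (1–5000 kb grid) anchored at bp 1, and each SNP gets
w_i = 1 / Σ_{i′ ∈ window} r²(i, i′), the self-term included so
0 < w_i ≤ 1 and an isolated SNP gets weight 1.  Weights are normalised to
mean 1 per window (`normalize="global"` for a genome-wide alternative —
the scope of the normalising sum is genuinely ambiguous in the source
descriptions, so both exist and window is the default).  No iterative
reweighting: only the simple inverse-sum-of-r² scheme is in scope.
SNP exclusion by weight threshold is available (`LDWeights.thresholded`)
because under the self-term convention no weight is exactly zero.

## REML

`reml_fit` maximises the restricted likelihood
−½[log|V| + log|XᵀV⁻¹X| + yᵀPy] (constant-free convention; tests compare
against a null-space-contrast likelihood, which differs by a fixed
constant) by average-information steps with step-halving, an active-set
treatment of components pinned at the variance floor
(10⁻⁸ · var(y)), and an EM-type multiplicative fallback when the AI
proposal is not an improvement.  A step is accepted only if the
likelihood does not decrease, so the iteration path is monotone.
Convergence: relative log-likelihood change < 10⁻⁶ and parameter change
< 10⁻⁶ · var(y); default cap 100 iterations (typical fits converge in
6–11).  Standard errors come from the inverse AI matrix at the optimum.
Boundary estimates are clamped non-negative and flagged, which keeps
enrichment folds non-negative.

## Synthetic genotype panel

The generator emulates a dense livestock chip panel (the real systems of
interest are cattle populations with strong LD: r² ≈ 0.5 at ~40 kb).

* **Positions**: a jittered regular grid over one or more synthetic
  chromosomes (1-based bp, strictly increasing).
* **Frequencies**: blockwise constant — one draw from the target MAF
  spectrum per 250 kb block (default spectrum: Beta(0.5, 1) mapped to
  [0.005, 0.5], an L-shaped, rare-heavy folded spectrum; any Beta or
  uniform shape on a sub-interval is configurable).  Equal frequencies
  within a block are what make high r² between neighbouring binary
  variants possible at all: two binary variants with mismatched
  frequencies f₁ < f₂ cannot exceed r² = f₁(1−f₂)/(f₂(1−f₁)).
* **Young sites**: a fraction (default 0.15) of sites draw a fresh,
  predominantly rare frequency (the rare tail of the spectrum is
  allocated to the young pool first, by an exact mixture split that
  leaves the site-level spectrum unchanged).  These emulate recent
  mutations: weakly coupled to their block, hence in systematically
  lower LD — which is why low-MAF SNPs end up with larger LD weights,
  as in real data.
* **Haplotypes**: a first-order Markov copy chain along each chromosome.
  With probability exp(−d/L) the allele at the next site is drawn from
  the comonotone (maximal-correlation) coupling with the previous site;
  otherwise independently from its margin.  Margins are exact by
  construction.  The copy scale L = 2·d₅₀/ln 2 puts the median pair r²
  at 0.5 at the requested decay distance d₅₀ (default 40 kb); measured
  medians on pilot panels are 0.45–0.49, inside the documented
  [0.4, 0.6] band.  The decay is exponential in distance, so the far
  tail (e.g. r² at 150 kb) sits below what a hyperbolic decay would
  give; only the half-decay anchor is calibrated.
* **Genotypes** are sums of two independent haplotypes; optional missing
  calls at a configurable rate for pre-QC panels.

What the generator does *not* emulate: genuine coalescent genealogy
(identity-by-descent segment structure, recombination hotspots),
population bottlenecks/admixture (a single homogeneous population per
call; structure can be planted by stacking panels), genotyping error,
and imputation artefacts.  Passing tests therefore demonstrate the
estimators' behaviour under controlled MAF/LD architectures, not
performance on any particular real population.

QC mirrors chip practice: drop variants with MAF < 0.005, call rate
< 0.90, or Hardy–Weinberg 1-df chi-square p < 10⁻⁶ (a variant failing
several filters is counted under the first, in that order, so the report
is deterministic).  The chi-square flavour (not the exact test) matches
the PLINK-style thresholding workflow the thresholds come from.
Monomorphic variants get HWE p = 1 by convention and fall to the MAF
filter.  Surviving missing dosages are mean-imputed (rounded), because
the kinship math needs complete dosages.  QC is applied before subsets
are defined.

The "functional" category is the union of gene-like intervals dropped
uniformly on the genome until the target SNP count is reached (±1
gene's worth).  The default interval length (250 kb) matches the
haplotype-block scale: in livestock genomes genic annotations span whole
LD blocks, and an interval length that sliced through blocks would
manufacture cross-category LD that real annotations do not have —
early experiments with 50 kb intervals in a 250 kb-block genome showed
exactly that artefact (cross-boundary leakage inflating the functional
fold).  The "non-functional" category is a uniform random SNP set of the
same size.

## Trait simulation

A trait has n_cv causal variants (CVs) drawn from a MAF range
(genome-wide [0.005, 0.5], common [0.05, 0.5], uncommon [0.01, 0.05) —
the half-open uncommon upper bound is deliberate), with a fixed number
inside the functional category (defaults: 2000 CVs, 500 functional at
full scale; desk-scale runs use 200/50).  Effects follow
var(u_i) ∝ h_i^{α_sim} normalised so Σ var(u_i)·h_i = h²; α_sim = −1
(default) gives every CV the same expected variance h²/n_cv.  Phenotypes
are y = g + e with g = Σ(x−2p)u and e ~ N(0, var̂(g)(1/h² − 1)) using the
*realised* sample variance of g, so each replicate hits the h² = 0.8
target in-sample (mean realised h² over 50 replicates is within ±0.02).

Truth is analytic: the category's true heritability is
Σ_{CV ∈ F} u²·2p(1−p) / var(pheno) with HWE-expected variances, which
makes truth exactly additive over genome partitions (no LD
double-counting).  For comparability, estimated and true folds are both
rescaled per replicate by nominal/true, so the corrected truth is
exactly 3.000 (functional) or 1.000 (random) — a ratio identity.  The
alternative interpretation (re-weighting the simulation until truth hits
3.000) was rejected because rescaling is the only reading that keeps the
estimate/truth comparison meaningful per replicate.

Replicates: the scenario harness redraws both the CV set and the
effects each replicate (`redraw_cvs=False` holds one CV placement).
Conditioning on a single CV placement leaves placement luck — which SNPs
happen to tag the category — un-averaged, so 30-replicate means would
inherit a panel-level bias of either sign; redrawing makes the replicate
mean estimate the design-level expected fold.  Equally, redrawing
effects (not only residuals) gives replicate means the between-replicate
spread that error bars imply.

## Scenario sizes

Desk-scale defaults are n = 500 individuals, m = 5000 SNPs, 200 CVs,
a 10% functional category holding 25% of the CVs (true fold 2.5,
corrected to 3.0), 30 replicates, 10 PCs — chosen to keep a full scenario
under ~10 s while the key recoveries remain statistically meaningful.
The full-scale configuration (`RunConfig`) mirrors the design this study
scales down from: 2000 individuals, hundreds of thousands of SNPs, 2000
CVs, 100 replicates.

Two desk-scale behaviours are worth knowing:

* Matched-model recovery (equal-variance architecture analysed with the
  α = −1 kinship pair) is accurate: corrected folds 2.97–3.10 for the
  functional category and 0.91–1.16 for the random category across panel
  seeds, each within two standard errors of nominal.
* Uncommon-CV traits are hard at n = 500: every kinship model
  overestimates the corrected fold (3–6 vs truth 3), and the spread is
  large.  The LD-weighted kinship helps in the replicate-level sense:
  on a strong-LD panel its per-replicate absolute errors are smaller
  than the unweighted α = −0.25 model's (mean paired improvement ≈ 0.4
  fold units, ~78% of replicates) — that per-replicate reading, not the
  difference of scenario means (which is dominated by panel-realisation
  noise at this scale), is the stable expression of the benefit.

## Numerical conventions

* Dosages are int8 with −1 as the missing code; kinship math is float64.
* Allele frequencies for kinships always come from the full analysis
  panel, so category and rest kinships share a frequency reference.
* PCA covariates always come from the all-SNP VanRaden kinship,
  whatever the enrichment model, so model comparisons share one fixed-
  effect design.
* Seed policy: every public operation takes an integer seed (or
  `SeedSequence`); the scenario harness spawns per-stage, per-replicate
  children from one master seed, so any stage is re-runnable alone.
* File formats: PLINK bed/bim/fam (SNP-major v1.00) for panels, GCTA
  `grm.bin` dialect (float32 lower triangle + id + N files) for
  kinships, whitespace FID/IID tables for phenotypes/covariates,
  two-column text for LD weights, YAML for run configuration.

## Known limitations

* The exponential LD-decay tail underestimates long-range LD relative
  to real cattle panels; weights at very long windows (5000 kb) are
  therefore less contrasted than they would be in real data.
* The copy-chain genome has no recombination-rate variation, so LD is
  homogeneous outside the young-site mechanism.
* Single population; no environmental covariates beyond PCs.
* The two-component GREML inherits the usual small-n instability of
  variance shares near the boundary; folds from n = 500 runs carry
  per-replicate SEs of the same order as the folds themselves for
  random categories.
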