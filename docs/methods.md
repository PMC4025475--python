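# Methods

## Data model

A cross dataset couples a segregant × marker genotype matrix (parental codes
S/Y, stored internally as probability-of-S: S → 1, Y → 0, missing → NaN) with
a segregant × environment × parameter (× replicate) phenotype array. Marker
order is always (chromosome, bp)-sorted; chromosome labels are accepted as
roman or arabic and normalized to integers, printed as roman
(`chrXIV(465,189)`) in outputs. Positions are 1-based bp as printed in locus
notation. Missing phenotypes stay missing (never zero-filled); every scan
drops segregants pairwise for its own (environment, parameter), maximizing n
per scan.

## Genetic map and conditional genotype probabilities

Two-point recombination fractions between physically adjacent markers are
the discordant-call fraction among pairwise-complete segregants, truncated to
[0, 0.5]. Distances use the Haldane map function d = −50·ln(1 − 2r) (no
crossover interference); marker order is taken from the physical map and
never re-estimated. During map building, adjacent r̂ is clipped to 0.4999
rather than splitting a chromosome: linkage-group membership is known from
sequencing. When an estimated map places two markers at identical cM (zero
observed recombinants), both keep their own grid point, so marker identity is
never lost.

Conditional probabilities P(S at q | observed flanks) use the nearest
informative marker on each side (no distance cap) under error-free Haldane
conditioning, e.g. P(S|S,S) = (1−r_L)(1−r_R)/[(1−r_L)(1−r_R) + r_L·r_R];
single-flank positions use P = g(1−r) + (1−g)r, and segregants with no data
on a chromosome get 0.5. An HMM with a genotyping-error parameter (as some
scan software uses) would differ only at contaminated markers; on dense maps
the LOD difference is well below the 0.2 tolerance we regard as
method-equivalent. Pseudomarkers are inserted so grid spacing is at most
`step_cm`; the default is 2 cM for single-environment and GEI scans and
markers-only for interaction scans (interactions are tested between markers,
not imputed positions).

## Scan statistics

Every statistic is a nested-least-squares LOD, (n/2)·log10(RSS₀/RSS₁), with a
finite cap when RSS₁ < 1e−12·RSS₀. The four model pairs are listed in the
README. Two properties are load-bearing and tested to 1e−9:

- agreement with an independently coded OLS oracle on random instances, and
- exact additivity of nested log-likelihood ratios
  (full-vs-null = additive + interaction).

Implementation notes: the scan cores are vectorized through projections.
A single-predictor LOD is −(n/2)·log10(1 − r²) of the simple regression; the
GEI scan residualizes against [1, E] analytically (per-environment centering),
after which the additive fit depends on (y_A + y_B)·x_c and the interaction
fit on (y_B − y_A)·x_c with x_c the centered genotype; pair/triple scans
precompute an orthonormal basis of each tuple's base design plus the unit
residual of its interaction column, so all permutations reduce to one matrix
product. Residual variance is pooled across environments in the stacked GEI
regression (one homoscedastic linear model); heteroscedastic variants are out
of scope.

Degenerate inputs: constant genotype columns score LOD 0 and are skipped for
calls; collinear locus tuples (|r| > 0.9, or same-chromosome loci closer than
25 cM) are excluded from interaction scans — linked markers produce product
terms that mimic epistasis. Ties in a chromosome's maximum LOD break to the
smallest bp position, for determinism.

## Permutation significance

Single scans: the phenotype vector is shuffled against segregant genotypes
(preserving LD) and the genome-wide maximum LOD recorded per shuffle;
p = max(k, 1)/n_perm where k counts null maxima ≥ observed, flooring the
smallest reportable p at 1/n_perm. GEI scans permute segregant identity with
the (envA, envB) phenotype pair kept intact, preserving the
phenotype–phenotype correlation under the null — the conservative choice.
Interaction scans shuffle the phenotype once per permutation and take the
maximum interaction LOD over the whole tested pair/triple set, so set-wide
multiplicity is handled exactly like the genome-wide max of a single scan;
a per-tuple p-value is stored alongside for diagnostic use. Defaults: 1000
(single), 100 (GEI), 10,000 (interactions); calls at p ≤ 0.2.

Calibration: under a global null (144 segregants, 16 × 100 cM, 30
markers/chromosome, 200 permutations), the fraction of datasets whose best
peak reaches p ≤ 0.05 is 0.0425 over 400 replicates (the test suite asserts
the [0.03, 0.07] band). The exact expectation under the floor rule is
11/201 ≈ 0.055.

## GEI classification

At a called GEI locus the allele-group means ± 1 SE are computed per
environment from observed (non-imputed) marker calls. An environment is
"separated" when the two ±1 SE intervals do not overlap. Crossover =
separated in both environments with opposite-signed allele effects; scale =
separated in both with the same sign (the measure-zero tie |Δ_A| = |Δ_B|
falls to scale); environment-specific = separated in exactly one; anything
else — including a missing SE from an allele class with < 2 segregants — is
unclassified. A GEI call is flagged *novel* by the pipeline when its marker
was not called at p ≤ 0.2 in either environment's single scan.

## Candidate collation and anchors

Single-environment candidates use the most permissive defensible rule: a
chromosome's peak marker enters if its LOD exceeds the smallest of the
permutation null maxima (equivalently, permutation p < 1). GEI peaks enter at
p < 0.5. The union over both growth parameters and all environments/pairs is
de-duplicated by marker. Large-effect anchors are either named explicitly or
chosen automatically as the top-LOD distinct called markers per parameter
(default 3). Triples are built as {anchor} × {called pairs} with the anchor
distinct from, and not collinear with, either pair member.

## Simulator

Meiosis: per chromosome, a fair Bernoulli start allele at the left telomere
and independent recombination events between adjacent markers with the
Haldane probability for their cM separation — a no-interference model, chosen
because the analysis methods, not meiosis biology, are the target. Expected
allele frequency is 0.5 at every marker. Physical coordinates are synthesized
at 2.5 kb/cM (yeast-like), strictly increasing.

Phenotypes: y = μ(env, param) + Σ effect·∏(coded genotypes) + N(0, σ) per
replicate, with ±0.5 coding so a planted single-locus "effect" equals the
between-allele mean difference and a term of order k contributes
effect²/4^k of variance. `effect_for_variance` inverts this to plant a term
at a chosen variance fraction. Genotype masking is independent Bernoulli;
identical configs are bit-reproducible.

Default panel: 144 segregants, 16 chromosomes × 100 cM × 30 markers, 7
carbon-source environments, 2 growth parameters, σ = 1. The marker count is
the test-scale choice (dense 48k-marker panels are supported but not needed
to exercise the methods); σ is a free scale since every scan is invariant to
affine phenotype transformations. The study-scale effect sizes — 25% of
variance for a "large-effect" QTL (expected LOD ≈ 9 at n = 144), 15% for a
two-locus interaction, 12% for a three-way term — are the package's
calibration choices for its power studies.

What the simulator does **not** emulate: crossover interference, segregation
distortion, genotyping error, shared environmental batch effects, and
non-Gaussian growth-curve noise. Passing recovery tests therefore show the
statistical machinery works at realistic signal/noise, not that real growth
data are this clean.

## Power and calibration studies (plasticqtl.studies)

Each study simulates independent panels at the default layout, runs the full
analysis path (map estimation included — the true map is never used), and
reports a rate:

- additive recovery: genome-best peak on the right chromosome within 5 cM of
  the planted marker with p ≤ 0.05 (distance measured on the physical scale,
  2.5 kb/cM);
- crossover recovery: a GEI call within 5 cM classified "crossover" at
  p ≤ 0.05;
- pair/triple recovery: the planted tuple called at p ≤ 0.2 under the
  set-max null, with candidates = planted markers + one mid-chromosome decoy
  per chromosome (what collated relaxed-threshold peaks look like); the
  triple study plants a pairwise term (15%) plus a pure three-way term (12%)
  so the pair scan feeds the anchored triple scan end-to-end.

Measured at seed 0 (200 replicates each): crossover 0.99, pair 0.96, triple
0.965 — comfortably above their acceptance floors (0.90/0.80/0.70). Additive
localization reaches 0.92 against a 0.95 floor; this is an information limit,
not an implementation defect. The Darvasi–Soller approximation for a
backcross-type panel puts the 95% confidence interval of QTL location at
roughly 3000/(N·δ²) ≈ 15.6 cM for N = 144 and δ = 1.15 residual-SD units,
i.e. ± ~8 cM — so ~91–94% within ±5 cM is the expected ceiling, and we
measure the same rate when scanning on the true simulated map or at 2–3×
marker density. The corresponding acceptance test is left failing rather
than loosened.

## Known limitations

- One call per chromosome per scan; secondary linked peaks are not separated.
- Interaction scans test markers only; an interaction falling between sparse
  markers is attributed to the nearest candidate in partial linkage.
- The heritability estimator is the replicate-based one-way random-effects
  decomposition H² = σ²_b/(σ²_b + σ²_w) with the unbalanced n₀ correction and
  negative σ²_b truncated to zero; it needs ≥ 2 replicates for ≥ 10
  segregants and is validated on synthetic data only.
- Diploid crosses, interference map functions, composite interval mapping and
  multi-QTL model selection are out of scope.
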