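# Methods

## The model

The package treats a gene regulatory network (GRN) as a recursive linear
structural equation model (SEM) over observed expression levels. Genes split
into an exogenous set ξ (no incoming regulatory paths) and an endogenous set
η (at least one incoming path):

    η = B η + Γ ξ + ζ,   ξ ~ N(0, Φ),   ζ ~ N(0, Ψ)

with B strictly lower-triangular after topological ordering (the endogenous
dependency graph is acyclic), Ψ diagonal (residuals of endogenous genes do
not co-vary), and Φ either diagonal ("no covariance"), fully free ("full
covariance"), or free on a named subset of pairs ("partial covariance").
Recursiveness plus diagonal Ψ makes every such model identified provided the
trivial counting rule t ≤ p(p+1)/2 holds; `check_identifiability` reports
both conditions. Self-loops (e.g. the well-known Sxl autoregulation) are
rejected at construction: they would break recursiveness, and their effect
on the cross-sectional covariance is absorbed by the gene's variance
parameter anyway.

Only the covariance structure is modeled. Means are saturated: they are
carried through simulation and reporting but never constrained, so they
contribute nothing to fit statistics.

## Fitting

The ML discrepancy is

    F_ML(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,

with Σ(θ) the model-implied covariance. For the model class above F_ML
separates exactly: writing the full system x = A x + e with
cov(e) = blockdiag(Φ, Ψ), one gets ln|Σ| = ln|Φ| + Σ_j ln ψ_j and
tr(S Σ⁻¹) = tr(S_ξξ Φ⁻¹) + Σ_j E_jj/ψ_j, where E_jj is the residual moment
of endogenous gene j given its parents, a function of row j of the
coefficient matrix only. Each endogenous equation therefore has the
closed-form minimizer of a regression computed from S (coefficients from the
parent-block linear solve, ψ̂ the Schur complement — automatically positive
for positive-definite S), and the exogenous block reduces to minimizing
ln|Φ| + tr(S_ξξ Φ⁻¹) over the covariance pattern. That subproblem is closed
form when the pattern is diagonal (φ̂_ii = s_ii) or saturated (Φ̂ = S_ξξ);
for a proper subset of free pairs it is solved by L-BFGS-B with the
variances log-transformed to enforce positivity, sample variances and zero
covariances as start values, and an analytic gradient
Φ⁻¹ − Φ⁻¹ S_ξξ Φ⁻¹ projected onto the free pattern. Non-positive-definite
trial points get a large finite penalty (quasi-Newton line searches cannot
digest infinities).

This factorized solution is the exact global ML estimate, deterministic,
and fast enough (well under a millisecond per model) to make exhaustive
scans and simulation-based calibration routine; the test suite verifies it
against an independent brute-force minimization of the full F_ML surface on
small models and against per-equation OLS on raw data for full-covariance
models (the classical recursive-system identity).

A fit is flagged converged when the analytic gradient norm over all free
parameters is ≤ 1e−6 (the subproblem iteration cap is 500). A
non-positive-definite sample covariance is a hard error with a diagnostic
message — no silent ridging, because any regularization would shift every
BIC in the scan.

## Fit statistics and conventions

χ² = (n − 1)·F_ML. GFI = 1 − tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²];
AGFI = 1 − [p(p+1)/(2 df)](1 − GFI) (reported as NaN when df = 0);
PGFI = [df/(p(p+1)/2)]·GFI. Information criteria use the χ² + penalty·t
convention: AIC = χ² + 2t, BIC = χ² + t ln n, CAIC = χ² + t(ln n + 1).
Different SEM packages differ by additive constants here (some use
χ² − df·penalty); differences between models on the same data — the only
quantity the expansion method consumes — are invariant to the choice, which
the tests assert algebraically.

## Baselines

The two sex-hierarchy baselines are reconstructed from the cascade's known
regulatory interactions. CEGS: 12 genes, 7 exogenous
{Spf45, snf, vir, fl(2)d, tra2, her, ix}, 5 endogenous
{Sxl, tra, fru, dsx, Yp2}, 14 paths (four splicing regulators into Sxl;
Sxl, vir, fl(2)d into tra; tra and tra2 into fru and into dsx; dsx, her, ix
into the Yp2 readout). DSPR: dsx was not measured in that population, so
the dsx branch is replaced by direct tra→Yp2 and tra2→Yp2 edges, giving 11
genes and 13 paths. These edge sets reproduce the published enumeration
sizes exactly (84/104 candidate paths, 34/37 gene placements), which pins
them combinatorially; any edge can nonetheless be overridden through the
model-spec text format. The partial-covariance variant frees exactly the
three empirically co-varying pairs tra2~~snf, tra2~~Spf45, tra2~~fl(2)d.

## Expansion scans

New-path candidates are all ordered gene pairs excluding existing edges and
their reversals (a reversal closes a 2-cycle): G(G−1) − 2E candidates.
Candidates that close a longer directed cycle are enumerated but recorded as
skipped with the cycle named — non-recursive models are out of scope.

Gene placements: one downstream placement per non-reporter gene (the
terminal readout never acts as a regulator source), one upstream placement
per gene, one insertion per baseline edge: 2G − 1 + E placements with a
deterministic 1-based model index. Insertions retain the direct src→dst
edge, so every candidate model nests its reference. A gene placed upstream
enters as a new exogenous variable with free variance; downstream or
inserted, as a new endogenous variable with free residual variance; a new
path into a formerly exogenous gene converts that gene to endogenous (its
free variance becomes a residual variance, and any free covariance pairs
naming it are dropped).

ΔBIC for a gene placement is computed against the baseline augmented with
the candidate gene as an isolated exogenous variable: candidate and
reference then share the same observed-variable set, so their BICs are
directly comparable, and the isolated-gene reference is nested in every
placement. Per gene, the best placement is the minimum BIC (ties broken by
smallest model index); the gene is accepted when best ΔBIC exceeds the
threshold.

## Threshold calibration

Each calibration replicate (i) simulates an expression matrix of the
original sample size from the fitted baseline (multivariate normal with the
implied covariance and the sample means), (ii) appends one null gene —
iid normal with mean and variance drawn with replacement from a pool of
(mean, variance) pairs harvested from the population expression matrix —
(iii) scans all placements, and (iv) records the best ΔBIC. Appending the
null gene to freshly simulated data (rather than to the observed data)
makes the null hypothesis exact by construction. The acceptance threshold
is the (1 − α) quantile, by default over the replicates whose best
placement improved on the baseline at all (an `all`-replicates mode is also
provided, matching the other reading of the published procedure); quantiles
use linear interpolation between order statistics. One master seed drives
per-replicate substreams, so calibration is exactly reproducible.

The improving fraction doubles as a baseline diagnostic: at or below 5% the
baseline is flagged `overfit_suspected` (a saturated baseline leaves noise
genes nothing to improve; the threshold falls back to 0), at or above 95%
`underfit_suspected` (almost any gene helps). Note a structural limit of
the exact-null design: because replicates are simulated *from the fitted
baseline*, a misspecified baseline cannot leak misfit into the null ΔBIC —
the pathway-misfit term cancels exactly between the reference and every
placement model. The underfit flag therefore fires only on improving
fractions driven by genuinely flexible placements, and the diagnostic
thresholds are tested at the contract level rather than by reconstructing a
misspecified-pathway scenario.

With 37 placements, each adding ≥1 parameter, the chance that at least one
placement of a pure-noise gene improves BIC at n = 75 is substantial
(roughly 1 − (1 − P[χ²₁ > ln 75])³⁷ ≈ 0.7), which is exactly why a
calibrated positive threshold — not 0 — is needed for genome-scale scans.

## Synthetic data

The generator draws from the structural equations directly (ξ from
N(0, Φ), ζ from N(0, Ψ), η by solving the triangular system), so the
generating parameters are exact ground truth. Two regimes mirror the
method's target populations: `dspr-like` (n = 596, DSPR baseline) and
`cegs-like` (n = 75, CEGS baseline). Default generating values are path
coefficients 0.5 (moderate regulatory strength, signal-to-noise 1 against
unit residuals), unit exogenous and residual variances, and zero means for
pathway genes. Null candidate genes draw means uniformly from [2, 12] and
variances from [0.25, 4], a realistic log2-expression spread; planted true
candidates are linear children of a named pathway parent with configurable
coefficient and noise. The candidate pool is scaled to hundreds of genes
(against the populations' ~7,400–8,800) to keep test runtimes in minutes;
all count identities are size-independent.

What the generator does *not* emulate: microarray probe effects, count
noise and mean–variance coupling of RNA-seq, batch structure, heavy tails,
or linkage between candidate genes. Passing tests therefore demonstrate
correctness of the machinery and its statistical calibration under the
model's own assumptions (multivariate normality after transformation), not
robustness to violations of them.

The genotype fixture writes a plain-text VCF 4.2 + BED6 pair whose per-gene
distinct-haplotype counts are computed by direct enumeration at generation
time, independent of the VCF-reading code under test.

## Unsupervised comparison

The graphical-Gaussian comparison network shrinks the sample correlation
matrix toward the identity with the analytic unbiased-risk intensity
λ* = Σ Var̂(r_ij) / Σ r_ij² (clipped to [0, 1]), inverts, and standardizes
to partial correlations — well-posed even for p > n. Edge significance uses
Fisher z with effective sample size max(n − p − 1, 3) and Benjamini–
Hochberg q-values rather than an empirical-null mixture; rankings by
|partial correlation| are identical to the reference approach, though
q-values can differ. Selection modes: FDR cutoff (0.2 in the comparisons of
interest) or top-k (k = 20). Neighborhood extraction is plain breadth-first
search to 1 or 2 steps on the undirected selected-edge set.

## Validation utilities

Differential-expression overlap requires a gene to pass the FDR cutoff in
*both* control comparisons with (by default) the same fold-change
direction; the cutoff is a required argument with no default because the
two natural choices (0.05 and 0.2) both appear in practice. Enrichment is
two-sided Fisher's exact (conditional-MLE odds ratio, hypergeometric
p-value), verified against exhaustive enumeration for small universes.
Allele counting concatenates each sample's SNP calls across a gene's CDS
intervals (BED half-open 0-based, VCF 1-based — converted internally) and
counts distinct strings: missing calls are set to reference in `reference`
mode, while `maf_drop` mode removes sites with minor-allele frequency < 5%
and then drops samples with residual missing calls rather than imputing
(no imputation method is defensible without the original genotyping
context). Heterozygous calls are counted by their first allele with a
warning — the intended inputs are inbred or hemizygous lines. Indels are
skipped and tallied.

## Problem sizes and numerical choices

Defaults used in the shipped tests and the reproduction script: n = 75
(cegs-like) and n = 596/600 for power checks; 2,000 calibration plus 2,000
evaluation replicates (the full procedure supports the 8,000 of the
original protocol); 50–100 replicates for power and recovery summaries;
candidate pools of 100–500 genes. Gradient tolerance 1e−6; quantiles by
linear interpolation; BIC ties in best-placement selection broken by
smallest model index; F_ML values within 1e−8 below zero are clamped to 0,
anything lower raises.

## Known limitations

- Non-recursive models (feedback loops, reciprocal paths fit as a single
  model) are out of scope; cyclic scan candidates are reported as skipped.
  Reciprocal relationships can still be *detected* as two separate accepted
  directed candidates intersected across populations.
- Standard errors and single-coefficient tests are not computed; inference
  is entirely model-comparison based.
- Absolute BIC/CAIC values are convention-dependent across SEM software;
  only Δ values are comparable.
- The calibration's exact-null design cannot surface baseline underfit
  caused by missing pathway-internal structure (see above).
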