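# Methods

## Mixing model

Seston PLFA composition is modelled as a linear mixture of taxon
signatures. Signatures are stored as a taxa × FA *ratio matrix* R with
every taxon's 16:0 entry equal to 1 (the GC-practical convention: ratios
to a ubiquitous reference FA are more stable across growth conditions
than absolute weight fractions). For fitting, each taxon row of R is
renormalized to proportions, F = R / rowsum(R); the 16:0 referencing
cancels in this step, so the model actually fit is scale-free per taxon.

For a sample composition **s** (proportions of total FA over the FAs
shared with R) the abundance vector solves

    min ‖Fᵀa − s‖²  subject to  a ≥ 0, Σa = 1.

The solve uses nonnegative least squares with a heavily weighted
sum-to-one augmentation row (weight 10⁴) followed by exact
renormalization. The augmentation matters: plain NNLS followed by
renormalization is *not* the simplex-constrained optimum and differs
from an exhaustive simplex grid search by up to ~5×10⁻³ on noisy
instances; the augmented solve agrees with the grid oracle to the grid
resolution (tested at 10⁻⁴ on random instances with ≤ 3 taxa).

Abundances are biomass *fractions*. No attempt is made to convert to
absolute biomass: that would require per-taxon FA-per-carbon conversion
factors the data do not constrain.

## Bounded ratio optimization

Field communities never match library signatures exactly, so R is
adjusted within a multiplicative box: each nonzero element is confined
to [r₀/b, b·r₀] with b = 1.5 (±50%) by default. Structural zeros (an FA
a taxon does not produce) are never created or adjusted, and the 16:0
reference entries stay frozen at 1.

The fit alternates:

1. abundances for all samples at the current R (simplex NNLS);
2. one projected gradient step on the free elements of R.

The gradient of the RMSE objective with respect to R at the inner
optimum is the fixed-A partial derivative (envelope theorem), computed
analytically through the row normalization:

    ∂mse/∂R_kj = (G_kj − ⟨G_k, F_k⟩) / s_k,   G = (2/N)·Aᵀ(AF − S).

The descent direction is preconditioned multiplicatively, d = −g·R²
(steepest descent in log-ratio coordinates). This is the natural metric
for parameters constrained to a multiplicative band, and it matters in
practice: unpreconditioned steepest descent — and, notably, L-BFGS-B on
the same objective — stalls in the ill-conditioned valleys this problem
develops when taxon signatures are correlated. The step is sized so the
largest relative element change is `step_init` (default 5%), backtracked
by halving (≤ 20 times) against the *joint* objective (abundances
re-solved at each trial matrix) and greedily doubled while the objective
keeps improving, so the RMSE trajectory is non-increasing by
construction. Iteration stops when the relative RMSE improvement falls
below `tol` (10⁻⁸) or after `max_iter` (500) iterations; non-convergence
is reported on the result object, never raised.

Residuals are unweighted across FAs by default. Whether the residual
should be weighted by FA abundance is genuinely open; a per-FA weight
hook (`UnmixingConfig.fa_weights`) is exposed for users who want
abundance weighting, and the objective is otherwise the plain RMSE
between observed and reconstructed proportions.

### Multi-run protocols

Two standard guards against sensitivity to the initial matrix:

* **successive runs** (`successive_runs`, default 8): each run's
  optimized matrix seeds the next; the best-RMSE run is returned. Since
  every run starts at the previous optimum, RMSE is non-increasing
  across runs.
* **randomized starts** (`randomized_starts`, default 60 starts): each
  start multiplies the free elements by seeded random factors drawn
  within the bound; the best 10% of optimized matrices are averaged
  element-wise and refit once. All starts and the final refit use the
  box anchored at the *original* R₀, so the returned matrix always
  respects the stated adjustment bound — compounding per-start boxes
  would silently widen it.

Both protocols agree to < 0.05 mean absolute abundance difference on
noisy synthetic data, which is the package's stability check.

### Identifiability

Parameter recovery of individual ratio elements depends on the
conditioning of the taxon signatures. With the packaged nine-taxon
matrix the two fungal phyla (Ascomycetes/Zygomycetes) and the two
Gram-positive phyla (Actinobacteria/Firmicutes) are nearly collinear;
a perturbed element of such a taxon can be compensated almost exactly
by abundance shifts, leaving a flat valley in the joint objective. On
those instances *no* optimizer pins the element (verified with an
independent quasi-Newton fit), although abundance recovery remains
good. Element-recovery tests therefore use a well-separated three-taxon
instance, where a ×1.3-scaled element is recovered to < 10⁻⁴ relative
error from noise-free data.

## Per-location fits

`run_by_location` restricts the ratio matrix to the taxa actually
present at each location (from microscopy/cultivation evidence) and fits
locations independently; excluded taxa are reported as exact zeros in
the merged abundance table. On synthetic data with truly disjoint taxon
subsets this is never worse than a pooled fit with the full matrix.

## Trophic markers and retention

Marker rules (ordered, first match wins, so each FA maps to at most one
group): fungi — 16:1ω5 (any geometry); bacteria — straight-chain 15:0,
all iso/anteiso FAs, hydroxy FAs, cyclopropyl FAs, 18:1ω8; autotrophs —
C16 and C18 PUFAs. The enumeration is deliberately exhaustive:
straight-chain odd FAs other than 15:0 are *not* counted as bacterial,
and C20/C22 PUFAs are not autotroph markers under this scheme. Group
proportions are the marker-FA weight sums renormalized over the three
groups; because it is ambiguous whether such panels should be read
relative to marker FA or to total FA, both modes are provided
(`relative=True/False`).

Consumer lipid fractions (neutral = reserve triacylglycerides,
acetone-mobile = glycolipids, free FA, phospholipid) are pooled by
FA-mass weighting. The retention ratio of an FA set (default EPA+DHA)
is the consumer-to-seston ratio of the set's share of total FA; values
above 1 indicate selective accumulation. Zero seston content is an
explicit error rather than an infinite ratio.

## Variable screening and PCA

Before ordination, FA variables are screened in three stages: (1) FAs
with fewer than 14 carbons are dropped — they can arise from de-novo
biosynthesis in the consumer and carry no dietary signal; (2) the worst
FA failing the Kaiser–Meyer–Olkin measure of sampling adequacy
(MSA ≤ 0.50) is dropped and the MSAs recomputed, iteratively; (3) FAs
with communality ≤ 0.50 under the Kaiser-rule solution (components with
eigenvalue > 1) are dropped. A communality removal can push a remaining
MSA back below threshold, so stages 2–3 alternate until both thresholds
hold on the retained set. Whether the original procedure removed
variables simultaneously or iteratively, and in which order the two
filters applied, is not standardized; the one-at-a-time worst-first
choice is the conservative reading and both thresholds are exposed as
arguments. KMO is computed from the correlation and anti-image
(partial) correlation matrices via the pseudo-inverse; no installed
package provides it.

PCA operates on SD-scaled (standardized) data, i.e. the correlation
matrix, by symmetric eigendecomposition. Loadings are component
correlations (eigenvector × √eigenvalue); signs are fixed by making the
largest-magnitude loading of each component positive; tiny negative
eigenvalues of rank-deficient data are clipped to zero, and explained
percentages always sum to 100.

Spearman correlation uses average ranks for ties and a two-sided
t-approximation p-value (scipy), cross-checked in the tests against an
explicit sort-based ranking.

## Synthetic data

The generator produces every input the pipeline consumes, from known
ground truth:

* **Seston samples** — true abundances are Dirichlet-distributed
  (symmetric α = 1 by default; preset regimes use a Dirichlet centred on
  the preset means with effective sample size 50). Each sample is the
  abundance mixture of the row-normalized signatures, perturbed by
  multiplicative lognormal noise with cv = 0.10 (unit mean; a Dirichlet
  resampling noise model is the alternative) and renormalized — a
  compositional perturbation. The 10% default reflects typical
  between-replicate scatter of FAME quantification.
* **Presets** — `heterotroph_dominated` (90% bacteria+fungi),
  `green_algae_dominated` (80% green algae) and `cyanobacteria_mixed`
  (50% cyanobacteria) encode the qualitative pond regimes the method is
  meant to distinguish.
* **Isolate libraries** — lognormal within-taxon variation (default
  cv = 0.2) applied to the mean *ratio* vector with the 16:0 reference
  held at 1, so that ratio averaging is an unbiased estimator of the
  taxon mean (noising numerator and denominator independently would
  inflate recovered ratios by a factor 1+cv², a Jensen bias of ratio
  estimators).
* **Consumers** — consumer FA shares proportional to seston shares times
  per-FA retention factors (resolvable by FA name, marker group, or
  structural tag), an optional de-novo SAFA admixture, a per-fraction
  PUFA boost (phospholipid ≥ neutral, reflecting membrane demand for
  PUFA), lognormal noise, renormalization. Note the compositional
  consequence: a retention factor ρ on a minor FA measures as a
  retention ratio ρ/(1 + (ρ−1)·share), slightly below ρ.

What the generator does *not* emulate: chromatographic co-elution and
peak-identification error, systematic between-run drift, covariance of
FA noise within biosynthetic pathways, protist intermediaries, and any
ecological dynamics. Passing closed-loop tests therefore demonstrates
correctness of the estimators under the stated statistical model, not
robustness to every artefact of real GC data.

## Problem sizes and numerical choices

Default test and acceptance runs use 20 samples × 9 taxa × 19 FAs —
the scale of a realistic pond campaign and comfortable for the
alternating optimizer (a full fit converges in a few hundred iterations,
seconds on one core). The NNLS sum constraint weight is 10⁴; descent
uses step_init = 0.05, ≤ 20 halvings, ≤ 10 doublings; convergence
tolerance 10⁻⁸ relative RMSE change. Ties in isolate identification are
broken lexicographically by taxon label; identical profiles score
exactly 1 under the 1/(1+Euclidean distance) similarity.

## Known limitations

* Abundances are relative; no absolute biomass conversion.
* Ratio-element recovery is only meaningful for identifiable (well-
  separated) taxa; see Identifiability above.
* The marker scheme is a fixed, auditable rule list; taxon-specific
  exceptions (e.g. 16:1ω7c in both diatoms and bacteria) are resolved by
  the unmixing engine, not by the marker sums, which are intentionally
  coarse.
* Multi-start spread is the only uncertainty measure; no formal
  confidence intervals on abundances.
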