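# Methods

This note documents the models, conventions and numerical choices behind
`daphnofit`, and what the synthetic-data generator does and does not
emulate.

## Conventions

Ages are integer days since birth (day 0 = birth). Treatments are
Ciprofloxacin concentrations in mg L⁻¹, with 0 denoting the control. OTU
tables are oriented samples × OTUs. Animals alive at the 21-day horizon are
right-censored; animals sacrificed for microbiome profiling are
right-censored at their sampling day. Missing taxonomy assignments carry an
explicit `unassigned` token; rank aggregation pools them into one
pseudo-taxon unless the caller drops them.

## Demography

**Life table.** l(x) is the literal fraction of the cohort alive at age x;
every animal (dying or censored) counts as alive through its last observed
day and not after. m(x) is total offspring released at age x divided by
mothers alive at age x, so l(x)·m(x) is the standard life-table product and
equals births-at-x over initial cohort size. With 16 of 25 animals removed
by scheduled sacrifice, late-age l(x) reflects that attrition — a property
of the design, mirrored deliberately.

**Euler-Lotka.** f(r) = Σ l(x)m(x)e^(−rx) − 1 is strictly decreasing, so
the root is unique. It is bracketed by geometric expansion from [−2, 2] d⁻¹
and refined by Brent's method to machine tolerance (|f| < 1e−10 enforced);
r may be negative when net reproduction is below 1. Bootstrap: individuals
are resampled with replacement (same n), the life table rebuilt and
re-solved per replicate; the CI is the percentile interval (2.5%, 97.5%).
Replicates with no reproduction are excluded and counted. BCa was not used;
the percentile interval is what disjoint-interval treatment comparisons
assume, and ties at interval endpoints count as overlap (conservative).
Percentile intervals undercover slightly at n = 25 (~92–94% observed in the
coverage tests) — within the binomial tolerance the tests allow.

**Survival.** Kaplan-Meier estimation and the k-group logrank test are
delegated to `lifelines`; the module owns the record validation and the
(time, n-at-risk, S(t)) reporting surface. Note one deliberate asymmetry:
the life table counts an animal dying on day d as alive through d (its
death-day clutch still counts), while Kaplan-Meier drops S(t) at d.

## Growth

The von Bertalanffy fit uses bounded nonlinear least squares with
initialization BL_max⁰ = 1.05·max(BL) and K⁰ from regressing
log(1 − BL/BL_max⁰) on −t, plus five jittered restarts. SEs come from the
Jacobian-based covariance at the optimum; CIs use t quantiles on n − 2 df;
Sy.x = √(SS/df). Constant-length input makes K unidentifiable and raises a
convergence error rather than returning a degenerate fit.

## Host statistics

GLMs are fitted by IRLS through `statsmodels` behind `host_stats.fit_glm`
(tolerance 1e−10, 100 iterations). Identity-link Poisson fits start from a
feasible point (intercept at the response mean) and the fitted means are
checked positive. Inference is Wald: z for Poisson, t for Gaussian. One-way
ANOVA uses the classical decomposition; Tukey(-Kramer) pairwise intervals
and adjusted p-values use `scipy.stats.studentized_range` (no hand-rolled
quadrature — the distribution is available natively). Factor-level
contrasts on a fitted GLM are Wald contrasts with Bonferroni adjustment by
default: conservative, and the exact single-step adjustment used by
R's multcomp is not required by any downstream decision.

## Alpha diversity

Shannon entropy is in nats. Chao1 uses the classic form S_obs + f₁²/(2f₂)
with the bias-corrected form S_obs + f₁(f₁−1)/(2(f₂+1)) when f₂ = 0. ACE
uses the rare/abundant split at 10 reads with γ² clipped at 0; when every
rare taxon is a singleton (C_ACE = 0) it falls back to Chao1 with a
warning. Fisher's alpha solves S = α·ln(1 + N/α) by bisection to 1e−9.
Sample coverage uses the Zhang-Huang alternating series
C = 1 − Σ_v (−1)^(v+1) f_v / C(n, v), clamped to [0, 1], whose first term
is the Good-Turing estimator 1 − f₁/n (also exposed separately); the series
is evaluated in log space so large binomial coefficients cannot overflow.

Rarefaction subsamples without replacement (multivariate hypergeometric),
drops samples below the target depth with a logged warning, and defaults to
the global minimum retained depth so indices are comparable across
treatments — the per-treatment reading of "equal depth at treatment level"
is available to callers but is not the default, because the index GLM pools
treatments. The index GLM is Gaussian with log link, concentration entering
numerically in mg L⁻¹ and time as sampling day; the time × concentration
interaction is fitted first and dropped when its Wald p > 0.05.

## Beta diversity

Distances are Bray-Curtis on relative abundances of family-aggregated
counts (transforms: none | relative | hellinger; default relative). PCoA is
classical scaling: Gower centering of −½d², eigendecomposition, axes
ordered by eigenvalue. Negative eigenvalues — expected for a semi-metric —
are reported, and their axes retained (scaled by √|λ|) for the distance
corrections. PERMANOVA uses the distance-based SS decomposition
(SS_T = Σ_{i<j} d²_ij / N; within-group analogues per group) with
pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)) and a label-permutation p-value with
the +1 correction (never exactly 0). Pairwise contrasts run PERMANOVA on
each pair's submatrix with BH adjustment. Betadisper computes each sample's
distance to its group centroid in the PCoA embedding (squared contributions
on negative-eigenvalue axes subtract, clipped at 0), takes the one-way
ANOVA F on those distances, and permutes group labels of the fixed
distances for the p-value — the residual-permutation scheme, chosen because
re-embedding per permutation changes nothing for centroid distances and the
reference R implementation permutes residuals likewise. Group centroids
(not spatial medians) match the "average distance to centroid" reporting
convention.

## Core microbiome and differential abundance

The core filter retains a taxon whose relative abundance reaches the
detection threshold (default 0.01%) in at least the prevalence fraction
(default 20%) of samples. Shared/unique sets apply the low-count filter
(≥ 4 reads in ≥ 20% of samples) **per treatment group** — the per-group
reading is what makes a Venn decomposition across groups meaningful — and
report all region cardinalities, the all-group core and the shared
fraction.

The differential-abundance stage is a from-scratch implementation of the
classic exact-test path for overdispersed count data:

* **TMM** factors against the sample whose upper-quartile count (scaled by
  library size) is closest to the mean; M-values trimmed 30% per tail,
  A-values 5% per tail, weighted by inverse asymptotic (binomial) variance;
  factors rescaled to multiply to 1.
* **Common dispersion** φ shared by all taxa, maximizing a Cox-Reid
  adjusted profile likelihood with per-(taxon, class) mean rates profiled
  out as total count over total effective library size; the adjustment
  (−½ log Fisher information per fitted mean) removes most of the downward
  bias of plain profile ML. A boundary check returns φ = 0 for
  Poisson-like data.
* **Exact test**: per taxon, class sums are modelled NB(mean, φ/n_c) on
  effective library sizes; conditioning on the total, the two-sided p is
  the mass of splits as or less likely than the observed one. At φ = 0
  this is exactly the conditional binomial test. log2 fold changes use
  normalized class rates with a 0.125 prior count.
* **BH FDR** step-up with cumulative-minimum enforcement.

Tagwise empirical-Bayes shrinkage and quasi-likelihood refinements are
deliberately not implemented; with a planted 8-fold genus the common-
dispersion exact test has essentially full power at the design's sample
sizes. Zeta scores standardize a trait within clutch (n−1 SD); class 1
means strictly above the clutch mean (a tie at the mean is "low"), and a
clutch with zero variance is an error naming the clutch. Exposure-mode
contrasts dichotomize control vs each concentration (FDR 5%);
phenotype-mode contrasts high vs low classes (FDR 1%).

## Synthetic data generator

The generator emulates the experiment's statistical structure, not its
biology:

* **Survival**: constant daily Bernoulli hazard per treatment (defaults
  0.008 control, 0.004–0.005 exposed → 84–92% 21-day survival, the range a
  healthy test should show).
* **Growth**: von Bertalanffy curves with Gaussian measurement noise;
  per-treatment defaults (BL_max 3.25–3.38 mm, K 0.29–0.31 d⁻¹,
  σ 0.10–0.13 mm) are the published parameter panel for this exposure
  design. Lengths are recorded at two juvenile scan days (3, 6) and at
  sacrifice/termination, so the rising limb of the curve is anchored.
* **Fecundity**: Poisson brood sizes with a per-treatment mean and a
  −0.4 neonates/clutch time trend (last brood smallest). The exposed-group
  means (8.6–9.4 vs 6.0 control) were chosen so the schedule-implied
  Euler-Lotka r gains match the reported hormetic fitness effect
  (+17/19/15% at 0.01/0.1/1 mg L⁻¹, control r ≈ 0.25 d⁻¹). Under the
  idealized 3-day clutch schedule those r gains require brood gains
  somewhat above the reported ~36–42%; the r pattern was prioritized as
  the headline statistic.
* **Clutch schedule**: maturation at day 9, clutches every 3 days, up to 4;
  4 animals per treatment sacrificed per clutch event (≤ 64 microbiome
  samples from 100 animals).
* **Microbiome**: expected composition is the softmax of log-normal
  baselines (σ = 1.5) plus per-OTU slopes on log10(1 + c/c_ref), c_ref =
  0.01 mg L⁻¹ — ~45% of OTUs strongly depleted (slope −5), ~10% enriched
  (slope +2), jitter 0.3 — plus taxon-specific per-clutch drift (σ = 0.15).
  Counts are Dirichlet-multinomial (θ = 0.02, the overdispersion scale
  typical of 16S data; θ = 0 reduces to multinomial) at log-normal depth
  (median 5000, σ_log = 0.3). 300 OTUs nested into genera/families/orders;
  5% of OTUs lack a genus assignment.
* **Coupling**: optional (OTU, trait, effect) triples shift a sampled
  animal's body length (mm) or brood sizes (rounded, floored at 0) by
  effect × standardized log10 relative abundance, planting a recoverable
  microbiome-fitness association.

Not emulated: taxonomic misassignment, chimeras, depth-dependent
contamination, true temporal succession, phylogenetic structure, or any
direct pharmacological effect mechanism — concentration acts on composition
and (through the configured means) on host traits, nothing else. Passing
tests therefore demonstrate that the estimators and tests recover effects
of known structure at realistic design scale; they say nothing about
read-processing upstream of the OTU table.

Problem sizes in the test suite (200 cohorts × 999 bootstrap resamples,
200 permutation-null simulations at 199 permutations, 50 power replicates,
one full pipeline run at 999 resamples/permutations) were chosen to keep
Monte-Carlo error within the stated binomial tolerances.

## Known limitations

* The empty-reproduction bootstrap replicates are excluded rather than
  imputed; with very high hazards the CI can be computed from few
  replicates (the count is reported).
* The Poisson/identity GLM can be infeasible for designs implying negative
  means; the fit raises rather than silently switching link.
* PERMANOVA permutes labels freely (no strata); the sampling design's
  clutch structure is not used as a blocking factor.
* The exact test conditions on class sums, which is exact only when
  effective library sizes are equal within a class; TMM plus the pooled
  rate make this a good approximation at the simulated depth spread, and
  the Poisson-limit and null-simulation tests bound the error in practice.
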