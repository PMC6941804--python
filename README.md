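# daphnofit

Life-table demography and gut-microbiome fitness analysis for chronic
antibiotic-exposure experiments on *Daphnia magna*.

Ecotoxicologists who run OECD-211-style reproduction tests while profiling
the animals' gut microbiota face two coupled analyses: a host side
(survival, somatic growth, fecundity, population growth) and a microbiome
side (diversity, community structure, core taxa, phenotype-linked
differential abundance). `daphnofit` implements both as a tested pipeline,
together with a synthetic-data generator that reproduces the statistical
structure of such an experiment — four Ciprofloxacin treatments (0, 0.01,
0.1, 1 mg L⁻¹), 25 animals each, 21 days, up to four clutches, four animals
per treatment sacrificed for 16S profiling at each clutch event.

## Core models and statistics

**Host fitness.** Survival is estimated by the Kaplan-Meier product-limit
estimator S(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) and compared across treatments by the
logrank test. Somatic growth is fitted by the von Bertalanffy model

    BL(t) = BL_max · (1 − e^(−K·t))

via nonlinear least squares, reported with SEs, 95% CIs, R², df, residual SS
and Sy.x. Fecundity is modelled by a Poisson GLM with identity link in
concentration and clutch number. The headline statistic is the intrinsic
rate of increase *r*, the unique root of the discrete Euler-Lotka equation

    Σ_{x=α}^{β} l(x) · m(x) · e^(−r·x) = 1

where l(x) is cohort survivorship and m(x) the per-capita birth rate at age
x (days). 95% limits come from a percentile bootstrap over individuals
(999 resamples); treatments differ when their intervals are disjoint.

**Microbiome.** Per-sample alpha diversity (Shannon, Chao1, ACE, Fisher's
alpha, Zhang-Huang sample coverage) on rarefied counts, with a Gaussian
log-link GLM linking each index to concentration and time. Community
structure at family level via Bray-Curtis dissimilarity, principal
coordinates, one-way PERMANOVA with pairwise FDR-corrected contrasts, and
multivariate dispersion homogeneity (betadisper) — all implemented from
first principles on the distance matrix. Core-microbiome filtering
(prevalence 20%, detection 0.01%), shared/unique OTU sets under a low-count
filter (≥ 4 reads in ≥ 20% of a group's samples), and differential
abundance at genus level by TMM normalization, a common negative-binomial
dispersion and a conditional exact test with Benjamini-Hochberg FDR.
High/low host-fitness classes come from within-clutch zeta scores of body
length and fecundity.

## Worked example

```sh
$ daphnofit simulate --seed 1 --out demo
wrote 100 records and 64 samples to demo

$ daphnofit demography --life-history demo/life_history.csv --n-boot 999 --seed 7
treatment   r        ci_low   ci_high  n_boot
0.0         0.25478  0.23812  0.26859  999
0.01        0.28177  0.26825  0.29394  999
0.1         0.28036  0.26044  0.29520  999
1.0         0.27116  0.25384  0.28459  999
```

The control cohort grows at r ≈ 0.255 d⁻¹; all three exposed cohorts grow
faster (here ~6–11% — the exposed animals' larger broods outweigh the
antibiotic's effect on their microbiota), and an exposed treatment counts as
significantly different when its 95% bootstrap interval does not overlap the
control's. `daphnofit report --seed 1 --out results/` runs every stage and
writes a JSON report plus TSV tables (growth panel, alpha indices and GLM,
distance matrix, PCoA coordinates, PERMANOVA and differential-abundance
tables).

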