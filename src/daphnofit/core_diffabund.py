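"""Core-microbiome filters and phenotype-linked differential abundance.

The differential-abundance stage re-implements the classic exact-test
path for sequencing count data: TMM (trimmed mean of M-values)
normalization, a single negative-binomial dispersion shared by all
taxa, a conditional exact test on class sums, and Benjamini-Hochberg
FDR control. Tagwise empirical-Bayes shrinkage and quasi-likelihood
refinements are deliberately out of scope.

Phenotype classes come from zeta scores: within-clutch standardization
of a host trait to zero mean and unit variance, class 1 for animals
strictly above their clutch mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

from .datatypes import OtuTable, ValidationError


# ---------------------------------------------------------------------------
# Filters

def core_filter(table: OtuTable, prevalence: float = 0.20,
                detection: float = 1e-4) -> pd.Index:
    """Taxa whose relative abundance reaches ``detection`` in at least a
    ``prevalence`` fraction of samples (the core-microbiome filter)."""
    if not 0 <= prevalence <= 1:
        raise ValidationError("prevalence must be in [0, 1]")
    rel = table.relative_abundance()
    frac_detected = (rel >= detection).mean(axis=0)
    return table.otu_ids[frac_detected.to_numpy() >= prevalence]


@dataclass
class SharedUniqueResult:
    """Per-group qualifying OTU sets and their Venn decomposition."""

    group_sets: dict
    regions: dict          # frozenset(groups) -> OTU count in that exact region
    core: set              # OTUs present in every group
    union: set
    shared_fraction: float

    def region_count(self, *groups) -> int:
        return self.regions.get(frozenset(groups), 0)


def shared_unique_sets(table: OtuTable, group_labels,
                       min_count: int = 4,
                       prevalence: float = 0.20) -> SharedUniqueResult:
    """Shared/unique OTU sets across groups under the low-count filter.

    Within each group an OTU qualifies iff its count is >= ``min_count``
    in at least a ``prevalence`` fraction of that group's samples. The
    Venn regions partition the union by the exact group subset an OTU
    belongs to; the core is the all-group intersection.
    """
    labels = np.asarray(group_labels)
    if len(labels) != table.counts.shape[0]:
        raise ValidationError("group_labels must match samples")
    group_sets = {}
    for g in pd.unique(labels):
        sub = table.counts.loc[labels == g]
        frac = (sub >= min_count).mean(axis=0)
        group_sets[g] = set(table.otu_ids[frac.to_numpy() >= prevalence])
    union = set().union(*group_sets.values()) if group_sets else set()
    regions: dict = {}
    for otu in union:
        member = frozenset(g for g, s in group_sets.items() if otu in s)
        regions[member] = regions.get(member, 0) + 1
    core = set.intersection(*group_sets.values()) if group_sets else set()
    shared_fraction = len(core) / len(union) if union else 0.0
    return SharedUniqueResult(group_sets=group_sets, regions=regions,
                              core=core, union=union,
                              shared_fraction=shared_fraction)


# ---------------------------------------------------------------------------
# Phenotype classes

def zeta_classify(traits: pd.DataFrame, clutch_labels) -> pd.DataFrame:
    """Within-clutch zeta scores and high/low classes per trait.

    z = (x - clutch mean) / clutch SD (n-1 denominator); class 1 iff
    z > 0 (strictly above the clutch mean), else 0. A clutch with fewer
    than two individuals or zero variance raises an error naming it.
    """
    clutch = pd.Series(np.asarray(clutch_labels), index=traits.index)
    out = pd.DataFrame(index=traits.index)
    for col in traits.columns:
        z = pd.Series(np.nan, index=traits.index, dtype=float)
        for c, idx in traits.groupby(clutch).groups.items():
            vals = traits.loc[idx, col].astype(float)
            if len(vals) < 2:
                raise ValidationError(f"clutch {c!r} has fewer than 2 individuals")
            sd = vals.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise ValidationError(f"clutch {c!r} has zero variance in {col!r}")
            z.loc[idx] = (vals - vals.mean()) / sd
        out[f"zeta_{col}"] = z
        out[f"class_{col}"] = (z > 0).astype(int)
    return out


# ---------------------------------------------------------------------------
# TMM normalization

def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim=0.3, sum_trim=0.05):
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 1.0
    o, r = obs[both] / n_obs, ref[both] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (binomial) variance of M
    w = (n_obs - obs[both]) / (n_obs * obs[both]) \
        + (n_ref - ref[both]) / (n_ref * ref[both])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
           (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        keep = np.ones(n, dtype=bool)
    wk = 1.0 / w[keep]
    f = np.sum(wk * m[keep]) / np.sum(wk)
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (samples x taxa).

    The reference is the sample whose upper-quartile count (scaled by
    library size) is closest to the mean upper quartile. M-values are
    trimmed 30% from each tail and A-values 5%; the trimmed mean is
    weighted by inverse asymptotic variance and factors are rescaled so
    their product is 1.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("TMM needs at least two samples")
    lib = x.sum(axis=1)
    if np.any(lib == 0):
        raise ValidationError("TMM: sample with zero total count")
    uq = np.array([np.quantile(row[row > 0], 0.75) / n if (row > 0).any() else 0
                   for row, n in zip(x, lib)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[ref_idx]
    factors = np.array([
        1.0 if j == ref_idx else _tmm_pair(x[j], ref, lib[j], lib[ref_idx])
        for j in range(x.shape[0])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.index, name="tmm_factor")


def effective_lib_sizes(counts: pd.DataFrame,
                        factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(counts)
    return counts.sum(axis=1) * factors


# ---------------------------------------------------------------------------
# Common dispersion

def _nb_loglik(y, mu, phi):
    if phi < 1e-10:
        return float(np.sum(poisson.logpmf(y, mu)))
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300)))


def estimate_common_dispersion(counts: pd.DataFrame, classes,
                               lib_sizes: pd.Series | None = None) -> float:
    """One NB dispersion shared by all taxa (profile likelihood).

    For each candidate dispersion the per-(taxon, class) mean rates are
    profiled out as total-count over total-effective-library-size, and a
    Cox-Reid degree-of-freedom adjustment (-0.5 log of the mean's Fisher
    information per fitted mean) reduces the downward bias of plain
    profile likelihood. Returns phi >= 0.
    """
    classes = np.asarray(classes)
    if len(classes) != counts.shape[0]:
        raise ValidationError("classes must match samples")
    if lib_sizes is None:
        lib_sizes = effective_lib_sizes(counts)
    L = lib_sizes.to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float)
    class_levels = np.unique(classes)

    def neg_profile(log_phi):
        phi = np.exp(log_phi)
        total = 0.0
        for c in class_levels:
            idx = classes == c
            yc, lc = y[idx], L[idx]
            lam = yc.sum(axis=0) / lc.sum()          # per-taxon rate
            mu = np.outer(lc, lam)
            ok = lam > 0
            if not ok.any():
                continue
            total += _nb_loglik(yc[:, ok], mu[:, ok], phi)
            # Cox-Reid: 0.5 * log Fisher info of each fitted mean rate
            info = (lc[:, None] ** 2 / (mu[:, ok] + phi * mu[:, ok] ** 2)).sum(axis=0)
            total -= 0.5 * np.sum(np.log(info))
        return -total

    res = minimize_scalar(neg_profile, bounds=(np.log(1e-6), np.log(10.0)),
                          method="bounded",
                          options={"xatol": 1e-6})
    phi = float(np.exp(res.x))
    # boundary check: Poisson-like data push the optimum to the lower bound
    if neg_profile(np.log(1e-6)) <= res.fun + 1e-9:
        return 0.0
    return phi


# ---------------------------------------------------------------------------
# NB exact test

def _class_sum_pmf(support, mu, n, phi):
    """pmf of a class sum modelled as NB(mean mu, dispersion phi/n)."""
    if phi < 1e-10:
        return poisson.pmf(support, mu)
    r = n / phi
    return nbinom.pmf(support, r, r / (r + mu))


def nb_exact_test(counts: pd.DataFrame, classes, phi: float,
                  factors: pd.Series | None = None,
                  prior_count: float = 0.125) -> pd.DataFrame:
    """Two-sided conditional exact test per taxon between two classes.

    Class sums are modelled as negative binomial with the common
    dispersion ``phi`` on effective (TMM-normalized) library sizes;
    conditioning on the taxon's total, the p-value is the probability of
    all splits as or less likely than the observed one. log2 fold
    changes use normalized class mean rates with a small-count prior.
    """
    classes = np.asarray(classes)
    levels = np.unique(classes)
    if len(levels) != 2:
        raise ValidationError("nb_exact_test requires exactly two classes")
    n0 = int(np.sum(classes == levels[0]))
    n1 = int(np.sum(classes == levels[1]))
    if n0 == 0 or n1 == 0:
        raise ValidationError("a class has zero samples")
    lib = effective_lib_sizes(counts, factors)
    L = lib.to_numpy(dtype=float)
    L0 = float(L[classes == levels[0]].sum())
    L1 = float(L[classes == levels[1]].sum())
    y = counts.to_numpy(dtype=float)
    rows = []
    for j, taxon in enumerate(counts.columns):
        s0 = float(y[classes == levels[0], j].sum())
        s1 = float(y[classes == levels[1], j].sum())
        t = int(round(s0 + s1))
        lam0 = (s0 + prior_count) / L0
        lam1 = (s1 + prior_count) / L1
        log2fc = float(np.log2(lam1 / lam0))
        if t == 0:
            rows.append({"taxon": taxon, "log2FC": 0.0, "p": 1.0})
            continue
        rate = (s0 + s1) / (L0 + L1)
        support = np.arange(t + 1)
        p0 = _class_sum_pmf(support, rate * L0, n0, phi)
        p1 = _class_sum_pmf(support[::-1], rate * L1, n1, phi)
        joint = p0 * p1
        total = joint.sum()
        if total <= 0:
            rows.append({"taxon": taxon, "log2FC": log2fc, "p": 1.0})
            continue
        p_obs = joint[int(round(s0))]
        p_val = float(joint[joint <= p_obs * (1 + 1e-10)].sum() / total)
        rows.append({"taxon": taxon, "log2FC": log2fc, "p": min(p_val, 1.0)})
    return pd.DataFrame(rows).set_index("taxon")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


# ---------------------------------------------------------------------------
# Orchestrated differential abundance

@dataclass
class DiffAbundResult:
    """Per-taxon fold change and FDR-adjusted significance."""

    table: pd.DataFrame          # log2FC, p, fdr, significant
    phi: float
    fdr_threshold: float
    contrast: str = ""

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def _diffabund_two_class(counts: pd.DataFrame, classes,
                         fdr_threshold: float, contrast: str) -> DiffAbundResult:
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    if counts.shape[1] == 0:
        raise ValidationError("no taxa left after aggregation/filtering")
    factors = tmm_factors(counts)
    phi = estimate_common_dispersion(counts, classes,
                                     effective_lib_sizes(counts, factors))
    res = nb_exact_test(counts, classes, phi, factors)
    res["fdr"] = bh_fdr(res["p"].to_numpy())
    res["significant"] = res["fdr"] < fdr_threshold
    return DiffAbundResult(table=res, phi=phi, fdr_threshold=fdr_threshold,
                           contrast=contrast)


def differential_abundance(table: OtuTable, grouping: str = "phenotype",
                           classes: pd.Series | None = None,
                           fdr_threshold: float | None = None,
                           rank: str | None = "genus",
                           drop_unassigned: bool = False):
    """Run the TMM + common-dispersion + exact-test pipeline.

    ``grouping='exposure'`` contrasts the control against each nonzero
    concentration in the sample metadata (default FDR threshold 0.05)
    and returns a dict keyed by concentration. ``grouping='phenotype'``
    takes a 0/1 ``classes`` Series aligned to samples (default FDR
    threshold 0.01) and returns a single :class:`DiffAbundResult`.
    Counts are aggregated at ``rank`` (genus by default) first.
    """
    if rank is not None and rank in table.taxonomy.columns:
        work = table.aggregate(rank, drop_unassigned=drop_unassigned)
    elif rank is not None:
        raise ValidationError(f"taxonomy has no {rank!r} column")
    else:
        work = table
    if grouping == "exposure":
        threshold = 0.05 if fdr_threshold is None else fdr_threshold
        conc = work.sample_meta["treatment"].astype(float)
        results = {}
        for c in sorted(conc.unique()):
            if c == 0:
                continue
            keep = conc.isin([0.0, c])
            sub = work.counts.loc[keep.to_numpy()]
            cls = (conc[keep] > 0).astype(int).to_numpy()
            results[c] = _diffabund_two_class(sub, cls, threshold,
                                              contrast=f"control_vs_{c}")
        if not results:
            raise ValidationError("no nonzero exposure level in metadata")
        return results
    if grouping == "phenotype":
        threshold = 0.01 if fdr_threshold is None else fdr_threshold
        if classes is None:
            raise ValidationError("phenotype grouping requires classes")
        cls = pd.Series(classes).reindex(work.sample_ids)
        if cls.isna().any():
            missing = cls.index[cls.isna()][0]
            raise ValidationError(f"no class for sample {missing!r}")
        return _diffabund_two_class(work.counts, cls.to_numpy(dtype=int),
                                    threshold, contrast="phenotype_high_vs_low")
    raise ValidationError(f"unknown grouping {grouping!r}")
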