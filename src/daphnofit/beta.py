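"""Beta-diversity: Bray-Curtis, PCoA, PERMANOVA and betadisper.

All machinery is implemented from first principles on the distance
matrix: Gower double-centering for principal coordinates (negative
eigenvalues are reported, not dropped), the distance-based sum-of-
squares decomposition for PERMANOVA with label-permutation p-values,
and multivariate homogeneity of dispersions via distances to group
centroids in the PCoA embedding with the standard imaginary-axis
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core_diffabund import bh_fdr
from .datatypes import DistanceMatrix, OtuTable, ValidationError

_TRANSFORMS = ("none", "relative", "hellinger")


def bray_curtis(table: OtuTable, rank: str | None = None,
                transform: str = "relative") -> DistanceMatrix:
    """Bray-Curtis dissimilarity d_ij = sum|x_i - x_j| / sum(x_i + x_j).

    With ``rank`` given, counts are first aggregated at that taxonomy
    rank (the community-structure tests run at family level). The
    default transform converts counts to relative abundances so that
    depth differences do not masquerade as composition differences.
    """
    if transform not in _TRANSFORMS:
        raise ValidationError(f"unknown transform {transform!r}")
    if rank is not None:
        table = table.aggregate(rank)
    totals = table.depths
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValidationError(f"sample {bad!r} has zero total count")
    x = table.counts.to_numpy(dtype=float)
    if transform == "relative":
        x = x / x.sum(axis=1, keepdims=True)
    elif transform == "hellinger":
        x = np.sqrt(x / x.sum(axis=1, keepdims=True))
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return DistanceMatrix(d, list(table.sample_ids))


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: pd.DataFrame      # samples x positive axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion_explained: np.ndarray  # over the positive eigenvalues
    neg_coordinates: np.ndarray    # axes with negative eigenvalues


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical scaling (Gower centering of -0.5 d^2).

    Negative eigenvalues — possible for semi-metric dissimilarities like
    Bray-Curtis — are retained in ``eigenvalues`` and their axes stored
    separately (scaled by sqrt(|lambda|)) for the imaginary-axis
    distance correction.
    """
    n = d.shape[0]
    a = -0.5 * d.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    neg = eigval < -tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    neg_coords = eigvec[:, neg] * np.sqrt(-eigval[neg])
    pos_sum = eigval[pos].sum()
    prop = eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    frame = pd.DataFrame(coords, index=d.ids,
                         columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    return PcoaResult(coordinates=frame, eigenvalues=eigval,
                      proportion_explained=prop, neg_coordinates=neg_coords)


def _ss_decomposition(d2: np.ndarray, labels: np.ndarray):
    """Total and within-group sums of squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n: int, a: int):
    ss_total, ss_within = _ss_decomposition(d2, labels)
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_total, ss_within, ss_among


def permanova(d: DistanceMatrix, labels, n_perm: int = 999,
              seed: int = 0) -> pd.Series:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_A/(a-1)) / (SS_W/(N-a)) with SS computed from
    squared inter-point distances; the p-value counts permuted labelings
    with pseudo-F >= observed, with the +1 correction.
    """
    labels = np.asarray(labels)
    n = d.shape[0]
    if len(labels) != n:
        raise ValidationError("labels must match distance matrix size")
    groups, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = groups[counts < 2][0]
        raise ValidationError(f"group {bad!r} has fewer than 2 samples")
    a = len(groups)
    d2 = d.data ** 2
    f_obs, ss_total, ss_within, ss_among = _pseudo_f(d2, labels, n, a)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        f_perm, *_ = _pseudo_f(d2, perm, n, a)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return pd.Series({"df": a - 1, "df_resid": n - a, "SS": ss_among,
                      "SS_resid": ss_within, "SS_total": ss_total,
                      "pseudo_F": f_obs, "R2": ss_among / ss_total, "p": p})


def pairwise_permanova(d: DistanceMatrix, labels, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """PERMANOVA on every label pair's submatrix, BH-adjusted across pairs."""
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    rows = []
    rng = np.random.default_rng(seed)
    for g1, g2 in combinations(groups, 2):
        keep = np.isin(labels, [g1, g2])
        sub = d.submatrix(keep)
        res = permanova(sub, labels[keep], n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)))
        rows.append({"group_a": g1, "group_b": g2,
                     "pseudo_F": res["pseudo_F"], "R2": res["R2"],
                     "p": res["p"]})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p"].to_numpy())
    return out


def _centroid_distances(d: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Squared contributions on negative-eigenvalue axes subtract (the
    standard correction for semi-metric dissimilarities); negative
    squared distances are clipped at zero.
    """
    emb = pcoa(d)
    real = emb.coordinates.to_numpy()
    imag = emb.neg_coordinates
    z2 = np.zeros(d.shape[0])
    for g in np.unique(labels):
        idx = labels == g
        c_real = real[idx].mean(axis=0)
        z2[idx] = ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.size:
            c_imag = imag[idx].mean(axis=0)
            z2[idx] -= ((imag[idx] - c_imag) ** 2).sum(axis=1)
    return np.sqrt(np.clip(z2, 0.0, None))


def _anova_f(z: np.ndarray, labels: np.ndarray) -> float:
    grand = z.mean()
    ss_b = ss_w = 0.0
    k = 0
    for g in np.unique(labels):
        zi = z[labels == g]
        ss_b += len(zi) * (zi.mean() - grand) ** 2
        ss_w += ((zi - zi.mean()) ** 2).sum()
        k += 1
    n = len(z)
    if ss_w <= 1e-14 * max(1.0, float(np.max(z)) ** 2):
        raise ValidationError("all distances to centroid are equal: "
                              "dispersion F undefined")
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def betadisper(d: DistanceMatrix, labels, n_perm: int = 999,
               seed: int = 0) -> dict:
    """Multivariate homogeneity of group dispersions.

    Computes each sample's distance to its group centroid, the one-way
    ANOVA F on those distances, and permutation p-values (overall and
    pairwise) obtained by permuting group labels of the distances.
    """
    labels = np.asarray(labels)
    if len(labels) != d.shape[0]:
        raise ValidationError("labels must match distance matrix size")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or np.any(counts < 2):
        raise ValidationError("betadisper needs >= 2 groups of >= 2 samples")
    z = _centroid_distances(d, labels)
    f_obs = _anova_f(z, labels)
    rng = np.random.default_rng(seed)
    perm = labels.copy()
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        try:
            if _anova_f(z, perm) >= f_obs - 1e-12:
                exceed += 1
        except ValidationError:  # pragma: no cover - degenerate shuffle
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    group_means = pd.Series({g: float(z[labels == g].mean()) for g in groups},
                            name="mean_distance_to_centroid")
    pair_rows = []
    for g1, g2 in combinations(groups, 2):
        keep = np.isin(labels, [g1, g2])
        z_sub, lab_sub = z[keep], labels[keep]
        f_pair = _anova_f(z_sub, lab_sub)
        sub_perm = lab_sub.copy()
        exc = 0
        for _ in range(n_perm):
            rng.shuffle(sub_perm)
            if _anova_f(z_sub, sub_perm) >= f_pair - 1e-12:
                exc += 1
        pair_rows.append({"group_a": g1, "group_b": g2, "F": f_pair,
                          "p": (exc + 1) / (n_perm + 1)})
    return {"distances": pd.Series(z, index=d.ids, name="dist_to_centroid"),
            "group_means": group_means, "F": f_obs, "p": p,
            "pairwise": pd.DataFrame(pair_rows)}
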