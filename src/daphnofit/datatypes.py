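"""Domain types shared by every stage of the pipeline.

Conventions used throughout:

* ages are integer days since birth, day 0 = birth;
* treatments are Ciprofloxacin concentrations in mg/L, 0 denoting the
  unexposed control;
* OTU tables are oriented samples x OTUs;
* an animal alive at the study horizon (default 21 d) is right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_HORIZON = 21

#: Token used for missing taxonomy assignments at any rank.
UNASSIGNED = "unassigned"

#: Canonical taxonomy ranks, coarsest first.
TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """Raised when input data violate a documented invariant."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge.

    Carries the best iterate found (if any) in ``best``.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class LifeHistoryRecord:
    """One animal's survival, clutch and length observations.

    The unit of bootstrap resampling for the population growth rate.

    Parameters
    ----------
    individual_id : str
        Opaque identifier, unique within a cohort.
    treatment : float
        Exposure concentration in mg/L (0 = control).
    last_day : int
        Day of death or censoring (day 0 = birth).
    event : bool
        True if death was observed on ``last_day``, False if the animal
        was censored (alive when sampled or at study termination).
    clutches : tuple of (day, brood_size)
        Neonate releases, in strictly increasing day order.
    lengths : tuple of (day, body_length_mm)
        Body length measurements.
    """

    individual_id: str
    treatment: float
    last_day: int
    event: bool
    clutches: tuple[tuple[int, int], ...] = ()
    lengths: tuple[tuple[int, float], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "clutches", tuple((int(d), int(b)) for d, b in self.clutches))
        object.__setattr__(self, "lengths", tuple((int(d), float(m)) for d, m in self.lengths))
        if self.treatment < 0:
            raise ValidationError(
                f"{self.individual_id}: treatment concentration must be >= 0"
            )
        if self.last_day < 0:
            raise ValidationError(f"{self.individual_id}: last_day must be >= 0")
        days = [d for d, _ in self.clutches]
        if any(b < 0 for _, b in self.clutches):
            raise ValidationError(f"{self.individual_id}: brood size must be >= 0")
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValidationError(
                f"{self.individual_id}: clutch days must be strictly increasing"
            )
        for d in days:
            if d > self.last_day:
                raise ValidationError(
                    f"{self.individual_id}: clutch on day {d} after last_day {self.last_day}"
                )
        for d, mm in self.lengths:
            if d > self.last_day:
                raise ValidationError(
                    f"{self.individual_id}: length observation on day {d} "
                    f"after last_day {self.last_day}"
                )
            if mm <= 0:
                raise ValidationError(f"{self.individual_id}: body length must be > 0")


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed survivorship l(x) and per-capita birth rate m(x).

    ``lx[i]`` is the fraction of the cohort alive at age ``ages[i]``;
    ``mx[i]`` is offspring released at that age per mother alive at that
    age. Input to the Euler-Lotka solver.
    """

    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        lx = np.asarray(self.lx, dtype=float)
        mx = np.asarray(self.mx, dtype=float)
        if not (ages.shape == lx.shape == mx.shape):
            raise ValidationError("ages, lx and mx must have identical shape")
        if lx.size and (lx[0] > 1 + 1e-12 or np.any(lx < -1e-12) or np.any(np.diff(lx) > 1e-12)):
            raise ValidationError("lx must be non-increasing and within [0, 1]")
        if np.any(mx < 0):
            raise ValidationError("mx must be >= 0")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lx", lx)
        object.__setattr__(self, "mx", mx)

    @property
    def reproductive_span(self) -> np.ndarray:
        """Ages with positive reproduction (alpha..beta of the model)."""
        return self.ages[self.mx > 0]


@dataclass(frozen=True)
class PopGrowthResult:
    """Intrinsic rate of increase r (1/day) with bootstrap 95% limits."""

    r: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_degenerate: int = 0  # resamples with no reproduction, excluded

    def __post_init__(self):
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if self.ci_low > self.ci_high + 1e-12:
                raise ValidationError("ci_low must be <= ci_high")


@dataclass(frozen=True)
class GrowthFit:
    """Von Bertalanffy fit BL(t) = BL_max * (1 - exp(-K t)) with inference."""

    bl_max: float
    k: float
    se_bl_max: float
    se_k: float
    ci_bl_max: tuple[float, float]
    ci_k: tuple[float, float]
    r2: float
    df: int
    ss: float
    sy_x: float
    n: int = 0
    converged: bool = True

    def __post_init__(self):
        if self.bl_max <= 0 or self.k <= 0:
            raise ValidationError("bl_max and k must be > 0")


class OtuTable:
    """Samples x OTUs count matrix plus taxonomy and sample metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer matrix; rows are samples, columns are OTUs.
    taxonomy : DataFrame
        Indexed by OTU id, columns a subset of
        ``('phylum', 'class', 'order', 'family', 'genus')``. Missing
        assignments use the token ``'unassigned'``.
    sample_meta : DataFrame
        Indexed by sample id; must cover every sample in ``counts``.
        Expected columns: ``treatment`` (mg/L), ``clutch`` (1-4),
        ``day`` (sampling day); extra columns pass through.
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: pd.DataFrame,
                 sample_meta: pd.DataFrame):
        counts = counts.copy()
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValidationError("sample and OTU labels must be unique")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(values < 0):
            raise ValidationError("counts must be >= 0")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integral")
        counts = counts.astype(np.int64)
        missing = counts.index.difference(sample_meta.index)
        if len(missing):
            raise ValidationError(
                f"samples missing from metadata: {', '.join(map(str, missing))}"
            )
        self.counts = counts
        self.taxonomy = taxonomy.reindex(counts.columns).fillna(UNASSIGNED)
        self.sample_meta = sample_meta.loc[counts.index].copy()

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    @property
    def zero_otus(self) -> pd.Index:
        """OTUs with zero total count (retained but flagged)."""
        return self.counts.columns[self.counts.sum(axis=0) == 0]

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return self.counts.div(totals, axis=0)

    def aggregate(self, rank: str, drop_unassigned: bool = False) -> "OtuTable":
        """Sum counts within each taxon at ``rank``.

        OTUs without an assignment at that rank pool into one
        ``'unassigned'`` pseudo-taxon unless ``drop_unassigned``.
        """
        if rank not in self.taxonomy.columns:
            raise ValidationError(f"taxonomy has no {rank!r} column")
        labels = self.taxonomy[rank].astype(str)
        agg = self.counts.T.groupby(labels).sum().T
        if drop_unassigned and UNASSIGNED in agg.columns:
            agg = agg.drop(columns=[UNASSIGNED])
        tax = pd.DataFrame({rank: agg.columns}, index=agg.columns)
        return OtuTable(agg, tax, self.sample_meta)

    def subset_samples(self, sample_ids: Sequence) -> "OtuTable":
        ids = pd.Index(sample_ids)
        return OtuTable(self.counts.loc[ids], self.taxonomy,
                        self.sample_meta.loc[ids])

    def __repr__(self):
        return (f"OtuTable({self.counts.shape[0]} samples x "
                f"{self.counts.shape[1]} OTUs)")


class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample labels."""

    def __init__(self, data: np.ndarray, ids: Sequence[str]):
        data = np.asarray(data, dtype=float)
        ids = list(ids)
        if data.ndim != 2 or data.shape[0] != data.shape[1]:
            raise ValidationError("distance matrix must be square")
        if len(ids) != data.shape[0]:
            raise ValidationError("label count must match matrix size")
        if not np.allclose(data, data.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(data), 0, atol=1e-10):
            raise ValidationError("distance matrix must have a zero diagonal")
        self.data = (data + data.T) / 2.0
        np.fill_diagonal(self.data, 0.0)
        self.ids = ids

    @property
    def shape(self):
        return self.data.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def submatrix(self, keep: np.ndarray) -> "DistanceMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return DistanceMatrix(self.data[np.ix_(keep, keep)],
                              [self.ids[i] for i in keep])

    def __repr__(self):
        return f"DistanceMatrix({self.shape[0]} samples)"


def records_to_frame(records: Sequence[LifeHistoryRecord]) -> pd.DataFrame:
    """Long-form view of life-history records (one row per observation)."""
    rows = []
    for rec in records:
        rows.append((rec.individual_id, rec.treatment, rec.last_day,
                     int(rec.event), "status", rec.last_day, int(rec.event)))
        for day, brood in rec.clutches:
            rows.append((rec.individual_id, rec.treatment, rec.last_day,
                         int(rec.event), "clutch", day, brood))
        for day, mm in rec.lengths:
            rows.append((rec.individual_id, rec.treatment, rec.last_day,
                         int(rec.event), "length", day, mm))
    return pd.DataFrame(rows, columns=["individual_id", "treatment", "last_day",
                                       "event", "obs_type", "day", "value"])
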