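"""Synthetic life-history and gut-microbiome data generator.

Emulates a chronic-exposure life-table experiment on *Daphnia magna*:
four Ciprofloxacin treatments (0, 0.01, 0.1 and 1 mg/L), 25 animals per
treatment followed individually for 21 days, up to four clutches, and
four animals per treatment sacrificed for gut microbiome profiling at
each clutch event. Microbiome counts follow a Dirichlet-multinomial
whose expected composition shifts with concentration on a
log10(1 + c/c_ref) scale, so sensitive taxa are depleted and refractory
taxa enriched as exposure rises; host traits can be coupled to
designated taxa to plant a recoverable microbiome-fitness signal.

Sampled (sacrificed) animals are right-censored at their sampling day,
so a record with ``event=False`` and ``last_day`` before the horizon
identifies a microbiome sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import LifeHistoryRecord, OtuTable, ValidationError
from .growth import von_bertalanffy


@dataclass
class GrowthParams:
    bl_max: float   # asymptotic length, mm
    k: float        # growth rate, 1/day
    sigma_length: float  # measurement SD, mm


@dataclass
class MicrobiomeParams:
    n_otus: int = 300
    base_sigma: float = 1.5        # SD of log baseline abundances
    frac_sensitive: float = 0.45   # fraction of OTUs depleted by exposure
    slope_sensitive: float = -5.0  # per log10(1 + c/c_ref) unit
    frac_refractory: float = 0.10
    slope_refractory: float = 2.0
    slope_jitter: float = 0.3      # SD of per-OTU slope noise
    drift_sigma: float = 0.15      # taxon-specific per-clutch drift SD
    theta: float = 0.02            # Dirichlet-multinomial overdispersion
    depth_mean: float = 5000.0     # sequencing depth (log-normal median)
    depth_sigma: float = 0.3       # log-scale SD; 0 = fixed depth
    conc_ref: float = 0.01         # reference concentration, mg/L
    n_sampled_per_clutch: int = 4
    frac_unassigned_genus: float = 0.05


@dataclass
class SimConfig:
    """Full description of a simulated experiment.

    Defaults mirror the design scale of a 21-day OECD-211 style
    reproduction test: 4 x 25 animals, clutches from day 9 every 3
    days, four animals sampled per treatment at each clutch event
    (at most 64 microbiome samples).
    """

    treatments: tuple = (0.0, 0.01, 0.1, 1.0)
    n_per_treatment: int = 25
    horizon: int = 21
    growth: dict = field(default_factory=lambda: {
        0.0: GrowthParams(3.252, 0.311, 0.099),
        0.01: GrowthParams(3.376, 0.287, 0.121),
        0.1: GrowthParams(3.314, 0.299, 0.111),
        1.0: GrowthParams(3.339, 0.286, 0.130),
    })
    survival: dict = field(default_factory=lambda: {
        0.0: 0.008, 0.01: 0.004, 0.1: 0.004, 1.0: 0.005})
    fecundity: dict = field(default_factory=lambda: {
        0.0: 6.0, 0.01: 8.9, 0.1: 9.4, 1.0: 8.6})
    fecundity_time_trend: float = -0.4   # brood-size change per clutch
    maturation_day: int = 9
    interclutch_interval: int = 3
    max_clutches: int = 4
    #: days on which live animals are scanned for length (non-invasive),
    #: in addition to the measurement at sacrifice or termination; early
    #: ages anchor the rising limb of the growth curve
    length_scan_days: tuple = (3, 6)
    microbiome: MicrobiomeParams = field(default_factory=MicrobiomeParams)
    coupling: tuple = ()   # (otu_id, trait, effect_size) triples
    seed: int = 0

    def __post_init__(self):
        if any(h < 0 or h > 1 for h in self.survival.values()):
            raise ValidationError("daily hazards must be in [0, 1]")
        if any(m < 0 for m in self.fecundity.values()):
            raise ValidationError("fecundity means must be >= 0")
        m = self.microbiome
        if m.depth_mean <= 0 or m.n_otus <= 0 or m.theta < 0:
            raise ValidationError("depth, n_otus must be > 0 and theta >= 0")
        for conc in self.treatments:
            if conc not in self.growth or conc not in self.survival \
                    or conc not in self.fecundity:
                raise ValidationError(f"missing parameters for treatment {conc}")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["growth"] = {str(k): dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                       else v for k, v in self.growth.items()}
        d["survival"] = {str(k): v for k, v in self.survival.items()}
        d["fecundity"] = {str(k): v for k, v in self.fecundity.items()}
        d["treatments"] = list(self.treatments)
        d["coupling"] = [list(c) for c in self.coupling]
        d["length_scan_days"] = list(self.length_scan_days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "growth" in d:
            d["growth"] = {float(k): GrowthParams(**v) if isinstance(v, dict)
                           else v for k, v in d["growth"].items()}
        for key in ("survival", "fecundity"):
            if key in d:
                d[key] = {float(k): float(v) for k, v in d[key].items()}
        if "microbiome" in d and isinstance(d["microbiome"], dict):
            d["microbiome"] = MicrobiomeParams(**d["microbiome"])
        if "treatments" in d:
            d["treatments"] = tuple(float(t) for t in d["treatments"])
        if "coupling" in d:
            d["coupling"] = tuple(tuple(c) for c in d["coupling"])
        if "length_scan_days" in d:
            d["length_scan_days"] = tuple(int(x) for x in d["length_scan_days"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _clutch_days(config: SimConfig) -> list[int]:
    return [config.maturation_day + config.interclutch_interval * j
            for j in range(config.max_clutches)]


def simulate_life_histories(config: SimConfig) -> list[LifeHistoryRecord]:
    """Simulate one cohort per treatment.

    Death days come from a daily Bernoulli hazard; brood sizes are
    Poisson with a per-treatment mean and a linear clutch (time) trend;
    body lengths follow the von Bertalanffy curve with Gaussian noise.
    Four animals per treatment are sacrificed at each clutch event
    (censored at that day, length measured); survivors are censored and
    measured at the horizon. Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    clutch_days = _clutch_days(config)
    records: list[LifeHistoryRecord] = []
    for conc in config.treatments:
        hazard = config.survival[conc]
        gp = config.growth[conc]
        brood_mean = config.fecundity[conc]
        n = config.n_per_treatment
        # death day per animal: first Bernoulli success on days 1..horizon
        if hazard > 0:
            draws = rng.random((n, config.horizon)) < hazard
            death_day = np.where(draws.any(axis=1),
                                 draws.argmax(axis=1) + 1, 0)
        else:
            death_day = np.zeros(n, dtype=int)
        # full clutch schedules (later truncated by death/sampling)
        broods = {}
        for i in range(n):
            broods[i] = [int(rng.poisson(max(brood_mean
                         + config.fecundity_time_trend * j, 0.1)))
                         for j in range(config.max_clutches)]
        # sampling plan: per clutch event, pick from alive unsampled animals
        sampled_at = np.zeros(n, dtype=int)  # 0 = not sampled, else day
        for day in clutch_days:
            if day > config.horizon:
                break
            candidates = [i for i in range(n)
                          if sampled_at[i] == 0
                          and (death_day[i] == 0 or death_day[i] > day)]
            take = min(config.microbiome.n_sampled_per_clutch, len(candidates))
            if take:
                chosen = rng.choice(candidates, size=take, replace=False)
                sampled_at[chosen] = day
        for i in range(n):
            if sampled_at[i] > 0:
                last_day, event = int(sampled_at[i]), False
            elif death_day[i] > 0:
                last_day, event = int(death_day[i]), True
            else:
                last_day, event = config.horizon, False
            clutches = tuple(
                (day, broods[i][j]) for j, day in enumerate(clutch_days)
                if day <= last_day and (not event or day < last_day))
            scan_days = [d for d in config.length_scan_days if d < last_day]
            if not event:  # final measurement at sacrifice or termination
                scan_days.append(last_day)
            lengths = tuple(
                (d, float(max(von_bertalanffy(d, gp.bl_max, gp.k)
                              + rng.normal(0.0, gp.sigma_length), 0.1)))
                for d in scan_days)
            records.append(LifeHistoryRecord(
                individual_id=f"c{conc:g}_i{i:02d}", treatment=conc,
                last_day=last_day, event=event,
                clutches=clutches, lengths=lengths))
    return records


def sampled_records(records: Sequence[LifeHistoryRecord],
                    horizon: int = 21) -> list[LifeHistoryRecord]:
    """Animals sacrificed for microbiome profiling: censored before the
    horizon (their last clutch day is the sampling day)."""
    return [r for r in records if not r.event and r.last_day < horizon]


def _taxonomy_frame(m: MicrobiomeParams, rng: np.random.Generator) -> pd.DataFrame:
    n = m.n_otus
    otus = [f"OTU{i:04d}" for i in range(n)]
    genus_of = np.arange(n) // 3
    family_of = genus_of // 3
    order_of = family_of // 2
    class_of = order_of // 2
    phylum_of = class_of // 3
    tax = pd.DataFrame({
        "phylum": [f"Phylum{p:02d}" for p in phylum_of],
        "class": [f"Class{c:02d}" for c in class_of],
        "order": [f"Order{o:02d}" for o in order_of],
        "family": [f"Family{f:03d}" for f in family_of],
        "genus": [f"Genus{g:03d}" for g in genus_of],
    }, index=otus)
    if m.frac_unassigned_genus > 0:
        mask = rng.random(n) < m.frac_unassigned_genus
        tax.loc[mask, "genus"] = "unassigned"
    return tax


def simulate_otu_table(config: SimConfig,
                       records: Sequence[LifeHistoryRecord]) -> OtuTable:
    """Dirichlet-multinomial OTU counts for the sacrificed animals.

    Expected relative abundances are the softmax of
    ``log baseline + slope * log10(1 + c/c_ref) + drift * (clutch - 1)``;
    counts are drawn at a log-normal sequencing depth with
    overdispersion ``theta`` (theta = 0 reduces to multinomial).
    """
    m = config.microbiome
    rng = np.random.default_rng(config.seed + 1)
    base = rng.normal(0.0, m.base_sigma, m.n_otus)
    n_sens = int(round(m.frac_sensitive * m.n_otus))
    n_refr = int(round(m.frac_refractory * m.n_otus))
    slopes = np.zeros(m.n_otus)
    slopes[:n_sens] = m.slope_sensitive
    slopes[n_sens:n_sens + n_refr] = m.slope_refractory
    slopes += rng.normal(0.0, m.slope_jitter, m.n_otus)
    drift = rng.normal(0.0, m.drift_sigma, m.n_otus)
    taxonomy = _taxonomy_frame(m, rng)

    samples = sampled_records(records, horizon=config.horizon)
    if not samples:
        raise ValidationError("no sampled individuals in records")
    rows, meta_rows, ids = [], [], []
    for rec in samples:
        clutch = len(rec.clutches)
        z = np.log10(1.0 + rec.treatment / m.conc_ref)
        logit = base + slopes * z + drift * (clutch - 1)
        logit -= logit.max()
        p = np.exp(logit)
        p /= p.sum()
        if m.depth_sigma > 0:
            depth = int(max(1, round(rng.lognormal(np.log(m.depth_mean),
                                                   m.depth_sigma))))
        else:
            depth = int(round(m.depth_mean))
        if m.theta > 0:
            p_sample = rng.dirichlet(np.maximum(p / m.theta, 1e-9))
        else:
            p_sample = p
        rows.append(rng.multinomial(depth, p_sample))
        ids.append(rec.individual_id)
        meta_rows.append({"treatment": rec.treatment, "clutch": clutch,
                          "day": rec.last_day})
    counts = pd.DataFrame(np.asarray(rows), index=ids,
                          columns=taxonomy.index)
    meta = pd.DataFrame(meta_rows, index=ids)
    return OtuTable(counts, taxonomy, meta)


def couple_phenotypes(records: Sequence[LifeHistoryRecord], table: OtuTable,
                      config: SimConfig) -> list[LifeHistoryRecord]:
    """Shift designated host traits by the coupled OTUs' abundances.

    For each ``(otu, trait, effect)`` triple the trait of every sampled
    animal moves by ``effect`` times the standardized log10 relative
    abundance of that OTU in the animal's gut sample. ``trait`` is
    ``'body_length'`` (shift in mm) or ``'fecundity'`` (shift in
    neonates per clutch, rounded, floored at 0). Records without a
    microbiome sample pass through unchanged.
    """
    shifts_bl = pd.Series(0.0, index=table.sample_ids)
    shifts_fec = pd.Series(0.0, index=table.sample_ids)
    rel = table.relative_abundance()
    for otu, trait, effect in config.coupling:
        if otu not in table.otu_ids:
            raise ValidationError(f"coupled OTU {otu!r} absent from table")
        if trait not in ("body_length", "fecundity"):
            raise ValidationError(f"unknown coupled trait {trait!r}")
        logab = np.log10(rel[otu] + 1e-6)
        sd = logab.std(ddof=1)
        z = (logab - logab.mean()) / sd if sd > 0 else logab * 0.0
        if trait == "body_length":
            shifts_bl += effect * z
        else:
            shifts_fec += effect * z
    out = []
    for rec in records:
        if rec.individual_id not in table.sample_ids:
            out.append(rec)
            continue
        d_bl = float(shifts_bl[rec.individual_id])
        d_fec = float(shifts_fec[rec.individual_id])
        lengths = tuple((day, max(mm + d_bl, 0.1)) for day, mm in rec.lengths)
        clutches = tuple((day, max(int(round(b + d_fec)), 0))
                         for day, b in rec.clutches)
        out.append(dataclasses.replace(rec, lengths=lengths, clutches=clutches))
    return out
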