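"""End-to-end orchestration of the demography + microbiome analysis.

``run_full_analysis`` wires the stages together in the order the study
design implies: survival and population growth -> somatic growth ->
fecundity GLM -> alpha diversity (rarefaction, indices, GLM) -> beta
diversity (PERMANOVA, betadisper) -> core microbiome and shared/unique
sets -> differential abundance (exposure and phenotype modes) ->
trait-diversity correlations. The orchestrator holds no hidden state:
every stage is independently callable with the same inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha, beta, core_diffabund, demography, growth, host_stats
from .datatypes import OtuTable, ValidationError
from .synthetic import (
    SimConfig,
    couple_phenotypes,
    sampled_records,
    simulate_life_histories,
    simulate_otu_table,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; ``partial`` holds results so far."""

    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


def sample_traits(records, table: OtuTable) -> pd.DataFrame:
    """Body length and last-clutch brood size of each sampled animal."""
    rows = {}
    by_id = {r.individual_id: r for r in records}
    for sid in table.sample_ids:
        rec = by_id[sid]
        if not rec.lengths or not rec.clutches:
            raise ValidationError(f"sample {sid!r} lacks length or clutch data")
        rows[sid] = {"body_length": rec.lengths[-1][1],
                     "fecundity": rec.clutches[-1][1],
                     "clutch": len(rec.clutches)}
    return pd.DataFrame.from_dict(rows, orient="index")


def fecundity_glm(records):
    """Poisson/identity GLM of brood size on concentration and clutch,
    with Wald contrasts between clutch numbers."""
    rows = []
    for rec in records:
        for j, (day, brood) in enumerate(rec.clutches, start=1):
            rows.append((rec.treatment, j, brood))
    if not rows:
        raise ValidationError("no clutches recorded")
    df = pd.DataFrame(rows, columns=["concentration", "clutch", "brood"])
    clutch_levels = sorted(df["clutch"].unique())
    X = pd.DataFrame({"intercept": 1.0,
                      "concentration": df["concentration"].astype(float)})
    for lev in clutch_levels[1:]:
        X[f"clutch_{lev}"] = (df["clutch"] == lev).astype(float)
    fit = host_stats.fit_glm(df["brood"], X, family="poisson", link="identity")
    mean_conc = float(df["concentration"].mean())
    design = {}
    for lev in clutch_levels:
        row = {"intercept": 1.0, "concentration": mean_conc}
        for other in clutch_levels[1:]:
            row[f"clutch_{other}"] = 1.0 if other == lev else 0.0
        design[f"clutch_{lev}"] = row
    level_design = pd.DataFrame(design).T[list(fit.params.index)]
    contrasts = host_stats.pairwise_glm_contrasts(fit, level_design)
    return fit, contrasts


def run_full_analysis(config: SimConfig, out_dir=None,
                      n_boot: int = 999, n_perm: int = 999,
                      rarefy_depth: str | int = "auto") -> dict:
    """Run every stage on a simulated dataset; optionally write a report.

    Returns a dict of per-stage results; with ``out_dir`` a JSON report
    and TSV tables are written. Reproducible for a fixed config seed.
    """
    report: dict = {"seed": config.seed}
    seed = config.seed

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("simulate")
        records = simulate_life_histories(config)
        table = simulate_otu_table(config, records)
        if config.coupling:
            records = couple_phenotypes(records, table, config)
        report["n_records"] = len(records)
        report["n_samples"] = int(table.counts.shape[0])

        name = stage("demography")
        treatments = sorted({r.treatment for r in records})
        by_treatment = {c: [r for r in records if r.treatment == c]
                        for c in treatments}
        km = {c: demography.kaplan_meier(rs) for c, rs in by_treatment.items()}
        labels = [r.treatment for r in records]
        chi2, dof, p_lr = demography.logrank_test(records, labels)
        growth_rates = {}
        for i, c in enumerate(treatments):
            growth_rates[c] = demography.bootstrap_population_growth(
                by_treatment[c], n_boot=n_boot, seed=seed + 100 + i)
        control = growth_rates[min(treatments)]
        r_sig = {c: demography.compare_by_ci(control, res)
                 for c, res in growth_rates.items() if c != min(treatments)}
        report["demography"] = {
            "logrank": {"chi2": chi2, "df": dof, "p": p_lr},
            "survival_at_horizon": {
                str(c): float(km[c]["survival"].iloc[-1]) for c in treatments},
            "r": {str(c): {"r": res.r, "ci_low": res.ci_low,
                           "ci_high": res.ci_high,
                           "n_degenerate": res.n_degenerate}
                  for c, res in growth_rates.items()},
            "r_significant_vs_control": {str(c): bool(v)
                                         for c, v in r_sig.items()},
        }

        name = stage("growth")
        fits = {}
        for c in treatments:
            pairs = [(day, mm) for r in by_treatment[c] for day, mm in r.lengths]
            fits[c] = growth.fit_von_bertalanffy(pairs)
        report["growth"] = {
            str(c): {"bl_max": f.bl_max, "k": f.k,
                     "ci_bl_max": list(f.ci_bl_max), "ci_k": list(f.ci_k),
                     "r2": f.r2, "df": f.df, "sy_x": f.sy_x}
            for c, f in fits.items()}

        name = stage("fecundity")
        fec_fit, fec_contrasts = fecundity_glm(records)
        report["fecundity"] = {
            "coefficients": {k: float(v) for k, v in fec_fit.params.items()},
            "pvalues": {k: float(v) for k, v in fec_fit.pvalues.items()},
            "clutch_contrasts": fec_contrasts.to_dict(orient="records"),
        }

        name = stage("alpha")
        depth = int(table.depths.min()) if rarefy_depth == "auto" \
            else int(rarefy_depth)
        rarefied = alpha.rarefy(table, depth, seed=seed + 200)
        indices = alpha.diversity_table(rarefied)
        div_glm = alpha.diversity_glm(indices, rarefied.sample_meta)
        report["alpha"] = {
            "rarefaction_depth": depth,
            "glm": div_glm.to_dict(orient="records"),
            "mean_zhang_huang_coverage":
                float(indices["zhang_huang_coverage"].mean()),
        }

        name = stage("beta")
        dm = beta.bray_curtis(rarefied, rank="family")
        treat_labels = rarefied.sample_meta["treatment"].to_numpy()
        ordination = beta.pcoa(dm)
        perma = beta.permanova(dm, treat_labels, n_perm=n_perm, seed=seed + 300)
        pairwise = beta.pairwise_permanova(dm, treat_labels, n_perm=n_perm,
                                           seed=seed + 301)
        disp = beta.betadisper(dm, treat_labels, n_perm=n_perm, seed=seed + 302)
        report["beta"] = {
            "permanova": {k: float(v) for k, v in perma.items()},
            "pairwise_permanova": pairwise.to_dict(orient="records"),
            "betadisper": {"F": float(disp["F"]), "p": float(disp["p"]),
                           "group_means": {str(k): float(v) for k, v
                                           in disp["group_means"].items()}},
            "pc1_proportion": float(ordination.proportion_explained[0]),
        }

        name = stage("core")
        core_taxa = core_diffabund.core_filter(rarefied)
        venn = core_diffabund.shared_unique_sets(rarefied, treat_labels)
        report["core"] = {
            "n_core_filter": int(len(core_taxa)),
            "per_group_otus": {str(g): len(s)
                               for g, s in venn.group_sets.items()},
            "n_shared_all_groups": len(venn.core),
            "n_union": len(venn.union),
            "shared_fraction": venn.shared_fraction,
        }

        name = stage("diffabund")
        exposure = core_diffabund.differential_abundance(
            rarefied, grouping="exposure")
        traits = sample_traits(records, rarefied)
        zeta = core_diffabund.zeta_classify(
            traits[["body_length", "fecundity"]], traits["clutch"])
        phenotype = {}
        for trait in ("body_length", "fecundity"):
            phenotype[trait] = core_diffabund.differential_abundance(
                rarefied, grouping="phenotype",
                classes=zeta[f"class_{trait}"])
        report["diffabund"] = {
            "exposure": {str(c): {"phi": res.phi,
                                  "significant": sorted(res.significant)}
                         for c, res in exposure.items()},
            "phenotype": {t: {"phi": res.phi,
                              "significant": sorted(res.significant)}
                          for t, res in phenotype.items()},
        }

        name = stage("correlations")
        corr = {}
        for index_name in ("fishers_alpha", "chao1", "ace", "shannon"):
            for trait in ("body_length", "fecundity"):
                rho, p = host_stats.spearman(indices[index_name],
                                             traits.loc[indices.index, trait])
                corr[f"{index_name}_vs_{trait}"] = {"rho": rho, "p": p}
        report["correlations"] = corr
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc, report) from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        growth.growth_table(fits).to_csv(out_dir / "growth_table.tsv", sep="\t")
        indices.to_csv(out_dir / "alpha_indices.tsv", sep="\t")
        div_glm.to_csv(out_dir / "alpha_glm.tsv", sep="\t", index=False)
        pairwise.to_csv(out_dir / "permanova_pairwise.tsv", sep="\t", index=False)
        dm.to_frame().to_csv(out_dir / "bray_curtis.tsv", sep="\t")
        ordination.coordinates.to_csv(out_dir / "pcoa_coordinates.tsv", sep="\t")
        for trait, res in phenotype.items():
            res.table.to_csv(out_dir / f"diffabund_{trait}.tsv", sep="\t")
    return report
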