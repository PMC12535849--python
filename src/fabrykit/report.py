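"""End-to-end pipeline driver and report tables.

``annotate_cohort`` turns a raw cohort table (genotypes, ICD-10 strings,
labs, pain items) into an analysis-ready frame with risk-factor flags,
FD-domain severities, and the FDF score columns. ``run_full_analysis``
drives the whole pipeline: cohort summary counts, FDF distribution, the CV
risk model with ROC metrics and the Youden cutoff check, CV-adjusted
carrier associations, CV-stratified associations, and mean +/- SD trait
tables with BH-adjusted p-values. All outputs are plain TSV/text and are
byte-identical under a fixed seed and config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from .cvrisk import CVRiskModel, roc_metrics
from .errors import DataError, ModelError
from .fdf import (
    ScoringMap,
    renal_component_points,
    score_flag_domain,
    score_pain,
    youden_cutoff,
)
from .phenotypes import CodeRegistry, map_cohort_codes
from .simulate import LAB_COLUMNS, PAIN_ITEMS, SimConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "annotate_cohort",
    "carrier_proportion",
    "cohort_counts_table",
    "trait_table",
    "run_full_analysis",
]

#: lipid traits whose linear models additionally adjust for statin therapy
LIPID_LABS = ("cholesterol", "triglycerides", "hdl", "apob", "lpa")

#: ordinal domain-score outcomes analysed per group alongside the FDF flag
DOMAIN_OUTCOMES = ("fdf_cardiac", "fdf_cerebrovascular", "fdf_renal")


def annotate_cohort(table: pd.DataFrame, registry: CodeRegistry | None = None,
                    scoring: ScoringMap | None = None) -> pd.DataFrame:
    """Add risk-factor flags, domain severities, and FDF score columns."""
    registry = registry or CodeRegistry()
    scoring = scoring or ScoringMap()
    out = pd.concat([table.reset_index(drop=True),
                     map_cohort_codes(table["icd10"].reset_index(drop=True), registry)], axis=1)

    egfr_pts, uacr_pts = renal_component_points(out["egfr"], out["uacr"], scoring)
    out["egfr_points"] = egfr_pts
    out["uacr_points"] = uacr_pts
    out["fdf_renal"] = np.minimum(np.maximum(egfr_pts, uacr_pts), scoring.domain_max)
    out["fdf_cardiac"] = score_flag_domain(
        out["cardiac_severity"].to_numpy(), scoring.cardiac_weights, scoring.domain_max
    )
    out["fdf_cerebrovascular"] = score_flag_domain(
        out["cerebrovascular_severity"].to_numpy(),
        scoring.cerebrovascular_weights, scoring.domain_max,
    )
    pain_pts, imputed = score_pain(out[list(PAIN_ITEMS)], scoring.pain_weights, scoring.domain_max)
    out["fdf_pain"] = pain_pts
    out["pain_imputed"] = imputed
    total = (out["fdf_pain"] + out["fdf_renal"] + out["fdf_cardiac"]
             + out["fdf_cerebrovascular"])
    out["fdf_total"] = total
    out["fdf_high"] = np.where(
        total.isna(), np.nan, (total > scoring.dichotomization_threshold).astype(float)
    )
    return out


def carrier_proportion(n_carriers: int, n_wildtype: int, digits: int = 4) -> float:
    """Carrier fraction n_c / (n_c + n_wt), rounded half-even to ``digits``."""
    if n_carriers < 0 or n_wildtype < 0:
        raise DataError("counts must be non-negative")
    total = n_carriers + n_wildtype
    if total == 0:
        raise DataError("carrier and wild-type counts are both zero")
    frac = Decimal(int(n_carriers)) / Decimal(int(total))
    return float(frac.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_EVEN))


def cohort_counts_table(cohort: pd.DataFrame, groups, digits: int = 5) -> pd.DataFrame:
    """Per-group carrier counts and same-sex proportions (summary-table style).

    Hemizygous males and heterozygous females count as carriers; homozygous
    females are reported in their own column, outside the carrier counts.
    """
    rows = []
    male = cohort[cohort["sex"] == "male"]
    female = cohort[cohort["sex"] == "female"]
    for group in groups:
        ac_m = male[f"ac_{group}"].astype(int)
        ac_f = female[f"ac_{group}"].astype(int)
        if (ac_m > 1).any():
            raise DataError(f"male allele count of 2 in group {group!r}")
        hemi = int((ac_m == 1).sum())
        het = int((ac_f == 1).sum())
        hom = int((ac_f == 2).sum())
        wt_m = len(male) - hemi
        wt_f = len(female) - het - hom
        rows.append({
            "group": group,
            "carriers_male": hemi,
            "wildtype_male": wt_m,
            "prop_male": carrier_proportion(hemi, wt_m, digits) if hemi + wt_m else 0.0,
            "carriers_female": het,
            "wildtype_female": wt_f,
            "prop_female": carrier_proportion(het, wt_f, digits) if het + wt_f else 0.0,
            "homozygous_female": hom,
        })
    return pd.DataFrame(rows)


def run_adjusted_associations(cohort: pd.DataFrame, groups,
                              domain_outcomes=DOMAIN_OUTCOMES,
                              sexes=("male", "female")) -> list[assoc.AssociationResult]:
    """CV-adjusted carrier models: logistic on FDF>4 plus proportional-odds
    models on each multi-level domain score, per group and sex."""
    results: list[assoc.AssociationResult] = []
    for sex in sexes:
        for group in groups:
            aset = assoc.build_analysis_set(cohort, group, sex, groups=tuple(groups))
            if aset.empty:
                logger.info("no %s carriers for %s; skipped", sex, group)
                continue
            try:
                results.append(
                    assoc.CarrierAssociation(aset, "fdf_high", kind="logistic").fit()
                )
            except (DataError, ModelError) as exc:
                logger.info("logistic %s/%s skipped: %s", group, sex, exc)
            for outcome in domain_outcomes:
                try:
                    results.append(
                        assoc.CarrierAssociation(aset, outcome, kind="ordinal").fit()
                    )
                except (DataError, ModelError) as exc:
                    logger.info("ordinal %s on %s/%s skipped: %s", outcome, group, sex, exc)
    return results


def trait_table(cohort: pd.DataFrame, groups, labs=LAB_COLUMNS,
                sexes=("male", "female")) -> list[assoc.AssociationResult]:
    """Linear carrier models for each continuous trait (mean +/- SD style
    output), statin-adjusted for lipid traits."""
    results: list[assoc.AssociationResult] = []
    for sex in sexes:
        for group in groups:
            aset = assoc.build_analysis_set(cohort, group, sex, groups=tuple(groups))
            if aset.empty:
                continue
            for lab in labs:
                try:
                    results.append(
                        assoc.CarrierAssociation(
                            aset, lab, kind="linear", statin_adjust=lab in LIPID_LABS
                        ).fit()
                    )
                except (DataError, ModelError) as exc:
                    logger.info("linear %s on %s/%s skipped: %s", lab, group, sex, exc)
    return results


def _results_frame(results: list[assoc.AssociationResult]) -> pd.DataFrame:
    frame = pd.DataFrame([r.to_row() for r in results])
    if not frame.empty:
        frame = frame.sort_values(["sex", "group", "stratum", "outcome"]).reset_index(drop=True)
    return frame


def _trait_frame(results: list[assoc.AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = r.to_row()
        row["carrier_mean"], row["carrier_sd"] = r.group_mean_sd
        row["control_mean"], row["control_sd"] = r.control_mean_sd
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["sex", "group", "outcome"]).reset_index(drop=True)
    return frame


@dataclass
class ReportBundle:
    """Everything ``run_full_analysis`` produces, plus where it was written."""

    counts: pd.DataFrame
    fdf_distribution: pd.DataFrame
    cv_summary: str
    roc: dict
    adjusted: pd.DataFrame
    stratified: pd.DataFrame
    traits: pd.DataFrame
    paths: dict


def run_full_analysis(sim_config: SimConfig | None = None,
                      cohort: pd.DataFrame | None = None,
                      registry: CodeRegistry | None = None,
                      scoring: ScoringMap | None = None,
                      out_dir=None,
                      groups=None,
                      domain_outcomes=DOMAIN_OUTCOMES,
                      trait_labs=LAB_COLUMNS) -> ReportBundle:
    """Run the whole pipeline on a provided or freshly simulated cohort.

    Applies one BH correction across the combined adjusted-association and
    trait p-values (the stratified set gets its own, inside
    :func:`fabrykit.association.run_stratified`).
    """
    t0 = time.time()
    truth = {}
    if cohort is None:
        sim_config = sim_config or SimConfig()
        generated = generate_cohort(sim_config)
        cohort, truth = generated.table, generated.truth
    ann = annotate_cohort(cohort, registry, scoring)
    groups = tuple(groups) if groups is not None else tuple(
        c[3:] for c in ann.columns if c.startswith("ac_")
    )
    logger.info("annotated %d subjects (%.1fs)", len(ann), time.time() - t0)

    counts = cohort_counts_table(ann, groups)

    fdf_dist = (
        ann.groupby("sex")["fdf_total"]
        .value_counts(dropna=True)
        .rename("n")
        .reset_index()
        .sort_values(["sex", "fdf_total"])
        .reset_index(drop=True)
    )

    # CV risk model: fitted on the FD phenotype, validated against
    # pathogenic-carrier status (ROC + Youden check where carriers exist)
    cv = CVRiskModel(ann, outcome="fdf_high").fit()
    scores, strata = cv.score(ann), cv.stratify(ann)
    roc: dict = {}
    pathogenic_cols = [f"ac_{g}" for g in groups if g.endswith("_P") or g == "ALL_P"]
    if pathogenic_cols:
        is_path = (ann[pathogenic_cols].astype(float) > 0).any(axis=1).astype(int)
        if is_path.sum() > 0:
            auc, sens, spec = roc_metrics(scores, is_path, cv.score_threshold)
            roc = {"auc": auc, "sensitivity": sens, "specificity": spec,
                   "threshold": cv.score_threshold}
            valid = ann["fdf_total"].notna()
            if is_path[valid].nunique() == 2:
                thr, j = youden_cutoff(ann.loc[valid, "fdf_total"], is_path[valid])
                roc["youden_threshold"], roc["youden_j"] = thr, j

    adjusted_results = run_adjusted_associations(ann, groups, domain_outcomes)
    trait_results = trait_table(ann, groups, labs=trait_labs)

    # one BH pass over the full adjusted + trait p-value set
    pooled = adjusted_results + trait_results
    ps = np.array([r.p_raw for r in pooled], dtype=float)
    if len(ps):
        adj = assoc.bh_adjust(np.where(np.isnan(ps), 1.0, ps))
        for r, a, raw in zip(pooled, adj, ps):
            r.p_adjusted = float(a) if np.isfinite(raw) else None

    stratified_results = assoc.run_stratified(ann, groups, strata)

    bundle = ReportBundle(
        counts=counts,
        fdf_distribution=fdf_dist,
        cv_summary=cv.summary(),
        roc=roc,
        adjusted=_results_frame(adjusted_results),
        stratified=_results_frame(stratified_results),
        traits=_trait_frame(trait_results),
        paths={},
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        writers = {
            "cohort_counts.tsv": bundle.counts,
            "fdf_distribution.tsv": bundle.fdf_distribution,
            "associations_adjusted.tsv": bundle.adjusted,
            "associations_stratified.tsv": bundle.stratified,
            "trait_models.tsv": bundle.traits,
        }
        for name, frame in writers.items():
            path = out / name
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            bundle.paths[name] = str(path)
        cv_path = out / "cv_model.txt"
        with open(cv_path, "w") as fh:
            fh.write(bundle.cv_summary + "\n")
            for key, value in bundle.roc.items():
                fh.write(f"{key}: {value:.4f}\n")
            if truth:
                fh.write(f"simulated: seed={truth.get('seed')} "
                         f"n={truth.get('n_males')}M/{truth.get('n_females')}F\n")
        bundle.paths["cv_model.txt"] = str(cv_path)
        logger.info("report written to %s (%.1fs)", out, time.time() - t0)
    return bundle
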