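"""End-to-end analysis pipeline: imputation → pooling → meta-regression.

`run_pipeline` executes the stages in the order the analysis defines them:
per-study effect sizes, trait-wise SD imputation and weighting scheme,
inverse-variance pooled effects with BCa bootstrap CIs (back-transformed to
the R − 1 scale), mixed-model meta-regression with backward elimination for
traits with more than 20 studies, and single-factor plant-grouping analyses
for traits spanning more than 20 species.  Everything is deterministic
given the input table and the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__ as _version
from .catalog import GAS_EXCHANGE_TRAITS
from .database import StudyDatabase, count_species, read_study_table
from .effects import estimate_from_record
from .imputation import ImputationReport, impute_database
from .metareg import (GROUPING_FACTORS, MIN_SPECIES_GROUPING,
                      MIN_STUDIES_METAREG, DesignSpec, EliminationRound,
                      MetaRegressionResults, minimal_adequate_model,
                      single_factor_analysis)
from .pooling import (DEFAULT_B, MIN_STUDIES_CI, PooledEffectResults,
                      summarize_trait)

logger = logging.getLogger(__name__)

POOLED_COLUMNS = ["trait", "condition", "n_studies", "n_species",
                  "L_star", "effect_size", "ci_low", "ci_high",
                  "ci_method", "weighting", "B", "seed"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, trait: str, cause: Exception):
        super().__init__(f"stage {stage!r}, trait {trait!r}: {cause}")
        self.stage, self.trait, self.cause = stage, trait, cause


@dataclass
class RunConfig:
    variance_form: str = "delta_method"
    cv_mode: str = "pooled_arms"
    B: int = DEFAULT_B
    seed: int = 0
    level: float = 0.95
    alpha: float = 0.05
    min_studies_ci: int = MIN_STUDIES_CI
    min_studies_metareg: int = MIN_STUDIES_METAREG
    min_species_grouping: int = MIN_SPECIES_GROUPING
    tau2_method: str = "reml"
    inference: str = "z"
    traits: Optional[list[str]] = None      # subset filter; None = all
    run_metareg: bool = True
    run_groupings: bool = True
    qvalues: bool = False                   # opt-in BH column (diagnostic,
                                            # not part of the source analysis)

    def validate(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")


@dataclass
class GroupingReport:
    factor: str
    fit: MetaRegressionResults
    level_counts: dict[str, dict[str, int]]  # level -> {"n": studies, "N": species}


@dataclass
class TraitRegressionReport:
    trait: str
    fit: MetaRegressionResults
    trace: list[EliminationRound]


@dataclass
class ResultBundle:
    pooled: list[PooledEffectResults]
    imputation: ImputationReport
    metareg: dict[str, TraitRegressionReport]
    groupings: dict[str, dict[str, GroupingReport]]
    skipped: dict[str, str]
    manifest: dict


def _conditions_for(db: StudyDatabase, trait: str) -> list[str]:
    conds = ["any"]
    if trait in GAS_EXCHANGE_TRAITS:
        for c in ("SC", "DC"):
            if db.filter_trait(trait, c):
                conds.append(c)
    return conds


def run_pipeline(source: StudyDatabase | str | Path,
                 config: Optional[RunConfig] = None) -> ResultBundle:
    """Run imputation, pooling, meta-regression and grouping analyses.

    ``source`` is a study database or a path to a study-table CSV.  Returns
    the in-memory bundle; use :func:`report_tables` to write files.
    """
    config = config if config is not None else RunConfig()
    config.validate()
    if not isinstance(source, StudyDatabase):
        db = read_study_table(source)
    else:
        db = source
    imputed, imp_report = impute_database(db, mode=config.cv_mode)
    traits = [t for t in imputed.traits()
              if config.traits is None or t in config.traits]

    pooled: list[PooledEffectResults] = []
    skipped: dict[str, str] = {}
    for trait in traits:
        for cond in _conditions_for(imputed, trait):
            try:
                pooled.append(summarize_trait(
                    imputed, trait, cond, report=imp_report,
                    variance_form=config.variance_form, B=config.B,
                    seed=config.seed, level=config.level))
            except ValueError as exc:
                raise PipelineError("pooled_effects", trait, exc) from exc

    metareg: dict[str, TraitRegressionReport] = {}
    groupings: dict[str, dict[str, MetaRegressionResults]] = {}
    for trait in traits:
        recs = imputed.filter_trait(trait, "any")
        if imp_report.scheme(trait) == "unit_weight":
            skipped[trait] = "unit-weight trait: no variances for meta-regression"
            continue
        ests = [estimate_from_record(r, form=config.variance_form)
                for r in recs]
        usable = [e for e in ests if e.v is not None]
        if config.run_metareg:
            if len(usable) >= config.min_studies_metareg:
                try:
                    fit, trace = minimal_adequate_model(
                        usable, DesignSpec(), alpha=config.alpha,
                        min_studies=config.min_studies_metareg,
                        method=config.tau2_method,
                        inference=config.inference)
                    metareg[trait] = TraitRegressionReport(trait, fit, trace)
                except ValueError as exc:
                    skipped[trait] = f"meta-regression: {exc}"
            else:
                skipped.setdefault(
                    trait, f"meta-regression gate: {len(usable)} studies "
                    f"< {config.min_studies_metareg}")
        if config.run_groupings:
            n_sp = count_species(recs)
            if n_sp >= config.min_species_grouping:
                by_factor: dict[str, GroupingReport] = {}
                for factor in GROUPING_FACTORS:
                    try:
                        fit = single_factor_analysis(
                            usable, factor,
                            min_species=config.min_species_grouping,
                            method=config.tau2_method,
                            inference=config.inference)
                        levels: dict[str, dict[str, int]] = {}
                        for e in usable:
                            lv = e.moderators.get(factor)
                            if lv is None:
                                continue
                            levels.setdefault(lv, {"n": 0, "species": set()})
                            levels[lv]["n"] += 1
                            levels[lv]["species"].add(
                                e.species.strip().casefold())
                        counts = {lv: {"n": d["n"], "N": len(d["species"])}
                                  for lv, d in levels.items()}
                        by_factor[factor] = GroupingReport(
                            factor, fit, counts)
                    except (ValueError, np.linalg.LinAlgError) as exc:
                        logger.info("grouping %s on %s skipped: %s",
                                    factor, trait, exc)
                if by_factor:
                    groupings[trait] = by_factor

    manifest = {
        "version": _version,
        "config": dataclasses.asdict(config),
        "n_records": len(db),
        "n_traits": len(traits),
        "n_pooled_rows": len(pooled),
        "n_metareg": len(metareg),
        "n_grouping_traits": len(groupings),
        "provenance": db.provenance,
    }
    return ResultBundle(pooled=pooled, imputation=imp_report, metareg=metareg,
                        groupings=groupings, skipped=skipped,
                        manifest=manifest)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def pooled_table_rows(bundle: ResultBundle, qvalues: bool = False
                      ) -> tuple[list[str], list[list]]:
    """Column names and rows of the pooled-effects table."""
    cols = list(POOLED_COLUMNS)
    rows = []
    for r in bundle.pooled:
        rows.append([r.trait, r.condition, r.n_studies, r.n_species,
                     repr(r.L_star), repr(r.effect_size),
                     "" if r.ci_low is None else repr(r.ci_low),
                     "" if r.ci_high is None else repr(r.ci_high),
                     r.ci_method or "", r.weighting, r.B, r.seed])
    if qvalues:
        # diagnostic only: normal-theory p from the fixed-effect SE,
        # Benjamini-Hochberg adjusted across rows; not part of the source
        # analysis, which reports bootstrap CIs without multiplicity control
        from scipy import stats as _st
        ps = []
        for r in bundle.pooled:
            if np.isfinite(r.se_fixed) and r.se_fixed > 0:
                ps.append(2 * _st.norm.sf(abs(r.L_star) / r.se_fixed))
            else:
                ps.append(np.nan)
        ps = np.asarray(ps)
        ok = ~np.isnan(ps)
        qs = np.full(len(ps), np.nan)
        if ok.any():
            qs[ok] = _benjamini_hochberg(ps[ok])
        cols += ["p_normal", "q_bh"]
        for row, p, q in zip(rows, ps, qs):
            row.extend(["" if np.isnan(p) else repr(float(p)),
                        "" if np.isnan(q) else repr(float(q))])
    return cols, rows


def _fit_dict(fit: MetaRegressionResults) -> dict:
    return {
        "coefficients": [
            {"name": n, "estimate": float(b), "se": float(s),
             "z": float(z), "p": float(p)}
            for n, b, s, z, p in zip(fit.names, fit.params, fit.bse,
                                     fit.zvalues, fit.pvalues)],
        "tau2": float(fit.tau2),
        "k": fit.k,
        "QM": float(fit.qm), "QM_df": fit.qm_df, "QM_p": float(fit.qm_pvalue),
        "loglik_reml": float(fit.loglike_reml),
        "inference": fit.inference,
        "dropped": fit.dropped,
    }


def report_tables(bundle: ResultBundle, outdir: str | Path,
                  fmt: str = "tsv") -> list[Path]:
    """Write the bundle's result tables; returns the written paths.

    Emits the pooled-effects table (TSV or CSV plus JSON), per-trait
    meta-regression reports with elimination traces, grouping reports,
    the imputation report and a run manifest.
    """
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    cols, rows = pooled_table_rows(bundle, qvalues=bundle.manifest
                                   .get("config", {}).get("qvalues", False))
    p = outdir / f"pooled_effects.{fmt}"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write(sep.join(cols) + "\n")
        for row in rows:
            fh.write(sep.join(str(c) for c in row) + "\n")
    written.append(p)

    p = outdir / "pooled_effects.json"
    payload = []
    for r in bundle.pooled:
        payload.append({
            "trait": r.trait, "condition": r.condition,
            "n_studies": r.n_studies, "n_species": r.n_species,
            "L_star": r.L_star, "effect_size": r.effect_size,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "ci_low_L": r.ci_low_L, "ci_high_L": r.ci_high_L,
            "ci_method": r.ci_method, "weighting": r.weighting,
            "B": r.B, "seed": r.seed})
    p.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(p)

    p = outdir / "meta_regression.json"
    payload = {
        trait: {
            "final_model": _fit_dict(rep.fit),
            "elimination_trace": [
                {"round": r.round, "removed": r.removed,
                 "p": float(r.pvalue), "remaining": r.remaining}
                for r in rep.trace],
        }
        for trait, rep in bundle.metareg.items()}
    p.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(p)

    p = outdir / "groupings.json"
    payload = {}
    for trait, by_factor in bundle.groupings.items():
        payload[trait] = {
            f: {**_fit_dict(rep.fit), "levels": rep.level_counts}
            for f, rep in by_factor.items()}
    p.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(p)

    p = outdir / "imputation_report.json"
    p.write_text(bundle.imputation.to_json())
    written.append(p)

    p = outdir / "skipped.json"
    p.write_text(json.dumps(bundle.skipped, indent=2, sort_keys=True))
    written.append(p)

    p = outdir / "manifest.json"
    p.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    written.append(p)
    return written
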