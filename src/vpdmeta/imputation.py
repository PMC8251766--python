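"""Missing-SD imputation by trait-wise coefficient of variation.

About a third of extracted studies report no standard deviations.  For a
trait with at least one SD-reporting study, each missing arm SD is imputed
as CV̄ · (that arm's mean), where CV̄ is the average coefficient of variation
over all reported arms of that trait.  Traits where no study reports any SD
cannot be variance-weighted at all; every study of such a trait is assigned
unit weight.

The pass is deterministic, single-shot (imputed SDs never feed back into
CV̄), and never alters means, sample sizes, or reported SDs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .database import StudyDatabase, StudyRecord

logger = logging.getLogger(__name__)

CV_POOLING_MODES = ("pooled_arms", "per_study")


class AllMissingTrait(ValueError):
    """No study of the trait has a usable SD; unit weighting applies."""


@dataclass
class TraitImputation:
    trait: str
    scheme: str                     # variance_weighted | unit_weight
    mean_cv: Optional[float]        # None under unit_weight
    n_complete: int                 # records with both SDs reported
    n_imputed: int                  # records that received >=1 imputed SD
    n_missing_n: int = 0            # records lacking a sample size (no v possible)


@dataclass
class ImputationReport:
    traits: dict[str, TraitImputation] = field(default_factory=dict)
    imputed_fields: dict[str, list[str]] = field(default_factory=dict)  # study_id -> arms

    def scheme(self, trait: str) -> str:
        return self.traits[trait].scheme

    def to_json(self) -> str:
        return json.dumps(
            {
                t: {
                    "scheme": ti.scheme,
                    "mean_cv": ti.mean_cv,
                    "n_complete": ti.n_complete,
                    "n_imputed": ti.n_imputed,
                    "n_missing_n": ti.n_missing_n,
                }
                for t, ti in self.traits.items()
            },
            indent=2, sort_keys=True,
        )


def _arm_cvs(rec: StudyRecord) -> list[float]:
    out = []
    if rec.sd_control is not None and rec.mean_control > 0:
        out.append(rec.sd_control / rec.mean_control)
    if rec.sd_high is not None and rec.mean_high > 0:
        out.append(rec.sd_high / rec.mean_high)
    return out


def trait_mean_cv(records: Iterable[StudyRecord], mode: str = "pooled_arms") -> float:
    """Average coefficient of variation over the reported arms of one trait.

    ``pooled_arms`` (default) averages every available arm-level CV
    (sc/x̄c and sh/x̄h) across studies; ``per_study`` first averages the
    available CVs within each study, then averages across studies, so a
    study reporting both arms does not count twice in the donor pool.
    """
    if mode not in CV_POOLING_MODES:
        raise ValueError(f"unknown CV pooling mode {mode!r}")
    records = list(records)
    if mode == "pooled_arms":
        cvs = [cv for rec in records for cv in _arm_cvs(rec)]
    else:
        per_study = [sum(c) / len(c) for rec in records if (c := _arm_cvs(rec))]
        cvs = per_study
    if not cvs:
        raise AllMissingTrait("no study of this trait reports an SD")
    return sum(cvs) / len(cvs)


def impute_database(db: StudyDatabase, mode: str = "pooled_arms"
                    ) -> tuple[StudyDatabase, ImputationReport]:
    """Fill missing SDs trait by trait; flag all-missing traits for unit weight.

    Returns a new database (the input is untouched) and a report recording,
    per trait, the weighting scheme, the mean CV used, and counts of
    complete/imputed records.  After this pass every trait is all-or-nothing:
    either each of its records can form a variance (given a sample size) or
    the whole trait is unit-weighted.
    """
    out = db.copy()
    report = ImputationReport()
    for trait in out.traits():
        recs = [r for r in out.records if r.trait == trait]
        try:
            cv = trait_mean_cv(recs, mode=mode)
        except AllMissingTrait:
            report.traits[trait] = TraitImputation(
                trait=trait, scheme="unit_weight", mean_cv=None,
                n_complete=0, n_imputed=0,
                n_missing_n=sum(r.n_control is None or r.n_high is None
                                for r in recs))
            logger.info("trait %s: all SDs missing, unit weighting", trait)
            continue
        n_complete = n_imputed = n_missing_n = 0
        for rec in recs:
            imputed_arms = []
            if rec.sd_control is None:
                rec.sd_control = cv * rec.mean_control
                imputed_arms.append("control")
            if rec.sd_high is None:
                rec.sd_high = cv * rec.mean_high
                imputed_arms.append("high")
            if imputed_arms:
                n_imputed += 1
                report.imputed_fields[rec.study_id] = imputed_arms
            else:
                n_complete += 1
            if rec.n_control is None or rec.n_high is None:
                n_missing_n += 1
                logger.info("trait %s study %s: missing sample size, "
                            "variance cannot be formed", trait, rec.study_id)
        report.traits[trait] = TraitImputation(
            trait=trait, scheme="variance_weighted", mean_cv=cv,
            n_complete=n_complete, n_imputed=n_imputed, n_missing_n=n_missing_n)
        logger.info("trait %s: mean CV %.4f, %d complete, %d imputed",
                    trait, cv, n_complete, n_imputed)
    return out, report
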