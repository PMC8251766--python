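"""Per-study effect sizes for VPD meta-analysis.

The response of a trait to elevated vapor pressure deficit is summarised per
study by the log response ratio

    L = ln(x̄h / x̄c),

the natural log of the ratio of the trait mean under high VPD to its mean
under control VPD.  Its sampling variance under the delta method is

    v = sh² / (nh · x̄h²) + sc² / (nc · x̄c²),

the standard large-sample variance of a log ratio of independent sample
means.  An alternative form with un-squared means in the denominators is
available as ``form="as_printed"`` for replication of sources that typeset
it that way; it is dimensionally inconsistent (not invariant under a change
of trait units) and is not the default.

The magnitude of the VPD manipulation is carried by the log VPD ratio
ln(VPDh / VPDc), and pooled log ratios are reported back on the effect-size
scale R − 1 = exp(L*) − 1 (proportional change under high VPD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .database import StudyRecord

VARIANCE_FORMS = ("delta_method", "as_printed")


class MissingVarianceError(ValueError):
    """Raised when a variance is requested but an SD is missing (needs imputation)."""


@dataclass
class EffectEstimate:
    """One study's contribution to a trait's pooled effect.

    ``v_source`` records how the variance was obtained: ``reported`` (both
    SDs extracted from the study), ``imputed`` (one or both SDs filled in
    from the trait-wise mean CV), or ``unit_weight`` (no study of the trait
    has a usable SD; every study gets weight 1 and ``v`` is None).
    """
    study_id: str
    L: float
    v: Optional[float]
    v_source: str  # reported | imputed | unit_weight
    log_vpd_ratio: Optional[float] = None
    species: str = ""
    moderators: dict = field(default_factory=dict)

    def __post_init__(self):
        if not math.isfinite(self.L):
            raise ValueError(f"L must be finite, got {self.L}")
        if self.v_source != "unit_weight" and not (self.v is not None and self.v > 0):
            raise ValueError(
                f"{self.study_id}: v must be positive unless unit_weight (got {self.v})")


def log_response_ratio(mean_high: float, mean_control: float) -> float:
    """ln(mean_high / mean_control); antisymmetric under swapping the means."""
    if mean_high <= 0 or mean_control <= 0:
        raise ValueError("means must be positive for a log response ratio")
    return math.log(mean_high / mean_control)


def log_rr_variance(sd_high: float, n_high: int, mean_high: float,
                    sd_control: float, n_control: int, mean_control: float,
                    form: str = "delta_method") -> float:
    """Sampling variance of the log response ratio.

    ``delta_method`` divides each arm's sd²/n by the squared arm mean (the
    canonical form); ``as_printed`` divides by the un-squared mean.
    """
    if form not in VARIANCE_FORMS:
        raise ValueError(f"unknown variance form {form!r}")
    if sd_high is None or sd_control is None:
        raise MissingVarianceError("missing SD: variance requires imputation")
    if mean_high <= 0 or mean_control <= 0:
        raise ValueError("means must be positive")
    if not n_high or not n_control or n_high < 1 or n_control < 1:
        raise ValueError("sample sizes must be >= 1")
    if sd_high < 0 or sd_control < 0:
        raise ValueError("SDs must be nonnegative")
    p = 2 if form == "delta_method" else 1
    return (sd_high ** 2 / (n_high * mean_high ** p)
            + sd_control ** 2 / (n_control * mean_control ** p))


def log_vpd_ratio(vpd_high: float, vpd_control: float) -> float:
    """ln(VPDh / VPDc); positive whenever the high treatment exceeds control."""
    if vpd_high <= 0 or vpd_control <= 0:
        raise ValueError("VPD levels must be positive")
    return math.log(vpd_high / vpd_control)


def to_effect_size(L_star: float) -> float:
    """Back-transform a (pooled) log response ratio to the effect size R − 1."""
    if not math.isfinite(L_star):
        raise ValueError("L* must be finite")
    return math.exp(L_star) - 1.0


_MODERATOR_FIELDS = ("day_temp", "irrigation", "soil_type",
                     "treatment_duration", "plant_age",
                     "evolutionary_history", "growth_habit",
                     "growth_duration", "end_use")


def estimate_from_record(rec: StudyRecord, form: str = "delta_method") -> EffectEstimate:
    """Build the :class:`EffectEstimate` for one (post-imputation) record.

    The record must carry a resolved ``v_source`` policy: if both SDs and
    both n are present a variance is formed; otherwise the caller should have
    marked the trait unit-weight (see :mod:`vpdmeta.imputation`).
    """
    L = log_response_ratio(rec.mean_high, rec.mean_control)
    has_var = (rec.sd_control is not None and rec.sd_high is not None
               and rec.n_control is not None and rec.n_high is not None)
    if has_var:
        v = log_rr_variance(rec.sd_high, rec.n_high, rec.mean_high,
                            rec.sd_control, rec.n_control, rec.mean_control,
                            form=form)
        source = "reported"
    else:
        v, source = None, "unit_weight"
    lvr = None
    if rec.vpd_control is not None and rec.vpd_high is not None:
        lvr = log_vpd_ratio(rec.vpd_high, rec.vpd_control)
    mods = {name: getattr(rec, name) for name in _MODERATOR_FIELDS}
    return EffectEstimate(study_id=rec.study_id, L=L, v=v, v_source=source,
                          log_vpd_ratio=lvr, species=rec.species,
                          moderators=mods)
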