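"""Synthetic study databases with known truth.

The generator emits study tables with the statistical structure the
meta-analysis assumes, so every pipeline stage can be tested against a
known answer.  For each study of trait t it draws moderators, a true study
effect

    θ_i = μ_t + βᵀ(x_i − x̄) + N(0, τ_t²),

and arm-level summary statistics: the control mean is drawn from the trait
scale, the high-VPD mean is the control mean times exp(θ_i), arm SDs come
from per-arm coefficients of variation, and the *observed* arm means are
normal sample means (mean, SD/√n) — so the realized log response ratio is a
noisy estimate of θ_i whose variance matches the delta-method formula.
Moderator contributions are centered at the scenario's central conditions
(e.g. the log VPD ratio at ln(1.6/0.4)), so μ_t remains the mean effect.

SDs are masked missing in study pairs with a configurable probability
(default 0.34, matching the two-thirds complete-SD share of the source
database); designated traits can be forced all-missing to exercise the
unit-weight fallback.

Per-trait random substreams are derived by stable hashing of the master
seed and the trait name, so adding or reordering traits never perturbs the
draws of another trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .catalog import (ALL_MISSING_SD_TRAITS, GAS_EXCHANGE_TRAITS,
                      TraitCatalog, default_catalog)
from .database import StudyDatabase, StudyRecord
from .util import derive_seed

# covariate marginals of the emulated database: VPD treatments segregate
# around 0.4 / 1.6 kPa, day temperature ~23 degC; plant groupings follow the
# reported species composition (74% dicots, 71% perennials, 70% non-crops,
# 90% forb-or-woody, 77% grown in hydroponics or artificial media).
_SOIL_PROBS = {"artificial": 0.42, "hydroponic": 0.35, "native": 0.08,
               "topsoil_mix": 0.08, "unspecified": 0.07}
_EVO_PROBS = {"dicot": 0.74, "monocot": 0.18, "gymnosperm": 0.05, "fern": 0.03}
_HABIT_PROBS = {"forb": 0.45, "woody": 0.45, "grass": 0.10}
_DURATION_PROBS = {"perennial": 0.71, "annual_biennial": 0.29}
_END_USE_PROBS = {"non_crop": 0.70, "crop": 0.30}


@dataclass
class TraitScenario:
    """True data-generating parameters for one trait."""
    name: str
    mu: float                     # true mean log response ratio
    tau: float = 0.1              # between-study SD of true effects
    k: int = 20                   # number of studies
    control_scale: float = 10.0   # typical control-arm mean (trait units)
    n_species: Optional[int] = None   # species pool (default: ~2 studies/species)
    beta: dict[str, float] = field(default_factory=dict)  # per-trait overrides
    force_all_missing_sd: bool = False


@dataclass
class GeneratorConfig:
    """Scenario definition for :func:`generate_database`."""
    traits: list[TraitScenario]
    beta: dict[str, float] = field(default_factory=dict)  # moderator -> coef
    cv_range: tuple[float, float] = (0.05, 0.30)
    n_range: tuple[int, int] = (3, 10)              # per-arm sample sizes
    vpd_control_mean: float = 0.4                   # kPa
    vpd_control_sd: float = 0.08
    vpd_high_mean: float = 1.6                      # kPa
    vpd_high_sd: float = 0.30
    day_temp_mean: float = 23.0                     # degC
    day_temp_sd: float = 2.0
    duration_range: tuple[float, float] = (5.0, 60.0)   # days
    plant_age_range: tuple[float, float] = (10.0, 100.0)
    missing_sd_prob: float = 0.34
    p_irrigation_frequent: float = 0.6
    max_studies_per_paper: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not self.traits:
            raise ValueError("config needs at least one trait")
        if not 0.0 <= self.missing_sd_prob <= 1.0:
            raise ValueError("missing_sd_prob must be in [0, 1]")
        if not 0.0 <= self.p_irrigation_frequent <= 1.0:
            raise ValueError("p_irrigation_frequent must be in [0, 1]")
        lo, hi = self.cv_range
        if not 0 < lo <= hi:
            raise ValueError("cv_range must be positive and ordered")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValueError("n_range must be ordered with minimum >= 2")
        for t in self.traits:
            if t.tau < 0:
                raise ValueError(f"{t.name}: tau must be >= 0")
            if t.k < 1:
                raise ValueError(f"{t.name}: k must be >= 1")
            if t.control_scale <= 0:
                raise ValueError(f"{t.name}: control scale must be positive")


@dataclass
class SyntheticTruth:
    """What the generator actually planted, for recovery tests."""
    mu: dict[str, float]
    tau: dict[str, float]
    beta: dict[str, dict[str, float]]       # trait -> moderator -> coef
    theta: dict[str, float]                 # study_id -> true effect
    missing_mask: dict[str, bool]           # study_id -> SDs masked?


def _categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    names = list(probs)
    return names[rng.choice(len(names), p=np.array(list(probs.values())))]


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     floor: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    return float(floor + abs(rng.normal(0.0, sd)))  # pathological configs only


def generate_database(config: GeneratorConfig,
                      catalog: Optional[TraitCatalog] = None
                      ) -> tuple[StudyDatabase, SyntheticTruth]:
    """Draw a study database and the truth object describing it."""
    config.validate()
    catalog = catalog if catalog is not None else default_catalog()
    records: list[StudyRecord] = []
    truth = SyntheticTruth(mu={}, tau={}, beta={}, theta={}, missing_mask={})
    central_lvr = float(np.log(config.vpd_high_mean / config.vpd_control_mean))
    for t_idx, tr in enumerate(config.traits):
        rng = np.random.default_rng(derive_seed(config.seed, "trait", tr.name))
        beta = {**config.beta, **tr.beta}
        truth.mu[tr.name] = tr.mu
        truth.tau[tr.name] = tr.tau
        truth.beta[tr.name] = dict(beta)
        n_species = tr.n_species or max(1, (tr.k + 1) // 2)
        # first N studies get distinct species so N is exactly attained,
        # remaining studies reuse the pool (N < n cases occur)
        species_idx = list(range(n_species))
        if tr.k > n_species:
            species_idx += list(rng.integers(0, n_species,
                                             size=tr.k - n_species))
        rng.shuffle(species_idx)
        for i in range(tr.k):
            sid = f"T{t_idx:02d}S{i:03d}"
            paper = f"P{t_idx:02d}_{i // config.max_studies_per_paper:03d}"
            vpd_c = _positive_normal(rng, config.vpd_control_mean,
                                     config.vpd_control_sd, 0.05)
            vpd_h = _positive_normal(rng, config.vpd_high_mean,
                                     config.vpd_high_sd, vpd_c + 0.1)
            day_temp = float(rng.normal(config.day_temp_mean,
                                        config.day_temp_sd))
            irrigation = ("hydroponic_or_daily"
                          if rng.random() < config.p_irrigation_frequent
                          else "less_than_daily_or_unreported")
            soil = _categorical(rng, _SOIL_PROBS)
            duration = float(rng.uniform(*config.duration_range))
            age = float(rng.uniform(*config.plant_age_range))
            evo = _categorical(rng, _EVO_PROBS)
            habit = _categorical(rng, _HABIT_PROBS)
            gdur = _categorical(rng, _DURATION_PROBS)
            end_use = _categorical(rng, _END_USE_PROBS)
            cond = ("SC" if rng.random() < 0.5 else "DC") \
                if tr.name in GAS_EXCHANGE_TRAITS else "NA"

            # true effect: moderator contributions centered at the scenario's
            # central conditions so mu stays the mean effect
            theta = tr.mu + tr.tau * rng.standard_normal()
            values = {
                "log_vpd_ratio": float(np.log(vpd_h / vpd_c)) - central_lvr,
                "day_temp": day_temp - config.day_temp_mean,
                "treatment_duration": duration - np.mean(config.duration_range),
                "plant_age": age - np.mean(config.plant_age_range),
                "irrigation": 1.0 if irrigation == "less_than_daily_or_unreported" else 0.0,
                "evolutionary_history": 1.0 if evo != "dicot" else 0.0,
                "growth_habit": 1.0 if habit != "forb" else 0.0,
                "growth_duration": 1.0 if gdur != "annual_biennial" else 0.0,
                "end_use": 1.0 if end_use != "crop" else 0.0,
            }
            for mod, coef in beta.items():
                theta += coef * values.get(mod, 0.0)
            truth.theta[sid] = theta

            m_c = float(tr.control_scale * rng.lognormal(0.0, 0.3))
            m_h = m_c * float(np.exp(theta))
            cv_c, cv_h = rng.uniform(*config.cv_range, size=2)
            n_c = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
            n_h = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
            sd_c, sd_h = cv_c * m_c, cv_h * m_h
            obs_c = _positive_normal(rng, m_c, sd_c / np.sqrt(n_c), 1e-9)
            obs_h = _positive_normal(rng, m_h, sd_h / np.sqrt(n_h), 1e-9)
            mask = (tr.force_all_missing_sd
                    or rng.random() < config.missing_sd_prob)
            truth.missing_mask[sid] = bool(mask)
            g = species_idx[i]
            records.append(StudyRecord(
                paper_id=paper, study_id=sid,
                species=f"species_{t_idx:02d}_{g:03d}",
                family=f"family_{g % 20:02d}", trait=tr.name,
                mean_control=obs_c, mean_high=obs_h,
                sd_control=None if mask else float(sd_c),
                sd_high=None if mask else float(sd_h),
                n_control=n_c, n_high=n_h,
                vpd_control=vpd_c, vpd_high=vpd_h, day_temp=day_temp,
                irrigation=irrigation, soil_type=soil,
                treatment_duration=duration, plant_age=age,
                evolutionary_history=evo, growth_habit=habit,
                growth_duration=gdur, end_use=end_use,
                measurement_condition=cond))
    db = StudyDatabase(records, catalog=catalog,
                       provenance=f"synthetic (seed={config.seed})")
    return db, truth


# true mean log response ratios for the paper-like scenario: conductance,
# leaf/biomass and height traits shrink under high VPD, transpiration and
# leaf nitrogen increase; unlisted traits are left at zero mean effect.
_PAPERLIKE_MU = {
    "whole_plant_transpiration_rate": 0.30,
    "leaf_transpiration_rate": 0.25,
    "stomatal_conductance": -0.15,
    "photosynthetic_rate": -0.10,
    "leaf_area": -0.15,
    "leaf_dry_mass": -0.15,
    "specific_leaf_area": -0.08,
    "stomatal_density": 0.08,
    "whole_plant_dry_mass": -0.20,
    "shoot_dry_mass": -0.20,
    "root_dry_mass": -0.15,
    "plant_height": -0.12,
    "leaf_number": -0.10,
    "yield": -0.15,
    "leaf_n": 0.10,
}

# traits where the strength of the VPD manipulation itself modulates the
# effect (slope on the centered log VPD ratio)
_PAPERLIKE_SLOPES = {
    "whole_plant_transpiration_rate": 0.30,
    "shoot_dry_mass": -0.30,
    "plant_height": -0.25,
}


def scenario_paperlike(seed: int = 0,
                       scale: float = 1.0) -> GeneratorConfig:
    """The packaged scenario emulating the source database.

    All 59 catalog traits, study and species counts echoing the catalog's
    reference counts, VPD marginals centered at 0.4 / 1.6 kPa, day
    temperature around 23 degC, ~66% of studies with complete SDs, and the
    three all-missing-SD traits forced onto the unit-weight path.  ``scale``
    multiplies every per-trait study count (for scaled-down test runs).
    """
    catalog = default_catalog()
    traits = []
    for entry in catalog.values():
        k = max(1, round(entry.n_studies * scale))
        n_sp = max(1, min(k, round(entry.n_species * scale)))
        traits.append(TraitScenario(
            name=entry.name,
            mu=_PAPERLIKE_MU.get(entry.name, 0.0),
            tau=0.10,
            k=k,
            control_scale=10.0,
            n_species=n_sp,
            beta={"log_vpd_ratio": _PAPERLIKE_SLOPES[entry.name]}
            if entry.name in _PAPERLIKE_SLOPES else {},
            force_all_missing_sd=entry.name in ALL_MISSING_SD_TRAITS))
    return GeneratorConfig(traits=traits, seed=seed)


def degrade(db: StudyDatabase, missing_prob: float,
            seed: int = 0) -> StudyDatabase:
    """Mask each study's SD pair missing with probability ``missing_prob``.

    Never unmasks an already-missing SD; at probability 0 the database is
    returned unchanged (as a copy).
    """
    if not 0.0 <= missing_prob <= 1.0:
        raise ValueError("missing_prob must be in [0, 1]")
    out = db.copy()
    rng = np.random.default_rng(derive_seed(seed, "degrade"))
    for rec in out.records:
        if rng.random() < missing_prob:
            rec.sd_control = None
            rec.sd_high = None
    return out
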