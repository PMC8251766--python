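import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vpdmeta.database import StudyDatabase, StudyRecord

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_record(study_id="s1", trait="stomatal_conductance", **kw):
    """StudyRecord factory with sensible complete defaults."""
    defaults = dict(
        paper_id="p1", species="Solanum lycopersicum", family="Solanaceae",
        mean_control=100.0, mean_high=80.0, sd_control=10.0, sd_high=8.0,
        n_control=5, n_high=5, vpd_control=0.4, vpd_high=1.6, day_temp=23.0,
        irrigation="hydroponic_or_daily", soil_type="artificial",
        treatment_duration=14.0, plant_age=30.0,
        evolutionary_history="dicot", growth_habit="forb",
        growth_duration="annual_biennial", end_use="crop",
        measurement_condition="SC",
    )
    defaults.update(kw)
    return StudyRecord(study_id=study_id, trait=trait, **defaults)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_db():
    """2 SC + 3 DC conductance studies plus 2 leaf-area studies."""
    recs = [
        make_record("c1", measurement_condition="SC", species="A a"),
        make_record("c2", measurement_condition="SC", species="A a "),
        make_record("c3", measurement_condition="DC", species="B b"),
        make_record("c4", measurement_condition="DC", species="C c"),
        make_record("c5", measurement_condition="DC", species="C c"),
        make_record("a1", trait="leaf_area", measurement_condition="NA",
                    species="A a"),
        make_record("a2", trait="leaf_area", measurement_condition="NA",
                    sd_control=None, sd_high=None, species="D d"),
    ]
    return StudyDatabase(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
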