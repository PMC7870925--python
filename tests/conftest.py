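import datetime as dt
import warnings

import pytest

import nicu_los as nl


def make_record(pid="P1", **kw):
    """A minimal valid admission record for unit tests."""
    defaults = dict(
        patient_id=pid,
        site="urban",
        gestation_weeks=33.0,
        birth_weight_g=1800.0,
        sex="male",
        delivery_mode="cesarean",
        multiple_pregnancy=False,
        inborn=True,
        antenatal_steroids="complete",
        maternal_disease=False,
        antenatal_infection=False,
        antenatal_risk_factor=False,
        need_ppv=False,
        apgar5_lt5=False,
        admission_date=dt.date(2019, 1, 1),
        los_days=5,
    )
    defaults.update(kw)
    return nl.NeonateRecord(**defaults)


@pytest.fixture(scope="session")
def guidelines():
    return nl.load_default_guidelines()


@pytest.fixture(scope="session")
def small_cohort(guidelines):
    """A 300-patient synthetic cohort with ground truth (seed fixed)."""
    config = nl.SimulationConfig(n_patients=300, seed=42)
    return nl.simulate_cohort(config, guidelines)


@pytest.fixture(scope="session")
def small_summaries(small_cohort, guidelines):
    cohort, _ = small_cohort
    return nl.compute_deviation_summaries(cohort, guidelines)


@pytest.fixture(scope="session")
def small_design(small_cohort, small_summaries):
    from nicu_los.regression import build_design_table

    cohort, _ = small_cohort
    return build_design_table(cohort.records, small_summaries)


@pytest.fixture(scope="session")
def pipeline_result(small_cohort, guidelines):
    from nicu_los.pipeline import run_pipeline

    cohort, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cohort, guidelines, seed=42, payload_timestamp="2020-01-01T00:00:00Z")
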