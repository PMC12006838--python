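import datetime as dt

import pandas as pd
import pytest

from carenet.simulate import CountDistribution, GeneratorConfig, generate_cohort

BASE = dt.date(2010, 1, 1)


def day(offset: int) -> dt.date:
    """Day-offset helper anchored at 2010-01-01."""
    return BASE + dt.timedelta(days=offset)


def make_appointments(rows) -> pd.DataFrame:
    """Build an appointments frame from (patient, provider, date-or-offset)."""
    records = []
    for patient, provider, when in rows:
        if isinstance(when, int):
            when = day(when)
        elif isinstance(when, str):
            when = dt.date.fromisoformat(when)
        records.append((patient, provider, when))
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in records],
            "provider_id": [r[1] for r in records],
            "date": pd.to_datetime([r[2] for r in records]),
        }
    )


def make_registry(rows) -> pd.DataFrame:
    records = []
    for patient, diagnosed, stage in rows:
        if isinstance(diagnosed, str):
            diagnosed = dt.date.fromisoformat(diagnosed)
        records.append((patient, diagnosed, stage))
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in records],
            "diagnosis_date": pd.to_datetime([r[1] for r in records]),
            "stage": [r[2] for r in records],
        }
    )


def make_providers(rows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "provider_id": [r[0] for r in rows],
            "specialty": [r[1] for r in rows],
            "oncology_related": [bool(r[2]) for r in rows],
            "fte_status": [r[3] if len(r) > 3 else "unknown" for r in rows],
        }
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_patients=40,
        seed=7,
        provider_pool_size=60,
        providers_per_patient=CountDistribution(mean=6.0, dispersion=2.0),
        appointments_per_patient=CountDistribution(mean=20.0, dispersion=1.5),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(registry, providers, appointments) for a tiny deterministic cohort."""
    return generate_cohort(small_config)
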