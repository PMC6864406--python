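import pytest

from glyscreen import SimConfig, extract_cohort, generate_population


@pytest.fixture(scope="session")
def pop5000():
    """Reference synthetic population at reduced scale (5000 patients)."""
    return generate_population(SimConfig(n_patients=5000, seed=1))


@pytest.fixture(scope="session")
def cohort5000(pop5000):
    return extract_cohort(pop5000)


def make_bundle(
    patient_id="P1",
    sex="male",
    birth_offset=22000,
    smoking="never",
    dx_day=100,
    treat_day=120,
    hba1c=((250, 6.1),),
    weights=((50, 80.0),),
    bmis=((50, 29.0),),
    extra_purchases=(),
):
    """Hand-built patient bundle for rule-level tests."""
    from glyscreen import PatientBundle

    labs = [(d, "HGA1C", v) for d, v in hba1c]
    labs += [(d, "WEIGHT", v) for d, v in weights]
    labs += [(d, "BMI", v) for d, v in bmis]
    purchases = [(treat_day, "AD_BIGUANIDE", "")] if treat_day is not None else []
    purchases += [(d, cls, "") for d, cls in extra_purchases]
    return PatientBundle(
        patient_id=patient_id,
        sex=sex,
        birth_offset=birth_offset,
        smoking=smoking,
        diagnoses=[(dx_day, "DM2")] if dx_day is not None else [],
        purchases=sorted(purchases),
        labs=sorted(labs),
    )
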