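import pytest

from scdpipe import cohort as cohort_mod
from scdpipe import simulate


@pytest.fixture(scope="session")
def study_cohort():
    """Default-condition synthetic cohort, imputed and harmonized."""
    table = simulate.generate_cohort(simulate.SimulationParams(seed=11))
    table = cohort_mod.impute_missing(table, seed=1)
    table = cohort_mod.combine_depression(table)
    return table


@pytest.fixture(scope="session")
def smri_reference():
    """Default 69 HC / 39 AD synthetic case-control reference."""
    return simulate.generate_smri_reference(simulate.SMRIReferenceParams(seed=1))


@pytest.fixture(scope="session")
def severity_fit(smri_reference):
    """Severity model + residualization fit on the default reference."""
    from scdpipe import severity

    features = simulate.smri_feature_names()
    model, res_fit = severity.fit_severity_model(
        smri_reference, features, n_orthogonal=1, seed=0)
    return model, res_fit
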