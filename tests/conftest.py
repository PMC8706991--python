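import pytest

from formudoe import ResponseSurface, datasets


@pytest.fixture(scope="session")
def factors():
    return datasets.finasteride_factors()


@pytest.fixture(scope="session")
def study_design():
    return datasets.proniosome_design()


@pytest.fixture(scope="session")
def fitted_models(study_design):
    return {
        name: ResponseSurface(study_design, name).fit()
        for name in datasets.RESPONSE_COLUMNS
    }


@pytest.fixture(scope="session")
def study_goals(study_design):
    return datasets.default_goals(
        study_design,
        {"size_nm": "minimize", "ee_pct": "maximize", "dl_pct": "maximize"},
    )
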