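import pytest

import scoremr as smr


@pytest.fixture(scope="session")
def panel():
    return smr.make_snp_panel(1)


@pytest.fixture(scope="session")
def truth():
    return smr.default_truth()


@pytest.fixture(scope="session")
def clean_truth():
    """Textbook structural model: no confounding, no covariate effects."""
    return smr.TrueModel(
        confounder_effect_bmi=0.0,
        confounder_effect_vitd=0.0,
        age_effect_lnbmi=0.0,
        age_effect_lnvitd=0.0,
        female_effect_lnbmi=0.0,
        female_effect_lnvitd=0.0,
    )


@pytest.fixture(scope="session")
def small_collab(panel, truth):
    """Five cohorts of 2,000 under the default (confounded) truth."""
    specs = smr.small_specs(5, 2000)
    return smr.simulate_collaboration(specs, panel, truth, 11)
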