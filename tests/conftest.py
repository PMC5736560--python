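import math

import numpy as np
import pandas as pd
import pytest

from cytoage.models import StructuralModel, VariabilityModel, cv_percent_to_omega
from cytoage.simulate import (PanelEntry, apply_quantification_limits,
                              default_panel, generate_cohort,
                              simulate_concentrations)

#: reference SEB TNF-a parameterisation: infancy 4740 pg/mL, 12-y 10859 pg/mL,
#: between-subject CV 66%
SEB_TNFA = dict(beta0=4740.0, beta1=math.log(10859.0 / 4740.0) / 12.0,
                omega=cv_percent_to_omega(66.0), sigma=0.2)


def seb_tnfa_panel():
    return {("TNF-a", "SEB"): PanelEntry(
        StructuralModel("M2_exponential", SEB_TNFA["beta0"], SEB_TNFA["beta1"]),
        VariabilityModel(SEB_TNFA["omega"], SEB_TNFA["sigma"]))}


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(271, seed=1234)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def observations(cohort, panel):
    latent = simulate_concentrations(cohort, panel, seed=5678)
    return apply_quantification_limits(latent)


@pytest.fixture(scope="session")
def seb_tnfa_observations(cohort):
    latent = simulate_concentrations(cohort, seb_tnfa_panel(), seed=91)
    return apply_quantification_limits(latent)
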