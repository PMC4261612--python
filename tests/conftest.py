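"""Shared fixtures: reference parameter sets and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pytest

from clozapk import (
    GeneratorConfig,
    ModelStructureConfig,
    REFERENCE_RANDOM_EFFECTS,
    REFERENCE_RAT_ESTIMATES,
    REFERENCE_RESIDUALS,
    default_rat_design,
    generate_study,
)
from clozapk.estimation import FitResult


@pytest.fixture(scope="session")
def reference_params():
    return REFERENCE_RAT_ESTIMATES


@pytest.fixture(scope="session")
def default_structure():
    return ModelStructureConfig()


@pytest.fixture(scope="session")
def rat_design():
    return default_rat_design()


@pytest.fixture(scope="session")
def noisy_dataset(rat_design):
    """Paper-sized study (4+5 rats) with BAV and residual noise."""
    return generate_study(rat_design, GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def clean_dataset(rat_design):
    """Noise-free, zero-variability study: observations equal predictions."""
    return generate_study(
        rat_design, GeneratorConfig(seed=3, include_bav=False, include_residual=False)
    )


@pytest.fixture(scope="session")
def reference_fit(default_structure):
    """A FitResult carrying the reference estimates (no fitting involved)."""
    return FitResult(
        fixed_effects=REFERENCE_RAT_ESTIMATES,
        random_effects=REFERENCE_RANDOM_EFFECTS,
        residual=REFERENCE_RESIDUALS,
        ofv=float("nan"),
        method="laplace",
        structure=default_structure,
    )


@pytest.fixture(scope="session")
def human_config_dict():
    """Synthetic stand-in for the literature human plasma constants.

    The real constants are user configuration; these values are invented but
    physiologically plausible, for exercising the translation pipeline.
    """
    return dict(
        cl_clo_plasma=0.7,   # L/min (42 L/h total CL/F)
        v_clo_plasma=500.0,  # L
        ka_clo=0.012,        # 1/min
        cl_met_plasma=0.5,   # L/min
        v_met_plasma=400.0,  # L
        fm=0.5,
        fu=0.03,
    )


@pytest.fixture(scope="session")
def receptor_panel_dict():
    """Synthetic receptor panel (Kd values invented, provenance-tagged)."""
    return dict(
        receptors=[
            dict(name="D2", compound="clozapine", kd_nm=120.0, reference="synthetic-example"),
            dict(name="5HT2A", compound="clozapine", kd_nm=8.0, reference="synthetic-example"),
            dict(name="M1", compound="clozapine", kd_nm=6.0, reference="synthetic-example"),
            dict(name="alpha1", compound="clozapine", kd_nm=4.0, reference="synthetic-example"),
            dict(name="alpha2", compound="clozapine", kd_nm=90.0, reference="synthetic-example"),
            dict(name="H1", compound="clozapine", kd_nm=2.0, reference="synthetic-example"),
            dict(name="D2", compound="norclozapine", kd_nm=180.0, reference="synthetic-example"),
        ]
    )
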