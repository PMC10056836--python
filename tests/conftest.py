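"""Shared fixtures: small rendered cohorts and calibration stacks.

Everything is generated at test time from the synthetic module; rendered
fixtures are session-scoped because rendering is the slow step.
"""

from __future__ import annotations

import pytest

from spinedyn.synthetic import (
    CohortSpec,
    TrajectoryModel,
    default_model,
    render_protrusion_calibration,
    simulate_cohort,
)


def noiseless_model(**overrides) -> TrajectoryModel:
    """Generator preset with every stochastic knob off."""
    kwargs = dict(sigma_day=0.0, sigma_size=0.0, sigma_gain=0.0,
                  mouse_coupling_sd=0.0, shot_noise=False, read_noise_sd=0.0,
                  bleedthrough=0.0)
    kwargs.update(overrides)
    return TrajectoryModel(**kwargs)


@pytest.fixture(scope="session")
def calibration():
    """Noiseless fixture with sub- and supra-criterion protrusions."""
    stack, centerline = render_protrusion_calibration([0.375, 0.625])
    return stack, centerline


@pytest.fixture(scope="session")
def rendered_dendrite():
    """One rendered WT-CH dendrite (25 spines, default noise), six sessions."""
    spec = CohortSpec(n_mice_per_group=1, groups=("WT-CH",),
                      dendrites_per_mouse=1, spines_per_dendrite=(25, 25),
                      seed=11)
    return simulate_cohort(spec, default_model())


@pytest.fixture(scope="session")
def noiseless_trend_cohort():
    """Tiny noiseless cohort with a programmed receptor accumulation."""
    model = noiseless_model(
        glua2_trend={"WT-CH": (1.0, 1.0, 1.1, 1.15, 1.2, 1.2)})
    spec = CohortSpec(n_mice_per_group=1, groups=("WT-CH",),
                      dendrites_per_mouse=1, spines_per_dendrite=(8, 8),
                      seed=5)
    return simulate_cohort(spec, model), model
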