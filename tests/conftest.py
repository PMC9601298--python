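import numpy as np
import pytest

from poispair import ModelParams, PanelData, SimConfig, SubjectData, simulate_panel

# Study conditions used throughout the simulation checks.
TRUE_PARAMS = dict(
    alpha=np.array([0.5, 0.3]),
    beta=np.array([-0.3, 0.4]),
    sigma2=0.3,
    tau2=np.array([0.5, 0.8]),
    rho=np.array([0.4, 0.3]),
)


@pytest.fixture
def true_params() -> ModelParams:
    return ModelParams(**TRUE_PARAMS)


@pytest.fixture
def small_panel(true_params) -> PanelData:
    """A 50-subject, 10-time simulated panel at the reference conditions."""
    return simulate_panel(SimConfig(m=50, T=10, params=true_params, seed=7))


@pytest.fixture
def tiny_panel() -> PanelData:
    """Hand-written 2-subject, 2-time panel with intercept + one covariate."""
    return PanelData(
        subjects=[
            SubjectData(
                subject="a",
                times=[1, 2],
                y1=[3, 0],
                y2=[1, 2],
                Z=[[1.0, 0.2], [1.0, -0.1]],
                X=[[1.0, 0.5], [1.0, 0.3]],
            ),
            SubjectData(
                subject="b",
                times=[1, 2],
                y1=[0, 1],
                y2=[4, 0],
                Z=[[1.0, -0.4], [1.0, 0.6]],
                X=[[1.0, -0.2], [1.0, 0.1]],
            ),
        ],
        z_names=["intercept", "w"],
        x_names=["intercept", "v"],
    )


@pytest.fixture
def tiny_params() -> ModelParams:
    return ModelParams(
        alpha=np.array([0.1, -0.2]),
        beta=np.array([0.3, 0.15]),
        sigma2=0.12,
        tau2=np.array([0.25, 0.4]),
        rho=np.array([0.5, 0.2]),
    )
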