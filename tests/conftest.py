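import numpy as np
import pytest

from stochexpr import (
    GeneralizedModel,
    LoopModel,
    MultiphasicModel,
    SSAConfig,
    estimate_stationary,
    simulate,
    validate_model,
)
from stochexpr.model import build_rate_matrices


@pytest.fixture
def classical_model():
    """Single-state model with protein mean 20 and Fano factor 6."""
    return validate_model(
        GeneralizedModel(
            K=1, lambda_m=[2.0], gamma_m=[1.0], q=[[0.0]], lambda_p=[10.0], gamma_p=1.0
        )
    )


@pytest.fixture
def loop_std():
    """Inactivation loop with gamma_eff = 2, protein mean 2.4, Fano 2."""
    return LoopModel(
        lambda_m=2.0, gamma_1m=1.0, gamma_2m=1.0, q12=3.0, q21=2.0, lambda_p=4.8, gamma_p=2.0
    )


@pytest.fixture
def loop_std_matrices(loop_std):
    return build_rate_matrices(loop_std.to_generalized())


def draw_loop(rng, lo=0.1, hi=4.0) -> LoopModel:
    """Random positive-rate loop model for property tests."""
    r = rng.uniform(lo, hi, size=7)
    return LoopModel(
        lambda_m=r[0], gamma_1m=r[1], gamma_2m=r[2], q12=r[3], q21=r[4],
        lambda_p=r[5], gamma_p=r[6],
    )


def run_ssa(model, t_end, n_replicates, seed, burn_in=None):
    cfg = SSAConfig(
        model=model, t_end=t_end, n_replicates=n_replicates, seed=seed, burn_in=burn_in
    )
    return estimate_stationary(simulate(cfg), cfg), cfg


@pytest.fixture(scope="session")
def ssa_classical_est():
    """Session-shared SSA estimate for the classical model (mean 20, F 6)."""
    model = validate_model(
        GeneralizedModel(
            K=1, lambda_m=[2.0], gamma_m=[1.0], q=[[0.0]], lambda_p=[10.0], gamma_p=1.0
        )
    )
    est, _ = run_ssa(model, t_end=120.0, n_replicates=80, seed=1234)
    return est


@pytest.fixture(scope="session")
def ssa_loop_est():
    """Session-shared SSA estimate for the standard loop model (F = 2)."""
    model = LoopModel(
        lambda_m=2.0, gamma_1m=1.0, gamma_2m=1.0, q12=3.0, q21=2.0, lambda_p=4.8, gamma_p=2.0
    ).to_generalized()
    est, _ = run_ssa(model, t_end=150.0, n_replicates=80, seed=4321)
    return est


@pytest.fixture(scope="session")
def ssa_multiphasic_ests():
    """Session-shared SSA estimates for multiphasic chains, K = 2 and 5."""
    out = {}
    for K, seed in ((2, 99), (5, 199)):
        mm = MultiphasicModel(K=K, lambda_m=4.0, gamma_eff=1.0, lambda_p=2.0, gamma_p=1.0)
        est, _ = run_ssa(mm.to_generalized(), t_end=120.0, n_replicates=80, seed=seed)
        out[K] = (mm, est)
    return out
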