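"""Multiphasic (Erlang-lifetime) mRNA model.

An mRNA molecule passes through K sequential lifetime stages, each
exponentially distributed with rate K * gamma_eff, before degrading.
The total lifetime is Erlang(K, K * gamma_eff) with mean 1/gamma_eff
and variance 1/(K * gamma_eff^2): increasing K narrows the lifetime
distribution and with it the protein noise.  Translation proceeds at
the same rate lambda_p from every stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import GeneralizedModel, validate_model

__all__ = [
    "MultiphasicModel",
    "MultiphasicMoments",
    "multiphasic_moments",
    "multiphasic_fano",
]


@dataclass
class MultiphasicModel:
    """K lifetime stages, one transcription/translation/decay rate each."""

    K: int
    lambda_m: float
    gamma_eff: float
    lambda_p: float
    gamma_p: float

    def validate(self) -> "MultiphasicModel":
        if int(self.K) != self.K or self.K < 1:
            raise ParameterError(f"K must be a positive integer, got {self.K}")
        for name in ("lambda_m", "gamma_eff", "lambda_p", "gamma_p"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and nonnegative, got {v}")
        if self.gamma_eff <= 0:
            raise ParameterError("gamma_eff must be positive")
        if self.gamma_p <= 0:
            raise ParameterError("protein decay must be positive (gamma_p > 0)")
        return self

    def to_generalized(self) -> GeneralizedModel:
        """Embed as a K-state chain in the generalized model.

        Production feeds stage 1 only; stage i hands over to stage i+1
        at rate K*gamma_eff; only the last stage decays (same rate).
        """
        K = int(self.K)
        kg = K * self.gamma_eff
        lam_m = np.zeros(K)
        lam_m[0] = self.lambda_m
        gam_m = np.zeros(K)
        gam_m[-1] = kg
        q = np.zeros((K, K))
        for i in range(K - 1):
            q[i, i + 1] = kg
        model = GeneralizedModel(
            K=K,
            lambda_m=lam_m,
            gamma_m=gam_m,
            q=q,
            lambda_p=np.full(K, self.lambda_p),
            gamma_p=self.gamma_p,
        )
        return validate_model(model)


@dataclass
class MultiphasicMoments:
    """Stage means, first-order coefficients and the first two cumulants."""

    b0: np.ndarray
    b1: np.ndarray
    u: float
    v: float
    a1: float
    a2: float
    fano: float


def _vK(v: float, K: int) -> float:
    """v**K in log space; (K*g/(K*g+gp))**K tends smoothly to e^{-gp/g}."""
    return math.exp(K * math.log(v))


def multiphasic_moments(model: MultiphasicModel) -> MultiphasicMoments:
    """Closed-form stage means, b1 coefficients, cumulants and Fano factor.

    The stage means are all lambda_m / (K gamma_eff); the first-order
    coefficients satisfy the affine recursion b1(i) = u + v b1(i-1) with
    u = lambda_p lambda_m / (K gamma_eff (K gamma_eff + gamma_p)) and
    v = K gamma_eff / (K gamma_eff + gamma_p), whose closed form is
    b1(i) = u/(1-v) + v^(i-1) (u - u/(1-v)).
    """
    model.validate()
    K = int(model.K)
    kg = K * model.gamma_eff
    gp = model.gamma_p
    lm, lp = model.lambda_m, model.lambda_p
    b0 = np.full(K, lm / kg)
    u = lp * lm / (kg * (kg + gp))
    v = kg / (kg + gp)
    i = np.arange(1, K + 1)
    b1 = u / (1.0 - v) + v ** (i - 1) * (u - u / (1.0 - v))
    a1 = lp * lm / (gp * model.gamma_eff)
    a2 = lp * u * (K + v * (-1.0 - K + _vK(v, K))) / (2.0 * gp * (1.0 - v) ** 2)
    fano = 1.0 + 2.0 * a2 / a1 if a1 > 0 else 1.0
    return MultiphasicMoments(b0=b0, b1=b1, u=u, v=v, a1=a1, a2=a2, fano=fano)


def multiphasic_fano(model: MultiphasicModel) -> float:
    """Protein Fano factor from the closed display.

    F_m = 1 + (lambda_p/gamma_p) (1 + (gamma_eff/gamma_p)
              (-1 + (K gamma_eff / (K gamma_eff + gamma_p))^K)).

    At K = 1 this collapses to the classical two-stage value
    1 + lambda_p / (gamma_eff + gamma_p).
    """
    model.validate()
    K = int(model.K)
    kg = K * model.gamma_eff
    gp = model.gamma_p
    v = kg / (kg + gp)
    return 1.0 + model.lambda_p / gp * (
        1.0 + model.gamma_eff / gp * (-1.0 + _vK(v, K))
    )
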