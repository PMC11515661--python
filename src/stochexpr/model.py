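"""Generalized multi-state mRNA gene-expression model.

The model extends the classical two-stage (transcription-translation)
scheme by allowing an mRNA molecule to occupy one of K discrete states.
State i is produced at rate ``lambda_m[i]``, decays at rate
``gamma_m[i]``, converts to state j at rate ``q[i, j]``, and templates
translation at rate ``lambda_p[i]``; protein decays at rate ``gamma_p``.
All rates are first-order rate constants in arbitrary consistent time
units (no unit conversion is performed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, StructuralError

__all__ = [
    "GeneralizedModel",
    "RateMatrices",
    "validate_model",
    "build_rate_matrices",
    "load_model",
]

#: Reciprocal-condition-number threshold below which the decay-plus-transition
#: matrix A - Q^T is treated as singular (no degradation path).
RCOND_THRESHOLD = 1e-12


@dataclass
class GeneralizedModel:
    """Parameter bundle for the K-state mRNA model.

    Parameters
    ----------
    K : int
        Number of mRNA states (>= 1).
    lambda_m : array-like of shape (K,)
        Per-state mRNA production rates (>= 0).
    gamma_m : array-like of shape (K,)
        Per-state mRNA decay rates (>= 0).
    q : array-like of shape (K, K)
        State-transition rates; entry (i, j) is the i -> j rate for
        i != j. The diagonal is ignored and recomputed.
    lambda_p : array-like of shape (K,)
        Per-state translation rates (>= 0).
    gamma_p : float
        Protein decay rate (> 0).
    """

    K: int
    lambda_m: np.ndarray
    gamma_m: np.ndarray
    q: np.ndarray
    lambda_p: np.ndarray
    gamma_p: float

    def __post_init__(self):
        self.K = int(self.K)
        self.lambda_m = np.atleast_1d(np.asarray(self.lambda_m, dtype=float))
        self.gamma_m = np.atleast_1d(np.asarray(self.gamma_m, dtype=float))
        self.lambda_p = np.atleast_1d(np.asarray(self.lambda_p, dtype=float))
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        self.gamma_p = float(self.gamma_p)


@dataclass
class RateMatrices:
    """Matrix form of the model used by the steady-state recurrences.

    ``A`` is the diagonal decay matrix, ``Q`` the generator-style
    transition matrix whose rows sum to zero, ``B`` the diagonal
    translation matrix and ``C`` the production-rate column vector.
    """

    A: np.ndarray
    Q: np.ndarray
    B: np.ndarray
    C: np.ndarray
    gamma_p: float = field(default=np.nan)

    @property
    def K(self) -> int:
        return self.A.shape[0]

    @property
    def M(self) -> np.ndarray:
        """The system matrix A - Q^T appearing on the left of every solve."""
        return self.A - self.Q.T


def _check_vector(name: str, v: np.ndarray, K: int) -> None:
    if v.shape != (K,):
        raise ParameterError(f"{name} must have length K={K}, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ParameterError(f"{name} contains non-finite entries")
    if np.any(v < 0):
        raise ParameterError(f"{name} contains negative rates")


def validate_model(model: GeneralizedModel) -> GeneralizedModel:
    """Check all model invariants; return the model unchanged if valid.

    Raises
    ------
    ParameterError
        For a negative rate (naming the offending field), non-positive
        protein decay, or K < 1.
    StructuralError
        If the decay-plus-transition matrix A - Q^T is (numerically)
        singular, i.e. some occupied state never reaches degradation.
    """
    if model.K < 1:
        raise ParameterError(f"K must be a positive integer, got {model.K}")
    _check_vector("lambda_m", model.lambda_m, model.K)
    _check_vector("gamma_m", model.gamma_m, model.K)
    _check_vector("lambda_p", model.lambda_p, model.K)
    if model.q.shape != (model.K, model.K):
        raise ParameterError(
            f"q must be a {model.K}x{model.K} matrix, got shape {model.q.shape}"
        )
    if not np.all(np.isfinite(model.q)):
        raise ParameterError("q contains non-finite entries")
    off = model.q - np.diag(np.diag(model.q))
    if np.any(off < 0):
        raise ParameterError("q contains negative off-diagonal rates")
    if not np.isfinite(model.gamma_p) or model.gamma_p <= 0:
        raise ParameterError("protein decay must be positive (gamma_p > 0)")

    matrices = build_rate_matrices(model, _validated=True)
    m = matrices.M
    # Structural solvability: A - Q^T must be invertible for the stationary
    # means to exist.  Checked once here via the reciprocal condition number.
    if model.K == 1:
        rcond = abs(m[0, 0])
    else:
        s = np.linalg.svd(m, compute_uv=False)
        rcond = s[-1] / s[0] if s[0] > 0 else 0.0
    if rcond <= RCOND_THRESHOLD:
        raise StructuralError(
            "no degradation path: A - Q^T is singular "
            f"(reciprocal condition number {rcond:.2e})"
        )
    return model


def build_rate_matrices(model: GeneralizedModel, _validated: bool = False) -> RateMatrices:
    """Assemble the (A, Q, B, C) matrices from a validated model.

    The diagonal of the user-supplied ``q`` is discarded; Q's diagonal
    is always recomputed as minus the off-diagonal row sum.
    """
    K = model.K
    off = model.q - np.diag(np.diag(model.q))
    Q = off.copy()
    np.fill_diagonal(Q, -off.sum(axis=1))
    A = np.diag(model.gamma_m)
    B = np.diag(model.lambda_p)
    C = model.lambda_m.copy()
    return RateMatrices(A=A, Q=Q, B=B, C=C, gamma_p=model.gamma_p)


def load_model(source: str | Path | dict) -> GeneralizedModel:
    """Build a validated model from a JSON/YAML file or a plain dict.

    The document must contain keys ``K``, ``lambda_m``, ``gamma_m``,
    ``q`` (dense K x K array), ``lambda_p`` and ``gamma_p``.
    """
    if isinstance(source, dict):
        doc = source
    else:
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    try:
        model = GeneralizedModel(
            K=doc["K"],
            lambda_m=doc["lambda_m"],
            gamma_m=doc["gamma_m"],
            q=doc["q"],
            lambda_p=doc["lambda_p"],
            gamma_p=doc["gamma_p"],
        )
    except KeyError as exc:
        raise ParameterError(f"model config missing key {exc}") from exc
    return validate_model(model)
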