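"""Steady-state power-series solver for the generalized model.

The stationary generating function of the joint (mRNA states, protein)
copy-number distribution has the log-linear form

    ln G(x, y) = sum_{n>=1} a_n (y-1)^n
               + sum_i (x_i - 1) sum_{n>=0} b_n^(i) (y-1)^n,

where the coefficient vectors X_n = (b_n^(1), ..., b_n^(K)) solve the
triangular linear recurrence

    (A - Q^T) X_0 = C,
    (A - Q^T + n*gamma_p*I) X_n = B X_{n-1},      n >= 1,

and the protein factorial cumulants follow as
a_n = (1 / n gamma_p) sum_i lambda_p[i] b_{n-1}^(i).

From the cumulants a_n the factorial moments h_n are obtained by a
convolution recurrence, and the protein probability mass function by the
alternating factorial-moment inversion, evaluated in extended precision
because the moments grow rapidly while the probabilities are small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import mpmath as mp
import numpy as np

from .errors import ConvergenceError, ParameterError, PrecisionError, StructuralError
from .model import RateMatrices

__all__ = [
    "CoefficientTable",
    "ProteinDistribution",
    "solve_initial_coefficients",
    "solve_coefficient_recurrence",
    "solve_adaptive",
    "evaluate_generating_function",
    "mrna_marginal_summary",
    "factorial_moments",
    "protein_pmf",
    "protein_distribution",
    "protein_summary",
]


@dataclass
class CoefficientTable:
    """Solved power-series coefficients of the stationary solution.

    Row n of ``b`` holds X_n; ``a`` holds the factorial cumulants with
    the normalisation a_0 = 0.  The recurrence is triangular, so rows of
    a longer table extend -- never change -- those of a shorter one.
    """

    b: np.ndarray  # (N+1, K)
    a: np.ndarray  # (N+1,), a[0] == 0
    gamma_p: float
    converged: bool = True
    matrices: "RateMatrices | None" = None

    @property
    def order(self) -> int:
        return self.a.shape[0] - 1

    @property
    def K(self) -> int:
        return self.b.shape[1]


def solve_initial_coefficients(matrices: RateMatrices) -> np.ndarray:
    """Solve (A - Q^T) X_0 = C for the stationary mRNA means b_0^(i)."""
    m = matrices.M
    try:
        x0 = np.linalg.solve(m, matrices.C)
    except np.linalg.LinAlgError as exc:
        raise StructuralError("A - Q^T is singular; no stationary mRNA means") from exc
    return x0


def solve_coefficient_recurrence(
    matrices: RateMatrices, N: int, gamma_p: float | None = None
) -> CoefficientTable:
    """Solve the coefficient recurrence up to order N (N >= 1)."""
    if N < 1:
        raise ParameterError(f"truncation order N must be >= 1, got {N}")
    gp = matrices.gamma_p if gamma_p is None else float(gamma_p)
    if not np.isfinite(gp) or gp <= 0:
        raise ParameterError("protein decay must be positive (gamma_p > 0)")
    K = matrices.K
    m0 = matrices.M
    lam_p = np.diag(matrices.B)
    b = np.empty((N + 1, K))
    a = np.zeros(N + 1)
    b[0] = solve_initial_coefficients(matrices)
    eye = np.eye(K)
    for n in range(1, N + 1):
        rhs = lam_p * b[n - 1]
        b[n] = np.linalg.solve(m0 + n * gp * eye, rhs)
        a[n] = rhs.sum() / (n * gp)
    return CoefficientTable(b=b, a=a, gamma_p=gp, matrices=matrices)


def solve_adaptive(
    matrices: RateMatrices,
    gamma_p: float | None = None,
    y_points=(0.0,),
    tol: float = 1e-14,
    max_order: int = 500,
) -> CoefficientTable:
    """Grow the coefficient table until the cumulant series has converged.

    The order is doubled until |a_N| * max(1, |y-1|)^N < tol for the
    largest evaluation point requested, up to a hard cap ``max_order``.
    If the cap is reached first the table is returned with
    ``converged=False``.
    """
    w = max((abs(float(y) - 1.0) for y in np.atleast_1d(y_points)), default=0.0)
    scale = max(1.0, w)
    N = 16
    while True:
        table = solve_coefficient_recurrence(matrices, min(N, max_order), gamma_p)
        if abs(table.a[-1]) * scale ** table.order < tol:
            return table
        if N >= max_order:
            table.converged = False
            return table
        N *= 2


def evaluate_generating_function(
    coeffs: CoefficientTable, x, y: float, tol: float = 1e-10
) -> float:
    """Evaluate the truncated stationary generating function G(x, y).

    Raises
    ------
    ConvergenceError
        If the magnitude of the last retained series term exceeds
        ``tol``, i.e. the truncation has not converged at (x, y).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (coeffs.K,):
        raise ParameterError(f"x must have length K={coeffs.K}, got shape {x.shape}")
    w = float(y) - 1.0
    N = coeffs.order
    wn = w ** N
    last = abs(coeffs.a[N] * wn) + abs(((x - 1.0) * coeffs.b[N]).sum() * wn)
    if last > tol:
        raise ConvergenceError(
            f"series truncation at order {N} has not converged at y={y} "
            f"(last term magnitude {last:.3e} > tol {tol:.1e})",
            last_term=last,
        )
    powers = w ** np.arange(N + 1)
    phi = float(coeffs.a @ powers) + float((x - 1.0) @ (coeffs.b.T @ powers))
    return math.exp(phi)


@dataclass
class MRNASummary:
    """Per-state stationary mRNA means and Fano factors."""

    means: np.ndarray
    fano: np.ndarray


def mrna_marginal_summary(coeffs: CoefficientTable) -> MRNASummary:
    """Stationary mRNA marginal summaries.

    At y = 1 the generating function factorises into independent Poisson
    marginals with means b_0^(i); the Fano factor of every state is
    therefore exactly 1.
    """
    means = coeffs.b[0].copy()
    return MRNASummary(means=means, fano=np.ones_like(means))


def factorial_moments(a, M: int) -> np.ndarray:
    """Factorial moments h_0..h_M from factorial cumulants a_0..a_M.

    Implements the convolution recurrence
    h_n = sum_{i=0}^{n-1} (1 - i/n) a_{n-i} h_i with h_0 = 1.
    """
    a = np.asarray(a, dtype=float)
    if M > a.shape[0] - 1:
        raise ParameterError(
            f"M={M} exceeds available cumulants (order {a.shape[0] - 1})"
        )
    h = np.zeros(M + 1)
    h[0] = 1.0
    for n in range(1, M + 1):
        i = np.arange(n)
        h[n] = np.sum((1.0 - i / n) * a[n - i] * h[:n])
    return h


def _factorial_moments_mp(a, M: int) -> list:
    """Moment recurrence in the current mpmath working precision.

    Cumulants beyond the length of ``a`` are taken as zero, which is
    accurate once the cumulant series has converged.
    """
    amp = [v if isinstance(v, mp.mpf) else mp.mpf(float(v)) for v in a]
    h = [mp.mpf(1)]
    for n in range(1, M + 1):
        s = mp.mpf(0)
        for i in range(n):
            k = n - i
            if k < len(amp) and amp[k] != 0:
                s += (1 - mp.mpf(i) / n) * amp[k] * h[i]
        h.append(s)
    return h


@dataclass
class ProteinDistribution:
    """Recovered protein pmf with truncation metadata."""

    h: np.ndarray
    pmf: np.ndarray
    n_max: int
    tail_mass_bound: float
    precision_digits: int
    inversion_error: float = 0.0
    clamped: int = 0

    @property
    def mean(self) -> float:
        return float(np.arange(self.n_max + 1) @ self.pmf)


def _invert_mp(h: list, n_max: int) -> tuple[list, float]:
    """Alternating factorial-moment inversion at working precision.

    p(n) = sum_{j>=0} (-1)^j C(n+j, n) h_{n+j}; the truncation error of
    each alternating sum is estimated by the magnitude of its last term.
    """
    M = len(h) - 1
    pmf = []
    worst_last = mp.mpf(0)
    for n in range(n_max + 1):
        s = mp.mpf(0)
        term = mp.mpf(0)
        for j in range(M - n + 1):
            term = mp.binomial(n + j, n) * h[n + j] * (-1) ** j
            s += term
        if M - n >= 1:
            worst_last = max(worst_last, abs(term))
        pmf.append(s)
    return pmf, float(worst_last)


def _solve_cumulants_mp(matrices: RateMatrices, gamma_p: float, N: int) -> list:
    """Cumulants a_0..a_N by the coefficient recurrence at working precision.

    Double-precision cumulants are accurate only in a relative sense;
    the alternating inversion amplifies their *absolute* truncation
    error by binomial factors, so for the pmf the whole triangular
    recurrence is re-run in mpmath.
    """
    K = matrices.K
    m0 = mp.matrix([[mp.mpf(matrices.M[i, j]) for j in range(K)] for i in range(K)])
    lam_p = [mp.mpf(v) for v in np.diag(matrices.B)]
    gp = mp.mpf(gamma_p)
    x = mp.lu_solve(m0, mp.matrix([mp.mpf(v) for v in matrices.C]))
    a = [mp.mpf(0)]
    for n in range(1, N + 1):
        rhs = mp.matrix([lam_p[i] * x[i] for i in range(K)])
        a.append(sum(rhs) / (n * gp))
        lhs = m0 + n * gp * mp.eye(K)
        x = mp.lu_solve(lhs, rhs)
    return a


def protein_pmf(h, n_max: int, precision_digits: int = 50) -> ProteinDistribution:
    """Recover the protein pmf on 0..n_max from factorial moments.

    The alternating inversion sum suffers severe cancellation (moments
    grow roughly like mean^n / n! times e^mean of headroom), so it is
    evaluated with ``precision_digits`` decimal digits and rounded to
    double at the end.  Tiny negative round-off values (magnitude below
    1e-12) are clamped to zero and counted in ``clamped``.

    ``h`` should carry enough orders that the alternating tail has
    decayed; otherwise a PrecisionError is raised.
    """
    with mp.workdps(precision_digits):
        hs = [v if isinstance(v, mp.mpf) else mp.mpf(float(v)) for v in h]
        M = len(hs) - 1
        if M < n_max:
            raise ParameterError(
                f"need factorial moments up to at least n_max={n_max}, got order {M}"
            )
        pmf_mp, worst_last = _invert_mp(hs, n_max)
        if worst_last > 1e-12:
            raise PrecisionError(
                "alternating inversion did not converge at the working "
                f"precision (last-term magnitude {worst_last:.3e}); supply "
                "higher-order moments, more digits, or a smaller n_max"
            )
        pmf = np.array([float(p) for p in pmf_mp])
    clamped = int(np.sum((pmf < 0) & (pmf > -1e-12)))
    pmf[(pmf < 0) & (pmf > -1e-12)] = 0.0
    if np.any(pmf < 0):
        raise PrecisionError(
            f"pmf has negative entries beyond round-off (min {pmf.min():.3e}); "
            "increase precision_digits"
        )
    total = pmf.sum()
    tail = max(0.0, 1.0 - total)
    return ProteinDistribution(
        h=np.array([float(v) for v in h], dtype=float),
        pmf=pmf,
        n_max=n_max,
        tail_mass_bound=tail,
        precision_digits=precision_digits,
        inversion_error=worst_last,
        clamped=clamped,
    )


def protein_distribution(
    coeffs: CoefficientTable,
    n_max: int | None = None,
    precision_digits: int | None = None,
) -> ProteinDistribution:
    """Protein pmf straight from a converged coefficient table.

    Factorial moments are recomputed from the cumulants at the working
    precision (double-precision moments would destroy the alternating
    sum for means beyond ~10), with sensible defaults for the support
    truncation and the number of digits.
    """
    a1 = coeffs.a[1] if coeffs.order >= 1 else 0.0
    a2 = coeffs.a[2] if coeffs.order >= 2 else 0.0
    fano = 1.0 + 2.0 * a2 / a1 if a1 > 0 else 1.0
    if n_max is None:
        n_max = int(math.ceil(a1 + 12.0 * math.sqrt(max(a1 * fano, 1.0)) + 25))
    if precision_digits is None:
        precision_digits = max(50, int(1.5 * a1) + 40)
    with mp.workdps(precision_digits):
        if coeffs.matrices is not None:
            # re-run the cumulant recurrence at working precision, far enough
            # for the neglected cumulants to be invisible at this dps
            floor = mp.mpf(10) ** (-(precision_digits + 10))
            N = max(coeffs.order, 32)
            while True:
                amp = _solve_cumulants_mp(coeffs.matrices, coeffs.gamma_p, N)
                if abs(amp[-1]) < floor or N >= 1000:
                    break
                N *= 2
        else:
            amp = [mp.mpf(float(v)) for v in coeffs.a]
        # grow the moment order until the alternating tails have decayed;
        # terms peak near j ~ mean and then fall off factorially
        M = n_max + max(60, int(3.0 * a1) + 20)
        while True:
            h = _factorial_moments_mp(amp, M)
            try:
                return protein_pmf(h, n_max, precision_digits)
            except PrecisionError:
                if M >= n_max + 1500:
                    raise
                M *= 2


@dataclass
class ProteinSummary:
    """First two protein moments in Fano/CV^2 form."""

    mean: float
    fano: float
    cv2: float
    degenerate: bool = False


def protein_summary(coeffs: CoefficientTable) -> ProteinSummary:
    """Protein mean a_1 and Fano factor 1 + 2 a_2 / a_1.

    A mean-zero (degenerate) distribution has an undefined 0/0 Fano
    factor; it is reported as 1 with ``degenerate=True`` so downstream
    summaries stay total.
    """
    if coeffs.order < 2:
        raise ParameterError("need cumulants up to order 2 for the Fano factor")
    a1, a2 = coeffs.a[1], coeffs.a[2]
    if a1 <= 0:
        return ProteinSummary(mean=0.0, fano=1.0, cv2=float("nan"), degenerate=True)
    fano = 1.0 + 2.0 * a2 / a1
    return ProteinSummary(mean=a1, fano=fano, cv2=fano / a1)
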