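"""Exact stochastic simulation (Gillespie direct method) oracle.

Simulates the generalized model's reaction network event by event:
production lambda_m[i], decay gamma_m[i]*m_i, conversions q[i,j]*m_i,
translation lambda_p[i]*m_i and protein decay gamma_p*n.  Stationary
moments are estimated by time-averaging each replicate after a burn-in,
with standard errors taken from the spread across independent
replicates (never from within-trajectory samples, which are strongly
autocorrelated).  Randomness comes from numpy's PCG64 generator; a
fixed seed makes the event sequence bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .model import GeneralizedModel, build_rate_matrices, validate_model
from .solver import solve_initial_coefficients

__all__ = ["SSAConfig", "Trajectory", "MomentEstimates", "simulate", "estimate_stationary"]


@dataclass
class SSAConfig:
    """Simulation protocol for the SSA oracle.

    ``burn_in`` defaults to 10 relaxation times, where the relaxation
    time is the slower of protein decay and effective mRNA decay; the
    default is overridable for stiff parameter sets.
    """

    model: GeneralizedModel
    t_end: float
    n_replicates: int = 1
    burn_in: float | None = None
    sample_interval: float | None = None
    seed: int = 0

    def resolved_burn_in(self) -> float:
        if self.burn_in is not None:
            return self.burn_in
        validate_model(self.model)
        mats = build_rate_matrices(self.model)
        b0 = solve_initial_coefficients(mats)
        total_m = b0.sum()
        lam_total = self.model.lambda_m.sum()
        if total_m > 0 and lam_total > 0:
            gamma_eff = lam_total / total_m
        else:
            positive = self.model.gamma_m[self.model.gamma_m > 0]
            gamma_eff = positive.min() if positive.size else self.model.gamma_p
        return 10.0 * max(1.0 / self.model.gamma_p, 1.0 / gamma_eff)

    def validate(self) -> "SSAConfig":
        validate_model(self.model)
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        burn = self.resolved_burn_in()
        if not (self.t_end > burn >= 0):
            raise ParameterError(
                f"need t_end > burn_in >= 0, got t_end={self.t_end}, burn_in={burn}"
            )
        return self


@dataclass
class Trajectory:
    """Event times and post-event states (m_1..m_K, n) of one replicate."""

    times: np.ndarray  # (n_events + 1,), starts at 0
    states: np.ndarray  # (n_events + 1, K + 1), integer copy numbers
    absorbed: bool = False  # halted in a zero-propensity state


def _reaction_table(model: GeneralizedModel):
    """Flat list of reactions as (kind, i, j) index tuples.

    Kinds: 0 production into i, 1 decay of i, 2 conversion i->j,
    3 translation from i, 4 protein decay.
    """
    K = model.K
    rxns = []
    for i in range(K):
        if model.lambda_m[i] > 0:
            rxns.append((0, i, -1, model.lambda_m[i]))
    for i in range(K):
        if model.gamma_m[i] > 0:
            rxns.append((1, i, -1, model.gamma_m[i]))
    for i in range(K):
        for j in range(K):
            if i != j and model.q[i, j] > 0:
                rxns.append((2, i, j, model.q[i, j]))
    for i in range(K):
        if model.lambda_p[i] > 0:
            rxns.append((3, i, -1, model.lambda_p[i]))
    rxns.append((4, -1, -1, model.gamma_p))
    return rxns


def _simulate_one(model: GeneralizedModel, t_end: float, rng: np.random.Generator) -> Trajectory:
    K = model.K
    rxns = _reaction_table(model)
    n_rxn = len(rxns)
    m = [0] * K
    n = 0
    t = 0.0
    times = [0.0]
    states = [tuple(m) + (n,)]
    props = [0.0] * n_rxn
    absorbed = False
    while True:
        total = 0.0
        for r in range(n_rxn):
            kind, i, j, rate = rxns[r]
            if kind == 0:
                p = rate
            elif kind == 4:
                p = rate * n
            else:
                p = rate * m[i]
            props[r] = p
            total += p
        if total <= 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = rng.random() * total
        acc = 0.0
        for r in range(n_rxn):
            acc += props[r]
            if u <= acc:
                break
        kind, i, j, _ = rxns[r]
        if kind == 0:
            m[i] += 1
        elif kind == 1:
            m[i] -= 1
        elif kind == 2:
            m[i] -= 1
            m[j] += 1
        elif kind == 3:
            n += 1
        else:
            n -= 1
        times.append(t)
        states.append(tuple(m) + (n,))
    return Trajectory(
        times=np.asarray(times), states=np.asarray(states, dtype=np.int64), absorbed=absorbed
    )


def simulate(config: SSAConfig) -> list[Trajectory]:
    """Run ``n_replicates`` independent trajectories up to ``t_end``.

    Replicate streams are spawned from a single SeedSequence, so the
    full output is reproducible from ``config.seed`` alone.  A model
    with no production halts in its absorbing empty state; the
    trajectory is returned with ``absorbed=True`` rather than erroring.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    return [
        _simulate_one(config.model, config.t_end, np.random.default_rng(s))
        for s in seeds
    ]


@dataclass
class MomentEstimates:
    """Replicate-averaged stationary moments with standard errors.

    Arrays are indexed by species: mRNA states 1..K first, protein
    last.  ``histogram`` is the time-weighted protein pmf estimate with
    per-bin standard errors across replicates.
    """

    mean: np.ndarray
    mean_se: np.ndarray
    variance: np.ndarray
    fano: np.ndarray
    fano_se: np.ndarray
    cv2: np.ndarray
    histogram: np.ndarray
    histogram_se: np.ndarray
    effective_sample_size: float
    low_ess_warning: bool = False


def _time_average(traj: Trajectory, burn_in: float, t_end: float):
    """Time-weighted first/second moments and protein dwell times."""
    t = np.minimum(np.maximum(traj.times, burn_in), t_end)
    t_next = np.append(t[1:], t_end if not traj.absorbed else max(t_end, t[-1]))
    dt = t_next - t
    span = dt.sum()
    if span <= 0:
        raise ParameterError("no stationary interval: burn_in >= trajectory span")
    s = traj.states.astype(float)
    mean = (s * dt[:, None]).sum(axis=0) / span
    second = (s**2 * dt[:, None]).sum(axis=0) / span
    prot = traj.states[:, -1]
    hist = np.bincount(prot, weights=dt)
    return mean, second, hist / span


def estimate_stationary(trajectories: list[Trajectory], config: SSAConfig) -> MomentEstimates:
    """Stationary moment estimates from simulated trajectories.

    Within-replicate time averages are combined across replicates; the
    standard errors are the replicate spread over sqrt(R).  The
    effective sample size counts protein relaxation times accumulated
    over all replicates; below 10 a warning flag is set.
    """
    burn = config.resolved_burn_in()
    t_end = config.t_end
    R = len(trajectories)
    means, seconds, hists = [], [], []
    for traj in trajectories:
        mean, second, hist = _time_average(traj, burn, t_end)
        means.append(mean)
        seconds.append(second)
        hists.append(hist)
    means = np.asarray(means)
    seconds = np.asarray(seconds)
    width = max(h.size for h in hists)
    H = np.zeros((R, width))
    for r, h in enumerate(hists):
        H[r, : h.size] = h

    mean = means.mean(axis=0)
    second = seconds.mean(axis=0)
    variance = np.maximum(second - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # replicates whose mean is zero contribute no Fano estimate; an
        # all-NaN column is legitimately summarised as NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        var_r = np.maximum(seconds - means**2, 0.0)
        fano_r = np.where(means > 0, var_r / np.where(means > 0, means, 1.0), np.nan)
        fano = np.nanmean(fano_r, axis=0)
        cv2 = np.where(mean > 0, variance / mean**2, np.nan)
        if R > 1:
            mean_se = means.std(axis=0, ddof=1) / np.sqrt(R)
            fano_se = np.nanstd(fano_r, axis=0, ddof=1) / np.sqrt(R)
            hist_se = H.std(axis=0, ddof=1) / np.sqrt(R)
        else:
            mean_se = np.full_like(mean, np.inf)
            fano_se = np.full_like(mean, np.inf)
            hist_se = np.full(width, np.inf)

    ess = R * (t_end - burn) * config.model.gamma_p
    low = ess < 10
    if low:
        warnings.warn(
            f"effective sample size {ess:.1f} < 10; estimates are unreliable",
            stacklevel=2,
        )
    return MomentEstimates(
        mean=mean,
        mean_se=mean_se,
        variance=variance,
        fano=fano,
        fano_se=fano_se,
        cv2=cv2,
        histogram=H.mean(axis=0),
        histogram_se=hist_se,
        effective_sample_size=float(ess),
        low_ess_warning=bool(low),
    )
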