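"""Dormancy detection and accelerometer imputation.

Phones go dormant (powered off, out of signal, airplane mode) mostly at
night, producing runs of hours with no accelerometer samples.  The hourly
missingness indicator is modeled with a 2-state hidden semi-Markov model
with Bernoulli state-dependent distributions and geometric dwell times.
A geometric dwell-time semi-Markov chain is exactly a first-order Markov
chain whose self-transition probability is the dwell parameter, so the
model is fitted as a plain 2-state Bernoulli-emission HMM by EM and
decoded with the Viterbi algorithm.

Missing mean accelerometer magnitudes X(t) are then filled with a
two-branch rule: hours labeled dormant get a floor value (a robust
"minimum excluding outliers" of the observed X), while non-dormant
missing hours are predicted from the screen-on count Y(t) by least
squares fitted on completely observed hours, clipped below at the floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import HourlySeries

MIN_SEQUENCE_LENGTH = 48
DEFAULT_FLOOR_QUANTILE = 0.025


class DegenerateSequenceError(ValueError):
    """Missingness indicator carries no signal (all observed or all missing).

    Callers should skip the HSMM and fall back to single-branch
    (regression-only) imputation.
    """


@dataclass
class DormancyModel:
    """Fitted 2-state Bernoulli-emission dormancy model.

    State 0 is "dormant" (higher probability of a missing hour); the dwell
    parameter of each state is its self-transition probability.
    """

    p_miss_dormant: float
    p_miss_active: float
    dwell_params: np.ndarray  # self-transition probability per state
    state_priors: np.ndarray
    labels: np.ndarray  # 1 = dormant, per hour
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in (self.p_miss_dormant, self.p_miss_active, *self.dwell_params, *self.state_priors):
            if not 0.0 <= p <= 1.0:
                raise ValueError("all model probabilities must lie in [0, 1]")
        if self.p_miss_dormant < self.p_miss_active:
            raise ValueError("canonical ordering requires p_miss_dormant >= p_miss_active")


@dataclass
class ImputationFit:
    """Parameters of the two-branch fill rule."""

    floor_value: float
    slope: float
    intercept: float
    n_complete: int


def _forward_backward_bernoulli(
    z: np.ndarray, pi: np.ndarray, A: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward for a Bernoulli-emission HMM; returns (gamma, xi_sum, loglik)."""
    T = len(z)
    B = np.where(z[:, None] == 1, p[None, :], 1.0 - p[None, :])  # (T, 2)
    B = np.clip(B, 1e-300, None)
    alpha = np.empty((T, 2))
    c = np.empty(T)
    alpha[0] = pi * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
        xi = alpha[t][:, None] * A * (B[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, xi_sum, float(np.log(c).sum())


def _viterbi_bernoulli(z: np.ndarray, pi: np.ndarray, A: np.ndarray, p: np.ndarray) -> np.ndarray:
    T = len(z)
    logB = np.log(np.clip(np.where(z[:, None] == 1, p[None, :], 1.0 - p[None, :]), 1e-300, None))
    logA = np.log(np.clip(A, 1e-300, None))
    delta = np.log(np.clip(pi, 1e-300, None)) + logB[0]
    back = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def fit_dormancy_hsmm(
    missing: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_restarts: int = 3,
    seed: int = 0,
) -> DormancyModel:
    """Fit the 2-state Bernoulli dormancy model to an hourly missingness indicator.

    EM with a fixed deterministic start (missingness probabilities split at
    0.9/0.1, symmetric 0.9 self-transitions) plus seeded random restarts;
    the best-likelihood fit is kept, states are reordered so state 0 has
    the higher missingness probability, and per-hour labels come from the
    most likely (Viterbi) state sequence.
    """
    z = np.asarray(missing).astype(int)
    if len(z) < MIN_SEQUENCE_LENGTH:
        raise ValueError(f"need at least {MIN_SEQUENCE_LENGTH} hours, got {len(z)}")
    if z.min() == z.max():
        raise DegenerateSequenceError(
            "missingness indicator is constant; skip the HSMM and use single-branch imputation"
        )

    rng = np.random.default_rng(seed)
    starts = [(np.array([0.9, 0.1]), np.array([[0.9, 0.1], [0.1, 0.9]]), np.array([0.5, 0.5]))]
    for _ in range(max(0, n_restarts - 1)):
        p0 = np.sort(rng.uniform(0.05, 0.95, size=2))[::-1]
        stay = rng.uniform(0.6, 0.98, size=2)
        A0 = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
        starts.append((p0, A0, rng.dirichlet([1, 1])))

    best: tuple[float, tuple, list[float]] | None = None
    for p, A, pi in starts:
        p, A, pi = p.copy(), A.copy(), pi.copy()
        trace: list[float] = []
        for _ in range(max_iter):
            gamma, xi_sum, ll = _forward_backward_bernoulli(z, pi, A, p)
            trace.append(ll)
            pi = gamma[0] / gamma[0].sum()
            A = xi_sum / np.clip(xi_sum.sum(axis=1, keepdims=True), 1e-300, None)
            denom = gamma.sum(axis=0)
            p = np.clip((gamma * z[:, None]).sum(axis=0) / np.clip(denom, 1e-300, None), 1e-6, 1 - 1e-6)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1):
                break
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], (p, A, pi), trace)

    assert best is not None
    _, (p, A, pi), trace = best
    order = np.argsort(-p)  # dormant (higher miss prob) first
    p, pi = p[order], pi[order]
    A = A[np.ix_(order, order)]
    path = _viterbi_bernoulli(z, pi, A, p)
    return DormancyModel(
        p_miss_dormant=float(p[0]),
        p_miss_active=float(p[1]),
        dwell_params=np.diag(A).copy(),
        state_priors=pi,
        labels=(path == 0).astype(int),
        loglik_trace=trace,
    )


def impute_accelerometer(
    series: HourlySeries,
    model: DormancyModel | None,
    floor_quantile: float = DEFAULT_FLOOR_QUANTILE,
) -> tuple[HourlySeries, ImputationFit]:
    """Fill missing X by the two-branch dormancy rule.

    Dormant-labeled missing hours get ``floor_value`` (the ``floor_quantile``
    quantile of observed X — a robust minimum); other missing hours are
    predicted from Y by least squares over completely observed hours,
    clipped below at the floor.  Observed values are never altered.  With
    ``model=None`` (degenerate missingness) every missing hour uses the
    regression branch.
    """
    x = series.data["X"].to_numpy(dtype=float)
    y = series.data["Y"].to_numpy(dtype=float)
    observed = ~np.isnan(x)
    if observed.sum() < 2:
        raise ValueError("imputation requires at least 2 hours with observed X")

    floor_value = float(np.quantile(x[observed], floor_quantile))
    res = stats.linregress(y[observed], x[observed]) if np.ptp(y[observed]) > 0 else None
    if res is None:  # constant Y among complete hours: fall back to their mean
        slope, intercept = 0.0, float(np.mean(x[observed]))
    else:
        slope, intercept = float(res.slope), float(res.intercept)

    if model is not None and len(model.labels) != len(series):
        raise ValueError("dormancy labels length must match the series")
    dormant = model.labels.astype(bool) if model is not None else np.zeros(len(series), dtype=bool)

    out = series.copy()
    filled = x.copy()
    miss = ~observed
    filled[miss & dormant] = floor_value
    pred = np.maximum(intercept + slope * y, floor_value)
    filled[miss & ~dormant] = pred[miss & ~dormant]
    out.data["X"] = filled
    out.data["imputed"] = miss
    out.data["dormant"] = dormant
    fit = ImputationFit(
        floor_value=floor_value,
        slope=slope,
        intercept=intercept,
        n_complete=int(observed.sum()),
    )
    return out, fit
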