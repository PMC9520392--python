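"""Mixed-effect continuous-time hidden Markov model of rest-activity rhythms.

Hourly screen-on counts Y(t) are emitted from one of two latent states —
rest (expected count near zero) and active (positive expected count) —
through state-dependent Poisson distributions.  The latent chain evolves
in continuous time with exponential proportional-hazard transition rates
carrying the mean accelerometer magnitude x(t) as a time-varying
covariate and a normally distributed random intercept for each of the
24 hours of the day:

    rest -> active:  lambda_1(t) = exp(alpha_1 + beta_1 x(t) + b_1[h(t)]),
                     b_1[h] ~ N(0, sigma_1^2)
    active -> rest:  lambda_2(t) = exp(alpha_2 + beta_2 x(t) + b_2[h(t)]),
                     b_2[h] ~ N(0, sigma_2^2)

Over a one-hour increment the transition probability matrix is the
matrix exponential Gamma(t) = exp(Q(t)) of the generator
Q = [[-l1, l1], [l2, -l2]] (state order: rest, active), for which the
2-state closed form is used.  Estimation is penalized EM: the E-step is
scaled forward-backward over the time-varying Gamma(t); the M-step
updates the Poisson means and initial distribution in closed form and
maximizes the expected transition log-likelihood over the hazard
parameters with a ridge penalty b^2 / (2 sigma^2) on each random
intercept (their MAP estimate under the normal model); the variances
are then updated as the mean of the 24 squared intercepts.  The summed
variances sigma_1^2 + sigma_2^2 are the Activity Rhythm Metric computed
downstream: a participant who rests and wakes at consistent clock hours
needs widely dispersed hour-of-day intercepts, hence a large ARM.

Runs of 24 or more consecutive originally-missing hours split the series
into segments whose likelihoods are treated as independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .features import HourlySeries

N_HOURS = 24
LOG_RATE_CLAMP = 30.0
SEGMENT_GAP_HOURS = 24

REST, ACTIVE = 0, 1  # latent state indices


class InsufficientDataError(ValueError):
    """Series too short (or too fragmented) to attempt a fit."""


@dataclass
class CTHMMParams:
    """Full parameter set of the mixed-effect CT-HMM."""

    alpha1: float  # rest->active log-hazard intercept
    beta1: float  # rest->active accelerometer coefficient
    alpha2: float  # active->rest log-hazard intercept
    beta2: float  # active->rest accelerometer coefficient
    b1: np.ndarray  # 24 hour-of-day intercepts, rest->active
    b2: np.ndarray  # 24 hour-of-day intercepts, active->rest
    sigma1_sq: float
    sigma2_sq: float
    mu_rest: float  # Poisson mean, rest state
    mu_active: float  # Poisson mean, active state
    delta: np.ndarray  # initial distribution over (rest, active)

    def __post_init__(self) -> None:
        self.b1 = np.asarray(self.b1, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.b1.shape != (N_HOURS,) or self.b2.shape != (N_HOURS,):
            raise ValueError("b1 and b2 must each have 24 entries")
        if self.sigma1_sq < 0 or self.sigma2_sq < 0:
            raise ValueError("variances must be non-negative")
        if self.mu_rest < 0 or self.mu_active < 0:
            raise ValueError("Poisson means must be non-negative")
        if abs(self.delta.sum() - 1.0) > 1e-8 or np.any(self.delta < 0):
            raise ValueError("delta must be a probability distribution")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("b1", "b2", "delta"):
            d[k] = list(map(float, d[k]))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CTHMMParams":
        return cls(**{**d, "b1": np.array(d["b1"]), "b2": np.array(d["b2"]), "delta": np.array(d["delta"])})


@dataclass(frozen=True)
class TransitionRates:
    lambda1: float  # rest->active, per hour
    lambda2: float  # active->rest, per hour

    def __post_init__(self) -> None:
        if not (self.lambda1 > 0 and np.isfinite(self.lambda1)):
            raise ValueError("lambda1 must be positive and finite")
        if not (self.lambda2 > 0 and np.isfinite(self.lambda2)):
            raise ValueError("lambda2 must be positive and finite")


@dataclass
class FitConfig:
    """Knobs of the EM fit; defaults follow the reference analysis protocol."""

    tol: float = 1e-6  # relative change in the penalized objective
    max_iter: int = 500
    min_hours: int = 336  # 14 days
    mstep_maxiter: int = 80
    sigma_init: float = 1.0  # ridge strength held fixed during the EM phase
    sigma_floor: float = 1e-4  # keeps the calibrated variances away from 0
    calibrate_sigma: bool = True  # Laplace fixed-point variance calibration after EM
    sigma_tol: float = 1e-4  # relative change stopping rule for the calibration
    sigma_max_iter: int = 200
    mu_rest_floor: float = 0.01
    collapse_tol: float = 0.1  # |mu_active - mu_rest| below this = state collapse
    standardize_x: bool = False
    fix_delta: np.ndarray | None = None
    seed: int = 0


@dataclass
class FittedModel:
    params: CTHMMParams
    loglik_trace: list[float]
    converged: bool
    state_posteriors: np.ndarray | None = None  # P(active) per modeled hour
    pairwise_posteriors: list[np.ndarray] | None = None  # xi per segment
    n_iter: int = 0
    message: str = ""
    segment_slices: list[tuple[int, int]] = field(default_factory=list)
    t_index: np.ndarray | None = None  # original hour indices of the modeled hours
    sigma_trace: list[tuple[float, float]] = field(default_factory=list)  # calibration path

    def to_json(self, path: str | Path) -> None:
        out = {
            "params": self.params.to_dict(),
            "loglik_trace": list(map(float, self.loglik_trace)),
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "message": self.message,
        }
        Path(path).write_text(json.dumps(out, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            params=CTHMMParams.from_dict(d["params"]),
            loglik_trace=d["loglik_trace"],
            converged=d["converged"],
            n_iter=d.get("n_iter", 0),
            message=d.get("message", ""),
        )


# ---------------------------------------------------------------------------
# Elementary model pieces
# ---------------------------------------------------------------------------


def log_rates(params: CTHMMParams, x: np.ndarray, hours: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamped log transition rates for arrays of covariates and clock hours."""
    eta1 = params.alpha1 + params.beta1 * x + params.b1[hours]
    eta2 = params.alpha2 + params.beta2 * x + params.b2[hours]
    return (
        np.clip(eta1, -LOG_RATE_CLAMP, LOG_RATE_CLAMP),
        np.clip(eta2, -LOG_RATE_CLAMP, LOG_RATE_CLAMP),
    )


def transition_rates(params: CTHMMParams, x: float, hour: int) -> TransitionRates:
    """Hazards of leaving rest (lambda1) and leaving active (lambda2) at one hour."""
    if not np.isfinite(x):
        raise ValueError("covariate x must be finite")
    if not 0 <= hour < N_HOURS:
        raise ValueError("hour must be in 0..23")
    e1, e2 = log_rates(params, np.array([x]), np.array([hour]))
    return TransitionRates(float(np.exp(e1[0])), float(np.exp(e2[0])))


def transition_matrix(rates: TransitionRates | tuple[float, float], dt: float = 1.0) -> np.ndarray:
    """Closed-form matrix exponential of the 2-state generator over dt hours.

    With s = l1 + l2 and A = (1 - e^{-s dt}) / s,
    Gamma = [[1 - l1 A, l1 A], [l2 A, 1 - l2 A]]; rows sum to one.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    l1, l2 = (rates.lambda1, rates.lambda2) if isinstance(rates, TransitionRates) else rates
    s = l1 + l2
    a = -np.expm1(-s * dt) / s  # stable for small s
    return np.array([[1.0 - l1 * a, l1 * a], [l2 * a, 1.0 - l2 * a]])


def transition_matrices(lam1: np.ndarray, lam2: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Vectorized closed form: stack of 2x2 matrices, shape (n, 2, 2)."""
    s = lam1 + lam2
    a = -np.expm1(-s * dt) / s
    g = np.empty((len(lam1), 2, 2))
    g[:, REST, ACTIVE] = lam1 * a
    g[:, REST, REST] = 1.0 - g[:, REST, ACTIVE]
    g[:, ACTIVE, REST] = lam2 * a
    g[:, ACTIVE, ACTIVE] = 1.0 - g[:, ACTIVE, REST]
    return g


def emission_logpmf(y: np.ndarray | int, state: int, params: CTHMMParams) -> np.ndarray | float:
    """Poisson log-pmf of screen-on counts under the given latent state."""
    arr = np.asarray(y)
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    mu = params.mu_rest if state == REST else params.mu_active
    out = stats.poisson.logpmf(arr, max(mu, 1e-12))
    return float(out) if np.isscalar(y) else out


def expected_holding_time(rate: float) -> float:
    """Expected time (hours) until leaving the current state: 1 / lambda."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return 1.0 / rate


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def split_segments(series: HourlySeries, gap_hours: int = SEGMENT_GAP_HOURS, min_len: int = 2) -> list[HourlySeries]:
    """Cut the series at runs of >= ``gap_hours`` consecutive originally-missing hours.

    Gap hours are dropped; hours missing in runs shorter than the gap are kept
    (they are expected to be imputed).  Pieces shorter than ``min_len`` are
    discarded.  Segment likelihoods are treated as independent downstream.
    """
    mask = series.missing_mask
    n = len(series)
    keep = np.ones(n, dtype=bool)
    boundaries = [0]
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= gap_hours:
                keep[i:j] = False
                boundaries.append(j)
            i = j
        else:
            i += 1
    segments: list[HourlySeries] = []
    boundaries.append(n)
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        idx = np.arange(lo, hi)[keep[lo:hi]]
        if len(idx) >= min_len:
            sub = series.data.iloc[idx].reset_index(drop=True)
            segments.append(HourlySeries(series.participant_id, sub, series.start_hour_epoch))
    return segments


# ---------------------------------------------------------------------------
# E-step: scaled forward-backward with time-varying transition matrices
# ---------------------------------------------------------------------------


def _emission_logB(y: np.ndarray, params: CTHMMParams) -> np.ndarray:
    logB = np.empty((len(y), 2))
    logB[:, REST] = stats.poisson.logpmf(y, max(params.mu_rest, 1e-12))
    logB[:, ACTIVE] = stats.poisson.logpmf(y, max(params.mu_active, 1e-12))
    return logB


def forward_backward(segment: HourlySeries, params: CTHMMParams) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior state and pairwise probabilities plus the exact log-likelihood.

    Returns ``(gamma, xi, loglik)`` with ``gamma`` of shape (T, 2) and ``xi``
    of shape (T-1, 2, 2); ``xi[t]`` is P(C_t = i, C_{t+1} = j | Y).
    """
    y = segment.data["Y"].to_numpy(dtype=int)
    x = segment.data["X"].to_numpy(dtype=float)
    hours = segment.data["hour_of_day"].to_numpy(dtype=int)
    if np.any(~np.isfinite(x)):
        raise ValueError("segment contains missing X; impute before fitting")
    e1, e2 = log_rates(params, x[:-1], hours[:-1])
    gammas = transition_matrices(np.exp(e1), np.exp(e2))
    logB = _emission_logB(y, params)
    return _forward_backward_core(logB, gammas, params.delta)


def _forward_backward_core(
    logB: np.ndarray, gammas: np.ndarray, delta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    T = logB.shape[0]
    # per-time shift keeps the scaled recursion in range even for extreme pmfs
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    alpha = np.empty((T, 2))
    c = np.empty(T)
    a = delta * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ gammas[t - 1]) * B[t]
        c[t] = a.sum()
        if not np.isfinite(c[t]) or c[t] <= 0:
            raise FloatingPointError(f"forward recursion degenerate at t={t}")
        alpha[t] = a / c[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    xi = np.empty((T - 1, 2, 2)) if T > 1 else np.empty((0, 2, 2))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (gammas[t] @ bb) / c[t + 1]
        xi[t] = alpha[t][:, None] * gammas[t] * bb[None, :] / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi, loglik


# ---------------------------------------------------------------------------
# M-step: penalized transition-hazard maximization
# ---------------------------------------------------------------------------


def _pack(params: CTHMMParams) -> np.ndarray:
    return np.concatenate([[params.alpha1, params.beta1], params.b1, [params.alpha2, params.beta2], params.b2])


def _unpack(theta: np.ndarray) -> tuple[float, float, np.ndarray, float, float, np.ndarray]:
    return theta[0], theta[1], theta[2:26], theta[26], theta[27], theta[28:52]


def _transition_objective(
    theta: np.ndarray,
    x: np.ndarray,
    hours: np.ndarray,
    xi: np.ndarray,
    sigma1_sq: float,
    sigma2_sq: float,
) -> tuple[float, np.ndarray]:
    """Negative expected transition log-likelihood with ridge penalty, and gradient.

    ``x``, ``hours`` and ``xi`` are the concatenation over segments of the
    per-transition covariate, clock hour, and pairwise posterior.
    """
    a1, be1, b1, a2, be2, b2 = _unpack(theta)
    eta1_raw = a1 + be1 * x + b1[hours]
    eta2_raw = a2 + be2 * x + b2[hours]
    eta1 = np.clip(eta1_raw, -LOG_RATE_CLAMP, LOG_RATE_CLAMP)
    eta2 = np.clip(eta2_raw, -LOG_RATE_CLAMP, LOG_RATE_CLAMP)
    l1, l2 = np.exp(eta1), np.exp(eta2)
    s = l1 + l2
    E = np.exp(-s)
    A = -np.expm1(-s) / s
    g01 = l1 * A
    g10 = l2 * A
    g00 = 1.0 - g01
    g11 = 1.0 - g10
    eps = 1e-300
    Q = (
        xi[:, REST, REST] * np.log(g00 + eps)
        + xi[:, REST, ACTIVE] * np.log(g01 + eps)
        + xi[:, ACTIVE, REST] * np.log(g10 + eps)
        + xi[:, ACTIVE, ACTIVE] * np.log(g11 + eps)
    ).sum()
    pen = (b1 @ b1) / (2.0 * sigma1_sq) + (b2 @ b2) / (2.0 * sigma2_sq)

    # gradient via dGamma/dlambda of the closed form
    dAds = (E - A) / s
    r01 = xi[:, REST, ACTIVE] / (g01 + eps) - xi[:, REST, REST] / (g00 + eps)
    r10 = xi[:, ACTIVE, REST] / (g10 + eps) - xi[:, ACTIVE, ACTIVE] / (g11 + eps)
    dQ_dl1 = r01 * (A + l1 * dAds) + r10 * (l2 * dAds)
    dQ_dl2 = r01 * (l1 * dAds) + r10 * (A + l2 * dAds)
    w1 = dQ_dl1 * l1 * (np.abs(eta1_raw) < LOG_RATE_CLAMP)
    w2 = dQ_dl2 * l2 * (np.abs(eta2_raw) < LOG_RATE_CLAMP)
    g_b1 = np.bincount(hours, weights=w1, minlength=N_HOURS) - b1 / sigma1_sq
    g_b2 = np.bincount(hours, weights=w2, minlength=N_HOURS) - b2 / sigma2_sq
    grad = np.concatenate([[w1.sum(), w1 @ x], g_b1, [w2.sum(), w2 @ x], g_b2])
    return -(Q - pen), -grad


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def _two_means(y: np.ndarray, n_iter: int = 25) -> tuple[float, float]:
    """Scalar 2-means for Poisson-mean initialization; returns (low, high)."""
    lo, hi = float(y.min()), float(y.max())
    if hi - lo == 0:
        return lo, hi
    for _ in range(n_iter):
        split = (lo + hi) / 2.0
        low_mask = y <= split
        new_lo = float(y[low_mask].mean())
        new_hi = float(y[~low_mask].mean()) if np.any(~low_mask) else new_lo
        if (new_lo, new_hi) == (lo, hi):
            break
        lo, hi = new_lo, new_hi
    return lo, hi


def _penalty_terms(params: CTHMMParams) -> float:
    """log prior of the intercepts plus the variance normalizing terms."""
    return float(
        -(params.b1 @ params.b1) / (2 * params.sigma1_sq)
        - (params.b2 @ params.b2) / (2 * params.sigma2_sq)
        - (N_HOURS / 2) * np.log(params.sigma1_sq)
        - (N_HOURS / 2) * np.log(params.sigma2_sq)
    )


class _StateCollapse(Exception):
    pass


def _estep(params, seg_y, seg_x, seg_h):
    gam_list, xi_list, ll = [], [], 0.0
    for s in range(len(seg_y)):
        e1, e2 = log_rates(params, seg_x[s][:-1], seg_h[s][:-1])
        gmats = transition_matrices(np.exp(e1), np.exp(e2))
        logB = _emission_logB(seg_y[s], params)
        gam, xi, l = _forward_backward_core(logB, gmats, params.delta)
        gam_list.append(gam)
        xi_list.append(xi)
        ll += l
    return gam_list, xi_list, ll


def _mstep(params, gam_list, xi_list, y_all, x_trans, h_trans, cfg):
    """One M-step sweep (Poisson means, delta, hazard parameters); mutates params.

    Each sub-update is a coordinate ascent of the expected complete-data
    penalized log-likelihood; the hazard update is accepted only when it
    improves, so the overall EM is a generalized (monotone) EM.  Raises
    ``_StateCollapse`` when the emission means become indistinguishable.
    """
    gam_all = np.vstack(gam_list)
    denom = gam_all.sum(axis=0)
    mu_rest = float((gam_all[:, REST] @ y_all) / max(denom[REST], 1e-12))
    mu_active = float((gam_all[:, ACTIVE] @ y_all) / max(denom[ACTIVE], 1e-12))
    params.mu_rest = max(mu_rest, cfg.mu_rest_floor)
    params.mu_active = max(mu_active, cfg.mu_rest_floor)
    if params.mu_active < params.mu_rest:
        _swap_states(params)
        gam_list = [g[:, ::-1] for g in gam_list]
        xi_list = [x[:, ::-1, :][:, :, ::-1] for x in xi_list]
    if params.mu_active - params.mu_rest < cfg.collapse_tol:
        raise _StateCollapse

    if cfg.fix_delta is None:
        d0 = np.sum([g[0] for g in gam_list], axis=0)
        params.delta = d0 / d0.sum()

    xi_all = np.concatenate(xi_list, axis=0)
    theta0 = _pack(params)
    args = (x_trans, h_trans, xi_all, params.sigma1_sq, params.sigma2_sq)
    res = optimize.minimize(
        _transition_objective, theta0, args=args, jac=True,
        method="L-BFGS-B", options={"maxiter": cfg.mstep_maxiter},
    )
    if res.fun <= _transition_objective(theta0, *args)[0]:
        params.alpha1, params.beta1, params.b1, params.alpha2, params.beta2, params.b2 = _unpack(res.x)
        params.b1 = np.asarray(params.b1).copy()
        params.b2 = np.asarray(params.b2).copy()
    return gam_list, xi_list


def _intercept_curvatures(params, gam_list, x_trans, h_trans):
    """Per-hour negative-Hessian proxies H_h of the data term at the MAP intercepts."""
    e1, e2 = log_rates(params, x_trans, h_trans)
    occ_rest = np.concatenate([g[:-1, REST] for g in gam_list])
    occ_act = np.concatenate([g[:-1, ACTIVE] for g in gam_list])
    h1 = np.bincount(h_trans, weights=occ_rest * np.exp(e1), minlength=N_HOURS)
    h2 = np.bincount(h_trans, weights=occ_act * np.exp(e2), minlength=N_HOURS)
    return h1, h2


def em_fit(series: HourlySeries, config: FitConfig | None = None) -> FittedModel:
    """Fit the mixed-effect CT-HMM to one participant's imputed hourly series.

    Two phases:

    1. *Penalized EM* for the hazard parameters, intercepts, Poisson means
       and initial distribution, with the ridge strength held fixed at
       ``sigma_init``.  The traced objective

           sum_seg log P(Y | theta, b) - sum_h b1[h]^2/(2 s1) - b2[h]^2/(2 s2)

       is non-decreasing by construction (every M-step sub-update is a
       coordinate ascent of its expected complete-data analogue) and the
       loop stops when its relative change falls below ``tol``.
    2. *Variance calibration*: the intercept variances are estimated by
       iterating the empirical-Bayes fixed point
       ``sigma^2 <- mean_h(b[h]^2 + v[h])``, ``v[h] = 1/(H_h + 1/sigma^2)``
       — the mean squared MAP intercept plus a Laplace curvature
       correction — refitting the intercepts under each new ridge.  A
       plain mean of squared MAP intercepts is a degenerate estimator
       here (MAP shrinkage feeds back into the penalty and collapses
       moderate rhythms to zero); the curvature term restores the mass
       the ridge removed.  The calibration path is kept in
       ``sigma_trace``.

    State collapse — Poisson means too close to tell rest from active —
    or hitting ``max_iter`` marks the fit ``converged = False``;
    downstream the ARM is withheld for such participants.
    """
    cfg = config or FitConfig()
    segments = split_segments(series)
    total = sum(len(s) for s in segments)
    if total < cfg.min_hours:
        raise InsufficientDataError(
            f"{total} usable hours < min_hours={cfg.min_hours} after segment splitting"
        )
    seg_y = [s.data["Y"].to_numpy(dtype=int) for s in segments]
    seg_x = [s.data["X"].to_numpy(dtype=float) for s in segments]
    seg_h = [s.data["hour_of_day"].to_numpy(dtype=int) for s in segments]
    if any(np.any(~np.isfinite(x)) for x in seg_x):
        raise ValueError("segments contain missing X; run imputation first")
    if cfg.standardize_x:
        allx = np.concatenate(seg_x)
        sd = allx.std() or 1.0
        seg_x = [x / sd for x in seg_x]

    y_all = np.concatenate(seg_y)
    mu_lo, mu_hi = _two_means(y_all)
    params = CTHMMParams(
        alpha1=float(np.log(0.25)),
        beta1=0.0,
        alpha2=float(np.log(0.25)),
        beta2=0.0,
        b1=np.zeros(N_HOURS),
        b2=np.zeros(N_HOURS),
        sigma1_sq=cfg.sigma_init,
        sigma2_sq=cfg.sigma_init,
        mu_rest=max(mu_lo, cfg.mu_rest_floor),
        mu_active=max(mu_hi, cfg.mu_rest_floor),
        delta=np.array([0.5, 0.5]) if cfg.fix_delta is None else np.asarray(cfg.fix_delta, float),
    )

    trace: list[float] = []
    sigma_trace: list[tuple[float, float]] = []
    converged = False
    message = ""
    gam_list: list[np.ndarray] = []
    xi_list: list[np.ndarray] = []

    def _finish() -> FittedModel:
        post = np.concatenate([g[:, ACTIVE] for g in gam_list]) if gam_list else None
        slices = []
        off = 0
        for s in segments:
            slices.append((off, off + len(s)))
            off += len(s)
        return FittedModel(
            params=params,
            loglik_trace=trace,
            converged=converged,
            state_posteriors=post,
            pairwise_posteriors=xi_list or None,
            n_iter=len(trace),
            message=message or ("converged" if converged else ""),
            segment_slices=slices,
            t_index=np.concatenate([s.data["t"].to_numpy() for s in segments]),
            sigma_trace=sigma_trace,
        )

    if params.mu_active - params.mu_rest < cfg.collapse_tol:
        message = "state collapse: emission means indistinguishable"
        return _finish()

    x_trans = np.concatenate([x[:-1] for x in seg_x])
    h_trans = np.concatenate([h[:-1] for h in seg_h])

    # ---- phase 1: penalized EM at fixed ridge strength --------------------
    try:
        for _ in range(cfg.max_iter):
            gam_list, xi_list, ll = _estep(params, seg_y, seg_x, seg_h)
            obj = ll + _penalty_terms(params)
            if trace and abs(obj - trace[-1]) < cfg.tol * (abs(trace[-1]) + 1):
                trace.append(obj)
                converged = True
                break
            trace.append(obj)
            gam_list, xi_list = _mstep(params, gam_list, xi_list, y_all, x_trans, h_trans, cfg)
        else:
            message = f"max_iter={cfg.max_iter} reached without convergence"
    except _StateCollapse:
        message = "state collapse: emission means indistinguishable"
        return _finish()
    except FloatingPointError as err:
        message = f"numerical failure in E-step: {err}"
        return _finish()

    if not converged:
        return _finish()

    # ---- phase 2: empirical-Bayes variance calibration --------------------
    if cfg.calibrate_sigma:
        try:
            for _ in range(cfg.sigma_max_iter):
                h1, h2 = _intercept_curvatures(params, gam_list, x_trans, h_trans)
                v1 = 1.0 / (h1 + 1.0 / params.sigma1_sq)
                v2 = 1.0 / (h2 + 1.0 / params.sigma2_sq)
                new1 = max(float(np.mean(params.b1**2 + v1)), cfg.sigma_floor)
                new2 = max(float(np.mean(params.b2**2 + v2)), cfg.sigma_floor)
                moved = abs(new1 - params.sigma1_sq) + abs(new2 - params.sigma2_sq)
                scale = params.sigma1_sq + params.sigma2_sq
                params.sigma1_sq, params.sigma2_sq = new1, new2
                sigma_trace.append((new1, new2))
                if moved < cfg.sigma_tol * scale:
                    break
                gam_list, xi_list, _ = _estep(params, seg_y, seg_x, seg_h)
                gam_list, xi_list = _mstep(params, gam_list, xi_list, y_all, x_trans, h_trans, cfg)
            gam_list, xi_list, _ = _estep(params, seg_y, seg_x, seg_h)
        except _StateCollapse:
            converged, message = False, "state collapse during variance calibration"
            return _finish()
        except FloatingPointError as err:
            converged, message = False, f"numerical failure in calibration: {err}"
            return _finish()

    if params.mu_active - params.mu_rest < cfg.collapse_tol:
        converged, message = False, "state collapse: emission means indistinguishable"
    return _finish()


def _swap_states(params: CTHMMParams) -> None:
    """Relabel states (rest <-> active), swapping the transition directions."""
    params.mu_rest, params.mu_active = params.mu_active, params.mu_rest
    params.alpha1, params.alpha2 = params.alpha2, params.alpha1
    params.beta1, params.beta2 = params.beta2, params.beta1
    params.b1, params.b2 = params.b2, params.b1
    params.sigma1_sq, params.sigma2_sq = params.sigma2_sq, params.sigma1_sq
    params.delta = params.delta[::-1].copy()
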