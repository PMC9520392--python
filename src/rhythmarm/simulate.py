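"""Synthetic smartphone-sensing cohorts with known ground truth.

Generates hour-by-hour latent rest/active chains under the mixed-effect
CT-HMM, emits screen-on counts (Poisson) and accelerometer magnitudes
(state-dependent log-normal), deletes accelerometer hours preferentially
during rest (emulating night-time dormancy), and writes Beiwe-style raw
CSV streams that round-trip exactly through the feature binning.  Cohort
simulation additionally draws demographics and EMA summaries with
configurable linear links to each participant's true intercept variance,
so that every pipeline stage — imputation, EM fitting, ARM scoring and
the association tests — can be checked against known truth.

Defaults mirror the kind of outpatient cohort the method targets:
38 participants, ages around 23 (SD 3.5), about one-third male, six
weeks of data per phone, Poisson means 5 (active) and 0.05 (rest), and
roughly a quarter of accelerometer hours missing overall, concentrated
at night.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cthmm import ACTIVE, LOG_RATE_CLAMP, N_HOURS, REST, CTHMMParams, transition_matrix
from .features import HourlySeries


def diurnal_templates() -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance, mean-zero hour-of-day intercept shapes.

    The rest->active template peaks over 7:00-10:00 (morning activation);
    the active->rest template peaks over 0:00-6:00 (night-time settling).
    Scaled by sqrt(sigma^2) they give intercepts whose population variance
    over the 24 hours is exactly sigma^2.
    """
    hours = np.arange(N_HOURS)
    b1 = ((hours >= 7) & (hours <= 10)).astype(float)
    b2 = ((hours >= 0) & (hours <= 6)).astype(float)

    def _standardize(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / v.std()

    return _standardize(b1), _standardize(b2)


@dataclass
class SimTruth:
    """Ground-truth generating parameters for one participant."""

    params: CTHMMParams
    sigma_sq_total: float  # population variance of b1 plus that of b2
    p_miss_rest: float = 0.55
    p_miss_active: float = 0.05
    # log-normal accelerometer magnitude per state: (mean of log, sd of log)
    accel_rest: tuple[float, float] = (np.log(0.02), 0.35)
    accel_active: tuple[float, float] = (np.log(1.0), 0.5)

    def __post_init__(self) -> None:
        if not (0 <= self.p_miss_rest <= 1 and 0 <= self.p_miss_active <= 1):
            raise ValueError("missingness probabilities must lie in [0, 1]")
        if self.sigma_sq_total < 0:
            raise ValueError("sigma_sq_total must be non-negative")


def make_truth(
    sigma_sq_total: float = 2.0,
    use_template: bool = True,
    rng: np.random.Generator | None = None,
    alpha1: float = float(np.log(0.25)),
    alpha2: float = float(np.log(0.25)),
    beta1: float = 0.5,
    beta2: float = -0.5,
    mu_active: float = 5.0,
    mu_rest: float = 0.05,
    **kwargs,
) -> SimTruth:
    """Build a SimTruth with intercepts from the diurnal template (default)
    or drawn i.i.d. from N(0, sigma^2/2) per direction."""
    if sigma_sq_total < 0:
        raise ValueError("sigma_sq_total must be non-negative")
    half = sigma_sq_total / 2.0
    if use_template:
        t1, t2 = diurnal_templates()
        b1, b2 = t1 * np.sqrt(half), t2 * np.sqrt(half)
    else:
        if rng is None:
            raise ValueError("rng required when sampling intercepts")
        b1 = rng.normal(0.0, np.sqrt(half), N_HOURS)
        b2 = rng.normal(0.0, np.sqrt(half), N_HOURS)
    params = CTHMMParams(
        alpha1=alpha1,
        beta1=beta1,
        alpha2=alpha2,
        beta2=beta2,
        b1=b1,
        b2=b2,
        sigma1_sq=half,
        sigma2_sq=half,
        mu_rest=mu_rest,
        mu_active=mu_active,
        delta=np.array([0.5, 0.5]),
    )
    return SimTruth(params=params, sigma_sq_total=sigma_sq_total, **kwargs)


def simulate_participant(
    truth: SimTruth,
    n_days: int = 42,
    seed: int = 0,
    participant_id: str = "sim",
    start_hour_epoch: int = 0,
) -> tuple[HourlySeries, np.ndarray]:
    """Simulate one participant; returns the hourly series (with injected
    missing X) and the latent state path (0 = rest, 1 = active).

    The chain is advanced hour by hour: each hour emits X (log-normal given
    the state) and Y ~ Poisson(state mean), then transitions with the
    closed-form matrix built from that hour's X and clock hour.  X is
    deleted with state-dependent probability, so missing runs track rest
    periods the way overnight dormancy does.  Identical seeds give
    identical output.
    """
    if n_days < 2:
        raise ValueError("n_days must be at least 2")
    rng = np.random.default_rng(seed)
    T = n_days * N_HOURS
    p = truth.params
    states = np.empty(T, dtype=int)
    x = np.empty(T)
    y = np.empty(T, dtype=int)
    hours = (start_hour_epoch + np.arange(T) + 1) % N_HOURS  # end-of-bin labels
    state = int(rng.random() < p.delta[ACTIVE])
    mu = np.array([p.mu_rest, p.mu_active])
    ln = (truth.accel_rest, truth.accel_active)
    for t in range(T):
        states[t] = state
        m, sd = ln[state]
        x[t] = rng.lognormal(m, sd)
        y[t] = rng.poisson(mu[state])
        if t + 1 < T:
            h = int(hours[t])
            l1 = np.exp(np.clip(p.alpha1 + p.beta1 * x[t] + p.b1[h], -LOG_RATE_CLAMP, LOG_RATE_CLAMP))
            l2 = np.exp(np.clip(p.alpha2 + p.beta2 * x[t] + p.b2[h], -LOG_RATE_CLAMP, LOG_RATE_CLAMP))
            g = transition_matrix((l1, l2))
            state = int(rng.random() < g[state, ACTIVE])
    p_miss = np.where(states == REST, truth.p_miss_rest, truth.p_miss_active)
    missing = rng.random(T) < p_miss
    x_obs = x.copy()
    x_obs[missing] = np.nan
    data = pd.DataFrame(
        {"t": np.arange(T), "hour_of_day": hours, "X": x_obs, "Y": y, "imputed": False}
    )
    series = HourlySeries(participant_id=participant_id, data=data, start_hour_epoch=start_hour_epoch)
    return series, states


# ---------------------------------------------------------------------------
# Raw Beiwe-style streams (round-trip with features.bin_hourly)
# ---------------------------------------------------------------------------


def series_to_raw_streams(
    series: HourlySeries, samples_per_hour: int = 6, events_spread: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render an hourly series as raw accelerometer and screen-event CSVs.

    Accelerometer rows are written only for hours with observed X, with
    magnitudes equal to the hourly mean so that re-binning reproduces X
    exactly; screen events are spread within their hour.
    """
    start = series.start_hour_epoch or 0
    acc_rows = []
    scr_rows = []
    for rec in series.data.itertuples(index=False):
        hour_start_ms = (start + rec.t) * 3_600_000
        if np.isfinite(rec.X):
            for k in range(samples_per_hour):
                ts = hour_start_ms + int((k + 0.5) / samples_per_hour * 3_600_000)
                acc_rows.append((ts, rec.X, 0.0, 0.0))
        for k in range(int(rec.Y)):
            frac = (k + 0.5) / rec.Y if events_spread else 0.5
            scr_rows.append((hour_start_ms + int(frac * 3_599_000), "screen_on"))
    accel = pd.DataFrame(acc_rows, columns=["timestamp", "x", "y", "z"])
    screens = pd.DataFrame(scr_rows, columns=["timestamp", "event"])
    return accel, screens


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Effect sizes are in ARM units per covariate unit and set to zero for a
    null cohort.  ``sigma_sq_base`` plus age/sex effects plus noise gives
    each participant's true total intercept variance (clipped at a small
    positive floor); EMA summaries are then generated from that truth with
    the corresponding link and noise.
    """

    n_participants: int = 38
    n_days: int = 42
    sigma_sq_base: float = 1.5
    sigma_sq_noise_sd: float = 0.6
    age_mean: float = 23.4
    age_sd: float = 3.5
    p_male: float = 0.32
    effect_age: float = 0.18  # ARM per year
    effect_male: float = 1.31  # ARM difference, male vs female
    # links from true ARM to EMA outcomes (outcome units per ARM unit)
    link_sleep: float = 0.6
    link_bed_sd: float = -0.45
    link_wake_sd: float = -0.45
    link_mood: float = -0.6
    link_bdi: float = -2.5
    sleep_base: float = 7.43
    sleep_noise_sd: float = 0.5
    bed_sd_base: float = 1.92
    wake_sd_base: float = 2.17
    time_sd_noise_sd: float = 0.4
    mood_base: float = 3.12
    mood_noise_sd: float = 0.7
    bdi_base: float = 7.0
    bdi_noise_sd: float = 4.0
    use_template: bool = True
    p_miss_rest: float = 0.55
    p_miss_active: float = 0.05


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    with_sensors: bool = True,
) -> tuple[dict[str, tuple[HourlySeries, np.ndarray]], pd.DataFrame, dict[str, SimTruth]]:
    """Simulate a full cohort: sensor series, covariate table, truth registry.

    Returns ``(sensors, cohort, truths)`` where ``sensors`` maps participant
    id to (series, latent states), ``cohort`` has one row per participant
    with the true ARM and the generated covariates, and ``truths`` records
    the generating parameters for recovery testing.  All randomness flows
    from ``seed`` through per-participant child seeds.
    """
    cfg = config or CohortConfig()
    if cfg.n_participants <= 0:
        raise ValueError("n_participants must be positive")
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=cfg.n_participants)

    sensors: dict[str, tuple[HourlySeries, np.ndarray]] = {}
    truths: dict[str, SimTruth] = {}
    rows = []
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(child_seeds[i])
        pid = f"P{i:03d}"
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 16, 35))
        male = int(rng.random() < cfg.p_male)
        sigma_sq = (
            cfg.sigma_sq_base
            + cfg.effect_age * (age - cfg.age_mean)
            + cfg.effect_male * male
            + rng.normal(0.0, cfg.sigma_sq_noise_sd)
        )
        sigma_sq = float(max(sigma_sq, 0.05))
        truth = make_truth(
            sigma_sq_total=sigma_sq,
            use_template=cfg.use_template,
            rng=rng,
            p_miss_rest=cfg.p_miss_rest,
            p_miss_active=cfg.p_miss_active,
        )
        truths[pid] = truth
        if with_sensors:
            series, states = simulate_participant(
                truth, n_days=cfg.n_days, seed=int(child_seeds[i]), participant_id=pid
            )
            sensors[pid] = (series, states)
        centered = sigma_sq - cfg.sigma_sq_base
        rows.append(
            {
                "participant_id": pid,
                "true_arm": sigma_sq,
                "age": age,
                "sex": male,  # 1 = male
                "mean_sleep_hours": cfg.sleep_base
                + cfg.link_sleep * centered
                + rng.normal(0, cfg.sleep_noise_sd),
                "sd_bed_time": max(
                    0.05,
                    cfg.bed_sd_base + cfg.link_bed_sd * centered + rng.normal(0, cfg.time_sd_noise_sd),
                ),
                "sd_wake_time": max(
                    0.05,
                    cfg.wake_sd_base + cfg.link_wake_sd * centered + rng.normal(0, cfg.time_sd_noise_sd),
                ),
                "mean_mood": float(
                    np.clip(cfg.mood_base + cfg.link_mood * centered + rng.normal(0, cfg.mood_noise_sd), 1, 7)
                ),
                "bdi": float(
                    np.clip(cfg.bdi_base + cfg.link_bdi * centered + rng.normal(0, cfg.bdi_noise_sd), 0, 63)
                ),
            }
        )
    cohort = pd.DataFrame(rows)
    return sensors, cohort, truths


def write_cohort_csvs(
    sensors: dict[str, tuple[HourlySeries, np.ndarray]],
    cohort: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write per-participant raw streams plus the covariate table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, (series, _) in sensors.items():
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        accel, screens = series_to_raw_streams(series)
        accel.to_csv(pdir / "accelerometer.csv", index=False)
        screens.to_csv(pdir / "screen_events.csv", index=False)
    cohort.to_csv(out / "covariates.csv", index=False)
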