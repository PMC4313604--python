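"""Synthetic ESM data with the exact structure the trajectory models assume.

The generator mirrors the study design: two arms (mindfulness training
``mbct`` vs waitlist ``control``), two assessment periods (pre / post), six
consecutive days with ten 90-minute beep blocks per day, 7-point Likert
items, completion delays, and missing responses.

Daily dynamics are a bivariate autoregressive latent trajectory process per
subject x period: a bivariate-normal trait pair (eta_PA, eta_PC) acting as a
constant intercept, a predetermined (exogenous) day 1 correlated with the
traits, and for days t = 2..6

    PA_t = eta_PA + rho_PA * PA_{t-1} + gamma_pc_pa * PC_{t-1} + e_PA,t
    PC_t = eta_PC + rho_PC * PC_{t-1} + gamma_pa_pc * PA_{t-1} + e_PC,t

with correlated same-day innovations.  In the mbct arm's post period the
trait means are shifted by the treatment effects (tau_PA, tau_PC).  Beeps
add momentary noise on top of the daily level; adjective items load on the
momentary PA with item noise and are discretized to the 1-7 scale.

All randomness flows from a single integer seed; every subject draws from
one reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .esm import MOOD_ITEMS

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_daily_panel",
    "generate_beep_panel",
    "inject_missingness",
]

#: Default raw item loadings; "relaxed" is deliberately low so that the
#: loading cutoff reproduces its exclusion from the PA composite.
DEFAULT_LOADINGS: dict[str, float] = {
    "happy": 0.70,
    "satisfied": 0.68,
    "strong": 0.62,
    "enthusiastic": 0.66,
    "curious": 0.60,
    "animated": 0.64,
    "inspired": 0.66,
    "relaxed": 0.25,
}


@dataclass
class SyntheticConfig:
    """All generative parameters.  Defaults are calibrated to the study's
    reported regime: daily means ~3.3 and SDs ~1.0 on the 7-point scale,
    lag-1 autocorrelation of daily positive affect ~0.25, an
    affect-to-cognition cross-lag ~0.17 with no reverse coupling, high
    same-day residual covariance, a PA composite with alpha ~0.89, and a
    treatment-by-time interaction on momentary positive cognition ~0.23.
    """

    # design
    n_control: int = 66
    n_mbct: int = 64
    n_days: int = 6
    n_blocks: int = 10

    # trait (intercept) structure
    mu_pa: float = 2.475  # trait means; steady-state daily level = mu/(1-rho)
    mu_pc: float = 2.574
    psi_pa: float = 0.40  # trait variances / covariance
    psi_pc: float = 0.30
    psi_pa_pc: float = 0.15
    trait_stability: float = 0.7  # share of trait variance common to pre & post

    # treatment effects added to post-period mbct trait means
    tau_pa: float = 0.15
    tau_pc: float = 0.2065

    # daily dynamics
    rho_pa: float = 0.25
    rho_pc: float = 0.05
    gamma_pa_pc: float = 0.17  # previous-day PA -> PC
    gamma_pc_pa: float = 0.0  # previous-day PC -> PA
    gamma_pa_pc_control: float | None = None  # per-arm override (None = same)
    theta_pa: float = 0.42  # daily innovation variances / covariance
    theta_pc: float = 0.45
    theta_pa_pc: float = 0.34

    # predetermined day 1
    day1_mean_offset_pa: float = 0.825  # day-1 mean = offset + trait mean
    day1_mean_offset_pc: float = 0.726
    day1_var_pa: float = 0.75  # residual variance of day 1 beyond the trait
    day1_var_pc: float = 0.55
    day1_cov: float = 0.385

    # beep / item measurement layer
    beep_sd: float = 0.8
    item_loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    item_anchor: float = 3.3  # scale point the loadings pivot around
    item_sd: float = 0.74
    thought_sd: float = 0.3
    discretize: bool = True

    # missingness and completion delays
    p_miss: float = 0.08
    p_late: float = 0.12
    delay_mean: float = 4.0  # minutes; exponential, truncated at 15
    late_delay_mean: float = 10.0  # minutes beyond the 15-min limit
    mar_by_day: bool = False
    mar_day_slope: float = 0.15

    seed: int = 0

    def validate(self) -> None:
        if min(self.psi_pa, self.psi_pc, self.theta_pa, self.theta_pc) <= 0:
            raise ValueError("variances must be positive")
        for rho in (self.rho_pa, self.rho_pc):
            if abs(rho) >= 1:
                raise ValueError("|rho| must be < 1")
        for p in (self.p_miss, self.p_late):
            if not (0 <= p < 1):
                raise ValueError("p_miss and p_late must be in [0, 1)")
        if not (0 <= self.trait_stability <= 1):
            raise ValueError("trait_stability must be in [0, 1]")
        for m in (self.psi_matrix(), self.theta_matrix(), self.day1_matrix()):
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError(f"covariance matrix not positive definite: {m}")

    def psi_matrix(self) -> np.ndarray:
        return np.array([[self.psi_pa, self.psi_pa_pc], [self.psi_pa_pc, self.psi_pc]])

    def theta_matrix(self) -> np.ndarray:
        return np.array([[self.theta_pa, self.theta_pa_pc], [self.theta_pa_pc, self.theta_pc]])

    def day1_matrix(self) -> np.ndarray:
        return np.array([[self.day1_var_pa, self.day1_cov], [self.day1_cov, self.day1_var_pc]])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**dict(d))


@dataclass
class GroundTruth:
    """Realized latent quantities behind a generated panel: the per-subject
    per-period trait values and the daily latent levels, plus the config."""

    config: SyntheticConfig
    traits: pd.DataFrame  # subject, condition, period, eta_pa, eta_pc
    daily: pd.DataFrame  # subject, condition, period, day, pa, pc (latent)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "traits": self.traits.to_dict(orient="list"),
            "daily": self.daily.to_dict(orient="list"),
        }
        import json

        Path(path).write_text(json.dumps(payload, indent=2))


def _subjects(config: SyntheticConfig) -> pd.DataFrame:
    ids = [f"c{i + 1:03d}" for i in range(config.n_control)] + [
        f"m{i + 1:03d}" for i in range(config.n_mbct)
    ]
    cond = ["control"] * config.n_control + ["mbct"] * config.n_mbct
    return pd.DataFrame({"subject": ids, "condition": cond})


def _simulate_latent_days(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw traits and daily latent levels for every subject x period.

    Traits are correlated across the two periods: a subject-level component
    carrying ``trait_stability`` of the trait variance is shared between pre
    and post, the remainder is period-specific.
    """
    config.validate()
    subj = _subjects(config)
    n = len(subj)
    is_mbct = (subj["condition"] == "mbct").to_numpy()

    psi = config.psi_matrix()
    w = config.trait_stability
    base = rng.multivariate_normal(np.zeros(2), w * psi, size=n)

    gamma_pa_pc = np.full(n, config.gamma_pa_pc)
    if config.gamma_pa_pc_control is not None:
        gamma_pa_pc[~is_mbct] = config.gamma_pa_pc_control

    traits_rows, daily_rows = [], []
    mu = np.array([config.mu_pa, config.mu_pc])
    tau = np.array([config.tau_pa, config.tau_pc])
    off1 = np.array([config.day1_mean_offset_pa, config.day1_mean_offset_pc])
    for period in ("pre", "post"):
        jitter = (
            rng.multivariate_normal(np.zeros(2), (1 - w) * psi, size=n)
            if w < 1
            else np.zeros((n, 2))
        )
        eta = mu + base + jitter
        if period == "post":
            eta = eta + np.where(is_mbct[:, None], tau, 0.0)

        # predetermined day 1: offset + trait + residual, so it covaries
        # with the trait pair through eta
        e1 = rng.multivariate_normal(np.zeros(2), config.day1_matrix(), size=n)
        level = eta + off1 + e1
        days = [level]
        for _ in range(2, config.n_days + 1):
            eps = rng.multivariate_normal(np.zeros(2), config.theta_matrix(), size=n)
            prev = days[-1]
            pa = eta[:, 0] + config.rho_pa * prev[:, 0] + config.gamma_pc_pa * prev[:, 1] + eps[:, 0]
            pc = eta[:, 1] + config.rho_pc * prev[:, 1] + gamma_pa_pc * prev[:, 0] + eps[:, 1]
            days.append(np.column_stack([pa, pc]))

        traits_rows.append(
            pd.DataFrame(
                {
                    "subject": subj["subject"],
                    "condition": subj["condition"],
                    "period": period,
                    "eta_pa": eta[:, 0],
                    "eta_pc": eta[:, 1],
                }
            )
        )
        for d, level_d in enumerate(days, start=1):
            daily_rows.append(
                pd.DataFrame(
                    {
                        "subject": subj["subject"],
                        "condition": subj["condition"],
                        "period": period,
                        "day": d,
                        "pa": level_d[:, 0],
                        "pc": level_d[:, 1],
                    }
                )
            )
    traits = pd.concat(traits_rows, ignore_index=True)
    daily = (
        pd.concat(daily_rows, ignore_index=True)
        .sort_values(["subject", "period", "day"])
        .reset_index(drop=True)
    )
    return traits, daily


def generate_daily_panel(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the day-level panel directly (no beep layer, no missing
    values).  Returns the daily series in the same long layout
    ``aggregate_daily`` produces, plus the ground truth."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    traits, daily = _simulate_latent_days(config, rng)
    panel = daily.copy()
    panel["n_beeps"] = config.n_blocks
    truth = GroundTruth(config=config, traits=traits, daily=daily)
    return panel, truth


def _draw_delays(n: int, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Completion delays in minutes: with probability ``p_late`` the report
    is late (> 15 min, shifted exponential), otherwise the delay is
    exponential with mean ``delay_mean`` truncated at 15 min."""
    late = rng.random(n) < config.p_late
    u = rng.random(n)
    trunc_mass = 1.0 - np.exp(-15.0 / config.delay_mean)
    on_time = -config.delay_mean * np.log1p(-u * trunc_mass)
    late_delay = 15.0 + rng.exponential(config.late_delay_mean, size=n)
    return np.where(late, late_delay, on_time)


def inject_missingness(
    records: pd.DataFrame,
    p_miss: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    by_day_slope: float = 0.0,
) -> pd.DataFrame:
    """Mark beeps as never completed with probability ``p_miss`` each
    (independently).  A nonzero ``by_day_slope`` makes the probability
    depend linearly on the (observed) day index — missing at random rather
    than completely at random — to exercise full-information estimation.

    A missing beep has no completion delay and no item responses.
    """
    if not (0 <= p_miss < 1):
        raise ValueError("p_miss must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = records.copy()
    p = p_miss * (1.0 + by_day_slope * (out["day"].to_numpy() - 3.5))
    p = np.clip(p, 0.0, 0.95)
    miss = rng.random(len(out)) < p
    cols = ["delay_min", *MOOD_ITEMS, "thought_pleasant"]
    out.loc[miss, cols] = np.nan
    return out


def generate_beep_panel(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the full beep-level panel: 10 blocks x 6 days x 2 periods
    per subject (exactly 60 scheduled beeps per subject per period).

    Momentary latent PA/PC = daily latent + beep noise; the eight adjective
    items load on momentary PA (item noise added, discretized to 1..7 unless
    ``config.discretize`` is off); the thought-pleasantness rating derives
    from momentary PC the same way.  Completion delays and missingness are
    then applied.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    traits, daily = _simulate_latent_days(config, rng)

    blocks = pd.DataFrame({"block": np.arange(1, config.n_blocks + 1)})
    beeps = daily.merge(blocks, how="cross")
    n = len(beeps)

    pa_mom = beeps["pa"].to_numpy() + rng.normal(0, config.beep_sd, n)
    pc_mom = beeps["pc"].to_numpy() + rng.normal(0, config.beep_sd, n)

    def finish(x: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(x), 1, 7) if config.discretize else x

    a = config.item_anchor
    for item in MOOD_ITEMS:
        lam = config.item_loadings[item]
        raw = a + lam * (pa_mom - a) + rng.normal(0, config.item_sd, n)
        beeps[item] = finish(raw)
    beeps["thought_pleasant"] = finish(pc_mom + rng.normal(0, config.thought_sd, n))

    beeps["delay_min"] = _draw_delays(n, config, rng)
    beeps = beeps.drop(columns=["pa", "pc"])
    cols = [
        "subject",
        "condition",
        "period",
        "day",
        "block",
        "delay_min",
        *MOOD_ITEMS,
        "thought_pleasant",
    ]
    beeps = beeps[cols]
    if config.p_miss > 0 or config.mar_by_day:
        beeps = inject_missingness(
            beeps,
            config.p_miss,
            rng=rng,
            by_day_slope=config.mar_day_slope if config.mar_by_day else 0.0,
        )
    truth = GroundTruth(config=config, traits=traits, daily=daily)
    return beeps, truth
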