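"""Synthetic patient-level trial data with closed-form ground truth.

Stands in for unshared individual participant data: utilities with a shared
patient-level random intercept (so neighbouring observations predict each
other), skewed non-negative per-category costs, Poisson hospitalisation
counts, configurable arm effects, visit-level missingness (optionally
monotone dropout) and deaths.  Every configured effect has a closed-form
expectation (:func:`true_values`) for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from copdcea.parameters import UTILITY_FLOOR
from copdcea.trial import PERIOD_MONTHS, TrialDataset, VISIT_MONTHS

ARMS = ("usual_care", "intervention")


def _default_cost_means() -> dict:
    # per-3-month-period category means (GBP), mirroring published 6-month
    # arm totals split evenly over two periods
    return {
        "intervention": {"usual_care": 0.0, "intervention": 90.645},
        "home_visits": {"usual_care": 0.0, "intervention": 62.715},
        "primary_care": {"usual_care": 25.58, "intervention": 36.705},
        "ae": {"usual_care": 17.465, "intervention": 17.185},
        "pharmacy": {"usual_care": 128.165, "intervention": 106.265},
        "rehab": {"usual_care": 66.945, "intervention": 85.20},
        "hospitalisation": {"usual_care": 190.19, "intervention": 131.13},
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic trial generator.

    ``utility_drift`` gives, per arm, the offsets of the month-3/6/9/12 mean
    utilities from the arm's baseline mean.  Cost category means are per
    3-month period; the ``intervention`` category is deterministic.
    """

    n_per_arm: int = 45
    n_sites: int = 4
    stage_d_share: float = 0.878
    age_mean: float = 68.0
    age_sd: float = 8.0
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"usual_care": 0.487, "intervention": 0.529})
    utility_drift: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"usual_care": (-0.024, 0.003, 0.003, 0.003),
                                 "intervention": (0.008, 0.058, 0.058, 0.058)})
    utility_intercept_sd: float = 0.15
    utility_visit_sd: float = 0.12
    cost_means: dict[str, dict[str, float]] = field(default_factory=_default_cost_means)
    cost_cv: float = 1.5
    hosp_rate: dict[str, float] = field(
        default_factory=lambda: {"usual_care": 0.073, "intervention": 0.064})
    missingness: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    monotone_dropout: bool = False
    death_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if not (0.0 <= self.stage_d_share <= 1.0):
            raise ValueError("stage_d_share outside [0, 1]")
        for p in list(self.missingness) + [self.death_prob]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if len(self.missingness) != len(VISIT_MONTHS) - 1:
            raise ValueError("missingness needs one probability per follow-up visit")
        for arm in ARMS:
            for mu in self.visit_means(arm):
                if not (UTILITY_FLOOR < mu < 1.0):
                    raise ValueError(
                        f"infeasible truncation: mean {mu} outside utility bounds")
            for r in (self.hosp_rate[arm],):
                if r < 0:
                    raise ValueError("hospitalisation rate negative")

    def visit_means(self, arm: str) -> np.ndarray:
        base = self.baseline_mean[arm]
        return np.array([base] + [base + d for d in self.utility_drift[arm]])

    def period_cost_mean(self, arm: str) -> float:
        return float(sum(cat[arm] for cat in self.cost_means.values()))


def _clipped_normal_mean(mu: float, sigma: float,
                         lo: float = UTILITY_FLOOR, hi: float = 1.0) -> float:
    """Mean of a normal draw clipped to [lo, hi] (closed form)."""
    if sigma == 0:
        return float(np.clip(mu, lo, hi))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return float(lo * stats.norm.cdf(a) + hi * stats.norm.sf(b)
                 + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
                 - sigma * (stats.norm.pdf(b) - stats.norm.pdf(a)))


def generate(config: GeneratorConfig) -> TrialDataset:
    """Draw one synthetic trial dataset (reproducible under ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    frames = []
    pid = 0
    for arm in ARMS:
        n = config.n_per_arm
        means = config.visit_means(arm)
        intercept = rng.normal(0.0, config.utility_intercept_sd, size=n)
        eq5d = np.clip(
            means[None, :] + intercept[:, None]
            + rng.normal(0.0, config.utility_visit_sd, size=(n, len(VISIT_MONTHS))),
            UTILITY_FLOOR, 1.0)

        df = pd.DataFrame({
            "patient_id": np.arange(pid, pid + n),
            "arm": arm,
            "age": rng.normal(config.age_mean, config.age_sd, size=n).round(1),
            "gender": rng.choice(["F", "M"], size=n),
            "site": rng.integers(0, config.n_sites, size=n),
            "gold_stage": np.where(rng.random(n) < config.stage_d_share, "D", "B"),
        })
        pid += n
        for k, m in enumerate(VISIT_MONTHS):
            df[f"eq5d_m{m}"] = eq5d[:, k]

        cv2 = config.cost_cv ** 2
        for p in PERIOD_MONTHS:
            total = np.zeros(n)
            for cat, per_arm in config.cost_means.items():
                mu = per_arm[arm]
                if mu <= 0:
                    draw = np.zeros(n)
                elif cat == "intervention" or cv2 == 0:
                    draw = np.full(n, mu)
                else:
                    draw = rng.gamma(1.0 / cv2, mu * cv2, size=n)
                df[f"cost_{cat}_m{p}"] = draw
                total += draw
            df[f"cost_m{p}"] = total
            df[f"hosp_m{p}"] = rng.poisson(config.hosp_rate[arm], size=n)

        died = rng.random(n) < config.death_prob
        death_month = np.where(died, rng.integers(1, 13, size=n), np.nan)
        df["died"] = died
        df["death_month"] = death_month

        # missingness after generation: a missing visit blanks the whole
        # questionnaire (utility, costs, counts) for that follow-up
        miss = rng.random((n, len(config.missingness))) < np.asarray(config.missingness)
        if config.monotone_dropout:
            miss = np.maximum.accumulate(miss, axis=1)
        for k, m in enumerate(VISIT_MONTHS[1:]):
            gone = miss[:, k] | (died & (death_month <= m))
            df.loc[gone, f"eq5d_m{m}"] = np.nan
            df.loc[gone, f"cost_m{m}"] = np.nan
            df.loc[gone, f"hosp_m{m}"] = np.nan
            for cat in config.cost_means:
                df.loc[gone, f"cost_{cat}_m{m}"] = np.nan
        frames.append(df)

    return TrialDataset(pd.concat(frames, ignore_index=True))


def true_values(config: GeneratorConfig, horizon: int = 6) -> dict[str, float]:
    """Closed-form expected increments implied by the generator.

    QALY means account for the clipping of utilities to the EQ-5D bounds
    (clipped-normal closed form); costs and counts are exact means.
    """
    visits = [m for m in VISIT_MONTHS if m <= horizon]
    sigma = float(np.hypot(config.utility_intercept_sd, config.utility_visit_sd))
    qaly = {}
    for arm in ARMS:
        mu = [_clipped_normal_mean(m, sigma)
              for m in config.visit_means(arm)[:len(visits)]]
        qaly[arm] = float(np.trapezoid(mu, visits) / 12.0)
    n_periods = sum(1 for p in PERIOD_MONTHS if p <= horizon)
    cost = {arm: config.period_cost_mean(arm) * n_periods for arm in ARMS}
    hosp = {arm: config.hosp_rate[arm] * n_periods for arm in ARMS}
    return {
        "delta_qaly": qaly["intervention"] - qaly["usual_care"],
        "delta_cost": cost["intervention"] - cost["usual_care"],
        "delta_hosp": hosp["intervention"] - hosp["usual_care"],
        "arm_qaly": qaly,
        "arm_cost": cost,
        "arm_hosp": hosp,
        "horizon": horizon,
    }
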