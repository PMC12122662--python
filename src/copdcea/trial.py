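"""Within-trial cost-utility and cost-effectiveness analysis.

QALYs by trapezoidal area-under-the-curve on EQ-5D utilities, chained
multiple imputation of missing follow-up data, seemingly-unrelated-
regression (FGLS) adjusted incremental costs and effects, non-parametric
bootstrap ICERs and cost-effectiveness acceptability curves, and the
cost-per-hospitalisation-averted analysis.

Patient-level tables use one row per patient with columns::

    patient_id, arm, age, gender, site, gold_stage, died, death_month,
    eq5d_m0, eq5d_m3, eq5d_m6, eq5d_m9, eq5d_m12,
    cost_m3, cost_m6, cost_m9, cost_m12,
    hosp_m3, hosp_m6, hosp_m9, hosp_m12

``arm`` is ``usual_care`` or ``intervention``; costs are GBP per follow-up
period; ``hosp_*`` are period hospitalisation counts.  Additional
``cost_<category>_m<p>`` columns may be present for disaggregation and are
carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from copdcea.markov import icer_and_label
from copdcea.parameters import UTILITY_FLOOR

VISIT_MONTHS = (0, 3, 6, 9, 12)
PERIOD_MONTHS = (3, 6, 9, 12)
ARMS = ("usual_care", "intervention")


class MissingDataError(ValueError):
    """Raised when an operation requiring complete data meets missing values."""


def qaly_auc(utilities: Sequence[float], times: Sequence[float]) -> float:
    """Trapezoidal QALYs (year units) from utilities observed at ``times`` months.

    Requires at least two observations at strictly increasing times starting
    at baseline; missing values must be imputed first.
    """
    u = np.asarray(utilities, dtype=float)
    t = np.asarray(times, dtype=float)
    if u.size < 2:
        raise ValueError("need at least two observations")
    if np.any(np.isnan(u)):
        raise MissingDataError("utilities contain missing values; impute first")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[0] != 0:
        raise ValueError("first observation must be at baseline (month 0)")
    return float(np.trapezoid(u, t) / 12.0)


@dataclass
class TrialDataset:
    """A validated patient-level trial table."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        required = (["patient_id", "arm", "age", "gender", "site", "gold_stage", "died"]
                    + [f"eq5d_m{m}" for m in VISIT_MONTHS]
                    + [f"cost_m{p}" for p in PERIOD_MONTHS]
                    + [f"hosp_m{p}" for p in PERIOD_MONTHS])
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing columns: {missing_cols}")
        if not set(df["arm"]).issubset(set(ARMS)):
            raise ValueError(f"unknown arm labels: {set(df['arm']) - set(ARMS)}")
        if df["eq5d_m0"].isna().any():
            raise ValueError("baseline EQ-5D must be present for all included patients")
        for p in PERIOD_MONTHS:
            costs = df[f"cost_m{p}"].dropna()
            if (costs < 0).any():
                raise ValueError(f"negative costs in cost_m{p}")
            hosp = df[f"hosp_m{p}"].dropna()
            if (hosp < 0).any():
                raise ValueError(f"negative counts in hosp_m{p}")
        if "excluded_from_imputation" not in df.columns:
            post = ([f"eq5d_m{m}" for m in VISIT_MONTHS if m > 0]
                    + [f"cost_m{p}" for p in PERIOD_MONTHS]
                    + [f"hosp_m{p}" for p in PERIOD_MONTHS])
            self.df = df = df.assign(
                excluded_from_imputation=df[post].isna().all(axis=1))

    # -- convenience ------------------------------------------------------
    def followup_columns(self, horizon: int = 12) -> list[str]:
        cols = [f"eq5d_m{m}" for m in VISIT_MONTHS if 0 < m <= horizon]
        cols += [f"cost_m{p}" for p in PERIOD_MONTHS if p <= horizon]
        cols += [f"hosp_m{p}" for p in PERIOD_MONTHS if p <= horizon]
        return cols

    def complete_case(self, horizon: int = 6) -> "TrialDataset":
        cols = self.followup_columns(horizon)
        return TrialDataset(self.df[self.df[cols].notna().all(axis=1)]
                            .reset_index(drop=True).copy())

    def analysis_frame(self, horizon: int = 6,
                       exclude_deaths: bool = True) -> pd.DataFrame:
        """Per-patient QALY, total cost and hospitalisation count.

        Requires complete data over the horizon (impute or filter first).
        """
        df = self.df
        if exclude_deaths and df["died"].any():
            df = df[~df["died"].astype(bool)]
        visits = [m for m in VISIT_MONTHS if m <= horizon]
        eq_cols = [f"eq5d_m{m}" for m in visits]
        cost_cols = [f"cost_m{p}" for p in PERIOD_MONTHS if p <= horizon]
        hosp_cols = [f"hosp_m{p}" for p in PERIOD_MONTHS if p <= horizon]
        if df[eq_cols + cost_cols + hosp_cols].isna().any().any():
            raise MissingDataError(
                "analysis horizon contains missing values; impute or use "
                "complete_case() first")
        out = df[["patient_id", "arm", "age", "gender", "site", "gold_stage"]].copy()
        out["baseline_eq5d"] = df["eq5d_m0"]
        out["qaly"] = [qaly_auc(row, visits) for row in df[eq_cols].to_numpy()]
        out["cost"] = df[cost_cols].sum(axis=1)
        out["hosp"] = df[hosp_cols].sum(axis=1)
        return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# multiple imputation


def impute(dataset: TrialDataset, n_imputations: int = 50, seed: int | None = 0,
           max_iter: int = 10) -> list[TrialDataset]:
    """Chained multiple imputation of follow-up EQ-5D, costs and counts.

    Linear-regression chained equations (Bayesian ridge with posterior-draw
    noise) cycling over the incomplete variables; predictors are age,
    gender, site, stage and the neighbouring observations, with
    hospitalisation counts in the model for costs.  Patients flagged
    ``excluded_from_imputation`` (no post-baseline returns) are dropped.
    Reproducible under ``seed``.
    """
    df = dataset.df[~dataset.df["excluded_from_imputation"]].reset_index(drop=True)
    target_cols = ([f"eq5d_m{m}" for m in VISIT_MONTHS if m > 0]
                   + [f"cost_m{p}" for p in PERIOD_MONTHS]
                   + [f"hosp_m{p}" for p in PERIOD_MONTHS])
    pred = pd.DataFrame({
        "age": df["age"].astype(float),
        "gender": pd.factorize(df["gender"])[0].astype(float),
        "stage": pd.factorize(df["gold_stage"])[0].astype(float),
        "arm": (df["arm"] == "intervention").astype(float),
        "baseline_eq5d": df["eq5d_m0"].astype(float),
    })
    site = pd.get_dummies(df["site"], prefix="site", drop_first=True, dtype=float)
    X = pd.concat([pred, site, df[target_cols].astype(float)], axis=1)
    if X[target_cols].notna().sum().min() == 0:
        empty = X[target_cols].columns[X[target_cols].notna().sum() == 0]
        raise ValueError(f"no observed records to anchor: {list(empty)}")

    seeds = np.random.SeedSequence(seed).generate_state(n_imputations)
    completed = []
    for k in range(n_imputations):
        imp = IterativeImputer(estimator=BayesianRidge(), sample_posterior=True,
                               max_iter=max_iter, random_state=int(seeds[k]),
                               keep_empty_features=True)
        filled = pd.DataFrame(imp.fit_transform(X), columns=X.columns, index=X.index)
        out = df.copy()
        for m in VISIT_MONTHS[1:]:
            out[f"eq5d_m{m}"] = filled[f"eq5d_m{m}"].clip(UTILITY_FLOOR, 1.0)
        for p in PERIOD_MONTHS:
            out[f"cost_m{p}"] = filled[f"cost_m{p}"].clip(lower=0.0)
            out[f"hosp_m{p}"] = filled[f"hosp_m{p}"].clip(lower=0.0)
        completed.append(TrialDataset(out))
    return completed


def impute_mean(dataset: TrialDataset, n_imputations: int = 50,
                seed: int | None = 0, max_iter: int = 10) -> TrialDataset:
    """Single completed dataset: the arithmetic mean of the imputations."""
    completed = impute(dataset, n_imputations=n_imputations, seed=seed,
                       max_iter=max_iter)
    out = completed[0].df.copy()
    cols = ([f"eq5d_m{m}" for m in VISIT_MONTHS if m > 0]
            + [f"cost_m{p}" for p in PERIOD_MONTHS]
            + [f"hosp_m{p}" for p in PERIOD_MONTHS])
    stack = np.stack([c.df[cols].to_numpy(dtype=float) for c in completed])
    out[cols] = stack.mean(axis=0)
    return TrialDataset(out)


# ---------------------------------------------------------------------------
# SUR-adjusted incremental costs and effects


def _design(frame: pd.DataFrame, with_baseline: bool):
    cols = {"const": np.ones(len(frame)),
            "arm": (frame["arm"] == "intervention").astype(float).to_numpy(),
            "age": frame["age"].astype(float).to_numpy(),
            "gender": pd.factorize(frame["gender"])[0].astype(float),
            "stage": pd.factorize(frame["gold_stage"])[0].astype(float)}
    X = pd.DataFrame(cols, index=frame.index)
    site = pd.get_dummies(frame["site"], prefix="site", drop_first=True, dtype=float)
    X = pd.concat([X, site], axis=1)
    if with_baseline:
        X["baseline_eq5d"] = frame["baseline_eq5d"].astype(float)
    # drop constant (degenerate) covariates, keeping the intercept and arm
    keep = [c for c in X.columns
            if c in ("const", "arm") or X[c].nunique() > 1]
    return X[keep]


def _sur_fgls(X1: np.ndarray, y1: np.ndarray, X2: np.ndarray, y2: np.ndarray,
              names1, names2):
    """Two-equation FGLS with cross-equation error correlation.

    Equation 1 is the cost equation, equation 2 the effect equation.  The
    error covariance is estimated from equation-by-equation OLS residuals.
    Returns the coefficient vectors and their covariance blocks.
    """
    def ols(X, y, names):
        XtX = X.T @ X
        if np.linalg.cond(XtX) > 1e12:
            raise np.linalg.LinAlgError(
                f"singular design (collinear covariates among {list(names)})")
        return np.linalg.solve(XtX, X.T @ y)

    b1 = ols(X1, y1, names1)
    b2 = ols(X2, y2, names2)
    r1 = y1 - X1 @ b1
    r2 = y2 - X2 @ b2
    n = len(y1)
    sigma = np.array([[r1 @ r1, r1 @ r2], [r1 @ r2, r2 @ r2]]) / n
    w = np.linalg.inv(sigma)
    k1, k2 = X1.shape[1], X2.shape[1]
    A = np.zeros((k1 + k2, k1 + k2))
    A[:k1, :k1] = w[0, 0] * (X1.T @ X1)
    A[:k1, k1:] = w[0, 1] * (X1.T @ X2)
    A[k1:, :k1] = w[1, 0] * (X2.T @ X1)
    A[k1:, k1:] = w[1, 1] * (X2.T @ X2)
    b = np.concatenate([w[0, 0] * (X1.T @ y1) + w[0, 1] * (X1.T @ y2),
                        w[1, 0] * (X2.T @ y1) + w[1, 1] * (X2.T @ y2)])
    beta = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)
    return beta[:k1], beta[k1:], cov


def adjusted_incrementals(dataset: TrialDataset, effect: str = "qaly",
                          horizon: int = 6, exclude_deaths: bool = True) -> dict:
    """Covariate-adjusted incremental cost and effect (arm coefficients).

    Cost and effect equations are estimated jointly (FGLS with
    cross-equation error correlation); covariates are age, gender, site and
    stage, with baseline EQ-5D added to the QALY equation.  For
    ``effect='hospitalisations'`` the effect is hospitalisations averted
    (a reduction counts as a gain).
    """
    if effect not in ("qaly", "hospitalisations"):
        raise ValueError(f"unknown effect {effect!r}")
    frame = dataset.analysis_frame(horizon=horizon, exclude_deaths=exclude_deaths)
    y_cost = frame["cost"].to_numpy(dtype=float)
    if effect == "qaly":
        y_eff = frame["qaly"].to_numpy(dtype=float)
        X_eff = _design(frame, with_baseline=True)
    else:
        y_eff = -frame["hosp"].to_numpy(dtype=float)
        X_eff = _design(frame, with_baseline=False)
    X_cost = _design(frame, with_baseline=False)
    b_cost, b_eff, cov = _sur_fgls(
        X_cost.to_numpy(), y_cost, X_eff.to_numpy(), y_eff,
        X_cost.columns, X_eff.columns)
    i_cost = list(X_cost.columns).index("arm")
    i_eff = list(X_eff.columns).index("arm")
    k1 = X_cost.shape[1]
    return {
        "delta_cost": float(b_cost[i_cost]),
        "delta_effect": float(b_eff[i_eff]),
        "se_cost": float(np.sqrt(cov[i_cost, i_cost])),
        "se_effect": float(np.sqrt(cov[k1 + i_eff, k1 + i_eff])),
        "effect": effect,
        "n": int(len(frame)),
    }


# ---------------------------------------------------------------------------
# bootstrap CEA


@dataclass
class BootstrapCEOutput:
    """Replicate-wise incremental (cost, effect) pairs and derived summaries."""

    replicates: np.ndarray  # (n_reps, 2): delta_cost, delta_effect
    delta_cost: float
    delta_effect: float
    se_cost: float
    se_effect: float
    effect_name: str
    wtp_grid: tuple[float, ...]
    ceac: dict[float, float] = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return int(self.replicates.shape[0])

    @property
    def icer(self) -> float | None:
        icer, _ = icer_and_label(self.delta_cost, self.delta_effect)
        return icer

    @property
    def dominance(self) -> str:
        _, label = icer_and_label(self.delta_cost, self.delta_effect)
        return label

    def prob_cost_effective(self, wtp: float) -> float:
        dc, de = self.replicates[:, 0], self.replicates[:, 1]
        return float(np.mean(wtp * de - dc > 0))

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "se_cost": self.se_cost,
            "se_effect": self.se_effect,
            "icer": self.icer,
            "dominance": self.dominance,
            "effect": self.effect_name,
            "n_reps": self.n_reps,
            "ceac": {str(k): v for k, v in self.ceac.items()},
        }


def bootstrap_cea(dataset: TrialDataset, n_reps: int = 5000,
                  wtp_grid: Sequence[float] = (0, 10000, 20000, 30000, 40000, 50000),
                  effect: str = "qaly", horizon: int = 6, seed: int | None = 0,
                  exclude_deaths: bool = True) -> BootstrapCEOutput:
    """Non-parametric bootstrap of the adjusted incremental cost and effect.

    Patients are resampled with replacement within arm (arm sizes
    preserved); the SUR adjustment is re-estimated per replicate.  The point
    ICER is the ratio of the full-sample adjusted increments; the CEAC is
    the fraction of replicates with positive net benefit at each threshold.
    """
    if n_reps < 100:
        raise ValueError("n_reps < 100 gives unstable probabilities")
    point = adjusted_incrementals(dataset, effect=effect, horizon=horizon,
                                  exclude_deaths=exclude_deaths)
    frame = dataset.analysis_frame(horizon=horizon, exclude_deaths=exclude_deaths)
    y_cost = frame["cost"].to_numpy(dtype=float)
    if effect == "qaly":
        y_eff = frame["qaly"].to_numpy(dtype=float)
        X_eff_df = _design(frame, with_baseline=True)
    else:
        y_eff = -frame["hosp"].to_numpy(dtype=float)
        X_eff_df = _design(frame, with_baseline=False)
    X_cost_df = _design(frame, with_baseline=False)
    X_cost, X_eff = X_cost_df.to_numpy(), X_eff_df.to_numpy()
    i_cost = list(X_cost_df.columns).index("arm")
    i_eff = list(X_eff_df.columns).index("arm")

    arm_idx = {a: np.flatnonzero((frame["arm"] == a).to_numpy()) for a in ARMS}
    rng = np.random.default_rng(seed)
    reps = np.empty((n_reps, 2))
    for r in range(n_reps):
        idx = np.concatenate([rng.choice(arm_idx[a], size=arm_idx[a].size,
                                         replace=True) for a in ARMS])
        try:
            b_cost, b_eff, _ = _sur_fgls(X_cost[idx], y_cost[idx],
                                         X_eff[idx], y_eff[idx],
                                         X_cost_df.columns, X_eff_df.columns)
            reps[r] = (b_cost[i_cost], b_eff[i_eff])
        except np.linalg.LinAlgError:
            # degenerate resample (e.g. a dummy collapses); fall back to the
            # unadjusted within-replicate arm-mean difference
            sel = frame.iloc[idx]
            grp_c = sel.groupby("arm")["cost"].mean()
            col = "qaly" if effect == "qaly" else "hosp"
            grp_e = sel.groupby("arm")[col].mean()
            de = grp_e.get("intervention", 0) - grp_e.get("usual_care", 0)
            if effect != "qaly":
                de = -de
            reps[r] = (grp_c.get("intervention", 0) - grp_c.get("usual_care", 0), de)

    ceac = {float(w): float(np.mean(w * reps[:, 1] - reps[:, 0] > 0))
            for w in wtp_grid}
    return BootstrapCEOutput(
        replicates=reps,
        delta_cost=point["delta_cost"],
        delta_effect=point["delta_effect"],
        se_cost=float(reps[:, 0].std(ddof=1)),
        se_effect=float(reps[:, 1].std(ddof=1)),
        effect_name=effect,
        wtp_grid=tuple(float(w) for w in wtp_grid),
        ceac=ceac,
    )


def hospitalisation_cea(dataset: TrialDataset, n_reps: int = 5000,
                        seed: int | None = 0, horizon: int = 6,
                        wtp_grid: Sequence[float] = (0, 500, 1000, 5000, 10000,
                                                     20000, 30000),
                        exclude_deaths: bool = True) -> BootstrapCEOutput:
    """Cost per hospitalisation averted (identical bootstrap machinery)."""
    return bootstrap_cea(dataset, n_reps=n_reps, wtp_grid=wtp_grid,
                         effect="hospitalisations", horizon=horizon, seed=seed,
                         exclude_deaths=exclude_deaths)


def unadjusted_summary(dataset: TrialDataset, horizon: int = 6,
                       exclude_deaths: bool = True) -> pd.DataFrame:
    """Arm-level mean (SE) QALYs, costs and hospitalisations."""
    frame = dataset.analysis_frame(horizon=horizon, exclude_deaths=exclude_deaths)
    rows = []
    for a in ARMS:
        sub = frame[frame["arm"] == a]
        rows.append({
            "arm": a, "n": len(sub),
            "mean_qaly": sub["qaly"].mean(),
            "se_qaly": sub["qaly"].std(ddof=1) / np.sqrt(len(sub)),
            "mean_cost": sub["cost"].mean(),
            "se_cost": sub["cost"].std(ddof=1) / np.sqrt(len(sub)),
            "mean_hosp": sub["hosp"].mean(),
            "se_hosp": sub["hosp"].std(ddof=1) / np.sqrt(len(sub)),
        })
    return pd.DataFrame(rows)
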