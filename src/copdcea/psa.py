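"""Probabilistic sensitivity analysis and value-of-information analysis.

Each PSA iteration samples every parameter from its stated distribution
(betas for probabilities and utilities, gammas/normals for costs, lognormal
for the relative risk), runs both arms through the Markov engine and records
totals plus the sampled-parameter digest.  Iterations draw from independent
child RNG streams of a single root seed, so results do not depend on
execution order.  The digest feeds regression-based EVPPI; a nested
two-level Monte Carlo estimator is retained as a small-scale oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures

from copdcea import markov
from copdcea.parameters import DistributionSpec, ParameterSet

ARMS = ("usual_care", "intervention")

#: Default parameter groups: digest-name prefixes.
DEFAULT_GROUPS = {
    "starting_states": "start.",
    "transitions": "tp.",
    "exacerbation_rates": "exac.",
    "utilities": "util.",
    "costs": "cost.",
    "treatment_effect": "eff.",
}

_MAX_ROW_RESAMPLES = 100


class ParameterSampler:
    """Draws a full sampled-parameter digest for one PSA iteration.

    ``center='point'`` (default) shifts beta/gamma draws additively so their
    sampling mean equals the deterministic point estimate while keeping the
    stated dispersion — several printed alpha/beta pairs imply means far from
    the printed points, which would otherwise make the PSA mean inconsistent
    with the deterministic base case.  ``center='printed'`` samples the raw
    stated distributions.

    ``variance_scale`` shrinks every draw toward its centre by
    ``sqrt(scale)`` (0 collapses the PSA to a deterministic run), used for
    variance-sensitivity checks.  ``fixed`` pins named parameters, enabling
    nested EVPPI conditioning.
    """

    def __init__(self, params: ParameterSet, variance_scale: float = 1.0,
                 center: str = "point"):
        if variance_scale < 0:
            raise ValueError("variance_scale must be non-negative")
        if center not in ("point", "printed"):
            raise ValueError(f"unknown center {center!r}")
        self.params = params
        self.variance_scale = variance_scale
        self.center = center
        self.resample_count = 0
        self._specs = self._collect_specs(params)
        # moment-match the normalised starting proportions to the points:
        # normalising independent beta draws shifts their means (Jensen), so
        # calibrate an additive correction on an internal stream once
        self._start_correction: dict[str, float] = {}
        if center == "point":
            rng = np.random.default_rng(987654321)
            for arm in ARMS:
                names = [f"start.{arm}.{st}" for st in params.stage_labels]
                draws = np.column_stack(
                    [self._specs[n].sample(rng, size=20000) for n in names])
                norm = draws / draws.sum(axis=1, keepdims=True)
                pts = np.array([self._specs[n].point for n in names])
                for n, c in zip(names, pts - norm.mean(axis=0)):
                    self._start_correction[n] = float(c)

    @staticmethod
    def _collect_specs(params: ParameterSet) -> dict[str, DistributionSpec]:
        sp = params.stage_params
        specs: dict[str, DistributionSpec] = {}
        for arm in ARMS:
            for st, spec in params.starting_states[arm].items():
                specs[f"start.{arm}.{st}"] = spec
        for (i, j), spec in sorted(params.usual_care_matrix.cells.items()):
            specs[f"tp.{i}.{j}"] = spec
        for st, spec in sp.exac_rates.items():
            specs[f"exac.{st}"] = spec
        for st, spec in sp.utilities.items():
            specs[f"util.{st}"] = spec
        specs["util.disutility"] = sp.exac_disutility
        specs["cost.stage_b"] = sp.monthly_cost_b
        specs["cost.stage_d"] = sp.monthly_cost_d
        specs["cost.ac_decrement"] = sp.ac_decrement
        specs["cost.admission"] = sp.admission_cost
        specs["cost.bed_day"] = sp.bed_day_cost
        specs["cost.intervention_monthly"] = sp.intervention_monthly_cost
        specs["eff.rr_year2"] = params.effects.base_rr_year2
        specs["eff.bed_day_reduction"] = params.effects.bed_day_reduction
        return specs

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def _draw(self, name: str, rng: np.random.Generator) -> float:
        spec = self._specs[name]
        x = float(spec.sample(rng))
        if self.center == "point" and spec.family in ("beta", "gamma"):
            x += spec.point - spec.mean()
        s = self.variance_scale
        if s != 1.0:
            m = spec.point if self.center == "point" else spec.mean()
            x = m + (x - m) * np.sqrt(s)
        if name.startswith(("start.", "tp.", "exac.")) or name.startswith("util."):
            if name.startswith("util.") and not name.endswith("disutility"):
                x = min(max(x, -0.594), 1.0)
            else:
                x = min(max(x, 0.0), 1.0)
        elif name.startswith("cost."):
            x = max(x, 0.0)
        elif name == "eff.rr_year2":
            x = max(x, 1e-9)
        return x

    def sample(self, rng: np.random.Generator,
               fixed: Mapping[str, float] | None = None) -> dict[str, float]:
        fixed = dict(fixed or {})
        out: dict[str, float] = {}
        labels = self.params.stage_labels
        if self.center == "point":
            # starting states: sample the arm's betas jointly, normalise and
            # apply the calibrated mean correction
            for arm in ARMS:
                names = [f"start.{arm}.{st}" for st in labels]
                raw = np.array([float(self._specs[n].sample(rng)) for n in names])
                norm = raw / raw.sum()
                for n, v in zip(names, norm):
                    v = v + self._start_correction[n]
                    if self.variance_scale != 1.0:
                        pt = self._specs[n].point
                        v = pt + (v - pt) * np.sqrt(self.variance_scale)
                    out[n] = fixed[n] if n in fixed else float(min(max(v, 0.0), 1.0))
        for name in self._specs:
            if name.startswith("tp.") or name in out:
                continue  # matrix rows handled below
            out[name] = fixed[name] if name in fixed else self._draw(name, rng)
        # matrix rows: resample a row whose off-diagonal sum exceeds 1; a
        # sampled RR above 1 inflates beneficial cells, so feasibility is
        # checked against the worst-case multiplier
        rr2 = out.get("eff.rr_year2", self.params.effects.base_rr_year2.point)
        beneficial = {tuple(c) for c in self.params.effects.beneficial_cells}
        mult = max(rr2, 1.0)
        for i in labels:
            row_names = [f"tp.{i}.{j}" for j in labels
                         if f"tp.{i}.{j}" in self._specs]
            if not row_names:
                continue
            for attempt in range(_MAX_ROW_RESAMPLES + 1):
                vals = {n: (fixed[n] if n in fixed else self._draw(n, rng))
                        for n in row_names}
                total = sum(v * (mult if (i, n.split(".")[2]) in beneficial else 1.0)
                            for n, v in vals.items())
                if total <= 1.0:
                    out.update(vals)
                    break
                self.resample_count += 1
                if attempt == _MAX_ROW_RESAMPLES or all(n in fixed for n in row_names):
                    raise RuntimeError(
                        f"transition row {i} exceeded probability 1 after "
                        f"{_MAX_ROW_RESAMPLES} resamples")
        return out


@dataclass
class PSAOutput:
    """Per-iteration per-arm totals plus the sampled-parameter digest."""

    costs: dict[str, np.ndarray]
    qalys: dict[str, np.ndarray]
    digest: pd.DataFrame
    seed: int | None
    params: ParameterSet | None = None
    resample_count: int = 0

    def __post_init__(self):
        horizon_years = (self.params.horizon_years if self.params is not None
                         else None)
        for arm in ARMS:
            if not np.all(np.isfinite(self.costs[arm])):
                raise ValueError(f"non-finite costs in arm {arm}")
            if not np.all(np.isfinite(self.qalys[arm])):
                raise ValueError(f"non-finite QALYs in arm {arm}")
            if horizon_years is not None:
                q = self.qalys[arm]
                if np.any(q < -1e-9) or np.any(q > horizon_years + 1e-9):
                    raise ValueError(f"QALYs outside [0, {horizon_years}] in {arm}")

    @property
    def n_iter(self) -> int:
        return int(self.costs["usual_care"].size)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs["intervention"] - self.costs["usual_care"]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qalys["intervention"] - self.qalys["usual_care"]

    def net_benefit(self, wtp: float) -> np.ndarray:
        """(n_iter, 2) array of per-arm net monetary benefit at ``wtp``."""
        return np.column_stack([wtp * self.qalys[a] - self.costs[a] for a in ARMS])

    def ce_plane(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost,
                             "delta_qaly": self.delta_qaly})


def run_psa(params: ParameterSet, n_iter: int = 10000, seed: int | None = 0,
            fixed: Mapping[str, float] | None = None,
            variance_scale: float = 1.0, center: str = "point") -> PSAOutput:
    """Run the probabilistic sensitivity analysis.

    One child RNG stream per iteration derived from ``seed``; the same seed
    reproduces every iteration bit-for-bit.
    """
    sampler = ParameterSampler(params, variance_scale=variance_scale,
                               center=center)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_iter)]
    costs = {a: np.empty(n_iter) for a in ARMS}
    qalys = {a: np.empty(n_iter) for a in ARMS}
    rows = []
    for k, rng in enumerate(streams):
        digest = sampler.sample(rng, fixed=fixed)
        ri = markov.resolve(params, digest)
        for arm in ARMS:
            tr = markov.run_cohort(params, arm, resolved=ri)
            costs[arm][k] = tr.total_cost
            qalys[arm][k] = tr.total_qaly
        rows.append(digest)
    return PSAOutput(costs=costs, qalys=qalys,
                     digest=pd.DataFrame(rows), seed=seed, params=params,
                     resample_count=sampler.resample_count)


def ceac(psa: PSAOutput, wtp_grid: Sequence[float]) -> dict[float, float]:
    """Probability the intervention is cost-effective at each threshold."""
    if psa.n_iter == 0:
        raise ValueError("empty PSA")
    dc, dq = psa.delta_cost, psa.delta_qaly
    return {float(w): float(np.mean(w * dq - dc > 0)) for w in wtp_grid}


def evpi(psa: PSAOutput, wtp: float) -> float:
    """Per-patient expected value of perfect information at ``wtp``.

    Mean over iterations of the best-arm net benefit, minus the net benefit
    of the best arm on average.
    """
    if psa.n_iter == 0:
        raise ValueError("empty PSA")
    nb = psa.net_benefit(wtp)
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def evpi_curve(psa: PSAOutput, wtp_grid: Sequence[float]) -> dict[float, float]:
    return {float(w): evpi(psa, w) for w in wtp_grid}


def _group_columns(psa: PSAOutput, parameter_group: str | Sequence[str]) -> list[str]:
    if isinstance(parameter_group, str):
        prefix = DEFAULT_GROUPS.get(parameter_group, parameter_group)
        cols = [c for c in psa.digest.columns if c.startswith(prefix)]
        if not cols:
            raise KeyError(f"parameter group {parameter_group!r} not recorded")
        return cols
    cols = list(parameter_group)
    missing = [c for c in cols if c not in psa.digest.columns]
    if missing:
        raise KeyError(f"parameters not recorded: {missing}")
    return cols


def evppi(psa: PSAOutput, parameter_group: str | Sequence[str], wtp: float,
          method: str = "regression", seed: int | None = 0,
          n_outer: int = 40, n_inner: int = 40) -> float:
    """Per-patient expected value of perfect information on a parameter group.

    ``regression`` (default) fits a flexible smoother of the incremental net
    benefit on the group's sampled values and evaluates
    ``E[max(fit, 0)] - max(E[fit], 0)`` — no extra model runs.  ``nested``
    re-runs the model in a two-level Monte Carlo at reduced scale (oracle
    use).  Results are clipped to ``[0, EVPI]``.
    """
    total = evpi(psa, wtp)
    if method == "regression":
        if psa.n_iter < 500:
            raise ValueError("regression EVPPI needs at least 500 iterations")
        cols = _group_columns(psa, parameter_group)
        X = psa.digest[cols].to_numpy(dtype=float)
        keep = X.std(axis=0) > 0
        if not keep.any():
            return 0.0
        X = X[:, keep]
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        degree = 2 if X.shape[1] <= 8 else 1
        feats = PolynomialFeatures(degree=degree, include_bias=False).fit_transform(X)
        inb = psa.net_benefit(wtp)
        g = LinearRegression().fit(feats, inb[:, 1] - inb[:, 0]).predict(feats)
        val = float(np.maximum(g, 0.0).mean() - max(g.mean(), 0.0))
        return float(np.clip(val, 0.0, total))
    if method == "nested":
        if psa.params is None:
            raise ValueError("nested EVPPI needs the parameter set on the PSA output")
        cols = _group_columns(psa, parameter_group)
        sampler = ParameterSampler(psa.params)
        outer_ss, inner_ss = np.random.SeedSequence(seed).spawn(2)
        outer_rngs = [np.random.default_rng(s) for s in outer_ss.spawn(n_outer)]
        inner_seeds = inner_ss.spawn(n_outer)
        best_cond = np.empty(n_outer)
        arm_means = np.zeros((n_outer, 2))
        for o, rng in enumerate(outer_rngs):
            outer_draw = sampler.sample(rng)
            fixed = {c: outer_draw[c] for c in cols}
            inner = run_psa(psa.params, n_iter=n_inner, seed=inner_seeds[o],
                            fixed=fixed)
            nb = inner.net_benefit(wtp)
            cond = nb.mean(axis=0)
            arm_means[o] = cond
            best_cond[o] = cond.max()
        val = float(best_cond.mean() - arm_means.mean(axis=0).max())
        return float(np.clip(val, 0.0, total))
    raise ValueError(f"unknown EVPPI method {method!r}")


@dataclass
class VoIResult:
    """Per-patient EVPI over thresholds, per-group EVPPI, population scaling."""

    wtp_grid: tuple[float, ...]
    evpi_per_patient: dict[float, float]
    evppi_per_group: dict[str, float] = field(default_factory=dict)
    population: int | None = None
    population_evpi: float | None = None

    def to_dict(self) -> dict:
        return {
            "wtp_grid": list(self.wtp_grid),
            "evpi_per_patient": {str(k): v for k, v in self.evpi_per_patient.items()},
            "evppi_per_group": self.evppi_per_group,
            "population": self.population,
            "population_evpi": self.population_evpi,
        }


def population_voi(per_patient_value: float, population: int,
                   horizon_years: int = 1, discount_rate: float = 0.0) -> float:
    """Scale a per-patient value to the eligible population over a horizon.

    The first year is undiscounted; each later year is discounted at the
    annual rate.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    factor = sum((1.0 + discount_rate) ** (-y) for y in range(horizon_years))
    return float(per_patient_value * population * factor)


def value_of_information(psa: PSAOutput, wtp_grid: Sequence[float],
                         groups: Sequence[str] = tuple(DEFAULT_GROUPS),
                         wtp_for_evppi: float = 20000.0,
                         population: int = 626129, horizon_years: int = 1,
                         discount_rate: float = 0.0,
                         seed: int | None = 0) -> VoIResult:
    """Convenience wrapper assembling the full VoI summary."""
    curve = evpi_curve(psa, wtp_grid)
    per_group = ({g: evppi(psa, g, wtp_for_evppi, seed=seed) for g in groups}
                 if psa.n_iter >= 500 else {})
    pop = population_voi(curve.get(float(wtp_for_evppi), evpi(psa, wtp_for_evppi)),
                         population, horizon_years, discount_rate)
    return VoIResult(wtp_grid=tuple(float(w) for w in wtp_grid),
                     evpi_per_patient=curve, evppi_per_group=per_group,
                     population=population, population_evpi=pop)
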