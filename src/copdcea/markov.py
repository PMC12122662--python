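"""Five-year monthly-cycle Markov cohort model with tunnel states.

State space: the living GOLD stages, a 3-month post-discharge tunnel chain
per stage, and one absorbing dead state.  Hospitalised exacerbations route
survivors through the tunnel chain of their post-admission landing stage
(admission history reclassifies low-risk stages to high-risk: A->C, B->D in
the four-stage structure; A->E, B->E when C and D are merged).

Within a cycle the event order is: exacerbation draw first, then the
transition matrix for non-exacerbators, then tunnel advancement.  Year-1
costs and QALYs are trial-derived totals taken as given (spread uniformly
over cycles 1-12, undiscounted); cycles 13 onwards evolve the cohort and are
discounted at ``(1 + r)^(-t/12)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from copdcea import effects as fx
from copdcea.parameters import (
    ACE_LANDING,
    ACE_STAGES,
    DistributionSpec,
    ParameterSet,
    StageParams,
    TransitionMatrix,
)

ARMS = ("usual_care", "intervention")
TUNNEL_MONTHS = 3


class StateSpace:
    """Index bookkeeping for stages, tunnel chains and the dead state."""

    def __init__(self, labels, landing: Mapping[str, str]):
        self.labels = tuple(labels)
        self.landing = dict(landing)
        if set(self.landing) != set(self.labels):
            raise ValueError("landing map must cover every living stage")
        for s, target in self.landing.items():
            if target not in self.labels:
                raise ValueError(f"landing target {target!r} not a living stage")
        self.n_stages = len(self.labels)
        self.n_states = self.n_stages * (1 + TUNNEL_MONTHS) + 1
        self.dead = self.n_states - 1
        self._stage_idx = {s: i for i, s in enumerate(self.labels)}

    def stage(self, label: str) -> int:
        return self._stage_idx[label]

    def tunnel(self, label: str, month: int) -> int:
        """Index of tunnel month 1..3 attached to a landing stage."""
        if not (1 <= month <= TUNNEL_MONTHS):
            raise ValueError(f"tunnel month {month} outside 1..{TUNNEL_MONTHS}")
        return self.n_stages + self._stage_idx[label] * TUNNEL_MONTHS + (month - 1)

    @property
    def state_names(self) -> tuple[str, ...]:
        names = list(self.labels)
        for s in self.labels:
            names += [f"tunnel_{s}_{m}" for m in range(1, TUNNEL_MONTHS + 1)]
        names.append("dead")
        return tuple(names)


@dataclass
class ResolvedInputs:
    """Plain numeric model inputs for one model run.

    Produced by :func:`resolve` either from point estimates or from a dict
    of PSA-sampled values keyed by the sampler's parameter names.
    """

    space: StateSpace
    start: dict[str, np.ndarray]  # arm -> stage-occupancy vector
    matrices: dict[str, dict[int, np.ndarray]]  # arm -> model year -> matrix
    utilities: dict[str, float]
    monthly_costs: dict[str, float]
    exac_rates: dict[str, dict[int, np.ndarray]]  # arm -> year -> per-stage vector
    tunnel_disutility: float  # per tunnel month
    admission_cost: dict[str, float]
    intervention_monthly_cost: float
    death_on_admission: float
    discount_rate: float
    horizon: int
    year1: dict[str, dict[str, float]]

    def discount_factor(self, t: int) -> float:
        if t <= 12:
            return 1.0
        return (1.0 + self.discount_rate) ** (-t / 12.0)


def _build_matrix(labels, points: Mapping[tuple[str, str], float]) -> np.ndarray:
    n = len(labels)
    idx = {lab: k for k, lab in enumerate(labels)}
    m = np.zeros((n, n))
    for (i, j), p in points.items():
        if p < 0:
            raise ValueError(f"negative transition probability at ({i}, {j})")
        m[idx[i], idx[j]] = p
    off = m.sum(axis=1)
    if np.any(off > 1.0 + 1e-12):
        bad = labels[int(np.argmax(off))]
        raise ValueError(f"row {bad}: off-diagonal sum {off.max():.6f} exceeds 1")
    np.fill_diagonal(m, 1.0 - off)
    return m


def resolve(params: ParameterSet, sampled: Mapping[str, float] | None = None) -> ResolvedInputs:
    """Turn a :class:`ParameterSet` (plus optional sampled values) into
    plain numbers the engine consumes."""
    s = sampled or {}
    get = lambda key, default: float(s.get(key, default))  # noqa: E731
    labels = params.stage_labels
    space = StateSpace(labels, params.landing)
    sched = params.effects

    # starting states: raw (possibly sampled) values normalised per arm
    start = {}
    for arm in ARMS:
        raw = np.array([get(f"start.{arm}.{st}", params.starting_states[arm][st].point)
                        for st in labels])
        if raw.sum() <= 0:
            raise ValueError(f"starting-state mass for {arm} is zero")
        start[arm] = raw / raw.sum()

    # usual-care matrix cells, then per-year intervention adjustment
    uc_points = {key: get(f"tp.{key[0]}.{key[1]}", spec.point)
                 for key, spec in params.usual_care_matrix.cells.items()}
    uc_matrix = _build_matrix(labels, uc_points)
    rr2 = get("eff.rr_year2", sched.base_rr_year2.point)
    years = range(2, params.horizon_years + 1)
    matrices = {"usual_care": {y: uc_matrix for y in years}, "intervention": {}}
    beneficial = set(tuple(c) for c in sched.beneficial_cells)
    for y in years:
        rr_y = 1.0 - (1.0 - rr2) * sched.decay ** (y - sched.first_effect_year)
        pts = {key: (p * rr_y if key in beneficial else p)
               for key, p in uc_points.items()}
        matrices["intervention"][y] = _build_matrix(labels, pts)

    # exacerbation rates; the reduction schedule is deterministic unless an
    # explicit scale override is sampled (rate uncertainty lives in the
    # per-stage beta specs)
    base_rates = np.array([get(f"exac.{st}", params.stage_params.exac_rates[st].point)
                           for st in labels])
    base_rates = np.clip(base_rates, 0.0, 1.0)
    scale = get("eff.exac_scale", 1.0)
    in_effect = np.array([st in sched.effect_stages for st in labels])
    exac = {"usual_care": {y: base_rates for y in years}, "intervention": {}}
    for y in years:
        mult = 1.0 - sched.exac_reduction_schedule.get(y, 0.0) * scale
        rates = base_rates.copy()
        rates[in_effect] = np.clip(rates[in_effect] * max(mult, 0.0), 0.0, 1.0)
        exac["intervention"][y] = rates

    # utilities and costs
    utilities = {st: get(f"util.{st}", params.stage_params.utilities[st].point)
                 for st in labels}
    disut = get("util.disutility", params.stage_params.exac_disutility.point)
    if params.tunnel_disutility_mode == "total_spread":
        disut = disut / TUNNEL_MONTHS
    cost_b = get("cost.stage_b", params.stage_params.monthly_cost_b.point)
    cost_d = get("cost.stage_d", params.stage_params.monthly_cost_d.point)
    dec = get("cost.ac_decrement", params.stage_params.ac_decrement.point)
    monthly_costs = {}
    for st in labels:
        if st == "A":
            monthly_costs[st] = max(cost_b - dec, 0.0)
        elif st == "B":
            monthly_costs[st] = max(cost_b, 0.0)
        elif st == "C":
            monthly_costs[st] = max(cost_d - dec, 0.0)
        else:  # D, or pooled E
            monthly_costs[st] = max(cost_d, 0.0)

    adm = get("cost.admission", params.stage_params.admission_cost.point)
    bed = get("cost.bed_day", params.stage_params.bed_day_cost.point)
    red = get("eff.bed_day_reduction", sched.bed_day_reduction.point)
    admission_cost = {"usual_care": max(adm, 0.0),
                      "intervention": max(adm - red * bed, 0.0)}

    return ResolvedInputs(
        space=space,
        start=start,
        matrices=matrices,
        utilities=utilities,
        monthly_costs=monthly_costs,
        exac_rates=exac,
        tunnel_disutility=disut,
        admission_cost=admission_cost,
        intervention_monthly_cost=get(
            "cost.intervention_monthly",
            params.stage_params.intervention_monthly_cost.point),
        death_on_admission=get("model.death_on_admission", params.death_on_admission),
        discount_rate=params.discount_rate_annual,
        horizon=params.horizon_months,
        year1=params.year1,
    )


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and accrued (discounted) costs and QALYs."""

    arm: str
    space: StateSpace
    occupancy: np.ndarray  # (horizon + 1, n_states); row 0 is the start
    admissions: np.ndarray  # newly admitted fraction in cycle t
    cost_inc: np.ndarray = None
    qaly_inc: np.ndarray = None
    cost_inc_disc: np.ndarray = None
    qaly_inc_disc: np.ndarray = None

    @property
    def total_cost(self) -> float:
        return float(self.cost_inc_disc.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_inc_disc.sum())

    def check_mass(self, tol: float = 1e-9):
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            t = int(np.argmax(np.abs(sums - 1.0)))
            raise AssertionError(f"cycle {t}: occupancy sums to {sums[t]!r}")
        if np.any(self.occupancy < -1e-12):
            raise AssertionError("negative occupancy")

    def to_frame(self) -> pd.DataFrame:
        names = self.space.state_names
        t_axis = np.arange(self.occupancy.shape[0])
        rows = []
        for t in t_axis:
            for k, name in enumerate(names):
                rows.append((t, name, self.occupancy[t, k]))
        df = pd.DataFrame(rows, columns=["cycle", "state", "occupancy"])
        inc = pd.DataFrame({
            "cycle": t_axis,
            "admissions": self.admissions,
            "cost_inc": self.cost_inc,
            "qaly_inc": self.qaly_inc,
            "cost_inc_disc": self.cost_inc_disc,
            "qaly_inc_disc": self.qaly_inc_disc,
        })
        return df.merge(inc, on="cycle")


def model_year(t: int) -> int:
    """Model year (1-based) containing cycle month ``t`` (1-based)."""
    return (t - 1) // 12 + 1


def cycle_step(occ: np.ndarray, matrix: np.ndarray, exac_rates: np.ndarray,
               death_on_admission: float, space: StateSpace):
    """Advance the cohort one month.

    Returns ``(new_occupancy, newly_admitted_fraction)``.  Exacerbators are
    drawn first (of whom ``death_on_admission`` die and survivors enter
    tunnel month 1 of their landing stage); the remainder move by the
    transition matrix; tunnel occupants advance, exiting after month 3.
    """
    S = space.n_stages
    stage_occ = occ[:S]
    new = np.zeros_like(occ)

    exa = stage_occ * exac_rates
    survivors = exa * (1.0 - death_on_admission)
    new[space.dead] = occ[space.dead] + exa.sum() * death_on_admission

    moved = (stage_occ - exa) @ matrix
    new[:S] += moved
    for i, s in enumerate(space.labels):
        new[space.tunnel(space.landing[s], 1)] += survivors[i]

    for s in space.labels:
        for m in range(1, TUNNEL_MONTHS):
            new[space.tunnel(s, m + 1)] += occ[space.tunnel(s, m)]
        new[space.stage(s)] += occ[space.tunnel(s, TUNNEL_MONTHS)]

    if np.any(new < -1e-12):
        raise ValueError("negative intermediate mass: invalid inputs")
    return new, float(exa.sum())


def accrue(trace: CohortTrace, resolved: ResolvedInputs) -> tuple[float, float]:
    """Fill per-cycle cost/QALY increments on ``trace``; return totals.

    Cycles 1-12 spread the trial-derived year-1 arm totals uniformly and
    undiscounted.  Later cycles accrue from start-of-cycle occupancy:
    state utilities (tunnels carry the landing-stage utility minus the
    post-discharge decrement), monthly stage costs, admission costs for the
    cycle's new admissions, and the monthly intervention cost for the alive
    fraction on the intervention arm.
    """
    space = trace.space
    S = space.n_stages
    T = resolved.horizon
    u_vec = np.zeros(space.n_states)
    c_vec = np.zeros(space.n_states)
    for s in space.labels:
        u_vec[space.stage(s)] = resolved.utilities[s]
        c_vec[space.stage(s)] = resolved.monthly_costs[s]
        for m in range(1, TUNNEL_MONTHS + 1):
            u_vec[space.tunnel(s, m)] = resolved.utilities[s] - resolved.tunnel_disutility
            c_vec[space.tunnel(s, m)] = resolved.monthly_costs[s]

    cost = np.zeros(T + 1)
    qaly = np.zeros(T + 1)
    cost_d = np.zeros(T + 1)
    qaly_d = np.zeros(T + 1)

    y1 = resolved.year1[trace.arm]
    cost[1:13] = y1["cost"] / 12.0
    qaly[1:13] = y1["qaly"] / 12.0
    cost_d[1:13] = cost[1:13]
    qaly_d[1:13] = qaly[1:13]

    adm_cost = resolved.admission_cost[trace.arm]
    int_monthly = (resolved.intervention_monthly_cost
                   if trace.arm == "intervention" else 0.0)
    for t in range(13, T + 1):
        occ = trace.occupancy[t - 1]
        alive = 1.0 - occ[space.dead]
        qaly[t] = float(occ @ u_vec) / 12.0
        cost[t] = float(occ @ c_vec) + trace.admissions[t] * adm_cost + alive * int_monthly
        df = resolved.discount_factor(t)
        qaly_d[t] = qaly[t] * df
        cost_d[t] = cost[t] * df

    trace.cost_inc, trace.qaly_inc = cost, qaly
    trace.cost_inc_disc, trace.qaly_inc_disc = cost_d, qaly_d
    return trace.total_cost, trace.total_qaly


def run_cohort(params: ParameterSet, arm: str,
               sampled: Mapping[str, float] | None = None,
               resolved: ResolvedInputs | None = None) -> CohortTrace:
    """Run the cohort for one arm and return the complete accrued trace."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    ri = resolved if resolved is not None else resolve(params, sampled)
    space = ri.space
    T = ri.horizon
    occ = np.zeros((T + 1, space.n_states))
    start = np.zeros(space.n_states)
    start[:space.n_stages] = ri.start[arm]
    occ[0:13] = start  # cohort held at the 12-month trial distribution
    admissions = np.zeros(T + 1)
    for t in range(13, T + 1):
        y = model_year(t)
        occ[t], admissions[t] = cycle_step(
            occ[t - 1], ri.matrices[arm][y], ri.exac_rates[arm][y],
            ri.death_on_admission, space)
    trace = CohortTrace(arm=arm, space=space, occupancy=occ, admissions=admissions)
    trace.check_mass()
    accrue(trace, ri)
    return trace


# ---------------------------------------------------------------------------
# cost-effectiveness results


@dataclass
class CEResult:
    """Incremental cost-effectiveness of intervention vs usual care."""

    arm_costs: dict[str, float]
    arm_effects: dict[str, float]
    effect_name: str = "qaly"
    wtp_grid: tuple[float, ...] = ()
    prob_ce: dict[float, float] | None = None

    @property
    def delta_cost(self) -> float:
        return self.arm_costs["intervention"] - self.arm_costs["usual_care"]

    @property
    def delta_effect(self) -> float:
        return self.arm_effects["intervention"] - self.arm_effects["usual_care"]

    @property
    def icer(self) -> float | None:
        icer, _ = icer_and_label(self.delta_cost, self.delta_effect)
        return icer

    @property
    def dominance(self) -> str:
        _, label = icer_and_label(self.delta_cost, self.delta_effect)
        return label

    def nmb(self, wtp: float) -> float:
        return wtp * self.delta_effect - self.delta_cost

    def to_dict(self) -> dict:
        return {
            "arm_costs": self.arm_costs,
            "arm_effects": self.arm_effects,
            "effect_name": self.effect_name,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "dominance": self.dominance,
            "nmb": {str(w): self.nmb(w) for w in self.wtp_grid},
            "prob_ce": ({str(k): v for k, v in self.prob_ce.items()}
                        if self.prob_ce else None),
        }


def icer_and_label(delta_cost: float, delta_effect: float,
                   eps: float = 1e-12) -> tuple[float | None, str]:
    """ICER with a dominance label replacing it when signs make it moot."""
    dc, de = delta_cost, delta_effect
    if abs(dc) <= eps and abs(de) <= eps:
        return None, "indifferent"
    if de >= -eps and dc <= eps and (de > eps or dc < -eps):
        return None, "dominant"
    if de <= eps and dc >= -eps and (de < -eps or dc > eps):
        return None, "dominated"
    label = "north_east" if de > 0 else "south_west"
    return dc / de, label


def deterministic_cua(params: ParameterSet,
                      sampled: Mapping[str, float] | None = None) -> CEResult:
    """Point-estimate cost-utility analysis of both arms."""
    ri = resolve(params, sampled)
    traces = {arm: run_cohort(params, arm, resolved=ri) for arm in ARMS}
    return CEResult(
        arm_costs={arm: traces[arm].total_cost for arm in ARMS},
        arm_effects={arm: traces[arm].total_qaly for arm in ARMS},
        wtp_grid=params.wtp_grid,
    )


# ---------------------------------------------------------------------------
# microsimulation oracle


def microsim_oracle(params: ParameterSet, arm: str, n_patients: int, seed,
                    sampled: Mapping[str, float] | None = None) -> dict[str, float]:
    """Individual-level simulation with identical per-cycle rules.

    Means converge to the cohort engine's totals; used as an independent
    validation oracle, not for production runs.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    ri = resolve(params, sampled)
    space = ri.space
    S = space.n_stages
    rng = np.random.default_rng(seed)

    # state coding mirrors StateSpace indices
    state = rng.choice(S, size=n_patients, p=ri.start[arm])
    cost = np.full(n_patients, ri.year1[arm]["cost"], dtype=float)
    qaly = np.full(n_patients, ri.year1[arm]["qaly"], dtype=float)

    u_vec = np.zeros(space.n_states)
    c_vec = np.zeros(space.n_states)
    for s in space.labels:
        u_vec[space.stage(s)] = ri.utilities[s]
        c_vec[space.stage(s)] = ri.monthly_costs[s]
        for m in range(1, TUNNEL_MONTHS + 1):
            u_vec[space.tunnel(s, m)] = ri.utilities[s] - ri.tunnel_disutility
            c_vec[space.tunnel(s, m)] = ri.monthly_costs[s]
    landing_t1 = np.array([space.tunnel(space.landing[s], 1) for s in space.labels])

    adm_cost = ri.admission_cost[arm]
    int_monthly = ri.intervention_monthly_cost if arm == "intervention" else 0.0
    for t in range(13, ri.horizon + 1):
        y = model_year(t)
        df = ri.discount_factor(t)
        alive = state != space.dead
        # accrue on start-of-cycle state
        qaly[alive] += u_vec[state[alive]] / 12.0 * df
        cost[alive] += (c_vec[state[alive]] + int_monthly) * df

        new_state = state.copy()
        in_stage = state < S
        if in_stage.any():
            st = state[in_stage]
            rates = ri.exac_rates[arm][y][st]
            exac = rng.random(st.size) < rates
            # admissions: cost now; death or tunnel entry
            adm_idx = np.flatnonzero(in_stage)[exac]
            cost[adm_idx] += adm_cost * df
            dies = rng.random(adm_idx.size) < ri.death_on_admission
            new_state[adm_idx[dies]] = space.dead
            surv = adm_idx[~dies]
            new_state[surv] = landing_t1[state[surv]]
            # matrix moves for non-exacerbators
            mv_idx = np.flatnonzero(in_stage)[~exac]
            if mv_idx.size:
                cum = np.cumsum(ri.matrices[arm][y], axis=1)
                u = rng.random(mv_idx.size)
                rows = cum[state[mv_idx]]
                new_state[mv_idx] = (u[:, None] > rows).sum(axis=1)
        in_tunnel = (state >= S) & (state != space.dead)
        if in_tunnel.any():
            ti = state[in_tunnel]
            rel = ti - S
            stage_of = rel // TUNNEL_MONTHS
            month = rel % TUNNEL_MONTHS + 1
            nxt = np.where(month < TUNNEL_MONTHS, ti + 1, stage_of)
            new_state[in_tunnel] = nxt
        state = new_state

    return {"mean_cost": float(cost.mean()), "mean_qaly": float(qaly.mean()),
            "se_cost": float(cost.std(ddof=1) / np.sqrt(n_patients)),
            "se_qaly": float(qaly.std(ddof=1) / np.sqrt(n_patients)),
            "n": int(n_patients)}


# ---------------------------------------------------------------------------
# merged-structure (A/B/E) variant


def _pool_specs(specs_weights: list[tuple[DistributionSpec, float]]) -> DistributionSpec:
    """Weighted pool of specs as a normal approximation (point and SE)."""
    point = sum(w * sp.point for sp, w in specs_weights)
    var = sum((w * sp.sd()) ** 2 for sp, w in specs_weights)
    return DistributionSpec(point=point, family="normal", params={"se": var ** 0.5})


def _sum_specs(specs: list[DistributionSpec]) -> DistributionSpec:
    point = sum(sp.point for sp in specs)
    var = sum(sp.sd() ** 2 for sp in specs)
    return DistributionSpec(point=point, family="normal", params={"se": var ** 0.5})


def merge_ace(params: ParameterSet) -> ParameterSet:
    """Pool stages C and D into a single high-risk stage E.

    Stage-E parameters are occupancy-weighted pools of C and D, weights taken
    from the combined-arm 12-month starting proportions; transitions into E
    sum the C and D columns and the E row is the weighted blend of the C and
    D rows.  This is the minimal-assumption merge and is config-overridable
    by supplying a native usual-care matrix.
    """
    if params.structure != "abcd":
        raise ValueError("merge_ace expects a four-stage parameter set")
    pC = sum(params.starting_states[a]["C"].point for a in ARMS)
    pD = sum(params.starting_states[a]["D"].point for a in ARMS)
    if pC + pD <= 0:
        raise ValueError("no occupancy mass in C or D to weight the merge")
    wC, wD = pC / (pC + pD), pD / (pC + pD)

    sp = params.stage_params
    labels = ("A", "B", "E")
    starting = {}
    for arm in ARMS:
        st = params.starting_states[arm]
        starting[arm] = {"A": st["A"], "B": st["B"], "E": _sum_specs([st["C"], st["D"]])}
        total = sum(s.point for s in starting[arm].values())
        if abs(total - 1.0) > 1e-9:  # guard against rounding in the pool
            starting[arm]["E"] = DistributionSpec(
                point=starting[arm]["E"].point + (1.0 - total),
                family=starting[arm]["E"].family, params=starting[arm]["E"].params)

    def merge_matrix(tm: TransitionMatrix) -> TransitionMatrix:
        cells: dict[tuple[str, str], DistributionSpec] = {}
        get = lambda i, j: tm.cells.get((i, j))  # noqa: E731
        # rows A and B: destination C+D pooled into E
        for i in ("A", "B"):
            for j in ("A", "B"):
                if i != j and get(i, j) is not None:
                    cells[(i, j)] = get(i, j)
            into_e = [c for c in (get(i, "C"), get(i, "D")) if c is not None]
            if into_e:
                cells[(i, "E")] = _sum_specs(into_e)
        # row E: weighted blend of rows C and D
        for j in ("A", "B"):
            parts = [(get("C", j), wC), (get("D", j), wD)]
            parts = [(sp_, w) for sp_, w in parts if sp_ is not None]
            if parts:
                cells[("E", j)] = _pool_specs(parts)
        return TransitionMatrix(labels, cells)

    uc = merge_matrix(params.usual_care_matrix)
    interv = merge_matrix(params.intervention_matrix_year2)

    def remap_cell(cell):
        i, j = cell
        i = "E" if i in ("C", "D") else i
        j = "E" if j in ("C", "D") else j
        return (i, j)

    beneficial = []
    for cell in params.effects.beneficial_cells:
        i, j = remap_cell(cell)
        if i != j and (i, j) not in beneficial:
            beneficial.append((i, j))

    effects = fx.TreatmentEffectSchedule(
        base_rr_year2=params.effects.base_rr_year2,
        decay=params.effects.decay,
        exac_reduction_schedule=dict(params.effects.exac_reduction_schedule),
        effect_stages=tuple(sorted({("E" if s in ("C", "D") else s)
                                    for s in params.effects.effect_stages})),
        bed_day_reduction=params.effects.bed_day_reduction,
        beneficial_cells=tuple(beneficial),
    )

    pooled_cost = _pool_specs([(sp.monthly_cost_d, wD)]) if wC == 0 else _pool_specs(
        [(DistributionSpec(point=max(sp.monthly_cost_d.point - sp.ac_decrement.point, 0.0),
                           family="normal",
                           params={"se": (sp.monthly_cost_d.sd() ** 2
                                          + sp.ac_decrement.sd() ** 2) ** 0.5}), wC),
         (sp.monthly_cost_d, wD)])
    stage_params = StageParams(
        utilities={"A": sp.utilities["A"], "B": sp.utilities["B"],
                   "E": _pool_specs([(sp.utilities["C"], wC), (sp.utilities["D"], wD)])},
        exac_disutility=sp.exac_disutility,
        monthly_cost_b=sp.monthly_cost_b,
        monthly_cost_d=pooled_cost,  # consumed as the stage-E cost
        ac_decrement=sp.ac_decrement,
        exac_rates={"A": sp.exac_rates["A"], "B": sp.exac_rates["B"],
                    "E": _pool_specs([(sp.exac_rates["C"], wC),
                                      (sp.exac_rates["D"], wD)])},
        admission_cost=sp.admission_cost,
        bed_day_cost=sp.bed_day_cost,
        intervention_monthly_cost=sp.intervention_monthly_cost,
    )

    return ParameterSet(
        stages=ACE_STAGES,
        starting_states=starting,
        intervention_matrix_year2=interv,
        usual_care_matrix=uc,
        stage_params=stage_params,
        effects=effects,
        year1=params.year1,
        discount_rate_annual=params.discount_rate_annual,
        horizon_months=params.horizon_months,
        death_on_admission=params.death_on_admission,
        wtp_grid=params.wtp_grid,
        half_cycle_correction=params.half_cycle_correction,
        tunnel_disutility_mode=params.tunnel_disutility_mode,
        structure="ace",
        landing=dict(ACE_LANDING),
        costing=params.costing,
        fill_log=list(params.fill_log) + ["structure merged to A/B/E by occupancy-weighted pooling"],
    )
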