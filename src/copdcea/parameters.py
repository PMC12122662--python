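"""Typed model inputs: distributions, transition matrices, stage parameters.

Every model input is represented as a :class:`DistributionSpec` carrying a
deterministic point estimate plus (optionally) a sampling distribution for
probabilistic sensitivity analysis.  :func:`load_parameters` reads a YAML/JSON
config, validates every invariant, fills documented defaults for the
explicitly optional keys and logs each fill.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Lowest EQ-5D utility representable on the UK 3L tariff scale.
UTILITY_FLOOR = -0.594

BASE_STAGE_LABELS = ("A", "B", "C", "D")
ACE_STAGE_LABELS = ("A", "B", "E")

#: Post-admission landing stage: admission history reclassifies low-risk
#: stages into their high-risk counterparts.
BASE_LANDING = {"A": "C", "B": "D", "C": "C", "D": "D"}
ACE_LANDING = {"A": "E", "B": "E", "E": "E"}


class ConfigError(ValueError):
    """A named-field schema or invariant violation in a config file."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class MatrixError(ValueError):
    """A transition-matrix invariant violation, naming the offending row."""

    def __init__(self, row: str, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class GoldStage:
    """A living health state in the GOLD risk/symptom classification."""

    label: str
    risk: str  # "low" | "high"
    symptoms: str  # "fewer" | "more" | "merged"

    def __post_init__(self):
        if self.risk not in ("low", "high"):
            raise ConfigError("risk", f"unknown risk level {self.risk!r}")
        if self.symptoms not in ("fewer", "more", "merged"):
            raise ConfigError("symptoms", f"unknown symptom level {self.symptoms!r}")


BASE_STAGES = (
    GoldStage("A", "low", "fewer"),
    GoldStage("B", "low", "more"),
    GoldStage("C", "high", "fewer"),
    GoldStage("D", "high", "more"),
)
ACE_STAGES = (
    GoldStage("A", "low", "fewer"),
    GoldStage("B", "low", "more"),
    GoldStage("E", "high", "merged"),
)


@dataclass(frozen=True)
class DistributionSpec:
    """A point estimate plus an optional sampling distribution.

    Supported families: ``beta`` (alpha, beta), ``gamma`` (kappa, theta —
    shape/scale), ``normal`` (se), ``lognormal`` (se, on the natural scale)
    and ``fixed``.
    """

    point: float
    family: str = "fixed"
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        fam = self.family
        p = self.params
        if fam == "beta":
            if p.get("alpha", 0) <= 0 or p.get("beta", 0) <= 0:
                raise ConfigError("beta", f"alpha/beta must be positive, got {dict(p)}")
        elif fam == "gamma":
            if p.get("kappa", 0) <= 0 or p.get("theta", 0) <= 0:
                raise ConfigError("gamma", f"kappa/theta must be positive, got {dict(p)}")
        elif fam in ("normal", "lognormal"):
            if p.get("se", -1.0) < 0:
                raise ConfigError(fam, f"se must be non-negative, got {dict(p)}")
            if fam == "lognormal" and self.point <= 0:
                raise ConfigError(fam, "lognormal requires a positive point value")
        elif fam != "fixed":
            raise ConfigError("family", f"unknown distribution family {fam!r}")

    # -- analytic moments -------------------------------------------------
    def mean(self) -> float:
        """Analytic mean of the sampling distribution."""
        p = self.params
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["kappa"] * p["theta"]
        if self.family in ("normal", "lognormal"):
            return self.point
        return self.point

    def sd(self) -> float:
        """Analytic standard deviation of the sampling distribution."""
        p = self.params
        if self.family == "beta":
            a, b = p["alpha"], p["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            return math.sqrt(p["kappa"]) * p["theta"]
        if self.family in ("normal", "lognormal"):
            return p["se"]
        return 0.0

    # -- sampling ---------------------------------------------------------
    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the sampling distribution (``fixed`` returns the point)."""
        p = self.params
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(p["kappa"], p["theta"], size=size)
        if self.family == "normal":
            return rng.normal(self.point, p["se"], size=size)
        if self.family == "lognormal":
            m, s = self.point, p["se"]
            sigma2 = math.log1p((s / m) ** 2)
            mu = math.log(m) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size=size)
        if size is None:
            return self.point
        return np.full(size, self.point)

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = {"point": self.point, "family": self.family}
        d.update(self.params)
        return d

    @classmethod
    def from_dict(cls, d: Mapping, field_name: str = "distribution") -> "DistributionSpec":
        if not isinstance(d, Mapping) or "point" not in d:
            raise ConfigError(field_name, f"expected a distribution block with 'point', got {d!r}")
        family = d.get("family", "fixed")
        params = {k: float(v) for k, v in d.items() if k not in ("point", "family")}
        return cls(point=float(d["point"]), family=family, params=params)


def fixed(value: float) -> DistributionSpec:
    """Shorthand for a deterministic spec."""
    return DistributionSpec(point=value, family="fixed")


def implied_count_proportion(spec: DistributionSpec, pseudo: float = 0.05) -> float:
    """Proportion implied by trial counts encoded in a beta spec.

    Starting-state betas encode successes in ``alpha`` and failures in
    ``beta`` plus a small pseudo-count (added so empty stages can be
    sampled), so the observed proportion is ``alpha / (alpha + beta - pseudo)``.
    """
    if spec.family != "beta":
        raise ValueError("count proportions require a beta spec")
    a, b = spec.params["alpha"], spec.params["beta"]
    return a / (a + b - pseudo)


def point_and_sample(spec: DistributionSpec, seed: int | None = None,
                     mode: str = "point") -> float:
    """Return the point value or one reproducible draw from ``spec``.

    ``mode='point'`` ignores the seed and returns the deterministic value;
    ``mode='sample'`` draws once from the stated family.
    """
    if mode == "point":
        return spec.point
    if mode == "sample":
        rng = np.random.default_rng(seed)
        return float(spec.sample(rng))
    raise ValueError(f"unknown mode {mode!r}")


class TransitionMatrix:
    """Monthly transition probabilities over living stages.

    Off-diagonal cells are stored explicitly (with per-cell specs for PSA);
    diagonals are residual stay probabilities filled so each row sums to 1.
    """

    def __init__(self, labels: Sequence[str],
                 cells: Mapping[tuple[str, str], DistributionSpec]):
        self.labels = tuple(labels)
        self.cells = dict(cells)
        for (i, j) in self.cells:
            if i not in self.labels or j not in self.labels or i == j:
                raise MatrixError(i, f"invalid off-diagonal cell ({i}, {j})")
        self._validate()

    def _validate(self):
        for i in self.labels:
            s = 0.0
            for j in self.labels:
                if i == j:
                    continue
                p = self.cells.get((i, j), fixed(0.0)).point
                if not (0.0 <= p <= 1.0):
                    raise MatrixError(i, f"cell ({i}, {j}) = {p} outside [0, 1]")
                s += p
            if s > 1.0 + 1e-12:
                raise MatrixError(i, f"off-diagonal sum {s:.6f} exceeds 1 before residual fill")

    def point_matrix(self) -> np.ndarray:
        """Dense row-stochastic matrix at point values (residual diagonal)."""
        n = len(self.labels)
        m = np.zeros((n, n))
        idx = {lab: k for k, lab in enumerate(self.labels)}
        for (i, j), spec in self.cells.items():
            m[idx[i], idx[j]] = spec.point
        np.fill_diagonal(m, 0.0)
        np.fill_diagonal(m, 1.0 - m.sum(axis=1))
        return m

    def with_cells(self, new_points: Mapping[tuple[str, str], float]) -> "TransitionMatrix":
        """Copy with selected off-diagonal points replaced (specs retained)."""
        cells = dict(self.cells)
        for key, p in new_points.items():
            old = cells.get(key, fixed(0.0))
            cells[key] = DistributionSpec(point=float(p), family=old.family,
                                          params=old.params)
        return TransitionMatrix(self.labels, cells)

    def to_dict(self) -> dict:
        out: dict = {}
        for (i, j), spec in sorted(self.cells.items()):
            out.setdefault(i, {})[j] = spec.to_dict()
        return out

    @classmethod
    def from_dict(cls, d: Mapping, labels: Sequence[str]) -> "TransitionMatrix":
        cells = {}
        for i, row in d.items():
            for j, spec in row.items():
                cells[(i, j)] = DistributionSpec.from_dict(spec, f"transitions[{i}][{j}]")
        return cls(labels, cells)


@dataclass
class StageParams:
    """Per-stage utilities, monthly costs and exacerbation machinery.

    Stage A monthly cost is stage B's minus ``ac_decrement``; stage C is
    stage D's minus the same decrement (derived, not stored independently).
    """

    utilities: dict[str, DistributionSpec]
    exac_disutility: DistributionSpec  # magnitude of the decrement
    monthly_cost_b: DistributionSpec
    monthly_cost_d: DistributionSpec
    ac_decrement: DistributionSpec
    exac_rates: dict[str, DistributionSpec]
    admission_cost: DistributionSpec
    bed_day_cost: DistributionSpec
    intervention_monthly_cost: DistributionSpec

    def __post_init__(self):
        for stage, u in self.utilities.items():
            if not (UTILITY_FLOOR <= u.point <= 1.0):
                raise ConfigError(f"utilities[{stage}]",
                                  f"{u.point} outside [{UTILITY_FLOOR}, 1]")
        for stage, r in self.exac_rates.items():
            if not (0.0 <= r.point <= 1.0):
                raise ConfigError(f"exac_rates[{stage}]", f"{r.point} outside [0, 1]")
        for name, c in (("monthly_cost_b", self.monthly_cost_b),
                        ("monthly_cost_d", self.monthly_cost_d),
                        ("ac_decrement", self.ac_decrement),
                        ("admission_cost", self.admission_cost),
                        ("bed_day_cost", self.bed_day_cost),
                        ("intervention_monthly_cost", self.intervention_monthly_cost)):
            if c.point < 0:
                raise ConfigError(name, f"cost {c.point} is negative")

    def monthly_costs(self) -> dict[str, float]:
        """Point monthly stage-membership costs (A/C derived by decrement)."""
        b = self.monthly_cost_b.point
        d = self.monthly_cost_d.point
        dec = self.ac_decrement.point
        costs = {"A": max(b - dec, 0.0), "B": b, "C": max(d - dec, 0.0), "D": d}
        if "E" in self.utilities:  # merged-structure variant
            costs["E"] = self.monthly_cost_d.point
        return {k: v for k, v in costs.items() if k in self.utilities}


@dataclass
class ParameterSet:
    """All validated model inputs for one run of the decision model."""

    stages: tuple[GoldStage, ...]
    starting_states: dict[str, dict[str, DistributionSpec]]  # arm -> stage -> spec
    intervention_matrix_year2: TransitionMatrix
    usual_care_matrix: TransitionMatrix
    stage_params: StageParams
    effects: "TreatmentEffectSchedule"  # noqa: F821 - defined in copdcea.effects
    year1: dict[str, dict[str, float]]  # arm -> {"cost": .., "qaly": ..}
    discount_rate_annual: float = 0.035
    horizon_months: int = 60
    death_on_admission: float = 0.05
    wtp_grid: tuple[float, ...] = (0, 10000, 20000, 30000, 40000, 50000)
    half_cycle_correction: bool = False
    tunnel_disutility_mode: str = "per_month"
    structure: str = "abcd"
    landing: dict[str, str] = field(default_factory=lambda: dict(BASE_LANDING))
    costing: dict | None = None
    fill_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.horizon_months % 12 != 0:
            raise ConfigError("horizon_months", f"{self.horizon_months} not divisible by 12")
        if not (0.0 <= self.death_on_admission <= 1.0):
            raise ConfigError("death_on_admission",
                              f"{self.death_on_admission} outside [0, 1]")
        labels = self.stage_labels
        for arm, states in self.starting_states.items():
            if set(states) != set(labels):
                raise ConfigError(f"starting_states[{arm}]",
                                  f"stage set {sorted(states)} != {sorted(labels)}")
            total = sum(s.point for s in states.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"starting_states[{arm}]",
                                  f"proportions sum to {total}, not 1")
        if set(self.landing) != set(labels):
            raise ConfigError("landing", "landing map must cover every stage")
        if self.tunnel_disutility_mode not in ("per_month", "total_spread"):
            raise ConfigError("tunnel_disutility_mode", self.tunnel_disutility_mode)

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.stages)

    @property
    def horizon_years(self) -> int:
        return self.horizon_months // 12

    def starting_vector(self, arm: str) -> np.ndarray:
        return np.array([self.starting_states[arm][s].point for s in self.stage_labels])

    # -- provenance dump --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "stages": [vars(s) for s in self.stages],
            "starting_states": {
                arm: {s: spec.to_dict() for s, spec in states.items()}
                for arm, states in self.starting_states.items()
            },
            "intervention_matrix_year2": self.intervention_matrix_year2.to_dict(),
            "usual_care_matrix": self.usual_care_matrix.to_dict(),
            "stage_params": {
                "utilities": {s: u.to_dict() for s, u in self.stage_params.utilities.items()},
                "exac_disutility": self.stage_params.exac_disutility.to_dict(),
                "monthly_costs": {
                    "B": self.stage_params.monthly_cost_b.to_dict(),
                    "D": self.stage_params.monthly_cost_d.to_dict(),
                    "ac_decrement": self.stage_params.ac_decrement.to_dict(),
                },
                "exac_rates": {s: r.to_dict() for s, r in self.stage_params.exac_rates.items()},
                "admission_cost": self.stage_params.admission_cost.to_dict(),
                "bed_day_cost": self.stage_params.bed_day_cost.to_dict(),
                "intervention_monthly_cost":
                    self.stage_params.intervention_monthly_cost.to_dict(),
            },
            "effects": self.effects.to_dict(),
            "year1": self.year1,
            "discount_rate_annual": self.discount_rate_annual,
            "horizon_months": self.horizon_months,
            "death_on_admission": self.death_on_admission,
            "wtp_grid": list(self.wtp_grid),
            "half_cycle_correction": self.half_cycle_correction,
            "tunnel_disutility_mode": self.tunnel_disutility_mode,
            "landing": self.landing,
            "fill_log": self.fill_log,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping or mapping[key] is None:
        raise ConfigError(f"{context}.{key}", "mandatory key missing")
    return mapping[key]


def default_config_path() -> Path:
    """Path to the packaged default YAML config."""
    return Path(str(resources.files("copdcea").joinpath("data/default.yaml")))


def load_config(config_path: str | Path | None = None) -> dict:
    """Read a YAML/JSON config file into a raw dict."""
    path = Path(config_path) if config_path is not None else default_config_path()
    if not path.exists():
        raise ConfigError("config_path", f"no such file: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_parameters(config_path: str | Path | None = None) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from a config file.

    With no argument the packaged default config is used.  Optional keys
    (``death_on_admission``, the usual-care matrix) are default-filled, each
    fill appended to ``fill_log`` and logged as a warning.
    """
    from copdcea.effects import TreatmentEffectSchedule, derive_usual_care_matrix

    cfg = load_config(config_path)
    fill_log: list[str] = []

    model = _require(cfg, "model", "config")
    structure = model.get("structure", "abcd")
    if structure not in ("abcd", "ace"):
        raise ConfigError("model.structure", f"unknown structure {structure!r}")
    # Config tables are always keyed by the four-stage structure; the merged
    # variant is produced by pooling C and D after loading.
    stages, landing = BASE_STAGES, dict(BASE_LANDING)
    labels = tuple(s.label for s in stages)

    # starting states
    ss_cfg = _require(cfg, "starting_states", "config")
    starting = {}
    for arm in ("usual_care", "intervention"):
        arm_cfg = _require(ss_cfg, arm, "starting_states")
        starting[arm] = {
            s: DistributionSpec.from_dict(_require(arm_cfg, s, f"starting_states.{arm}"),
                                          f"starting_states.{arm}.{s}")
            for s in labels
        }

    # stage parameters
    sp = _require(cfg, "stage_params", "config")
    util_cfg = _require(sp, "utilities", "stage_params")
    cost_cfg = _require(sp, "monthly_costs", "stage_params")
    rate_cfg = _require(sp, "exac_rates", "stage_params")
    stage_params = StageParams(
        utilities={s: DistributionSpec.from_dict(_require(util_cfg, s, "utilities"),
                                                 f"utilities.{s}") for s in labels},
        exac_disutility=DistributionSpec.from_dict(
            _require(sp, "exac_disutility", "stage_params"), "exac_disutility"),
        monthly_cost_b=DistributionSpec.from_dict(
            _require(cost_cfg, "B", "monthly_costs"), "monthly_costs.B"),
        monthly_cost_d=DistributionSpec.from_dict(
            _require(cost_cfg, "D", "monthly_costs"), "monthly_costs.D"),
        ac_decrement=DistributionSpec.from_dict(
            _require(cost_cfg, "ac_decrement", "monthly_costs"), "monthly_costs.ac_decrement"),
        exac_rates={s: DistributionSpec.from_dict(_require(rate_cfg, s, "exac_rates"),
                                                  f"exac_rates.{s}") for s in labels},
        admission_cost=DistributionSpec.from_dict(
            _require(sp, "admission_cost", "stage_params"), "admission_cost"),
        bed_day_cost=DistributionSpec.from_dict(
            _require(sp, "bed_day_cost", "stage_params"), "bed_day_cost"),
        intervention_monthly_cost=DistributionSpec.from_dict(
            _require(sp, "intervention_monthly_cost", "stage_params"),
            "intervention_monthly_cost"),
    )

    # treatment effects
    eff_cfg = _require(cfg, "effects", "config")
    sched_cfg = _require(eff_cfg, "exac_reduction_schedule", "effects")
    effects = TreatmentEffectSchedule(
        base_rr_year2=DistributionSpec.from_dict(
            _require(eff_cfg, "base_rr_year2", "effects"), "effects.base_rr_year2"),
        decay=float(eff_cfg.get("decay", 0.5)),
        exac_reduction_schedule={int(k): float(v) for k, v in sched_cfg.items()},
        effect_stages=tuple(eff_cfg.get("effect_stages", ["B", "D"])),
        bed_day_reduction=DistributionSpec.from_dict(
            _require(eff_cfg, "bed_day_reduction", "effects"), "effects.bed_day_reduction"),
    )

    # transition matrices
    tr_cfg = _require(cfg, "transitions", "config")
    interv = TransitionMatrix.from_dict(
        _require(tr_cfg, "intervention_year2", "transitions"), labels)
    beneficial = tuple(tuple(c) for c in tr_cfg.get("beneficial_cells", []))
    if tr_cfg.get("usual_care"):
        usual = TransitionMatrix.from_dict(tr_cfg["usual_care"], labels)
    else:
        usual = derive_usual_care_matrix(interv, effects.base_rr_year2.point, beneficial)
        msg = ("transitions.usual_care absent: back-derived from the year-2 "
               "intervention matrix by dividing beneficial cells by "
               f"RR={effects.base_rr_year2.point} (placeholder, not ground truth)")
        fill_log.append(msg)
        logger.warning(msg)
    effects.beneficial_cells = beneficial

    # year-1 accruals
    y1 = _require(cfg, "year1", "config")
    year1 = {arm: {"cost": float(_require(y1[arm], "cost", f"year1.{arm}")),
                   "qaly": float(_require(y1[arm], "qaly", f"year1.{arm}"))}
             for arm in ("usual_care", "intervention")}

    if "death_on_admission" in model and model["death_on_admission"] is not None:
        death = float(model["death_on_admission"])
    else:
        death = 0.05
        msg = ("model.death_on_admission absent: filled placeholder 0.05 "
               "(source table is supplementary-only)")
        fill_log.append(msg)
        logger.warning(msg)

    ps = ParameterSet(
        stages=stages,
        starting_states=starting,
        intervention_matrix_year2=interv,
        usual_care_matrix=usual,
        stage_params=stage_params,
        effects=effects,
        year1=year1,
        discount_rate_annual=float(model.get("discount_rate_annual", 0.035)),
        horizon_months=int(model.get("horizon_months", 60)),
        death_on_admission=death,
        wtp_grid=tuple(float(w) for w in model.get("wtp_grid", (0, 20000, 30000))),
        half_cycle_correction=bool(model.get("half_cycle_correction", False)),
        tunnel_disutility_mode=model.get("tunnel_disutility_mode", "per_month"),
        structure="abcd",
        landing=landing,
        costing=cfg.get("intervention_costing"),
        fill_log=fill_log,
    )
    if structure == "ace":
        from copdcea.markov import merge_ace

        ps = merge_ace(ps)
    return ps


def default_parameters() -> ParameterSet:
    """The packaged default :class:`ParameterSet`."""
    return load_parameters(None)
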