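"""Bottom-up per-patient costing of the intervention.

Reproduces the published first-year and subsequent-year per-patient NHS cost
build-up.  Two recomputed subtotals disagree with the printed figures by
less than 50p (the prescription setting mix and the subsequent-year total);
the printed values are the defaults and the recomputed arithmetic is exposed
via ``strict=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from copdcea.parameters import ConfigError, load_config

RECURRENCES = ("first_year_only", "annual")


@dataclass(frozen=True)
class CostComponent:
    """One line of the costing table.

    ``weight`` is the proportion of patients incurring the cost;
    ``amortisation_years`` spreads a one-off purchase over its lifetime.
    """

    name: str
    unit_cost: float
    weight: float = 1.0
    amortisation_years: int = 1
    recurrence: str = "annual"

    def __post_init__(self):
        if self.unit_cost < 0:
            raise ConfigError(self.name, f"unit_cost {self.unit_cost} is negative")
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigError(self.name, f"weight {self.weight} outside [0, 1]")
        if self.amortisation_years < 1:
            raise ConfigError(self.name, f"amortisation_years {self.amortisation_years} < 1")
        if self.recurrence not in RECURRENCES:
            raise ConfigError(self.name, f"unknown recurrence {self.recurrence!r}")


@dataclass(frozen=True)
class InterventionCost:
    """Per-patient intervention cost by model year."""

    first_year: float
    subsequent_year: float
    monthly_model_cost: float = 39.90

    def __post_init__(self):
        if not (self.first_year >= self.subsequent_year >= 0.0):
            raise ConfigError(
                "intervention_cost",
                f"require first_year >= subsequent_year >= 0, got "
                f"({self.first_year}, {self.subsequent_year})")


def weighted_cost(component: CostComponent) -> float:
    """Per-patient annual cost of one component."""
    return component.unit_cost * component.weight / component.amortisation_years


def setting_mix_cost(hospital_cost: float, community_cost: float,
                     hospital_share: float) -> float:
    """Blend hospital and community unit costs by the hospital share."""
    if not (0.0 <= hospital_share <= 1.0):
        raise ConfigError("hospital_share", f"{hospital_share} outside [0, 1]")
    return hospital_share * hospital_cost + (1.0 - hospital_share) * community_cost


def total_intervention_cost(components: Iterable[CostComponent], year: str) -> float:
    """Sum applicable component costs for ``year`` ('first' | 'subsequent')."""
    if year not in ("first", "subsequent"):
        raise ValueError(f"year must be 'first' or 'subsequent', got {year!r}")
    total = 0.0
    for c in components:
        if year == "first" or c.recurrence == "annual":
            total += weighted_cost(c)
    return total


def components_from_subtotals(subtotals: Mapping[str, Mapping[str, float]]) -> list[CostComponent]:
    """Decompose printed {first_year, subsequent_year} subtotals into components.

    Each subtotal becomes an ``annual`` component at its subsequent-year value
    plus a ``first_year_only`` component for the set-up excess, so the yearly
    aggregation is an exact sum of printed figures.
    """
    out: list[CostComponent] = []
    for name, block in subtotals.items():
        first = float(block["first_year"])
        sub = float(block.get("subsequent_year", 0.0))
        if first < sub:
            raise ConfigError(name, f"first-year {first} below subsequent-year {sub}")
        if sub > 0:
            out.append(CostComponent(name=name, unit_cost=sub, recurrence="annual"))
        if first - sub > 0:
            out.append(CostComponent(name=f"{name}_setup", unit_cost=first - sub,
                                     recurrence="first_year_only"))
    return out


def compute_intervention_cost(costing_cfg: Mapping | None = None,
                              strict: bool = False) -> InterventionCost:
    """Build the per-patient intervention cost from a costing config block.

    ``strict=False`` (default) returns the printed totals where they exist;
    ``strict=True`` returns the arithmetic sum of the printed subtotals.
    """
    cfg = costing_cfg if costing_cfg is not None else default_costing_config()
    components = components_from_subtotals(cfg["subtotals"])
    first = total_intervention_cost(components, "first")
    sub = total_intervention_cost(components, "subsequent")
    printed = cfg.get("printed_totals", {})
    if not strict:
        first = float(printed.get("first_year", first))
        sub = float(printed.get("subsequent_year", sub))
    monthly = float(cfg.get("monthly_model_cost", 39.90))
    return InterventionCost(first_year=first, subsequent_year=sub,
                            monthly_model_cost=monthly)


def prescription_setup_cost(costing_cfg: Mapping | None = None,
                            strict: bool = False) -> float:
    """Per-patient prescription & set-up cost from the setting mix."""
    cfg = costing_cfg if costing_cfg is not None else default_costing_config()
    mix = cfg["prescription_mix"]
    computed = setting_mix_cost(float(mix["hospital_cost"]),
                                float(mix["community_cost"]),
                                float(mix["hospital_share"]))
    if strict or "printed" not in mix:
        return computed
    return float(mix["printed"])


def itemised_breakdown(costing_cfg: Mapping | None = None) -> pd.DataFrame:
    """Tidy per-item cost build-up (for CSV export and audit)."""
    cfg = costing_cfg if costing_cfg is not None else default_costing_config()
    rows = []
    for item in cfg.get("items", []):
        c = CostComponent(name=item["name"], unit_cost=float(item["unit_cost"]),
                          weight=float(item.get("weight", 1.0)),
                          amortisation_years=int(item.get("amortisation_years", 1)),
                          recurrence=item.get("recurrence", "annual"))
        rows.append({"name": c.name, "unit_cost": c.unit_cost, "weight": c.weight,
                     "amortisation_years": c.amortisation_years,
                     "recurrence": c.recurrence, "weighted_cost": weighted_cost(c)})
    rows.append({"name": "prescription_setup",
                 "unit_cost": prescription_setup_cost(cfg), "weight": 1.0,
                 "amortisation_years": 1, "recurrence": "first_year_only",
                 "weighted_cost": prescription_setup_cost(cfg)})
    for year, total in (("first", None), ("subsequent", None)):
        ic = compute_intervention_cost(cfg)
        rows.append({"name": f"TOTAL_{year}_year", "unit_cost": float("nan"),
                     "weight": float("nan"), "amortisation_years": 0,
                     "recurrence": "", "weighted_cost":
                         ic.first_year if year == "first" else ic.subsequent_year})
    return pd.DataFrame(rows)


def default_costing_config() -> dict:
    """The packaged default costing block."""
    cfg = load_config(None)
    return cfg["intervention_costing"]
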