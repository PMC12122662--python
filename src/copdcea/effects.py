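"""The four modelled treatment effects of the intervention.

1. improved 12-month starting states (held in the parameter set);
2. a relative-risk adjustment of beneficial transition cells whose risk
   reduction halves each model year;
3. a per-year fractional reduction in severe-exacerbation rates in the
   admission-defined stages;
4. fewer bed days per hospitalised exacerbation, lowering the admission
   cost on the intervention arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

Cell = tuple[str, str]


def rr_schedule(base_rr: float, decay: float, n_years: int) -> list[float]:
    """Per-year relative risks starting from the first effect year.

    The risk reduction ``1 - rr`` shrinks by ``decay`` each subsequent year:
    ``rr[k+1] = 1 - (1 - rr[k]) * decay``.
    """
    if not (0.0 < base_rr <= 1.0):
        raise ValueError(f"base_rr {base_rr} outside (0, 1]")
    if not (0.0 <= decay <= 1.0):
        raise ValueError(f"decay {decay} outside [0, 1]")
    out = [base_rr]
    for _ in range(n_years - 1):
        out.append(1.0 - (1.0 - out[-1]) * decay)
    return out


@dataclass
class TreatmentEffectSchedule:
    """Magnitudes and timing of the intervention's modelled effects."""

    base_rr_year2: "DistributionSpec"  # noqa: F821
    decay: float = 0.5
    exac_reduction_schedule: dict[int, float] = field(
        default_factory=lambda: {2: 0.12, 3: 0.06, 4: 0.03, 5: 0.015})
    effect_stages: tuple[str, ...] = ("B", "D")
    bed_day_reduction: "DistributionSpec" = None  # noqa: F821
    beneficial_cells: tuple[Cell, ...] = ()

    def __post_init__(self):
        if not (0.0 < self.base_rr_year2.point <= 1.0):
            raise ValueError(f"base RR {self.base_rr_year2.point} outside (0, 1]")
        years = sorted(self.exac_reduction_schedule)
        reductions = [self.exac_reduction_schedule[y] for y in years]
        if any(b > a + 1e-12 for a, b in zip(reductions, reductions[1:])):
            raise ValueError("exacerbation reductions must be non-increasing over years")
        if any(not (0.0 <= r <= 1.0) for r in reductions):
            raise ValueError("exacerbation reductions must lie in [0, 1]")

    @property
    def first_effect_year(self) -> int:
        return min(self.exac_reduction_schedule) if self.exac_reduction_schedule else 2

    def rr_for_year(self, model_year: int, base_rr: float | None = None) -> float:
        """Transition-cell relative risk in a given model year (year >= 2)."""
        rr0 = self.base_rr_year2.point if base_rr is None else base_rr
        k = model_year - self.first_effect_year
        if k < 0:
            return 1.0
        # closed form of the halving recursion
        return 1.0 - (1.0 - rr0) * self.decay ** k

    def exac_rr_for_year(self, model_year: int, scale: float = 1.0) -> float:
        """Exacerbation-rate multiplier: 1 minus the year's reduction.

        ``scale`` rescales all reductions proportionally (used when the PSA
        samples the treatment effect).
        """
        red = self.exac_reduction_schedule.get(model_year, 0.0)
        return max(1.0 - red * scale, 0.0)

    def to_dict(self) -> dict:
        return {
            "base_rr_year2": self.base_rr_year2.to_dict(),
            "decay": self.decay,
            "exac_reduction_schedule": dict(self.exac_reduction_schedule),
            "effect_stages": list(self.effect_stages),
            "bed_day_reduction": self.bed_day_reduction.to_dict(),
            "beneficial_cells": [list(c) for c in self.beneficial_cells],
        }


def null_effects(schedule: TreatmentEffectSchedule) -> TreatmentEffectSchedule:
    """A copy with every effect switched off (for falsification runs)."""
    from copdcea.parameters import DistributionSpec

    return TreatmentEffectSchedule(
        base_rr_year2=DistributionSpec(point=1.0, family="fixed"),
        decay=schedule.decay,
        exac_reduction_schedule={y: 0.0 for y in schedule.exac_reduction_schedule},
        effect_stages=schedule.effect_stages,
        bed_day_reduction=DistributionSpec(point=0.0, family="fixed"),
        beneficial_cells=schedule.beneficial_cells,
    )


def adjust_matrix(usual, rr: float, beneficial_cells: Sequence[Cell]):
    """Multiply beneficial cells by ``rr``; diagonals re-absorb the residual.

    ``rr = 1`` returns a matrix equal to the input.  Raises if an adjusted
    row's off-diagonal sum would exceed 1.
    """
    if rr < 0:
        raise ValueError(f"relative risk {rr} is negative")
    new_points = {}
    for cell in beneficial_cells:
        key = tuple(cell)
        if key in usual.cells:
            new_points[key] = usual.cells[key].point * rr
    return usual.with_cells(new_points)


def derive_usual_care_matrix(intervention_matrix, rr_year2: float,
                             beneficial_cells: Sequence[Cell]):
    """Back-derive a usual-care matrix from the year-2 intervention matrix.

    Beneficial cells are divided by the year-2 relative risk (the inverse of
    :func:`adjust_matrix`); diagonals re-absorb the residual.  This is a
    documented placeholder for a matrix that is not published in-table.
    """
    if not (0.0 < rr_year2 <= 1.0):
        raise ValueError(f"rr_year2 {rr_year2} outside (0, 1]")
    new_points = {}
    for cell in beneficial_cells:
        key = tuple(cell)
        if key in intervention_matrix.cells:
            new_points[key] = intervention_matrix.cells[key].point / rr_year2
    return intervention_matrix.with_cells(new_points)


def effective_exac_rate(stage: str, model_year: int, arm: str,
                        exac_rates: Mapping[str, float],
                        schedule: TreatmentEffectSchedule,
                        scale: float = 1.0) -> float:
    """Monthly severe-exacerbation probability for a stage, year and arm."""
    base = exac_rates[stage]
    base = base.point if hasattr(base, "point") else float(base)
    if arm == "usual_care" or stage not in schedule.effect_stages:
        return base
    return base * schedule.exac_rr_for_year(model_year, scale=scale)


def admission_cost(arm: str, stage_params, schedule: TreatmentEffectSchedule,
                   admission: float | None = None, bed_day: float | None = None,
                   bed_day_reduction: float | None = None) -> float:
    """Cost per hospitalised exacerbation, lower on the intervention arm.

    The intervention saves ``bed_day_reduction`` bed days per admission.
    Overrides allow PSA-sampled values; the result is floored at zero only in
    the sense that a negative configuration raises.
    """
    adm = stage_params.admission_cost.point if admission is None else admission
    if arm == "usual_care":
        return adm
    bd = stage_params.bed_day_cost.point if bed_day is None else bed_day
    red = schedule.bed_day_reduction.point if bed_day_reduction is None else bed_day_reduction
    out = adm - red * bd
    if out < 0:
        raise ValueError(
            f"intervention admission cost {out:.2f} is negative "
            f"(admission {adm}, bed-day {bd}, reduction {red})")
    return out
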