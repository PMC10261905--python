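"""Grid search over selection conditions (target cells, nontarget excess).

The question the search answers: how many target cells C_T, and what fold
excess of nontarget cells, are needed so that antibodies to *wanted*
biomolecule categories (low-expressed target-restricted receptors, and
strongly upregulated receptors) are recovered and enriched, while antibodies
to *unwanted* categories (receptors less than 5-fold upregulated, i.e. shared
between the cell types) are competed away.

Rules are defined on expected copy numbers from the equilibrium model:

* a wanted category passes if the expected number of antibodies *bound to
  target cells* is at least ``capture_floor`` (default one copy) in every
  round — a clone whose expected capture falls below one copy is expected to
  be stochastically lost — and its recovered copies grow from the first to
  the final round;
* an unwanted category is depleted if its expected target-bound copies in
  round 1 already fall below the floor: the clone is expected to be lost at
  the very first capture bottleneck.

Both rules are pluggable via the ``capture_floor`` and the criteria's
category lists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

from .mass_action import (
    BindingSystem,
    CellInput,
    InvalidParameterError,
    ReceptorProfile,
    RecoveryFactors,
    partition_to_target,
    solve_bound_total,
)
from .simulate import SelectionProtocol, SelectionRoundParams
from . import defaults

__all__ = [
    "OptimizationCriteria",
    "CategoryReport",
    "ConditionReport",
    "OptimizationResult",
    "default_criteria",
    "constant_cell_protocol",
    "evaluate_condition",
    "optimize",
    "DEFAULT_CT_GRID",
    "DEFAULT_EXCESS_GRID",
]

DEFAULT_CT_GRID: tuple[float, ...] = (1e5, 1e6, 1e7, 1e8)
DEFAULT_EXCESS_GRID: tuple[float, ...] = (0.0, 1.0, 10.0, 100.0, 1000.0, 1e4)


@dataclass(frozen=True)
class OptimizationCriteria:
    """Wanted/unwanted biomolecule categories and the copy-count floor."""

    wanted: tuple[ReceptorProfile, ...]
    unwanted: tuple[ReceptorProfile, ...]
    kd: float = defaults.MEDIAN_KD
    capture_floor: float = 1.0

    def __post_init__(self) -> None:
        names_w = {r.name for r in self.wanted}
        names_u = {r.name for r in self.unwanted}
        if names_w & names_u:
            raise InvalidParameterError(
                f"wanted and unwanted categories overlap: {sorted(names_w & names_u)}")
        if not self.wanted:
            raise InvalidParameterError("need at least one wanted category")
        if not self.capture_floor > 0:
            raise InvalidParameterError(
                f"capture_floor must be > 0, got {self.capture_floor}")


def default_criteria() -> OptimizationCriteria:
    """The shipped optimization goal.

    Wanted: target-restricted receptors from 5e3 to 1e6 copies/cell, and
    10-fold upregulated receptors at >= 2e5 copies/cell (10-fold being the
    panel's strongly-upregulated exemplar).  Unwanted: 2-fold and 4-fold
    upregulated receptors over the same expression range.
    """
    restricted_levels = (5e3, 2.5e4, 1.25e5, 6.25e5, 1e6)
    wanted = tuple(
        ReceptorProfile(f"restricted_{lvl:.3g}", lvl, 0.0) for lvl in restricted_levels
    ) + (
        ReceptorProfile("up10x_2e5", 2e5, 2e4),
        ReceptorProfile("up10x_1e6", 1e6, 1e5),
    )
    unwanted = tuple(
        ReceptorProfile(f"up{ratio:g}x_{lvl:.3g}", lvl, lvl / ratio)
        for ratio in (2.0, 4.0)
        for lvl in restricted_levels
    )
    return OptimizationCriteria(wanted=wanted, unwanted=unwanted)


def constant_cell_protocol(
    c_t: float,
    excess: float,
    volume: float = defaults.DEFAULT_VOLUME,
    initial_copies: float = defaults.INITIAL_COPIES,
    amplification: Sequence[float] = defaults.AMPLIFICATION,
    recovery: RecoveryFactors = RecoveryFactors(defaults.ELUTION, defaults.CELL_RECOVERY),
) -> SelectionProtocol:
    """A 4-round protocol template with the same cell input every round.

    Used as the optimization template: the per-round cell numbers of the
    executed study were an output of this optimization, so the search itself
    holds C_T constant across rounds.  Hit rates are irrelevant to copy-based
    rules and left at 1.
    """
    amps = tuple(amplification) + (0.0,)
    rounds = tuple(
        SelectionRoundParams(
            cells=CellInput(n_target=c_t, n_nontarget=excess * c_t),
            recovery=recovery,
            volume=volume,
            amplification_into_next=amps[i],
        )
        for i in range(len(amps))
    )
    return SelectionProtocol(rounds=rounds, arm="optimization", initial_copies=initial_copies)


@dataclass(frozen=True)
class CategoryReport:
    name: str
    role: str  # "wanted" | "unwanted"
    passed: bool
    bound_target_per_round: tuple[float, ...]
    recovered_per_round: tuple[float, ...]


@dataclass(frozen=True)
class ConditionReport:
    c_t: float
    excess: float
    categories: tuple[CategoryReport, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.categories)


def _bound_and_recovered(
    receptor: ReceptorProfile, kd: float, protocol: SelectionProtocol
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-round expected target-bound and recovered copies for one clone."""
    bound_t: list[float] = []
    recovered: list[float] = []
    a = protocol.initial_copies
    for rnd in protocol.rounds:
        total_b = (receptor.copies_target * rnd.cells.n_target
                   + receptor.copies_nontarget * rnd.cells.n_nontarget)
        if total_b == 0.0:
            b_t = 0.0
        else:
            sys = BindingSystem(total_antibodies=a, kd=kd, volume=rnd.volume)
            b_t = partition_to_target(solve_bound_total(sys, total_b), receptor, rnd.cells)
        r_at = b_t * rnd.recovery.elution * rnd.recovery.cell_recovery
        bound_t.append(b_t)
        recovered.append(r_at)
        a = r_at * rnd.amplification_into_next
    return tuple(bound_t), tuple(recovered)


def evaluate_condition(
    criteria: OptimizationCriteria,
    c_t: float,
    excess: float,
    protocol_factory: Callable[[float, float], SelectionProtocol] = constant_cell_protocol,
) -> ConditionReport:
    """Apply the enrichment/depletion rules at one (C_T, excess) grid point."""
    if not c_t > 0:
        raise InvalidParameterError(f"c_t must be > 0, got {c_t}")
    if excess < 0:
        raise InvalidParameterError(f"excess must be >= 0, got {excess}")
    protocol = protocol_factory(c_t, excess)
    floor = criteria.capture_floor

    reports: list[CategoryReport] = []
    for receptor in criteria.wanted:
        bound_t, recovered = _bound_and_recovered(receptor, criteria.kd, protocol)
        ok = all(b >= floor for b in bound_t) and recovered[-1] > recovered[0]
        reports.append(CategoryReport(receptor.name, "wanted", ok, bound_t, recovered))
    for receptor in criteria.unwanted:
        bound_t, recovered = _bound_and_recovered(receptor, criteria.kd, protocol)
        ok = bound_t[0] < floor
        reports.append(CategoryReport(receptor.name, "unwanted", ok, bound_t, recovered))
    return ConditionReport(c_t=c_t, excess=excess, categories=tuple(reports))


@dataclass(frozen=True)
class OptimizationResult:
    """Exhaustive grid evaluation plus the minimal passing condition."""

    reports: tuple[ConditionReport, ...]
    selected: ConditionReport | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "c_t": rep.c_t,
                "excess": rep.excess,
                "category": cat.name,
                "role": cat.role,
                "passed": cat.passed,
                "condition_passed": rep.passed,
            }
            for rep in self.reports
            for cat in rep.categories
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_grid_points": len(self.reports),
            "n_passing": sum(r.passed for r in self.reports),
            "selected_c_t": self.selected.c_t if self.selected else None,
            "selected_excess": self.selected.excess if self.selected else None,
        }


def optimize(
    criteria: OptimizationCriteria,
    ct_grid: Sequence[float] = DEFAULT_CT_GRID,
    excess_grid: Sequence[float] = DEFAULT_EXCESS_GRID,
    protocol_factory: Callable[[float, float], SelectionProtocol] = constant_cell_protocol,
) -> OptimizationResult:
    """Evaluate every grid point; select the minimal passing condition.

    The ordering is lexicographic: smallest target-cell number first, then
    smallest nontarget excess.  An empty passing set is reported via
    ``selected=None``, not raised.
    """
    if len(ct_grid) == 0 or len(excess_grid) == 0:
        raise InvalidParameterError("optimization grid must be non-empty")
    reports = tuple(
        evaluate_condition(criteria, ct, ex, protocol_factory)
        for ct, ex in itertools.product(sorted(ct_grid), sorted(excess_grid))
    )
    selected = next((r for r in reports if r.passed), None)
    return OptimizationResult(reports=reports, selected=selected)
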