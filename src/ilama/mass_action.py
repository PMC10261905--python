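"""Equilibrium antibody-biomolecule binding for one selection round.

A phage-displayed antibody clone A binding its cognate cell-surface
biomolecule B follows the law of mass action,

    A + B <-> AB,    K_d = [A_free][B_free] / [AB].

Working in absolute copy numbers (A antibodies, B biomolecules in a reaction
volume V), the number of bound antibodies bA is the relevant (smaller) root of

    bA^2 - (A + B + K_d N_A V) bA + A B = 0,

where N_A is Avogadro's constant.  Bound antibodies partition between target
and nontarget cells in proportion to where the biomolecule sits, and only a
fraction E (elution) x Y (cell recovery) of target-bound antibodies is carried
into the next round.

All quantities are continuous expected copy numbers: the equilibrium equations
are deterministic expectations, and stochastic (read-sampling) noise is the
business of :mod:`ilama.synthetic`, not of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "InvalidParameterError",
    "BindingSystem",
    "ReceptorProfile",
    "CellInput",
    "RecoveryFactors",
    "solve_bound_total",
    "partition_to_target",
    "recovered_on_target",
    "recovered_round",
]

#: Avogadro's constant, molecules per mole.
AVOGADRO = 6.022e23


class InvalidParameterError(ValueError):
    """A physically meaningless parameter (negative count, zero volume, ...)."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class BindingSystem:
    """One clone's binding problem: antibody copies, affinity, reaction volume.

    Parameters
    ----------
    total_antibodies:
        Total antibody copies A in the reaction (dimensionless count).
    kd:
        Equilibrium dissociation constant K_d in molar. Lower is tighter.
    volume:
        Reaction volume V in dm^3 (1 dm^3 = 1 L).
    """

    total_antibodies: float
    kd: float
    volume: float = 1e-3

    def __post_init__(self) -> None:
        _require(math.isfinite(self.total_antibodies) and self.total_antibodies >= 0,
                 f"total_antibodies must be finite and >= 0, got {self.total_antibodies}")
        _require(math.isfinite(self.kd) and self.kd >= 0,
                 f"kd must be finite and >= 0, got {self.kd}")
        _require(math.isfinite(self.volume) and self.volume > 0,
                 f"volume must be finite and > 0 dm^3, got {self.volume}")


@dataclass(frozen=True)
class ReceptorProfile:
    """Copy numbers of one biomolecule per target and per nontarget cell."""

    name: str
    copies_target: float
    copies_nontarget: float = 0.0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.copies_target) and self.copies_target >= 0,
                 f"copies_target must be finite and >= 0, got {self.copies_target}")
        _require(math.isfinite(self.copies_nontarget) and self.copies_nontarget >= 0,
                 f"copies_nontarget must be finite and >= 0, got {self.copies_nontarget}")

    def scaled(self, factor: float, name: str | None = None) -> "ReceptorProfile":
        """Return a copy with both per-cell copy numbers multiplied by *factor*."""
        return ReceptorProfile(
            name=name if name is not None else self.name,
            copies_target=self.copies_target * factor,
            copies_nontarget=self.copies_nontarget * factor,
        )


@dataclass(frozen=True)
class CellInput:
    """Numbers of target and nontarget cells in the selection reaction."""

    n_target: float
    n_nontarget: float = 0.0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.n_target) and self.n_target >= 0,
                 f"n_target must be finite and >= 0, got {self.n_target}")
        _require(math.isfinite(self.n_nontarget) and self.n_nontarget >= 0,
                 f"n_nontarget must be finite and >= 0, got {self.n_nontarget}")


@dataclass(frozen=True)
class RecoveryFactors:
    """Post-binding losses: elution fraction E and target-cell recovery Y."""

    elution: float = 0.5
    cell_recovery: float = 0.5

    def __post_init__(self) -> None:
        _require(0.0 <= self.elution <= 1.0,
                 f"elution must lie in [0, 1], got {self.elution}")
        _require(0.0 <= self.cell_recovery <= 1.0,
                 f"cell_recovery must lie in [0, 1], got {self.cell_recovery}")


def solve_bound_total(sys: BindingSystem, total_biomolecules: float) -> float:
    """Bound antibody copies bA at equilibrium, for B total biomolecule copies.

    Evaluates the smaller root of ``x^2 - S x + A B = 0`` with
    ``S = A + B + K_d N_A V`` in the cancellation-free form

        bA = 2 A B / (S + sqrt(S^2 - 4 A B)),

    which stays accurate in the dilute regime ``A B << S^2`` where the
    textbook ``S/2 - sqrt(S^2/4 - AB)`` form loses every significant digit.
    The discriminant is expanded as ``(A - B)^2 + K (K + 2(A + B))`` so it is
    manifestly non-negative.

    Returns a value in ``[0, min(A, B)]``.
    """
    a = sys.total_antibodies
    b = float(total_biomolecules)
    _require(math.isfinite(b) and b >= 0,
             f"total_biomolecules must be finite and >= 0, got {b}")
    if a == 0.0 or b == 0.0:
        return 0.0
    k = sys.kd * AVOGADRO * sys.volume  # copies-equivalent of K_d
    if k == 0.0:
        return min(a, b)
    s = a + b + k
    disc = (a - b) ** 2 + k * (k + 2.0 * (a + b))
    b_bound = 2.0 * a * b / (s + math.sqrt(disc))
    # guard against last-ulp overshoot of the conservation bound
    return min(b_bound, a, b)


def partition_to_target(bound_total: float, r: ReceptorProfile, cells: CellInput) -> float:
    """Fraction of bound antibodies sitting on target cells.

    bA_T = bA * B_T C_T / (B_T C_T + B_N C_N); the remainder bA_N = bA - bA_T
    is on nontarget cells, so the partition conserves bound copies exactly.
    """
    _require(math.isfinite(bound_total) and bound_total >= 0,
             f"bound_total must be finite and >= 0, got {bound_total}")
    on_target = r.copies_target * cells.n_target
    on_nontarget = r.copies_nontarget * cells.n_nontarget
    total = on_target + on_nontarget
    _require(total > 0, "no biomolecule present on either cell type")
    return bound_total * (on_target / total)


def recovered_on_target(bound_on_target: float, f: RecoveryFactors) -> float:
    """Recovered antibody copies rA_T = bA_T * E * Y."""
    _require(math.isfinite(bound_on_target) and bound_on_target >= 0,
             f"bound_on_target must be finite and >= 0, got {bound_on_target}")
    return bound_on_target * f.elution * f.cell_recovery


def recovered_round(
    sys: BindingSystem,
    r: ReceptorProfile,
    cells: CellInput,
    f: RecoveryFactors,
) -> float:
    """Recovered antibody copies after one full round (bind, partition, elute).

    The total biomolecule pool is B = B_T C_T + B_N C_N.  If the clone's
    biomolecule is absent from both cell types, nothing binds and the round
    recovers zero (rather than raising, since the 0/0 partition is moot).
    """
    _require(cells.n_target + cells.n_nontarget > 0, "no cells in the reaction")
    total_b = r.copies_target * cells.n_target + r.copies_nontarget * cells.n_nontarget
    if total_b == 0.0:
        return 0.0
    bound = solve_bound_total(sys, total_b)
    bound_t = partition_to_target(bound, r, cells)
    return recovered_on_target(bound_t, f)
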