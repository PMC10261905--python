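"""Multi-round selection simulation and predicted enrichment signatures.

A selection protocol chains rounds: the antibody input to round 1 is the
clone's displayed copy number in the naive library; the input to each later
round is the previous round's recovered copies times an inter-round
amplification factor (bacterial phage amplification).  For each clone the
per-round recovered copies are turned into predicted pool frequencies by
normalizing over a panel of model binders and scaling by the round's hit rate
HR (the experimentally determined fraction of the selected pool that is
target-specific):

    F_i,r = rA_i,r / sum_j rA_j,r * HR_r    (reported in ppm)

so that per round the specific panel members share exactly HR_r of the pool.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .mass_action import (
    BindingSystem,
    CellInput,
    InvalidParameterError,
    ReceptorProfile,
    RecoveryFactors,
    recovered_round,
)

__all__ = [
    "PPM",
    "DegenerateRoundError",
    "SelectionRoundParams",
    "SelectionProtocol",
    "CloneModel",
    "Trajectory",
    "PredictedSignature",
    "initial_copies",
    "simulate_protocol",
    "build_panel",
    "predict_signatures",
    "sensitivity_scan",
    "signatures_to_frame",
]

#: parts-per-million scale factor, applied once at signature construction
PPM = 1e6

WITH_COMPETITION = "with_competition"
WITHOUT_COMPETITION = "without_competition"


class DegenerateRoundError(RuntimeError):
    """Raised when no panel member recovers anything in some round."""


@dataclass(frozen=True)
class SelectionRoundParams:
    """Conditions of one selection round.

    ``amplification_into_next`` is the fold-amplification applied to the
    recovered copies before the next round; it is ignored for the final round.
    ``hit_rate`` is the fraction of the selected pool that is target-specific.
    """

    cells: CellInput
    recovery: RecoveryFactors = RecoveryFactors()
    volume: float = 1e-3
    amplification_into_next: float = 0.0
    hit_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hit_rate <= 1.0):
            raise InvalidParameterError(f"hit_rate must lie in [0, 1], got {self.hit_rate}")
        if not (math.isfinite(self.amplification_into_next) and self.amplification_into_next >= 0):
            raise InvalidParameterError(
                f"amplification_into_next must be finite and >= 0, got {self.amplification_into_next}")
        if not (math.isfinite(self.volume) and self.volume > 0):
            raise InvalidParameterError(f"volume must be > 0 dm^3, got {self.volume}")


@dataclass(frozen=True)
class SelectionProtocol:
    """An ordered chain of selection rounds for one arm."""

    rounds: tuple[SelectionRoundParams, ...]
    arm: str = WITH_COMPETITION
    initial_copies: float = 200.0

    def __post_init__(self) -> None:
        if len(self.rounds) < 1:
            raise InvalidParameterError("a protocol needs at least one round")
        if not self.initial_copies > 0:
            raise InvalidParameterError(
                f"initial_copies must be > 0, got {self.initial_copies}")

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def hit_rates(self) -> tuple[float, ...]:
        return tuple(r.hit_rate for r in self.rounds)

    def truncated(self, n_rounds: int) -> "SelectionProtocol":
        """The same protocol cut after ``n_rounds`` rounds."""
        return SelectionProtocol(self.rounds[:n_rounds], self.arm, self.initial_copies)


@dataclass(frozen=True)
class CloneModel:
    """One model antibody clone: identity, affinity, cognate biomolecule."""

    clone_id: str
    kd: float
    receptor: ReceptorProfile

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise InvalidParameterError(f"kd must be > 0 M, got {self.kd}")


@dataclass(frozen=True)
class Trajectory:
    """Per-round antibody input copies and recovered copies for one clone."""

    clone_id: str
    input_copies: tuple[float, ...]
    recovered: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.input_copies) != len(self.recovered):
            raise InvalidParameterError("input/recovered length mismatch")


@dataclass(frozen=True)
class PredictedSignature:
    """Per-round predicted pool frequencies (ppm) for one clone or category."""

    clone_id: str
    arm: str
    frequencies_ppm: tuple[float, ...]


def initial_copies(library_copy_number: float, display_level: float) -> float:
    """Displayed antibody copies entering round 1.

    The naive library carries ``library_copy_number`` phage copies of each
    clone, of which a fraction ``display_level`` actually displays the
    antibody; only displayed copies can be selected.
    """
    if not library_copy_number > 0:
        raise InvalidParameterError(
            f"library_copy_number must be > 0, got {library_copy_number}")
    if not 0.0 < display_level <= 1.0:
        raise InvalidParameterError(
            f"display_level must lie in (0, 1], got {display_level}")
    return library_copy_number * display_level


def simulate_protocol(clone: CloneModel, protocol: SelectionProtocol) -> Trajectory:
    """Chain the rounds of *protocol* for one clone.

    A_1 is the protocol's initial copy number; A_{r+1} = rA_T,r x amplification.
    """
    inputs: list[float] = []
    outputs: list[float] = []
    a = protocol.initial_copies
    for rnd in protocol.rounds:
        inputs.append(a)
        sys = BindingSystem(total_antibodies=a, kd=clone.kd, volume=rnd.volume)
        r_at = recovered_round(sys, clone.receptor, rnd.cells, rnd.recovery)
        outputs.append(r_at)
        a = r_at * rnd.amplification_into_next
    return Trajectory(clone.clone_id, tuple(inputs), tuple(outputs))


def build_panel(
    min_copies: float,
    max_copies: float,
    fold_step: float,
    categories: Sequence[float | None],
) -> list[ReceptorProfile]:
    """Hypothetical biomolecule panel on a geometric expression grid.

    Target-cell copy numbers run from ``min_copies`` in ``fold_step``
    multiples; the grid is capped at ``max_copies``, which is always included
    as the final level.  Each ``categories`` entry produces one variant per
    level: ``None`` means a target-restricted biomolecule (no nontarget
    expression) and a number ``r`` means the biomolecule is expressed on
    nontarget cells at ``B_T / r`` copies (r-fold upregulated on target cells;
    r > 5 counts as upregulated, r <= 5 as similarly expressed).  Copy numbers
    are held constant across rounds.
    """
    if not (0 < min_copies <= max_copies):
        raise InvalidParameterError(
            f"need 0 < min_copies <= max_copies, got {min_copies}, {max_copies}")
    if not fold_step > 1:
        raise InvalidParameterError(f"fold_step must be > 1, got {fold_step}")
    if len(categories) == 0:
        raise InvalidParameterError("categories must be non-empty")

    levels: list[float] = []
    level = float(min_copies)
    while level < max_copies and not math.isclose(level, max_copies, rel_tol=1e-9):
        levels.append(level)
        level *= fold_step
    levels.append(float(max_copies))

    panel: list[ReceptorProfile] = []
    for lvl, cat in itertools.product(levels, categories):
        if cat is None:
            panel.append(ReceptorProfile(f"restricted_{lvl:.3g}", lvl, 0.0))
        else:
            if not cat > 1:
                raise InvalidParameterError(
                    f"upregulation ratio must be > 1, got {cat}")
            panel.append(ReceptorProfile(f"up{cat:g}x_{lvl:.3g}", lvl, lvl / cat))
    return panel


def predict_signatures(
    panel_trajectories: Sequence[Trajectory],
    hit_rates: Sequence[float],
    arm: str = WITH_COMPETITION,
) -> list[PredictedSignature]:
    """Predicted per-round frequencies (ppm) for every panel member.

    Per round r, F_i = rA_i / sum_j rA_j * HR_r, so the panel's frequencies
    sum to HR_r exactly (x 10^6 in ppm).
    """
    if not panel_trajectories:
        raise InvalidParameterError("empty trajectory panel")
    n_rounds = len(panel_trajectories[0].recovered)
    if any(len(t.recovered) != n_rounds for t in panel_trajectories):
        raise InvalidParameterError("trajectories span different numbers of rounds")
    if len(hit_rates) != n_rounds:
        raise InvalidParameterError(
            f"need {n_rounds} hit rates, got {len(hit_rates)}")

    totals = [sum(t.recovered[r] for t in panel_trajectories) for r in range(n_rounds)]
    for r, tot in enumerate(totals):
        if tot <= 0.0:
            raise DegenerateRoundError(
                f"round {r + 1}: every panel member recovered 0 copies")

    out = []
    for t in panel_trajectories:
        freqs = tuple(
            t.recovered[r] / totals[r] * hit_rates[r] * PPM for r in range(n_rounds)
        )
        out.append(PredictedSignature(t.clone_id, arm, freqs))
    return out


def sensitivity_scan(
    clone: CloneModel,
    protocol: SelectionProtocol,
    reference_panel: Sequence[ReceptorProfile],
    kd_factors: Sequence[float] = (0.1, 1.0, 10.0),
    expression_factors: Sequence[float] = (0.5, 1.0, 2.0),
) -> pd.DataFrame:
    """Signature sensitivity to affinity and receptor-quantification error.

    For every (kd_factor, expression_factor) pair the clone is re-modeled with
    K_d scaled by ``kd_factor`` and the *target-cell* copy number scaled by
    ``expression_factor`` (nontarget expression held fixed: a quantification
    error on the target cells also perturbs the upregulation ratio, which is
    what makes upregulated-receptor signatures sensitive to it), embedded in
    the fixed ``reference_panel`` for normalization, and its predicted
    signature recorded.

    Returns a tidy frame with columns ``kd_factor``, ``expression_factor``,
    ``round`` (1-based) and ``frequency_ppm``.
    """
    for fct in itertools.chain(kd_factors, expression_factors):
        if not fct > 0:
            raise InvalidParameterError(f"scan factors must be > 0, got {fct}")
    panel_traj = [
        simulate_protocol(CloneModel(rp.name, clone.kd, rp), protocol)
        for rp in reference_panel
    ]
    rows = []
    for kf, ef in itertools.product(kd_factors, expression_factors):
        receptor = ReceptorProfile(
            clone.receptor.name,
            clone.receptor.copies_target * ef,
            clone.receptor.copies_nontarget,
        )
        variant = CloneModel(
            clone_id=f"{clone.clone_id}|kd x{kf:g}|expr x{ef:g}",
            kd=clone.kd * kf,
            receptor=receptor,
        )
        traj = simulate_protocol(variant, protocol)
        sigs = predict_signatures([*panel_traj, traj], protocol.hit_rates, protocol.arm)
        for r, f in enumerate(sigs[-1].frequencies_ppm, start=1):
            rows.append({
                "clone_id": clone.clone_id,
                "kd_factor": kf,
                "expression_factor": ef,
                "round": r,
                "frequency_ppm": f,
            })
    return pd.DataFrame(rows)


def signatures_to_frame(signatures: Sequence[PredictedSignature]) -> pd.DataFrame:
    """Long-format table: clone/category id, arm, round index, frequency_ppm."""
    rows = [
        {"clone_id": s.clone_id, "arm": s.arm, "round": r, "frequency_ppm": f}
        for s in signatures
        for r, f in enumerate(s.frequencies_ppm, start=1)
    ]
    return pd.DataFrame(rows, columns=["clone_id", "arm", "round", "frequency_ppm"])
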