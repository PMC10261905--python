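"""Shipped default selection conditions.

These are the study conditions of the DU145 (target) vs Jurkat (nontarget)
screen this package models: four selection rounds with 10, 2.5, 5 and 5
million target cells, a 1000-fold nontarget-cell excess in the competition
arm (none in the no-competition arm), elution and cell-recovery fractions of
0.5, inter-round amplification factors of 10^4, 10^5 and 10^4, and a round-1
hit rate of 0.09%.

Two values are not experimentally reported and are shipped as explicit
estimates rather than silently invented in logic:

* the reaction volume V (default 1 mL = 1e-3 dm^3) — a warning is logged on
  every use because V enters the equilibrium solution directly;
* the round 2-4 hit rates (defaults 0.10, 0.40, 0.70), a typical steep
  cell-panning progression in which nonspecific clones dominate early rounds
  and specific binders dominate later ones.
"""

from __future__ import annotations

import logging

from .mass_action import CellInput, RecoveryFactors
from .simulate import (
    WITH_COMPETITION,
    WITHOUT_COMPETITION,
    SelectionProtocol,
    SelectionRoundParams,
    build_panel,
)

__all__ = [
    "DEFAULT_VOLUME",
    "TARGET_CELLS",
    "NONTARGET_EXCESS",
    "AMPLIFICATION",
    "HIT_RATES",
    "ELUTION",
    "CELL_RECOVERY",
    "INITIAL_COPIES",
    "MEDIAN_KD",
    "PANEL_MIN_COPIES",
    "PANEL_MAX_COPIES",
    "PANEL_MAX_COPIES_ALT",
    "PANEL_FOLD_STEP",
    "PANEL_CATEGORIES",
    "default_protocol",
    "default_panel",
    "warn_unreported_volume",
]

log = logging.getLogger("ilama")

#: reaction volume in dm^3; not experimentally reported, see module docstring
DEFAULT_VOLUME = 1e-3
#: target cells per round
TARGET_CELLS = (1e7, 2.5e6, 5e6, 5e6)
#: nontarget cells = NONTARGET_EXCESS x target cells in the competition arm
NONTARGET_EXCESS = 1000.0
#: amplification factors between rounds 1-2, 2-3 and 3-4
AMPLIFICATION = (1e4, 1e5, 1e4)
#: per-round hit rates; round 1 measured (0.09%), rounds 2-4 are estimates
HIT_RATES = (0.0009, 0.10, 0.40, 0.70)
ELUTION = 0.5
CELL_RECOVERY = 0.5
#: displayed copies per clone entering round 1 (2000 copies x 10% display)
INITIAL_COPIES = 200.0
#: median clone affinity
MEDIAN_KD = 1e-8

#: hypothetical-biomolecule panel: 5-fold expression grid
PANEL_MIN_COPIES = 5e3
PANEL_MAX_COPIES = 4e6
#: alternative ceiling (the optimization-stage expression range)
PANEL_MAX_COPIES_ALT = 1e6
PANEL_FOLD_STEP = 5.0
#: restricted plus 2x / 4x / 10x upregulation variants (CD71/CD59/CD55-like)
PANEL_CATEGORIES: tuple[float | None, ...] = (None, 2.0, 4.0, 10.0)

_volume_warned = False


def warn_unreported_volume(volume: float) -> None:
    """Log, once per process, that the reaction volume is an assumption."""
    global _volume_warned
    if not _volume_warned:
        log.warning(
            "reaction volume is not an experimentally reported parameter; "
            "using V = %g dm^3 — override it in the config if known", volume,
        )
        _volume_warned = True


def default_protocol(
    arm: str = WITH_COMPETITION,
    volume: float = DEFAULT_VOLUME,
    hit_rates: tuple[float, ...] = HIT_RATES,
    nontarget_excess: float = NONTARGET_EXCESS,
    initial_copies: float = INITIAL_COPIES,
) -> SelectionProtocol:
    """The shipped four-round protocol for one selection arm."""
    if arm not in (WITH_COMPETITION, WITHOUT_COMPETITION):
        raise ValueError(f"unknown arm {arm!r}")
    warn_unreported_volume(volume)
    excess = nontarget_excess if arm == WITH_COMPETITION else 0.0
    amps = AMPLIFICATION + (0.0,)
    rounds = tuple(
        SelectionRoundParams(
            cells=CellInput(n_target=ct, n_nontarget=excess * ct),
            recovery=RecoveryFactors(ELUTION, CELL_RECOVERY),
            volume=volume,
            amplification_into_next=amps[i],
            hit_rate=hit_rates[i],
        )
        for i, ct in enumerate(TARGET_CELLS)
    )
    return SelectionProtocol(rounds=rounds, arm=arm, initial_copies=initial_copies)


def default_panel(max_copies: float = PANEL_MAX_COPIES):
    """The shipped hypothetical-biomolecule panel (24 members at the 4e6 cap)."""
    return build_panel(PANEL_MIN_COPIES, max_copies, PANEL_FOLD_STEP, PANEL_CATEGORIES)
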