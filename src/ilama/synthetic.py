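"""Ground-truthed synthetic clone cohorts and simulated sequencing counts.

The generator emulates the selection study's data so every downstream stage is
testable without external files: a cohort of antibody clones is drawn with

* a true receptor-expression category per clone — highly expressed restricted
  (above 1e6 copies/cell), intermediate restricted (1e5-1e6), low restricted,
  >5-fold upregulated, <5-fold upregulated ("similar"), or nonspecific;
* log-normal affinities around a 10 nM median;
* model-expected per-round frequencies: specific clones share each round's
  hit-rate mass in proportion to their equilibrium-model recovered copies,
  and the nonspecific background carries the residual (1 - HR) mass,
  uniformly by default with optional multiplicative log-normal jitter to
  mimic the stochastic enrichment of nonspecific phage;
* multinomial read sampling at a configurable depth per (arm, round).

Clone identifiers are synthetic CDR-H3-like peptide strings.  A single seed
governs every random draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mass_action import InvalidParameterError, ReceptorProfile
from .ngs import CountTable, ExperimentalSignature
from .simulate import (
    PPM,
    CloneModel,
    SelectionProtocol,
    simulate_protocol,
)

__all__ = [
    "CAT_GT_1M",
    "CAT_100K_TO_1M",
    "CAT_RESTRICTED_LOW",
    "CAT_UPREGULATED",
    "CAT_SIMILAR",
    "CAT_NONSPECIFIC",
    "DEFAULT_CATEGORY_RECEPTORS",
    "SyntheticClone",
    "SyntheticCohortSpec",
    "generate_cohort",
    "expected_frequencies",
    "sample_counts",
    "write_count_table",
    "write_truth_table",
]

CAT_GT_1M = "gt_1M"
CAT_100K_TO_1M = "100k_to_1M"
CAT_RESTRICTED_LOW = "restricted_low"
CAT_UPREGULATED = "upregulated"
CAT_SIMILAR = "similar"
CAT_NONSPECIFIC = "nonspecific"

#: cognate-receptor expression per truth category (None = nonspecific clone).
#: Levels sit well inside their group: 4e6 restricted (upper modeled range),
#: 3e5 restricted (geometric middle of 1e5-1e6), 1e4 restricted (low), 3e5 at
#: 10-fold upregulation (CD55-like) and 3e5 at 2-fold (CD71-like).
DEFAULT_CATEGORY_RECEPTORS: dict[str, ReceptorProfile | None] = {
    CAT_GT_1M: ReceptorProfile("cat_gt_1M", 4e6, 0.0),
    CAT_100K_TO_1M: ReceptorProfile("cat_100k_to_1M", 3e5, 0.0),
    CAT_RESTRICTED_LOW: ReceptorProfile("cat_restricted_low", 1e4, 0.0),
    CAT_UPREGULATED: ReceptorProfile("cat_upregulated", 3e5, 3e4),
    CAT_SIMILAR: ReceptorProfile("cat_similar", 3e5, 1.5e5),
    CAT_NONSPECIFIC: None,
}

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticClone:
    """One generated clone; ``receptor`` is None for nonspecific clones."""

    clone_id: str
    kd: float
    receptor: ReceptorProfile | None
    category: str


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """What to generate: category sizes, affinity spread, sequencing depth."""

    clones_per_category: Mapping[str, int]
    kd_median: float = 1e-8
    kd_sigma_ln: float = 0.4
    receptors: Mapping[str, ReceptorProfile | None] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_RECEPTORS))
    read_depth: int = 25_000_000
    nonspecific_jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.clones_per_category.values()) <= 0:
            raise InvalidParameterError("cohort must contain at least one clone")
        if any(n < 0 for n in self.clones_per_category.values()):
            raise InvalidParameterError("negative clone count in cohort spec")
        unknown = set(self.clones_per_category) - set(self.receptors)
        if unknown:
            raise InvalidParameterError(f"categories without receptor definition: {unknown}")
        if not self.kd_median > 0 or self.kd_sigma_ln < 0:
            raise InvalidParameterError("kd_median must be > 0 and kd_sigma_ln >= 0")
        if self.read_depth <= 0:
            raise InvalidParameterError("read_depth must be > 0")


def _random_cdrh3(rng: np.random.Generator, existing: set[str]) -> str:
    """A unique synthetic CDR-H3-like peptide (length 8-18)."""
    while True:
        length = int(rng.integers(8, 19))
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
        if seq not in existing:
            existing.add(seq)
            return seq


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[list[SyntheticClone], dict[str, str]]:
    """Draw the cohort; returns (clones, truth table clone_id -> category).

    Deterministic given ``spec.seed``; category sizes match the requested
    ``clones_per_category`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    existing: set[str] = set()
    clones: list[SyntheticClone] = []
    truth: dict[str, str] = {}
    for category in sorted(spec.clones_per_category):
        receptor = spec.receptors[category]
        for _ in range(spec.clones_per_category[category]):
            clone_id = _random_cdrh3(rng, existing)
            kd = float(spec.kd_median * math.exp(rng.normal(0.0, spec.kd_sigma_ln)))
            clones.append(SyntheticClone(clone_id, kd, receptor, category))
            truth[clone_id] = category
    return clones, truth


def expected_frequencies(
    clones: Sequence[SyntheticClone],
    protocols: Mapping[str, SelectionProtocol],
    rng: np.random.Generator | None = None,
    nonspecific_jitter_sigma: float = 0.0,
) -> list[ExperimentalSignature]:
    """Model-expected per-round frequencies (ppm) for every clone and arm.

    Specific clones split each round's hit-rate mass HR_r in proportion to
    their recovered copies; nonspecific clones share the residual (1 - HR_r)
    uniformly, optionally with log-normal jitter (renormalized so the
    residual mass is preserved).  Per (arm, round) the frequencies sum to
    exactly 10^6 ppm whenever the cohort contains nonspecific clones.
    """
    if nonspecific_jitter_sigma > 0 and rng is None:
        raise InvalidParameterError("jitter requested but no rng supplied")
    specific = [c for c in clones if c.receptor is not None]
    nonspecific = [c for c in clones if c.receptor is None]

    out: list[ExperimentalSignature] = []
    for arm, protocol in protocols.items():
        n_rounds = protocol.n_rounds
        hit_rates = protocol.hit_rates

        trajectories = [
            simulate_protocol(CloneModel(c.clone_id, c.kd, c.receptor), protocol)
            for c in specific
        ]
        totals = [sum(t.recovered[r] for t in trajectories) for r in range(n_rounds)]
        for c, traj in zip(specific, trajectories):
            freqs = tuple(
                (traj.recovered[r] / totals[r] * hit_rates[r] * PPM)
                if totals[r] > 0 else 0.0
                for r in range(n_rounds)
            )
            out.append(ExperimentalSignature(c.clone_id, arm, freqs))

        if nonspecific:
            weights = np.ones((len(nonspecific), n_rounds))
            if nonspecific_jitter_sigma > 0:
                weights = rng.lognormal(
                    0.0, nonspecific_jitter_sigma, size=weights.shape)
            weights = weights / weights.sum(axis=0, keepdims=True)
            for i, c in enumerate(nonspecific):
                freqs = tuple(
                    (1.0 - hit_rates[r]) * weights[i, r] * PPM
                    for r in range(n_rounds)
                )
                out.append(ExperimentalSignature(c.clone_id, arm, freqs))
    return out


def sample_counts(
    frequencies: Sequence[ExperimentalSignature],
    depth: int,
    seed: int,
) -> CountTable:
    """Multinomial read sampling of the expected frequencies.

    Per (arm, round) the clone probabilities are the ppm frequencies over
    10^6; they must sum to 10^6 ppm (relative tolerance 1e-6).  The recorded
    library-wide total equals ``depth`` for every (arm, round).
    """
    if depth <= 0:
        raise InvalidParameterError(f"depth must be > 0, got {depth}")
    rng = np.random.default_rng(seed)
    arms = sorted({s.arm for s in frequencies})
    n_rounds = len(frequencies[0].frequencies_ppm)

    rows: list[dict] = []
    totals: dict[tuple[str, int], int] = {}
    for arm in arms:
        arm_sigs = [s for s in frequencies if s.arm == arm]
        freq = np.array([s.frequencies_ppm for s in arm_sigs])  # clones x rounds
        col_sums = freq.sum(axis=0)
        if not np.allclose(col_sums, PPM, rtol=1e-6):
            raise InvalidParameterError(
                f"{arm}: per-round frequencies must sum to 1e6 ppm, got {col_sums}")
        for r in range(n_rounds):
            counts = rng.multinomial(depth, freq[:, r] / col_sums[r])
            totals[(arm, r + 1)] = int(depth)
            for sig, n in zip(arm_sigs, counts):
                if n > 0:
                    rows.append({"clone_id": sig.clone_id, "arm": arm,
                                 "round": r + 1, "reads": int(n)})
    counts_df = pd.DataFrame(rows, columns=["clone_id", "arm", "round", "reads"])
    return CountTable(counts=counts_df, totals=totals)


def write_count_table(table: CountTable, counts_path: str | Path,
                      totals_path: str | Path) -> None:
    """Emit the same tab-separated format :func:`ilama.ngs.load_counts` reads."""
    table.counts.to_csv(counts_path, sep="\t", index=False)
    tot = pd.DataFrame(
        [{"arm": a, "round": r, "total_reads": n} for (a, r), n in sorted(table.totals.items())]
    )
    tot.to_csv(totals_path, sep="\t", index=False)


def write_truth_table(truth: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"clone_id": k, "true_category": v} for k, v in sorted(truth.items())]
    ).to_csv(path, sep="\t", index=False)
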