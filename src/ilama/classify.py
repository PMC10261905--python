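"""Three-step classification of clones by enrichment-signature matching.

Each sequenced clone carries one enrichment signature per selection arm: its
frequencies (ppm) over the four consecutive rounds, F_S1..F_S4.  The rules,
applied to the with-competition arm unless stated otherwise:

1. *Relevance*: a clone is a relevant binder if F_S2 > F_S1 while F_S2 and
   F_S3 are nonzero; everything else is nonenriched.
2. *Expression group* from F_S4, against thresholds equal to the predicted
   round-4 frequencies of 10 nM model binders to restricted receptors at 1e5
   and 1e6 copies/target cell (printed constants 1.32 and 750 ppm):
   F_S4 > 750 ppm -> receptor above 1e6 copies/cell; 1.32 < F_S4 < 750 ppm ->
   1e5-1e6; F_S4 < 1.32 ppm -> below 1e5 *or* a >5-fold upregulated receptor.
3. *Subgroup* for the low/upregulated group only, comparing arms:
   upregulated if F_S4(without)/F_S4(with) > 100, or — when F_S4(with) = 0 —
   if F_S4(without) > 0 and F_S3(without)/F_S3(with) > 10; restricted-low if,
   without competition, F_S1 != 0 while F_S2 = F_S3 = F_S4 = 0; otherwise
   unclassified.

The printed group criteria are all strict inequalities, which leaves the exact
boundary values unassigned; a frequency landing exactly on a threshold is
assigned to the lower-expression group (conservative toward the rarer, more
valuable category; a measure-zero event on real data).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .mass_action import InvalidParameterError, ReceptorProfile
from .simulate import (
    CloneModel,
    SelectionProtocol,
    Trajectory,
    WITH_COMPETITION,
    WITHOUT_COMPETITION,
    predict_signatures,
    simulate_protocol,
)
from .ngs import ExperimentalSignature
from . import defaults

__all__ = [
    "GROUP_NONENRICHED",
    "GROUP_GT_1M",
    "GROUP_100K_TO_1M",
    "GROUP_LT_100K_OR_UPREGULATED",
    "SUB_UPREGULATED",
    "SUB_RESTRICTED_LOW",
    "SUB_UNCLASSIFIED",
    "SUB_NOT_APPLICABLE",
    "ClassifierThresholds",
    "ClassificationResult",
    "filter_relevant",
    "assign_group",
    "subclassify",
    "derive_thresholds",
    "classify_all",
]

log = logging.getLogger("ilama")

GROUP_NONENRICHED = "nonenriched"
GROUP_GT_1M = "gt_1M"
GROUP_100K_TO_1M = "100k_to_1M"
GROUP_LT_100K_OR_UPREGULATED = "lt_100k_or_upregulated"

SUB_UPREGULATED = "upregulated"
SUB_RESTRICTED_LOW = "restricted_low"
SUB_UNCLASSIFIED = "unclassified"
SUB_NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Group boundaries (ppm) and the arm-comparison ratio thresholds."""

    low_threshold_ppm: float = 1.32
    high_threshold_ppm: float = 750.0
    ratio_threshold: float = 100.0
    fallback_round3_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.low_threshold_ppm < self.high_threshold_ppm:
            raise InvalidParameterError(
                "need 0 < low_threshold_ppm < high_threshold_ppm, got "
                f"{self.low_threshold_ppm}, {self.high_threshold_ppm}")
        if self.ratio_threshold <= 1 or self.fallback_round3_ratio <= 1:
            raise InvalidParameterError("ratio thresholds must be > 1")


@dataclass(frozen=True)
class ClassificationResult:
    clone_id: str
    relevant: bool
    group: str
    subgroup: str


def _check_signature(freqs: Sequence[float], who: str) -> None:
    if len(freqs) < 4:
        raise InvalidParameterError(
            f"{who}: need a 4-round signature, got {len(freqs)} rounds")
    if any(f < 0 or not math.isfinite(f) for f in freqs):
        raise InvalidParameterError(f"{who}: frequencies must be finite and >= 0")


def filter_relevant(sig_with_competition: Sequence[float]) -> bool:
    """Step 1: F_S2 > F_S1 while F_S2 > 0 and F_S3 > 0 (competition arm)."""
    _check_signature(sig_with_competition, "relevance filter")
    f1, f2, f3 = sig_with_competition[0], sig_with_competition[1], sig_with_competition[2]
    return f2 > f1 and f2 > 0 and f3 > 0


def assign_group(f_s4_ppm: float, t: ClassifierThresholds) -> str:
    """Step 2: expression group from the competition-arm round-4 frequency."""
    if f_s4_ppm < 0 or not math.isfinite(f_s4_ppm):
        raise InvalidParameterError(f"F_S4 must be finite and >= 0, got {f_s4_ppm}")
    if f_s4_ppm > t.high_threshold_ppm:
        return GROUP_GT_1M
    if f_s4_ppm > t.low_threshold_ppm:
        return GROUP_100K_TO_1M
    return GROUP_LT_100K_OR_UPREGULATED


def subclassify(
    sig_with: Sequence[float],
    sig_without: Sequence[float],
    t: ClassifierThresholds,
) -> str:
    """Step 3: upregulated / restricted-low / unclassified, in that order.

    Ratio comparisons treat a zero with-competition frequency against a
    positive without-competition one as an infinite ratio (passes any
    threshold); both zero means no evidence and the rule fails.
    """
    _check_signature(sig_with, "subclassify (with competition)")
    _check_signature(sig_without, "subclassify (without competition)")
    w4, wo4 = sig_with[3], sig_without[3]

    if w4 > 0:
        if wo4 / w4 > t.ratio_threshold:
            return SUB_UPREGULATED
    else:  # printed fallback branch for F_S4(with) = 0
        w3, wo3 = sig_with[2], sig_without[2]
        if wo4 > 0:
            round3_ok = (wo3 / w3 > t.fallback_round3_ratio) if w3 > 0 else wo3 > 0
            if round3_ok:
                return SUB_UPREGULATED

    if sig_without[0] != 0 and sig_without[1] == 0 and sig_without[2] == 0 and wo4 == 0:
        return SUB_RESTRICTED_LOW
    return SUB_UNCLASSIFIED


def derive_thresholds(
    protocol_with_competition: SelectionProtocol,
    pool_trajectories: Sequence[Trajectory] | None = None,
    kd: float = defaults.MEDIAN_KD,
    ratio_threshold: float = 100.0,
    fallback_round3_ratio: float = 10.0,
) -> ClassifierThresholds:
    """Recompute the group boundaries from the model (recompute mode).

    The low/high thresholds are the predicted final-round frequencies of
    model binders (affinity ``kd``) to target-restricted receptors at 1e5 and
    1e6 copies/cell, normalized within ``pool_trajectories`` (default: the
    shipped biomolecule panel under the same protocol).  The shipped default
    thresholds are instead the printed constants (1.32 / 750 ppm), because
    recomputation requires round parameters the study does not report.
    """
    refs = (
        ReceptorProfile("__threshold_ref_1e5", 1e5, 0.0),
        ReceptorProfile("__threshold_ref_1e6", 1e6, 0.0),
    )
    ref_traj = [
        simulate_protocol(CloneModel(r.name, kd, r), protocol_with_competition)
        for r in refs
    ]
    if pool_trajectories is None:
        pool_trajectories = [
            simulate_protocol(CloneModel(rp.name, kd, rp), protocol_with_competition)
            for rp in defaults.default_panel()
        ]
    sigs = predict_signatures(
        [*pool_trajectories, *ref_traj],
        protocol_with_competition.hit_rates,
        protocol_with_competition.arm,
    )
    low = sigs[-2].frequencies_ppm[-1]
    high = sigs[-1].frequencies_ppm[-1]
    return ClassifierThresholds(low, high, ratio_threshold, fallback_round3_ratio)


def classify_all(
    signatures: Iterable[ExperimentalSignature],
    thresholds: ClassifierThresholds,
) -> tuple[list[ClassificationResult], dict]:
    """Run the three steps for every clone; return results and summary counts.

    A clone present in only one arm is classified with the available arm for
    steps 1-2; if the missing arm is needed for step 3, the subgroup is
    ``unclassified`` (logged).  Results are sorted by clone id, so the output
    is invariant to input order.
    """
    by_clone: dict[str, dict[str, tuple[float, ...]]] = {}
    for sig in signatures:
        by_clone.setdefault(sig.clone_id, {})[sig.arm] = sig.frequencies_ppm

    results: list[ClassificationResult] = []
    n_single_arm = sum(1 for arms in by_clone.values() if len(arms) < 2)
    for clone_id in sorted(by_clone):
        arms = by_clone[clone_id]
        primary = arms.get(WITH_COMPETITION)
        if primary is None:
            primary = arms[WITHOUT_COMPETITION]

        if not filter_relevant(primary):
            results.append(ClassificationResult(
                clone_id, False, GROUP_NONENRICHED, SUB_NOT_APPLICABLE))
            continue
        group = assign_group(primary[3], thresholds)
        if group != GROUP_LT_100K_OR_UPREGULATED:
            results.append(ClassificationResult(clone_id, True, group, SUB_NOT_APPLICABLE))
            continue
        sig_with = arms.get(WITH_COMPETITION)
        sig_without = arms.get(WITHOUT_COMPETITION)
        if sig_with is None or sig_without is None:
            subgroup = SUB_UNCLASSIFIED
        else:
            subgroup = subclassify(sig_with, sig_without, thresholds)
        results.append(ClassificationResult(clone_id, True, group, subgroup))

    if n_single_arm:
        log.warning("%d clone(s) present in a single selection arm", n_single_arm)

    group_counts = Counter(r.group for r in results)
    subgroup_counts = Counter(
        r.subgroup for r in results if r.group == GROUP_LT_100K_OR_UPREGULATED
    )
    summary = {
        "n_clones": len(results),
        "groups": dict(group_counts),
        "subgroups": dict(subgroup_counts),
    }
    return results, summary
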