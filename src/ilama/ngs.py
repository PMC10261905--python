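"""Per-clone per-round read counts and normalized experimental signatures.

Input is a tab-separated long-format count file with the header
``clone_id  arm  round  reads`` (one row per clone per selection arm per
round) plus a totals file ``arm  round  total_reads`` giving the library-wide
usable read count of each pooled sample.  Clone identity is the exact clone
string (in the study, the CDR-H3 amino-acid sequence); no clustering of
near-identical sequences is attempted.

Processing order is fixed: the minimum-read filter acts on raw counts (a cell
with fewer than two reads is treated as unobserved, per-sample and per-round),
and normalization divides by the library-wide totals, which are *pre-filter*
read counts and are left untouched by filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .simulate import PPM, WITH_COMPETITION, WITHOUT_COMPETITION

__all__ = [
    "ARMS",
    "CountTableError",
    "CountTable",
    "ExperimentalSignature",
    "load_counts",
    "apply_min_read_filter",
    "normalize_to_ppm",
    "signatures_to_frame",
    "write_signatures",
]

log = logging.getLogger("ilama")

ARMS = (WITH_COMPETITION, WITHOUT_COMPETITION)

_COUNT_COLUMNS = ["clone_id", "arm", "round", "reads"]
_TOTAL_COLUMNS = ["arm", "round", "total_reads"]


class CountTableError(ValueError):
    """Malformed or inconsistent count input."""


@dataclass(frozen=True)
class CountTable:
    """Validated read counts plus per-(arm, round) library-wide totals.

    ``counts`` is a long-format frame with columns clone_id/arm/round/reads
    (one row per observed cell; absent cells mean zero reads).  ``totals``
    maps (arm, round) to the pooled library's usable read count; totals are
    library-wide, so they need not equal the column sums of retained clones.
    """

    counts: pd.DataFrame
    totals: dict[tuple[str, int], int]

    @property
    def n_rounds(self) -> int:
        return max(r for _, r in self.totals)

    @property
    def clone_ids(self) -> list[str]:
        return sorted(self.counts["clone_id"].unique())

    @property
    def arms(self) -> list[str]:
        return sorted({a for a, _ in self.totals})


def _validate_counts_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if list(df.columns) != _COUNT_COLUMNS:
        raise CountTableError(
            f"{source}: expected header {_COUNT_COLUMNS}, got {list(df.columns)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        if row.arm not in ARMS:
            raise CountTableError(f"{source} line {i}: unknown arm {row.arm!r}")
        if not float(row.round).is_integer() or int(row.round) < 1:
            raise CountTableError(f"{source} line {i}: round must be a positive integer")
        if row.reads < 0 or not float(row.reads).is_integer():
            raise CountTableError(
                f"{source} line {i}: reads must be a non-negative integer, got {row.reads}")
    out = df.copy()
    out["round"] = out["round"].astype(int)
    out["reads"] = out["reads"].astype(int)
    out["clone_id"] = out["clone_id"].astype(str)
    return out


def load_counts(counts_path: str | Path, totals_path: str | Path) -> CountTable:
    """Read and validate the count and totals files.

    Duplicate (clone, arm, round) rows are summed with a logged warning.
    Malformed rows raise :class:`CountTableError` naming the offending line.
    """
    counts_path, totals_path = Path(counts_path), Path(totals_path)
    try:
        raw = pd.read_csv(counts_path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CountTableError(f"{counts_path}: cannot parse: {exc}") from exc
    raw = _validate_counts_frame(raw, str(counts_path))

    dup = raw.duplicated(subset=["clone_id", "arm", "round"], keep=False)
    if dup.any():
        n = raw.loc[dup, "clone_id"].nunique()
        log.warning("%s: %d clone id(s) duplicated within an arm/round; summing reads",
                    counts_path, n)
        raw = raw.groupby(["clone_id", "arm", "round"], as_index=False)["reads"].sum()

    try:
        tot = pd.read_csv(totals_path, sep="\t")
    except Exception as exc:  # pragma: no cover
        raise CountTableError(f"{totals_path}: cannot parse: {exc}") from exc
    if list(tot.columns) != _TOTAL_COLUMNS:
        raise CountTableError(
            f"{totals_path}: expected header {_TOTAL_COLUMNS}, got {list(tot.columns)}")
    totals: dict[tuple[str, int], int] = {}
    for i, row in enumerate(tot.itertuples(index=False), start=2):
        if row.arm not in ARMS:
            raise CountTableError(f"{totals_path} line {i}: unknown arm {row.arm!r}")
        if row.total_reads < 0:
            raise CountTableError(f"{totals_path} line {i}: negative total_reads")
        totals[(row.arm, int(row.round))] = int(row.total_reads)

    missing = {(a, r) for a, r in zip(raw["arm"], raw["round"])} - set(totals)
    if missing:
        raise CountTableError(f"no total_reads for (arm, round) pairs: {sorted(missing)}")
    return CountTable(counts=raw.reset_index(drop=True), totals=totals)


def apply_min_read_filter(table: CountTable, min_reads: int = 2) -> CountTable:
    """Zero out count cells below ``min_reads`` (default: omit <2-read cells).

    The filter acts cell-wise per (arm, round): a clone may be zeroed in one
    round and kept in another.  Library-wide totals are unchanged.
    """
    if min_reads < 0:
        raise CountTableError(f"min_reads must be >= 0, got {min_reads}")
    counts = table.counts.copy()
    counts.loc[counts["reads"] < min_reads, "reads"] = 0
    return CountTable(counts=counts, totals=dict(table.totals))


@dataclass(frozen=True)
class ExperimentalSignature:
    """One clone's per-round frequencies (ppm) in one selection arm."""

    clone_id: str
    arm: str
    frequencies_ppm: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.frequencies_ppm):
            raise CountTableError(
                f"{self.clone_id}/{self.arm}: negative frequency")


def normalize_to_ppm(table: CountTable) -> list[ExperimentalSignature]:
    """Convert read counts to ppm of the pooled library: F = reads/total x 10^6.

    A round whose total is zero while some clone has reads there is an
    inconsistency and raises.  Clones absent from an arm get no signature for
    that arm (they are simply not in the output for it).
    """
    n_rounds = table.n_rounds
    for (arm, rnd), total in table.totals.items():
        if total == 0 and (
            (table.counts["arm"].eq(arm) & table.counts["round"].eq(rnd)
             & table.counts["reads"].gt(0)).any()
        ):
            raise CountTableError(
                f"({arm}, round {rnd}): zero total_reads but nonzero clone counts")

    out: list[ExperimentalSignature] = []
    grouped = table.counts.groupby(["clone_id", "arm"])
    for (clone_id, arm), grp in grouped:
        by_round = dict(zip(grp["round"], grp["reads"]))
        freqs = []
        for rnd in range(1, n_rounds + 1):
            reads = by_round.get(rnd, 0)
            total = table.totals.get((arm, rnd), 0)
            freqs.append(reads / total * PPM if total > 0 else 0.0)
        out.append(ExperimentalSignature(clone_id, arm, tuple(freqs)))
    return out


def signatures_to_frame(signatures: Sequence[ExperimentalSignature]) -> pd.DataFrame:
    """Wide table ``clone_id  arm  F_S1_ppm ... F_SR_ppm``."""
    if not signatures:
        return pd.DataFrame(columns=["clone_id", "arm"])
    n_rounds = len(signatures[0].frequencies_ppm)
    cols = [f"F_S{r}_ppm" for r in range(1, n_rounds + 1)]
    rows = [
        {"clone_id": s.clone_id, "arm": s.arm,
         **dict(zip(cols, s.frequencies_ppm))}
        for s in signatures
    ]
    return pd.DataFrame(rows, columns=["clone_id", "arm", *cols])


def write_signatures(signatures: Iterable[ExperimentalSignature], path: str | Path) -> None:
    signatures_to_frame(list(signatures)).to_csv(path, sep="\t", index=False)
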