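"""Deletion detection from per-base coverage and amplicon presence prediction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageProfile",
    "DeletionCall",
    "PrimerPair",
    "find_zero_runs",
    "predict_amplicons",
    "feature_loss_report",
    "read_coverage_table",
]


@dataclass
class CoverageProfile:
    """Per-position read depth along one scaffold (1-based positions)."""

    scaffold: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if len(self.depth) and self.depth.min() < 0:
            raise ValueError("depths must be >= 0")


@dataclass(frozen=True)
class DeletionCall:
    """A maximal low-coverage run, 1-based inclusive coordinates.

    ``length_bp = end - start + 1`` under the inclusive convention; the
    rounded kb value is the reporting contract.
    """

    scaffold: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return round(self.length_bp / 1000.0, 1)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer sites on the reference, 1-based inclusive."""

    name: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int

    def __post_init__(self):
        if not self.fwd_start <= self.fwd_end < self.rev_start <= self.rev_end:
            raise ValueError(f"{self.name}: primer coordinates out of order")

    @property
    def amplicon_length(self) -> int:
        return self.rev_end - self.fwd_start + 1


def find_zero_runs(
    profile: CoverageProfile,
    min_length: int = 1000,
    max_depth: int = 0,
) -> list[DeletionCall]:
    """Maximal runs with depth <= max_depth and length >= min_length.

    Calls are disjoint and maximal: extending any call by one position
    would violate the depth criterion or the scaffold boundary.
    """
    if len(profile.depth) == 0:
        raise ValueError("empty coverage profile")
    low = np.concatenate([[0], (profile.depth <= max_depth).astype(np.int8), [0]])
    edges = np.diff(low)
    starts = np.flatnonzero(edges == 1) + 1  # 1-based
    ends = np.flatnonzero(edges == -1)  # inclusive, 1-based
    return [
        DeletionCall(profile.scaffold, int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s + 1 >= min_length
    ]


def predict_amplicons(
    primers: Sequence[PrimerPair], deletions: Sequence[DeletionCall]
) -> pd.DataFrame:
    """Presence/absence of each amplicon over the called deletions.

    A pair is ABSENT iff either primer site lies inside a deletion;
    present pairs report their expected reference amplicon length.
    Monotone: enlarging a deletion never turns ABSENT into PRESENT.
    """

    def _inside(lo: int, hi: int) -> bool:
        return any(d.start <= lo and hi <= d.end for d in deletions)

    rows = []
    for p in primers:
        absent = _inside(p.fwd_start, p.fwd_end) or _inside(p.rev_start, p.rev_end)
        rows.append(
            {
                "primer": p.name,
                "status": "ABSENT" if absent else "PRESENT",
                "amplicon_bp": None if absent else p.amplicon_length,
            }
        )
    return pd.DataFrame(rows)


def feature_loss_report(
    deletions: Sequence[DeletionCall], annotation: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Classify annotated genes as lost, truncated or unaffected.

    ``annotation`` columns: gene, scaffold, start, end (1-based
    inclusive).  Fully contained genes are lost; genes overlapping a call
    boundary are truncated; abutting non-overlapping genes are unaffected.
    """
    if annotation is None or not len(annotation):
        return pd.DataFrame(columns=["gene", "scaffold", "status"])
    rows = []
    for row in annotation.itertuples(index=False):
        status = "unaffected"
        for d in deletions:
            if d.scaffold != row.scaffold or row.end < d.start or row.start > d.end:
                continue
            if d.start <= row.start and row.end <= d.end:
                status = "lost"
                break
            status = "truncated"
        if status != "unaffected":
            rows.append({"gene": row.gene, "scaffold": row.scaffold, "status": status})
    return pd.DataFrame(rows, columns=["gene", "scaffold", "status"])


def read_coverage_table(path, scaffold: Optional[str] = None) -> CoverageProfile:
    """Load a per-base coverage TSV (scaffold, pos, depth) into a profile.

    Positions are 1-based; absent positions up to the maximum listed
    position default to depth 0.
    """
    df = pd.read_csv(path, sep="\t")
    if scaffold is not None:
        df = df[df["scaffold"] == scaffold]
    elif df["scaffold"].nunique() > 1:
        raise ValueError("multiple scaffolds present; pass scaffold=")
    if df.empty:
        raise ValueError("no coverage rows")
    name = str(df["scaffold"].iloc[0])
    depth = np.zeros(int(df["pos"].max()), dtype=np.int64)
    depth[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
    return CoverageProfile(scaffold=name, depth=depth)
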