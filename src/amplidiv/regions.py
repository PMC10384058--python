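"""Dereplication, alignment-region selection and coverage-based length
filtering.

Amplicon studies target different 16S subregions, so an integrated,
co-aligned collection covers the master alignment unevenly.  The
per-column base counts locate the most-represented contiguous region;
records are trimmed to it and kept only when they carry more than a set
fraction (default 80%) of the bases a designated full-length reference
(E. coli in the classical workflow) holds inside the same window.

All column coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import GAP_CHARS, AlignedRecord, check_equal_width


@dataclass
class PositionCoverage:
    """Number of records contributing a base (non-gap character,
    including N) at each alignment column."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)


@dataclass
class RegionWindow:
    """Half-open column interval of the master alignment plus the
    length-filter parameters derived from a reference record."""

    start: int
    end: int
    expected_bases: int | None = None
    min_fraction: float = 0.8
    min_bases_override: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def threshold(self) -> int:
        """Minimum base count a trimmed record must reach to be kept:
        the override when set, else the smallest integer strictly
        greater than min_fraction * expected_bases ("more than 80%")."""
        if self.min_bases_override is not None:
            return int(self.min_bases_override)
        if self.expected_bases is None:
            raise ValueError("window has neither expected_bases nor min_bases_override")
        x = self.min_fraction * self.expected_bases
        return int(math.floor(x + 1e-9)) + 1


@dataclass
class Multiplicities:
    """Dereplication bookkeeping: per retained id, how many originals it
    stands for and which ones."""

    counts: dict[str, int] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": rid, "multiplicity": self.counts[rid], "members": ",".join(self.members[rid])}
            for rid in self.counts
        ]
        return pd.DataFrame(rows, columns=["id", "multiplicity", "members"])


def dereplicate(records: Sequence[AlignedRecord]) -> tuple[list[AlignedRecord], Multiplicities]:
    """Collapse records with byte-identical column strings.

    The retained id is the lexicographically smallest member id; the
    retained records keep the order of first appearance of their group.
    """
    check_equal_width(records)
    groups: dict[str, list[AlignedRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.columns not in groups:
            groups[rec.columns] = []
            order.append(rec.columns)
        groups[rec.columns].append(rec)
    unique: list[AlignedRecord] = []
    mult = Multiplicities()
    for cols in order:
        members = groups[cols]
        keeper = min(members, key=lambda r: r.id)
        unique.append(keeper)
        mult.counts[keeper.id] = len(members)
        mult.members[keeper.id] = sorted(r.id for r in members)
    return unique, mult


def compute_position_coverage(records: Sequence[AlignedRecord]) -> PositionCoverage:
    """Per-column count of records carrying a base at that column."""
    if not records:
        raise ValueError("coverage of an empty record collection is undefined")
    width = check_equal_width(records)
    counts = np.zeros(width, dtype=np.int64)
    gap_bytes = {ord(c) for c in GAP_CHARS}
    for rec in records:
        arr = np.frombuffer(rec.columns.encode("ascii"), dtype=np.uint8)
        mask = np.ones(width, dtype=bool)
        for g in gap_bytes:
            mask &= arr != g
        counts += mask
    return PositionCoverage(counts)


def select_represented_region(
    coverage: PositionCoverage,
    plateau_fraction: float = 0.8,
    override: tuple[int, int] | None = None,
) -> RegionWindow:
    """Longest contiguous run of columns with coverage at least
    plateau_fraction * max(coverage); leftmost run wins ties.  A manual
    ``override`` window bypasses the scan."""
    if override is not None:
        return RegionWindow(start=override[0], end=override[1])
    counts = coverage.counts
    if counts.size == 0 or counts.max() == 0:
        raise ValueError("cannot select a region from all-zero coverage")
    if not (0 < plateau_fraction <= 1):
        raise ValueError("plateau_fraction must be in (0, 1]")
    cut = plateau_fraction * counts.max()
    best_start, best_len = 0, 0
    i = 0
    n = counts.size
    while i < n:
        if counts[i] >= cut:
            j = i
            while j < n and counts[j] >= cut:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    return RegionWindow(start=best_start, end=best_start + best_len)


def expected_bases_in_window(reference: AlignedRecord, window: RegionWindow) -> int:
    """Ungapped bases the reference contributes inside the window."""
    if window.end > len(reference.columns):
        raise ValueError(
            f"window [{window.start}, {window.end}) exceeds reference width "
            f"{len(reference.columns)}"
        )
    segment = reference.columns[window.start : window.end]
    return sum(1 for c in segment if c not in GAP_CHARS)


def trim_and_filter(
    records: Sequence[AlignedRecord],
    window: RegionWindow,
) -> tuple[list[AlignedRecord], pd.DataFrame]:
    """Slice each record to the window, drop gaps, and keep it iff its
    base count reaches the window's threshold.

    Returns the kept records (ungapped, input order preserved) and a
    discard log with one row per removed record.
    """
    threshold = window.threshold
    kept: list[AlignedRecord] = []
    discarded: list[dict] = []
    for rec in records:
        segment = rec.columns[window.start : window.end]
        bases = "".join(c for c in segment if c not in GAP_CHARS)
        if len(bases) >= threshold:
            kept.append(
                AlignedRecord(id=rec.id, columns=bases, lineage=rec.lineage, sample_id=rec.sample_id)
            )
        else:
            discarded.append({"id": rec.id, "bases": len(bases), "reason": f"bases<{threshold}"})
    log = pd.DataFrame(discarded, columns=["id", "bases", "reason"])
    return kept, log


def write_discard_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, sep="\t", index=False)
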