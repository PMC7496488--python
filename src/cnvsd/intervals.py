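"""Interval algebra on genome coordinates.

Every coordinate in this package is 0-based, half-open ``[start, end)`` —
the BED convention.  GFF3 input (1-based, fully closed) is converted at the
parsing boundary (:mod:`cnvsd.io`) so that no other module ever sees a
1-based coordinate.  Strand is carried through for bookkeeping but ignored
by every overlap and distance computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_STRANDS = ("+", "-", ".")


class IntervalError(ValueError):
    """A malformed interval or interval collection."""


@dataclass(frozen=True)
class GenomeInterval:
    """One half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise IntervalError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomeInterval") -> int:
        """Gap in bp between disjoint intervals; 0 when overlapping.

        The gap is ``start_of_later - end_of_earlier``. Raises for intervals
        on different chromosomes, where the distance is undefined.
        """
        if self.chrom != other.chrom:
            raise IntervalError(
                f"distance undefined across chromosomes "
                f"({self.chrom} vs {other.chrom})"
            )
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


class IntervalSet:
    """An ordered collection of intervals, optionally with payload columns.

    Backed by a :class:`pandas.DataFrame` with at least the columns
    ``chrom``, ``start``, ``end``; any further columns (``name``, ``score``,
    ``strand`` ...) ride along untouched. The canonical order is
    ``(chrom, start, end)``; :meth:`normalize` returns a sorted copy.
    """

    REQUIRED = ("chrom", "start", "end")

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame({"chrom": [], "start": [], "end": []})
        df = df.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise IntervalError(f"missing required column {col!r}")
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            bad = (df["start"] < 0) | (df["start"] >= df["end"])
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                rec = df.iloc[i]
                raise IntervalError(
                    f"record {i}: invalid interval "
                    f"{rec['chrom']}:{rec['start']}-{rec['end']}"
                )
            if (df["chrom"].astype(str) == "").any():
                raise IntervalError("empty chromosome name")
        self.df = df

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomeInterval]) -> "IntervalSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        if not rows:
            df = pd.DataFrame({"chrom": [], "start": [], "end": [], "strand": []})
        return cls(df)

    @classmethod
    def from_arrays(cls, chroms, starts, ends, **extra) -> "IntervalSet":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, **extra})
        return cls(df)

    # -- basic protocol -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomeInterval]:
        strands = (
            self.df["strand"].tolist()
            if "strand" in self.df.columns
            else ["."] * len(self.df)
        )
        for (c, s, e), st in zip(
            self.df[["chrom", "start", "end"]].itertuples(index=False), strands
        ):
            yield GenomeInterval(c, int(s), int(e), st if st in _STRANDS else ".")

    def normalize(self) -> "IntervalSet":
        """Sorted copy in canonical (chrom, start, end) order."""
        df = self.df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet(df)

    def total_length(self) -> int:
        if not len(self.df):
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].astype(str).unique().tolist())

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays in start order."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            sub = sub.sort_values(["start", "end"])
            out[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
            )
        return out


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals; touching intervals (end == start) merge."""
    order = np.lexsort((ends, starts))
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:  # overlap or touch
            cur_e = max(cur_e, int(e))
        else:
            out_s.append(cur_s)
            out_e.append(cur_e)
            cur_s, cur_e = int(s), int(e)
    out_s.append(cur_s)
    out_e.append(cur_e)
    return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)


def merge_intervals(iset: IntervalSet) -> IntervalSet:
    """Collapse overlapping and touching intervals into a disjoint set.

    BED-merge semantics: the base-level union is preserved and intervals
    whose end touches the next start are joined. The result is sorted in
    canonical order and idempotent under re-merging.
    """
    if not len(iset):
        return IntervalSet()
    rows = []
    for chrom, (starts, ends) in iset.by_chrom().items():
        ms, me = _merge_arrays(starts, ends)
        for s, e in zip(ms, me):
            rows.append((chrom, int(s), int(e)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df).normalize()


def _overlap_mask(
    a_starts: np.ndarray,
    a_ends: np.ndarray,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
) -> np.ndarray:
    """Boolean mask over a-intervals overlapping >=1 bp of merged-b intervals.

    ``b_starts``/``b_ends`` must describe disjoint sorted intervals.
    """
    if len(b_starts) == 0:
        return np.zeros(len(a_starts), dtype=bool)
    idx = np.searchsorted(b_starts, a_ends, side="left")
    mask = idx > 0
    prev_end = np.where(mask, b_ends[np.maximum(idx - 1, 0)], 0)
    return mask & (prev_end > a_starts)


def overlap_count(a: IntervalSet, b: IntervalSet) -> int:
    """Number of intervals of ``a`` overlapping >= 1 bp with any of ``b``.

    Each a-interval is counted at most once; the answer is therefore
    invariant to merging ``b`` first.
    """
    b_merged = merge_intervals(b).by_chrom()
    n = 0
    for chrom, (a_s, a_e) in a.by_chrom().items():
        if chrom not in b_merged:
            continue
        b_s, b_e = b_merged[chrom]
        n += int(_overlap_mask(a_s, a_e, b_s, b_e).sum())
    return n


def complement_intervals(
    mask: IntervalSet, chrom_lengths: dict[str, int]
) -> IntervalSet:
    """The non-masked space: per-chromosome complement of ``mask`` within
    ``[0, length)``. Chromosomes absent from the mask are returned whole."""
    merged = merge_intervals(mask).by_chrom()
    rows = []
    for chrom, length in sorted(chrom_lengths.items()):
        pos = 0
        for s, e in zip(*merged.get(chrom, (np.array([]), np.array([])))):
            if s > pos:
                rows.append((chrom, pos, int(s)))
            pos = max(pos, int(e))
        if pos < length:
            rows.append((chrom, pos, length))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def closest_distances(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Distance in bp from each a-interval to its nearest b-interval.

    Distances are 0 for overlapping pairs and ``start_of_later -
    end_of_earlier`` otherwise. a-intervals on chromosomes with no
    b-interval have no defined distance; they are excluded and their count
    is logged.
    """
    b_merged = merge_intervals(b).by_chrom()
    dists: list[np.ndarray] = []
    n_undefined = 0
    for chrom, (a_s, a_e) in a.by_chrom().items():
        if chrom not in b_merged:
            n_undefined += len(a_s)
            continue
        b_s, b_e = b_merged[chrom]
        idx = np.searchsorted(b_s, a_s)  # first b with b_start >= a_start
        right = np.where(idx < len(b_s), b_s[np.minimum(idx, len(b_s) - 1)] - a_e, np.iinfo(np.int64).max)
        left = np.where(idx > 0, a_s - b_e[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        d = np.minimum(np.maximum(right, 0), np.maximum(left, 0))
        d[_overlap_mask(a_s, a_e, b_s, b_e)] = 0
        dists.append(d)
    if n_undefined:
        logger.warning(
            "closest_distances: %d interval(s) on chromosomes absent from b "
            "excluded", n_undefined,
        )
    if not dists:
        return np.array([], dtype=np.int64)
    return np.concatenate(dists)
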