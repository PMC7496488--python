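"""Readers and writers for the plain-text formats the pipeline touches.

BED is treated as 0-based half-open, GFF3 as 1-based fully closed and
converted on ingest, FASTA is wrapped at 60 columns on write.  The read
count matrix is a TSV whose first column is ``target_id`` followed by one
integer column per sample; a companion target BED maps ``target_id`` to
genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import IntervalSet


class ParseError(ValueError):
    """A format violation, carrying the offending line number where known."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet` (payload columns kept)."""
    rows = []
    n_fields = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not (0 <= start < end):
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {parts[0]}:{start}-{end}"
                )
            n_fields = max(n_fields or 0, min(len(parts), 6))
            rows.append(parts[:6])
    if not rows:
        return IntervalSet()
    cols = ["chrom", "start", "end", "name", "score", "strand"][: n_fields or 3]
    df = pd.DataFrame([r + [None] * (len(cols) - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return IntervalSet(df)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED3 or BED6 depending on the payload columns present."""
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in iset.df.columns:
            cols.append(extra)
        else:
            break
    with open(path, "w") as fh:
        for row in iset.df[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff3_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> IntervalSet:
    """Read selected GFF3 feature types, converting to 0-based half-open.

    A GFF3 feature at ``start..end`` (1-based inclusive) becomes the interval
    ``[start-1, end)``. The feature ``ID`` attribute is kept as ``name`` and
    the ``Parent`` attribute as ``parent``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 fields")
            if parts[2] not in feature_types:
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: invalid 1-based span {start1}..{end1}")
            rows.append(
                (
                    parts[0],
                    start1 - 1,
                    end1,
                    _gff3_attr(parts[8], "ID") or f"{parts[2]}_{lineno}",
                    parts[6] if parts[6] in ("+", "-") else ".",
                    parts[2],
                    _gff3_attr(parts[8], "Parent"),
                )
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "strand", "type", "parent"]
    )
    if not rows:
        df = pd.DataFrame(
            {c: [] for c in ["chrom", "start", "end", "name", "strand", "type", "parent"]}
        )
    return IntervalSet(df)


def read_gff3_genes(path: str | Path) -> IntervalSet:
    return read_gff3(path, feature_types=("gene",))


def write_gff3(iset: IntervalSet, path: str | Path, source: str = "cnvsd") -> None:
    """Write features (with ``type``/``name``/optional ``parent``) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in iset.df.itertuples(index=False):
            attrs = f"ID={row.name}"
            parent = getattr(row, "parent", None)
            if parent:
                attrs += f";Parent={parent}"
            strand = getattr(row, "strand", ".") or "."
            ftype = getattr(row, "type", "region")
            fh.write(
                f"{row.chrom}\t{source}\t{ftype}\t{row.start + 1}\t{row.end}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Exome-capture fragment counts: targets x samples plus target metadata.

    ``counts`` is indexed by ``target_id`` with one integer column per
    sample. ``targets`` has columns ``chrom, start, end, target_id`` (plus
    optional extras such as ``gene``) aligned row-for-row with ``counts``.
    """

    counts: pd.DataFrame
    targets: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.targets["target_id"]):
            self.targets = (
                self.targets.set_index("target_id")
                .loc[self.counts.index]
                .reset_index()
            )
        lengths = self.targets["end"] - self.targets["start"]
        if (lengths <= 0).any():
            raise ParseError("non-positive target length")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_targets(self) -> int:
        return len(self.counts)

    def target_lengths(self) -> np.ndarray:
        return (self.targets["end"] - self.targets["start"]).to_numpy(np.int64)

    def target_intervals(self) -> IntervalSet:
        return IntervalSet(self.targets.rename(columns={"target_id": "name"}))

    def subset_targets(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[mask].copy(), self.targets.loc[mask].reset_index(drop=True)
        )

    def sorted_by_position(self) -> "CountMatrix":
        order = self.targets.sort_values(["chrom", "start", "end"]).index
        return CountMatrix(
            self.counts.iloc[order].copy(),
            self.targets.iloc[order].reset_index(drop=True),
        )


def read_count_matrix(counts_path: str | Path, targets_bed: str | Path) -> CountMatrix:
    """Read the counts TSV and its companion target BED.

    Validates integer non-negative counts and unique target ids; any
    violation raises :class:`ParseError` naming the offending cell/line.
    """
    df = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if df.columns[0] != "target_id":
        raise ParseError(f"{counts_path}: first column must be 'target_id'")
    if df["target_id"].duplicated().any():
        dup = df["target_id"][df["target_id"].duplicated()].iloc[0]
        raise ParseError(f"{counts_path}: duplicate target id {dup!r}")
    df = df.set_index("target_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ParseError(f"{counts_path}: non-numeric count at ({row}, {col})")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ParseError(f"{counts_path}: negative count at ({row}, {col})")
        if not np.allclose(vals, np.round(vals)):
            row = df.index[~np.isclose(vals, np.round(vals))][0]
            raise ParseError(f"{counts_path}: non-integer count at ({row}, {col})")
        df[col] = vals.astype(np.int64)
    bed = read_bed(targets_bed)
    targets = bed.df.rename(columns={"name": "target_id"})
    if "target_id" not in targets.columns:
        raise ParseError(f"{targets_bed}: target BED needs a name column")
    missing = set(df.index) - set(targets["target_id"])
    if missing:
        raise ParseError(
            f"{targets_bed}: {len(missing)} target id(s) missing, e.g. "
            f"{sorted(missing)[0]!r}"
        )
    targets = targets.set_index("target_id").loc[df.index].reset_index()
    return CountMatrix(df, targets)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, targets_bed: str | Path) -> None:
    cm.counts.reset_index().rename(columns={"index": "target_id"}).to_csv(
        counts_path, sep="\t", index=False
    )
    bed = IntervalSet(cm.targets.rename(columns={"target_id": "name"}))
    write_bed(bed, targets_bed)
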