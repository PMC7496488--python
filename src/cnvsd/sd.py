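"""Segmental duplication discovery by genome self-alignment.

The genome is hard-masked with N over annotated repeats, split into 250-kb
chunks, and each chunk is aligned back against the whole masked genome.
The aligner is a minimal seed-chain-extend design: exact k-mer seeds
(N-free only), chaining of seeds on nearby diagonals, ungapped X-drop
extension, and a final gapped edit-distance pass (edlib) that yields the
percent identity (matches / alignment columns, the blast convention, here
computed as ``100 (1 - dist / max(len_q, len_s))``).  Hits shorter than
1 kb, below the identity floor, or matching a locus against itself are
discarded; both sides of the survivors are projected to the genome and
merged into disjoint SD regions.

Precomputed tabular alignments (12-column blast outfmt-6 dialect) can be
ingested instead of running the internal aligner, so the stage scales to
genomes the internal aligner is not meant for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge_intervals

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qchrom", "qstart", "qend", "schrom", "sstart", "send",
    "pident", "length", "score",
]


@dataclass
class SdParams:
    chunk_size: int = 250_000
    min_identity: float = 95.0
    min_length: int = 1000
    seed_kmer_size: int = 31
    seed_stride: int = 4
    band_width: int = 100
    max_seed_gap: int = 2000
    min_seeds: int = 3
    xdrop: int = 30
    identity_thresholds: tuple[float, ...] = (95.0, 96.0, 97.0, 98.0, 99.0)

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (90.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity must be in [90, 100]")
        if self.chunk_size < 10_000:
            raise ValueError("chunk_size must be >= 10 kb")


# ---------------------------------------------------------------------------
# masking and chunking
# ---------------------------------------------------------------------------

def mask_genome(seqs: dict[str, str], repeats: IntervalSet) -> dict[str, str]:
    """Hard-mask annotated repeat bases with N.

    The masked-base count equals the merged annotation length; everything
    else is untouched. Out-of-bounds annotations are an error naming the
    record.
    """
    merged = merge_intervals(repeats).by_chrom()
    out = {}
    for chrom, seq in seqs.items():
        if chrom not in merged:
            out[chrom] = seq
            continue
        starts, ends = merged[chrom]
        if len(ends) and ends[-1] > len(seq):
            raise ValueError(
                f"repeat annotation out of bounds on {chrom}: "
                f"end {int(ends[-1])} > length {len(seq)}"
            )
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        for s, e in zip(starts, ends):
            arr[s:e] = b"N"
        out[chrom] = arr.tobytes().decode()
    return out


def chunk_genome(seqs: dict[str, str], chunk_size: int) -> list[tuple[str, int, str]]:
    """Consecutive non-overlapping (chrom, offset, sequence) windows.

    The last chunk of a chromosome may be short; concatenating the chunks
    reproduces the chromosome and offsets back-map hit coordinates exactly.
    """
    chunks = []
    for chrom in sorted(seqs):
        seq = seqs[chrom]
        for off in range(0, len(seq), chunk_size):
            chunks.append((chrom, off, seq[off : off + chunk_size]))
    return chunks


# ---------------------------------------------------------------------------
# seeding, chaining, extension
# ---------------------------------------------------------------------------

def _build_seed_index(seqs: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in seqs.items():
        for pos in range(0, len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((chrom, pos))
    return index


def _xdrop_extend(
    q: str, s: str, qlo: int, qhi: int, slo: int, xdrop: int
) -> tuple[int, int]:
    """Extend the ungapped match [qlo, qhi) vs s starting at slo both ways.

    Match +1 / mismatch -2 with an X-drop stop; returns the extended
    (qlo, qhi). N bases terminate extension.
    """
    d = slo - qlo
    # rightward
    score = best = 0
    best_q = qhi
    i = qhi
    while i < len(q) and i + d < len(s):
        a, b = q[i], s[i + d]
        if a == "N" or b == "N":
            break
        score += 1 if a == b else -2
        if score > best:
            best, best_q = score, i + 1
        if best - score > xdrop:
            break
        i += 1
    qhi = best_q
    # leftward
    score = best = 0
    best_q = qlo
    i = qlo - 1
    while i >= 0 and i + d >= 0:
        a, b = q[i], s[i + d]
        if a == "N" or b == "N":
            break
        score += 1 if a == b else -2
        if score > best:
            best, best_q = score, i
        if best - score > xdrop:
            break
        i -= 1
    return best_q, qhi


def self_align(
    seqs_masked: dict[str, str],
    params: SdParams | None = None,
) -> pd.DataFrame:
    """Align every chunk of the masked genome against the whole of it.

    Returns raw hits (before :func:`filter_hits`): query/subject intervals
    in genome coordinates, percent identity, alignment length and score.
    Chunks with no N-free seed are skipped with a log entry.
    """
    params = params or SdParams()
    k = params.seed_kmer_size
    index = _build_seed_index(seqs_masked, k)
    rows = []
    for chrom, offset, chunk in chunk_genome(seqs_masked, params.chunk_size):
        # seed matches grouped by (subject chrom, diagonal)
        clusters: dict[tuple[str, int], list[int]] = {}
        n_seeds = 0
        for qpos in range(0, len(chunk) - k + 1, params.seed_stride):
            kmer = chunk[qpos : qpos + k]
            if "N" in kmer:
                continue
            n_seeds += 1
            for tchrom, tpos in index.get(kmer, ()):
                qg = offset + qpos
                if tchrom == chrom and tpos == qg:
                    continue  # the locus matching itself
                clusters.setdefault((tchrom, tpos - qg), []).append(qg)
        if n_seeds == 0:
            logger.info("chunk %s:%d has no N-free seed; skipped", chrom, offset)
            continue
        merged_clusters = _merge_diagonals(clusters, params)
        for (tchrom, diag), qlist in merged_clusters:
            for qlo, qhi in _split_on_gaps(sorted(qlist), params.max_seed_gap, k):
                if qhi - qlo < max(params.min_length // 2, k) :
                    continue
                rows.append(
                    _extend_and_score(
                        seqs_masked[chrom], seqs_masked[tchrom],
                        chrom, tchrom, qlo, qhi, diag, params,
                    )
                )
    hits = pd.DataFrame([r for r in rows if r is not None], columns=HIT_COLUMNS)
    return hits.drop_duplicates().reset_index(drop=True)


def _merge_diagonals(
    clusters: dict[tuple[str, int], list[int]], params: SdParams
) -> list[tuple[tuple[str, int], list[int]]]:
    """Fold seed groups on nearby diagonals (within band_width) together.

    Indel-free duplications put every seed on one diagonal; small indels
    scatter them over a few neighbouring ones. Groups are keyed by the
    diagonal of their largest member.
    """
    out: list[tuple[tuple[str, int], list[int]]] = []
    by_chrom: dict[str, list[tuple[int, list[int]]]] = {}
    for (tchrom, d), qs in clusters.items():
        if len(qs) >= params.min_seeds:
            by_chrom.setdefault(tchrom, []).append((d, qs))
    for tchrom, groups in by_chrom.items():
        groups.sort(key=lambda g: g[0])
        cur_d, cur_qs = groups[0]
        merged: list[tuple[int, list[int]]] = []
        for d, qs in groups[1:]:
            if d - cur_d <= params.band_width:
                if len(qs) > len(cur_qs):
                    cur_d = d
                cur_qs = cur_qs + qs
            else:
                merged.append((cur_d, cur_qs))
                cur_d, cur_qs = d, qs
        merged.append((cur_d, cur_qs))
        out.extend(((tchrom, d), qs) for d, qs in merged)
    return out


def _split_on_gaps(qs: list[int], max_gap: int, k: int):
    lo = qs[0]
    prev = qs[0]
    for q in qs[1:]:
        if q - prev > max_gap:
            yield lo, prev + k
            lo = q
        prev = q
    yield lo, prev + k


def _extend_and_score(
    qseq: str, sseq: str, qchrom: str, schrom: str,
    qlo: int, qhi: int, diag: int, params: SdParams,
):
    qlo, qhi = _xdrop_extend(qseq, sseq, qlo, qhi, qlo + diag, params.xdrop)
    slo, shi = qlo + diag, qhi + diag
    if qhi - qlo < params.seed_kmer_size or slo < 0 or shi > len(sseq):
        return None
    a, b = qseq[qlo:qhi], sseq[slo:shi]
    res = edlib.align(a, b, task="distance")
    columns = max(len(a), len(b))
    dist = res["editDistance"]
    pident = 100.0 * (1.0 - dist / columns)
    matches = columns - dist
    return (
        qchrom, int(qlo), int(qhi), schrom, int(slo), int(shi),
        float(pident), int(columns), int(matches - 2 * dist),
    )


# ---------------------------------------------------------------------------
# filtering, merging, summarizing
# ---------------------------------------------------------------------------

def filter_hits(hits: pd.DataFrame, params: SdParams | None = None) -> pd.DataFrame:
    """Apply the SD predicates and canonicalize symmetric duplicates.

    Removed: (i) self-hits — query and subject on the same chromosome and
    diagonal (within band_width) with > 50% reciprocal overlap; (ii) hits
    with alignment length < min_length; (iii) hits with identity <
    min_identity. A -> B and B -> A records are reduced to one canonical
    row (lexicographically smaller side first).
    """
    params = params or SdParams()
    if not len(hits):
        return hits.copy()
    df = hits.copy()
    # self-hit predicate
    same = df["qchrom"] == df["schrom"]
    diag_close = (df["sstart"] - df["qstart"]).abs() <= params.band_width
    ov = np.minimum(df["qend"], df["send"]) - np.maximum(df["qstart"], df["sstart"])
    qlen = df["qend"] - df["qstart"]
    slen = df["send"] - df["sstart"]
    recip = (ov > 0.5 * qlen) & (ov > 0.5 * slen)
    selfhit = same & diag_close & recip
    df = df[~selfhit]
    df = df[df["length"] >= params.min_length]
    df = df[df["pident"] >= params.min_identity]
    # canonical orientation
    qkey = list(zip(df["qchrom"], df["qstart"], df["qend"]))
    skey = list(zip(df["schrom"], df["sstart"], df["send"]))
    flip = [q > s for q, s in zip(qkey, skey)]
    if any(flip):
        flip = np.array(flip)
        for qcol, scol in (("qchrom", "schrom"), ("qstart", "sstart"), ("qend", "send")):
            tmp = df.loc[flip, qcol].copy()
            df.loc[flip, qcol] = df.loc[flip, scol]
            df.loc[flip, scol] = tmp
    return df.drop_duplicates(
        subset=["qchrom", "qstart", "qend", "schrom", "sstart", "send"]
    ).reset_index(drop=True)


def merge_sd_regions(hits: pd.DataFrame) -> pd.DataFrame:
    """Project both sides of every hit to the genome and merge the union.

    Returns disjoint SD regions (chrom, start, end) with the number of
    supporting hit sides and the maximum identity among them.
    """
    if not len(hits):
        return pd.DataFrame(columns=["chrom", "start", "end", "n_hits", "max_identity"])
    sides = pd.concat(
        [
            hits[["qchrom", "qstart", "qend", "pident"]].rename(
                columns={"qchrom": "chrom", "qstart": "start", "qend": "end"}
            ),
            hits[["schrom", "sstart", "send", "pident"]].rename(
                columns={"schrom": "chrom", "sstart": "start", "send": "end"}
            ),
        ],
        ignore_index=True,
    )
    merged = merge_intervals(IntervalSet(sides[["chrom", "start", "end"]]))
    rows = []
    bych = {c: sub for c, sub in sides.groupby("chrom")}
    for iv in merged.df.itertuples(index=False):
        sub = bych[iv.chrom]
        inside = (sub["start"] < iv.end) & (sub["end"] > iv.start)
        rows.append(
            (
                iv.chrom, iv.start, iv.end,
                int(inside.sum()),
                float(sub.loc[inside, "pident"].max()),
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_hits", "max_identity"])


def sd_summary(
    hits: pd.DataFrame,
    regions: pd.DataFrame,
    genome_lengths: dict[str, int],
    params: SdParams | None = None,
    window: int = 50_000,
) -> dict:
    """Counts at the identity-threshold ladder, 1-kb length histogram,
    per-chromosome 50-kb window counts, and footprint statistics.

    Threshold counts use strict '>' (a ladder of nested subsets) and are
    monotonically non-increasing.
    """
    params = params or SdParams()
    out: dict = {}
    out["n_hits"] = len(hits)
    out["n_regions"] = len(regions)
    out["threshold_counts"] = {
        f">{t:g}": int((hits["pident"] > t).sum()) if len(hits) else 0
        for t in params.identity_thresholds
    }
    if len(hits):
        max_len = int(hits["length"].max())
        edges = np.arange(0, max_len + 1000, 1000)
        counts, _ = np.histogram(hits["length"], bins=edges)
        out["length_histogram"] = {
            int(edges[i]): int(c) for i, c in enumerate(counts) if c
        }
    else:
        out["length_histogram"] = {}
    footprint = int((regions["end"] - regions["start"]).sum()) if len(regions) else 0
    genome_size = sum(genome_lengths.values())
    out["footprint_bp"] = footprint
    out["footprint_mb"] = footprint / 1e6
    out["genome_fraction"] = footprint / genome_size if genome_size else 0.0
    windows = {}
    for chrom, glen in sorted(genome_lengths.items()):
        nbin = int(np.ceil(glen / window)) or 1
        counts = np.zeros(nbin, dtype=int)
        if len(regions):
            sub = regions[regions["chrom"] == chrom]
            mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
            for m in mids:
                counts[min(int(m // window), nbin - 1)] += 1
        windows[chrom] = counts
    out["window_counts"] = windows
    return out


def read_blast_hits(path: str | Path) -> pd.DataFrame:
    """Ingest 12-column blast outfmt-6 alignments as hit records.

    Alignment coordinates are 1-based inclusive and may be reversed on the
    subject for minus-strand hits; both are normalized to 0-based half-open
    forward intervals. Query ids of the form ``chrom:offset`` (the chunk
    naming used when blasting chunked queries) are mapped back to genome
    coordinates.
    """
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    rows = []
    for r in df.itertuples(index=False):
        qid, qoff = str(r.qseqid), 0
        if ":" in qid:
            qid, off_s = qid.rsplit(":", 1)
            qoff = int(off_s)
        qs, qe = sorted((int(r.qstart), int(r.qend)))
        ss, se = sorted((int(r.sstart), int(r.send)))
        rows.append(
            (
                qid, qoff + qs - 1, qoff + qe, str(r.sseqid), ss - 1, se,
                float(r.pident), int(r.length),
                int(r.length - r.mismatch - r.gapopen),
            )
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def detect_sds(
    genome: dict[str, str],
    repeats: IntervalSet,
    params: SdParams | None = None,
    external_hits: pd.DataFrame | None = None,
) -> dict:
    """Full SD pipeline: mask -> chunk/self-align (or ingest) -> filter ->
    merge -> summarize. Returns dict with hits, regions, summary."""
    params = params or SdParams()
    masked = mask_genome(genome, repeats)
    raw = external_hits if external_hits is not None else self_align(masked, params)
    hits = filter_hits(raw, params)
    regions = merge_sd_regions(hits)
    summary = sd_summary(
        hits, regions, {c: len(s) for c, s in genome.items()}, params
    )
    return {"hits": hits, "regions": regions, "summary": summary, "masked": masked}
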