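"""Synthetic genomes and exome-capture panels with planted truth.

The generator emulates the structure the pipeline is built for: a few-Mb
multi-chromosome genome carrying interspersed repeats (copies of a small
motif library), segmental-duplication pairs of 1-10 kb at 95-99% identity
created by copying a high-complexity donor segment and applying
substitutions, and multi-exon genes whose exons double as capture targets.
On top of it, a panel of accessions (wild / landrace / cultivar) receives
planted CNV sites — deletions (copy ratio 0.5) about four times more
frequent than duplications (1.5), a rare-dominated carrier-frequency
spectrum, and site placement optionally biased towards SD-rich windows —
and per-target fragment counts at ~40x mean depth with per-target capture
efficiency and Gamma-Poisson overdispersion.

Every random choice flows from one numpy Generator seeded by ``seed``:
fixing the seed fixes every output byte.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .io import CountMatrix, write_bed, write_fasta, write_gff3

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Requested features cannot be packed into the genome."""


@dataclass
class SimGenomeParams:
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    gc_content: float = 0.44
    repeat_fraction: float = 0.25
    n_sd_pairs: int = 25
    sd_length_range: tuple[int, int] = (1000, 10_000)
    sd_identity_range: tuple[float, float] = (0.95, 0.99)
    n_genes: int = 400
    exons_per_gene_range: tuple[int, int] = (4, 8)
    exon_length_range: tuple[int, int] = (150, 500)
    intron_length_range: tuple[int, int] = (100, 600)
    gene_sd_overlap_fraction: float = 0.3
    sd_terminal_bias: float = 4.0  # SDs denser towards chromosome-arm ends
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.sd_length_range, self.sd_identity_range,
            self.exons_per_gene_range, self.exon_length_range,
            self.intron_length_range,
        ):
            if lo > hi:
                raise ValueError("range low must be <= high")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if not (0 <= self.repeat_fraction < 1):
            raise ValueError("repeat_fraction must be in [0, 1)")
        if not (0.90 <= self.sd_identity_range[0] <= self.sd_identity_range[1] <= 1.0):
            raise ValueError("sd identity range must lie in [0.90, 1.0]")


@dataclass
class SimGenome:
    seqs: dict[str, str]
    repeats: IntervalSet
    genes: IntervalSet  # gene + exon features (gff-style rows)
    targets: pd.DataFrame  # chrom, start, end, target_id, gene
    sd_truth: pd.DataFrame  # chrom_a, start_a, end_a, chrom_b, ..., identity, length

    def target_intervals(self) -> IntervalSet:
        return IntervalSet(self.targets.rename(columns={"target_id": "name"}))

    def sd_footprint(self) -> IntervalSet:
        rows = []
        for r in self.sd_truth.itertuples(index=False):
            rows.append((r.chrom_a, r.start_a, r.end_a))
            rows.append((r.chrom_b, r.start_b, r.end_b))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@dataclass
class SimPanelParams:
    n_samples: int = 200
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {"wild": 0.06, "landrace": 0.45, "cultivar": 0.49}
    )
    mean_depth: float = 40.0
    fragment_footprint: int = 200
    capture_efficiency_sd: float = 0.5  # log-scale sd of per-target efficiency
    low_capture_fraction: float = 0.15  # poorly captured targets (below-5x tail)
    low_capture_efficiency: float = 0.05
    library_size_sd: float = 0.2  # log-scale sd of per-sample factor
    overdispersion: float = 0.01  # Gamma-Poisson dispersion of counts
    n_cnv_sites: int = 150
    deletion_fraction: float = 0.79
    carrier_freq_beta: tuple[float, float] = (0.4, 4.0)
    group_private_fraction: float = 0.0
    private_carrier_beta: tuple[float, float] = (3.0, 1.5)
    wild_deletion_multiplier: float = 1.5
    sd_enrichment: float = 1.0  # beta: CNV placement weight ~ 1 + beta * SD fraction
    sd_window: int = 100_000
    min_targets_per_cnv: int = 3
    max_targets_per_cnv: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.deletion_fraction <= 1):
            raise ValueError("deletion_fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.sd_enrichment < 0:
            raise ValueError("sd_enrichment must be >= 0")


@dataclass
class PanelTruth:
    sites: pd.DataFrame  # planted CNV sites with carriers and detectability
    groups: pd.Series  # sample -> group
    capture_efficiency: np.ndarray  # e_j per target
    library_factors: np.ndarray  # s_k per sample
    copy_ratio: pd.DataFrame  # targets x samples c_jk


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

class _Layer:
    """Sorted non-overlapping intervals with O(log n) collision queries."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def append(self, iv: tuple[int, int]) -> None:
        i = bisect.bisect_left(self.starts, iv[0])
        self.starts.insert(i, iv[0])
        self.ends.insert(i, iv[1])

    def collides(self, start: int, end: int, pad: int) -> bool:
        i = bisect.bisect_left(self.starts, start)
        if i < len(self.starts) and self.starts[i] < end + pad:
            return True
        return i > 0 and self.ends[i - 1] + pad > start

    def __iter__(self):
        return iter(zip(self.starts, self.ends))

    def __len__(self) -> int:
        return len(self.starts)


class _Allocator:
    """Non-overlapping interval placement with rejection sampling."""

    def __init__(self, length: int, rng: np.random.Generator, pad: int = 20):
        self.length = length
        self.rng = rng
        self.pad = pad

    def _collides(self, start: int, end: int, layers) -> bool:
        return any(layer.collides(start, end, self.pad) for layer in layers)

    def place(
        self, length: int, avoid, max_tries: int = 300, terminal_bias: float = 0.0
    ) -> tuple[int, int]:
        """Place an interval; ``terminal_bias`` > 0 weights candidate
        positions towards the chromosome ends with density
        ``1 + bias * (2|x - L/2| / L)^2`` (rejection sampling)."""
        if length > self.length:
            raise SimulationError("feature longer than chromosome")
        for _ in range(max_tries):
            start = int(self.rng.integers(0, self.length - length + 1))
            if terminal_bias > 0:
                x = abs((start + length / 2) / self.length - 0.5) * 2
                if self.rng.random() >= (1 + terminal_bias * x * x) / (1 + terminal_bias):
                    continue
            if not self._collides(start, start + length, avoid):
                return start, start + length
        raise SimulationError("could not place feature; genome too crowded")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly round(rate * len) positions to different bases."""
    out = seq.copy()
    n_mut = int(round(rate * len(seq)))
    if n_mut == 0:
        return out
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = BASES[BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def simulate_genome(params: SimGenomeParams) -> SimGenome:
    """Generate the genome, its repeat/gene annotation and the SD truth.

    Placement order: SD pairs first (donor copied onto acceptor with the
    target substitution rate), then genes (a configurable fraction forced to
    overlap an SD copy), then repeat copies filling towards
    ``repeat_fraction`` per chromosome. Infeasible packing raises before
    anything is produced.
    """
    rng = np.random.default_rng(params.seed)
    L, C = params.chrom_length, params.n_chroms
    mean_sd = sum(params.sd_length_range) / 2
    mean_span = (
        sum(params.exons_per_gene_range) / 2 * sum(params.exon_length_range) / 2
        + (sum(params.exons_per_gene_range) / 2 - 1) * sum(params.intron_length_range) / 2
    )
    demand = (
        2 * params.n_sd_pairs * mean_sd
        + params.n_genes * mean_span
        + params.repeat_fraction * C * L
    )
    if demand > 0.85 * C * L:
        raise SimulationError(
            f"requested features (~{demand / 1e6:.1f} Mb) exceed 85% of the "
            f"{C * L / 1e6:.1f} Mb genome"
        )

    chrom_names = [f"chr{i + 1}" for i in range(C)]
    seqs = {c: _random_seq(rng, L, params.gc_content) for c in chrom_names}
    alloc = {c: _Allocator(L, rng) for c in chrom_names}
    sd_layer = {c: _Layer() for c in chrom_names}
    gene_layer = {c: _Layer() for c in chrom_names}
    repeat_layer = {c: _Layer() for c in chrom_names}

    # --- segmental duplications ------------------------------------------
    sd_rows = []
    for i in range(params.n_sd_pairs):
        sd_len = int(rng.integers(params.sd_length_range[0], params.sd_length_range[1] + 1))
        identity = float(rng.uniform(*params.sd_identity_range))
        ca = chrom_names[int(rng.integers(C))]
        cb = chrom_names[int(rng.integers(C))]
        sa, ea = alloc[ca].place(sd_len, [sd_layer[ca]], terminal_bias=params.sd_terminal_bias)
        sd_layer[ca].append((sa, ea))
        sb, eb = alloc[cb].place(sd_len, [sd_layer[cb]], terminal_bias=params.sd_terminal_bias)
        sd_layer[cb].append((sb, eb))
        donor = seqs[ca][sa:ea]
        seqs[cb][sb:eb] = _mutate(donor, 1.0 - identity, rng)
        realized = float(np.mean(seqs[ca][sa:ea] == seqs[cb][sb:eb]))
        sd_rows.append((ca, sa, ea, cb, sb, eb, 100.0 * realized, sd_len))
    sd_truth = pd.DataFrame(
        sd_rows,
        columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "identity", "length"],
    )

    # --- genes and exons ---------------------------------------------------
    gene_rows = []
    target_rows = []
    n_overlap = int(round(params.gene_sd_overlap_fraction * params.n_genes))
    all_sds = [(c, s, e) for c in chrom_names for (s, e) in sd_layer[c]]
    for gi in range(params.n_genes):
        n_ex = int(rng.integers(params.exons_per_gene_range[0], params.exons_per_gene_range[1] + 1))
        ex_lens = rng.integers(
            params.exon_length_range[0], params.exon_length_range[1] + 1, n_ex
        )
        in_lens = rng.integers(
            params.intron_length_range[0], params.intron_length_range[1] + 1, max(n_ex - 1, 0)
        )
        span = int(ex_lens.sum() + in_lens.sum())
        gene_id = f"g{gi:04d}"
        placed = False
        if gi < n_overlap and all_sds:
            for _ in range(60):  # aim the gene at a random SD copy
                c, s, e = all_sds[int(rng.integers(len(all_sds)))]
                lo = max(0, s - span + 1)
                hi = min(L - span, e - 1)
                if hi < lo:
                    continue
                gstart = int(rng.integers(lo, hi + 1))
                if not alloc[c]._collides(gstart, gstart + span, [gene_layer[c]]):
                    placed = True
                    break
        if not placed:
            # genes place independently of SDs: co-location happens by
            # chance; gene_sd_overlap_fraction only forces extra overlap
            for _ in range(60):
                c = chrom_names[int(rng.integers(C))]
                try:
                    gstart, _ = alloc[c].place(span, [gene_layer[c]])
                    placed = True
                    break
                except SimulationError:
                    continue
            if not placed:
                raise SimulationError(f"could not place gene {gene_id}")
        gene_layer[c].append((gstart, gstart + span))
        gene_rows.append((c, gstart, gstart + span, gene_id, "+", "gene", None))
        pos = gstart
        for ei in range(n_ex):
            ex_end = pos + int(ex_lens[ei])
            gene_rows.append(
                (c, pos, ex_end, f"{gene_id}.e{ei + 1}", "+", "exon", gene_id)
            )
            target_rows.append((c, pos, ex_end, f"{gene_id}.e{ei + 1}", gene_id))
            pos = ex_end + (int(in_lens[ei]) if ei < n_ex - 1 else 0)

    genes = IntervalSet(
        pd.DataFrame(
            gene_rows,
            columns=["chrom", "start", "end", "name", "strand", "type", "parent"],
        )
    )
    targets = (
        pd.DataFrame(target_rows, columns=["chrom", "start", "end", "target_id", "gene"])
        .sort_values(["chrom", "start", "end"])
        .reset_index(drop=True)
    )

    # --- repeats -----------------------------------------------------------
    motif_lens = rng.integers(200, 2001, 12)
    motifs = [_random_seq(rng, int(m), params.gc_content) for m in motif_lens]
    repeat_rows = []
    for c in chrom_names:
        budget = int(params.repeat_fraction * L)
        placed_bp = 0
        failures = 0
        while placed_bp < budget and failures < 200:
            motif = motifs[int(rng.integers(len(motifs)))]
            rl = len(motif)
            try:
                s, e = alloc[c].place(
                    rl, [sd_layer[c], gene_layer[c], repeat_layer[c]], max_tries=30
                )
            except SimulationError:
                failures += 1
                continue
            seqs[c][s:e] = motif
            repeat_layer[c].append((s, e))
            repeat_rows.append((c, s, e))
            placed_bp += rl
        if placed_bp < 0.8 * budget:
            logger.warning(
                "repeat placement on %s reached only %.0f%% of the requested fraction",
                c, 100 * placed_bp / max(budget, 1),
            )
    repeats = IntervalSet(pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"]))

    return SimGenome(
        seqs={c: "".join(seqs[c]) for c in chrom_names},
        repeats=repeats.normalize(),
        genes=genes,
        targets=targets,
        sd_truth=sd_truth,
    )


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def _sample_names(params: SimPanelParams) -> tuple[list[str], pd.Series]:
    groups = list(params.group_proportions)
    raw = np.array([params.group_proportions[g] for g in groups], dtype=float)
    counts = np.floor(raw / raw.sum() * params.n_samples).astype(int)
    while counts.sum() < params.n_samples:  # largest remainder
        frac = raw / raw.sum() * params.n_samples - counts
        counts[int(np.argmax(frac))] += 1
    names, labels = [], []
    for g, n in zip(groups, counts):
        for i in range(n):
            names.append(f"{g}_{i:03d}")
            labels.append(g)
    return names, pd.Series(labels, index=names, name="group")


def _sd_weight(targets: pd.DataFrame, sd_footprint: IntervalSet, window: int) -> np.ndarray:
    """Fraction of a window centred on each target covered by SD bases."""
    from .intervals import merge_intervals

    merged = merge_intervals(sd_footprint).by_chrom()
    mids = ((targets["start"] + targets["end"]) // 2).to_numpy(np.int64)
    chroms = targets["chrom"].to_numpy()
    frac = np.zeros(len(targets))
    half = window // 2
    for chrom, (s, e) in merged.items():
        sel = np.flatnonzero(chroms == chrom)
        if not len(sel):
            continue
        lo = mids[sel] - half
        hi = mids[sel] + half
        cum = np.concatenate([[0], np.cumsum(e - s)])
        # SD bp within [lo, hi): clip each SD interval into the window
        for out_i, (a, b) in zip(sel, zip(lo, hi)):
            i0 = np.searchsorted(e, a, side="right")
            i1 = np.searchsorted(s, b, side="left")
            if i1 > i0:
                bp = (np.minimum(e[i0:i1], b) - np.maximum(s[i0:i1], a)).sum()
                frac[out_i] = bp / window
    return frac


def simulate_panel_counts(
    genome: SimGenome, params: SimPanelParams
) -> tuple[CountMatrix, PanelTruth]:
    """Plant CNV sites on the capture targets and draw the count matrix.

    Expected count for sample k at target j is
    ``lambda_jk = s_k e_j len_j c_jk / Z`` with library factor s_k,
    log-normal capture efficiency e_j, planted copy ratio c_jk in
    {0.5, 1, 1.5} and Z normalizing the panel-mean per-base depth to
    ``mean_depth``. Counts are Gamma-Poisson with dispersion
    ``overdispersion``. Site start positions are drawn with probability
    weight ``1 + sd_enrichment * (SD bp in a 100-kb window) / window``.
    """
    rng = np.random.default_rng(params.seed)
    targets = genome.targets.reset_index(drop=True)
    n_t = len(targets)
    names, groups = _sample_names(params)
    n_s = len(names)
    lens = (targets["end"] - targets["start"]).to_numpy(np.int64)

    # --- choose CNV sites --------------------------------------------------
    chroms = targets["chrom"].to_numpy()
    weight = 1.0 + params.sd_enrichment * _sd_weight(
        targets, genome.sd_footprint(), params.sd_window
    )
    c_matrix = np.ones((n_t, n_s))
    used = np.zeros(n_t, dtype=bool)
    site_rows = []
    group_names = list(params.group_proportions)
    max_site = params.max_targets_per_cnv
    feasible_starts = np.array(
        [
            j
            for j in range(n_t)
            if j + params.min_targets_per_cnv <= n_t
            and chroms[j] == chroms[min(j + params.min_targets_per_cnv - 1, n_t - 1)]
        ]
    )
    if params.n_cnv_sites and not len(feasible_starts):
        raise SimulationError("no feasible CNV site start positions")
    attempts = 0
    sid = 0
    while sid < params.n_cnv_sites and attempts < params.n_cnv_sites * 60:
        attempts += 1
        w = weight[feasible_starts].copy()
        w[used[feasible_starts]] = 0.0
        if w.sum() == 0:
            break
        j0 = int(rng.choice(feasible_starts, p=w / w.sum()))
        size = int(rng.integers(params.min_targets_per_cnv, max_site + 1))
        j1 = j0
        while (
            j1 + 1 < n_t
            and j1 + 1 - j0 < size
            and chroms[j1 + 1] == chroms[j0]
            and not used[j1 + 1]
        ):
            j1 += 1
        if j1 - j0 + 1 < params.min_targets_per_cnv or used[j0:j1 + 1].any():
            continue
        is_del = rng.random() < params.deletion_fraction
        ctype, ratio = ("DEL", 0.5) if is_del else ("DUP", 1.5)
        private_group = None
        if rng.random() < params.group_private_fraction:
            private_group = group_names[int(rng.integers(len(group_names)))]
            f = float(rng.beta(*params.private_carrier_beta))
            pool = [s for s in names if groups[s] == private_group]
            carry = np.array([rng.random() < f for s in pool])
            carriers = [s for s, c in zip(pool, carry) if c]
        else:
            f = float(rng.beta(*params.carrier_freq_beta))
            probs = np.full(n_s, min(f, 1.0))
            if ctype == "DEL" and params.wild_deletion_multiplier != 1.0:
                wild_mask = (groups.to_numpy() == "wild")
                probs[wild_mask] = np.minimum(f * params.wild_deletion_multiplier, 1.0)
            carry = rng.random(n_s) < probs
            carriers = [names[i] for i in np.flatnonzero(carry)]
        if not carriers:
            pool = (
                [s for s in names if groups[s] == private_group]
                if private_group
                else names
            )
            carriers = [pool[int(rng.integers(len(pool)))]]
        used[j0:j1 + 1] = True
        cidx = [names.index(s) for s in carriers]
        c_matrix[np.ix_(range(j0, j1 + 1), cidx)] = ratio
        site_rows.append(
            (
                sid,
                chroms[j0],
                int(targets["start"].iloc[j0]),
                int(targets["end"].iloc[j1]),
                ctype,
                ratio,
                j1 - j0 + 1,
                ",".join(targets["target_id"].iloc[j0:j1 + 1]),
                ",".join(sorted(carriers)),
                len(carriers),
                len(carriers) >= 3,
                private_group or "",
            )
        )
        sid += 1
    if sid < params.n_cnv_sites:
        logger.warning("placed %d of %d requested CNV sites", sid, params.n_cnv_sites)
    sites = pd.DataFrame(
        site_rows,
        columns=[
            "site_id", "chrom", "start", "end", "type", "copy_ratio", "n_targets",
            "target_ids", "carriers", "n_carriers", "detectable", "private_group",
        ],
    )

    # --- draw counts --------------------------------------------------------
    e_j = rng.lognormal(0.0, params.capture_efficiency_sd, n_t)
    low = rng.random(n_t) < params.low_capture_fraction
    e_j[low] *= params.low_capture_efficiency  # poorly captured tail (< 5x)
    s_k = rng.lognormal(0.0, params.library_size_sd, n_s)
    # fragment counting includes one footprint of capture flank: a fragment
    # whose midpoint falls within ~footprint/2 of either edge still overlaps
    # the target, so the effective counted length is len + footprint
    eff_len = lens + params.fragment_footprint
    z = params.fragment_footprint * float(np.mean(np.outer(e_j, s_k))) / params.mean_depth
    lam = (e_j * eff_len)[:, None] * s_k[None, :] * c_matrix / z
    if params.overdispersion > 0:
        shape = 1.0 / params.overdispersion
        g = rng.gamma(shape, 1.0 / shape, size=lam.shape)
        lam = lam * g
    counts = rng.poisson(lam)
    depth = counts * params.fragment_footprint / eff_len[:, None]
    if not (depth.mean(axis=1) >= 5).any():
        logger.warning("no target reaches 5x mean depth; mean_depth too low?")

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(targets["target_id"], name="target_id"), columns=names),
        targets.copy(),
    )
    truth = PanelTruth(
        sites=sites,
        groups=groups,
        capture_efficiency=e_j,
        library_factors=s_k,
        copy_ratio=pd.DataFrame(
            c_matrix, index=targets["target_id"], columns=names
        ),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_simulation(
    genome: SimGenome,
    outdir: str | Path,
    cm: CountMatrix | None = None,
    truth: PanelTruth | None = None,
) -> None:
    """Write genome.fa, repeats.bed, genes.gff3, targets.bed, truth_sd.tsv
    and, when a panel was simulated, counts.tsv / truth_cnv.tsv /
    samples.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.seqs, outdir / "genome.fa")
    write_bed(genome.repeats, outdir / "repeats.bed")
    write_gff3(genome.genes, outdir / "genes.gff3")
    write_bed(
        IntervalSet(genome.targets.rename(columns={"target_id": "name"})),
        outdir / "targets.bed",
    )
    genome.sd_truth.to_csv(outdir / "truth_sd.tsv", sep="\t", index=False)
    if cm is not None:
        from .io import write_count_matrix

        write_count_matrix(cm, outdir / "counts.tsv", outdir / "targets.bed")
    if truth is not None:
        truth.sites.to_csv(outdir / "truth_cnv.tsv", sep="\t", index=False)
        truth.groups.rename_axis("sample").reset_index().to_csv(
            outdir / "samples.tsv", sep="\t", index=False
        )
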