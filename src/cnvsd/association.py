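"""Permutation tests and binned rank-correlation profiles for interval
association.

The null model randomizes one feature set over the non-masked space of each
chromosome (features keep their chromosome and length; placements are
uniform over all valid start positions and may overlap each other), and the
observed overlap count or mean closest distance is compared with the
permutation null.  The SD-CNV co-occurrence profile bins chromosomes at a
ladder of bin sizes (40 kb to 2 Mb) and reports the Spearman rank
correlation between per-bin SD and CNV counts at each size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    IntervalSet,
    _overlap_mask,
    closest_distances,
    merge_intervals,
    overlap_count,
)

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZES = (40_000, 80_000, 160_000, 320_000, 640_000, 1_000_000, 1_500_000, 2_000_000)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    z_score: float | None
    alternative: str

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null))

    @property
    def null_low(self) -> float:
        """Most extreme null value on the non-rejecting side (Figure-8-style
        lower/upper bound of the expected statistic)."""
        return float(np.min(self.null))

    @property
    def null_high(self) -> float:
        return float(np.max(self.null))


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------

def randomize_intervals(
    features: IntervalSet,
    placement_space: IntervalSet,
    rng: np.random.Generator | int | None = None,
) -> IntervalSet:
    """Place each feature uniformly at random inside its chromosome's
    non-masked space.

    Each feature keeps its chromosome and length. Valid start positions are
    all offsets at which the feature fits entirely inside one placement
    interval, weighted by the number of such slots per interval; features
    may overlap each other after placement. A feature longer than every
    placement interval on its chromosome is an error.
    """
    rng = np.random.default_rng(rng)
    space = merge_intervals(placement_space).by_chrom()
    out_chrom: list[str] = []
    out_start: list[np.ndarray] = []
    out_len: list[np.ndarray] = []
    for chrom, sub in features.df.groupby("chrom", sort=True):
        if chrom not in space:
            raise ValueError(f"no placement space on chromosome {chrom}")
        p_s, p_e = space[chrom]
        p_len = p_e - p_s
        lens = (sub["end"] - sub["start"]).to_numpy(np.int64)
        slots = np.maximum(p_len[None, :] - lens[:, None] + 1, 0)  # feat x space
        total = slots.sum(axis=1)
        if (total == 0).any():
            i = int(np.flatnonzero(total == 0)[0])
            raise ValueError(
                f"feature of length {int(lens[i])} on {chrom} does not fit in "
                "any placement interval"
            )
        cum = np.cumsum(slots, axis=1)
        u = np.floor(rng.random(len(lens)) * total).astype(np.int64)
        u = np.minimum(u, total - 1)
        idx = (u[:, None] >= cum).sum(axis=1)
        before = np.where(idx > 0, np.take_along_axis(cum, np.maximum(idx - 1, 0)[:, None], 1)[:, 0], 0)
        starts = p_s[idx] + (u - before)
        out_chrom.extend([chrom] * len(lens))
        out_start.append(starts)
        out_len.append(lens)
    if not out_chrom:
        return IntervalSet()
    starts = np.concatenate(out_start)
    lens = np.concatenate(out_len)
    return IntervalSet.from_arrays(out_chrom, starts, starts + lens)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _statistic(a: IntervalSet, b: IntervalSet, statistic: str) -> float:
    if statistic == "overlap_count":
        return float(overlap_count(a, b))
    if statistic == "mean_closest_distance":
        d = closest_distances(a, b)
        return float(np.mean(d)) if len(d) else float("nan")
    raise ValueError(f"unknown statistic {statistic!r}")


class _PermEngine:
    """Precomputed state for fast repeated randomization of one feature set.

    Holds the merged placement space, per-chromosome feature lengths and
    slot cumulative sums, and the merged fixed set b, so one permutation is
    a handful of vectorized array operations.
    """

    def __init__(self, a: IntervalSet, b: IntervalSet, placement_space: IntervalSet):
        self.space = merge_intervals(placement_space).by_chrom()
        self.b = merge_intervals(b).by_chrom()
        self.chroms: list[str] = []
        self.lens: dict[str, np.ndarray] = {}
        self.slots: dict[str, np.ndarray] = {}
        self.cum: dict[str, np.ndarray] = {}
        self.totals: dict[str, np.ndarray] = {}
        for chrom, sub in a.df.groupby("chrom", sort=True):
            if chrom not in self.space:
                raise ValueError(f"no placement space on chromosome {chrom}")
            p_s, p_e = self.space[chrom]
            lens = (sub["end"] - sub["start"]).to_numpy(np.int64)
            slots = np.maximum((p_e - p_s)[None, :] - lens[:, None] + 1, 0)
            total = slots.sum(axis=1)
            if (total == 0).any():
                i = int(np.flatnonzero(total == 0)[0])
                raise ValueError(
                    f"feature of length {int(lens[i])} on {chrom} does not "
                    "fit in any placement interval"
                )
            self.chroms.append(str(chrom))
            self.lens[str(chrom)] = lens
            self.slots[str(chrom)] = slots
            self.cum[str(chrom)] = np.cumsum(slots, axis=1)
            self.totals[str(chrom)] = total

    def place(self, rng: np.random.Generator) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom in self.chroms:
            p_s, _ = self.space[chrom]
            total, cum = self.totals[chrom], self.cum[chrom]
            u = np.minimum(
                np.floor(rng.random(len(total)) * total).astype(np.int64), total - 1
            )
            idx = (u[:, None] >= cum).sum(axis=1)
            before = np.where(
                idx > 0,
                np.take_along_axis(cum, np.maximum(idx - 1, 0)[:, None], 1)[:, 0],
                0,
            )
            starts = p_s[idx] + (u - before)
            out[chrom] = (starts, starts + self.lens[chrom])
        return out

    def statistic(self, placed: dict[str, tuple[np.ndarray, np.ndarray]], statistic: str) -> float:
        if statistic == "overlap_count":
            n = 0
            for chrom, (s, e) in placed.items():
                if chrom in self.b:
                    b_s, b_e = self.b[chrom]
                    order = np.argsort(s, kind="stable")
                    n += int(_overlap_mask(s[order], e[order], b_s, b_e).sum())
            return float(n)
        dists = []
        for chrom, (s, e) in placed.items():
            if chrom not in self.b:
                continue
            b_s, b_e = self.b[chrom]
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
            idx = np.searchsorted(b_s, s)
            big = np.iinfo(np.int64).max
            right = np.where(idx < len(b_s), b_s[np.minimum(idx, len(b_s) - 1)] - e, big)
            left = np.where(idx > 0, s - b_e[np.maximum(idx - 1, 0)], big)
            d = np.minimum(np.maximum(right, 0), np.maximum(left, 0))
            d[_overlap_mask(s, e, b_s, b_e)] = 0
            dists.append(d)
        if not dists:
            return float("nan")
        return float(np.mean(np.concatenate(dists)))


def permutation_test(
    a: IntervalSet,
    b: IntervalSet,
    placement_space: IntervalSet,
    statistic: str = "overlap_count",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Observed statistic of (a, b) against the null of random placement of a.

    b stays fixed; a is randomized ``n_permutations`` times over the
    non-masked space. The empirical p uses the add-one rule
    ``(1 + #{null as-or-more-extreme}) / (n + 1)`` so it is never 0. The
    direction is 'greater' for overlap enrichment and 'less' for distance
    (features closer than expected). ``z = (obs - mean) / sd`` is reported
    as None when the null is degenerate (sd = 0).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    alternative = "greater" if statistic == "overlap_count" else "less"
    observed = _statistic(a, b, statistic)
    engine = _PermEngine(a, b, placement_space)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = engine.statistic(engine.place(rng), statistic)
    if alternative == "greater":
        extreme = int(np.sum(null >= observed))
    else:
        extreme = int(np.sum(null <= observed))
    p = (1 + extreme) / (n_permutations + 1)
    sd = float(np.std(null))
    z = (observed - float(np.mean(null))) / sd if sd > 0 else None
    if z is None:
        logger.info("degenerate permutation null (sd = 0); z undefined")
    return PermutationResult(observed, null, p, z, alternative)


# ---------------------------------------------------------------------------
# binned densities and the Spearman profile
# ---------------------------------------------------------------------------

def binned_density(
    features: IntervalSet,
    bin_size: int,
    chrom_lengths: dict[str, int],
) -> dict[str, np.ndarray]:
    """Per-chromosome counts of feature midpoints in tiling bins from 0.

    The midpoint rule counts each feature exactly once, so bin counts sum
    to the feature count.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out = {}
    feats = features.by_chrom()
    for chrom, glen in sorted(chrom_lengths.items()):
        nbin = max(int(np.ceil(glen / bin_size)), 1)
        counts = np.zeros(nbin, dtype=np.int64)
        if chrom in feats:
            s, e = feats[chrom]
            mids = (s + e) // 2
            idx = np.minimum(mids // bin_size, nbin - 1)
            np.add.at(counts, idx, 1)
        out[chrom] = counts
    return out


def spearman_rho(x, y) -> tuple[float, float]:
    """Tie-corrected (average-rank) Spearman correlation with the two-sided
    t-approximation p-value (n - 2 df). Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need two equal-length vectors of length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def sd_cnv_profile(
    sd_features: IntervalSet,
    cnv_features: IntervalSet,
    chrom_lengths: dict[str, int],
    bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Spearman rho between per-bin SD and CNV counts as a function of bin
    size, pooling bins over chromosomes; the ``significant`` mask marks bin
    sizes with p < alpha."""
    rows = []
    for bs in bin_sizes:
        sd_bins = binned_density(sd_features, bs, chrom_lengths)
        cnv_bins = binned_density(cnv_features, bs, chrom_lengths)
        x = np.concatenate([sd_bins[c] for c in sorted(chrom_lengths)])
        y = np.concatenate([cnv_bins[c] for c in sorted(chrom_lengths)])
        if len(x) < 4:
            raise ValueError(f"fewer than 4 bins at bin size {bs}")
        rho, p = spearman_rho(x, y)
        rows.append((bs, rho, p, len(x), bool(p < alpha) if np.isfinite(p) else False))
    return pd.DataFrame(rows, columns=["bin_size", "rho", "p", "n_bins", "significant"])
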