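"""Panel-level CNV post-processing.

Per-sample calls are collapsed into panel-level CNV sites (same-type calls
linked by any overlap), rare sites (< 3 carrier accessions by default) are
discarded, and the module derives the descriptive statistics the analysis
reports: per-chromosome deletion/duplication densities over the captured
sequence, pairwise exact Poisson rate comparisons between chromosomes,
group-wise density summaries with bootstrap intervals, and the carrier
frequency spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet, merge_intervals

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["sample", "chrom", "start", "end", "type", "n_targets", "confidence"]
SITE_COLUMNS = ["site_id", "chrom", "start", "end", "type", "n_carriers", "frequency", "carriers"]


def _as_call_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls.reset_index(drop=True)
    return pd.DataFrame([vars(c) for c in calls], columns=CALL_COLUMNS)


# ---------------------------------------------------------------------------
# site collapsing and the >= 3 accession filter
# ---------------------------------------------------------------------------

def collapse_to_sites(
    calls, panel_size: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Single-linkage collapse of same-type overlapping calls into CNV sites.

    Calls of the same type whose intervals share >= 1 bp belong to one site;
    the site interval is the union footprint of its calls and its frequency
    is distinct carriers / panel size x 100. DEL and DUP sites may coexist
    at the same locus as distinct sites. Returns the site table and the
    per-call site-id assignment (aligned with the call order given).
    """
    df = _as_call_frame(calls)
    site_ids = np.full(len(df), -1, dtype=np.int64)
    sites = []
    next_id = 0
    for (chrom, ctype), sub in df.groupby(["chrom", "type"], sort=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        cur_end = None
        cur_calls: list[int] = []
        for row in sub.itertuples():
            if cur_end is None or row.start >= cur_end:  # touching does not link
                if cur_calls:
                    sites.append((next_id, chrom, ctype, cur_calls))
                    next_id += 1
                cur_calls = [row.Index]
                cur_end = row.end
            else:
                cur_calls.append(row.Index)
                cur_end = max(cur_end, row.end)
        if cur_calls:
            sites.append((next_id, chrom, ctype, cur_calls))
            next_id += 1
    rows = []
    for sid, chrom, ctype, members in sites:
        site_ids[members] = sid
        sub = df.loc[members]
        carriers = sorted(set(sub["sample"]))
        rows.append(
            (
                sid,
                chrom,
                int(sub["start"].min()),
                int(sub["end"].max()),
                ctype,
                len(carriers),
                100.0 * len(carriers) / panel_size,
                ",".join(carriers),
            )
        )
    site_df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if len(site_df):
        if int(site_df["n_carriers"].max()) > panel_size:
            raise ValueError("panel_size smaller than a site's carrier count")
        site_df = site_df.sort_values(["chrom", "start", "type"]).reset_index(drop=True)
    return site_df, site_ids


def filter_rare_calls(
    calls, panel_size: int, min_accessions: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard calls whose CNV site has fewer than ``min_accessions``
    distinct carriers; returns (surviving calls, surviving sites)."""
    df = _as_call_frame(calls)
    sites, site_ids = collapse_to_sites(df, panel_size)
    if not len(sites):
        return df, sites
    ok_sites = set(sites.loc[sites["n_carriers"] >= min_accessions, "site_id"])
    keep = np.array([sid in ok_sites for sid in site_ids])
    kept_calls = df.loc[keep].reset_index(drop=True)
    kept_sites = sites[sites["site_id"].isin(ok_sites)].reset_index(drop=True)
    return kept_calls, kept_sites


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def panel_stats(calls, sites: pd.DataFrame, panel_size: int, n_targets: int | None = None) -> dict:
    """Headline panel numbers: totals, mean calls per sample, affected-target
    fraction (when the target count is supplied)."""
    df = _as_call_frame(calls)
    out = {
        "total_calls": len(df),
        "total_sites": len(sites),
        "panel_size": panel_size,
        "mean_calls_per_sample": (len(df) / panel_size) if panel_size else 0.0,
        "mean_calls_per_sample_display": int(round(len(df) / panel_size)) if panel_size else 0,
    }
    if n_targets:
        affected = df["n_targets"].sum()
        out["fraction_targets_affected"] = float(min(affected / n_targets, 1.0))
    return out


def captured_length_per_chrom(targets: IntervalSet) -> pd.Series:
    """Mb of merged capture-target sequence per chromosome."""
    merged = merge_intervals(targets)
    lengths = merged.df.assign(length=lambda d: d["end"] - d["start"])
    mb = lengths.groupby("chrom")["length"].sum() / 1e6
    return mb


def density_table(sites: pd.DataFrame, captured_mb: pd.Series) -> pd.DataFrame:
    """Per-chromosome deletion/duplication counts, densities per Mb of
    captured sequence, and the deletion/duplication ratio.

    The totals row is computed from summed counts over summed lengths.
    """
    if (captured_mb <= 0).any():
        bad = captured_mb.index[captured_mb <= 0][0]
        raise ValueError(f"zero captured length on chromosome {bad}")
    rows = []
    chroms = sorted(captured_mb.index)
    for chrom in chroms:
        sub = sites[sites["chrom"] == chrom] if len(sites) else sites
        n_del = int((sub["type"] == "DEL").sum()) if len(sub) else 0
        n_dup = int((sub["type"] == "DUP").sum()) if len(sub) else 0
        mb = float(captured_mb[chrom])
        rows.append((chrom, n_del, n_dup, mb))
    tot_del = sum(r[1] for r in rows)
    tot_dup = sum(r[2] for r in rows)
    tot_mb = sum(r[3] for r in rows)
    rows.append(("all", tot_del, tot_dup, tot_mb))
    df = pd.DataFrame(rows, columns=["chrom", "n_del", "n_dup", "captured_mb"])
    df["del_density"] = df["n_del"] / df["captured_mb"]
    df["dup_density"] = df["n_dup"] / df["captured_mb"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["del_dup_ratio"] = np.where(
            df["n_dup"] > 0, df["n_del"] / df["n_dup"], np.nan
        )
    return df


def exact_poisson_two_sample(
    k1: int, k2: int, e1: float, e2: float
) -> float:
    """Exact conditional two-sample Poisson rate test.

    Conditional on the summed count, ``k1 ~ Binomial(k1 + k2, e1/(e1+e2))``
    under equal rates; the two-sided p sums outcomes whose probability does
    not exceed the observed one (the "minlike" convention). Symmetric in
    argument exchange and invariant to common exposure scaling.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    if e1 <= 0 or e2 <= 0:
        raise ValueError("exposures must be positive")
    n = k1 + k2
    if n == 0:
        return 1.0
    return float(binomtest(k1, n, e1 / (e1 + e2), alternative="two-sided").pvalue)


def pairwise_poisson_tests(
    counts: pd.Series, exposures: pd.Series, adjust: str | None = "holm"
) -> pd.DataFrame:
    """All chromosome-pair exact Poisson rate comparisons.

    Returns a long table (chrom_a, chrom_b, p, p_adj); adjustment is applied
    across all pairs (default Holm, ``adjust=None`` for raw p only).
    """
    chroms = list(counts.index)
    rows = []
    for i, a in enumerate(chroms):
        for b in chroms[i + 1 :]:
            p = exact_poisson_two_sample(
                int(counts[a]), int(counts[b]), float(exposures[a]), float(exposures[b])
            )
            rows.append((a, b, p))
    df = pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "p"])
    if adjust and len(df):
        df["p_adj"] = np.minimum(multipletests(df["p"], method=adjust)[1], 1.0)
    return df


def group_density(
    calls,
    groups: pd.Series,
    captured_mb: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-wise mean per-sample CNV density with bootstrap intervals.

    ``groups`` maps sample -> group label; every sample must be assigned.
    Densities are per-sample per-chromosome counts / captured Mb; the group
    summary is the mean over samples with a percentile bootstrap (resampling
    samples) 95% interval. An 'all' pseudo-group covers the whole panel.
    """
    df = _as_call_frame(calls)
    unknown = set(df["sample"]) - set(groups.index)
    if unknown:
        raise ValueError(f"samples without group label: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)
    chroms = sorted(captured_mb.index)
    rows = []
    group_map = {"all": list(groups.index)}
    for g in sorted(groups.unique()):
        group_map[g] = list(groups.index[groups == g])
    for g, members in group_map.items():
        if not members:
            logger.warning("empty group %s excluded", g)
            continue
        for ctype in ("DEL", "DUP"):
            for chrom in chroms:
                sub = df[(df["type"] == ctype) & (df["chrom"] == chrom)]
                per_sample = sub.groupby("sample").size()
                dens = np.array(
                    [per_sample.get(s, 0) / captured_mb[chrom] for s in members]
                )
                boots = np.array(
                    [
                        dens[rng.integers(0, len(dens), len(dens))].mean()
                        for _ in range(n_boot)
                    ]
                )
                rows.append(
                    (
                        g,
                        ctype,
                        chrom,
                        float(dens.mean()),
                        float(np.percentile(boots, 2.5)),
                        float(np.percentile(boots, 97.5)),
                        len(members),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["group", "type", "chrom", "mean_density", "ci_low", "ci_high", "n_samples"],
    )


def frequency_spectrum(sites: pd.DataFrame) -> pd.DataFrame:
    """Carrier-frequency spectrum rows (chrom, midpoint, type, frequency%)."""
    if not len(sites):
        return pd.DataFrame(columns=["chrom", "midpoint", "type", "frequency"])
    out = sites.assign(midpoint=(sites["start"] + sites["end"]) // 2)[
        ["chrom", "midpoint", "type", "frequency"]
    ]
    return out.reset_index(drop=True)
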