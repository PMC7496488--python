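"""Read-count CNV detection for exome-capture panels.

The detector follows the classical optimized-reference read-ratio design:
for each test sample an aggregate reference is assembled from the most
correlated panel members, the test count at each capture target is modelled
as beta-binomial against ``n_j = x_j + r_j`` trials, and a 3-state HMM
(deletion / diploid / duplication, copy ratios 0.5 / 1 / 1.5) is decoded by
Viterbi.  Maximal runs of a non-diploid state become per-sample CNV calls —
this is where contiguous duplicated or deleted exons are merged into one
event.

The model cannot quantify integer copy number: states are categorical
"fewer reads than expected" (DEL) and "more reads than expected" (DUP).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln

from .io import CountMatrix

logger = logging.getLogger(__name__)

DEL, DIP, DUP = 0, 1, 2
STATE_NAMES = {DEL: "DEL", DIP: "DIP", DUP: "DUP"}


@dataclass
class CallerParams:
    """Tuning knobs of the CNV caller.

    ``expected_cnv_length`` is the expected genomic extent of a CNV event in
    bp: the probability of remaining inside a CNV state decays with the
    inter-target distance d as exp(-d/L), so runs of nearby exons are glued
    into single events while distant exons are not.
    """

    min_mean_coverage: float = 5.0
    fragment_footprint: int = 200  # bp of genome covered per counted fragment
    transition_prob: float = 1e-4
    expected_cnv_length: float = 1000.0
    copy_ratios: tuple[float, float, float] = (0.5, 1.0, 1.5)
    overdispersion: float | None = None  # estimated per sample when None
    max_reference_size: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.transition_prob < 0.5):
            raise ValueError("transition_prob must be in (0, 1/2)")
        if self.expected_cnv_length <= 0:
            raise ValueError("expected_cnv_length must be positive")
        if self.overdispersion is not None and self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


@dataclass
class ReferenceSet:
    """The aggregated reference chosen for one test sample."""

    test_sample: str
    reference_samples: list[str]
    aggregate_counts: np.ndarray  # r_j, summed over chosen samples

    def __post_init__(self) -> None:
        if self.test_sample in self.reference_samples:
            raise ValueError("test sample cannot be its own reference")


@dataclass
class CnvCall:
    sample: str
    chrom: str
    start: int
    end: int
    type: str  # DEL or DUP
    n_targets: int
    confidence: float  # summed log-likelihood ratio vs the diploid state


@dataclass
class TargetStatePath:
    """Viterbi decoding for one sample over the filtered targets."""

    target_ids: list[str]
    states: np.ndarray  # int in {DEL, DIP, DUP}
    loglik: np.ndarray  # (n_targets, 3) per-state emission log-likelihoods


# ---------------------------------------------------------------------------
# beta-binomial emission model
# ---------------------------------------------------------------------------

def betabin_loglik(x, n, p, phi) -> np.ndarray | float:
    """Log pmf of the beta-binomial with mean ``p`` and intra-class
    correlation ``phi``.

    Parameterization: a Beta(a, b) success probability with ``a = p(1-phi)/phi``
    and ``b = (1-p)(1-phi)/phi``, so the count variance is
    ``n p (1-p) (1 + (n-1) phi)``. The continuous limit ``phi -> 0`` is the
    binomial log pmf, returned exactly when ``phi == 0``.
    """
    x = np.asarray(x, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("require 0 <= x <= n")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("require p in (0, 1)")
    if phi < 0 or phi >= 1:
        raise ValueError("require 0 <= phi < 1")
    choose = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    if phi == 0:
        out = choose + x * np.log(p) + (n - x) * np.log1p(-p)
    else:
        a = p * (1 - phi) / phi
        b = (1 - p) * (1 - phi) / phi
        out = choose + betaln(x + a, n - x + b) - betaln(a, b)
    return out if out.shape else float(out)


def estimate_overdispersion(
    x: np.ndarray, n: np.ndarray, p: float | None = None, trim: float = 0.02
) -> float:
    """Maximum-likelihood intra-class correlation of test-vs-reference counts.

    ``x`` are test counts, ``n = x + r`` total trials across targets; the
    diploid proportion ``p`` defaults to the smoothed pooled ratio. The
    targets with the most extreme ``trim`` fraction of standardized
    residuals on each side are excluded so that the sample's own CNVs do
    not inflate the dispersion of its diploid background. 1-D bounded
    optimization; a boundary solution is returned with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    keep = n > 0
    x, n = x[keep], n[keep]
    if len(x) < 10:
        raise ValueError("need >= 10 informative targets to estimate overdispersion")
    if p is None:
        p = float((x.sum() + 1) / (n.sum() + 2))
    if trim > 0 and len(x) >= 50:
        resid = (x / n - p) * np.sqrt(n)
        lo_q, hi_q = np.quantile(resid, [trim, 1.0 - trim])
        central = (resid >= lo_q) & (resid <= hi_q)
        x, n = x[central], n[central]
    lo, hi = 1e-8, 0.5

    def nll(phi: float) -> float:
        return -float(np.sum(betabin_loglik(x, n, p, phi)))

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    phi = float(res.x)
    if phi <= lo * 2 and nll(0.0) <= nll(phi):
        return 0.0
    if phi >= hi - 1e-6:
        logger.warning("overdispersion estimate hit the upper bound %.2f", hi)
        return hi
    return phi


def _moment_phi(x: np.ndarray, n: np.ndarray, p: float) -> float:
    """Cheap method-of-moments phi used inside reference-set search."""
    keep = n > 0
    x, n = x[keep], n[keep]
    if len(x) < 2 or not (0 < p < 1):
        return 0.0
    y = x / n
    s2 = float(np.mean((y - p) ** 2))
    m1 = float(np.mean(1.0 / n))
    denom = 1.0 - m1
    if denom <= 0:
        return 0.0
    phi = (s2 / (p * (1 - p)) - m1) / denom
    return float(min(max(phi, 0.0), 0.5))


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------

def filter_low_coverage_targets(
    cm: CountMatrix,
    min_mean_coverage: float = 5.0,
    fragment_footprint: int = 200,
) -> CountMatrix:
    """Drop capture targets whose panel-mean per-base depth is below threshold.

    Depth at target j is ``mean fragment count x footprint / target length``;
    below ~5x, capture bias cannot be told apart from real copy change, so
    those targets are removed before calling. The removal tally is logged.
    """
    lengths = cm.target_lengths().astype(np.float64)
    mean_counts = cm.counts.to_numpy(np.float64).mean(axis=1)
    depth = mean_counts * fragment_footprint / lengths
    keep = depth >= min_mean_coverage
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "coverage filter: removed %d/%d targets (%d bp) below %.1fx",
            removed, len(keep), int(lengths[~keep].sum()), min_mean_coverage,
        )
    if not keep.any():
        raise ValueError(
            "coverage filter removed every target; check sequencing depth"
        )
    return cm.subset_targets(keep)


# ---------------------------------------------------------------------------
# reference-set optimization
# ---------------------------------------------------------------------------

def _power_proxy(x: np.ndarray, r: np.ndarray, subsample: int = 500) -> float:
    """Expected log-likelihood ratio for detecting a copy-ratio-0.5 event.

    Evaluated at the expected deleted count per target under the current
    aggregate reference, with phi re-estimated by moments: adding reference
    samples grows the trial counts (more power) but heterogeneous references
    inflate phi (less power).
    """
    n = x + r
    p0 = float((x.sum() + 1) / (n.sum() + 2))
    phi = _moment_phi(x, n, p0)
    p_del = 0.5 * p0 / (0.5 * p0 + (1 - p0))
    keep = n > 0
    n_k = n[keep]
    if len(n_k) > subsample:  # deterministic thinning, power is a mean
        n_k = n_k[:: max(1, len(n_k) // subsample)]
    x_star = np.round(p_del * n_k)
    phi_eff = max(phi, 1e-8)
    return float(
        np.sum(
            betabin_loglik(x_star, n_k, p_del, phi_eff)
            - betabin_loglik(x_star, n_k, p0, phi_eff)
        )
    )


def select_reference_set(
    test_sample: str,
    cm: CountMatrix,
    params: CallerParams | None = None,
    correlations: pd.Series | None = None,
) -> ReferenceSet:
    """Rank candidates by Pearson correlation with the test profile and
    greedily aggregate them while detection power still increases.

    Deterministic given inputs. ``correlations`` may be precomputed (e.g.
    one panel-wide correlation matrix) to avoid quadratic recomputation.
    """
    params = params or CallerParams()
    candidates = [s for s in cm.samples if s != test_sample]
    if not candidates:
        raise ValueError("no candidate reference samples")
    X = cm.counts.to_numpy(np.float64)
    totals = X.sum(axis=0)
    totals[totals == 0] = 1.0
    prof = X / totals  # per-sample normalized profiles
    cols = {s: i for i, s in enumerate(cm.samples)}
    x = X[:, cols[test_sample]]
    if correlations is None:
        t = prof[:, cols[test_sample]]
        with np.errstate(invalid="ignore"):
            cors = {
                s: float(np.corrcoef(t, prof[:, cols[s]])[0, 1]) for s in candidates
            }
    else:
        cors = {s: float(correlations[s]) for s in candidates}
    ranked = sorted(
        (s for s in candidates if math.isfinite(cors[s])),
        key=lambda s: (-cors[s], s),
    )
    if not ranked:
        raise ValueError("no candidate with a finite correlation (constant profiles?)")

    chosen: list[str] = [ranked[0]]
    agg = X[:, cols[ranked[0]]].copy()
    best = _power_proxy(x, agg)
    for s in ranked[1:]:
        if len(chosen) >= params.max_reference_size:
            break
        trial = agg + X[:, cols[s]]
        proxy = _power_proxy(x, trial)
        if proxy > best:  # larger LLR at deleted data = more power
            best = proxy
            chosen.append(s)
            agg = trial
        else:
            break
    return ReferenceSet(test_sample, chosen, agg.astype(np.int64))


# ---------------------------------------------------------------------------
# HMM decoding
# ---------------------------------------------------------------------------

def _check_position_sorted(cm: CountMatrix) -> None:
    """Targets must arrive in (chrom, start) order with contiguous
    chromosome blocks; the HMM chains consecutive targets."""
    chroms = cm.targets["chrom"].tolist()
    starts = cm.targets["start"].to_numpy(np.int64)
    seen: set[str] = set()
    prev = None
    for i, c in enumerate(chroms):
        if c != prev:
            if c in seen:
                raise ValueError(f"chromosome ordering violated: {c} not contiguous")
            seen.add(c)
            prev = c
        elif starts[i] < starts[i - 1]:
            raise ValueError(f"chromosome ordering violated: {c} starts decrease")

def _transition_logs(gaps: np.ndarray, t: float, L: float) -> np.ndarray:
    """(n-1, 3, 3) log transition matrices for consecutive target pairs.

    From DIP the chance of entering either CNV state is ``t``. Inside a CNV
    state the self-transition is ``(1 - 2t) exp(-d/L)`` so the expected CNV
    genomic extent is about ``L``; the remainder returns to DIP apart from a
    ``t``-sized direct switch to the opposite CNV state.
    """
    stay_cnv = (1.0 - 2.0 * t) * np.exp(-np.maximum(gaps, 0.0) / L)
    A = np.zeros((len(gaps), 3, 3))
    A[:, DIP, DEL] = t
    A[:, DIP, DUP] = t
    A[:, DIP, DIP] = 1.0 - 2.0 * t
    for cnv, other in ((DEL, DUP), (DUP, DEL)):
        A[:, cnv, cnv] = stay_cnv
        A[:, cnv, other] = t
        A[:, cnv, DIP] = 1.0 - stay_cnv - t
    with np.errstate(divide="ignore"):
        return np.log(A)


def _viterbi(emissions: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray) -> np.ndarray:
    """Most probable state path; log-space dynamic programming."""
    m, k = emissions.shape
    delta = log_init + emissions[0]
    psi = np.zeros((m, k), dtype=np.int8)
    for j in range(1, m):
        cand = delta[:, None] + log_trans[j - 1]  # prev x next
        psi[j] = np.argmax(cand, axis=0)
        delta = cand[psi[j], np.arange(k)] + emissions[j]
    path = np.zeros(m, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for j in range(m - 1, 0, -1):
        path[j - 1] = psi[j, path[j]]
    return path


def call_cnvs_sample(
    cm: CountMatrix,
    ref: ReferenceSet,
    params: CallerParams | None = None,
) -> tuple[TargetStatePath, list[CnvCall]]:
    """Decode the per-target copy state of one sample and emit merged calls.

    Emission at target j under copy ratio c is
    ``BetaBin(x_j; n_j = x_j + r_j, p_j(c), phi)`` with
    ``p_j(c) = c mu / (c mu + (1 - mu))`` and ``mu`` the diploid expected
    proportion from the smoothed test/reference totals. Targets with
    ``n_j = 0`` contribute no evidence (all-state log-likelihood 0) and are
    counted in the log. The Viterbi path is decoded per chromosome and each
    maximal non-diploid run becomes one call whose confidence is the summed
    log-likelihood ratio against the diploid state.
    """
    params = params or CallerParams()
    _check_position_sorted(cm)
    x_all = cm.counts[ref.test_sample].to_numpy(np.int64)
    if len(ref.aggregate_counts) != len(x_all):
        raise ValueError("reference aggregate length does not match target list")
    r_all = np.asarray(ref.aggregate_counts, dtype=np.int64)
    n_all = x_all + r_all

    mu = float((x_all.sum() + 1) / (n_all.sum() + 2))
    phi = params.overdispersion
    if phi is None:
        phi = estimate_overdispersion(x_all, n_all, mu)
    ratios = np.asarray(params.copy_ratios, dtype=np.float64)
    p_states = ratios * mu / (ratios * mu + (1 - mu))

    n_empty = int((n_all == 0).sum())
    if n_empty:
        logger.info("%s: %d target(s) with zero trials skipped", ref.test_sample, n_empty)

    emissions = np.zeros((len(x_all), 3))
    nz = n_all > 0
    for k, p_k in enumerate(p_states):
        emissions[nz, k] = betabin_loglik(x_all[nz], n_all[nz], p_k, phi)

    chroms = cm.targets["chrom"].to_numpy()
    starts = cm.targets["start"].to_numpy(np.int64)
    ends = cm.targets["end"].to_numpy(np.int64)

    t, L = params.transition_prob, params.expected_cnv_length
    log_init = np.log(np.array([t, 1.0 - 2.0 * t, t]))
    states = np.zeros(len(x_all), dtype=np.int8)
    calls: list[CnvCall] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        em = emissions[idx]
        gaps = (starts[idx][1:] - ends[idx][:-1]).astype(np.float64)
        path = _viterbi(em, _transition_logs(gaps, t, L), log_init)
        states[idx] = path
        # maximal runs of identical non-DIP states -> calls
        j = 0
        while j < len(path):
            if path[j] == DIP:
                j += 1
                continue
            k = j
            while k + 1 < len(path) and path[k + 1] == path[j]:
                k += 1
            run = idx[j : k + 1]
            conf = float((emissions[run, path[j]] - emissions[run, DIP]).sum())
            calls.append(
                CnvCall(
                    sample=ref.test_sample,
                    chrom=str(chrom),
                    start=int(starts[run[0]]),
                    end=int(ends[run[-1]]),
                    type=STATE_NAMES[int(path[j])],
                    n_targets=len(run),
                    confidence=conf,
                )
            )
            j = k + 1

    path_obj = TargetStatePath(
        target_ids=list(cm.counts.index), states=states, loglik=emissions
    )
    return path_obj, calls


def call_cnvs_panel(
    cm: CountMatrix, params: CallerParams | None = None
) -> pd.DataFrame:
    """Run reference selection + calling for every sample of the panel.

    Returns the call table (sample, chrom, start, end, type, n_targets,
    confidence). One panel-wide correlation matrix of normalized profiles is
    computed once and reused.
    """
    params = params or CallerParams()
    cm = cm.sorted_by_position()
    X = cm.counts.to_numpy(np.float64)
    totals = X.sum(axis=0)
    totals[totals == 0] = 1.0
    prof = X / totals
    with np.errstate(invalid="ignore"):
        corr = pd.DataFrame(
            np.corrcoef(prof.T), index=cm.samples, columns=cm.samples
        )
    rows = []
    for sample in cm.samples:
        ref = select_reference_set(sample, cm, params, correlations=corr[sample])
        _, calls = call_cnvs_sample(cm, ref, params)
        rows.extend(vars(c) for c in calls)
    cols = ["sample", "chrom", "start", "end", "type", "n_targets", "confidence"]
    return pd.DataFrame(rows, columns=cols)
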