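"""CNV-based accession phylogeny.

Binary presence/absence genotypes per typed CNV site, Euclidean distances
between accessions, and a neighbor-joining tree (Saitou-Nei) written as
Newick. NJ is exact on additive distance matrices; negative branch-length
estimates on noisy input are clamped to zero with a warning, the usual
convention.
"""

from __future__ import annotations

import io as _io
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

logger = logging.getLogger(__name__)


def genotype_matrix(sites: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Samples x sites binary carrier matrix.

    Column order is deterministic (chrom, start, type). Site carrier lists
    are comma-joined sample ids (as produced by
    :func:`cnvsd.summary.collapse_to_sites`).
    """
    sample_set = set(samples)
    cols = {}
    if len(sites):
        ordered = sites.sort_values(["chrom", "start", "type"])
        for row in ordered.itertuples():
            carriers = set(str(row.carriers).split(",")) if row.carriers else set()
            bad = carriers - sample_set
            if bad:
                raise ValueError(f"carrier(s) not in sample list: {sorted(bad)[:3]}")
            col = f"{row.chrom}:{row.start}-{row.end}:{row.type}"
            cols[col] = [1 if s in carriers else 0 for s in samples]
    return pd.DataFrame(cols, index=samples, dtype=np.int8)


def euclidean_distances(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between accession genotype rows.

    For binary genotypes this is the square root of the Hamming count.
    """
    if len(m) < 2:
        raise ValueError("need at least two samples")
    if m.shape[1] == 0:
        d = np.zeros((len(m), len(m)))
    else:
        d = squareform(pdist(m.to_numpy(np.float64), metric="euclidean"))
    return pd.DataFrame(d, index=m.index, columns=m.index)


def neighbor_joining(d: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> TreeNode:
    """Standard neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimizing
    ``Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``,
    with branch lengths from the Saitou-Nei formulas, ties broken by the
    lowest (row, col) index. Exact (topology and branch lengths) on
    additive matrices. Returns an unrooted tree as a trifurcating-root
    :class:`skbio.TreeNode`.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        D = d.to_numpy(np.float64).copy()
    else:
        D = np.asarray(d, dtype=np.float64).copy()
        labels = labels or [f"t{i}" for i in range(len(D))]
    n = len(D)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.abs(D - D.T).max() > 1e-8:
        raise ValueError("distance matrix not symmetric within 1e-8")
    if np.abs(np.diag(D)).max() > 0:
        raise ValueError("distance matrix diagonal must be zero")

    nodes: list[TreeNode] = [TreeNode(name=str(l)) for l in labels]
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(D)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum row-major = lowest (row, col)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        nodes[i].length = _clamp(li)
        nodes[j].length = _clamp(lj)
        parent.extend([nodes[i], nodes[j]])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # closed-form star for the final three nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = TreeNode()
    nodes[0].length = _clamp(0.5 * (dab + dac - dbc))
    nodes[1].length = _clamp(0.5 * (dab + dbc - dac))
    nodes[2].length = _clamp(0.5 * (dac + dbc - dab))
    root.extend(nodes)
    if clamped:
        logger.warning("clamped %d negative NJ branch length(s) to zero", clamped)
    return root


def write_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(text), format="newick")
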