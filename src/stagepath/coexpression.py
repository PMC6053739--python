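"""Per-phase Pearson co-expression, signed pair classification, stable
pairs, and hierarchical clustering.

A gene pair is "positively correlated" in a phase when its Pearson r over
that phase's samples is strictly greater than the threshold (default 0.5)
and "negatively correlated" below the negative threshold; everything
else, including the exact boundary, is unclassified.  Pairs that keep the
same non-null sign in every phase are "stable pairs" — the backbone of
the cross-phase comparison.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_correlation",
    "classify_pairs",
    "pair_counts",
    "stable_pairs",
    "ClusterResult",
    "hierarchical_cluster",
    "linkage_to_newick",
]


def pairwise_correlation(
    matrix: pd.DataFrame,
    genes: Sequence[str],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlation matrix for the given genes over the given samples.

    Genes constant over the window get NaN against every partner (their
    correlation is undefined); the diagonal is 1 for well-defined genes.
    """
    genes, samples = list(genes), list(samples)
    if len(samples) < 3:
        raise ValueError("need >=3 samples for a meaningful correlation")
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    sub = matrix.loc[genes, samples].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("correlation undefined for %d constant gene(s)",
                       int(constant.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(sub)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(corr, index=genes, columns=genes)


def classify_pairs(
    corr: pd.DataFrame, phase: str, threshold: float = 0.5
) -> pd.DataFrame:
    """Classify every unordered gene pair by the sign of its correlation.

    Strict inequalities at +-threshold: r = threshold exactly is "none".
    Rows carry (gene_a < gene_b lexicographically, phase, r, class);
    undefined correlations are classed "none" with NaN r.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    genes = list(corr.index)
    order = np.argsort(genes)  # lexicographic, so gene_a < gene_b holds
    sorted_genes = [genes[i] for i in order]
    c = corr.to_numpy()[np.ix_(order, order)]
    iu, ju = np.triu_indices(len(genes), k=1)
    r = c[iu, ju]
    cls = np.where(r > threshold, "positive",
                   np.where(r < -threshold, "negative", "none"))
    cls[~np.isfinite(r)] = "none"
    return pd.DataFrame({
        "gene_a": [sorted_genes[i] for i in iu],
        "gene_b": [sorted_genes[j] for j in ju],
        "phase": phase,
        "r": r,
        "class": cls,
    })


def pair_counts(table: pd.DataFrame) -> dict[str, int]:
    """Positive/negative/total counts for one phase's pair table."""
    pos = int((table["class"] == "positive").sum())
    neg = int((table["class"] == "negative").sum())
    return {"positive": pos, "negative": neg, "total": pos + neg}


def stable_pairs(
    tables: Iterable[pd.DataFrame],
) -> tuple[pd.DataFrame, set[str]]:
    """Pairs with the same non-null correlation sign in every phase.

    Returns (table of stable pairs with their per-phase sign, set of
    endpoint genes).  The result does not depend on the order phases are
    supplied.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need >=2 phase tables to intersect")
    signs: dict[tuple[str, str], list[str]] = {}
    for tab in tables:
        for a, b, cls in zip(tab["gene_a"], tab["gene_b"], tab["class"]):
            signs.setdefault((a, b), []).append(cls)
    rows = []
    for (a, b), cls_list in sorted(signs.items()):
        if len(cls_list) == len(tables) and len(set(cls_list)) == 1 \
                and cls_list[0] != "none":
            rows.append((a, b, cls_list[0]))
    stable = pd.DataFrame(rows, columns=["gene_a", "gene_b", "class"])
    genes = set(stable["gene_a"]) | set(stable["gene_b"])
    return stable, genes


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterResult:
    """Average-linkage trees over genes and samples with 1 - r distance."""
    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    distance: str = "1 - pearson r"
    linkage: str = "average"


def _corr_linkage(data: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str]]:
    sd = data.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"correlation undefined for: {bad[:5]}")
    corr = np.corrcoef(data)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [labels[i] for i in hierarchy.leaves_list(link)]
    return link, order


def hierarchical_cluster(
    matrix: pd.DataFrame, genes: Sequence[str]
) -> ClusterResult:
    """Cluster genes (over all samples) and samples (over the given genes).

    Distance is 1 - Pearson r, linkage is average; ordering is
    deterministic given the input order (scipy breaks merge ties by
    index).
    """
    genes = list(genes)
    if len(genes) < 2 or matrix.shape[1] < 2:
        raise ValueError("need >=2 genes and >=2 samples to cluster")
    sub = matrix.loc[genes]
    gene_link, gene_order = _corr_linkage(sub.to_numpy(dtype=float),
                                          list(sub.index))
    sample_link, sample_order = _corr_linkage(sub.to_numpy(dtype=float).T,
                                              list(sub.columns))
    return ClusterResult(gene_order, sample_order, gene_link, sample_link)


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (heights as branch lengths)."""
    tree = hierarchy.to_tree(link)

    def _render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _render(node.left, node.dist)
        right = _render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _render(tree, tree.dist) + ";"
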