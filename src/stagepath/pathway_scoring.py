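"""Pathway enrichment, the degree-weighted deviation score, and its
permutation calibration.

The deviation score of a pathway with k differentially expressed member
genes is the running-mean maximum

    A(P) = max over 1 <= t <= k of (1 / sqrt(t)) * sum of the t largest Z'

where Z' = weight * Phi^{-1}(1 - p) combines each gene's ANOVA p-value
with its network-degree weight.  Because A grows with pathway size, it is
standardized against a permutation null: mu_k and sigma_k are the mean
and sd of A over random size-k gene sets drawn from the background pool,
and A_corrected = (A - mu_k) / sigma_k.

Per-sample score profiles reuse the same running-mean maximum on the
sample's weighted z-scored expression, giving one value per (pathway,
sample) for the phase-wise ANOVA screen.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_enrichment",
    "gene_anova",
    "p_to_z",
    "deviation_score",
    "calibrate_score",
    "score_pathways",
    "sample_scores",
    "sample_score_matrix",
    "pathway_anova",
]

#: p-values are floored here before the normal-quantile conversion so the
#: resulting Z stays finite in double precision.
P_FLOOR = 1e-16


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    query: set[str],
    collection: Mapping[str, "object"],
    universe: set[str],
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test per pathway.

    Pathways are intersected with the universe first; the p-value is the
    hypergeometric upper tail P(X >= overlap) of the 2x2 table with
    margins |query|, |pathway ∩ universe|, |universe| (Fisher's exact
    test, greater alternative).  Rows are sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    rows = []
    for name, gs in collection.items():
        members = set(gs.genes) & universe
        overlap = len(members & query)
        p = stats.hypergeom.sf(overlap - 1, len(universe), len(members),
                               len(query)) if members else 1.0
        rows.append((name, overlap, len(members), float(p)))
    out = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size",
                                      "p_value"])
    out = out.sort_values(["p_value", "pathway"], kind="mergesort") \
        .reset_index(drop=True)
    out["significant"] = out["p_value"] < p_cut
    return out


# ---------------------------------------------------------------------------
# gene-level ANOVA and Z conversion
# ---------------------------------------------------------------------------

def _anova_pvalues(values: np.ndarray, group_cols: Sequence[np.ndarray]) -> np.ndarray:
    """Vectorized one-way fixed-effects ANOVA across rows.

    ``group_cols`` holds column index arrays, one per group.  Degenerate
    rows (zero between- and within-group variance) get p = 1.
    """
    n_total = sum(len(c) for c in group_cols)
    k = len(group_cols)
    grand = values[:, np.concatenate(group_cols)].mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for cols in group_cols:
        sub = values[:, cols]
        m = sub.mean(axis=1)
        ssb += len(cols) * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    scale = np.maximum((values ** 2).max(axis=1), 1.0)
    tiny = np.finfo(float).eps * scale * n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(f, df_b, df_w)
    p = np.where(ssw <= tiny, np.where(ssb <= tiny, 1.0, 0.0), p)
    return p


def gene_anova(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> pd.Series:
    """Per-gene one-way ANOVA p across the control/early/late phases."""
    from .io_formats import PHASES, phase_samples

    sub = matrix if genes is None else matrix.loc[list(genes)]
    cols = list(sub.columns)
    group_cols = []
    for ph in PHASES:
        ids = [s for s in phase_samples(metadata, ph) if s in sub.columns]
        if len(ids) < 2:
            raise ValueError(f"phase {ph!r} has {len(ids)} samples; need >=2")
        group_cols.append(np.array([cols.index(s) for s in ids]))
    p = _anova_pvalues(sub.to_numpy(dtype=float), group_cols)
    return pd.Series(p, index=sub.index, name="p_value")


def p_to_z(p, weight=1.0):
    """Convert a p-value to a weighted upper-tail normal quantile.

    Z = Phi^{-1}(1 - p), with p floored at 1e-16 so Z stays finite;
    returns weight * Z.  Accepts scalars or arrays.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr > 1):
        raise ValueError("p-values above 1")
    if np.any(p_arr <= 0):
        logger.warning("non-positive p-value(s) floored at %.0e", P_FLOOR)
    z = stats.norm.isf(np.maximum(p_arr, P_FLOOR))
    out = np.asarray(weight, dtype=float) * z
    return float(out) if np.isscalar(p) and np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# deviation score
# ---------------------------------------------------------------------------

def deviation_score(z_values: Sequence[float]) -> tuple[float, int]:
    """Running-mean maximum of the sorted weighted Z values.

    Sorts descending and returns (A, t_max) where
    A = max_t prefix_sum(t)/sqrt(t) and t_max is the smallest t achieving
    it.  Invariant to input order; positively homogeneous in Z.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("deviation score of an empty gene list")
    z = np.sort(z)[::-1]
    t = np.arange(1, z.size + 1)
    scores = np.cumsum(z) / np.sqrt(t)
    i = int(np.argmax(scores))  # first occurrence = smallest t on ties
    return float(scores[i]), i + 1


def _null_scores(
    pool: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """A-scores of ``n_perm`` random size-k subsets of the background pool.

    Subsets are uniform without replacement (random-key argpartition);
    the whole batch is vectorized.
    """
    n = pool.size
    if k > n:
        raise ValueError(f"cannot draw {k} genes from a pool of {n}")
    if k == n:
        idx = np.tile(np.arange(n), (n_perm, 1))
    else:
        keys = rng.random((n_perm, n))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
    draws = pool[idx]
    draws = -np.sort(-draws, axis=1)  # descending
    t = np.arange(1, k + 1)
    return (np.cumsum(draws, axis=1) / np.sqrt(t)).max(axis=1)


def calibrate_score(
    A: float,
    k: int,
    gene_z: Mapping[str, float] | Sequence[float] | np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Standardize A against size-matched random gene sets.

    Draws ``n_perm`` random sets of k genes (without replacement) from the
    background pool, scores each with the running-mean maximum, and
    returns (mu_k, sigma_k, (A - mu_k) / sigma_k) with the n-1 sd.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    pool = np.asarray(list(gene_z.values()) if isinstance(gene_z, Mapping)
                      else gene_z, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = _null_scores(pool, k, n_perm, rng)
    mu = float(null.mean())
    sigma = float(null.std(ddof=1))
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError(
            "degenerate permutation null (sigma_k = 0); the background "
            "pool carries no variation at this set size")
    return mu, sigma, (A - mu) / sigma


def score_pathways(
    pathway_de_genes: Mapping[str, Sequence[str]],
    gene_z: Mapping[str, float],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every pathway's DE member genes and calibrate by size.

    ``gene_z`` is the background pool: every gene with a defined weighted
    Z.  Pathways with no DE member present in the pool are skipped with a
    log entry.  Permutation streams are derived from the master seed and
    the set size k, so results are independent of pathway evaluation
    order and equal-k pathways share the same null (identical Z multisets
    therefore get identical A_corrected).
    """
    pool = np.asarray(list(gene_z.values()), dtype=float)
    null_cache: dict[int, tuple[float, float]] = {}
    rows = []
    for name in pathway_de_genes:
        members = [g for g in pathway_de_genes[name] if g in gene_z]
        if not members:
            logger.info("pathway %s has no scored DE members; skipped", name)
            continue
        z = np.array([gene_z[g] for g in members])
        A, t_max = deviation_score(z)
        k = len(members)
        if k not in null_cache:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=0 if seed is None else seed,
                                       spawn_key=(k,)))
            null = _null_scores(pool, k, n_perm, rng)
            null_cache[k] = (float(null.mean()), float(null.std(ddof=1)))
        mu, sigma = null_cache[k]
        if sigma <= 1e-12 * max(1.0, abs(mu)):
            raise ValueError(f"degenerate null for pathway {name} (k={k})")
        rows.append((name, k, A, t_max, mu, sigma, (A - mu) / sigma))
    out = pd.DataFrame(rows, columns=["pathway", "k", "A", "t_max",
                                      "mu_k", "sigma_k", "A_corrected"])
    return out.sort_values("A_corrected", ascending=False, kind="mergesort") \
        .reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-sample profiles and the pathway-level ANOVA screen
# ---------------------------------------------------------------------------

def sample_scores(
    matrix: pd.DataFrame,
    member_genes: Sequence[str],
    weights: Mapping[str, float] | None = None,
) -> pd.Series:
    """Per-sample running-mean-maximum score of one pathway.

    For each sample, the member genes' weighted z-scored expression values
    are sorted descending and pushed through the same max-prefix statistic
    as the gene-level score, yielding one value per sample.
    """
    members = [g for g in member_genes if g in matrix.index]
    if not members:
        raise KeyError("no member genes present in the matrix")
    vals = matrix.loc[members].to_numpy(dtype=float)
    if weights is not None:
        w = np.array([weights.get(g, 1.0) for g in members])
        vals = vals * w[:, None]
    vals = -np.sort(-vals, axis=0)  # descending within each sample
    t = np.sqrt(np.arange(1, len(members) + 1))
    scores = (np.cumsum(vals, axis=0) / t[:, None]).max(axis=0)
    return pd.Series(scores, index=matrix.columns, name="score")


def sample_score_matrix(
    matrix: pd.DataFrame,
    pathway_de_genes: Mapping[str, Sequence[str]],
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Stack per-sample scores for many pathways (pathways x samples)."""
    rows = {}
    for name, members in pathway_de_genes.items():
        present = [g for g in members if g in matrix.index]
        if not present:
            logger.info("pathway %s has no members in the matrix; skipped",
                        name)
            continue
        rows[name] = sample_scores(matrix, present, weights)
    return pd.DataFrame(rows).T


def pathway_anova(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of per-sample pathway scores across the three phases."""
    from .io_formats import PHASES, phase_samples

    cols = list(profiles.columns)
    group_cols = []
    for ph in PHASES:
        ids = [s for s in phase_samples(metadata, ph) if s in profiles.columns]
        if len(ids) < 2:
            raise ValueError(f"phase {ph!r} has {len(ids)} samples; need >=2")
        group_cols.append(np.array([cols.index(s) for s in ids]))
    p = _anova_pvalues(profiles.to_numpy(dtype=float), group_cols)
    out = pd.DataFrame({"pathway": profiles.index, "p_value": p})
    out["significant"] = out["p_value"] < p_cut
    return out.sort_values(["p_value", "pathway"], kind="mergesort") \
        .reset_index(drop=True)
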