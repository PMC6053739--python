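"""Synthetic expression cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a three-group blood
transcriptome cohort (control / early-stage / late-stage) on the
control-referenced z-score scale: background genes are independent
standard normal in every sample, differentially expressed genes carry a
mean shift in their designated phase(s), correlated blocks share a
per-phase latent factor, and "deviated" pathways are populated mainly
with planted DE genes so the pathway-level scoring has a known answer.

Group sizes default to the 81/28/53 control/early/late split of the
motivating cohort; gene counts are desk-scale.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSet, PHASES

__all__ = [
    "SimulationTruth",
    "simulate_dataset",
    "inject_missing",
    "denormalize",
]


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort.

    planted_de maps gene id -> (phase in {early, late, both},
    direction in {up, down}, shift in z-score units).  planted_blocks is a
    list of (gene tuple, per-phase correlation) pairs; planted_pathways a
    list of (pathway name, deviated-in phase).
    """
    planted_de: dict[str, tuple[str, str, float]]
    planted_blocks: list[tuple[tuple[str, ...], dict[str, float]]]
    planted_pathways: list[tuple[str, str]]
    group_sizes: tuple[int, int, int]

    @property
    def shared_genes(self) -> set[str]:
        return {g for g, (ph, _, _) in self.planted_de.items() if ph == "both"}

    @property
    def de_genes(self) -> set[str]:
        return set(self.planted_de)

    def de_in_phase(self, phase: str) -> set[str]:
        """Genes shifted in the given cancer phase (includes 'both')."""
        return {g for g, (ph, _, _) in self.planted_de.items()
                if ph in (phase, "both")}

    def to_dict(self) -> dict:
        return {
            "planted_de": {g: list(v) for g, v in self.planted_de.items()},
            "planted_blocks": [
                {"genes": list(gs), "rho": dict(r)}
                for gs, r in self.planted_blocks
            ],
            "planted_pathways": [list(p) for p in self.planted_pathways],
            "group_sizes": list(self.group_sizes),
        }


def _as_phase_rho(rho) -> dict[str, float]:
    if isinstance(rho, Mapping):
        out = {ph: float(rho.get(ph, 0.0)) for ph in PHASES}
    elif isinstance(rho, Sequence) and not isinstance(rho, str):
        if len(rho) != 3:
            raise ValueError("per-phase rho needs 3 values (control, early, late)")
        out = dict(zip(PHASES, (float(r) for r in rho)))
    else:
        out = {ph: float(rho) for ph in PHASES}
    for ph, r in out.items():
        if not -1 < r < 1:
            raise ValueError(f"|rho| must be < 1, got {r} for phase {ph}")
    return out


def simulate_dataset(
    n_genes: int = 2000,
    group_sizes: tuple[int, int, int] = (81, 28, 53),
    *,
    n_de_early: int = 100,
    n_de_late: int = 100,
    n_shared: int = 30,
    shift: float = 2.0,
    n_blocks: int = 3,
    block_size: int = 10,
    rho: float | Mapping[str, float] | Sequence[float] = 0.7,
    n_pathways: int = 50,
    pathway_size: int = 20,
    n_deviated: int = 5,
    de_member_fraction: float = 0.8,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, GeneSet], SimulationTruth]:
    """Simulate an expression cohort with planted effects.

    Returns (expression genes x samples, metadata, gene-set collection,
    truth).  Background cells are iid N(0,1); a gene planted for phase p
    has its mean shifted by +-``shift`` in that phase's samples ("both"
    genes are shifted identically in early and late).  Each correlated
    block shares a per-phase latent factor f so that members
    x = sqrt(rho) f + sqrt(1-rho) eps have pairwise correlation rho within
    the phase.  The first ``n_deviated`` pathways draw at least
    ``de_member_fraction`` of their members from shared planted DE genes
    (falling back to phase-specific ones); the rest draw from background.

    The same seed reproduces the outputs bit for bit.
    """
    if n_shared > min(n_de_early, n_de_late):
        raise ValueError("n_shared cannot exceed min(n_de_early, n_de_late)")
    n_block_genes = n_blocks * block_size
    n_special = n_de_early + n_de_late - n_shared + n_block_genes
    if n_special > n_genes:
        raise ValueError(
            f"planted genes ({n_special}) exceed n_genes ({n_genes})")
    if not 0 < de_member_fraction <= 1:
        raise ValueError("de_member_fraction must be in (0,1]")
    if min(group_sizes) < 0 or sum(group_sizes) == 0:
        raise ValueError("group sizes must be non-negative with >=1 sample")
    phase_rho = _as_phase_rho(rho)

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    n_ctrl, n_early, n_late = group_sizes
    samples = (
        [f"ctrl_{i:03d}" for i in range(1, n_ctrl + 1)]
        + [f"early_{i:03d}" for i in range(1, n_early + 1)]
        + [f"late_{i:03d}" for i in range(1, n_late + 1)]
    )
    phase_cols = {
        "control": np.arange(n_ctrl),
        "early": np.arange(n_ctrl, n_ctrl + n_early),
        "late": np.arange(n_ctrl + n_early, n_ctrl + n_early + n_late),
    }

    values = rng.standard_normal((n_genes, len(samples)))

    # pick disjoint special genes: early-only, late-only, shared, blocks
    special_idx = rng.choice(n_genes, size=n_special, replace=False)
    pos = 0
    early_only = special_idx[pos:pos + n_de_early - n_shared]; pos += n_de_early - n_shared
    late_only = special_idx[pos:pos + n_de_late - n_shared]; pos += n_de_late - n_shared
    shared = special_idx[pos:pos + n_shared]; pos += n_shared
    block_idx = special_idx[pos:].reshape(n_blocks, block_size) if n_block_genes \
        else np.empty((0, block_size), dtype=int)

    planted_de: dict[str, tuple[str, str, float]] = {}

    def _plant(idx: np.ndarray, phase: str) -> None:
        cols = (np.concatenate([phase_cols["early"], phase_cols["late"]])
                if phase == "both" else phase_cols[phase])
        for j, gi in enumerate(idx):
            direction = "up" if j % 2 == 0 else "down"
            delta = shift if direction == "up" else -shift
            values[gi, cols] += delta
            planted_de[genes[gi]] = (phase, direction, float(delta))

    _plant(early_only, "early")
    _plant(late_only, "late")
    _plant(shared, "both")

    planted_blocks: list[tuple[tuple[str, ...], dict[str, float]]] = []
    for b in range(n_blocks):
        members = block_idx[b]
        for ph in PHASES:
            cols = phase_cols[ph]
            if len(cols) == 0:
                continue
            r = phase_rho[ph]
            f = rng.standard_normal(len(cols))
            eps = rng.standard_normal((block_size, len(cols)))
            # shared latent factor: pairwise corr = |r| (sign s_i*s_j when
            # r < 0, where member loadings alternate in sign)
            load = np.full(block_size, math.sqrt(abs(r)))
            if r < 0:
                load[1::2] *= -1.0
            values[np.ix_(members, cols)] = (
                load[:, None] * f + math.sqrt(1 - abs(r)) * eps)
        planted_blocks.append(
            (tuple(genes[i] for i in members), dict(phase_rho)))

    expr = pd.DataFrame(values, index=genes, columns=samples)

    stages = ["I"] * n_early + [("II", "III", "IV")[i % 3] for i in range(n_late)]
    meta = pd.DataFrame(
        {
            "phase": ["control"] * n_ctrl + ["early"] * n_early + ["late"] * n_late,
            "stage": [pd.NA] * n_ctrl + stages,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # pathways: deviated ones draw mostly from planted DE genes
    background_pool = np.setdiff1d(np.arange(n_genes), special_idx)
    if n_pathways > 0 and len(background_pool) < pathway_size:
        raise ValueError(
            f"only {len(background_pool)} background genes left for "
            f"pathways of size {pathway_size}; increase n_genes")
    de_pool = list(shared) + list(early_only) + list(late_only)
    collection: dict[str, GeneSet] = {}
    planted_pathways: list[tuple[str, str]] = []
    n_de_members = int(math.ceil(de_member_fraction * pathway_size))
    pw_width = len(str(max(n_pathways, 1)))
    for p in range(n_pathways):
        if p < n_deviated:
            name = f"DEV{p + 1:0{pw_width}d}"
            take = min(n_de_members, len(de_pool))
            # prefer genes shifted in both phases; widen the pool only if
            # the shared set is too small
            pool = list(shared) if len(shared) >= take else de_pool
            de_members = rng.choice(pool, size=take, replace=False)
            filler = rng.choice(background_pool,
                                size=pathway_size - take, replace=False)
            members = np.concatenate([de_members, filler])
            planted_pathways.append((name, "both"))
        else:
            name = f"P{p + 1:0{pw_width}d}"
            members = rng.choice(background_pool, size=pathway_size,
                                 replace=False)
        collection[name] = GeneSet(
            name, "synthetic pathway",
            frozenset(genes[i] for i in members))

    truth = SimulationTruth(planted_de, planted_blocks, planted_pathways,
                            tuple(group_sizes))
    return expr, meta, collection, truth


def inject_missing(
    matrix: pd.DataFrame, fraction: float, seed: int | None = None
) -> pd.DataFrame:
    """Blank out exactly floor(fraction * cells) entries uniformly at random."""
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0,1), got {fraction}")
    out = matrix.copy()
    n_cells = out.size
    n_missing = int(fraction * n_cells)
    if n_missing == 0:
        return out
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_missing, replace=False)
    vals = out.to_numpy(dtype=float, copy=True)
    vals.flat[flat] = np.nan
    out.iloc[:, :] = vals
    return out


def denormalize(
    matrix: pd.DataFrame,
    *,
    mean_range: tuple[float, float] = (6.0, 12.0),
    sd_range: tuple[float, float] = (0.5, 2.0),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map a z-scale matrix onto a raw intensity scale.

    Applies a per-gene affine transform x -> mu_g + s_g * x with mu_g, s_g
    drawn uniformly from the given ranges, emulating raw microarray-like
    intensities so the preprocessing stage has something to undo.  Returns
    (raw matrix, per-gene parameter table).
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(*mean_range, size=matrix.shape[0])
    sd = rng.uniform(*sd_range, size=matrix.shape[0])
    raw = matrix.mul(sd, axis=0).add(mu, axis=0)
    params = pd.DataFrame({"mean": mu, "sd": sd}, index=matrix.index)
    return raw, params
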