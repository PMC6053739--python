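"""Missing-value handling and control-referenced z-score normalization.

The preprocessing contract: genes and then samples with more than 10%
missing entries are dropped, remaining gaps are imputed with the gene's
mean over observed samples, and every gene is standardized against the
control group so that control values are mean 0 / variance 1 and case
values are expressed in control standard deviations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import phase_samples

__all__ = [
    "NormalizedMatrix",
    "filter_missing",
    "impute_missing",
    "zscore_to_control",
    "preprocess_pipeline",
]


@dataclasses.dataclass
class NormalizedMatrix:
    """A fully observed genes x samples matrix on the control z-scale.

    ``control_mean``/``control_sd`` record the per-gene parameters of the
    reference (control) group used for the transform, so the mapping back
    to the input scale is ``x_raw = mean + sd * z``.
    """
    data: pd.DataFrame
    control_mean: pd.Series
    control_sd: pd.Series
    reference: str = "control"

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("normalized matrix must have no missing entries")


def filter_missing(matrix: pd.DataFrame, max_fraction: float = 0.10) -> pd.DataFrame:
    """Drop genes, then samples, whose missing fraction exceeds the cutoff.

    Two-pass rule: genes with missing fraction strictly greater than
    ``max_fraction`` go first; sample fractions are then re-evaluated over
    the surviving genes.  Order is otherwise preserved.
    """
    if not 0 <= max_fraction < 1:
        raise ValueError(f"max_fraction must be in [0,1), got {max_fraction}")
    gene_frac = matrix.isna().mean(axis=1)
    kept = matrix.loc[gene_frac <= max_fraction]
    if kept.empty:
        raise ValueError("all genes removed by the missing-value filter")
    sample_frac = kept.isna().mean(axis=0)
    kept = kept.loc[:, sample_frac <= max_fraction]
    if kept.shape[1] == 0:
        raise ValueError("all samples removed by the missing-value filter")
    return kept


def impute_missing(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing cell with the gene's mean over observed samples."""
    obs_counts = matrix.notna().sum(axis=1)
    dead = obs_counts[obs_counts == 0]
    if len(dead):
        raise ValueError(
            f"gene(s) with no observed values (filter first): {list(dead.index)}")
    gene_means = matrix.mean(axis=1, skipna=True)
    return matrix.T.fillna(gene_means).T


def zscore_to_control(
    matrix: pd.DataFrame, metadata: pd.DataFrame
) -> NormalizedMatrix:
    """Standardize every gene against its control-group mean and sd.

    Uses the n-1 (sample) standard deviation.  Case columns are
    transformed with the same per-gene parameters, so a case value of 2
    reads as "two control standard deviations above the control mean".
    """
    controls = [s for s in phase_samples(metadata, "control")
                if s in matrix.columns]
    if len(controls) < 2:
        raise ValueError(f"need >=2 control samples, found {len(controls)}")
    if matrix.isna().any().any():
        raise ValueError("impute missing values before normalization")
    mean = matrix[controls].mean(axis=1)
    sd = matrix[controls].std(axis=1, ddof=1)
    zero_sd = sd[sd == 0]
    if len(zero_sd):
        raise ValueError(
            "zero control-group standard deviation for gene(s): "
            f"{list(zero_sd.index)}; drop them before normalization")
    data = matrix.sub(mean, axis=0).div(sd, axis=0)
    return NormalizedMatrix(data=data, control_mean=mean, control_sd=sd)


def preprocess_pipeline(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    max_fraction: float = 0.10,
) -> NormalizedMatrix:
    """filter -> impute -> z-score, dropping zero-variance genes if needed."""
    filtered = filter_missing(matrix, max_fraction)
    imputed = impute_missing(filtered)
    controls = [s for s in phase_samples(metadata, "control")
                if s in imputed.columns]
    if len(controls) >= 2:
        sd = imputed[controls].std(axis=1, ddof=1)
        imputed = imputed.loc[sd > 0]
    return zscore_to_control(imputed, metadata)
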