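"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices are genes-in-rows TSV (series-matrix orientation),
sample metadata is a three-column TSV (sample_id, phase, optional stage),
and pathway membership comes from standard GMT files.  All readers
validate identifier uniqueness and label vocabulary up front rather than
letting malformed input propagate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Valid phase labels, in display order.
PHASES = ("control", "early", "late")
#: Valid clinical stage labels.
STAGES = ("I", "II", "III", "IV")
#: Strings treated as missing values in expression TSVs.
NA_SENTINELS = ("", "NA", "NaN", "nan")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


def read_expression(
    path: str | Path,
    *,
    transpose: bool = False,
    na_values: Iterable[str] = NA_SENTINELS,
) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    First column holds gene ids, header row holds sample ids.  Empty cells
    or any of ``na_values`` denote missing entries (kept as NaN, never
    coerced to zero).  ``transpose=True`` reads samples-in-rows files.

    Raises
    ------
    ValueError
        On duplicate gene/sample ids or ragged rows (message carries the
        offending identifier or line number).
    """
    path = Path(path)
    # Light structural pass: pandas silently NaN-fills short rows and
    # renames duplicate header fields, so check both on the raw lines.
    with open(path) as fh:
        n_fields = None
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if n_fields is None:
                n_fields = len(fields)
                _check_unique(fields[1:],
                              "gene" if transpose else "sample")
            elif len(fields) != n_fields:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} fields, expected {n_fields})"
                )
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(na_values),
        keep_default_na=False,
    )
    if transpose:
        df = df.T
    df.index = pd.Index([str(i) for i in df.index])
    df.columns = pd.Index([str(c) for c in df.columns])
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    return df.astype(float)


def write_expression(
    matrix: pd.DataFrame,
    path: str | Path,
    *,
    na_rep: str = "NA",
    float_format: str = "%.10g",
) -> None:
    """Write a genes x samples matrix as TSV (gene ids in the first column)."""
    matrix.to_csv(path, sep="\t", na_rep=na_rep, float_format=float_format,
                  index_label="gene")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame indexed by sample id.

    Requires a ``phase`` column in {control, early, late}; an optional
    ``stage`` column must be consistent with phase (early -> I,
    late -> II/III/IV) where present.
    """
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    bad = set(meta["phase"]) - set(PHASES)
    if bad:
        raise ValueError(f"unknown phase label(s): {sorted(bad)}; "
                         f"expected one of {PHASES}")
    if "stage" in meta.columns:
        staged = meta["stage"].notna()
        bad_stage = set(meta.loc[staged, "stage"]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stage label(s): {sorted(bad_stage)}")
        early_bad = meta[(meta["phase"] == "early") & staged
                         & (meta["stage"] != "I")]
        if len(early_bad):
            raise ValueError(
                f"early-phase samples must be stage I: {list(early_bad.index)}")
        late_bad = meta[(meta["phase"] == "late") & staged
                        & ~meta["stage"].isin(("II", "III", "IV"))]
        if len(late_bad):
            raise ValueError(
                f"late-phase samples must be stage II-IV: {list(late_bad.index)}")
    else:
        meta = meta.copy()
        meta["stage"] = pd.NA
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, phase[, stage]."""
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[""])
    required = {"sample_id", "phase"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}, "
                         f"got {list(meta.columns)}")
    meta = meta.set_index("sample_id")
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def phase_samples(meta: pd.DataFrame, phase: str) -> list[str]:
    """Sample ids with the given phase label, in metadata order."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    return list(meta.index[meta["phase"] == phase])


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneSet:
    """One named pathway: description plus a set of member gene ids."""
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no members")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file into an ordered mapping name -> GeneSet.

    One pathway per line: name, description, then member genes.  Member
    duplicates within a line are collapsed; duplicate pathway names are an
    error.
    """
    collection: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description and >=1 gene")
            name, desc = fields[0], fields[1]
            if name in collection:
                raise ValueError(f"{path}: duplicate pathway name {name!r} "
                                 f"at line {lineno}")
            members = frozenset(g for g in fields[2:] if g)
            collection[name] = GeneSet(name, desc, members)
    return collection


def write_gmt(collection: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection.values():
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    """Write a 3+ column edge list (gene_a, gene_b, r, ...) as TSV."""
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration and summary
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """All tunable thresholds of the pipeline in one place.

    Defaults follow the analysis conventions: 10% missing-value cutoff,
    top-50% CV filter, DE thresholds P<0.05 and |logFC|>=1, co-expression
    at |r|>0.5, enrichment/ANOVA at P<0.05, 10,000 permutations and
    fivefold cross-validation.
    """
    max_missing: float = 0.10
    cv_quantile: float = 0.5
    de_p: float = 0.05
    de_lfc: float = 1.0
    de_method: str = "moderated"  # or "ttest"
    corr_threshold: float = 0.5
    enrich_p: float = 0.05
    anova_p: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    cv_folds: int = 5
    svm_costs: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gammas: tuple[float | str, ...] = ("scale", 0.001, 0.01, 0.1)
    label_scheme: str = "benign_vs_malignant"

    def __post_init__(self) -> None:
        for name in ("de_p", "enrich_p", "anova_p"):
            p = getattr(self, name)
            if not 0 < p < 1:
                raise ValueError(f"{name} must be in (0,1), got {p}")
        if not 0 <= self.max_missing < 1:
            raise ValueError("max_missing must be in [0,1)")
        if not 0 < self.cv_quantile <= 1:
            raise ValueError("cv_quantile must be in (0,1]")
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must be in (0,1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("svm_costs", "svm_gammas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_run_summary(summary: Mapping, path: str | Path) -> None:
    """Serialize the machine-readable run summary (config, seed, counts)."""
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (set, frozenset, tuple)):
            return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_default)
        fh.write("\n")
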