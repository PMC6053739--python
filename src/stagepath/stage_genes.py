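"""Stage-specific differentially expressed gene extraction.

Three steps: (1) a coefficient-of-variation filter discards genes whose
expression barely fluctuates across cancer samples; (2) each cancer phase
is compared against controls with a moderated two-sample t-statistic
(empirical-Bayes shrinkage of per-gene variances toward a pooled prior,
the standard shrinkage scheme for expression arrays); (3) genes passing
P and |logFC| cutoffs form the early-specific (delta0), late-specific
(delta1) and shared (delta2 = intersection) sets with up/down directions.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "compute_cv",
    "cv_filter",
    "differential_expression",
    "StageGeneSets",
    "extract_stage_sets",
]


def compute_cv(matrix: pd.DataFrame, case_samples: Sequence[str]) -> pd.DataFrame:
    """Per-gene mean, sd (n-1) and CV = sd/mean over the cancer samples.

    Genes whose case mean is exactly zero get CV = NaN (undefined) and are
    excluded from downstream ranking.
    """
    case = list(case_samples)
    if len(case) < 2:
        raise ValueError("need >=2 case samples for a coefficient of variation")
    sub = matrix[case]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv = cv.where(mean != 0)
    n_undef = int(cv.isna().sum())
    if n_undef:
        logger.warning("CV undefined (zero mean) for %d gene(s)", n_undef)
    return pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})


def cv_filter(stats_table: pd.DataFrame, keep_quantile: float = 0.5) -> list[str]:
    """Keep genes whose |CV| ranks in the top ``keep_quantile`` fraction.

    The cut is the (1 - keep_quantile) quantile of all defined |CV|
    values; boundary ties are all kept.
    """
    if not 0 < keep_quantile <= 1:
        raise ValueError("keep_quantile must be in (0,1]")
    abs_cv = stats_table["cv"].abs().dropna()
    if abs_cv.empty:
        raise ValueError("no genes with a defined CV")
    cut = np.quantile(abs_cv.to_numpy(), 1 - keep_quantile)
    return list(abs_cv.index[abs_cv >= cut])


# ---------------------------------------------------------------------------
# moderated two-sample t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = np.where(x > 1e7, 1.0 / np.sqrt(x), 0.5 + 1.0 / x)
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-8 * y):
            break
    return np.where(x < 1e-6, 1.0 / x, y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to gene variances.

    Returns (prior df d0, prior variance s0^2); d0 = inf means the
    observed log-variances are less dispersed than sampling alone would
    produce, i.e. complete shrinkage to a common variance.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return 0.0, float("nan")  # nothing to pool: fall back to plain t
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return float("inf"), float(np.exp(emean))
    d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
    s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def differential_expression(
    matrix: pd.DataFrame,
    group: Sequence[str],
    control: Sequence[str],
    genes: Sequence[str] | None = None,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-gene group-vs-control test on the normalized scale.

    log_fc is the difference of group means (the data are already log-like
    z-scores).  ``method="moderated"`` shrinks per-gene pooled variances
    toward an empirical-Bayes prior estimated across all tested genes and
    tests with df = residual + prior df; ``method="ttest"`` is the plain
    pooled-variance two-sample t (the moderated statistic with prior
    weight zero).

    Returns a frame indexed by gene with columns log_fc, t, p_value.
    """
    group, control = list(group), list(control)
    overlap = set(group) & set(control)
    if overlap:
        raise ValueError(f"group and control overlap: {sorted(overlap)[:5]}")
    if len(group) < 2 or len(control) < 2:
        raise ValueError("need >=2 samples on each side")
    if method not in ("moderated", "ttest"):
        raise ValueError(f"unknown method {method!r}")

    sub = matrix if genes is None else matrix.loc[list(genes)]
    g = sub[group].to_numpy(dtype=float)
    c = sub[control].to_numpy(dtype=float)
    n1, n0 = g.shape[1], c.shape[1]
    df_resid = n1 + n0 - 2

    log_fc = g.mean(axis=1) - c.mean(axis=1)
    v1 = g.var(axis=1, ddof=1)
    v0 = c.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df_resid

    if method == "moderated":
        d0, s0 = _fit_variance_prior(s2, df_resid)
    else:
        d0, s0 = 0.0, float("nan")

    if d0 == 0.0 or not np.isfinite(s0):
        s2_post = s2
        df_total = float(df_resid)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / se
    # se = 0: a gene constant within both groups; identical means carry no
    # evidence (t = 0), distinct means are unambiguous (t = +-inf)
    with np.errstate(invalid="ignore"):
        t = np.where(se == 0,
                     np.where(log_fc == 0, 0.0, np.sign(log_fc) * np.inf),
                     t)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return pd.DataFrame({"log_fc": log_fc, "t": t, "p_value": p},
                        index=sub.index)


# ---------------------------------------------------------------------------
# stage gene sets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StageGeneSets:
    """delta0/delta1: gene -> direction; delta2: gene -> (early, late) dirs."""
    delta0: dict[str, str]
    delta1: dict[str, str]
    delta2: dict[str, tuple[str, str]]

    def counts(self) -> dict[str, int]:
        def _ud(d: dict[str, str]) -> tuple[int, int]:
            ups = sum(1 for v in d.values() if v == "up")
            return ups, len(d) - ups

        up0, down0 = _ud(self.delta0)
        up1, down1 = _ud(self.delta1)
        return {
            "delta0_total": len(self.delta0), "delta0_up": up0, "delta0_down": down0,
            "delta1_total": len(self.delta1), "delta1_up": up1, "delta1_down": down1,
            "delta2_total": len(self.delta2),
        }


def _significant(de: pd.DataFrame, p_cut: float, lfc_cut: float) -> dict[str, str]:
    mask = (de["p_value"] < p_cut) & (de["log_fc"].abs() >= lfc_cut)
    sig = de.loc[mask]
    return {g: ("up" if lfc > 0 else "down")
            for g, lfc in sig["log_fc"].items()}


def extract_stage_sets(
    de_early: pd.DataFrame,
    de_late: pd.DataFrame,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> StageGeneSets:
    """Threshold the two phase tests and intersect on gene id.

    A gene is phase-specific iff p < p_cut and |log_fc| >= lfc_cut; the
    shared set keeps each gene's direction in both phases (they may
    differ).
    """
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must be in (0,1)")
    if lfc_cut < 0:
        raise ValueError("lfc_cut must be >= 0")
    delta0 = _significant(de_early, p_cut, lfc_cut)
    delta1 = _significant(de_late, p_cut, lfc_cut)
    delta2 = {g: (delta0[g], delta1[g]) for g in delta0 if g in delta1}
    return StageGeneSets(delta0, delta1, delta2)
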