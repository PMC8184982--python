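"""Functional-diversity and carbon-partition statistics.

Downstream summaries of the per-taxon flux table: Pielou's evenness of
relative abundance versus relativized carbon use, cumulative consolidation
curves (how few taxa carry half the community's C flux), the partition of
each taxon's carbon use into glucose-derived and native soil C from its
13C enrichment, and a Levene-type test for treatment shifts in the
variance of the 13C-use ~ 12C-use relationship.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)


def pielou_evenness(weights) -> float:
    """Pielou's evenness J = H' / ln(S) of a non-negative weight vector.

    H' is Shannon diversity (natural log) over the positive entries and S
    their count; zeros carry no information and do not count toward
    richness.  A single positive entry is trivially even (J = 1).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("evenness undefined for an all-zero vector")
    if w.size == 1:
        return 1.0
    p = w / w.sum()
    h = -float((p * np.log(p)).sum())
    return h / np.log(w.size)


def consolidation_curve(weights, threshold: float = 0.5) -> tuple[pd.DataFrame, float]:
    """Cumulative share of total weight versus taxon rank.

    Weights are sorted descending and cumulated; the second return value
    is the minimal *fraction* of taxa needed to reach ``threshold`` of the
    total (e.g. how small a slice of the community carries half its carbon
    use).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    srt = np.sort(w)[::-1] / total
    cum = np.cumsum(srt)
    curve = pd.DataFrame({
        "rank": np.arange(1, w.size + 1),
        "share": srt,
        "cumulative_share": cum,
    })
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return curve, k / w.size


def relativize(values) -> np.ndarray:
    """Scale a non-negative vector to sum to one."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot relativize an all-zero vector")
    return v / total


def partition_carbon_13c(
    eaf_13c,
    c_use,
    glucose_atom_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-taxon carbon use into glucose-derived and native soil C.

    The glucose-derived fraction is ``f = 13C-EAF / a_g`` where ``a_g`` is
    the 13C atom fraction of the added glucose; glucose C is ``f * C_use``
    and native C the remainder, so the partition conserves total C use
    exactly.  EAF values above ``a_g`` are clamped with a warning.
    """
    if not 0 < glucose_atom_fraction <= 1:
        raise ValueError("glucose atom fraction must be in (0, 1]")
    eaf = np.asarray(eaf_13c, dtype=float)
    use = np.asarray(c_use, dtype=float)
    if np.any(eaf < 0):
        raise ValueError("13C EAF must be non-negative")
    over = eaf > glucose_atom_fraction
    if over.any():
        logger.warning("%d 13C EAF value(s) above the glucose atom fraction; "
                       "clamped", int(over.sum()))
        eaf = np.minimum(eaf, glucose_atom_fraction)
    f = eaf / glucose_atom_fraction
    glucose_c = f * use
    return glucose_c, use - glucose_c


def levene_test(groups, center: str = "median"):
    """Levene's test for equal variances across groups (Brown-Forsythe
    median centering by default; ``center="mean"`` for the classical
    statistic).  Returns (F, (df_between, df_within), p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    stat, p = stats.levene(*groups, center=center)
    n = sum(len(g) for g in groups)
    return float(stat), (len(groups) - 1, n - len(groups)), float(p)


def variance_shift_test(
    use_13c,
    use_12c,
    treatments,
    replicates,
    center: str = "median",
) -> dict:
    """Test whether the spread of the 13C-use ~ 12C-use relationship
    differs between treatments.

    A linear model of relativized 13C use on 12C use is fitted across all
    genera and replicates; residual deviations are taken from each
    treatment x replicate cell's center (median by default, the
    Brown-Forsythe choice), and a one-way ANOVA of those deviations across
    treatments gives the treatment-level F — a Levene-type test that
    respects the replicate structure.
    """
    df = pd.DataFrame({
        "y13": np.asarray(use_13c, dtype=float),
        "y12": np.asarray(use_12c, dtype=float),
        "treatment": np.asarray(treatments),
        "replicate": np.asarray(replicates),
    })
    cells = df.groupby(["treatment", "replicate"]).size()
    trts = df["treatment"].unique()
    if len(trts) < 2 or (cells.groupby("treatment").size() < 2).any():
        raise ValueError("need >= 2 treatments with >= 2 replicates each")

    exog = sm.add_constant(df["y12"].to_numpy())
    fit = sm.OLS(df["y13"].to_numpy(), exog).fit()
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("singular fit: 12C use has no variance")
    df["resid"] = fit.resid

    centerer = "median" if center == "median" else "mean"
    df["dev"] = np.abs(
        df["resid"]
        - df.groupby(["treatment", "replicate"])["resid"].transform(centerer)
    )
    by_trt = [grp["dev"].to_numpy() for _, grp in df.groupby("treatment")]
    f_stat, p = stats.f_oneway(*by_trt)
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "f_statistic": float(f_stat),
        "df": (len(trts) - 1, len(df) - len(trts)),
        "p_value": float(p),
        "n_cells": int(len(cells)),
        "center": center,
    }


def evenness_table(flux: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Pielou evenness of relative abundance, production,
    respiration and total C use, from a per-(sample, ASV) flux table."""
    rows = []
    for sample, grp in flux.groupby("sample_id", sort=False):
        rows.append({
            "sample_id": sample,
            "evenness_abundance": pielou_evenness(grp["y"]),
            "evenness_production": pielou_evenness(grp["p_ug"]),
            "evenness_respiration": pielou_evenness(grp["r_ug"]),
            "evenness_c_use": pielou_evenness(grp["c_use_ug"]),
        })
    return pd.DataFrame(rows)
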