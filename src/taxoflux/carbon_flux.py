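"""Per-taxon biomass-C production, CUE and respiration.

Scales qSIP growth estimates to carbon fluxes (ug C per g dry soil per
week) through genome traits and cell-mass allometry, computes the
community carbon use efficiency (CUE) from 18O-labeled biomass production
and respired CO2, evaluates candidate per-taxon growth->CUE functional
forms, and selects among them by a combined AIC criterion that weighs the
fit to measured respiration twice as heavily as the fit to community CUE.

The flux chain per taxon i is::

    M_i:   log10(M_i) = (log10(G_i) - 9.4) / 0.24        cell mass (g)
    P_i  = dN_i/dt / C_i * M_i * 0.2 / divisor           biomass-C production
    r_g  = g_i / CUE_i - g_i;  r_m = beta * r_g          per-capita respiration
    R_i  = P_i * r_g + P_i * r_m                         respired CO2-C

with C_i the 16S copy number per cell, 0.2 the carbon fraction of cell
mass, divisor the biomass calibration against measured MBC (10 by
default) and beta = 0.01 the maintenance share of energy use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .qsip_core import RANKS

logger = logging.getLogger(__name__)

#: candidate growth -> CUE functional forms
CUE_FORMS = (
    "linear_positive",
    "linear_negative",
    "exponential_decline",
    "unimodal_0.5",
    "unimodal_0.05",
)

#: default unconstrained CUE bounds; (0, 0.85) is an equally supported
#: alternative — both appear in the source material for the method
UNCONSTRAINED_BOUNDS = (0.0, 0.7)

BETA_MAINTENANCE = 0.01
CARBON_FRACTION = 0.2
MASS_DIVISOR = 10.0

#: numerical floor applied to evaluated CUE before respiration: a nominal
#: lower bound of exactly 0 (unconstrained mode) would make g/CUE diverge
CUE_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# genome traits and cell mass
# ---------------------------------------------------------------------------


def assign_genome_traits(
    taxonomy: pd.DataFrame,
    reference: pd.DataFrame,
    ranks: list[str] = RANKS,
) -> pd.DataFrame:
    """Assign 16S copy number and genome length to each ASV.

    An ASV with an exact entry in the reference (matched on ``asv_id``)
    takes that entry.  Otherwise the reference is searched at the most
    specific taxonomic rank shared with the ASV's lineage, descending to
    coarser ranks until any reference rows match; the median copy number
    and genome length of the matching rows are assigned and the rank used
    is recorded.  With no match at any rank the whole-table median is used
    (kingdom-level fallback, logged).
    """
    if len(reference) == 0:
        raise ValueError("empty genome-trait reference table")
    for col in ("copy_number", "genome_bp"):
        if col not in reference.columns:
            raise ValueError(f"reference table lacks required column {col!r}")

    shared = [r for r in ranks if r in taxonomy.columns and r in reference.columns]
    # median trait values grouped by every lineage prefix depth
    medians = {}
    for depth in range(1, len(shared) + 1):
        key = shared[:depth]
        medians[depth] = reference.groupby(key)[["copy_number", "genome_bp"]].median()

    exact = None
    if "asv_id" in reference.columns:
        exact = reference.set_index("asv_id")[["copy_number", "genome_bp"]]
        exact = exact[~exact.index.duplicated()]

    global_median = reference[["copy_number", "genome_bp"]].median()
    rows = []
    n_fallback = 0
    for _, tax in taxonomy.iterrows():
        asv = tax["asv_id"]
        if exact is not None and asv in exact.index:
            hit = exact.loc[asv]
            rows.append((asv, hit["copy_number"], hit["genome_bp"], "exact"))
            continue
        for depth in range(len(shared), 0, -1):
            key = tuple(tax[r] for r in shared[:depth])
            tab = medians[depth]
            lookup = key if depth > 1 else key[0]
            if lookup in tab.index:
                hit = tab.loc[lookup]
                rows.append((asv, hit["copy_number"], hit["genome_bp"], shared[depth - 1]))
                break
        else:
            n_fallback += 1
            rows.append((asv, global_median["copy_number"],
                         global_median["genome_bp"], "kingdom"))
    if n_fallback:
        logger.warning(
            "%d ASV(s) matched the reference at no rank; whole-table median used",
            n_fallback,
        )
    traits = pd.DataFrame(
        rows, columns=["asv_id", "copy_number", "genome_bp", "assignment_rank"]
    )
    traits["cell_mass_g"] = cell_mass(traits["genome_bp"].to_numpy())
    return traits


def cell_mass(genome_bp):
    """Allometric cell mass (g) from genome length (bp):
    ``log10(M) = (log10(G) - 9.4) / 0.24``."""
    g = np.asarray(genome_bp, dtype=float)
    if np.any(g <= 0):
        raise ValueError("genome length must be positive")
    return 10 ** ((np.log10(g) - 9.4) / 0.24)


def calibrate_cell_mass(
    initial_copies: pd.DataFrame,
    traits: pd.DataFrame,
    measurements: pd.DataFrame,
    mode: str = "fixed",
    carbon_fraction: float = CARBON_FRACTION,
    fixed_divisor: float = MASS_DIVISOR,
) -> tuple[float, pd.DataFrame]:
    """Calibration divisor reconciling trait-based biomass C with measured
    MBC.

    ``initial_copies``: per (sample_id, asv_id) 16S copies g^-1 at t0
    (column ``n0``).  In "fixed" mode the divisor is the conventional 10;
    in "estimated" mode it is the geometric mean over samples of
    (summed trait-based biomass C) / (measured MBC_0).  Samples with
    non-positive MBC are excluded.  Returns (divisor, per-sample diagnostics).
    """
    if mode not in ("fixed", "estimated"):
        raise ValueError("mode must be 'fixed' or 'estimated'")
    df = initial_copies.merge(
        traits[["asv_id", "copy_number", "cell_mass_g"]], on="asv_id", how="inner")
    df["biomass_c_ug"] = (
        df["n0"] / df["copy_number"] * df["cell_mass_g"] * carbon_fraction * 1e6
    )
    per_sample = df.groupby("sample_id")["biomass_c_ug"].sum().rename("estimate_ug")
    diag = per_sample.to_frame().join(
        measurements.set_index("sample_id")["mbc0_ug_c_g"])
    ok = diag["mbc0_ug_c_g"] > 0
    if (~ok).any():
        logger.warning("%d sample(s) with non-positive MBC excluded from "
                       "calibration", int((~ok).sum()))
    diag["ratio"] = np.where(ok, diag["estimate_ug"] / diag["mbc0_ug_c_g"], np.nan)
    if mode == "fixed":
        divisor = fixed_divisor
    else:
        ratios = diag.loc[ok, "ratio"]
        if len(ratios) == 0:
            raise ValueError("no usable samples for cell-mass calibration")
        divisor = float(np.exp(np.log(ratios).mean()))
    return divisor, diag.reset_index()


def biomass_production(
    dn_dt_wk,
    copy_number,
    cell_mass_g,
    carbon_fraction: float = CARBON_FRACTION,
    divisor: float = MASS_DIVISOR,
):
    """Biomass-C production P_i (ug C g^-1 wk^-1) from 16S copy production:
    ``P = dN/dt / C * M * carbon_fraction / divisor`` with M converted from
    g to ug here (the only g->ug seam in the chain)."""
    dn = np.asarray(dn_dt_wk, dtype=float)
    if np.any(dn < 0):
        raise ValueError("copy production must be non-negative")
    return dn / np.asarray(copy_number, float) * np.asarray(cell_mass_g, float) \
        * carbon_fraction * 1e6 / divisor


# ---------------------------------------------------------------------------
# community CUE
# ---------------------------------------------------------------------------


def mbc_dna_slope(measurements: pd.DataFrame, zero_intercept: bool = True) -> float:
    """Slope of the MBC_0 ~ DNA_0 relationship across samples (ug C per ug
    DNA), used to convert DNA-based enrichment to biomass C.  Zero-intercept
    least squares by default (the slope acts as a multiplicative conversion
    factor); set ``zero_intercept=False`` for a free intercept."""
    if len(measurements) < 2:
        raise ValueError("need at least 2 samples to fit MBC ~ DNA")
    y = measurements["mbc0_ug_c_g"].to_numpy(dtype=float)
    x = measurements["dna0_ug_g"].to_numpy(dtype=float)
    exog = x[:, None] if zero_intercept else sm.add_constant(x)
    fit = sm.OLS(y, exog).fit()
    return float(fit.params[-1])


def community_18p(eaf, y, dna0: float, slope: float) -> float:
    """Gross production of 18O-labeled biomass C for one sample
    (ug C g^-1 wk^-1): ``sum(EAF_i * y_i) * DNA_0 * slope``."""
    y = np.asarray(y, dtype=float)
    total = y.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"relative abundances must sum to 1, got {total:.6f}")
    return float((np.asarray(eaf, float) * y).sum() * dna0 * slope)


def community_cue(p18: float, r: float) -> float:
    """Community carbon use efficiency ``18P / (18P + R)``."""
    if p18 < 0 or r < 0:
        raise ValueError("18P and R must be non-negative")
    if p18 + r == 0:
        raise ValueError("community CUE undefined: 18P + R = 0")
    return p18 / (p18 + r)


# ---------------------------------------------------------------------------
# per-taxon CUE functional forms
# ---------------------------------------------------------------------------


def per_taxon_cue(
    g,
    form: str,
    cue_min: float,
    cue_max: float,
    g_lo: float | None = None,
    g_hi: float | None = None,
    g_mid: float | None = None,
):
    """Per-taxon CUE as a function of per-capita growth rate (day^-1).

    Forms:

    * ``unimodal_0.5``: ``-4 * range * (g - 0.5)^2 + max`` — peak CUE at
      g = 0.5, falling to the minimum at g = 0 and g = 1.
    * ``unimodal_0.05``: the same parabola re-centred at g = 0.05 (the
      global median growth rate), descending branch clipped at the bounds.
    * ``linear_positive`` / ``linear_negative``: interpolate between the
      bounds over the observed growth range [g_lo, g_hi].
    * ``exponential_decline``: ``min + range * exp(-g / g_mid)`` with
      ``g_mid`` the median observed growth (the decay scale).

    All outputs are clipped to [cue_min, cue_max].
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("growth rates must be non-negative")
    if not cue_min < cue_max:
        raise ValueError(f"CUE bounds out of order: {cue_min} >= {cue_max}")
    rng = cue_max - cue_min
    if form == "unimodal_0.5":
        cue = -4.0 * rng * (g - 0.5) ** 2 + cue_max
    elif form == "unimodal_0.05":
        cue = -4.0 * rng * (g - 0.05) ** 2 + cue_max
    elif form in ("linear_positive", "linear_negative"):
        if g_lo is None or g_hi is None:
            g_lo, g_hi = float(g.min()), float(g.max())
        span = g_hi - g_lo
        t = np.clip((g - g_lo) / span, 0.0, 1.0) if span > 0 else np.full_like(g, 0.5)
        cue = cue_min + rng * t if form == "linear_positive" else cue_max - rng * t
    elif form == "exponential_decline":
        if g_mid is None:
            g_mid = float(np.median(g))
        if g_mid <= 0:
            raise ValueError("exponential decline needs a positive decay scale")
        cue = cue_min + rng * np.exp(-g / g_mid)
    else:
        raise ValueError(f"unknown CUE form {form!r}; expected one of {CUE_FORMS}")
    return np.clip(cue, cue_min, cue_max)


def cue_bounds(
    community_cues,
    constrained: bool = True,
    unconstrained: tuple[float, float] = UNCONSTRAINED_BOUNDS,
) -> tuple[float, float]:
    """CUE bounds for one replicate group: (min, max) of the group's
    community CUE values when constrained, else the fixed global bounds."""
    if not constrained:
        return unconstrained
    vals = np.asarray(community_cues, dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if not lo < hi:
        # degenerate group (e.g. a single sample): open a token interval
        eps = max(1e-6, abs(hi) * 1e-6)
        lo, hi = lo - eps, hi + eps
    return lo, hi


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------


def per_capita_respiration(g, cue, beta: float = BETA_MAINTENANCE):
    """Growth and maintenance per-capita respiration:
    ``r_g = g/CUE - g`` and ``r_m = beta * r_g``."""
    g = np.asarray(g, dtype=float)
    cue = np.asarray(cue, dtype=float)
    if np.any(cue <= 0) or np.any(cue > 1):
        raise ValueError("CUE must lie in (0, 1]; check bounds configuration")
    r_g = g / cue - g
    return r_g, r_g * beta


def taxon_respiration(p, r_g, r_m):
    """Respired CO2-C per taxon (ug C g^-1 wk^-1):
    ``R_i = P_i * r_g + P_i * r_m``."""
    p = np.asarray(p, dtype=float)
    return p * np.asarray(r_g, float) + p * np.asarray(r_m, float)


def null_respiration(
    abundances: pd.DataFrame,
    measurements: pd.DataFrame,
) -> tuple[float, pd.DataFrame, float]:
    """Abundance-only null model: fit measured respiration on total 16S
    abundance through the origin across samples, then allocate
    ``R_i = N_i * slope``.

    ``abundances``: per (sample_id, asv_id) final copies (column ``n_t``).
    Returns (slope, per-taxon frame with ``r_null_ug``, fit R^2).  R^2 is
    computed against the centred total sum of squares, so a zero-intercept
    fit of uncorrelated data can score near or below zero.
    """
    totals = abundances.groupby("sample_id")["n_t"].sum().rename("n_total")
    df = measurements.set_index("sample_id").join(totals, how="inner")
    if len(df) < 2:
        raise ValueError("need at least 2 samples for the abundance null model")
    x = df["n_total"].to_numpy(dtype=float)
    y = df["co2_ug_c_g_wk"].to_numpy(dtype=float)
    if np.all(x == 0):
        raise ValueError("all abundances are zero")
    slope = float((x * y).sum() / (x * x).sum())
    resid = y - slope * x
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else np.nan
    out = abundances.copy()
    out["r_null_ug"] = out["n_t"] * slope
    return slope, out, r2


# ---------------------------------------------------------------------------
# CUE model selection
# ---------------------------------------------------------------------------


@dataclass
class CueModelSpec:
    """A candidate growth->CUE functional form.

    ``bounds`` may be None (derive from community CUE per group when
    constrained, fixed global bounds otherwise), a (min, max) tuple applied
    to every group, or a dict keyed by (ecosystem, treatment).
    """

    form: str
    constrained: bool = True
    bounds: tuple[float, float] | dict | None = None
    unconstrained_bounds: tuple[float, float] = UNCONSTRAINED_BOUNDS

    def group_bounds(self, group_key, group_community_cues) -> tuple[float, float]:
        if isinstance(self.bounds, dict):
            return self.bounds[group_key]
        if self.bounds is not None:
            return self.bounds
        if self.constrained:
            return cue_bounds(group_community_cues, constrained=True)
        return self.unconstrained_bounds


def default_candidates() -> list[CueModelSpec]:
    """The ten candidates: five functional forms, constrained and not."""
    return [CueModelSpec(form=f, constrained=c)
            for c in (True, False) for f in CUE_FORMS]


def _aic_z_regression(x: np.ndarray, y: np.ndarray, k: int = 3) -> tuple[float, bool]:
    """AIC of a simple linear regression between z-transformed vectors.

    Both variables are standardised, so the fit (and hence the AIC) is
    symmetric in x and y.  Returns (aic, degenerate_flag); a predictor with
    zero variance is degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for the AIC regression")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx <= 1e-12 * max(1.0, abs(x.mean())) or \
            sy <= 1e-12 * max(1.0, abs(y.mean())):
        return np.inf, True
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    fit = sm.OLS(zy, sm.add_constant(zx)).fit()
    rss = float((fit.resid ** 2).sum())
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k, False


def evaluate_cue_candidate(
    spec: CueModelSpec,
    per_taxon: pd.DataFrame,
    samples: pd.DataFrame,
    beta: float = BETA_MAINTENANCE,
) -> dict:
    """Score one candidate CUE form against measured respiration and
    community CUE.

    ``per_taxon``: one row per (sample, ASV) with ecosystem, treatment,
    sample_id, g_day, p_ug (production) and y (relative abundance).
    ``samples``: per sample measured co2_ug_c_g_wk and community_cue.
    """
    df = per_taxon.merge(
        samples[["sample_id", "community_cue"]], on="sample_id", how="inner")
    parts = []
    for key, grp in df.groupby(["ecosystem", "treatment"], sort=False):
        group_cues = grp.drop_duplicates("sample_id")["community_cue"]
        lo, hi = spec.group_bounds(key, group_cues)
        g = grp["g_day"].to_numpy()
        cue = per_taxon_cue(
            g, form=spec.form, cue_min=lo, cue_max=hi,
            g_lo=float(g.min()), g_hi=float(g.max()), g_mid=float(np.median(g)),
        )
        r_g, r_m = per_capita_respiration(g, np.maximum(cue, CUE_FLOOR), beta=beta)
        part = grp[["sample_id", "y"]].copy()
        part["cue_i"] = cue
        part["r_i"] = taxon_respiration(grp["p_ug"].to_numpy(), r_g, r_m)
        parts.append(part)
    scored = pd.concat(parts)
    scored["ycue"] = scored["cue_i"] * scored["y"]
    per_sample = scored.groupby("sample_id").agg(
        modeled_r=("r_i", "sum"), weighted_cue=("ycue", "sum"))
    per_sample = per_sample.join(
        samples.set_index("sample_id")[["co2_ug_c_g_wk", "community_cue"]],
        how="inner")
    aic_co2, bad1 = _aic_z_regression(
        per_sample["modeled_r"].to_numpy(), per_sample["co2_ug_c_g_wk"].to_numpy())
    aic_cue, bad2 = _aic_z_regression(
        per_sample["weighted_cue"].to_numpy(), per_sample["community_cue"].to_numpy())
    return {
        "form": spec.form,
        "constrained": spec.constrained,
        "aic_co2": aic_co2,
        "aic_cue": aic_cue,
        "aic_combined": 2 * aic_co2 + aic_cue,
        "degenerate": bad1 or bad2,
    }


def select_cue_model(
    candidates: list[CueModelSpec],
    per_taxon: pd.DataFrame,
    samples: pd.DataFrame,
    beta: float = BETA_MAINTENANCE,
) -> pd.DataFrame:
    """Rank candidate CUE forms by combined AIC.

    Each candidate's summed per-taxon respiration is regressed (after
    z-transformation) against measured respiration, and its
    abundance-weighted mean CUE against community CUE; the combined score
    is ``2 * AIC_co2 + AIC_cue``.  Delta-AIC columns are reported relative
    to each column's minimum, the combined delta being
    ``2 * dAIC_co2 + dAIC_cue``.  Degenerate candidates (zero-variance
    regressions) are flagged and ranked last.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate CUE specifications")
    rows = [evaluate_cue_candidate(spec, per_taxon, samples, beta=beta)
            for spec in candidates]
    report = pd.DataFrame(rows)
    ok = ~report["degenerate"]
    if not ok.any():
        raise ValueError("every candidate produced a degenerate regression")
    for col in ("aic_co2", "aic_cue"):
        report[f"delta_{col}"] = report[col] - report.loc[ok, col].min()
    report["delta_aic_combined"] = (
        2 * report["delta_aic_co2"] + report["delta_aic_cue"])
    report = report.sort_values(
        ["degenerate", "delta_aic_combined"], kind="mergesort"
    ).reset_index(drop=True)
    return report


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def compute_fluxes(
    kinetics: pd.DataFrame,
    traits: pd.DataFrame,
    measurements: pd.DataFrame,
    form: str = "unimodal_0.5",
    constrained: bool = True,
    bounds: tuple[float, float] | dict | None = None,
    beta: float = BETA_MAINTENANCE,
    carbon_fraction: float = CARBON_FRACTION,
    divisor: float = MASS_DIVISOR,
    zero_intercept: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full flux chain: production, community CUE, per-taxon CUE and
    respiration for every labeled sample.

    Returns ``(flux, community)``: per (sample, ASV) fluxes and the
    per-sample community table (18P, community CUE, measurements).
    """
    df = kinetics.merge(
        traits[["asv_id", "copy_number", "cell_mass_g"]], on="asv_id", how="inner")
    missing = set(kinetics["asv_id"]) - set(traits["asv_id"])
    if missing:
        logger.warning("%d ASV(s) lack genome traits and were skipped", len(missing))
    df["p_ug"] = biomass_production(
        df["dn_dt_wk"], df["copy_number"], df["cell_mass_g"],
        carbon_fraction=carbon_fraction, divisor=divisor)
    df["y"] = df["n_t"] / df.groupby("sample_id")["n_t"].transform("sum")

    slope = mbc_dna_slope(measurements, zero_intercept=zero_intercept)
    meas = measurements.set_index("sample_id")
    comm_rows = []
    for sample, grp in df.groupby("sample_id", sort=False):
        dna0 = float(meas.loc[sample, "dna0_ug_g"])
        r = float(meas.loc[sample, "co2_ug_c_g_wk"])
        p18 = community_18p(grp["eaf"], grp["y"], dna0, slope)
        comm_rows.append({
            "sample_id": sample,
            "ecosystem": grp["ecosystem"].iloc[0],
            "treatment": grp["treatment"].iloc[0],
            "p18_ug_c_g_wk": p18,
            "co2_ug_c_g_wk": r,
            "community_cue": community_cue(p18, r),
            "mbc0_ug_c_g": float(meas.loc[sample, "mbc0_ug_c_g"]),
            "dna0_ug_g": dna0,
        })
    community = pd.DataFrame(comm_rows)

    spec = CueModelSpec(form=form, constrained=constrained, bounds=bounds)
    parts = []
    for key, grp in df.groupby(["ecosystem", "treatment"], sort=False):
        group_cues = community.loc[
            (community["ecosystem"] == key[0]) & (community["treatment"] == key[1]),
            "community_cue"]
        lo, hi = spec.group_bounds(key, group_cues)
        g = grp["g_day"].to_numpy()
        cue = per_taxon_cue(
            g, form=form, cue_min=lo, cue_max=hi,
            g_lo=float(g.min()), g_hi=float(g.max()), g_mid=float(np.median(g)))
        r_g, r_m = per_capita_respiration(g, np.maximum(cue, CUE_FLOOR), beta=beta)
        part = grp.copy()
        part["cue"] = cue
        part["r_ug"] = taxon_respiration(part["p_ug"].to_numpy(), r_g, r_m)
        parts.append(part)
    flux = pd.concat(parts, ignore_index=True)
    flux["c_use_ug"] = flux["p_ug"] + flux["r_ug"]
    cols = ["ecosystem", "treatment", "replicate", "sample_id", "asv_id",
            "g_day", "eaf", "n_t", "y", "p_ug", "cue", "r_ug", "c_use_ug"]
    return flux[[c for c in cols if c in flux.columns]], community
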