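"""Quantitative stable isotope probing (qSIP) estimators.

This module turns per-fraction density-gradient data (fraction buoyant
density, total 16S copies from qPCR, per-ASV sequence counts) into
per-taxon isotope tracers and kinetics:

* weighted mean buoyant density per ASV in labeled and unlabeled samples,
* excess atom fraction (EAF) of the heavy isotope in each ASV's DNA,
* per-capita gross growth rate under an exponential growth model, and
* production of new 16S copies over the incubation.

The buoyant-density -> EAF conversion follows the standard 18O-qSIP
formulation: GC content is inferred from the unlabeled ("light") density,
GC sets the mean nucleotide molecular weight, and the relative density
shift of the labeled DNA gives the added isotope mass, expressed as atom
fraction excess above natural abundance.  All conversion constants live in
:class:`IsotopeConstants` and can be overridden.

Growth follows from the labeled/unlabeled partition of DNA: the fraction
of 16S copies that are newly synthesised during the incubation is
``EAF / a_w`` where ``a_w`` is the atom fraction of the heavy isotope in
the substrate (soil water for 18O), so the unlabeled copy number at time t
is ``N_t * (1 - EAF/a_w)`` and ``g = ln(N_t / N_light) / t``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: taxonomic ranks used throughout, most inclusive first
RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

#: days per week — growth rates are daily, fluxes are reported weekly
WEEK_DAYS = 7.0

#: paper defaults for the retained buoyant-density window (g cm^-3)
DENSITY_LO = 1.640
DENSITY_HI = 1.735


@dataclass(frozen=True)
class IsotopeConstants:
    """Constants of the density -> GC -> molecular-weight -> EAF chain.

    ``gc_intercept``/``gc_slope`` map unlabeled buoyant density to GC
    content; ``mw_gc_slope``/``mw_intercept`` map GC content to the mean
    molecular weight of a nucleotide at natural isotope abundance;
    ``max_mass_gain`` is the molecular-weight increase of a nucleotide
    when every atom of the traced element is the heavy isotope;
    ``natural_abundance`` is the heavy isotope's natural atom fraction.
    """

    gc_intercept: float = 1.646057
    gc_slope: float = 0.083506
    mw_gc_slope: float = 0.496
    mw_intercept: float = 307.691
    max_mass_gain: float = 12.07747
    natural_abundance: float = 0.002000429

    def gc_from_density(self, w_light):
        return (np.asarray(w_light, dtype=float) - self.gc_intercept) / self.gc_slope

    def density_from_gc(self, gc):
        return self.gc_intercept + self.gc_slope * np.asarray(gc, dtype=float)

    def mw_light(self, gc):
        return self.mw_gc_slope * np.asarray(gc, dtype=float) + self.mw_intercept


#: ready-made constant tables for the two isotopes used in the study
ISOTOPE_CONSTANTS = {
    "18O": IsotopeConstants(),
    "13C": IsotopeConstants(max_mass_gain=9.974564, natural_abundance=0.01111233),
}


def isotope_constants(isotope: str, **overrides) -> IsotopeConstants:
    """Return the constants table for ``isotope``, with optional overrides."""
    try:
        base = ISOTOPE_CONSTANTS[isotope]
    except KeyError:
        raise ValueError(
            f"unknown isotope {isotope!r}; expected one of {sorted(ISOTOPE_CONSTANTS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# fraction-level filtering and abundance conversion
# ---------------------------------------------------------------------------


def retain_fractions(
    fractions: pd.DataFrame,
    lo: float = DENSITY_LO,
    hi: float = DENSITY_HI,
) -> pd.DataFrame:
    """Keep fractions with buoyant density in ``[lo, hi]`` (inclusive).

    Samples whose fractions are all removed are flagged with a warning and
    excluded from the result.
    """
    if not lo < hi:
        raise ValueError(f"density bounds must satisfy lo < hi, got {lo} >= {hi}")
    dens = fractions["density_g_cm3"]
    kept = fractions[(dens >= lo) & (dens <= hi)]
    lost = set(fractions["sample_id"].unique()) - set(kept["sample_id"].unique())
    for sample in sorted(lost):
        logger.warning(
            "sample %s: all fractions outside [%g, %g] g cm^-3; sample excluded",
            sample, lo, hi,
        )
    return kept.reset_index(drop=True)


def filter_asvs(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    min_reps: int = 2,
    min_fracs: int = 5,
) -> pd.DataFrame:
    """Occupancy filter: retain an ASV in an ecosystem x treatment group iff
    it occurs (count > 0) in at least ``min_reps`` replicates of that group,
    each of those qualifying replicates showing it in at least ``min_fracs``
    fractions.  Retention is treatment-specific: an ASV removed from one
    treatment may be kept in another.

    Returns a frame with columns ``ecosystem``, ``treatment``, ``asv_id``.
    """
    meta = metadata.set_index("sample_id")
    df = fractions.loc[fractions["count"] > 0, ["sample_id", "fraction_id", "asv_id"]]
    df = df.join(meta[["ecosystem", "treatment", "replicate"]], on="sample_id")

    # fractions occupied per ASV within each replicate
    occ = (
        df.groupby(["ecosystem", "treatment", "replicate", "asv_id"], sort=False)
        ["fraction_id"].nunique().rename("n_fracs").reset_index()
    )
    qualifying = occ[occ["n_fracs"] >= min_fracs]
    reps_per_group = (
        meta.reset_index()
        .groupby(["ecosystem", "treatment"])["replicate"].nunique()
    )
    retained = []
    n_reps_ok = (
        qualifying.groupby(["ecosystem", "treatment", "asv_id"], sort=False)
        ["replicate"].nunique().rename("n_reps").reset_index()
    )
    for (eco, trt), grp in n_reps_ok.groupby(["ecosystem", "treatment"], sort=False):
        if reps_per_group.get((eco, trt), 0) < min_reps:
            logger.warning(
                "group %s:%s has fewer than %d replicates; treatment skipped",
                eco, trt, min_reps,
            )
            continue
        keep = grp.loc[grp["n_reps"] >= min_reps, "asv_id"]
        retained.append(
            pd.DataFrame({"ecosystem": eco, "treatment": trt, "asv_id": keep})
        )
    if not retained:
        return pd.DataFrame(columns=["ecosystem", "treatment", "asv_id"])
    out = pd.concat(retained, ignore_index=True)
    logger.info("ASV occupancy filter retained %d (group, ASV) pairs", len(out))
    return out


def absolute_abundance(fractions: pd.DataFrame) -> pd.DataFrame:
    """Convert per-fraction sequence counts to 16S copies per g dry soil.

    ``copies = count / sum(counts in fraction) * total qPCR copies of the
    fraction``.  Per-fraction copy totals are conserved exactly.  Fractions
    with zero total count contribute zero copies (logged).
    """
    out = fractions.copy()
    totals = out.groupby(["sample_id", "fraction_id"], sort=False)["count"].transform("sum")
    zero = totals == 0
    if zero.any():
        nz = out.loc[zero, ["sample_id", "fraction_id"]].drop_duplicates()
        logger.info("%d fraction(s) with zero total count contribute no copies", len(nz))
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(zero, 0.0, out["count"] / totals.replace(0, np.nan))
    out["copies"] = share * out["copies_per_g"]
    return out


# ---------------------------------------------------------------------------
# per-taxon density, EAF, growth
# ---------------------------------------------------------------------------


def weighted_mean_density(copies: np.ndarray, densities: np.ndarray) -> float:
    """Copy-weighted mean buoyant density of one ASV across fractions."""
    copies = np.asarray(copies, dtype=float)
    densities = np.asarray(densities, dtype=float)
    total = copies.sum()
    if total <= 0:
        raise ValueError("weighted mean density undefined: zero total copies")
    return float((densities * copies).sum() / total)


def excess_atom_fraction(
    w_lab,
    w_light,
    constants: IsotopeConstants = ISOTOPE_CONSTANTS["18O"],
    clip: bool = True,
):
    """Excess atom fraction of the heavy isotope from the density shift.

    ``EAF = (M_lab - M_light) / max_mass_gain - natural_abundance`` with
    ``M_lab = (W_lab / W_light) * M_light``.  With ``clip`` the estimate is
    clamped to [0, 1]; negative raw estimates (sampling noise pushing the
    labeled density below the light density) are counted and logged.
    """
    w_lab = np.asarray(w_lab, dtype=float)
    w_light = np.asarray(w_light, dtype=float)
    if np.any(w_light <= 0):
        raise ValueError("light density must be positive")
    gc = constants.gc_from_density(w_light)
    m_light = constants.mw_light(gc)
    m_lab = (w_lab / w_light) * m_light
    eaf = (m_lab - m_light) / constants.max_mass_gain - constants.natural_abundance
    if clip:
        n_neg = int(np.sum(eaf < 0))
        if n_neg:
            logger.info("%d negative EAF estimate(s) floored at 0", n_neg)
        eaf = np.clip(eaf, 0.0, 1.0)
    return eaf


def growth_rate(eaf, atom_fraction_substrate: float, t_days: float):
    """Per-capita gross growth rate (day^-1) from excess atom fraction.

    The fraction of copies newly synthesised during the incubation is
    ``EAF / a_w``; the unlabeled copy number at time t is
    ``N_light = N_t * (1 - EAF/a_w)`` and ``g = ln(N_t/N_light)/t``.
    Estimates where ``N_light >= N_t`` (EAF <= 0) give g = 0; EAF at or
    above ``a_w`` (complete turnover) is nudged just below it so g stays
    finite.
    """
    if t_days <= 0:
        raise ValueError("incubation duration must be positive")
    if not 0 < atom_fraction_substrate <= 1:
        raise ValueError("substrate atom fraction must be in (0, 1]")
    frac_new = np.asarray(eaf, dtype=float) / atom_fraction_substrate
    n_over = int(np.sum(frac_new >= 1))
    if n_over:
        logger.warning(
            "%d EAF estimate(s) at or above the substrate atom fraction; "
            "growth capped", n_over,
        )
    frac_new = np.clip(frac_new, 0.0, 1.0 - 1e-12)
    return -np.log1p(-frac_new) / t_days


def copy_production(n_t, g, t_days: float = WEEK_DAYS):
    """New 16S copies produced over the incubation, reported per week.

    ``dN/dt = N_t - N_t * exp(-g t)`` (equivalently ``N_t - N_0``), scaled
    to a weekly basis when ``t_days != 7``.
    """
    if t_days <= 0:
        raise ValueError("incubation duration must be positive")
    n_t = np.asarray(n_t, dtype=float)
    g = np.asarray(g, dtype=float)
    produced = n_t * (1.0 - np.exp(-g * t_days))
    return produced * (WEEK_DAYS / t_days)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

UNLABELED = "none"


def _per_sample_asv(table: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, ASV): weighted mean density and total copies."""
    tmp = table[["sample_id", "asv_id", "copies"]].copy()
    tmp["dx"] = table["density_g_cm3"].to_numpy() * table["copies"].to_numpy()
    agg = tmp.groupby(["sample_id", "asv_id"], sort=False)[["copies", "dx"]].sum()
    dropped = agg["copies"] <= 0
    if dropped.any():
        logger.info("%d (sample, ASV) pairs dropped: zero copies", int(dropped.sum()))
        agg = agg[~dropped]
    out = pd.DataFrame({
        "w_mean": agg["dx"] / agg["copies"],
        "n_t": agg["copies"],
    }).reset_index()
    return out


def estimate_kinetics(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    isotope: str = "18O",
    atom_fraction_substrate: float = 0.97,
    density_lo: float = DENSITY_LO,
    density_hi: float = DENSITY_HI,
    min_reps: int = 2,
    min_fracs: int = 5,
    constants: IsotopeConstants | None = None,
    light_scope: str = "treatment",
) -> pd.DataFrame:
    """Full qSIP chain: filter fractions and ASVs, convert to absolute
    abundances, and estimate per-replicate EAF, growth and copy production.

    Parameters
    ----------
    fractions
        Long table: sample_id, fraction_id, density_g_cm3, copies_per_g,
        asv_id, count.
    metadata
        Per sample: sample_id, ecosystem, treatment, replicate, isotope,
        t_days.  ``isotope == "none"`` marks unlabeled controls.
    isotope
        Label of the treated samples to analyse ("18O" or "13C").
    atom_fraction_substrate
        Atom fraction of the heavy isotope in the assimilated substrate
        (0.97 for the 18O water used in the study).  Growth rates are only
        computed for 18O.
    light_scope
        "treatment": mean light density across unlabeled replicates within
        each ecosystem x treatment (falling back to the ecosystem mean);
        "ecosystem": always pool unlabeled replicates across treatments.

    Returns
    -------
    DataFrame with one row per labeled sample x retained ASV:
    ecosystem, treatment, replicate, sample_id, asv_id, w_light, w_lab,
    eaf, n_t and, for 18O, g_day and dn_dt_wk.
    """
    if light_scope not in ("treatment", "ecosystem"):
        raise ValueError("light_scope must be 'treatment' or 'ecosystem'")
    constants = constants or isotope_constants(isotope)
    meta = metadata.set_index("sample_id")

    kept = retain_fractions(fractions, density_lo, density_hi)
    kept = absolute_abundance(kept)
    labeled_ids = meta.index[meta["isotope"] == isotope]
    light_ids = meta.index[meta["isotope"] == UNLABELED]
    if len(labeled_ids) == 0:
        raise ValueError(f"no samples labeled with {isotope!r}")
    if len(light_ids) == 0:
        raise ValueError("no unlabeled control samples for light densities")

    retained = filter_asvs(
        kept[kept["sample_id"].isin(labeled_ids)], metadata,
        min_reps=min_reps, min_fracs=min_fracs,
    )

    per = _per_sample_asv(kept)
    per = per.join(meta[["ecosystem", "treatment", "replicate", "isotope", "t_days"]],
                   on="sample_id")

    # light (unlabeled) mean density per ASV
    light = per[per["isotope"] == UNLABELED]
    w_eco = light.groupby(["ecosystem", "asv_id"])["w_mean"].mean()
    if light_scope == "treatment":
        w_trt = light.groupby(["ecosystem", "treatment", "asv_id"])["w_mean"].mean()
    lab = per[per["isotope"] == isotope].copy()
    lab = lab.merge(retained, on=["ecosystem", "treatment", "asv_id"], how="inner")

    key_eco = pd.MultiIndex.from_frame(lab[["ecosystem", "asv_id"]])
    w_light = pd.Series(w_eco.reindex(key_eco).to_numpy(), index=lab.index)
    if light_scope == "treatment":
        key_trt = pd.MultiIndex.from_frame(lab[["ecosystem", "treatment", "asv_id"]])
        w_light_trt = pd.Series(w_trt.reindex(key_trt).to_numpy(), index=lab.index)
        w_light = w_light_trt.fillna(w_light)
    lab["w_light"] = w_light
    n_miss = int(lab["w_light"].isna().sum())
    if n_miss:
        logger.warning(
            "%d labeled (sample, ASV) pairs lack an unlabeled light density; dropped",
            n_miss,
        )
        lab = lab[lab["w_light"].notna()]

    lab = lab.rename(columns={"w_mean": "w_lab"})
    lab["eaf"] = excess_atom_fraction(lab["w_lab"], lab["w_light"], constants)
    if isotope == "18O":
        t = lab["t_days"].to_numpy(dtype=float)
        if np.any(t <= 0):
            raise ValueError("t_days must be positive for growth estimation")
        # growth_rate at t=1 gives -log1p(-frac_new); each row has its own t
        lab["g_day"] = growth_rate(lab["eaf"], atom_fraction_substrate, 1.0) / t
        lab["dn_dt_wk"] = (
            lab["n_t"].to_numpy() * (1.0 - np.exp(-lab["g_day"].to_numpy() * t))
            * (WEEK_DAYS / t)
        )
    cols = ["ecosystem", "treatment", "replicate", "sample_id", "asv_id",
            "w_light", "w_lab", "eaf", "n_t"]
    if isotope == "18O":
        cols += ["g_day", "dn_dt_wk"]
    out = lab.reset_index(drop=True)[cols]
    logger.info("kinetics estimated for %d (sample, ASV) pairs", len(out))
    return out


def summarize_kinetics(kinetics: pd.DataFrame) -> pd.DataFrame:
    """Average per-replicate kinetics across replicates of each
    ecosystem x treatment group (mean aggregation)."""
    value_cols = [c for c in ("eaf", "g_day", "n_t", "dn_dt_wk") if c in kinetics]
    return (
        kinetics.groupby(["ecosystem", "treatment", "asv_id"], sort=False)[value_cols]
        .mean().reset_index()
    )
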