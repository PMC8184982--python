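"""Tests for trait assignment, the flux chain and CUE model selection."""

import numpy as np
import pandas as pd
import pytest

from taxoflux import (
    CUE_FORMS,
    CueModelSpec,
    assign_genome_traits,
    biomass_production,
    calibrate_cell_mass,
    cell_mass,
    community_18p,
    community_cue,
    compute_fluxes,
    cue_bounds,
    default_candidates,
    estimate_kinetics,
    mbc_dna_slope,
    null_respiration,
    per_capita_respiration,
    per_taxon_cue,
    select_cue_model,
    taxon_respiration,
)
from taxoflux.qsip_core import RANKS

from conftest import traits_from_truth, truth_bounds


def _lineage(**kw):
    base = {r: f"{r}x" for r in RANKS}
    base.update(kw)
    return base


class TestAssignGenomeTraits:
    def test_exact_match_wins(self):
        tax = pd.DataFrame([{"asv_id": "a1", **_lineage()}])
        ref = pd.DataFrame([
            {"asv_id": "a1", **_lineage(), "copy_number": 4, "genome_bp": 5e6},
            {"asv_id": "a2", **_lineage(), "copy_number": 9, "genome_bp": 9e6},
        ])
        out = assign_genome_traits(tax, ref)
        assert out.loc[0, "copy_number"] == 4
        assert out.loc[0, "assignment_rank"] == "exact"

    def test_family_median_when_genus_absent(self):
        tax = pd.DataFrame([{"asv_id": "q", **_lineage(genus="missing",
                                                       species="missing")}])
        ref = pd.DataFrame([
            {**_lineage(genus=f"g{i}", species=f"s{i}"),
             "copy_number": c, "genome_bp": g}
            for i, (c, g) in enumerate([(2, 3e6), (4, 4e6), (6, 8e6)])
        ])
        out = assign_genome_traits(tax, ref)
        assert out.loc[0, "genome_bp"] == 4e6
        assert out.loc[0, "copy_number"] == 4
        assert out.loc[0, "assignment_rank"] == "family"

    def test_no_match_falls_back_to_table_median(self, caplog):
        tax = pd.DataFrame([{"asv_id": "q",
                             **{r: f"other_{r}" for r in RANKS}}])
        ref = pd.DataFrame([
            {**_lineage(), "copy_number": 2, "genome_bp": 3e6},
            {**_lineage(), "copy_number": 8, "genome_bp": 7e6},
        ])
        with caplog.at_level("WARNING"):
            out = assign_genome_traits(tax, ref)
        assert out.loc[0, "copy_number"] == 5
        assert out.loc[0, "assignment_rank"] == "kingdom"

    def test_empty_reference_rejected(self):
        tax = pd.DataFrame([{"asv_id": "q", **_lineage()}])
        with pytest.raises(ValueError):
            assign_genome_traits(tax, pd.DataFrame(
                columns=["copy_number", "genome_bp"]))


class TestCellMass:
    def test_allometric_identity(self):
        assert cell_mass(10 ** 9.4) == pytest.approx(1.0)

    def test_scalar_oracle(self):
        want = 10 ** ((np.log10(4e6) - 9.4) / 0.24)
        assert cell_mass(4e6) == pytest.approx(want)
        assert want == pytest.approx(2.2e-12, rel=0.01)

    def test_strictly_increasing(self):
        g = np.linspace(1e6, 1.5e7, 50)
        assert (np.diff(cell_mass(g)) > 0).all()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cell_mass(0.0)


class TestCalibration:
    def _inputs(self):
        traits = pd.DataFrame({
            "asv_id": ["a", "b"], "copy_number": [2.0, 4.0],
            "genome_bp": [4e6, 6e6],
            "cell_mass_g": cell_mass(np.array([4e6, 6e6])),
        })
        n0 = pd.DataFrame({
            "sample_id": ["s1", "s1", "s2", "s2"],
            "asv_id": ["a", "b", "a", "b"],
            "n0": [1e8, 2e8, 2e8, 1e8],
        })
        est = (n0.merge(traits, on="asv_id")
               .assign(c=lambda d: d.n0 / d.copy_number * d.cell_mass_g * 0.2 * 1e6)
               .groupby("sample_id")["c"].sum())
        return traits, n0, est

    def test_fixed_mode_returns_ten(self):
        traits, n0, est = self._inputs()
        meas = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "mbc0_ug_c_g": (est / 10).to_numpy()})
        div, diag = calibrate_cell_mass(n0, traits, meas, mode="fixed")
        assert div == 10.0

    def test_estimated_mode_recovers_true_divisor(self):
        traits, n0, est = self._inputs()
        meas = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "mbc0_ug_c_g": (est / 10).to_numpy()})
        div, _ = calibrate_cell_mass(n0, traits, meas, mode="estimated")
        assert div == pytest.approx(10.0)

    def test_estimate_equal_to_mbc_gives_one(self):
        traits, n0, est = self._inputs()
        meas = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "mbc0_ug_c_g": est.to_numpy()})
        div, _ = calibrate_cell_mass(n0, traits, meas, mode="estimated")
        assert div == pytest.approx(1.0)

    def test_nonpositive_mbc_excluded(self):
        traits, n0, est = self._inputs()
        meas = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "mbc0_ug_c_g": [est.iloc[0] / 10, 0.0]})
        div, diag = calibrate_cell_mass(n0, traits, meas, mode="estimated")
        assert div == pytest.approx(10.0)
        assert diag["ratio"].isna().sum() == 1


class TestBiomassProduction:
    def test_zero_production(self):
        assert biomass_production(0.0, 2.0, 1e-12) == 0.0

    def test_arithmetic_oracle(self):
        # 1000 copies / 1 per cell * 1e-12 g * 0.2 / 10 = 2e-11 g = 2e-5 ug
        assert biomass_production(1000.0, 1.0, 1e-12) == pytest.approx(2e-5)

    def test_halving_copy_number_doubles_production(self):
        p1 = biomass_production(1000.0, 4.0, 1e-12)
        p2 = biomass_production(1000.0, 2.0, 1e-12)
        assert p2 == pytest.approx(2 * p1)

    def test_negative_production_rejected(self):
        with pytest.raises(ValueError):
            biomass_production(-1.0, 2.0, 1e-12)


class TestCommunityLevel:
    def test_18p_arithmetic_oracle(self):
        assert community_18p([0.5], [1.0], 2.0, 3.0) == pytest.approx(3.0)

    def test_18p_zero_when_unlabeled(self):
        assert community_18p([0.0, 0.0], [0.4, 0.6], 5.0, 2.0) == 0.0

    def test_18p_linear_in_eaf(self):
        one = community_18p([0.1, 0.2], [0.5, 0.5], 4.0, 2.0)
        two = community_18p([0.2, 0.4], [0.5, 0.5], 4.0, 2.0)
        assert two == pytest.approx(2 * one)

    def test_18p_requires_normalized_abundances(self):
        with pytest.raises(ValueError):
            community_18p([0.1], [0.5], 1.0, 1.0)

    def test_mbc_dna_slope_zero_intercept(self):
        meas = pd.DataFrame({"sample_id": ["a", "b", "c"],
                             "dna0_ug_g": [1.0, 2.0, 3.0],
                             "mbc0_ug_c_g": [10.0, 20.0, 30.0]})
        assert mbc_dna_slope(meas) == pytest.approx(10.0)

    def test_mbc_dna_slope_needs_two_samples(self):
        meas = pd.DataFrame({"sample_id": ["a"], "dna0_ug_g": [1.0],
                             "mbc0_ug_c_g": [10.0]})
        with pytest.raises(ValueError):
            mbc_dna_slope(meas)

    @pytest.mark.parametrize("p18, r, want", [
        (2.0, 2.0, 0.5), (3.0, 0.0, 1.0), (1.0, 3.0, 0.25)])
    def test_community_cue(self, p18, r, want):
        assert community_cue(p18, r) == want

    def test_community_cue_undefined_at_zero(self):
        with pytest.raises(ValueError):
            community_cue(0.0, 0.0)


class TestPerTaxonCue:
    """The unimodal form with the control-soil community CUE bounds."""

    BOUNDS = dict(cue_min=0.18, cue_max=0.53)

    def test_vertex_reaches_maximum(self):
        assert per_taxon_cue(0.5, "unimodal_0.5", **self.BOUNDS) == 0.53

    def test_zero_growth_reaches_minimum(self):
        # -4 * range * 0.25 = -range, so the parabola lands on the minimum
        assert per_taxon_cue(0.0, "unimodal_0.5", **self.BOUNDS) == pytest.approx(0.18)

    def test_linear_endpoints(self):
        g = np.array([0.1, 0.2, 0.4])
        up = per_taxon_cue(g, "linear_positive", **self.BOUNDS)
        assert up[0] == 0.18 and up[-1] == 0.53
        down = per_taxon_cue(g, "linear_negative", **self.BOUNDS)
        assert down[0] == 0.53 and down[-1] == 0.18

    def test_exponential_starts_at_max(self):
        got = per_taxon_cue(np.array([0.0, 0.05, 1.0]), "exponential_decline",
                            g_mid=0.05, **self.BOUNDS)
        assert got[0] == pytest.approx(0.53)
        assert got[1] == pytest.approx(0.18 + 0.35 * np.exp(-1))
        assert got[-1] >= 0.18

    @pytest.mark.parametrize("form", CUE_FORMS)
    def test_always_within_bounds(self, form):
        g = np.linspace(0, 2, 200)
        cue = per_taxon_cue(g, form, g_mid=0.05, **self.BOUNDS)
        assert (cue >= 0.18).all() and (cue <= 0.53).all()

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            per_taxon_cue(np.array([-0.1]), "unimodal_0.5", **self.BOUNDS)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            per_taxon_cue(0.1, "quadratic", **self.BOUNDS)

    def test_bounds_modes(self):
        assert cue_bounds([0.2, 0.5, 0.3]) == (0.2, 0.5)
        assert cue_bounds([0.2, 0.5], constrained=False) == (0.0, 0.7)


class TestRespiration:
    def test_perfect_efficiency_no_respiration(self):
        r_g, r_m = per_capita_respiration(0.3, 1.0)
        assert r_g == 0.0 and r_m == 0.0

    def test_arithmetic_oracle(self):
        r_g, r_m = per_capita_respiration(0.1, 0.5)
        assert r_g == pytest.approx(0.1)
        assert r_m == pytest.approx(0.001)

    def test_decreasing_in_cue(self):
        cues = np.linspace(0.1, 1.0, 30)
        r_g, _ = per_capita_respiration(0.2, cues)
        assert (np.diff(r_g) < 0).all()

    def test_zero_cue_rejected(self):
        with pytest.raises(ValueError):
            per_capita_respiration(0.1, 0.0)

    def test_taxon_respiration_oracle(self):
        assert taxon_respiration(2.0, 0.1, 0.001) == pytest.approx(0.202)
        assert taxon_respiration(0.0, 0.1, 0.001) == 0.0
        assert taxon_respiration(4.0, 0.1, 0.001) == pytest.approx(2 * 0.202)


class TestNullRespiration:
    def _proportional_case(self, c=2e-6, shuffle=False):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(5)]
        rows = []
        for s in samples:
            n = rng.uniform(1e6, 1e8, 4)
            for j, nj in enumerate(n):
                rows.append((s, f"a{j}", nj))
        ab = pd.DataFrame(rows, columns=["sample_id", "asv_id", "n_t"])
        totals = ab.groupby("sample_id")["n_t"].sum()
        meas = pd.DataFrame({"sample_id": totals.index,
                             "co2_ug_c_g_wk": totals.to_numpy() * c})
        if shuffle:
            meas = meas.sample(frac=1, random_state=1)
        return ab, meas

    def test_exact_proportionality_recovered(self):
        ab, meas = self._proportional_case()
        slope, out, r2 = null_respiration(ab, meas)
        assert slope == pytest.approx(2e-6)
        assert r2 == pytest.approx(1.0)
        per_sample = out.groupby("sample_id")["r_null_ug"].sum()
        want = meas.set_index("sample_id")["co2_ug_c_g_wk"]
        assert np.allclose(per_sample, want.loc[per_sample.index])

    def test_slope_invariant_to_sample_order(self):
        ab, meas = self._proportional_case(shuffle=True)
        slope, _, _ = null_respiration(ab, meas)
        assert slope == pytest.approx(2e-6)

    def test_dominant_taxon_takes_all(self):
        ab = pd.DataFrame({"sample_id": ["s1", "s1", "s2", "s2"],
                           "asv_id": ["a", "b", "a", "b"],
                           "n_t": [1e8, 0.0, 2e8, 0.0]})
        meas = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "co2_ug_c_g_wk": [10.0, 20.0]})
        _, out, _ = null_respiration(ab, meas)
        assert (out.loc[out["asv_id"] == "b", "r_null_ug"] == 0).all()

    def test_all_zero_abundance_rejected(self):
        ab = pd.DataFrame({"sample_id": ["s1", "s2"], "asv_id": ["a", "a"],
                           "n_t": [0.0, 0.0]})
        meas = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "co2_ug_c_g_wk": [1.0, 2.0]})
        with pytest.raises(ValueError):
            null_respiration(ab, meas)


def _selection_inputs(noiseless_ds):
    ds = noiseless_ds
    cfg = ds.config
    kin = estimate_kinetics(ds.fractions, ds.metadata,
                            density_lo=cfg.density_min,
                            density_hi=cfg.density_max)
    traits = traits_from_truth(ds.truth)
    flux, comm = compute_fluxes(kin, traits, ds.measurements,
                                bounds=truth_bounds(cfg))
    per_taxon = flux[["ecosystem", "treatment", "sample_id", "asv_id",
                      "g_day", "p_ug", "y"]]
    samples = comm[["sample_id", "co2_ug_c_g_wk", "community_cue"]]
    return per_taxon, samples, flux, comm


class TestSelectCueModel:
    def test_identical_specs_tie(self, noiseless_ds):
        per_taxon, samples, _, _ = _selection_inputs(noiseless_ds)
        spec = CueModelSpec("unimodal_0.5", True)
        report = select_cue_model([spec, spec], per_taxon, samples)
        assert report["aic_combined"].nunique() == 1
        assert (report["delta_aic_combined"] == 0).all()

    def test_combined_delta_is_weighted_sum(self, noiseless_ds):
        per_taxon, samples, _, _ = _selection_inputs(noiseless_ds)
        report = select_cue_model(default_candidates(), per_taxon, samples)
        ok = ~report["degenerate"]
        want = 2 * report.loc[ok, "delta_aic_co2"] + report.loc[ok, "delta_aic_cue"]
        assert np.allclose(report.loc[ok, "delta_aic_combined"], want)

    def test_needs_two_candidates(self, noiseless_ds):
        per_taxon, samples, _, _ = _selection_inputs(noiseless_ds)
        with pytest.raises(ValueError):
            select_cue_model([CueModelSpec("unimodal_0.5")], per_taxon, samples)

    def test_degenerate_candidate_ranked_last(self, noiseless_ds):
        per_taxon, samples, _, _ = _selection_inputs(noiseless_ds)
        # bounds collapsed to a point: the candidate's weighted-CUE column
        # has (numerically) zero variance and its regression is degenerate
        tight = CueModelSpec("unimodal_0.5", True, bounds=(0.5 - 1e-13, 0.5))
        report = select_cue_model(
            [CueModelSpec("unimodal_0.5"), tight], per_taxon, samples)
        assert not report["degenerate"].iloc[0]
        assert report["degenerate"].iloc[-1]
        assert np.isinf(report["aic_combined"].iloc[-1])


class TestComputeFluxes:
    def test_respiration_closed_loop(self, noiseless_ds):
        """At zero noise, summed per-taxon respiration reproduces the
        simulated bacterial CO2 exactly."""
        _, _, flux, _ = _selection_inputs(noiseless_ds)
        got = flux.groupby("sample_id")["r_ug"].sum()
        want = noiseless_ds.measurements.set_index("sample_id")["co2_bacterial_true"]
        rel = np.abs(got - want.loc[got.index]) / want.loc[got.index]
        assert rel.max() < 1e-9

    def test_uniform_cue_reconstruction(self):
        """If every taxon shares CUE = c the abundance-weighted sum is c."""
        y = np.array([0.2, 0.3, 0.5])
        cue = np.full(3, 0.37)
        assert float((y * cue).sum()) == pytest.approx(0.37)

    def test_constrained_cue_within_observed_community_range(self, noiseless_ds):
        ds = noiseless_ds
        cfg = ds.config
        kin = estimate_kinetics(ds.fractions, ds.metadata,
                                density_lo=cfg.density_min,
                                density_hi=cfg.density_max)
        flux, comm = compute_fluxes(kin, traits_from_truth(ds.truth),
                                    ds.measurements, constrained=True)
        merged = flux.merge(comm[["sample_id"]], on="sample_id")
        for (eco, trt), grp in flux.groupby(["ecosystem", "treatment"]):
            cues = comm.loc[(comm["ecosystem"] == eco)
                            & (comm["treatment"] == trt), "community_cue"]
            lo, hi = cue_bounds(cues)
            assert (grp["cue"] >= lo - 1e-12).all()
            assert (grp["cue"] <= hi + 1e-12).all()
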