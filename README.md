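# taxoflux

Taxon-resolved soil carbon flux from ¹⁸O quantitative stable isotope
probing (qSIP).

Soil respiration is usually modeled as a bulk process, yet it is carried
out by thousands of bacterial taxa whose contributions are wildly
unequal.  `taxoflux` turns density-fractionated 16S amplicon data from
¹⁸O-water incubations into per-taxon carbon budgets: growth rate,
biomass-carbon production, carbon use efficiency (CUE) and respired
CO₂-C, per gram of dry soil per week.  It is aimed at microbial
ecologists who run qSIP experiments and want to ask *which* organisms
process soil carbon, not just how much carbon is processed.

## The model

For each amplicon sequence variant (ASV) *i*, sequencing counts in each
CsCl gradient fraction are converted to absolute 16S copies using
per-fraction qPCR totals, and the copy-weighted mean buoyant density in
labeled (*W*ₗₐᵦ) and unlabeled (*W*ₗᵢ₉ₕₜ) samples gives the excess atom
fraction (EAF) of ¹⁸O in the taxon's DNA via the standard GC →
molecular-weight conversion.  Growth follows an exponential model: the
newly synthesised fraction of DNA is EAF/*a*_w (with *a*_w the ¹⁸O atom
fraction of soil water), so

    gᵢ = ln(Nᵢ,ₜ / N_light,i,t) / t            (day⁻¹)
    dNᵢ/dt = Nᵢ,ₜ − Nᵢ,ₜ e^(−gᵢ t)             (16S copies g⁻¹ wk⁻¹)

Copy production is scaled to carbon through genome traits: 16S copy
number per cell *C*ᵢ, genome length *G*ᵢ, and the allometric cell mass
log₁₀(*M*ᵢ) = (log₁₀ *G*ᵢ − 9.4)/0.24, of which 20 % is carbon, divided
by a calibration factor of 10 anchored to measured microbial biomass C:

    Pᵢ = (dNᵢ/dt) / Cᵢ · Mᵢ · 0.2 / 10          (µg C g⁻¹ wk⁻¹)

Community CUE comes from ¹⁸O-labeled biomass production
¹⁸P = Σᵢ(EAFᵢ·yᵢ)·DNA₀·f(MBC₀~DNA₀) and measured respiration *R*:
CUE = ¹⁸P/(¹⁸P+*R*).  Per-taxon CUE is modeled as a function of growth
rate; the selected form is a parabola constrained by the community CUE
range of each replicate group,

    CUEᵢ = −4·range·(gᵢ − 0.5)² + CUE_max,

and per-taxon respiration follows from growth and maintenance
components: r_g = g/CUE − g, r_m = 0.01·r_g, Rᵢ = Pᵢ(r_g + r_m).
Five candidate CUE forms (linear up/down, exponential decline, parabola
peaked at 0.5 or at 0.05 day⁻¹), each constrained or not, are compared
by a combined criterion 2·AIC_resp + AIC_CUE from z-scored regressions
of modeled against measured respiration and of abundance-weighted CUE
against community CUE.  An abundance-only null model (Rᵢ ∝ Nᵢ) provides
the contrast.

Because real deposits are enormous, the package ships a forward
simulator (`taxoflux.synthetic_data`) that generates the whole
experiment — lognormal communities, Gaussian density profiles shifted by
isotope incorporation, multinomial sequencing, qPCR noise, community
CO₂/MBC/DNA measurements — from the same equations the pipeline
inverts, with exported ground truth, so every stage is testable.

## Worked example

```python
import taxoflux as tf

cfg = tf.SimConfig(n_taxa=150, seed=42, simulate_13c=False)
ds = tf.simulate_dataset(cfg)
kin = tf.estimate_kinetics(ds.fractions, ds.metadata,
                           density_lo=cfg.density_min,
                           density_hi=cfg.density_max)
traits = ds.taxonomy[["asv_id"]].assign(
    copy_number=ds.truth.copies_per_cell,
    genome_bp=ds.truth.genome_bp,
    cell_mass_g=tf.cell_mass(ds.truth.genome_bp))
flux, community = tf.compute_fluxes(kin, traits, ds.measurements)
report = tf.select_cue_model(
    tf.default_candidates(),
    flux[["ecosystem", "treatment", "sample_id", "asv_id",
          "g_day", "p_ug", "y"]],
    community[["sample_id", "co2_ug_c_g_wk", "community_cue"]])

print(f"retained ASVs: {kin['asv_id'].nunique()} of {cfg.n_taxa}")
print(f"median growth rate: {kin['g_day'].median():.4f} day^-1")
ctrl = community[community["treatment"] == "control"]["community_cue"]
print(f"control community CUE: {ctrl.min():.3f}-{ctrl.max():.3f}")
best = report.iloc[0]
print(f"best CUE model: {best['form']} "
      f"({'constrained' if best['constrained'] else 'unconstrained'}), "
      f"delta-AIC to runner-up: "
      f"{report['delta_aic_combined'].iloc[1]:.2f}")
curve, frac = tf.consolidation_curve(
    flux[flux.sample_id == flux.sample_id.iloc[0]]["c_use_ug"].to_numpy())
print(f"fraction of taxa carrying half of C use: {frac:.3f}")
```

which prints:

```
retained ASVs: 72 of 150
median growth rate: 0.0375 day^-1
control community CUE: 0.217-0.361
best CUE model: unimodal_0.5 (constrained), delta-AIC to runner-up: 2.27
fraction of taxa carrying half of C use: 0.024
```

Read: of 150 simulated taxa, 72 pass the occupancy filter (present in ≥2
replicates, ≥5 fractions each); recovered growth rates center near
0.04 day⁻¹; community CUE in unamended soils spans 0.22–0.36 across
replicates; model selection correctly identifies the constrained
unimodal CUE–growth relationship the data were generated under; and
2.4 % of taxa account for half of all bacterial carbon use — the
consolidation the method exists to quantify.

The same pipeline runs from the shell on CSV/TSV inputs:

```sh
taxoflux simulate --config config.yml --out sim/ --seed 42
taxoflux growth --fractions sim/fractions.csv --meta sim/metadata.csv --out growth/
taxoflux flux --kinetics growth/kinetics.csv --taxonomy sim/taxonomy.tsv \
              --traits traits.tsv --measurements sim/measurements.csv --out flux/
taxoflux select-cue ... ; taxoflux stats --flux flux/flux.csv --out stats/
```

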