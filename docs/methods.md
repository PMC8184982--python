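# Methods

## Scope and model chain

`taxoflux` implements a taxon-resolved carbon-flux model for soil
bacteria measured by ¹⁸O-water quantitative stable isotope probing
(qSIP), together with a forward simulator used for validation.  The
estimation chain is: density-window and occupancy filtering → absolute
abundance per gradient fraction → per-taxon buoyant-density shift →
excess atom fraction (EAF) → per-capita growth rate → 16S copy
production → biomass-C production via genome traits and cell-mass
allometry → community carbon use efficiency (CUE) → per-taxon CUE from a
growth→CUE functional form → growth and maintenance respiration →
diversity and partition statistics.

Assumptions worth stating plainly: growth is exponential over the
incubation and strictly non-negative (gross cell division; negative
density shifts are treated as noise and floored); all 16S copies of a
taxon share one buoyant-density profile; newly synthesised DNA carries
the isotope at the substrate's atom fraction; traits (copy number,
genome size) are adequately predicted by taxonomy when no exact match
exists; and the maintenance share of energy use is a fixed proportion
β of growth respiration.

## Isotope conversion constants

The buoyant-density → EAF conversion uses the standard ¹⁸O-qSIP
formulation: GC content from unlabeled density (slope 0.083506,
intercept 1.646057 g cm⁻³), mean nucleotide molecular weight
0.496·GC + 307.691, maximum mass gain per nucleotide 12.07747 (¹⁸O) or
9.974564 (¹³C), and natural abundances 0.002000429 and 0.01111233.  All
five constants live in one frozen dataclass (`IsotopeConstants`) and can
be overridden per call.  Unlabeled ("light") densities are averaged
across the unlabeled replicates of an ecosystem × treatment group, with
an ecosystem-wide fallback; pooling scope is a parameter
(`light_scope`) because either convention is defensible.

## Key parameters

| parameter | default | units | meaning |
|---|---|---|---|
| density window | 1.640–1.735 (inclusive) | g cm⁻³ | retained gradient fractions |
| occupancy filter | ≥2 replicates, ≥5 fractions | — | ASV retention per ecosystem × treatment |
| `atom_fraction_water` | 0.97 | — | ¹⁸O atom fraction of incubation water |
| `t_days` | 7 | days | incubation length; fluxes reported per week |
| carbon fraction | 0.2 | — | carbon share of cell mass |
| mass divisor | 10 | — | calibration of trait-based biomass against MBC |
| β | 0.01 | — | maintenance respiration as share of growth respiration |
| unconstrained CUE bounds | (0, 0.7) | — | alternative (0, 0.85) supported via config |
| extraction efficiency | 0.45 | — | fumigation–extraction MBC conversion |

The cell-mass divisor can instead be *estimated* as the geometric mean
over samples of trait-based biomass C over measured MBC₀
(`calibrate_cell_mass(mode="estimated")`); on synthetic data generated
with divisor 10 the estimate recovers 10 exactly at zero noise.

The growth→CUE candidate forms are: the parabola
−4·range·(g−0.5)² + max (vertex at g = 0.5 day⁻¹); the same parabola
re-centred at 0.05 day⁻¹ (the typical global median growth rate), with
its descending branch clipped at the bounds; linear increase and
decrease anchored at the observed growth range of the replicate group;
and exponential decline min + range·e^(−g/ḡ) with ḡ the median observed
growth (a configurable decay scale).  Bounds are the min/max community
CUE of the replicate group (constrained) or fixed global limits
(unconstrained).  Model comparison z-scores both the modeled and
measured vectors, fits an ordinary least-squares line, computes
AIC = n·ln(RSS/n) + 2k with k = 3 (slope, intercept, error variance; the
constant k cancels in ΔAIC), and combines the two criteria as
2·AIC_resp + AIC_CUE; Δ columns are reported against each column's
minimum and the combined Δ is 2·ΔAIC_resp + ΔAIC_CUE.  Because both
variables are standardised, the fit depends only on their correlation
and is symmetric in x and y.  z-scoring is global across samples; the
growth rates entering the CUE forms are daily rates.

## The synthetic world

The generator emulates the full design: four ecosystems × three
amendments (control, glucose, glucose+N) × three labeled and three
unlabeled replicates, 18 fractions spanning 1.600–1.800 g cm⁻³, 7-day
incubation at 97 atom% ¹⁸O, sequencing depth 5×10⁴ reads per fraction,
10 % qPCR error, and lognormal taxon abundances (ln-σ 1.5) with growth
rates drawn lognormally (median 0.05 day⁻¹, ln-σ 0.8) *independently of
abundance*.  Growth passes through a smooth resource-limitation cap
g = cap·(1−e^(−g_raw/cap)) with cap 0.60 day⁻¹: uncapped lognormal
tails would imply >10⁴-fold weekly blow-ups and gram-scale CO₂ fluxes,
and the cap keeps ¹⁸O enrichment strictly below the water's atom
fraction while placing fast glucose responders in the vertex region of
the CUE parabola.  Replicate soils share the community but differ in
overall activity (lognormal factor, cv 0.5) and per-taxon abundance
(cv 0.2), reflecting the large replicate-to-replicate spread of
community CUE seen in field incubations.

Two design choices matter for interpretation:

1. **Moment-matched density profiles.** Each taxon's copies follow a
   Gaussian over the *discrete* fraction grid (sd 0.006 g cm⁻³, a
   typical within-taxon spread; the grid spacing is ~0.012, so a taxon
   occupies ~3–7 fractions and the ≥5-fraction filter removes rare,
   shallowly sequenced taxa, as it does on real data).  Because the
   estimator computes a discrete copy-weighted mean, profile centres are
   Newton-solved so that the discrete mean equals the intended centre
   exactly.  This removes grid aliasing and truncation bias and makes
   the zero-noise closed loop exact to machine precision — the isotope
   shift itself uses exactly the constants the estimator assumes, so
   noise is the only inverse-problem difficulty.

2. **Aggregation-consistent measured respiration.** Bacterial CO₂ is
   the sum of per-taxon respiration under the true CUE values and is
   recorded as ground truth (`co2_bacterial_true`).  *Measured* CO₂ is
   set so that the sample's community CUE — ¹⁸O-labeled production over
   production plus respiration — equals the abundance-weighted mean of
   the true per-taxon CUEs, floored at bacterial CO₂ inflated by the
   non-bacterial fraction (0.2).  The excess over the bacterial sum is
   the non-bacterial share (fungal, root, abiotic respiration), which in
   real incubations makes measured respiration exceed the modeled
   bacterial component.  This construction makes the synthetic world
   self-consistent: the community CUE that the pipeline estimates from
   the measurements genuinely bounds the per-taxon CUE that generated
   them, so constrained-bound estimation and CUE-model selection are
   well-posed.  Without it (e.g. deriving measured CO₂ purely from the
   taxon sums), the community CUE implied by the measurements drifts to
   degenerate values and no functional form is identifiable — a
   limitation of the flux equations' feedback structure, not of the
   selection statistic.

What passing tests therefore show: the estimators exactly invert the
stated forward model, degrade gracefully under realistic sequencing,
qPCR, density and assay noise, and identify the generating CUE form in
a majority of replicated experiments under the stated design.  What
they do not show: robustness to features the generator omits — PCR and
primer bias, chimeras, compositional distortions of sequencing,
ultracentrifugation artefacts, taxon-specific density anomalies
(e.g. methylation), non-exponential growth, or trait databases that are
systematically wrong for uncultured lineages.

## Numerical choices and degenerate inputs

- Negative EAF estimates are clamped to 0 (counted and logged); EAF at
  or above the substrate atom fraction caps the new-DNA fraction at
  1 − 10⁻¹² so growth stays finite (logged).
- Evaluated CUE is floored at 10⁻⁶ before respiration: a nominal lower
  bound of exactly 0 in unconstrained mode would divide by zero.
- A replicate group whose community CUEs coincide gets a token interval
  (±10⁻⁶) so constrained bounds remain ordered; regressions whose
  variance falls below 10⁻¹² (relative) are flagged degenerate and
  ranked last rather than fitted.
- Pielou's evenness of a single positive entry is defined as 1 (the
  0/0 limit convention); zeros never count toward richness; Shannon
  entropy uses natural logarithms.
- Levene-type testing uses absolute deviations from the
  treatment × replicate cell median (Brown–Forsythe; mean-centering is
  an option), with the treatment-level F from a one-way ANOVA of those
  deviations.
- Fractions with zero total sequence count contribute zero copies;
  samples that lose every fraction to the density window are excluded
  with a warning; mass units cross g → µg exactly once, inside
  `biomass_production`.

## Validation sizes

The end-to-end checks run at desk scale, chosen to finish in minutes on
one CPU while keeping the statistics meaningful: closed-loop recovery at
200 taxa × 18 fractions × 3 replicates (zero noise; growth recovered to
~10⁻¹³ relative error); noisy recovery at the default depth/error
settings over 10 seeds (median growth error 1–4 %, bound 15 %);
CUE-model selection over 20 seeded experiments of 150 taxa under the
full 4-ecosystem design (the generating form ranks first in ≈75 % of
runs); the abundance-only null model contrast over 10 seeds; and a
1000-matrix brute-force audit of the occupancy filter.

## Known limitations

The ¹³C partition (glucose-derived fraction = ¹³EAF/a_g, applied to
total C use) is the simplest mass-balance reading of a one-line verbal
description and is flagged as a reconstruction.  The per-taxon
respiration equation multiplies a carbon flux by a per-capita rate, so
its absolute scale inherits that convention; comparisons against
measured respiration are therefore made on z-scores.  Whether growth
rates in the CUE forms should be daily or weekly is convention-dependent
(daily here); the unconstrained bound 0.7 vs 0.85 ambiguity is exposed
as configuration.  Trait assignment by taxonomic medians ignores
within-genus variance; the `assignment_rank` column records how coarse
each fallback was so users can filter.
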