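# Methods

## Closed-vessel tracer model

An incubation bottle (default: 250 mL serum bottle, 200 mL seawater,
50 mL headspace of synthetic air) receives a ¹³C-labelled substrate at
t = 0 and is sampled at 0, 6, 12, 24 and 48 h.  Each sampling withdraws
v_s = 5 mL of headspace gas and replaces it with methane-free synthetic
air.  The vessel is treated as fully equilibrated at every sampling
instant (bottles are mixed after each manipulation); a dimensionless
partition coefficient K_H (dissolved/gas-phase concentration at
equilibrium, default 0.032 for warm seawater, configurable) fixes the
headspace share of the methane inventory,

    f_g = V_g / (V_g + K_H · V_l),

so one sampling event removes the fraction φ = (v_s/V_g)·f_g of the
vessel's methane.  No kinetic gas-exchange model is applied.

**Excess ¹³C-CH₄.**  The quantity of interest is methane attributable to
tracer turnover: total CH₄ × (x¹³(t) − x¹³(0)), with the bottle's own t₀
atom fraction as baseline (not canonical natural abundance).  Negative
excess values are retained so that regression noise stays unbiased;
excess at t₀ is identically zero.  δ¹³C input is converted via
x¹³ = R/(1+R), R = (δ/1000 + 1)·R_VPDB, R_VPDB = 0.0111802; the
conversion is strictly monotone and inverts to < 1e-12.  Mole-fraction
(ppm) input is converted to amounts by the ideal-gas law at 1 atm and
the incubation temperature.

**Dilution correction.**  Two corrections are implemented.  The default,
`mass_balance`, is exact for any production history: the aliquot taken at
event j removed φ·M_j of the vessel excess M_j inferred from that
measurement, so cumulative production is E_k = M_k + φ·Σ_{j<k} M_j.  The
alternative, `factor`, is the conventional multiplier
D_k = (1−φ)^(−k); it is exact only for a pool entirely present before
the first sampling and over-corrects methane produced after earlier
events (≈ +20 % on a linear 0–24 h series under the default protocol).
The package reports D_k alongside either correction.  Both corrections
assume the replaced air re-equilibrates with the liquid before the next
sampling; whether repartitioning after replacement is part of "the
dilution factor" is not observable from the data, and the
mass-conserving formulation was chosen because it makes the corrector an
exact inverse of the forward process.  Methane oxidation inside the
vessel is *not* corrected; a first-order loss term exists in the
simulator to quantify the resulting underestimation of net rates.

## Rate inference

Ordinary least squares of excess vs time over the first four time points
(0–24 h), slope converted to per-day units.  Significance: one-sided
t-test of H₁: slope > 0 with df = n − 2 = 2, p ≤ 0.05, jointly with
R² > 0.81 (strict inequality).  At df = 2 the R² cut corresponds to
|t| > 2.920, essentially the same threshold as the one-sided t cut, so
the joint filter's null acceptance is at most the nominal 5 % (measured
≈ 3.4 % under the default measurement model, in which the baseline is
noise-free by construction).  Negative slopes are never significant and
never reported as consumption.  Accepted slopes are divided by the
labelling fraction of the substrate pool: 1.0 for methylphosphonate
additions (in-situ MPn unknown, assumed fully labelled — rates are
therefore potential net rates) and ~0.10 for ¹³C-DIC additions.

Series failing the filter are classed `insignificant` (net rate 0)
unless formation appears essentially only at the last fitted time point:
excess(24 h) > 0 and greater than `exp_ratio` (default 3) times the
larger of the intermediate points and a detection floor
(`detection_sd`, default the simulator's noise SD; with real data, the
SD of t₀ replicate blanks).  Such late-onset ("exponential") series get
net rate 0.  The threshold-3 operationalization of "clearly
late-onset" is a design choice; the class label does not affect any
downstream number since both classes carry zero rate.

Carbon fixation: rate = (A_POC(t) − A_POC(0)) / (A_DIC − A_POC(0)) ×
[POC] / Δt, with a validation error when the DIC labelling does not
exceed the initial biomass enrichment and a warning (not an error) for
negative uptake.

## Water chemistry

LOD = blank mean + 3 sample SDs (n−1).  Default LODs (nmol L⁻¹): Pi 10,
NH₄ 24, NOx 583, NO₂ 33 — configurable.  Pools: OP = TP − Pi,
DOP = OP − POP, NO₃ = NOx − NO₂; negative differences are floored at 0
and flagged.  Censoring: a below-LOD value is a `Censored` marker
carrying its LOD; arithmetic on censored operands yields censored
results, and N:P ratios are censored (never LOD/2-substituted) when
phosphate — or the whole nitrogen numerator — is below detection.  One
deliberate exception: OP/DOP derived with a censored Pi are reported as
numbers (Pi contributes at most its 10 nmol L⁻¹ LOD to a pool an order
of magnitude larger) with an `op_upper_bound_pi_censored` flag;
censoring them would censor the organic-phosphorus pools over the whole
upper water column and contradict how such profiles are reported.

## Statistics

Kruskal–Wallis (tie-corrected, χ² p, df = k − 1) for the omnibus;
pairwise unpaired Wilcoxon rank-sum tests, exact when both n ≤ 10 and
tie-free, else normal approximation with tie correction; BH step-up
adjustment applied once over all pairs of a family.  One-sided
directions are configuration, with defaults: +Pi tested for repression
(less than MPn), +NO₃ for enhancement (greater), depth contrasts
shallower-greater.  Replicate incubations are pooled (not averaged)
before testing, and zero rates from insignificant/late-onset incubations
stay in the groups.  For small samples an exact permutation p for H is
provided by full enumeration (pooled n ≤ 12).  Spearman correlation uses
average ranks, complete cases per pair, and reports pairs with < 4
complete cases as not estimable.

## Redfield coupling

Phosphate demand = carbon fixation / (C:P), C:P default 106.  MPn
demethylation liberates CH₄ and Pi 1:1, so percent support =
100 × CH₄ rate / demand, unclamped (values > 100 % mean liberation
exceeding demand).  Distribution summaries use type-7 (linear
interpolation) quartiles.  For reporting, demand is rounded to one
decimal and percentages to integers.  The default scope is surface
incubations against the surface carbon-fixation median; any subset can
be supplied.

## Marker genes

Counts are assumed post-clustering (one row per representative ORF) and
post-mapping, filtered at strictly > 80 % read identity.  TPM_i =
10⁶ · (c_i/l_i) / Σ_j (c_j/l_j).  phnJ relative abundance =
100 × Σ_phnJ c_i/l_i / Σ_recA c_i/l_i, i.e. per-cluster length
normalization *before* family summation (splitting a cluster into equal
halves leaves the result unchanged), assuming one recA copy per
bacterium.

## Synthetic data: what it emulates, what it does not

The vessel simulator advances the true excess pool interval by interval
(linear, late-onset geometric, or null production; optional first-order
oxidative loss), applies each subsampling event to the inventory, and
emits headspace CH₄ amounts and atom fractions over a background of
ambient methane at natural abundance.  Noise (default SD 0.05 nmol L⁻¹)
is injected in the excess domain — the quantity the regression consumes
— with the t₀ baseline exact; an atom-fraction-noise mode is the obvious
extension but measurement-domain noise keeps the filter's error rates
interpretable.  The campaign generator draws net rates lognormally
around the depth medians 0.40 / 0.30 / 0.07 / 0.06 nmol L⁻¹ d⁻¹
(surface / intermediate / DCM / below), with log-scale σ = 1.36 set from
the surface quartile ratio and per-depth zero-rate shares (0.10 above
the DCM, 0.30 at and below it) so that deep quartile-1 rates are zero
while surface quartile 1 stays quantifiable.  Phosphate is censored
(< 10 nmol L⁻¹) above and within the DCM and 100–400 nmol L⁻¹ below it;
phosphorus pool identities hold exactly by construction.  Count tables
are multinomial around specified length-normalized rates.

Not emulated: instrument physics (CRDS drift, calibration), bottle
effects, diel variability, real taxonomic composition, sequencing error.
Passing tests therefore demonstrate correctness of the arithmetic and
the statistical machinery under the stated error model, not field
accuracy of any particular rate.

## Numerical and scale choices

All generators run from a single `numpy` Generator seeded explicitly;
campaign runs are byte-reproducible and the manifest stores SHA-256
checksums of every output.  The test suite and the acceptance script use
a simulated campaign of 288 incubations and 10,000 null simulations for
the filter's error rate — sizes at which every quantity they assert is
stable across seeds at the stated tolerances while the whole suite runs
in well under a minute.  Degenerate inputs are errors, not NaNs:
non-increasing times, missing t₀ baseline, subsample ≥ headspace, zero
recA signal, all-zero counts, constant input to Shapiro–Wilk or to the
fluorescence calibration.  Exactly collinear regression input yields
p → 0 (rising) or 1 (not rising) rather than a 0/0 t-statistic.

## Known limitations

The equilibrium-partitioning treatment ignores transfer kinetics between
liquid and headspace between samplings; rates from vessels far from
equilibrium would be biased low.  The labelling-fraction correction is a
single scalar per treatment.  The late-onset rule is a heuristic on four
points.  The exact Wilcoxon path switches to the asymptotic
approximation in the presence of ties (common here, since zero rates
tie), which is the standard, but not exact, treatment.
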