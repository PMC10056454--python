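# Methods

## Electron-mole accounting

The package treats a sealed batch vial as a closed electron system. Each
species CcHhOoNn is assigned the electron count of its complete oxidation
half-reaction to CO₂ and H₂O (NH₃ as the nitrogen reference):

    CcHhOo + (2c − o) H₂O → c CO₂ + (4c + h − 2o) H⁺ + (4c + h − 2o) e⁻

giving `e = 4C + H − 2O − 3N` per mole. Water and CO₂ therefore carry
zero electrons and drop out of every sum automatically; N₂, a filler gas
whose formula value would be meaningless (−6), is flagged inert and
assigned zero. Dividing by the carbon count gives the degree of
reduction (e per C-mol): acetate 4, butyrate 5, caproate 16/3 ≈ 5.33,
ethanol and butanol 6. For the saturated mono-acid series CnH2nO2 this
is (6n − 4)/n, strictly increasing with chain length — chain elongation
moves product electrons up this ladder.

A batch is summarised by three statistics computed from start/end
measurements only:

* **yield** `Yᵢ = 100 · Δeᵢ / Σⱼ|Δeⱼ|`, where j ranges over compounds
  with net electron consumption. Product yields are positive, source
  yields negative and sum to exactly −100 by construction;
* **electron recovery** `100 · Σe(end) / Σe(start)` over all measured
  compounds; 100% means every electron fed is found in a measured
  product;
* **distribution** — each net product's share of total net-product
  electrons (sums to 100).

These obey the identity `ΣᵢYᵢ − 100 = 100·(Σe_end − Σe_start)/Σⱼ|Δeⱼ|`,
which the test-suite asserts on random ledgers: yields over-count or
under-count exactly insofar as recovery departs from 100%.

Start/end-only sampling means intra-batch cycling nets out: H₂ produced
by elongation and re-consumed by homoacetogenesis within the same batch
is invisible. This is inherent to the design, not a defect of the
implementation.

### Dead-band

Measurement noise can flip a near-zero change between "consumed" and
"produced" and thereby move a compound across the yield sign boundary.
Changes with `|Δe|` below a configurable fraction of total consumed
electrons (default 0.5%, the order of triplicate scatter) are classed as
unchanged. For noiseless data the dead-band is unnecessary and the
conservation tests disable it (`dead_band_fraction=0`), since zeroing a
genuinely produced trace compound would break the exact Σ-yields = 100
identity that noiseless data satisfies.

### Accounting conventions

* Concentrations are total species; acid/anion speciation is not
  resolved (pH is carried as metadata only).
* Biomass electrons are not tracked: recovery is over measured compounds
  only, so growth shows up as recovery < 100%.
* Initial amounts are the measured t₀ state (nominal additions plus
  inoculum carry-over), not nominal additions alone.
* Minor calibrated analytes (1,3-propanediol, lactate, formate) are
  registered but excluded from default reports.

## Gas phase

Headspace amounts follow the ideal gas law, `n = PV/RT` with
R = 0.082057 L·atm·mol⁻¹·K⁻¹; pressures are stored in atm with a
bar ↔ atm conversion (1 atm = 1.01325 bar). Headspace volume is vessel
volume minus working volume (300 − 100 = 200 mL serum vials;
500 − 165 = 335 mL activation flasks). Serum-vial loadings use the
310.15 K incubation temperature, at which the nominal per-gas amounts
(9.9 mmol H₂ at 70%, 1.4 mmol CO at 10%, 10.2 at 72%, 10.6 at 75%)
reproduce to one decimal. The activation-flask amounts (12.5/5.4/6.6
mmol at 51/22/27%) back-calculate self-consistently to ≈300 K, i.e.
gases added at ambient temperature before incubation, so flask
bookkeeping uses a 300.15 K reference; each vessel config can carry its
own reference temperature. Two printed loadings (3.9 mmol H₂ at 22% and
1.9 mmol CO at 11%) are not consistent with 1.8 atm/200 mL at any
plausible temperature and are treated as data discrepancies, not
reproduced.

The Syngas Quality Index `SQI = 2(%CO + %H₂)/(%CO + %CO₂)` is the e-mol
per C-mol of the feed gas (CO and H₂ donate 2 electrons; CO and CO₂
carry one carbon each). It is scale-invariant (percent or fractions) and
undefined for carbon-free mixtures (H₂/N₂), which is signalled as an
error rather than returned as infinity.

## Reaction network

Nine reactions cover acetogenesis (from CO₂/H₂ and from CO), acetate
reduction to ethanol, reverse β-oxidation to butyrate and caproate,
butyrate reduction to butanol, and ethanol oxidation. Every reaction is
verified balanced in C, H and O on construction, and electron balance is
checked independently (it is implied by element balance for C/H/O
species, but asserting both guards the arithmetic). The butyrate
elongation 5 EtOH + 3 HAc → 4 BA + 2 H₂ + 3 H₂O carries 84 electrons on
each side and releases 0.4 H₂ per ethanol; the caproate condensation
EtOH + BA → CA + H₂O releases none, which is why H₂-rich feeds favour
caproate once butyrate is available. Caproate formation is modelled as
the minimal 1:1 condensation; a 5:4 reverse-β-oxidation variant
releasing acetate and H₂ ships as an optional alternative
(`CAPROATE_RBO_VARIANT`) for users preferring that stoichiometry.

**Extent estimation.** Net production vectors over the measured
compounds (everything except water) are inverted to per-reaction extents
by non-negative least squares, `min ‖S_m ξ − Δ‖₂, ξ ≥ 0` — exact for
noiseless data when `S_m` has full column rank. The full nine-reaction
network is structurally rank-deficient over measured compounds: the
direct ethanol route from H₂/CO₂ equals homoacetogenesis followed by
acetate reduction (R3 = R1 + R5), and ethanol oxidation is the exact
reverse of acetate reduction (R9 = −R5). Start/end data cannot
distinguish these; the fitter reports rank and the null-space basis as a
warning rather than silently picking a solution. Fitting is therefore
done on the identifiable six-reaction sub-network {R1, R2, R5, R6, R7,
R8}, where R5 is read as the *net* acetate ↔ ethanol interconversion.

## Synthetic enrichment generator

The generator emulates the serial-transfer design: triplicate 300 mL
vials (100 mL broth, 1.8 atm, 37 °C), 3–4 transfers, an 18% inoculum
carry-over, and selection of the vial with the highest summed e-mol
yield of the target products (butyrate, caproate, butanol) as the next
inoculum. Headspace gas is freshly flushed each transfer; t₀ liquid
amounts are nominal additions plus carry-over of the winning broth.

Per-vial conversion is generated statistically, not kinetically: each
reaction's extent is drawn from an independent Gamma distribution
(mean/CV parameterisation, CV 0.3 for vial-to-vial biological
variability; Gamma for its non-negative support), truncated greedily in
declared reaction order against substrate availability (gas-consuming
reactions first, elongation next, reductions last — a substrate-
precedence stand-in), and applied through the stoichiometric matrix.
Measured amounts then receive multiplicative log-normal noise with CV
2%, the order of replicate scatter in triplicate batch data, applied to
both the t₀ and end samples.

Two extent regimes are built in:

* **transfer-0 default** — acetogenesis-dominated (homoacetogenesis
  mean 1.2 mmol, CO acetogenesis 0.3) with modest elongation (butyrate
  0.2, caproate 0.1) and trace solventogenesis (0.03), matching an
  unenriched consortium whose activation products are mostly acetate and
  butyrate with butanol in traces. Enrichment multiplies the three
  target-reaction means by a gain of 1.3 per transfer.
* **enriched culture** (`enriched_spec()`) — extents at final-transfer
  scale, back-calculated from typical end-of-enrichment product levels
  (≈2 g/L butyrate and caproate, ≈0.3 g/L butanol in 100 mL): butyrate
  elongation 0.85 mmol, caproate 1.2, butanol 0.35, net acetate
  reduction 0.6. This is the regime the extent-recovery study
  characterises, since extent fitting is a tool for analysing active
  (enriched) cultures.

The direct ethanol routes and ethanol oxidation default to zero extent:
being linearly dependent on the active reactions over measured
compounds, any conversion through them is attributed to the equivalent
identifiable combination anyway (see above).

With zero noise every simulated vial is exactly electron-balanced, so
ledger recovery is 100% and product yields sum to 100 — the end-to-end
conservation oracle asserted over 1000 seeds. All outputs are bitwise
reproducible given (seed, spec).

**What the generator does not emulate:** microbial community dynamics
and growth, gas–liquid transfer limitation, pH trajectories (initial pH
is metadata; its mechanistic influence on solventogenesis is out of
scope), intra-batch kinetics, incomplete analyte coverage (real
recoveries of 75–99% reflect biomass and undetected products; simulated
recoveries deviate from 100% only through measurement noise). Passing
tests therefore validate the *accounting* — conservation, invariances,
estimator behaviour under noise — not any biological prediction.

## Numerical choices

* Atomic masses: IUPAC 2021 standard weights rounded to 3 decimals
  (C 12.011, H 1.008, O 15.999, N 14.007).
* Reaction coefficients are exact rationals (`fractions.Fraction`);
  balance checks are exact, not tolerance-based.
* Gamma draws with CV = 0 degenerate to the mean; log-normal noise uses
  σ² = ln(1 + CV²) with mean-one correction.
* Feasibility truncation clips extents at `min(available/|ν|)` per
  substrate in declared order; `apply_extents` tolerates −1e-9 mmol of
  rounding before declaring an extent infeasible.
* NNLS via `scipy.optimize.nnls`; rank via `numpy.linalg.matrix_rank`
  at its default tolerance; null space via `scipy.linalg.null_space`.
* Yield/recovery denominators of zero (nothing consumed, zero initial
  electrons, no net product) raise explicit errors rather than returning
  NaN.

## Problem sizes

The statistical suites use 1000 noiseless vials for conservation, 200
fits for the extent-recovery study, and 100 seeded four-transfer series
(3 replicates each) for enrichment monotonicity; each completes in
seconds, and the sizes are large enough that the reported medians and
means are stable to well within the asserted margins across seeds.

## Known limitations

* Yields, recovery and distribution are only as meaningful as the
  analyte coverage; unmeasured sinks (biomass, undetected products)
  depress recovery and inflate nothing — the statistics make missing
  electrons visible but cannot attribute them.
* Extent estimation assumes the network is correct and complete;
  conversion through reactions outside the fitted set is forced onto
  the nearest non-negative combination of fitted ones.
* The plain (unweighted) least-squares objective weights all measured
  compounds equally in mmol, so high-abundance gas pools dominate the
  fit; extents much smaller than the absolute noise on those pools
  (≈0.02 × amount) are recovered with proportionally larger relative
  error.
* The enrichment gain is a phenomenological selection model; it does not
  arise from competition between community members.
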