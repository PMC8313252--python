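# Methods

This note documents the models behind `phytascreen`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices a maintainer should know about.

## Stereochemistry and the class model

A species is a subset of the ring carbons {1..6} bearing phosphate. The
only symmetry applied is the ring mirror σ: 1↔3, 4↔6 with 2 and 5 fixed —
the unique convention under which the meso InsP5 species are the 2-OH and
5-OH forms and the enantiomeric pairs are 1/3-OH and 4/6-OH, as the
column resolves them. Orbits under σ are the chromatographic classes:
40 in total by Burnside's lemma ((2⁶+2⁴)/2), distributed 1/4/9/12/9/4/1
over levels 6..0. D/L enantiomers are never distinguished (the detection
is achiral); any enantiomer-specific input maps to its orbit.

Naming: InsP5 classes use missing-position bracket notation
(`InsP5 [4/6-OH]`); all other classes are `Ins(locants)Pn` using the
orbit member with the lexicographically smallest locant sequence, with a
`d/l-` prefix for pairs. This is deterministic and matches the dual
labels conventionally printed for pairs (e.g. 1256/2345).

Lumping: by default levels 3, 2 and 1 each collapse to a single
chromatographic class — the gradient resolves a single InsP3 region, and
InsP1 co-elutes with inorganic phosphate at the solvent front, so those
two always pool as `Pi/InsP1`. Unlumped enumeration remains available
(`lumping=False`). Free inositol carries no phosphate, gives no detector
response, and is excluded from chromatographic profiles; its amount is
implied by mass balance.

## Kinetics

The enzyme model is memoryless and distributive: the preference weight
for removing phosphate *p* depends only on *p*, not on the current
species, and the removal rate from species *S* is k·w(p), first order in
*S* (substrate far below Km; no saturation, no processivity). This is
the minimal model that generates the observed pathway biases; only the
ratios of weights carry positional information (doubling all weights and
halving k leaves trajectories unchanged). A hook for species-conditional
behaviour would require per-species weights and deliberately does not
exist — terminal products can still be expressed by zero weights.

A community adds: mixing weights per enzyme; first-order sorption of
InsP6 only (the most strongly bound species) into an inert pool;
first-order uptake of free Pi; and a logistic activation
1/(1+exp(−(t−t_lag)/τ)) scaling all enzyme rates, with τ = 0.25 day.
`t_lag = 0` means no lag (activation ≡ 1), not a logistic centred at
zero, which would halve rates at t = 0. Sorption and uptake are treated
as abiotic/constitutive and are not lagged.

The full state — 64 species, sorbed pool, Pi pool, cumulative uptake —
is linear, so the default propagator is the matrix exponential of the
augmented generator: exact between grid points for lag-free communities,
midpoint-activated substeps of 0.01 day under a lag (second-order in the
activation profile, which is ample at τ = 0.25). A classical fixed-step
RK4 integrator (step 0.001 day) exists as an independent cross-check; no
stochastic simulation, because abundances are ensemble concentrations.
Invariants enforced by tests: total inositol and total phosphate are
conserved to 1e-6 relative; abundances stay non-negative within 1e-9.

Pathway flux is a dynamic program down the DAG: flux(InsP6) = 1, split at
each species proportionally to its positive weights. Per-level fluxes
each sum to one unless a terminal product strands flux. The ODE and the
DP are connected by an oracle test: out-rate × ∫x_S dt equals the DP
visit probability.

## Chromatography

Forward model: each class contributes `amount × response` area in a
Gaussian at its retention time; baseline is flat; noise is white and
seeded. Peak widths default to σ = 0.25 min.

Default retention table (minutes): `Pi/InsP1` 2.8 (solvent front),
InsP2 8.0, InsP3 14.0, the seven standards-ladder InsP4 classes at
18.0–24.0 in ladder order, the two orbits absent from the acid-reflux
ladder (`Ins(1,2,3,5)P4`, `Ins(1,3,4,6)P4`) in configurable slots at
25.0/26.0, InsP5 2-OH 27.0 / 1/3-OH 28.0 / 4/6-OH 29.5 / 5-OH 31.0, and
InsP6 37.0. Only 2.8, 28 and 37 are anchored to the emulated gradient;
the rest are plausible defaults, monotone with phosphate number, and all
config-overridable. Whether 2-OH elutes before 1/3-OH is not anchored;
the default places it earlier. The two extra InsP4 slots are included by
default because promiscuous (MINPP-like) communities route real flux
through those orbits and synthesis requires an entry for every nonzero
class.

Response model: equal molar response by default — percentage statements
about profiles are mole-fraction statements, and the detection chemistry
is deliberately not modelled. A per-phosphate proportional model is
available.

Inverse path: Savitzky–Golay smoothing (window 11, polyorder 3); local
maxima above a floor that is the larger of 5× the estimated noise (MAD
of first differences) and 0.5% of the tallest excursion; parabolic apex
interpolation; peaks closer than 0.3 min merge keeping the taller apex.
Integration is trapezoidal over ±3σ windows bounded by midpoint valleys
toward neighbouring peaks, baseline-subtracted *without* pointwise
clipping so negative noise excursions cancel and the area estimator
stays unbiased; a final negative area clips to zero. Assignment is
nearest retention-time entry within a 0.4 min tolerance (validated to be
below half the minimum inter-class gap); two peaks assigned to one class
co-elute — the taller keeps the class and the areas pool. Unassigned
peaks are carried on the output, never dropped.

A detected, assigned peak counts as "an identified intermediate" when
its mole fraction of total inositol phosphate reaches θ_report = 1%.

## Classification

The cascade (all gates config-exposed, defaults in parentheses):

1. InsP6 loss below the activity threshold (5% of starting) →
   `NO_ACTIVITY`.
2. InsP5 shares among total InsP5; dominance = share ≥ 0.5 and ≥ 2× the
   runner-up.
3. Dominant 1/3-OH → `PHYTASE_3`; dominant 4/6-OH with 5-OH share < 5% →
   `PHYTASE_4_6`; dominant 5-OH → `PHYTASE_5`; dominant 2-OH →
   `UNCLASSIFIED_2POS` (no known phytase class starts at the 2-position).
4. Dominant 4/6-OH with 5-OH ≥ 5% and 1/3-OH < 5% → `MINPP_LIKE`.
5. Otherwise `MIXED_COMMUNITY`; when ≥ 3 InsP5 and ≥ 3 InsP4 classes
   exceed θ_report the evidence notes that a single promiscuous MINPP is
   an equally compatible reading — the same multi-peak pattern arises
   from one promiscuous enzyme or several specific ones, and the method
   alone cannot separate them, so the label takes the cascade value and
   the note preserves the ambiguity.

The numeric gates operationalize qualitative descriptions ("dominant",
"smaller", "little to no"); the 5% MINPP gate in particular is a free
choice with no quantitative anchor. One case falls outside the cascade:
InsP6 lost with *no* InsP5 intermediate above threshold (strong sorption,
or turnover already complete). It returns `MIXED_COMMUNITY` with an
explicit note naming sorption/complete turnover, because position-of-
attack classification is genuinely impossible there.

Classification is invariant to overall profile scaling and to inclusion
or exclusion of the Pi pool (shares are internal to InsP5).

## Synthetic data and calibration

The clean substrate is 95% InsP6 + 5% InsP5 [1/3-OH] — the typical
contamination of a purified phytate preparation; the `commercial` preset
adds lower inositol phosphates and free Pi and fails QC by construction.
In scenario simulations the substrate ships species-resolved, with the
1/3-OH contaminant as the d-1-OH enantiomer: the column cannot
distinguish the pair, but downstream products differ, and this member is
the one consistent with the AppA-type isolate showing exactly two InsP4
products (the dominant d/l-Ins(1,2,5,6)P4 — locants 2345 in its other
notation — and minor d/l-Ins(1,2,3,4)P4) after it consumes the impurity
along with the phytate. Class-level (racemic) initial states remain the
default everywhere else.

Enzyme presets (weights w₁..w₆; k in 1/day): the β-propeller 3-phytase
(0.01, 0.01, 1.0, 0.01, 0.01, 0.01; k 0.2), the AppA-family 6-phytase
(0.20, 0.001, 0.001, 0.001, 0.05, 10.0; k 0.2), the MINPP-like isolate
enzyme (0.02, 0.05, 0.02, 0.8, 0.5, 1.6; k 0.3), a broader MINPP
(0.3, 0.15, 0.3, 1.0, 0.6, 1.3; k 0.3), a 5-phytase
(0.01, 0.01, 0.01, 0.01, 1.0, 0.01; k 1.0), and a null strain (k 0).
Weight ratios carry the positional signal; the rates were chosen so the
two-day isolate scenarios sit in an informative regime — enough
degradation to clear the activity gate, enough InsP6 and intermediates
left to keep every diagnostic peak above the detection floor once the
growing Pi peak dominates the trace. The soil community mixes the three
isolate enzymes (mixing 3.0 / 0.25 / 1.5) behind a lag of t_lag 3.2 d,
τ 0.25 d, giving ~80% of InsP6 intact at day 3 and ~1% at day 5. The
sorbing soil uses sorption 1.5/d with Pi uptake 2/d and no enzymes; its
supplemented counterpart adds the 3-phytase (mixing 3.0) with sorption
0.4/d, so the 1/3-OH signature appears over 8 days while free Pi stays
scavenged. Relative enzyme abundances in real soils are unknown; the
mixing weights are calibration artifacts of the emulation, not
measurements.

Simulations for scenario rendering run on a 161-point grid over the
sampling span with the matrix-exponential propagator; chromatograms are
4001 samples (0–40 min at 0.01 min). Scenario noise defaults to S/N 50
on the tallest day-0 peak with per-day seeds spawned from the scenario
seed, so a scenario regenerates bit-identically.

What the generator does **not** emulate: retention-time drift and peak
asymmetry, baseline drift and gradient artifacts, extraction-efficiency
variation (absorbed by normalization), detector response chemistry,
microbial growth dynamics (the lag is a phenomenological stand-in),
Michaelis–Menten saturation, enantiomer-resolved chemistry, and the
plate-assay physics around cleared/non-cleared zones. Passing tests
therefore certify the analysis logic against the forward model's
assumptions, not against instrument-level artifacts.

## Known limitations

* The memoryless enzyme model cannot express species-dependent rates;
  real MINPPs are likely context-sensitive.
* The MINPP vs mixed-community distinction rests on a 5% gate with no
  quantitative anchor; treat `MINPP_LIKE` on community samples as "MINPP-
  compatible".
* Near-complete degradation starves the classifier: once intermediates
  fall below the detection floor the label degrades gracefully but
  informatively later sampling points should be preferred.
* Retention defaults outside the three anchored values are synthetic;
  real gradients need a measured table (`read_retention_table`).
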