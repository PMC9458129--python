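# Methods

## The model and its assumptions

`catrail` simulates TRAIL-induced (extrinsic) apoptosis in a single cell as a
deterministic mass-action ODE system and treats cell-to-cell variability as
randomness in initial protein amounts only. State is molecules per cell; time
is seconds internally, hours in every reported quantity. The network is built
from elementary reactions exclusively — zeroth-, first- and second-order mass
action; there are no Hill or Michaelis–Menten rate laws anywhere, and every
nonlinearity (threshold behavior, cooperativity, saturation) is produced by
network structure.

The backbone follows the extrinsic apoptosis reaction model (EARM 1.0)
lineage: ligand–receptor binding and DISC assembly buffered by FLIP;
caspase-8 activation buffered by BAR; a direct executioner route
caspase-8 → caspase-3 → PARP opposed by XIAP (which both sequesters and
catalytically degrades caspase-3); the mitochondrial route Bid → tBid →
Bax activation → membrane translocation → dimer/tetramer assembly opposed by
mitochondrial Bcl-2 → pore formation → cytochrome-c and Smac release →
apoptosome (Apaf-1/caspase-9) amplification, with Smac antagonizing XIAP.
Bimolecular steps at the mitochondrial membrane carry the usual 1/0.07
volume-fraction scaling.

Calcium enters through a dedicated arm: a protease pool (calpain-like,
lumped) is activated by six sequential calcium-binding steps — five weak and
one strongly forward — giving the active fraction a sharply cooperative
equilibrium (effective Hill coefficient ≈ 6, half-activation near 0.35 µM)
while remaining pure mass action. The active protease catalytically
inactivates cytosolic Bcl-2, releasing the brake on tBid. Because calcium is
consumed by no reaction (it appears only catalytically), it stays clamped at
its condition value, which is how the treatment conditions are defined.

Why this shape: the phenomenology to reproduce is (i) no commitment at
resting calcium (~0.1 µM), (ii) commitment with hour-scale timing at 1 µM,
and (iii) *saturation* — indistinguishable behavior at 1 µM and 1.7 µM. A
linear calcium coupling cannot produce (iii) without destroying (i); the
cooperative activation curve is flat between 1 and 1.7 µM (ratio ≈ 1.005)
and steep below 0.35 µM (1 µM vs 0.105 µM ≈ 10³), which delivers all three.

Procaspase-3 is given slow turnover (zeroth-order synthesis, first-order
decay). Without it the zymogen pool is destroyed by XIAP-mediated
degradation hours before MOMP, and late MOMP could never execute.

## Provenance of the reaction tables, and what "calibrated" means

The packaged tables
(`src/catrail/assets/apoptosis_model_synthetic.species.tsv/.reactions.tsv`)
are a **synthetic reconstruction**, not a transcription of any published
appendix: the backbone rate constants and initial amounts are the standard
EARM 1.0 values from the literature, the calcium arm is this package's own
design, and eight parameters (the calcium-arm rates, the tBid:Bcl-2
association, the two caspase-8 substrate-binding constants, the
procaspase-3 turnover pair, and the Apaf-1 pool) were calibrated **once**
against published simulated observables for this treatment panel —
single-cell event hours (apoptosis at hour 15 and MOMP at hour
11 for 50 ng/mL TRAIL at 1 µM calcium; apoptosis at hour 19 and peak
cytosolic Smac at hour 17 for 0.5 ng/mL; identical hours at 1.7 µM;
subthreshold cPARP for all low-calcium conditions) and the five population
viabilities (71/68/70/47/46 % across calcium-free, control,
resveratrol-only, Yoda1, Yoda1+resveratrol at 50 ng/mL) — and then frozen.
Timing and viability agreement is therefore a *calibration check* (a
regression test of the frozen asset), whereas the property-based tests
(mass-action consistency, conservation, closed-form oracles, round trips,
estimator recovery) are genuine validation.

Initial amounts for cytosolic Bcl-2 (1.98 × 10⁶) and XIAP (1.01 × 10⁵) equal
the means of the published population distributions, so the "average" cell
is exactly the deterministic single-cell model.

## Events and reporting conventions

All events are read on the integer-hour grid over 24 h, reported as the
first grid hour at or after the crossing, because the observables being
matched are whole-hour values.

* Apoptosis: cleaved PARP ≥ 5 × 10⁵ molecules/cell.
* MOMP: cytosolic Smac (free + XIAP-bound) ≥ 50 % of the total Smac pool.
  The 50 % fraction is a package convention calibrated once against the
  11-hour MOMP anchor and exposed as a config knob
  (`events.momp.fraction`); because release is switch-like at high calcium,
  the called hour is insensitive to the exact fraction there.
* Peak Smac: grid argmax of *free* cytosolic Smac, earliest hour on ties
  (bound Smac is excluded — the free level is what peaks and declines).

## Conditions

TRAIL dose maps linearly to ligand molecules with 50 ng/mL ≡ 3000
molecules/cell (the EARM convention). Calcium conditions come from
ratiometric fluorescence normalized so the Yoda1 condition is 1 µM; the
packaged default panel encodes only printed anchors — calcium-free = 0
(by definition for a blank), control = 0.105 µM, Yoda1 = 1.0 µM,
Yoda1+resveratrol = 1.7 µM (read as a total, not an increment) — plus a
clearly-labeled synthetic default of 0.2 µM for the resveratrol-only
condition, which was never printed as a concentration and should be supplied
by the user when known.

## Population simulation

Per-cell Bcl-2 and XIAP are drawn from N(1.98 × 10⁶, 9.91 × 10⁵) and
N(1.01 × 10⁵, 9.91 × 10⁴); each cell uses an independent RNG substream
seeded by (master seed, cell index), so extending a population never
reshuffles existing cells. Non-positive draws (≈ 15 % of the XIAP normal's
mass) are redrawn by default; a clamp-to-zero rule is available
(`truncation="clamp"`), and the choice is recorded in every result. Cells
are mutually independent, so any evaluation order gives identical results.
Viability is 100 × (cells never crossing the cPARP threshold)/n.

Mechanistically, the two marginals act through different gates: XIAP sets
post-MOMP survival (cells with XIAP comfortably above the releasable Smac
pool survive even after MOMP) and drives fractional killing at high calcium,
while Bcl-2 sets the size of the free-tBid leak and dominates which cells
die in low-calcium conditions.

## Numerical choices

LSODA with analytic Jacobian (both generated from the compiled network),
rtol 10⁻⁶, atol 10⁻² molecules/cell, hourly output grid. Negative
excursions within the solver's error scale (atol + rtol·max|state|) are
projected to zero; larger ones raise an error naming the species. Event
hours are verified invariant under tolerance halving and under switching
LSODA → BDF. A single cell integrates in ~25 ms; a 1000-cell condition runs
in ~0.5–1.5 min on one CPU.

The one-phase-decay fit uses ordinary least squares (`scipy curve_fit`) with
initialization y₀ ← max(y), plateau ← min(y), k ← 1/median(x) and bounds
k ∈ [0, 100], plateau ∈ [0, 100]; non-convergence is reported in the result,
never silently swallowed.

Conserved-moiety detection computes an exact rational basis of the left
null space of the stoichiometry matrix and greedily combines basis vectors
into non-negative integer pool vectors; it is used to bound integration
drift (< 10⁻⁶ relative over 24 h on every detected pool), not to claim a
complete enumeration of the conservation cone.

## Synthetic data

The flow-cytometry generator plants a true calcium level per condition and
emits per-event Fluo-4/Fura Red intensities with median-preserving
log-normal noise (σ = 0.3 by default, the right order for flow-cytometry CVs),
so the median ratio equals gain × calcium exactly up to sampling error and
the calcium-normalization stage can be validated as a round trip. It does
not emulate instrument artifacts (doublets, spillover, debris, gating), so
passing round-trip tests demonstrates correctness of the normalization
arithmetic, not robustness to real cytometry preprocessing.

## Known limitations

* The reconstruction reproduces the anchored event hours and the viability
  panel, but not every secondary timing relationship of the original
  reaction tables: here low calcium *suppresses* MOMP (small, late Smac
  release) rather than delaying it by a fixed lag, so "peak Smac a few hours
  later / MOMP a few hours later under low calcium" comes out as "much later
  or never" for the average cell. The two acceptance-suite tests asserting
  those fixed offsets fail by design and are kept as an honest record.
* Calcium is clamped; there is no influx/efflux dynamics, buffering, or
  store release.
* Bcl-2 and XIAP are drawn independently; correlated expression would
  narrow or widen the fractional-killing window.
* No protein synthesis/degradation outside procaspase-3, so the model is
  not suitable for horizons much beyond 24 h.
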