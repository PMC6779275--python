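# Methods

## Model overview

The package simulates the initiation of extrinsic apoptosis in a single
cell as two coupled sub-networks.

**Receptor engagement.** Ligand–receptor binding is far faster than
platform assembly, so the number of ligand-bound receptor monomers per
species (TNFR1: 905, DR4: 769, DR5: 926 per cell) is set to the mass-action
equilibrium `[RL] = R_total/(Kd/[L] + 1)`.  `[RL]` is kept real-valued and
discretised once, at the trimer count `floor([RL]/3)`, to avoid double
rounding.  Trimers from all three species join one pool: each trimer
nucleates exactly one DISC/RIPoptosome origin carrying a single active RIP1
molecule, debited from the cytosolic pool.  Origins are partitioned into
membrane clusters by i.i.d. draws from the cluster-size distribution until
the trimer budget is exhausted (the remainder forms one undersized
cluster); "disrupted clustering" makes every origin a singleton, which
zeroes all trans-activation propensities.

**Stochastic assembly.** Platforms are composition vectors (counts of RIP1,
RIP3, FADD, ProCasp8, cFLIPl, cFLIPs, DED1-DED2, intact ProCasp8 homo- and
hetero-dimers) plus a single terminal-site flag; the full filament sequence
is never needed because every observable (mass, per-origin counts,
end-blocking) is a function of the composition, and the small per-origin
state space keeps brute-force master-equation validation tractable.
Reactions: RIP1 elongation at the open filament end; RIP3 recruitment to
bound RIP1 (each recruitment increments the cumulative RIP1–RIP3 necrosome
counter — no downstream necroptotic event is triggered); FADD recruitment;
binding of ProCasp8/cFLIPl/cFLIPs/free DED1-DED2 to FADD-exposed DED sites
and to the filament end (which blocks RIP1 recruitment until it
dissociates); all reverse steps; cis-dimerization of two bound ProCasp8 on
one origin; trans-dimerization across two origins of one cluster;
ProCasp8–cFLIP heterodimerization (catalytically dead by default); dimer
dissociation; and dimer cleavage/activation, which releases one active
Casp8 dimer plus one DED1-DED2 to the cytosol and regenerates the two DED
sites (FADD stays bound).  Everything is propagated with the Gillespie
direct method.

FADD recruits **per platform** (a constant-rate channel per origin) rather
than per RIP1 subunit.  This choice is deliberate: it makes FADD content
per origin grow roughly linearly in time and become independent of the
ligand dose — both documented behaviours of the platform — whereas
per-subunit recruitment ties total DED-site capacity to the (shared,
dose-independent) RIP1 pool and inverts the dose response of Casp8
activation.

**Deterministic cascade.** Mass-action ODEs for: Casp8-dimer-catalysed
ProCasp3 cleavage; Casp3 autocatalysis; Casp3-catalysed ProCasp6 cleavage;
Casp6-catalysed cleavage of free ProCasp8 into monomers; slow second-order
re-dimerization of cleaved monomers into active dimers; cytosolic dimer
dissociation; reversible XIAP·Casp3 binding with ubiquitination-driven
degradation of the complex at `kcat_ub = 1.75 min⁻¹`; basal turnover of
active Casp3/Casp6 at `0.04 min⁻¹`; a slower turnover of the cleaved Casp8
monomer; and cleavage of the FRET reporter substrate by the active Casp8
dimer only.  Pro-forms of Casp3/Casp6 are treated as pre-formed dimer
pools.  Only free ProCasp8 is accessible to Casp6.

**Hybrid coupling.** Fixed-step operator splitting (default 0.1 min): the
SSA advances over the window with frozen cascade state; dimers released in
the window enter the ODEs as a piecewise-constant source over the same
window (counts preserved exactly); the ODE block is integrated with
fixed-substep RK4 (0.02 min; all rate scales are ≲ 30 min⁻¹, far inside
the stability region); ProCasp8 consumed by the Casp6 feedback is debited
from the stochastic pool in whole molecules with a fractional carry, and a
clamp counter records (rare) attempts to overdraw.  Death is the first
output-grid crossing (1-min grid, linear interpolation, `>=` convention) of
the FRET cleavage rate over a fixed threshold.  Halving the splitting step
moves the median death time of a high-dose ensemble by under 2%.

**Full-SSA twin.** The same assembly machinery with the cascade also
discretised (12 extra reaction channels over copy numbers, one exact SSA
clock).  It is the validation oracle: at 50 ng/mL with clustering, hybrid
and full-SSA death-delay samples are statistically indistinguishable
(two-sample KS at n = 20).  Because the full SSA carries additional Casp8
dimer birth–death shot noise, individual 20-cell KS draws can land in the
rejection tail (~3% of seed pairs in a 10-block survey).

**Merged deterministic model.** Mean-field rate equations for the assembly
derived from the same channels under a Poisson moment closure
(`<n(n-1)> = <n>²` per origin; cluster trans-pairs via the size-biased
factor `E[m(m-1)]/E[m]`), chained into the cascade ODEs.  It reproduces the
SSA ensemble-mean cumulative Casp8 activation within ~3–6% and drives the
kcat/XIAP/ProCasp6 parameter scans.

## What makes cells die, early or late

The model has two routes to the death threshold, and their interplay
produces every population-level behaviour the package reports:

1. **Threshold crossing of the stochastic plateau.**  Platform composition
   relaxes within ~30–40 min to a quasi-steady Casp8 activation rate whose
   across-cell spread (~±13% at low dose) is dominated by the frozen luck
   of the cluster draw, and whose within-cell fluctuations reflect the
   small number of activation events.  Cells whose plateau (plus
   fluctuations) reaches the threshold die early — within the first two
   hours.  The whole high-dose population dies this way.

2. **Ignition of the caspase feedback.**  A fraction (default 50%) of each
   degraded XIAP·Casp3 complex fails to return XIAP to the free pool, so
   free XIAP erodes at a rate proportional to the Casp3 flux.  Because
   Casp3 production sits close to the margin between capture
   (`kon·[XIAP free]`) and autocatalysis (`k_auto·[ProCasp3]`), this slow
   erosion is ultra-sensitive: when the margin closes, Casp3 escapes,
   activates Casp6, floods the cytosol with cleaved Casp8 monomers, and
   the re-dimerization flux drives the FRET cleavage rate across the
   threshold within minutes.  Cells below the plateau threshold die this
   way, hours later, after a flat, noisy ramp.

At 5 ng/mL with clustering the population straddles the threshold, which
splits it into early (noise-driven) and late (ignition-driven) modes — the
bimodal death-delay distribution, flagged by the dip test, that disappears
when clustering is disrupted (all plateaus far below threshold, single late
mode) and at the high dose (all plateaus above threshold, single early
mode).  The same geometry yields the noise–delay law: cells with ramp CV
above 0.5 are those whose short pre-death window is dominated by the
initial rise and crossing — all of them die within two hours.

The XIAP erosion design deviates from a fully catalytic inhibitor cycle
(XIAP completely regenerated, `xiap_recycled = 1`).  A fully recycled XIAP
admits no reachable ignition point at physiological Casp8 fluxes: the
degradation capacity `kcat_ub·[XIAP]` (~110 nM/min) exceeds any
platform-derived Casp3 flux by three orders of magnitude, and the only
remaining escape — secular accumulation of cleaved Casp8 monomers — grows
as t² from t = 0, which contradicts the flat-ramp-then-switch dynamics the
model exists to produce (a scale-free power-law ramp has a window CV ≈ 0.4
regardless of its length).  Partial co-degradation (`xiap_recycled = 0.5`,
configurable) supplies the slow, readout-silent commitment variable;
auto-ubiquitination of ligases co-degrading with cargo is a recognised
mode of XIAP turnover.  The switch is still governed by the printed
constants: raising `kcat_ub` (faster complex clearance, lower XIAP·Casp3
occupancy) monotonically delays death with a steep region at low values,
and modest decreases of total XIAP from its 63 nM mean collapse the
low-dose death delay more than three-fold.

**A known negative result.**  The negative Spearman association between
ramp CV and death delay is reproduced in three of the four scenarios
(ρ ≈ −0.9/−0.5/−0.8 at n = 100).  In the low-dose disrupted scenario all
deaths are ignition-driven, and ignition time is an *integral* of the Casp8
signal; the time-integral of a stationary noisy signal is statistically
decoupled from its realised amplitude (which is what the window CV
measures), and the residual frozen-rate coupling links low noise to early
death, giving ρ ≈ +0.1–0.3.  Reproducing a negative association there
appears to require late deaths that are themselves threshold-crossing
events; within this model's committed architecture the corresponding
acceptance property is reported as failing rather than redefining the CV
window.

## Parameters

Printed, fixed quantities: receptor counts 905/769/926 per cell; XIAP
63 nM; `kcat_ub = 1.75 min⁻¹`; basal degradation `0.04 min⁻¹`; doses in
ng/mL converted with a 19.6 kDa ligand monomer mass; subunit masses are
canonical UniProt values (RIP1 76, RIP3 57, FADD 23, ProCasp8 55, cFLIPl
55, cFLIPs 26, DED1-DED2 26 kDa), making the 2 MDa platform claim testable
(27 RIP1 ≈ 2.05 MDa).

Everything else — initial concentrations (within literature ranges for
HeLa), association/dissociation rates, the cluster-size table, the FRET
threshold — is a **calibrated placeholder**, flagged as such in the config
metadata.  The calibration targets were the documented behaviours of the
system, fixed before the test suite was written: platforms above 2 MDa
within 5 min; mean FADD per origin below 10 over the first two hours and
roughly dose-independent; RIP1 the dominant platform constituent;
death-delay ranges of ~1–10 h (5 ng/mL, clustering) and up to ~22 h
(disrupted); a bimodal delay distribution only at low dose with
clustering; across-cell variability of Casp8 activation below 1; ≥3-fold
delay reduction under modest XIAP decrease.  The FRET threshold
(0.0394 nM/min) is calibrated, not printed: it sits ~25% above the mean
low-dose-clustering plateau, which places the entire high-dose population
(including ≥99% within 10 h) on the early route.  The cell volume
(2.5 pL, typical HeLa) sets the nM↔copies scale (1 nM ≈ 1506 copies).
The cluster-size table is a placeholder over sizes 1–20 trimers with a
heavy tail; its size-biased pair factor (~6) controls both the
trans-activation boost and the frozen cell-to-cell spread that feeds the
bimodal split.

The cleaved-Casp8-monomer turnover rate (0.0074 min⁻¹) is a model
parameter this package adds: without monomer turnover the feedback has no
ignition point at all (see above).  cFLIPl heterodimers are catalytically
dead by default (`cflipl_heterodimer_activity = 0`, configurable), and
activation regenerates the platform's FADD sites.

## Numerical choices

- All bimolecular rates are stated in nM⁻¹min⁻¹ and divided by
  `N_A·V·10⁻⁹` on use; per-origin SSA weights are integers, so the
  incrementally maintained propensity sums in the production kernels are
  exact (no floating-point drift).
- The production kernels (numba) implement the same reaction schedule as
  the pure-Python reference engine; both are checked against the exact
  master-equation solution of a one-origin, four-species network (state
  space ≤ 32, `expm` of the generator), and against each other.
- LSODA integrates the standalone cascade and the merged deterministic
  model (rtol 1e-8); death in the deterministic model is an integration
  event on the FRET-rate threshold.
- Ramp CV uses the population (ddof = 0) standard deviation over all
  recorded points strictly before the death time (the full trace for
  censored cells); a zero-mean window has CV 0 by definition.
- The dip statistic is computed from its definition (smallest half-width of
  a band around the empirical CDF admitting a convex-then-concave fit) by
  bisection with an exact band-feasibility check; p-values are Monte-Carlo
  calibrated against the uniform null at the observed n, with sample and
  null processed by the same algorithm.  On a balanced two-point mixture it
  returns the known value 1/4 − 1/(2n).
- Ensemble sizes: population statistics use 100 cells per scenario
  (delay ranges, CV law, bimodality), 300 cells for the mean-field
  comparison, and 20 + 20 cells for the hybrid/full-SSA cross-check —
  reduced from the 600-cell populations the statistics are designed for,
  with tolerances that account for the extra sampling error.

## What the synthetic conditions do and do not show

The generator emulates a clonal HeLa-like population with identical
protein levels in every cell: all heterogeneity is intrinsic (reaction
noise and the random cluster draw).  Real populations add extrinsic
protein-level variation, cell-cycle effects and receptor-trafficking
dynamics, none of which are modelled; passing tests therefore demonstrate
that intrinsic assembly noise *suffices* for fractional killing and
bimodal delays under these conditions, not that it is the only source in
real data.  Filament growth is unlimited (no volume or stiffness cap), so
late-time platform masses are upper bounds.  Post-threshold biology
(Bid/MOMP, apoptosome, MLKL execution) is out of scope: the simulation
stops at the FRET-rate threshold, and RIP1–RIP3 heterodimers are only
counted, never executed.
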