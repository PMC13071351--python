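# Methods

## Model

Each local ecosystem (patch) *i* carries three stocks: inorganic
nutrients `N_i`, primary producers `P_i` and consumers `C_i`.  Producers
take up nutrients and consumers graze producers with saturating (Monod)
functional responses `f_P(N) = a_P N / (b_P + N)` and
`f_C(P) = a_C P / (b_C + P)`.  Fractions `r_P`, `r_C` of producer and
consumer mortality are recycled into the local nutrient pool; the rest
leaves the system, together with hydrological export `e_N N_i`.  Each
patch receives a constant nutrient input `I_N`.

Patches are coupled by two kinds of spatial flow, each encoded in an
n-by-n connectivity matrix whose entry `s_ij >= 0` (i != j) is the flow
entering patch *i* from patch *j* and whose diagonal is the outflow:

* passive **resource flows** of inorganic nutrients at rate `d_N`
  (matrix `S_N`), linking *nearby patches of different ecosystem types*;
* **consumer dispersal** at per-patch rates `d_C[i]` (matrix `S_C`),
  linking *distant patches of the same type*.

The dynamics per patch are

    dN_i/dt = I_N - e_N N_i + m_P r_P P_i + m_C r_C C_i - P_i f_P(N_i)
              + d_N (S_N N)_i
    dP_i/dt = P_i f_P(N_i) - m_P P_i - C_i f_C(P_i)
    dC_i/dt = C_i f_C(P_i) - m_C C_i + d_C[i] (S_C C)_i

Producer dispersal is assumed to act within a patch and is off by
default; `S_P` with rate `d_P` is available as a hook for relaxing
this assumption.

**Baseline parameters** (defaults of `ModelParams`): `I_N = 0.05`,
`e_N = 0.01`, `m_P = 0.05`, `m_C = 0.24`, `a_P = 1`, `b_P = 10`,
`a_C = 0.6`, `b_C = 6`, `r_P = r_C = 0.8`.  Rates are per unit time,
half-saturation constants in stock units.  With these values one
isolated patch has a unique stable interior equilibrium
`P* = b_C m_C / (a_C - m_C) = 4` exactly, and `(N*, C*)` from a
quadratic reduction (`N* ~ 0.5842`, `C* ~ 0.0866`); the implementation
derives the quadratic for arbitrary parameters and selects the root with
`N* > 0` (the other root is unphysical).  The time scale is set by the
slowest rate, `e_N = 0.01` (turnover time 100).

## Topologies

The **spatially nested** design places two ecosystem types (A, B) at
each of two (or more) locations, ordered `(A1, B1, A2, B2, ...)`:
resource flows connect the A-B pair within a location, dispersal
connects same-type patches across locations.  The **fully connected**
control keeps dispersal identical but lets resource flows connect every
patch pair, removing the scale contrast between the two flow types.

The published description does not fix whether `d_N` is a per-link or a
total-outflow rate.  The default here is *donor-normalized*
(`diagonal -1`, donated mass split equally among receivers), so every
patch emigrates at total rate `d_N` (resp. `d_C[i]`) regardless of
degree; this makes the nested and fully connected designs comparable at
equal rate constants, which the control comparison presupposes.  A
`per_link` convention is available; for the 4-patch nested design
(degree 1 everywhere) the two coincide, so the nested-topology results
are convention-independent.  Column sums of every connectivity matrix
are zero: transported mass is conserved in transit.  Patches joined by
a dispersal link must share one `d_C` value, otherwise the dispersal
flux itself would create or destroy consumers; `validate()` enforces
this and the other structural invariants.

## Numerical integration

The right-hand side is compiled (numba) and integrated with LSODA
(`scipy.integrate.odeint`): an Adams method that switches automatically
to BDF when the problem becomes stiff, covering the non-stiff/stiff
solver pairing commonly used for this kind of model with a single
method.  Default tolerances are `rtol = 1e-8`, `atol = 1e-10` — tight,
because heterogeneity detection compares patches at ~1e-4.  Evaluation
windows are sampled every 1.25 time units (limit-cycle periods here are
of order 300, so extrema are well resolved).  Trajectory values below
-1e-9 abort the run as a solver failure; smaller excursions are clipped
to zero for reporting.

Measured on this implementation: accumulated solver drift over
horizons of 1e5 time units produces a peak-to-peak noise floor of about
2e-6 in a 5000-unit window.  The single-window classifier
(`classify_trajectory`) keeps the strict amplitude tolerance
`tol_eq = 1e-6`; the long-horizon settling protocol (below) uses
`1e-5`, comfortably above that floor and 4-5 orders of magnitude below
every genuine cycle amplitude encountered in the swept region.

## Stable-state protocol

For each parameter combination, 50 (configurable; the transect
pipelines use at least 10) random initial conditions are drawn uniformly
per patch-compartment on `(0, 2x]` the closed-patch equilibrium value —
wide enough to discover both branches of the bistable heterogeneous
state.  Draws are strictly positive and fully determined by the seed.

**Classification.**  A state is an *equilibrium* when every state
variable's peak-to-peak amplitude over the evaluation window is below
the amplitude tolerance, else an *oscillation*.  It is *spatially
heterogeneous* when time-averaged stocks differ across same-type
("homologous") patches by more than a heterogeneity tolerance.  Two
numerical precautions:

* Time averages over oscillatory windows are taken over an integer
  number of detected periods (dominant period from refined peak
  spacings of the largest-amplitude variable).  Without this, two
  patches following the *same* cycle at different phases show a
  spurious mean difference of order amplitude x period / window.
* Equilibria are compared at `tol_het = 1e-4`; oscillatory means, which
  retain residual phase/quadrature bias of order 1e-3, at
  `tol_het_osc = 1e-2`.  Both sit orders of magnitude below the O(1)
  stock differences of genuinely heterogeneous attractors.

A window too short to hold two full cycles yields an explicit
"inconclusive" flag, never a silent label.  A phase-lag diagnostic
(cross-correlation lag between the first same-type pair) is recorded
but does not affect labels.

**Adaptive settling.**  Transients near the two bifurcation boundaries
are critically slow: the synchronization of same-type patches near the
heterogeneity onset, and the decay of the cycle amplitude near the
stabilization boundary, both have timescales of order 1e5 time units at
baseline.  A fixed burn-in therefore cannot classify cells near the
thresholds.  `settle_and_classify` integrates in chunks of 20,000 time
units, re-evaluating a trailing 5,000-unit window, and exits when

1. the amplitude falls below tolerance (point equilibrium), or
2. amplitude and heterogeneity have both plateaued (relative
   between-window change < 1%), giving a converged oscillation, or
3. a hard cap (400,000 time units) is reached; the state is then
   labelled from the current window with `converged=False`, and a
   heterogeneity measure still in clean monotone decay (>1% per window
   over the last four windows) is classified homogeneous — it is
   synchronizing, merely slowly.

The cap resolves the reported thresholds to their grid step while
keeping a 31-cell, 10-ensemble transect at a few minutes on one CPU.
States *at* a boundary remain genuinely ambiguous at any finite
horizon; the ensemble consensus then reports `MIXED`, which the
threshold extraction treats as not-yet-heterogeneous.

**Ensemble verdict.**  Per-trajectory reports are grouped into
attractors on time-averaged stocks (relative 1e-3, absolute 1e-2).
Because the two-location design is spatially symmetric, the
heterogeneous equilibrium comes as a mirror pair related by swapping
locations; groups that coincide after canonicalization (larger type-A
producer stock at location 1) are flagged as the bistable pair.  The
consensus label requires all conclusive members to agree, else `MIXED`.

## Emergent metrics

*Net flows* per patch and compartment are the time averages of
`d_x (S_x x)_i`; being linear in the stocks, they equal the flow term at
the time-averaged stocks.  Negative = net exporter = **source**;
positive = net importer = **sink**.  Their sum over patches (within a
same-rate dispersal group for consumers) is zero by conservation.

*Net trophic effect* `E_i` compares the shift in secondary production
against the shift in primary production relative to an uncoupled
reference run with identical non-spatial parameters:
`E_i = [<C f_C(P)> - <C f_C(P)>_ref] - [<P f_P(N)> - <P f_P(N)>_ref]`.
`E_i > 0` is a net top-down impact on producers, `E_i < 0` net
bottom-up.  Averages are taken over the evaluation window (on a fixed
point this reduces to the equilibrium value; on cycles the full products
are averaged, not products of averages).

*Functions*: primary production `<P_i f_P(N_i)>`, secondary production
`<C_i f_C(P_i)>`, and nutrient retention as a turnover time —
total stocks `(N+P+C)_i` divided by the instantaneous rate at which
nutrients leave the meta-ecosystem through patch *i*:
`L_i = e_N N_i + (1 - r_P) m_P P_i + (1 - r_C) m_C C_i`.  Spatial
transfers are not losses (they stay in the system).  Local retention
averages the ratio over time; the meta-ecosystem level uses the pooled
ratio `<sum stocks / sum L>`.  On equilibria the two conventions
coincide.  All averages use trapezoidal quadrature on the solver grid.

## Sweep pipelines and problem sizes

`state_diagram`, `bifurcation_transect`, `dispersal_plane` and
`run_functions_transect` iterate the ensemble protocol over grids;
cells are independent, seeded individually (derived deterministically
from the master seed), written incrementally, and a failing cell is
coded `FAILED` without aborting the grid.  Default grid steps are 0.05
in `d_N` (resolving the thresholds to the step used in the published
diagrams) and 0.02 in `d_C`.  The replication presets use 50 initial
conditions per cell; the transect pipelines and the acceptance script
use 10 per cell and a 0.05 grid, which reproduces the same thresholds
at a few minutes per transect on one CPU.  The `ci` preset (8 initial
conditions, coarse grid, shortened settling cap) is a smoke test only;
with so few draws the discovery of both bistable branches is not
guaranteed.

## What the synthetic inputs do and do not cover

The only random input is the initial-condition ensemble; the model
itself is deterministic.  The ensemble emulates the protocol of
repeated runs from arbitrary positive states, and its range brackets
the attractors present at baseline.  It does not probe states far
outside twice the closed-patch equilibrium, demographic or
environmental stochasticity, parameter heterogeneity across patches, or
larger numbers of trophic levels — so passing tests show robustness of
the reported state structure to initial conditions, not to model
misspecification.

## Known limitations

* Thresholds are grid-resolved (one step of 0.05 in `d_N`), not
  continued; there is no continuation/AUTO-style tracking by design.
* At cells within one grid step of a boundary the finite settling cap
  decides the label; the `converged` flag and `MIXED` verdicts make
  this explicit rather than hiding it.
* The location-swap canonicalization (and hence bistability flagging)
  is implemented for two-location topologies; larger meta-ecosystems
  report attractor counts without mirror pairing.
* Quasiperiodic regimes (observed at high `d_N` under the fully
  connected control) make window statistics fluctuate; the plateau
  rules tolerate ~1% fluctuation, beyond which such cells settle only
  at the cap.
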