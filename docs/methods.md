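# Methods

This note records the models implemented in `refuge_phage`, the reasoning
behind parameter defaults and numerical choices, what the synthetic-data
generator does and does not emulate, and known limitations.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Agent-based infection model (`abm`)

**Model.**  Time is discrete in units of the bacterial generation time.
Each bacterium carries two heritable traits: a receptor-expression level
ρ ∈ [0.5, 1], interpreted directly as the probability that an infection
attempt on that cell succeeds, and a binary genetic-resistance flag γ that
confers full protection regardless of ρ.  Free phage are not tracked;
infection pressure is summarised by the secondary-infection number R: an
infected cell gives rise on average to R_t = R·N_sus/(N_sus + N_inf)
new infections, where N_sus and N_inf are the uninfected and infected
counts of its mixing pool at the start of the generation.  The realised
number of attempts per pool is Poisson(R_t · N_inf).  In the structured
environment each 20-cell channel is its own mixing pool with its own R_t;
in the unstructured environment the whole population is one pool.

**One generation** (fixed order): (1) draw attempt counts from
start-of-generation pool counts and resolve attempts; (2) all cells that
*entered* the generation infected lyse and are removed; (3) every
remaining uninfected cell produces one daughter, subject to capacity; (4)
record the state.  Newly infected cells do not replicate and lyse next
generation.  This ordering lets current-generation infections use
start-of-step counts while keeping "infected cells die from one generation
to the next"; it is deliberately not configurable, so results remain
comparable across runs.

**Attempt resolution.**  Each attempt picks a target uniformly at random
among the pool's currently uninfected cells; it succeeds with probability
ρ (never for γ = 1).  A successful target is removed from the candidate
list; a failed target remains available to later attempts.  Attempts
beyond pool exhaustion are discarded.  This is the simplest reading of
"possible secondary infections" that avoids double-infection bookkeeping;
the sequential kernel is compiled with numba and is reproduced exactly by
a pure-Python reference in the tests.

**Inheritance and trait range.**  Daughters copy γ exactly and draw
ρ ~ N(ρ_parent, 0.1), clipped back to [0.5, 1].  Clipping (rather than
redrawing or reflecting) preserves the stated trait range with minimal
distributional distortion and is recorded in the config metadata
(`rho_constraint="clip"`).  Initial ρ ~ N(0.7, 0.08), clipped likewise.

**Defaults** (the study conditions): K = 10⁶ (unstructured) or
4 × 10⁴ = 2000 channels × 20 cells (structured); N_ini = 10⁴ founders
(25 % of structured K, 1 % of unstructured K); 200 founders start
infected; genetic-resistance background frequency 5/10 000; R = 20;
20 replicates.  The 200 initially infected cells are drawn from the
genetically *sensitive* founders only — seeding a γ = 1 cell would be a
silent no-op and would make the realised initial infection pressure
fluctuate; the choice is logged here because the alternative (drawing from
all founders) is equally defensible.  Capacity flushing removes excess
daughters uniformly at random within the channel.  Replicate *i* of a run
uses the child stream (seed, *i*) of one root seed, making every output
bit-reproducible.

**Survivor/susceptible receptor comparison.**  After a run, 200 uninfected
cells are sampled; each sampled "potential infection" kills its target
with probability ρ (never for γ = 1).  The ρ values of killed vs spared
targets are compared with a two-sided Mann–Whitney U test.  ρ is both the
trait and the kill probability, so this is a direct read-out of the
selection differential on receptor expression.

## Phage transport (`flow`, `transport`)

**Geometry.**  A periodic unit cell of a mother machine: main channel
25 μm (z) × 100 μm (y) in cross-section, periodic in x with period 25 μm;
two dead-end side channels of 1 × 1 μm cross-section and 25 μm length
open into the y = 0 wall at floor level (z ∈ [0, 1]), 12.5 μm apart.  The
exact pitch is configurable; arrival statistics are reported per channel.

**Flow.**  For steady unidirectional creeping flow the axial Stokes
equation reduces to a 2-D Poisson problem for u_x(y, z) with no-slip
walls.  Two independent solvers are provided and cross-checked in the
tests: the classical rectangular-duct Fourier series (default; evaluated
with overflow-safe cosh ratios) and a sparse finite-difference solve.
The profile is rescaled so the integrated flux equals the requested rate
exactly; at 100 μl/h the mean axial speed through 25 × 100 μm is
1.11 × 10⁴ μm/s.  Flow inside the dead-end side channels is set to zero
(they carry no net flux and their 1 μm openings sit in the near-wall
corner region).  A lattice-Boltzmann solve of the same field would add
nothing physically and is far outside a single-core memory/time budget at
the 0.125 μm lattice this geometry implies.

**Particles.**  Phages are non-interacting point particles advanced with
a 5 ms timestep: advection by the bilinearly interpolated local velocity
plus an isotropic Gaussian step of rms √(2·D·dt) ≈ 0.2 μm per axis at
D = 4 μm²/s (the positional accuracy the geometry resolves).  Walls
reflect specularly, axis by axis; the x-coordinate wraps periodically.  A
particle whose end-of-step position moves from the main channel through an
opening footprint into a side channel logs an entry; crossing back logs an
exit.  No minimum-dwell filter is applied (dwell filters belong to the
imaging analysis, not the transport model).  Particle count is conserved;
a post-run containment check guards against escape bugs.

**Arrival rates.**  The headline quantity is the *per-simulated-particle
entry rate* (side-channel entries per particle per hour, summed over the
unit cell's refuges), the statistic that corresponds to the study's
"particles reaching a refuge per hour" at its reference concentration of
10⁷ particles/ml.  A concentration-rescaled variant
(entries-per-particle-per-hour × C·V_fluid / n_channels) is also computed;
note that at 10⁷ ml⁻¹ the 6.3 × 10⁴ μm³ unit cell holds only ~0.6
particles in expectation, and equilibrium kinetic theory pins this
rescaled per-visit rate near C·a·√(D/(π·dt)) ≈ 0.6 h⁻¹ — the raw
per-particle rate is the quantity on the published scale.  Repeat visits
by one particle count separately in `per_visit` mode; `first_visit`
deduplicates per particle and channel.  The Monte-Carlo standard error
comes from the spread of per-particle counts.

**Flow (in)sensitivity — a limitation to know about.**  With end-of-step
crossing detection, an incompressible axial flow leaves the entry rate
unchanged at steady state: the flow preserves the uniform particle
measure (the x-displacement depends only on (y, z), a measure-preserving
shear), and the wall-normal step is flow-independent, so the crossing
flux through the openings is the same with and without flow.  Simulations
confirm this within noise for both a corner-mounted and a floor-mounted
channel layout.  The package therefore does not reproduce a flow-induced
*reduction* of arrival rates; if one is observed experimentally it must
involve physics outside this model (e.g. finite observation windows with
non-periodic boundaries, or particle–wall interactions).

**Residence times.**  At 5 ms resolution most logged visits are immediate
recrossings of the opening plane, so the *median* residence sits at the
timestep scale; genuinely exploring visits (tail of the distribution)
scale as L²/2D and shrink with D, which is what the tests assert.
Imaging-based residence times measured with a ≥0.3 s dwell filter are not
comparable to the unfiltered simulated median.

**Phage-free fraction.**  First arrivals per refuge form a Poisson
process whose rate scales linearly with bulk concentration from the
simulated reference; the fraction of phage-free refuges at time t is
exp(−λ(C)·t).  An empirical variant computes the same curve directly from
simulated first-arrival times.

## Encounter-rate theory (`encounter`)

k = 2πDl / ln(2l/w) for a rod of length l = 3 μm and width w = 0.8 μm at
D = 4 μm²/s gives 37.42 μm³/s = 2.2 × 10⁻⁹ ml/min (1 ml = 10¹² μm³).
E = C_B·C_P·k and the per-cell rate C_P·k are reported per hour.  At
C_B = C_P = 10⁷ ml⁻¹ the formula gives E ≈ 1.35 × 10⁷ ml⁻¹ h⁻¹; published
round-offs of this quantity differ by a few percent at 2 significant
figures, and no adjustment is made to force agreement.  The domain
requires 2l/w > 1; no sub-diffusion-limit adsorption efficiency or shape
correction beyond the prolate-rod formula is applied.

## Trajectory analysis (`trajectory`)

Input is a tidy table of hourly founder-cell observations (occupancy,
length, events, 24-h live/dead label, initial reporter fluorescence).
Fate rules, in precedence order: *filamented* if the maximum observed
length exceeds 7 μm (twice the vegetative length; filamenters are a
distinct class even if they later lyse — they are counted in the
filamentation curve regardless); *lysed* if a lysis event exists (a lysis
event plus a live end-label is a record-level validation error);
*flushed* if the cell was lost; otherwise survived, split by whether it
ever divided.  Flushed cells can be imputed a fate, either by drawing
from the empirical fate frequencies of observed cells or as fractional
expected counts; imputation preserves totals in expectation.

Population curves sum channel occupancy within a replicate and average
across replicates; the SEM is across replicates (n = 3 by default) and is
NaN when fewer than two units contribute.  The division-count
distribution pools ≥3 divisions into "3+" for display; means use exact
counts when available, else 3 for the pooled class.  The extinction-time
regression fits OLS on the t = 2–7 h window and reports −intercept/slope;
the x-intercept is invariant under any positive rescaling of y (proved in
a property test), so the choice of survival-fraction normalisation is
immaterial.  A non-negative slope yields a no-extinction flag, not a
number.  The filamentation curve evaluates *current* length > 7 μm among
live cells per time point (the per-cell fate label uses max length).

Receptor comparisons run Shapiro–Wilk normality checks per group
(α = 0.05); a Welch t test is chosen when both groups look normal, the
Mann–Whitney rank test otherwise; both statistics are always reported
with the chosen one flagged, and groups smaller than 3 force the rank
test.  Type-I calibration under the null is asserted in the tests.

## Synthetic data (`synthetic`)

The generator emulates what hourly mother-machine imaging records, with
all latent events kept as ground truth.  Per channel: 1–2 founders;
exponential division times (mean 0.5 h); phage arrivals as a Poisson
process at 1.2 per channel per hour; an arrival targets a random resident
cell and infects with a probability given by a bounded logistic in the
cell's log₁₀ fluorescence (receptor-abundant cells are easier to infect);
infected cells stop dividing and lyse 25 min later, and the released
burst attacks each remaining channel mate with probability 0.25 —
this local amplification is what makes channel populations collapse
after the initial growth phase and sharpens the selection for low-receptor
survivors.  5 % of founders are dormant persister-like cells (no growth,
no lysis), providing the surviving-but-non-growing class.  Filamentation
onset follows a Gaussian-bump hazard in time; filamenting cells elongate
from 8 μm and are swept out after 2 h.  Channel capacity is 6; excess
daughters are flushed (the dead-end founder is shielded and instead
carries a small background loss hazard, so a few percent of founders end
up unobservable, exercising the imputation step).

Calibration notes: the hazard scale (0.09 per hour at peak) was set once
so that the *realised* filamenting fraction among present founders peaks
near the intended 0.26 level at the default conditions — the realised
level also depends on how fast non-filamenting founders are lost, so the
raw hazard cannot be read off the target directly.  The fluorescence
scale is an order-of-magnitude placeholder (the real reporter
distribution is published only as violin plots); the logistic slope and
the attack parameters were chosen so the killed-vs-survivor fluorescence
separation at the published group sizes (108 vs 42) is detected reliably
(standardised effect ≈ 0.8).

What the generator does *not* emulate: phage depletion or decay, channel
re-seeding from the main channel after extinction, lysis inhibition,
segmentation/tracking errors, fluorescence measurement noise, or any
fitting of generator parameters to real supplementary data.  Passing
tests therefore demonstrate that the analysis stage recovers the truth of
*this* data-generating process (≥99 % fate agreement, arrival-rate and
filamentation-peak recovery), not that the process is a complete model of
the experiment.

The well-mixed companion generator delegates to the unstructured ABM and
book-keeps free phage with burst size 100 per lysis (no decay or
adsorption losses), producing collapse-then-regrowth exactly when a
genetically resistant founder is present.

## Problem sizes and determinism

Acceptance-scale runs: 800 particles × 1 simulated hour (720 000 steps of
5 ms) per transport condition, chosen to hold the Monte-Carlo standard
error of the arrival rate near 0.1 h⁻¹; 20 replicates × 25 generations
for each ABM environment; 100–200 channels × 3 replicates for synthetic
datasets.  Every stochastic component draws from child streams of one
root seed (numpy SeedSequence; the numba kernels are seeded from the same
streams), so all results in the README and the acceptance output are
bit-reproducible.

## Known limitations

- The ABM proxies phage through R only: no free-phage pool, no de novo
  resistance mutation, no fitness cost of resistance, no continuous-time
  variant.
- The transport model has no particle–wall interaction beyond specular
  reflection and no adsorption; entry statistics at 5 ms resolution are
  dominated by plane recrossings (see the residence-time caveat), and the
  arrival rate is provably insensitive to the imposed axial flow.
- The duct flow profile is x-invariant; the local perturbation of the
  flow by the 1 μm openings is neglected.
- The published supplementary spreadsheet is required to recompute the
  study's single-cell summary numbers (extinction intercepts, division
  means, filamentation maximum); without it those checks fail with an
  explanatory message rather than silently passing.
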