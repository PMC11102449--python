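# Methods

`tmesim` simulates the growth of a solid tumor and its interaction with
innate and adaptive immune agents on a two-dimensional lattice, coupled to
an oxygen reaction–diffusion field and a global adenosine pool, under
combination immunotherapy: a HIF-inhibitor drug (Px-478), a CD73-silencing
siRNA nanoparticle, and a dendritic-cell (DC) vaccine.  This note records
the model, its numerical choices, and the places where the design was
genuinely open, so that results can be interpreted with the right caveats.

## The hybrid model

**Lattice and agents.**  The tumor microenvironment is an `N × N` grid
(default 210, site spacing χ = 10 µm) with Moore (8-neighbor)
connectivity, hard walls, and single occupancy.  Agents are tumor cells,
dendritic cells (inactive/active), inactive T lymphocytes, regulatory T
cells (Tregs), and effector (cytotoxic) cells.  Time advances in Δt =
2 min steps; every rate below is a per-step Bernoulli probability or Euler
increment.

**Tumor growth.**  A single tumor cell starts at the grid center.  A tumor
cell with at least one empty Moore neighbor divides with probability
P̄_tumor, placing the daughter uniformly at random on an empty neighbor;
fully enclosed cells cannot divide, so growth is rim-limited.  There is no
spontaneous tumor death and no metastasis.

**Immune motility.**  Inactive cells perform a Levy walk: run lengths are
drawn from F(z) = 1 − z^(−l) (l = 1.15) by inverse CDF
(z = ⌈(1−u)^(−1/l)⌉), a direction is drawn uniformly from currently empty
neighbors, and the cell persists for z steps; blocked moves are forfeited
but still consume a step of the run, and a move that would exit the grid
mirrors the offending direction component ("bounce").  Activated cells
switch to Brownian motion: one uniformly random Moore direction per step,
moving only onto empty in-grid sites.

**Contact rules (per step).**  An inactive DC adjacent to tumor activates
with probability D_act = 0.003.  An active DC activates each adjacent
inactive T cell with probability C_act = 0.24; the activated T cell
becomes a Treg with probability P̄_Treg (evaluated at the activating DC's
site) and an effector otherwise.  An effector adjacent to tumor removes
one uniformly chosen tumor neighbor with probability µ̄ and survives
(serial killing; at most one kill per effector per step).  An active DC
adjacent to a Treg deactivates with probability D_inact = 0.01 and resumes
Levy motion.  Immune cells neither proliferate nor die, so the T-lineage
and DC totals are conserved (a property the test suite audits).

**Oxygen.**  Vessels live on the grid border, pinned at U_b = 0.8 mMol.
Following the block-coarsened diffusion scheme, the grid is partitioned
into fixed 3×3 blocks; each block value relaxes toward the mean of its 3×3
Moore neighborhood *of blocks* at rate α ∈ (0,1) (default 0.5), tumor
sites consume f̄ = 0.0023 per site per step (spread over the block), and
the hypoxia inhibitor adds a spatially uniform source k·px.  The new block
value is redistributed to all 9 sites, clamped at 0, and the boundary is
re-pinned.  Note the coupling must be *between* blocks: averaging only
within a block moves no oxygen anywhere and the field would never feel the
vessels.  The update is computed on the residual U − U_b so the uniform
vessel concentration is an exactly idempotent fixed point.

**Hypoxia, adenosine, and drugs.**  Local hypoxia is 1/(U + c) with
c = 0.01.  A single grid-wide adenosine pool follows

    Ad' = β + a/(U_eff + c) − r·Ad − γ·S_t·Ad

with U_eff the mean oxygen over tumor sites and their Moore neighbors
(falling back to the grid mean when no tumor exists).  The two drugs
follow bolus–decay kinetics, px' = v(t) − η·px and s' = v_s(t) − λ·s, with
boluses of 40 and 4200 on their scheduled days; because the siRNA particle
adheres and accumulates in the tumor area, the level that acts on Ad is a
moving average S_t of s over the last M = 800 steps (zero-padded).  All
three ODEs use forward Euler with the 2-min step; at the calibrated rates
the iteration is a contraction and converges monotonically to the
closed-form steady state Ad* = (β + a/(U+c)) / (r + γS).

**Modulated probabilities.**  Hypoxia and adenosine tilt three per-step
probabilities, each clamped to [0, 1] and evaluated at the site of the
event:

    P̄_Treg  = P_Treg + r_Hr/(U+c) + r_Ar·Ad
    P̄_tumor = P_tumor + r_Ht·(1/(U+c) − H₀) + r_At·(Ad − Ad₀)
    µ̄       = µ − r_He/(U+c) − r_Ae·Ad

The Treg and cytotoxicity modulations use absolute levels: their base
values were fitted in vivo *in context*, and with the calibrated couplings
the standing adenosine level Ad₀ ≈ 188 yields a strongly suppressed
baseline immunity (P̄_Treg ≈ 0.58, µ̄ ≈ 0.23) — the immunosuppressed
microenvironment the therapy targets.  The tumor-division base rate
P_tumor = 0.001 (a cell cycle of ~33 h), by contrast, comes from an
adenosine-free source model and is therefore baseline-inclusive; wiring
the absolute adenosine level into it would multiply baseline growth
roughly six-fold (a ~6 h doubling time), which is biologically untenable
and incompatible with treatable tumors.  The division modulation therefore
responds to the *excess* of adenosine over its healthy-tissue steady state
Ad₀ = (β + a/(U_b+c))/r = 188.028 (and of hypoxia over a reference H₀,
default 0).  Both references are `ParameterSet` fields
(`adenosine_ref`, `hypoxia_ref`); setting them to 0 recovers the raw
absolute-level form for users who want it.

**Step order.**  Per step: protocol doses → drug ODEs → oxygen diffusion →
adenosine ODE → one shuffled agent phase in which every immune agent
applies its interaction rule and then moves, and every rim tumor cell
attempts division.  Shuffling (a fresh uniform permutation each step)
removes lattice-scan-order bias.  Daughters born within a step do not act
until the next step; cells killed earlier in a step no longer act.  Rim
membership is evaluated at the start of the phase (interior cells cannot
divide anyway), which lets the engine skip enclosed cells and keeps the
per-step cost proportional to the tumor surface rather than its area.

## Numerical choices

* **Diffusion sub-stepping.**  One relaxation sweep per 2-min step would
  give the oxygen field an equilibration time of ~13 h across the 2.1 mm
  domain — far slower than physical oxygen transport, which equilibrates
  in minutes.  Under a single-sweep scheme the zero-oxygen interior makes
  the first simulated hours anoxic everywhere (hypoxia level 1/c = 100),
  producing an artifactual division burst, and later a consumption-driven
  anoxic collapse around any mid-sized tumor.  The elementary update is
  therefore applied `diffusion_substeps` = 10 times per step with the
  consumption and source terms split evenly across sub-iterations, i.e.
  the field relaxes on a ~1.3 h timescale: fast enough to avoid the
  artifacts, slow enough that a large tumor still carves out a visible
  peritumoral hypoxia dip that feeds back on adenosine late in a run.
* **Initial oxygen.**  The field starts at the perfused steady state
  (uniform U_b), modeling vascularized tissue at the moment of tumor
  implantation.  A zero-interior start (`oxygen_equilibrated=False`) is
  available; it reinstates the early anoxic transient.
* **Clamps.**  Oxygen is clamped at 0; µ̄ can go negative under severe
  hypoxia/adenosine and is floored at 0; all probabilities are capped
  at 1.
* **Blocked Levy moves** consume a step of the run rather than pausing it,
  preventing deadlocked pile-ups in crowded regions.
* **Volume conversion.**  Occupied sites × 10⁻⁴ mm² × 2200 = 0.22 mm³ per
  site, the 2D→3D factor used for the murine 4T1 calibration; both factors
  are parameters.
* **Determinism.**  A run is a pure function of (parameters, protocol,
  seed): one `numpy.random.Generator` drives every stochastic decision,
  including inside the compiled kernels.  Replicate *i* of an experiment
  uses seed `base + i`.

## Dynamical regime

With the calibrated defaults the model sits in an immunosurveillance
regime: an untreated tumor grows at the rim (~1 site of radius per day,
accelerating as peritumoral hypoxia raises adenosine), while wandering DCs
eventually discover it and trigger a T-cell response that is strongly
Treg-biased (P̄_Treg ≈ 0.58) and of weak cytotoxicity (µ̄ ≈ 0.23).
Replicates are bimodal: some tumors escape to a few hundred mm³ by day 18,
others are cleared — which is the biology the model is about.  Treatments
act on both sides of the balance: the siRNA vaccine lowers adenosine
(faster effector polarization, higher µ̄, slower division), the HIF
inhibitor raises oxygen, and the DC vaccine short-circuits the discovery
delay by seeding 70 active DCs.  Replicate means over this mixture are the
primary endpoints (average and final-day tumor volume), so confidence
intervals are wide by nature and treatment contrasts are assessed on
means across matched seed sets.

## Analyses

* **Goodness of fit** is the coefficient of determination R² computed
  against a reference tumor-volume series; a bundled generator
  (`synthetic_reference_curve`) emits a synthetic logistic curve shaped
  like a murine growth experiment for demonstrations, since no measured
  curve ships with the package.
* **Global sensitivity** uses Latin-hypercube sampling of each parameter
  within ±50% of its default (`scipy.stats.qmc`), runs the untreated model
  per sample, and ranks parameters by the partial rank correlation
  coefficient (PRCC) between parameter and mean tumor volume over the
  horizon.  PRCC is appropriate for monotone input–output relationships;
  the statistic is pluggable.  The shipped experiment runs at reduced
  scale (N = 60, 3-day horizon, 100 samples, 2–3 replicates averaged per
  sample) to keep the analysis to minutes, and analyzes the raw
  absolute-level form of the modulation equations (references set to 0),
  since that is the form whose parameter roles the analysis is meant to
  characterize.  In that form the adenosine parameters dominate (top
  |PRCC|: r, β, r_At) and γ — inert without treatment — serves as a null
  control; under the default baseline-referenced tumor rate, r_At's main
  effect is largely absorbed into the baseline and r_Ht takes its place.
* **Identifiability** computes, for each parameter, central
  finite-difference sensitivity trajectories (δ = 10% relative, common
  random numbers on both sides, replicate-averaged) of seven outputs —
  tumor volume, adenosine, hypoxia, mean cytotoxicity, effector, Treg and
  active-DC counts — and correlates trajectory pairs.  A parameter pair is
  flagged non-identifiable only if |corr| ≥ 0.9 in *every* output.
  Parameters with zero or constant sensitivity carry no trajectory-shape
  signal and are excluded with a warning.

## Problem sizes used by the shipped experiments

Full-scale treatment-protocol experiments (210×210 grid, 18 days, 12,960
steps) run in roughly 5–8 s per replicate; the packaged ordering
experiments and the reproduction script use 6–8 replicates per protocol,
and the sensitivity/identifiability analyses use the reduced scale above.
These sizes are the package's chosen defaults for its own experiment
battery; all of them are arguments that can be raised.

## What the simulations do and do not show

The generator *is* the model: experiments probe the model's internal
logic (orderings of dosing schedules, directionality of parameter
effects), not mouse biology.  Real tumors are three-dimensional, layered
(necrotic/quiescent/proliferating), vascularized beyond the border, and
their immune compartment proliferates and dies; none of that is modeled
here.  Known limitations: adenosine does not feed back on hypoxia;
drugs are spatially uniform; the 18-day horizon precludes angiogenesis;
and the tumor is a single proliferating layer, so oxygen consumption is
uniform across tumor sites.
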