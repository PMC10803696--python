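# Methods

## Model

`pbrpk` simulates the whole-body kinetics of a receptor-targeting
radiolabeled ligand (the packaged default emulates a ¹⁷⁷Lu-labelled
PSMA-targeting small molecule) as a compartmental ODE system expressed as
a *reaction graph*: compartments are well-mixed containers (organ
subspaces) holding several species, and all dynamics are reactions between
species.  This replaces the older "parallel tracks" construction — where
every new interacting entity (the unlabeled ligand, albumin, …) required
duplicating the entire compartment chain — with a single graph to which new
species and reactions are appended.

Each organ contributes a vascular and an interstitial compartment;
receptor-expressing organs (kidneys, salivary glands, tumor by default)
additionally carry a membrane binding-site pool and an intracellular
space.  Arterial and venous plasma pools close the circulation.  The
processes are:

* **Plasma flow** — arterial pool → organ vascular space → venous pool at
  the organ's plasma flow Q (L/min); venous → arterial return at ΣQ.
* **Capillary exchange** — free ligand crosses vascular ↔ interstitial at
  a permeability–surface product PS (L/min), symmetric in concentration.
* **Receptor binding** — free interstitial ligand binds a finite shared
  receptor pool with rate k_on·[L][R]·V_int; dissociation at
  k_off = k_on·K_D.  Hot (labeled) and cold (unlabeled) ligand are
  chemically identical and compete for the same pool — this competition is
  the source of every non-linearity the twist/MRDC analyses measure.
* **Internalization / release** — the bound complex internalizes at λ_int,
  returning the receptor to the free pool (the pool is finite and
  conserved) and moving the ligand to the intracellular space, whence it
  is released back to the interstitium at λ_rel.
* **Renal filtration** — free ligand in the kidney vascular space is
  filtered at GFR into a urine compartment.  Nothing else is filtered.
* **Physical decay** — every hot species converts to its cold counterpart
  *in place* at λ_phys (hot_bound → cold_bound, hot·Alb → cold·Alb, also
  in urine).  The ligand molecule outlives its radionuclide and keeps
  competing; this choice is what makes the total ligand count an exact
  invariant and the total hot amount decay exactly exponentially after the
  last bolus — both are enforced as tests.

State variables are **amounts in nmol**, never concentrations; rate laws
convert through compartment volumes where needed.  Conservation audits
therefore reduce to exact sums over state entries.  The default
whole-body model has 97 states without albumin and 163 with it, across 19
organs plus blood pools and urine.

### Albumin extension

With albumin enabled, an albumin binding-site pool is placed in every
plasma compartment and ligand binds it reversibly 1:1
(k_off^alb = k_on^alb · K_D^alb).  Complexes travel with plasma flow, are
**not** renally filtered (a ~70 kDa protein is not filtered by the
glomerulus), can **not** bind receptors (steric exclusion), and cross the
vascular wall only in the tumor — the porous tumor vasculature leaks
albumin and complexes into the tumor interstitium with the *same* PS as
the free ligand, deliberately an upper-bound assumption for the benefit of
albumin binding.  `K_D^alb = inf` is a sentinel that omits the albumin
machinery entirely, so the "binding disabled" baseline is exact rather
than a large-k_off approximation; a test asserts the inf-sentinel model is
bit-identical in behavior to the albumin-free build.

## Numerics

The graph compiles to `d(state)/dt = S·r(state)` where every rate is a
first- or second-order monomial in amounts; the analytic Jacobian is the
constant linear part plus a cheap bilinear correction.  Integration uses
`scipy.integrate.solve_ivp` (BDF) with that Jacobian; default tolerances
rtol 1e-8 / atol 1e-12 nmol, leaving two orders of magnitude of margin
under the 1e-6 conservation audits (halving tolerances moves organ doses
by ~1e-8 relative).  Boluses are discontinuous state jumps with an
integrator restart at each bolus time — exact and reproducible, unlike
narrow-pulse forcing.  The default output grid is 400 log-spaced points on
(0, 50 000] min plus t = 0 and every bolus time; the reported value *at* a
bolus time is the post-jump state.  Amounts more negative than 10·atol
abort the run; smaller negatives are clamped to zero on output.  A
whole-body run over the full 50 000-minute horizon takes a few tenths of a
second on one CPU, which is what makes the grid studies tractable.

Fractionation splits totals equally across boluses (totals/n each).  The
split rule is not dictated by anything physical; explicit per-bolus
fraction lists are accepted for non-equal splits.

## Dosimetry

Organ activity is A(t) = λ_phys × (total hot-moiety amount in the organ's
compartments), in Bq; *all* hot forms count (free, bound, internalized,
albumin-complexed).  TIA is the trapezoid integral on the output grid plus
an analytic tail A(t_end)/λ_phys assuming pure physical decay beyond the
horizon (50 000 min ≈ 5.2 ¹⁷⁷Lu half-lives — small but not negligible).
Absorbed dose uses local deposition (self-dose) only:
dose = decays × Δ / mass, with Δ = 2.37×10⁻¹⁴ J (¹⁷⁷Lu mean energy per
decay ≈ 148 keV) and mass = organ volume × 1.04 kg/L.  Self-dose is the
appropriate model for a β⁻ emitter at organ scale and makes dose and TIA
proportional per organ, a proportionality the metrics rely on (MRDC is
identical computed from dose or TIA).  Blood residence time is the vein
TIA over injected activity; activity units cancel, so it is
∫H_vein dt / H₀ in minutes.

## Metrics

**Twist.**  Iso-dose contours of the (hot, cold) dose surface are
extracted by marching squares on the sweep grid.  Each contour is fitted
with a total-least-squares line — neither axis is a response variable, so
orthogonal regression is the right estimator — after dividing each axis
by its sweep range.  Without that standardization the "angle" would
depend on the units and spans of the two axes (nmol of hot vs nmol of
cold differ by ~8×); with it, twist is invariant under relabeling dose
units and rescaling either axis, both asserted as tests.  Twist of a
level is the angle to the lowest-level contour folded into [0°, 90°].
Default levels are the nine interior deciles of the surface's dose range.
A vertical contour means zero competition; tilt grows with receptor
saturation.

**MRDC.**  max over the (n, τ) schedule table of
(Dose(n, τ) − Dose_single)/Dose_single, ties broken toward the smallest
n then τ; if no fractionated schedule beats the single bolus, MRDC = 0 at
n = 1.

**EF.**  (TumorDose/OARDose at K_D^alb) ÷ (the same ratio with albumin
binding disabled), computed against both kidneys and salivary glands.

## Parameter table

The packaged table (`pbrpk/data/psma_lu177_params.yaml`) is a
representative adult physiology: 19 organs with population volumes,
plasma flows and vascular/interstitial fractions; PSMA-617-like binding
kinetics (k_on 0.04 L/(nmol·min), K_D 0.5 nmol/L, λ_int 1e-3/min,
λ_rel 2e-4/min); GFR 0.11 L/min; λ_phys from the 6.647 d ¹⁷⁷Lu half-life.
Receptor amount is receptor density × total organ volume.  Tumor plasma
flow (0.1 /min per L) and PS (0.05 /min per L) scale linearly with tumor
volume, so the tumor-sink strength grows with tumor burden.  The albumin
binding-site pool is 1×10⁴ nmol/L of plasma with k_on^alb fixed at
1e-3 L/(nmol·min) and only K_D^alb swept: the pool concentration sits
inside the swept K_D^alb range [5, 1e5] nmol/L so the sweep traverses the
weak-binding, transition and saturated-binding regimes.  All defaults
live in the YAML file, never in code.

## Synthetic conditions — what the tests do and do not show

All studies run on deterministic virtual-patient grids (tumor volume ×
receptor density), not sampled populations; there is no inter-individual
variability, no measurement noise, and no radiobiology (dose is the
endpoint, not cell kill).  Passing the qualitative suites shows the
*mechanistic* phenomena — saturation-driven iso-dose tilt, the tumor sink
effect, fractionation gains at low receptor density, residence-time
extension and tumor-selective enhancement from albumin binding — emerge
from the model structure under a realistic parameterization.  It does not
validate the parameter values against patient data.

Reduced problem sizes used by the test suite and the acceptance script
(5×5 injection grids, 10-point K_D^alb sweeps, 25–100 random schedules)
are the package's own choice of desk-scale defaults; the full published
grids (10×10×10×10 and 20-point sweeps) run through the same code paths
via `default_spec` and `scale_grid`.

## Known limitations and open choices

* Kidney behavior under albumin binding: because the kidney is both a
  receptor-expressing organ and the clearance organ, blocking filtration
  re-routes ligand onto kidney receptors and the kidney dose *rises* with
  albumin affinity here; the enhancement factor versus the kidney
  therefore stays below 1 while EF versus salivary glands exceeds 2.5 at
  strong affinity.  Increased kidney uptake is in fact reported for
  real albumin-binding PSMA ligands; whether a parameterization exists
  where the kidney is spared depends on the balance between baseline
  receptor saturation and clearance, which population tables do not pin
  down.  EF versus salivary glands is also not globally monotone in
  K_D^alb: a shallow dip below 1 appears in the weak-binding transition
  (partial receptor blocking before the residence-time gain dominates).
* Albumin binding is strictly 1:1; no multi-site binding, no albumin
  synthesis/turnover, no molecular-weight scaling of the tumor leak.
* Self-dose only — no cross-organ S-values, no voxel dosimetry.
* Deterministic ODEs only — no stochastic (SSA) or spatial (PDE) variants.
* SBML interchange targets Level 3 Version 2 core, amounts as the
  substance quantity, kinetic laws as amount-based monomials; rules,
  constraints, function definitions, initial assignments and event delays
  are rejected explicitly rather than silently dropped.
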