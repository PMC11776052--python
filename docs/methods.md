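# Methods

This note records the models behind `porecv`, the parameter choices that
matter, what the synthetic systems do and do not emulate, and the numerical
decisions a maintainer would want written down.

## The Full-Path collective variable

The CV tracks pore formation through two regimes with one smooth scalar.

**Defect coordinate.**  `CV_cyl = 1 − d/CV_eq`, where
`d = Σᵢ w(ρᵢ/R_cyl)` sums a rational membership weight
`w(x) = (1 − xⁿ)/(1 − xᵐ)` (defaults n=6, m=12, for which
`w = 1/(1+x⁶)` exactly) over the xy distances ρᵢ of all lipid-tail beads
from the pore axis.  The cylinder spans the whole box along the normal, so
tail beads anywhere above or below the midplane count.  `CV_eq` is the same
soft count averaged over frames of an equilibrated intact bilayer, making
`CV_cyl` 0 at equilibrium and 1 when the cylinder is empty (its upper
limit); an over-crowded cylinder gives small negative values, which is why
umbrella grids may start slightly below zero.  The removable singularity of
the rational form at ρ = R_cyl (limit n/m) is handled exactly for m = 2n and
by a local Taylor expansion otherwise.

**Radius coordinate.**  `CV_radius = r_min/r_unit` with
`r_min = β / ln Σᵢ exp(β/dᵢ)`, a converging-sum soft minimum over the same
xy distances.  This form underestimates the true minimum, is continuously
differentiable, and converges monotonically to the exact minimum as β grows.
Default β = 200: at β of a few tens the underestimation bias at 2 nm
distances reaches ~10% (`r_soft ≈ d_min/(1 + d_min·ln N_eff/β)` with N_eff
near-minimal beads), which would dominate the CV's error budget for the pore
sizes of interest; β = 200 keeps it at 1–3% while staying numerically safe
under a 10⁻³ nm distance floor with a log-sum-exp evaluation.

**Switching.**  `s1(x) = 1/(1 + exp(α(x − CV0)))`, `s2 = 1 − s1`, evaluated
at `x = CV_radius` with α = 20 and CV0 = 0.95.  Only complementarity, the
crossing at CV0, and the rate α are essential; the logistic pair is the
simplest C∞ choice.  Feeding the *radius* to the switch makes the joint CV
exactly the dimensionless pore radius once the pore is open (s2 → 1), and
keeps the defect term in charge below CV0; the alternative (switching on
CV_cyl) never fully releases the defect term because s1(CV_cyl = 1) =
1/(1+e^{α(1−CV0)}) ≈ 0.27 at the default parameters, so an open pore would
misreport its radius by ~20%.  A practical consequence, visible in the toy
runs: between an empty cylinder and an established pore the joint value is
temporarily non-monotone in CV_radius, and systems linger below
CV_radius ≈ 0.85 before committing to expansion.

**Pore centre and gradient.**  The pore centre is the geometric box
xy-centre, so the CV depends only on tail-bead positions and its analytic
gradient is exact and vanishes for head and water particles.  Drifted
trajectories should be preprocessed with `membranes.recenter_lipids`.
Gradients are validated against central finite differences (h = 10⁻⁵ nm) to
better than 10⁻⁵ on flat, pore and stripe geometries.

## The Rapid method

A stripe (bilayer ribbon periodic along y with two free edges along z,
membrane normal x fixed at 8.5 nm) models a pore of infinite radius.  The CV
is simply the box edge along y; stretching it lengthens both rims at
constant area, so the free energy is linear with slope `m = 2γ`.  γ is
reported per molecule, `γ = m/(2·N_A)`, i.e. `m/2` in kJ mol⁻¹ nm⁻¹ and
×1.66054 in pN.  Flat-bottom restraints (k_fb = 1000 kJ mol⁻¹ nm⁻²,
half-width 2.5 nm) on head beads along the normal, referenced to the
instantaneous head centre of mass, stop the stripe from drifting into its
periodic image; the rim–rim gap of the builders is kept ≥ 2 nm for the same
reason.

## Pore state and lifetime

The membrane interval [−2.125, 2.125] nm around the lipid centre of
geometry is split into 17 slices of 0.25 nm.  Each water particle
contributes a peak-normalised Gaussian weight (bandwidth 0.1 nm, truncated
at the slice boundaries) to its slice, so a molecule at a slice centre
counts as exactly one; a slice is *wet* when its weighted count reaches 1
(boundary counts as wet — a deterministic tie-break), and
`s = wet fraction`.  The weighted count was chosen over the raw count so the
observable responds smoothly to molecules crossing slice boundaries.  s = 1
while a transmembrane water thread exists; after closure only the solvent
slabs stay wet.  Closure series are fitted with
`s(t) = A0·(1 − tanh(A1·(t − A2)))` — the minimal three-parameter sigmoidal
decay whose inflection point A2 is the pore lifetime.  A2 is initialised at
the first time s drops below half its initial plateau; a series that never
decreases is rejected rather than fitted.  With Gaussian noise σ = 0.05 the
lifetime is recovered to well under 5% mean relative error over 20 seeded
replicates.

## Synthetic membranes

Builders produce geometry, not chemistry: 3-bead lipids (head, tail,
terminal tail, 0.5 nm spacing) on jittered leaflet grids, point-particle
water at a configurable density (default 8 nm⁻³ — enough for occupancy
observables; no claim of liquid structure).  The pore builder relocates the
lipids that fell inside the pore footprint onto the rim — heads lining the
wall, first tail bead just outside the nominal radius — so the closest-tail
definition of the pore radius agrees with the requested radius to a few
percent and lipid/role counts are conserved.  The water column fills the
pore channel slice by slice at the configured density; whether every core
slice is wet is therefore an emergent property (a 0.1 nm pore at coarse
density has dry slices).  What these fixtures do **not** emulate: thermal
undulations, realistic area per lipid, lipid tilt disorder, solvent
structure.  Tests passing on them validate geometry, arithmetic and
calibration logic, not force-field realism.

## Toy dynamics engine

A Cooke-style implicit-solvent model: WCA repulsion (σ = 0.6 nm, heads
0.95σ), FENE bonds (k = 216 kJ mol⁻¹ nm⁻², r∞ = 0.9 nm), a harmonic
head–terminal straightening term (72 kJ mol⁻¹ nm⁻², rest 4σ), and a
broadened tail–tail attraction between different lipids
(−ε cos²(π(r−r_c)/2w_c) out to r_c + w_c, w_c = 1.6σ).  ε = 2.3 kJ/mol puts
kT/ε ≈ 1.12 at 310 K, inside the model's fluid-bilayer window — chosen
because a gelled membrane shows seeding memory (spurious hysteresis) in
umbrella runs.  Masses are 100 amu, units GROMACS-style (nm, ps, kJ/mol),
BAOAB Langevin integration at Δt = 0.02 ps and friction 1 ps⁻¹; a tethered
bead reproduces the Boltzmann position variance kT/k within ~1%.

Rim-length biasing uses Metropolis volume moves on the rim edge (affine y
rescaling every few steps, Gaussian proposals of 0.015 nm) whose acceptance
includes the `N ln(L'/L)` configurational-measure term, so the sampled
marginal of L is exactly `Z(L)·exp(−U_bias(L)/kT)`.  A naive piston force
`−∂U/∂L` would omit an `N·kT/L ≈ 80 kJ mol⁻¹ nm⁻¹` measure term that would
swamp the ~5 kJ mol⁻¹ nm⁻¹ rim signal.  The stripe's free ends make a
barostat unnecessary: the ribbon width relaxes on its own as the rim
stretches.

## Umbrella sampling and WHAM

Windows are harmonic with per-window seeds derived from one master seed.
Self-consistent WHAM is solved in the window free energies with log-sum-exp
stabilisation; convergence is the largest per-iteration change (tolerance
10⁻⁸ kJ/mol, cap 10⁵ iterations, non-convergence raises naming the worst
adjacent-histogram overlap).  Two numerical details matter for stiff
springs:

- the bias Boltzmann factor per bin is the **bin average**
  (Gaussian log-CDF form), not the bin-centre value — with κ = 5000 the
  bias varies by several kT across a reasonable bin;
- window spacing follows the standard overlap rule of ~2–3 thermal widths
  `sqrt(kT/κ)`.  With κ = 5000 at 310 K the width is 0.023, so 20 windows
  span about ±0.6; spacing windows 4–5 widths apart leaves adjacent
  histograms disjoint and the stitched profile performs a random walk of
  several tenths of kJ/mol.

The WHAM oracle draws exact inverse-CDF samples from the biased Boltzmann
densities of G(x) = 10(x²−1)² and demands < 0.3 kJ/mol RMS agreement over
the sampled range, "sampled" meaning bins holding ≥ 10 samples (a single
5-sigma tail sample carries shot noise, not information).

Profile fits: the nucleation coefficient k is an ordinary least-squares fit
of G against CV² for CV ≤ 0.5; the line tension is a linear fit for
CV ≥ 1.2 with `γ = slope/(2π·r_unit)` (one circular rim) in Full-Path mode
and `γ = slope/2` (two straight rims) in Rapid mode.  Errors: halves (half
the |difference| between first- and second-half estimates), complete
bootstrap over samples within windows (default 200 replicates; 1 replicate
degenerates to zero error by construction), and block-wise profile overlays
for convergence checks.

## Desk-scale protocols and problem sizes

The `pipelines` module fixes the demonstration scale of the package; these
sizes are the package's own choices for a single-core workstation run:

- *WHAM oracle*: 20 windows × 5000 exact samples, κ = 5000, span ±0.6,
  120 bins.
- *Toy stripe → γ*: 60 lipids, rim edge ≈ 3.9 nm, 11 windows (κ = 2000)
  spanning −5%…+12% of the rim edge, 8000 steps per window, second half
  kept.  Typical result: γ ≈ 40–60 pN, rising steeply (roughly factor ~2)
  when ε is raised 25% — more cohesive membranes resist rim lengthening,
  the qualitative force-field sensitivity one expects.
- *Toy Full-Path umbrella*: 98 lipids, R_cyl = 0.8 nm (the default 1.2 nm
  cylinder would displace ~20% of this small membrane's area; 0.8 nm keeps
  the strain tolerable and lies within the radius range over which the CV
  behaves well), 9 windows (κ = 300) over CV 0.05–0.85, 20000 steps per
  window with the final 35% kept, windows seeded from an 18000-step steered
  pull (κ = 1500).  The range deliberately stops below the switching
  threshold — the regime a small implicit-solvent membrane traverses
  reversibly — and covers the whole quadratic fit range.
- *Hysteresis check*: the same umbrella run seeded from an opening pull vs
  from a closing pull (after a fresh opening), compared bin-by-bin on a
  common grid after mean alignment against the summed per-bin halves-error
  bands of the two runs.

## Known limitations

- The toy model is not parameterised against any real lipid; its k and γ
  values are internally consistent, not literature-comparable.
- The Full-Path switch argument and the exact closed forms of the switching
  and soft-minimum functions satisfy the documented contracts
  (complementarity, crossing, convergence, smoothness) but other smooth
  forms satisfying the same contracts exist.
- The stripe toy protocol fixes the lateral z edge; only the rim edge is a
  dynamical variable.  Semi-isotropic pressure coupling is out of scope.
- WHAM assumes a single temperature across windows and raises otherwise;
  MBAR-style binless estimation is not implemented.
- Multi-frame trajectories are carried in the package's extended XYZ
  dialect (box on the comment line); GRO I/O is single-frame.
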