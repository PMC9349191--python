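# Methods

## Model structure

A lineage topology is a directed graph of cell compartments on a grid of
stage levels (0 = tip stem cells) and marker columns (Sca-1 state).
Differentiation edges are unidirectional in stage; horizontal edges
change the marker state at constant stage and may, in the candidate
space, run in either direction (reversible marker transitions are part
of the hypothesis space and are rejected or retained by the data).
Candidate models share one compartment roster and differ only in their
edge sets; the shipped `hsc_to_cmp_clp` possibility graph (9
compartments: tip ES HSC, CD201⁻/ˡᵒ HSCs, MPPs and HPC-1s split by
Sca-1, terminals CMP and CLP) admits exactly 144 admissible subgraphs
under its enumeration rules (Sca-1-high backbone and the lower Sca-1-low
chain mandatory; the tip diagonal, all horizontal transitions in both
directions, and the upper Sca-1-low vertical optional; all compartments
and both terminals reachable).  Enumeration is exhaustive over the
optional-edge power set and is tested against a brute-force oracle.

Kinetics are linear compartment ODEs for total cells `N`, labelled
cells `L` and total H2B-GFP content `G` (see README for the equations).
Assumptions: label induction is instantaneous at chase start and
heritable; the label is neutral (L obeys the same operator as N, so a
compartment with no inflow keeps its labelling frequency forever — the
tip criterion); division conserves total GFP, so the measured
population-mean retention is `G/N`, which in a closed dividing
compartment decays as `e^(−pt)` (this population-mean convention
deliberately differs from the lineage-average `2^−K` of a single cell's
division count `K`); loss `δ` is a lumped term covering death plus
differentiation into unobserved compartments.  Sizes are relative
(fraction of lin⁻ cells); the normaliser is absorbed into `N0`.

Because the system is linear, trajectories are evaluated through the
matrix exponential rather than step-wise integration: a spectral path
when the eigenbasis is well conditioned (condition number < 1e8) and a
stepping Padé-13 scaling-and-squaring exponential otherwise.  The
package ships its own `matrix_exponential` because lineage operators are
routinely defective — two compartments sharing one net turnover rate
form a Jordan block — and this regime is validated in the test suite
against high-accuracy Runge–Kutta integration (observed agreement
~1e-14; a third-party exponential showed percent-level errors here).
Demographic steady states solve the linear flux balance with the tip
size fixed; a non-negative dominant eigenvalue of the non-tip block or a
non-positive solution is flagged as divergence, not raised.

## Fitting

`LineageModel.fit` minimises the Gaussian negative log-likelihood
`Σ[(y−ŷ)²/(2σ²) + ln σ]` over log10-parameters.  Free parameters are the
per-edge differentiation rates, non-tip proliferation rates (where the
compartment allows proliferation), loss rates (where allowed), the tip
size and the tip induction frequency; by default sizes are tied to the
demographic steady state (tip proliferation balances its outflow), which
is how fits to native, unperturbed hematopoiesis are initialised.
`init="free"` releases all initial sizes for non-stationary conditions.
Default bounds are 1e-4–10 per day for rates.

The default error model takes each observation's reported SEM as its
known σ (weighted least squares on mean ± SEM summary curves, one
residual per compartment × timepoint × observable).  A fitted-constant
per-observable σ (profiled analytically, counted in k) and fixed σs are
available; the fitted-σ mode is noticeably less discriminating for model
selection because a wrong model can inflate its σ̂ to absorb misfit.

The multistart schedule: `n_starts` Latin-hypercube points in the
log-bound box (default 64; thousands are appropriate for full
production runs), each refined by a budgeted trust-region pass
(`scan_max_nfev`=12 iterations), the best `n_polish`=2 polished to
tolerance 1e-12 with a larger budget.  Parameter sets without a stable
positive steady state receive a large penalty residual with a gradient
toward stability.  Everything is deterministic given the seed; identical
seeds give bit-identical results.  Subsampling refits and
profile-likelihood scans warm-start from the full-data optimum — this is
the intended optimizer schedule, not a shortcut, since those surfaces
differ only perturbatively from the full fit.

Noise-free recovery of the toy model's 14 free parameters is exact to ~1e-14
relative with a deeper schedule (64 starts, 25 scan iterations, 3
polishes), which is what the recovery experiment uses.

Profile-likelihood intervals walk each parameter on an adaptive log10
grid (step chosen from local curvature so roughly five steps reach the
χ²₁/2 = 1.92 threshold for 95%), re-optimising all other parameters with
warm starts, and interpolate the crossing; hitting a bound first flags
the interval one-sided (this is also how unidentifiable parameters
announce themselves).  All profile points inside the threshold are kept
as band samples and propagate parameter uncertainty into fluxes, shares
and ratios (2.5/97.5 percentiles).

## Per-mouse normalisation

The study design induces the label with substantial mouse-to-mouse
variability (lognormal, CV 25% by default).  That variability is shared
by *all* of a mouse's label measurements, so fitting raw label fractions
with an independent-Gaussian likelihood is overconfident — measured
profile coverage drops to roughly 80–85%.  The pipeline therefore
divides each mouse's label fractions by that mouse's own tip labelling
at its (final bone-marrow) sacrifice timepoint before aggregation; the
induction level cancels from the normalised observable `f_i/f_tip`,
which the model predicts directly, and the induction parameter is
dropped when only normalised label data are fitted.  Normalised tip rows
are identically 1 and carry no information; aggregated rows with zero or
degenerate SEM (including replicates stuck at a detection floor) are
excluded with a logged count.

Residual profile-interval coverage is measurably below the nominal 95%
(81% over 70 replicate cohorts for the tip output rate): the intervals
are ~1.4× too narrow for two stacked reasons.  First, with σ taken as
the SEM estimated from 8 mice, the implied inverse-variance weights are
biased upward (Jensen's inequality, E[1/σ̂²] = 1.4/σ² at 7 degrees of
freedom), narrowing intervals ~18%.  Second, normalisation divides every
compartment's label fraction by the same noisy tip measurement, so all
label means of a timepoint share a ~3% common scale error that the
independent-Gaussian likelihood cannot represent.  We keep the
reported-SEM convention — it is the standard fitting surface for
published mean ± SEM curves, and weight-unbiasing corrections degenerate
for the 3–4-mouse cells that arise under data subsampling — and document
the calibration consequence here; when calibrated intervals matter, use
a parametric bootstrap over the full generative design.

## The synthetic cohort generator

`StudyDesign` defaults emulate the study: cross-sectional cohorts (each
mouse sacrificed once), 7 chase timepoints at 3–168 days, 8 mice per
timepoint, all three observables on all observed compartments.  Noise
defaults: label fractions get binomial counting noise (500 cells scored)
plus additive Gaussian SD 0.02; sizes multiplicative lognormal CV 20%;
GFP retention additive Gaussian SD 0.05 (clipped to (0, 1.05]); per-mouse
tip induction lognormal CV 25% around a mean of 0.3.  These magnitudes
were chosen to resemble published SEM scales and are config-exposed.

The toy model is a generic five-compartment branching topology: tip S
(slow, demographically balanced turnover 0.015/day) feeds two
progenitor columns — A1, a fast-dividing, fast-equilibrating progenitor
(p = 0.9/day), and B1, a slow-dividing progenitor (p = 0.02/day) with a
lumped loss rate (δ = 0.1/day, mirroring the high-loss stem compartment
of the native system) — ending in a proliferating mature fate A2 and a
post-mitotic mature fate B2.  One horizontal cross-edge (A1→B1) and one
diagonal convergence edge (A1→B2) make compartment origins genuinely
multi-pathway: the candidate space of its subgraphs has 9 members (all
demographically feasible), and B2 receives cells by three distinct
ancestral paths.  The rates were chosen so that the two defining
in-silico regimes hold structurally: label equilibration is fast
relative to the chase (fate mapping alone leaves several minimal
candidates within ΔAICc < 2 — the A1-fed and S-fed variants are
label-equivalent), while the division-history contrast (mean GFP ~0.3
vs ~1.0 in the two feeder branches, read out directly by the
post-mitotic B2) and the size constraints make every edge identifiable
from the joint surface (each single-edge-dropped competitor carries a
structural misfit of χ² ≥ 26 at cohort SEM scale).

What the generator does *not* emulate: flow-cytometry gating artifacts,
spectral spillover, longitudinal blood sampling (supported but off by
default), age structure within compartments, or non-stationary
demography during the chase.  Passing tests on these cohorts therefore
demonstrate correctness and calibration of the inference machinery under
the model's own assumptions, not robustness to real-data artifacts.

## Stochastic oracle

`simulate_stochastic` is an exact event-driven (exponential waiting
time) simulation of the linear birth–death–migration process with the
same rate semantics as the ODE operator: division duplicates a cell and
halves its continuous GFP register; differentiation moves it along an
edge and appends to its ancestry path; loss removes it.  Initial cells
("founders") evolve independently, so founder clusters provide exact
standard errors for any population summary from a single run; the
oracle tests compare N, label fraction and mean GFP per compartment as
z-scores over founder-cluster SEs.  Because ~100 z-scores are checked
simultaneously, the acceptance check is family-wise (≥95% within 3 SE,
none beyond 4.5) — the maximum of a hundred standard normals routinely
exceeds 3, whereas a genuine formulation error produces z-scores an
order of magnitude larger.

Pathway-origin probabilities are defined by composing incoming-flux
fractions backwards along each tip-to-target path at steady state;
within-node proliferation amplifies output but does not change any
cell's ancestral path, so it cancels.  This definition is *validated*
against ancestry frequencies of the simulator rather than assumed
(agreement within 3 SE on the three-path toy fate; probabilities sum to
1 to 1e-9).  Cyclic topologies (reversible marker transitions) are
rejected by the closed-form decomposition and deferred to the
stochastic estimator.

## Problem sizes

The validation experiments run at desk scale: 10 cohorts for the
selection and ambiguity experiments, 20 half-data resamples, 70
replicate cohorts for coverage, 2×10⁴ cells per stochastic oracle run
and 6×10⁴ founders for the pathway oracle, with 64 multistart points per
fit.  Scaling any of these up is a matter of configuration.

## Known limitations

- AICc uses the residual count n of the summary surface; at label-only
  n = 30 the small-sample correction dominates the ranking, strongly
  rewarding parsimony.
- Profile coverage is ~90–93% (see above); parametric bootstrap is the
  config alternative when calibrated intervals matter.
- The pathway decomposition requires acyclic differentiation structure.
- Platelet-specific biology (anucleate cells, platelet lifespan) is not
  modelled; megakaryocytes are a terminal compartment with turnover.
- Absolute cells-per-day calibration against marrow cellularity is out
  of scope; fluxes are in relative size units.
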