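# Methods

## Model

Two species interact repeatedly: a host with discrimination ability α ≥ 0
and a partner with trait β, the net effect of one realized interaction on
host fitness ("partner effect"; β = b_H − c_H b_P, so the host's benefit and
the cost of provisioning the partner are folded into a single trait).
Interaction frequency is f(α, β) = 1/(1 + e^(−αβ)): a non-discriminating
host (α = 0) interacts at frequency 1/2 regardless of partner quality, while
a strongly discriminating host almost always interacts with mutualists and
almost never with antagonists. Per-capita interaction fitness is
w_H = f β − c_D α and w_P = f ŵ_P with ŵ_P = (1 − c_P c_H) b_P − c_P β.
Analyses are restricted to β < β_max = (1 − c_H c_P) b_P / c_P, where the
interaction remains beneficial for the partner (ŵ_P > 0).

Mean traits follow the canonical equations dα/dt = v_H ∂w_H/∂α,
dβ/dt = v_P ∂w_P/∂β, which arise from quantitative genetics in the
small-variance (monomorphic) limit; v_H and v_P are additive genetic
variances per generation time and act only as species-specific clocks.
Gradients and the Jacobian are implemented analytically:

    G_H = β² f (1−f) − c_D
    G_P = f (α (1−f) ŵ_P − c_P)

with finite differences used only as an independent oracle in the tests.
Because discrimination cannot be negative, dα/dt is set to 0 when α = 0 and
G_H < 0; the trajectory then slides along the boundary until selection on α
turns positive.

Population densities are not modelled: selection acts only through the
per-capita interaction fitness, and no density-dependent feedback enters
the gradients.

## Parameters

| parameter | meaning | default |
|---|---|---|
| b_P | benefit to the partner per interaction | 5 |
| c_H | host cost factor per unit service | 0.6 |
| c_P | partner cost factor per unit service | 0.6 |
| c_D | host cost per unit discrimination | 0.1 |
| v_H, v_P | adaptation speeds (trait variance / generation time) | 0.02 |

A common factor on (v_H, v_P) only rescales time; the ratio v_H/v_P shapes
trajectories and basin boundaries. Three named scenarios are used
throughout: fast partner evolution (0.001, 0.02), equal speeds (0.02, 0.02)
and fast host evolution (0.4, 0.02).

## Equilibrium analysis

The partner null-isocline α(1−f)ŵ_P = c_P is strictly monotone in β for
fixed α > 0, so it is represented single-valued as β(α) (bracketed Brent
root, expanding the lower bracket since β(α) → −∞ as α → 0⁺). As a function
of β it has 0, 1 or 2 α-roots (two for β > 0, where α(1−σ(αβ)) is unimodal);
`partner_isocline_alpha` returns all of them. The host isocline
β² f(1−f) = c_D is solved in closed form (f = (1 + √(1−4c_D/β²))/2 on the
feasible branch); it is empty for β² < 4c_D — in particular the host
isocline never touches β = 0, which is why no commensalistic fixed point can
exist for any parameter values and why cost changes can never move a stable
fixed point smoothly across the continuum.

Fixed points are found by two independent routes. The default is multi-start
Newton refinement (`scipy.optimize.root`, analytic Jacobian) from a 60×60
seed grid over α ∈ [0, 8], β ∈ [−3, min(3, β_max − 0.01)] (the window
contains all baseline structure with margin; it is a reproduction choice,
exposed as an argument). The second route scans the host gradient along the
single-valued partner isocline β(α); since every fixed point lies on that
isocline, sign changes of G_H along it enumerate all interior fixed points
at the scan resolution. The scan is ~10× faster and is used inside parameter
sweeps and fold bisection; the test suite checks that both routes agree to
10⁻⁸. Candidates are accepted only if both gradients vanish to 10⁻¹⁰ and
deduplicated at distance 10⁻⁴. Stability comes from the eigenvalues of the
analytic Jacobian of (v_H G_H, v_P G_P): stable if both real parts < −τ,
unstable if any > +τ, marginal otherwise (τ = 10⁻¹², logged as a warning and
never silently relabelled). Interaction type uses |β*| ≤ 10⁻⁶ as the
commensalism tolerance.

## Trajectories

Integration uses SciPy's adaptive RK45 with rtol 10⁻⁸, atol 10⁻¹⁰ (the
system is smooth, two-dimensional and non-stiff). Runs stop at the first of:
entry into a 10⁻³ ball around a supplied stable attractor; phase-velocity
norm below 10⁻¹⁰ (the state is at some fixed point); or the horizon t_end
(default 10⁶, since the model itself prescribes no timescale). The dense
interpolant is resampled at ≥ 500 points, with α clamped to ≥ 0 against
round-off from the boundary rule.

A transition of interaction type is a sign change of β(t). Crossings are
debounced: a crossing counts only between excursions with |β| > 10⁻³ on both
sides, and a start with |β₀| ≤ 10⁻³ has no defined initial type (label
`other`). Labels: `none`, `M_to_A`, `A_to_M`, `back_and_forth`
(−→+ then +→−), `other`.

## Basins and the preadaptation threshold

Basin grids integrate every start of a rectangular grid (default
α₀ ∈ [0, 4] × β₀ ∈ [−3, 3], 81×81; the window is a choice covering all
reported structure — smaller grids are used in the tests) and label cells M,
A or `unresolved` (horizon hit; never guessed).

The preadaptation threshold asks how much initial discrimination guarantees
that an initially antagonistic partner is driven to stable mutualism. For
each β₀ in {−3, −2.5, …, −0.5} the α₀ axis is scanned at step 0.1 and the
boundary above the *largest* antagonism-labelled α₀ is refined by bisection
to 0.01. Taking the supremum of the antagonistic set makes the result
meaningful even where the basin boundary is non-monotone in α₀ — which
genuinely happens for strongly antagonistic starts (e.g. β₀ = −2.5 under
fast partner evolution, where α₀ = 0 converges to mutualism but a band of
small positive α₀ does not); such cases are flagged in the report. The
reported threshold is the maximum over the β₀ set: the discrimination level
that guarantees mutualism for all tested antagonistic starts.

## Bifurcation and hysteresis

Folds are located by bisection on the number of mutualistic fixed points
(β* > 10⁻⁶): 2 on one side of the saddle-node, 0 on the other, to bracket
width 10⁻³. Counting via the isocline scan is cheap and unambiguous in a
2-D system, so pseudo-arclength continuation would be machinery without
benefit. Sweeps link fixed points across parameter steps by
nearest-neighbour matching (default steps 0.005 for cost factors, 0.05 for
b_P); loss of the mutualistic pair terminates those branches and records
the fold estimate.

The partner gradient's zero set depends on (b_P, c_H, c_P) only through
β_max: dividing the isocline equation by c_P gives α(1−f)(β_max − β) = 1.
`equivalent_tipping_check` verifies numerically that parameter combinations
with equal β_max produce pointwise-identical partner isoclines — raising
c_H, lowering b_P and raising c_P are interchangeable routes to the same
tipping point.

The hysteresis experiment starts at the stable mutualistic attractor, sets a
cost beyond the fold, integrates to the antagonistic attractor, then
restores the base value and integrates again: the system stays in the
antagonistic basin (final distance to the mutualistic attractor > 0.5). A
sub-fold shock is the negative control (no transition).

## Individual-based model

The stochastic counterpart relaxes the monomorphic-limit assumptions:
fixed-size host and partner populations (default 150 each) evolve in
discrete non-overlapping generations. Each host is paired with one uniformly
drawn partner (and vice versa) — discrimination here is adjustment of
interaction strength with a single present partner, not choice among
alternatives. Offspring are drawn by fitness-proportional multinomial
sampling with relative weights e^w (positive for negative w_H, and
equivalent to weak selection for small fitness differences); each offspring
mutates with probability 0.05 by a Gaussian deviate (default s.d. 0.15
trait units), with α reflected at 0. A single seeded generator drives the
whole run, so identical configurations give bit-identical output; replicate
seeds are derived by fixed offsets.

The mean state is assigned per generation to the basin of the nearest
stable attractor (or by lookup in a supplied deterministic basin grid), and
a basin switch counts only if the new label persists for ≥ 50 consecutive
generations, debouncing demographic noise at the basin boundary. Defaults
(population size, mutation rate and effect, 4000 generations, founding at
the antagonistic attractor) were chosen once so that stochastic basin
switching is observable at desk scale; with them, mean sustained-switch
counts rise monotonically over mutation effect sizes {0.02, 0.1, 0.3}
(Spearman ρ > 0 across ≥ 10 replicates per effect size).

`ode_limit_check` verifies the quantitative-genetics limit: with small
mutational effects and large populations, the IBM mean-trait path is
compared against the deterministic trajectory run at speeds equal to the
realized per-generation trait variances (one generation = one time unit).
The transient can lag — the founding population is monomorphic and variance
builds up over ~1/μ generations, and the matched-variance clock is an
approximation — so agreement is judged by the final state and the attractor
reached, with the full deviation profile reported.

What the IBM does *not* emulate: explicit demography (population sizes are
fixed), spatial or network structure, multiple simultaneous partners per
host, linkage or diploidy, and any environmental stochasticity. Passing
tests therefore show robustness of the deterministic predictions to
demographic noise and mutational input, not realism of any particular
empirical system.

## Numerical choices and limitations

* Sigmoid evaluated on the exp-of-negative branch only; stable for |αβ|
  up to at least the float overflow range (IBM fitness clips αβ at ±700).
* Root tolerances: isocline roots 10⁻¹², fixed-point gradient residuals
  10⁻¹⁰, dedup distance 10⁻⁴.
* The Jacobian is undefined on the clamped boundary α = 0; requesting it
  there is an explicit error rather than a one-sided guess. No boundary
  equilibria exist (dβ/dt < 0 whenever α = 0), so this does not affect
  fixed-point searches.
* Fold and threshold values are bisection midpoints, so their precision is
  the bracket width (10⁻³ in the swept parameter; 0.01 in α₀), not the
  printed number of digits.
* Both isoclines approach their asymptotes (α → 0 for |β| → ∞; β → 0⁺ for
  α → ∞) only logarithmically; tests assert the decay, not spuriously fast
  convergence.
* Default problem sizes (scan resolutions, grid sizes, IBM population and
  replicate counts) are desk-scale choices that resolve all reported
  structure; every one of them is an explicit argument.
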