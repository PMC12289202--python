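# coevodyn

Coevolutionary dynamics of a two-species interaction along the
mutualism–antagonism continuum.

Many interspecific interactions — legume–rhizobium nutrient exchange,
yucca–yucca moth pollination, cleaner-fish mutualisms — are not fixed as
"mutualism" or "antagonism" but move along a continuum as the two partners
coevolve. `coevodyn` implements a minimal coevolutionary model of this
process for theoretical ecologists: one species (the *host*) evolves a
discrimination ability α ≥ 0 that couples interaction frequency to partner
quality, while the other (the *partner*) evolves the net fitness effect β of
one interaction on the host (β > 0 mutualism, β < 0 antagonism). The package
provides the analysis pipeline end to end: analytic selection gradients,
trait-ODE integration, fixed points and linear stability, saddle-node
(tipping point) detection, basin-of-attraction mapping, hysteresis
experiments, and a stochastic individual-based counterpart.

## Model

Interaction frequency follows a sigmoid in the product of the two traits,

    f(α, β) = 1 / (1 + e^(−αβ)),

and per-capita interaction fitness is

    w_H = f(α, β)·β − c_D·α
    w_P = f(α, β)·((1 − c_P c_H)·b_P − c_P β),

where b_P is the benefit the host provides to the partner, c_H and c_P are
the cost factors of providing service, and c_D is the host's cost of
discrimination. Mean traits evolve down the canonical equations of
quantitative trait evolution,

    dα/dt = v_H · ∂w_H/∂α = v_H · (β² f (1−f) − c_D)
    dβ/dt = v_P · ∂w_P/∂β = v_P · f · (α (1−f) ŵ_P − c_P),

with ŵ_P = (1 − c_P c_H) b_P − c_P β and dα/dt clamped to 0 at the α = 0
boundary when selection on discrimination is negative. The baseline
parameterization is b_P = 5, c_H = c_P = 0.6, c_D = 0.1, v_H = v_P = 0.02.

At baseline the system has two attractors — a stable mutualism and a stable
antagonism — separated by an unstable mutualistic saddle. Raising the cost
of service (c_P, or equivalently c_H up / b_P down) or of discrimination
(c_D) annihilates the mutualistic pair in a saddle-node bifurcation: an
evolutionary tipping point with hysteresis.

## Worked example

```python
from coevodyn import (BASELINE, TraitState, find_fixed_points,
                      integrate_trajectory, locate_fold)

for fp in find_fixed_points(BASELINE):
    print(f"({fp.alpha:.3f}, {fp.beta:.3f})  {fp.stability:8s} "
          f"{fp.interaction_type}  eigenvalues {fp.eigenvalues}")

stable = [fp for fp in find_fixed_points(BASELINE) if fp.stability == "stable"]
traj = integrate_trajectory(TraitState(0.4, -1.5), BASELINE, attractors=stable)
print(traj.pathway_label, "->", traj.final)

print("cP tipping point:", locate_fold(BASELINE, "cP", (0.6, 1.0)))
```

prints

```
(0.306, -0.635)  stable   antagonistic  eigenvalues ((-0.0008893427347362055+0.01094187165493965j), (-0.0008893427347362055-0.01094187165493965j))
(0.508, 0.641)  unstable mutualistic  eigenvalues ((0.006512712087800614+0j), (-0.010261587604879312+0j))
(2.065, 1.003)  stable   mutualistic  eigenvalues ((-0.0017247042979593036+0j), (-0.02184382402749278+0j))
back_and_forth -> TraitState(alpha=0.30630786959090867, beta=-0.6360462390310881)
cP tipping point: 0.7855468750000001
```

Reading: three fixed points; the antagonistic attractor has complex
eigenvalues (trajectories spiral in), the mutualistic attractor real ones.
A start at (α₀ = 0.4, β₀ = −1.5) makes a *back-and-forth* transition —
transient mutualism, then a return to the antagonistic attractor. The stable
and unstable mutualistic fixed points collide near c_P ≈ 0.79: above this
cost of mutualistic service, only antagonism remains, and lowering the cost
again does not restore mutualism (see `hysteresis_experiment`).

The same stages are available from the shell:

```
coevodyn fixed-points --out out/
coevodyn bifurcation --param cP --range 0.6:1.0 --out out/
coevodyn basins --scenario fast-partner --out out/
coevodyn hysteresis --param cP --high 0.9 --out out/
coevodyn ibm --sigma-grid 0.02,0.1,0.3 --replicates 10 --out out/
```

Each command writes CSV/JSON artifacts plus a `manifest.json` recording the
configuration hash, package version and seed.

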