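# crisprdyn

Population dynamics of CRISPR adaptive immunity in bacteria–phage systems.

Bacteria defend against lytic phage by integrating short phage-derived
sequences (spacers) into their CRISPR locus; a spacer blocks reinfection
except with a failure probability η, can be acquired during an unsuccessful
infection with probability α, and is lost at rate κ. `crisprdyn` implements
the resulting compartment ODE models — wild-type and spacer-enhanced
bacteria, their infected counterparts, and free phage — for a single spacer
type and for N spacer types with heterogeneous (αᵢ, ηᵢ), together with the
analytic steady-state theory, a stiff integrator front-end, regime
classification, reference scenario generators and spacer-diversity
summaries. It is aimed at quantitative microbiologists and modellers who
want to explore coexistence conditions or extract CRISPR parameters
(spacer effectiveness, acquisition and loss rates) from population-level
measurements.

## The model in brief

Single spacer type (n = n₀ + n₁ + I₀ + I₁ total bacteria, v free phage):

    ṅ₀ = f₀(1 − n/K)n₀ + κn₁ − gvn₀
    ṅ₁ = f₁(1 − n/K)n₁ − κn₁ − ηgvn₁ + αμI₀
    İ₀ = gvn₀ − μI₀
    İ₁ = ηgvn₁ − μI₁
    v̇  = b(1−α)μI₀ + bμI₁ − gv(n₀+n₁)

with carrying capacity K, adsorption rate g, lysis rate μ and burst size b.
Coexistence of bacteria and phage requires spacer loss (κ > 0) and an
effective spacer (η below a critical value η_c ≈ 1/b); the bacteria then
plateau below capacity at n = K(1−F) with

    F = (κ/f₀)·(b(1−α)−1) / ((b−1)(1−bη)),   n₁/n₀ = (b(1−α)−1)/(1−bη).

The N-spacer generalization replaces η by the abundance-weighted mean
failure probability η̄, making the steady state an implicit self-consistency
problem that `solve_coexistence_multi` solves exactly; its distribution of
spacer abundances interpolates between diverse (acquisition-dominated) and
winner-take-all (effectiveness-dominated) regimes.

## Worked example

```python
import crisprdyn as cd

p = cd.SingleSpacerParams(f0=1.0, r=1.0, K=1e5, kappa=1e-2, g=1e-5,
                          eta=0.005, alpha=1e-4, mu=1.0, b=100.0)
print("eta_c =", cd.critical_failure_probability(p))
print("F     =", cd.unused_capacity_single(p))
print("n1/n0 =", cd.spacer_ratio_single(p))

traj = cd.integrate(p, cd.SingleState(n0=1000.0, v=1e4))
end = traj.final_state
print("n_end/K =", end.n_total / p.K, " outcome =", cd.classify_outcome(traj).value)

spec = cd.multi_spacer_scenario("effectiveness_varying", N=20, alpha_total=0.0972)
sol = cd.solve_coexistence_multi(spec.params)
d = cd.spacer_fractions(sol)
print("eta_bar =", sol.eta_bar, " entropy =", cd.shannon_entropy(d),
      " winner share =", cd.winner_share(d))
```

prints

```
eta_c = 0.0099000101010101
F     = 0.0199979797979798
n1/n0 = 197.98
n_end/K = 0.9800020202020201  outcome = coexistence
eta_bar = 0.0013694194883048269  entropy = 1.4731096882193948  winner share = 0.6692432015528736
```

The spacer is effective enough (η = 0.005 < η_c ≈ 0.0099) for coexistence:
the culture plateaus 2% below capacity (n/K = 1 − F) with spacer-enhanced
cells outnumbering wild type 198:1, and the long-time integration reproduces
the closed forms to machine precision. In the 20-spacer run where spacers
differ only in effectiveness, the best (lowest-η) spacer captures 67% of the
carriers at the reference total acquisition probability — between the
winner-take-all limit at rare acquisition and the uniform limit at high
acquisition.

## Command line

```
crispr-dyn scenario --list
crispr-dyn scenario --scenario single-invasion --out run.yaml
crispr-dyn simulate --config run.yaml --out results/ --override params.eta=0.005
crispr-dyn steady   --config run.yaml
crispr-dyn sweep    --config sweep.yaml --out sweep.csv
```

`simulate` writes a trajectory CSV (`time, n0, n_1.., I0, I_1.., v, n_total`)
and a JSON summary (outcome, phage peak, bacterial bottleneck, oscillation
count, steady state); `steady` reports the analytic/numeric fixed point;
`sweep` tabulates F, η̄, regime and diversity metrics over parameter grids.
Configs are YAML with strict key checking; rates are given relative to the
growth rate by default.

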