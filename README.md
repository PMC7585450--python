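# hypersis

SIS contagion on hypergraphs: a hyperdegree mean-field theory with
bistability analysis, plus an exact stochastic simulator.

## The problem

Epidemic and social contagion often spreads through group interactions, not
just pairwise contacts. `hypersis` models susceptible–infected–susceptible
(SIS) dynamics on a *hypergraph*: N nodes joined by hyperedges of sizes
m = 2 (links), 3 (triangles), and beyond, where a triangle need not have its
pairwise links present. Infected nodes heal at rate γ. A size-m hyperedge
infects a susceptible member at rate β_m either when **all** other members
are infected (*collective contagion*) or when **at least one** is
(*individual contagion*); triangles can instead act to *heal* their infected
members (a "hipster effect"). Link/triangle structure is wired either
**degree-correlated** (triangle membership ∝ product of the members' link
degrees, f₃(k, k₁, k₂) = 2 k k₁ k₂/(N⟨k⟩)²) or **uncorrelated**
(f₃ = 2⟨k⟩/N²), with links following the configuration model
f₂(k, k′) = k k′/(N⟨k⟩).

The scientific question is when group contagion creates **bistability**: a
stable disease-free state coexisting with a stable endemic state, producing
hysteresis and explosive transitions. The package is aimed at network
scientists and epidemic modellers who want the mean-field phase structure,
the critical rates in terms of degree-distribution moments, and exact
microscopic simulations to check them.

## The theory in brief

Writing x_k for the fraction of infected nodes with link degree k,
U = Σ_k P(k) x_k / N for the prevalence, and
V = Σ_k k P(k) x_k / (N⟨k⟩) for the fraction of infected link ends, the
mean-field closure gives (collective contagion, links+triangles):

* correlated wiring — a scalar self-consistency equation
  V = (1/N⟨k⟩) Σ_k k P(k) (β₂kV + β₃kV²)/(γ + β₂kV + β₃kV²);
* uncorrelated wiring — a coupled (U, V) system with triangle pressure
  β₃⟨k⟩U² in place of β₃kV².

Key closed forms, all in moments ⟨kⁿ⟩ of the link degree distribution:

* epidemic threshold: β₂c = γ⟨k⟩/⟨k²⟩ (both wirings, both rules);
* individual-rule threshold: β₂ + 2β₃ = γ⟨k⟩/⟨k²⟩ (correlated) and a
  rational generalization for the uncorrelated case;
* bistability onset, correlated: β₃c = γ⟨k³⟩⟨k⟩²/⟨k²⟩³;
* bistability onset, uncorrelated: piecewise formula from the quartic
  expansion h(V, β₂c) = (a₀ + a₁V + a₂V²)V² — saddle-node branch when the
  discriminant root is admissible, transcritical branch γ⟨k³⟩/⟨k⟩⁴ otherwise;
* all-sizes propagation condition (individual rule):
  Σ_m (m−1) β_m ⟨k^(m)⟩/⟨k⟩ > γ⟨k⟩/⟨k²⟩.

Numerically, fixed points are enumerated by dense scanning + bisection of
the reduced residual, the onset β₃c is located by bisecting a bistability
predicate on the critical line β₂ = β₂c, and the stochastic model is sampled
exactly with a rejection-free Gillespie scheme (Fenwick-tree rate sampling,
incremental hyperedge eligibility counters).

## Worked example

```python
import hypersis as hs

dist = hs.from_spec("powerlaw-4-67-1000")   # P(k) ∝ k^-4, mean degree ~100
gamma = 2.0

b2c = hs.epidemic_threshold_beta2c(dist, gamma)
b3c_corr = hs.beta3c_analytic_correlated(dist, gamma)
b3c_unc = hs.beta3c_numeric(dist, gamma, "uncorrelated")
print(f"beta2c = {b2c:.5f}")
print(f"beta3c correlated   = {b3c_corr:.5f}  (ratio {b3c_corr/b2c:.2f})")
print(f"beta3c uncorrelated = {b3c_unc:.5f}  (ratio {b3c_unc/b2c:.2f})")

params = hs.EpidemicParams(gamma=gamma, beta2=0.97 * b2c, beta3=2 * b3c_corr)
print(hs.find_fixed_points(dist, params).to_frame())
```

prints

```
beta2c = 0.01604
beta3c correlated   = 0.02483  (ratio 1.55)
beta3c uncorrelated = 0.03924  (ratio 2.45)
          V         U stability
0  0.000000  0.000000    stable
1  0.019518  0.015708  unstable
2  0.568002  0.533429    stable
```

Reading: the pairwise threshold is β₂c ≈ 0.016. Bistability needs a
triangle rate about 1.55× larger than β₂c under correlated wiring but
2.45× under uncorrelated wiring — degree heterogeneity suppresses explosive
transitions when triangles are placed independently of the links. At
β₂ just below β₂c and β₃ twice the onset, the system is bistable: a stable
healthy state, an unstable separatrix near U ≈ 0.016, and a stable endemic
state at U ≈ 0.53. An initial infection above the separatrix tips into the
endemic state; below it, the epidemic dies out.

The same analyses are scriptable from the shell — see `hypersis --help`
(subcommands `generate`, `meanfield`, `threshold`, `beta3c`, `bindex`,
`phase`, `simulate`, `sweep`, `fixture`).

`scripts/hysteresis_demo.py` runs the full N = 10⁴ hysteresis sweeps (prevalence
vs β₂, up then down, for three β₃ values around the uncorrelated onset) and
writes the microscopic and mean-field branches as CSV; the agreement is
qualitative, as expected of an independence closure.

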