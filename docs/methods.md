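# Methods

This note records the model, the numerical choices, and the design decisions
behind `hypersis`, at the level of detail a maintainer or a careful user
needs. Empirical claims here are limited to what the test suite and
`scripts/acceptance.py` themselves compute.

## Model and assumptions

The state space is SIS on a hypergraph: each node is susceptible or
infected; infected nodes heal at rate γ (Markovian, rate units 1/time
throughout). A size-m hyperedge carries rate β_m and acts under one of two
rules — *collective* (the single susceptible member is infected at β_m only
when all m−1 others are infected) or *individual* (every susceptible member
with ≥1 infected co-member is infected at β_m). For m = 2 the rules
coincide with ordinary pairwise SIS. With `triangle_sign="healing"` the
size-3 channel keeps its eligibility condition but recovers infected
members at β₃ instead.

The mean-field theory assumes (i) nodes of equal link degree are
statistically exchangeable and (ii) node states are independent (no pair
correlations). Both are closures, not facts about the chain: the simulator
and the mean field agree *qualitatively*, and quantitative agreement is
only expected where the closure is exact in the large-N limit (e.g. the
regular links-only graph, which the tests use as the quantitative anchor).
The wiring probabilities are
f₂(k,k′) = kk′/(N⟨k⟩); f₃ = 2kk₁k₂/(N⟨k⟩)² (degree-correlated) or 2⟨k⟩/N²
(uncorrelated), both normalized so the mean triangle degree ⟨q⟩ equals ⟨k⟩
unless the caller overrides it; and, for general m, the correlated form
f_m = (m−1)! (k k₁…k_{m−1}/(N⟨k⟩)^{m−1}) ⟨k^(m)⟩/⟨k⟩.

Triangles are *not* closed into simplicial complexes: the three members of
a triangle need not share links. Duplicate hyperedges are legal and kept,
because each copy is an independent exponential clock in the rate model.

## Degree distributions

Distributions live on explicit integer supports and are normalized by
direct summation (not by continuous integration); all moments ⟨kⁿ⟩ are
exact sums over the support. The three calibrated presets — uniform on
51..149, power law r=4 on 67..1000, power law r=3 on 53..1000 — read
strictly-written bounds as exclusive, which makes the uniform preset's mean
exactly 100 and the power-law means 100 within 2%.

## Fixed-point analysis

**Reduction.** For correlated wiring every rule/sign combination reduces to
a scalar residual in V because the per-class infection pressure factorizes
as A_k = kV·s(V) with
s = β₂ + σβ₃V (collective) or β₂ + σ(2β₃ − β₃V) (individual), σ = ±1 the
triangle sign. For uncorrelated wiring the pressure is
A_k = β₂kV + σβ₃⟨k⟩T(U), T = U² or 2U − U², giving a coupled (U, V) system.

**Elimination for the uncorrelated system.** At fixed U > 0 the V-equation
has a right-hand side that is concave and increasing in V with a positive
value at V = 0 (contagion sign), so it has exactly one root V*(U), found by
vectorized bisection (60 iterations). Substituting V*(U) into the
U-equation yields a scalar residual F(U) on (0, 1]; its roots are the
nonzero equilibria, the origin is handled separately. This keeps root
*counting* one-dimensional, which is what phase diagrams need.

**Scanning and polishing.** Residuals are scanned on a grid of ~1600 points
that is geometric on [10⁻⁸, 0.05] and uniform on [0.05, 1]: saddle-node
pairs near onset are born at small V, and a uniform grid misses them. Sign
changes are polished by Brent's method to 10⁻¹⁴ and merged if closer than
10⁻⁶ in V (separates genuine saddle-node pairs from polish noise).

**Physical validity with the healing sign.** When σ = −1 the pressure A_k
can be negative, the algebraic fixed point x_k = A_k/(γ + A_k) leaves
[0, 1], and denominators can vanish for large k. Because the sign of A_k is
shared across k (it is kV·s(V)), the physical region is simply
{V : s(V) ≥ 0}, and roots are counted only there. This restriction is what
produces the observed topologies: collective healing never yields a third
solution, while individual healing has a narrow three-solution band along
the shifted threshold β₂ ≈ β₂c + 2β₃ — far above the default contagion-case
β₂ range, so the healing-individual phase diagram widens its default β₂
grid to cover 1.2·(β₂c + 2β₃max). Fixed-point enumeration for the
*uncorrelated* healing variant is not implemented (the V-elimination
uniqueness argument fails when the triangle pressure is negative); its
epidemic threshold is still available in closed form.

**Stability.** The origin is labeled by the linearization: β₂ < β₂c
(collective), β₂ + 2σβ₃ < γ⟨k⟩/⟨k²⟩ (individual correlated), or the
eigenvalues of the 2×2 (δU, δV) Jacobian (individual uncorrelated).
Interior roots take the sign of the residual slope — these reduced systems
are effectively one-dimensional along their slow manifold — and the labels
are cross-validated in the tests by integrating the ODE from perturbed
roots. The ODE integrator is adaptive RK45 with derivatives projected at
the box boundary (a component at 0 or 1 cannot be pushed outward) and an
early-stop event at max|dx/dt| < 10⁻¹⁰.

## Bistability onset

**Numeric (default).** h(V, β₂) is monotone in β₂ and h(0, β₂c) = 0, so
bistability for some β₂ < β₂c is equivalent to h(·, β₂c) having a positive
excursion at V > 0 — the continuity argument that also yields the closed
form. The default predicate therefore evaluates sup h on the critical line
and bisects β₃ to relative width 10⁻⁴. The literal alternative
(`method="grid"`): count roots over a β₂ grid concentrated in
[0.9, 1.02]·β₂c (2/3 of the points) and bisect on "3 roots somewhere".
It is kept because it makes no monotonicity argument, but near onset the
bistable β₂-window shrinks quadratically, so a fixed grid resolves the
onset only to a few percent; the tests check the two agree at that level.

**Analytic, correlated.** β₃c = γ⟨k³⟩⟨k⟩²/⟨k²⟩³, from ∂h/∂V(0, β₂c) > 0.

**Analytic, uncorrelated.** The coefficients of
h(V, β₂c) = (a₀ + a₁V + a₂V²)V² were re-derived symbolically (sympy)
rather than transcribed, because typeset fraction grouping is ambiguous in
the source material: expand U(V) to second order at β₂ = β₂c by
*subtracting* the U- and V-equations (the subtraction cancels the triangle
term at first order, pinning the U–V relation), substitute into the
V-equation, expand to fourth order. The derivation is anchored by two
exact identities it must and does reproduce: a₀ = 0 ⟺ β₃ = γ⟨k³⟩/⟨k⟩⁴, and
the k-regular case gives β₃c/β₂c = 1. The derived expressions (m_n ≡ ⟨kⁿ⟩):

    a₀ = − m₁m₃/m₂² + β₃ m₁⁵/(γ m₂²)
    a₁ = m₁²m₄/m₂³ + β₃ (2 m₁⁴m₃/m₂³ − 4 m₁⁵/m₂²)/γ
    a₂ = − m₁³m₅/m₂⁴
         + β₃ (5 m₁⁵/m₂² + 3 m₁⁶m₃/m₂⁴ − 6 m₁⁴m₃/m₂³ + m₁³m₃²/m₂⁴)/γ
         − β₃² m₁¹⁰/(γ² m₂⁴)

The coefficients are polynomials in β₃ (a₀, a₁ linear; a₂ quadratic), so
the saddle-node
condition a₁² − 4a₀a₂ = 0 is a cubic in β₃ solved by companion-matrix
roots; a root is admissible if a₂ < 0 and the vertex −a₁/(2a₂) ∈ [0, 1],
and the smallest admissible root wins, else the transcritical branch
γ⟨k³⟩/⟨k⟩⁴. The quartic truncation is the accuracy limit: for the r=4
preset the piecewise formula gives 0.0415 against the bisection onset
0.0392 (≈6%), and the error grows with heterogeneity; the expansion is
deliberately not pushed beyond fourth order.

**Bistability index.** B(β₃) = max over a β₂ grid (default
[0.5, 1.5]·β₂c, 201 points) of the spread between the largest and smallest
*stable* equilibrium U, the disease-free state included when stable.

## Stochastic simulator

Exact continuous-time Gillespie, rejection-free. All hyperedges (any size)
share one flat representation; per node the simulator keeps the summed rate
of its currently eligible contagion channels (w) and healing channels (wh),
per hyperedge the count of infected members. A node flip touches only its
incident hyperedges; eligibility deltas update the co-members' sums, and
per-node total rates live in a Fenwick tree (O(log N) sampling and
update). A refresh of the tree every 2²⁰ events bounds float drift. The
absorbing state (total rate 0) ends the run. Seeds: one integer seed per
run feeds a numpy Generator; the jitted kernel receives a derived 31-bit
seed, so trajectories are bit-reproducible.

The hysteresis protocol ramps β₂ linearly up and back down, carrying the
end state of each step into the next, discarding a transient (default
10/γ) and averaging prevalence over a window (default 30/γ) per step; the
defaults follow the adiabatic-sweep idea and are config-overridable. If the
chain goes extinct on the *up* branch it is re-seeded with the initial
infected fraction and a warning is logged; down-branch extinction at small
β₂ is the physical answer and is left alone. Near a continuous transition
(β₃ = 0) the finite-size chain needs long windows per step, otherwise
extinction/regrowth lag masquerades as a branch gap — the tests use a
15-time-unit window per step (30/γ at γ = 2) at N = 10³ for that reason.

## What the generators emulate, and what they do not

The fixture generators produce the study conditions: power-law r=4 degrees
on 67..1000 (mean ≈ 100), uncorrelated or correlated triangles with
⟨q⟩ = ⟨k⟩, N = 10⁴ ("powerlaw-10k") or N = 10³ ("powerlaw-1k"), and a k = 100
regular links-only graph at N = 2000. Link generation fixes the edge count
at round(N⟨k⟩/2) and draws endpoints ∝ degree — this matches f₂ in
expectation without the self-loop/multi-edge cleanup of stub matching
distorting P(k); stub matching (exact degrees, self-loops dropped) is the
option used where an exact degree sequence matters. These synthetic
hypergraphs have no clustering beyond what the wiring probabilities imply,
no degree–degree assortativity, and no temporal structure; passing tests
on them validates the engine and the theory's internal consistency, not
the realism of any particular contact network.

## Problem sizes and tolerances used in the shipped checks

Scan grids of 1201–1601 points; β₃ bisection to 10⁻⁴ relative (10⁻⁷ for
the regular-network ratio check); phase-diagram grids of a few hundred to
~12 000 cells; simulations at N = 2000–10³ nodes with 10³–10⁴ replicates
for distributional tests (KS at α = 0.01). These sizes resolve every
qualitative claim and keep the full suite in a few minutes; all are
parameters, not constants, and scale up directly.

## Known limitations

* Mean field is quantitatively biased at moderate prevalence (no pair
  correlations); only qualitative agreement with simulation is claimed.
* No q-resolved (triangle-degree-specified) variant: connection
  probabilities depend on link degrees only.
* No quorum (j-of-m) rule; collective and individual are the two extremes.
* Uncorrelated + healing fixed-point enumeration unimplemented (above).
* The all-sizes model implements the degree-correlated structure only,
  with the contagion sign.
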