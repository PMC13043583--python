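# xlinkdyn

Dynamics of two-species polymer solutions reversibly cross-linked by dedicated
dumbbell particles: a field-theoretic analytic engine for the effective
networking potentials and coupled dynamic structure factors, paired with a
desk-scale Langevin simulator of semi-flexible bead-spring chains with
reversible cross-linking and the trajectory estimators used to compare the two.

## Who this is for

Researchers in coarse-grained biopolymer and soft-matter modelling who want a
tractable analytic handle on how transient cross-linking by mediator particles
(think actin cross-linking proteins, or telechelic linkers in associative
gels) reshapes collective density dynamics — and a small, fully scripted
molecular-dynamics counterpart to validate the qualitative predictions.

## The model in brief

A cross-linker is a dumbbell: two endpoints joined by a spring (constant
κ), each endpoint with drag γ_y and Gaussian noise λ_y, so the centre of mass
diffuses with D_ρ = λ_y/(4γ_y²). Reversible binding of endpoints to monomers
of species A or B is encoded by Gaussian networking fields; a doubly bound
linker gets a statistical advantage e^ε (bridging A–B) or e^{μ_A}, e^{μ_B}
(within one species). In the strong cross-linking limit the field integrals
are evaluated at their saddle point and expanded to second order in density
fluctuations, giving six effective couplings (w_A, w_B, w_ρ diagonal; v_AB,
v_Aρ, v_Bρ cross). Adding a same-species repulsion v, the coupled dynamic
structure factors follow from inverting

    [[1/S0_A + w_A + v,   v_AB,              v_Aρ           ],
     [v_AB,               1/S0_B + w_B + v,  v_Bρ           ],
     [v_Aρ,               v_Bρ,              1/S0_ρ + w_ρ + v]]

at each (k, ω), where S0 are the bare diffusive Lorentzians. The minimum
repulsion v_min that keeps the system from collapsing is the largest real
root of a cubic in v.

The simulator realises the same system concretely: FENE/WCA bead-spring
chains (k = 30, R0 = 1.6, cosine bending k_θ = 20), dumbbell cross-linkers,
a Langevin thermostat (T = 1, damp = 1, dt = 0.005, reduced units), and an
explicit stochastic binding/unbinding rule applied every few steps. Estimators
compute persistence lengths ℓ_p = −⟨ℓ_bond⟩/ln⟨cos θ⟩, the local nematic
order parameter S(r) from the second Legendre polynomial, the cross-link
census (AA/BB/AB/singly-bound/free), and S(q, ω) from collective density
modes on the reciprocal lattice of the periodic box.

See `docs/methods.md` for conventions, calibrations and limitations.

## Worked example

Analytic half — reference parameter set (ε = μ = 50, ρ̄ = 0.25,
C̄_A = C̄_B = 1, α = τ = γ = κ = λ = 1, L = 100):

```python
>>> from xlinkdyn import network_potentials, v_min
>>> from xlinkdyn.cli_io import paper_model
>>> pots = network_potentials(paper_model())
>>> {k: float(f"{v:.6g}") for k, v in pots.as_dict().items()}
{'w_A': 1.33333, 'w_B': 1.33333, 'w_rho': 18.6667,
 'v_AB': -1.52395e-22, 'v_Arho': -5.33333, 'v_Brho': -5.33333}
>>> round(v_min(pots), 4)
1.4891
```

The diagonal couplings are repulsive (positive) and the polymer–linker cross
couplings strongly attractive; the direct A–B coupling is negligibly small at
ε = 50 because a shared linker, not a direct interaction, mediates it. The
collapse threshold v_min ≈ 1.49 confirms that the repulsion v = 2 used for
the reference spectra keeps every (k, ω) stable. The same pipeline from the
shell, writing the potentials and the full spectra as TSV:

```sh
xlinkdyn analytic --fig7 --v 2.0 --out out/
# v_min = 1.48913; stable at v = 2.0; wrote out/spectra.tsv
```

Simulation half — a small smoke run and its analysis:

```sh
xlinkdyn simulate --small --steps 1000 --seed 7 --out run/
xlinkdyn analyze --traj run/traj.dump --census run/census.tsv --out run/analysis/
```

which writes per-chain persistence lengths (`lp.tsv`), the order parameter
versus cutoff radius (`order.tsv`), per-species S(q, ω) tables and a census
summary. `xlinkdyn fixtures --paper-composition` emits the full published
topology (29 000 particles: 600 chains × 40 beads + 2500 dumbbells) and its
run configuration without running it.

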