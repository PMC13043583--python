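# Methods

`xlinkdyn` has two halves that describe the same physical system — two species
of polymers reversibly bridged by dedicated dumbbell cross-linkers — at two
levels: a field-theoretic analytic model whose output is effective potentials
and coupled dynamic structure factors, and a coarse-grained Langevin simulator
whose trajectories are reduced to the same observables.

## Analytic model

### Cross-linker dynamics

A cross-linker is two endpoints joined by a harmonic spring (constant
`kappa`), each endpoint overdamped with drag `gamma_y` and driven by Gaussian
noise of strength `lambda_y`. In centre-of-mass/extension coordinates the
centre diffuses with `D_rho = lambda_y / (4 gamma_y^2)` and the extension
relaxes on the time `gamma_y / kappa`. The propagator
(`linker_model.linker_propagator`, normalisation fixed to 1) decays in the
extension sector to a finite plateau for lags well beyond `gamma_y / kappa`;
that steady state is the basis of the *pre-averaging* of the endpoint density:
in Fourier space the density of endpoints is `(2 - (lambda_y / kappa gamma_y)
k^2) rho_0(k)`, two endpoints per linker with a curvature correction from the
finite spring extension. The prefactor changes sign at
`k^2 = 2 kappa gamma_y / lambda_y`; beyond that the short-extension expansion
no longer represents a density, and `endpoint_density_fourier` flags it.

The bare (pre-networking) dynamic structure factors are the diffusive
Lorentzians of a flexible-polymer solution,
`S0_p = 2 gamma_p k^2 / (gamma_p^2 w^2 + k^4 / L^2)`, and of a Brownian
particle, `S0_rho = D k^2 / (D^2 k^4 + w^2)`. Their frequency integrals are
`2 pi L` and `pi` for every nonzero `k` — a sum rule the tests verify by
quadrature. The `k = 0` mode of either spectrum vanishes identically, so its
inverse is undefined; all grids therefore start at the smallest nonzero
wavenumber.

### Networking potentials

Reversible binding is encoded by Gaussian networking fields that intermittently
constrain linker endpoints to attachment points, with statistical advantages
`exp(mu_A)`, `exp(mu_B)` (both endpoints on one species) and `exp(eps)` (one
on each). In the strong cross-linking limit (`exp(mu), exp(eps) >> 1`) the
field integrals have closed saddle points — `phi_bar = (C - P)/(alpha tau)`,
`phi_star_bar = P/(C - P)` intra-species, and the analogous four-field
solution inter-species — valid only while the attachment density exceeds the
(endpoint) linker density; the package raises a collapse error otherwise.

Expanding the saddle free energy to second order in density fluctuations
around uniform backgrounds yields quadratic couplings between the fields
(`Delta C_A`, `Delta C_B`, `Delta rho`). **Convention:** every coupling equals
minus the corresponding Hessian entry of the free-energy density; the sign is
anchored by the inter-species `v_AB`, which is manifestly negative
(attraction between the two species induced by shared linkers). The
inter-species closed forms and the intra-species diagonal forms match that
Hessian exactly (verified symbolically during development and by
finite-difference oracles in the tests). The published closed form of the
intra-species *cross* coupling does not — it is mutually inconsistent with
the free energy it is derived from — so `intra_potentials` evaluates the
corrected analytic mixed derivative, and the literal published expression is
retained as `intra_cross_coupling_printed` for reference. A second, harmless
inconsistency (an `alpha tau` versus `alpha^2 tau^2` factor inside the large
logarithm) is below `exp(-mu)` in relative terms in the strong-linking regime
and vanishes identically at `alpha = tau = 1`, the reference convention.

Two numerical rules apply throughout: advantage exponents of order 50
overflow naive evaluation, so every ratio is written in terms of `exp(-mu)` /
`exp(-eps)` with the dominant exponential cancelled analytically; and the
three channels (inter, intra-A, intra-B) are combined additively at `k = 0`
(the inter-species channel provides no k-dependence, so a common point-linker
convention keeps the channels comparable).

### Spectra and the collapse threshold

The networked generating functional is Gaussian with inverse-spectrum kernels
`B_X = 1/S0_X + w_X + v`, where `v` is a same-species repulsion added to keep
the quadratic form positive. The six correlation/cross-correlation spectra
are exactly the entries of the inverse of the symmetric 3x3 coupling matrix
`[[B_A, v_AB, v_Arho], [v_AB, B_B, v_Brho], [v_Arho, v_Brho, B_rho]]` — the
tests check the printed ratio forms against a brute-force matrix inverse to
1e-12. The collapse threshold `v_min` is the largest real root of the cubic
`det = 0` with the bare inverse spectra dropped; the largest root is the only
one above which the form is positive definite, and since `1/S0 > 0` adds
positive diagonal weight, stability at `v >= v_min` extends to every finite
`(k, w)` (re-verified numerically by `stability_scan`). For the reference
parameter set (`eps = mu = 50`, `rho_bar = 0.25`, `C_A = C_B = 1`,
`alpha = tau = gamma = kappa = lambda = 1`, `L = 100`) the package obtains
`v_min ~= 1.489`, consistent with the repulsion `v = 2` used downstream.

## Langevin simulator

### Force field

Reduced units (`sigma = epsilon = m = 1`) throughout. Chains of 40 beads:
FENE backbone bonds (`k = 30`, `R0 = 1.6`) combined with a WCA core at
`sigma = 1` inside the bond — the Kremer–Grest convention, which puts the
bond minimum at `r ~= 0.97`; bonded pairs are excluded from the pair table.
Bending is a cosine potential `k_theta (1 - cos theta)` with `theta` the
deviation from a straight triplet (`U = 0` for collinear bonds), `k_theta =
20`; the alternative sign convention would collapse rather than stiffen the
chains. Nonbonded excluded volume is truncated-shifted Lennard-Jones at the
WCA cutoff per pair class: (1.0, 1.0, 1.12) monomer–monomer, (1.0, 1.5, 1.68)
linker–monomer, (1.0, 2.0, 2.24) linker–linker. Cross-linkers are dumbbells:
two beads joined by the same FENE+core bond.

Integration is velocity Verlet with a Langevin thermostat: friction
`-m v / damp` and Gaussian kicks of per-component force variance
`2 m T / (damp dt)` enter each force evaluation (`T = 1`, `damp = 1`,
`dt = 0.005`). The contract is the thermostatted temperature and the Einstein
diffusion constant (`D = T damp / m`), not trajectory identity with any other
code. Equilibration begins with a short warm-up at `dt/5` to relax residual
packing overlaps. A per-step displacement cap (default 0.1) guards against
the rare large transient right after a bond-formation event; at thermal
speeds (`~0.009` per step) it never engages. Neighbour search is a linked
cell list rebuilt every step (cheap at these sizes), with the cell count
capped so sparse systems with small cutoffs do not pay for empty cells.

### Reversible cross-linking

Binding and unbinding are an explicit stochastic rule applied every
`sweep_interval` steps (the supplementary reaction templates of the original
workflow are not part of the published text, so the rule is stated fully
here). Each dynamic bond breaks with probability `p_break`; each unbound
linker bead then draws a uniformly chosen *eligible* monomer (no dynamic bond
yet) within the capture radius and binds with `p_bond1` (first bead of its
dumbbell) or `p_bond2` (second). No detailed balance is assumed; the design
target is a stationary census.

Two geometric facts shape the scheme. First, a FENE bond cannot form at or
beyond `R0 = 1.6`, so the capture radius is clamped to `0.95 R0 = 1.52` even
though the configured `r_react` (default 1.95) is larger. Second, the
linker–monomer excluded volume (`sigma = 1.5`, contact 1.68) holds unbound
pairs near or beyond the whole FENE range; excluding a freshly bonded pair
from the pair table would therefore inject the full difference (tens of kT)
as kinetic energy at every binding event and destabilise the integrator.
Dynamic bonds are therefore *bare* FENE with the nonbonded repulsion
retained: the bound pair sits at the combined minimum (`r ~= 1.33`), the
kinetic energy released per event is small, and breaking simply releases a
mildly repulsive pair. Permanent bonds are unaffected.

By default the second bead may not complete the cross-link on the chain its
partner is already attached to (`allow_same_chain = False`): geometrically
the dangling bead is almost always nearest to that same chain, and the
resulting short loops neither bridge chains nor perturb conformations, while
the published observations (species-pair census magnitudes, chain clumping,
reduced persistence length and local order) are signatures of chain-bridging
links. The switch is in the configuration, and the census always records a
same-chain count alongside the AA/BB/AB species-pair classes.

The default rates (`p_bond1 = 0.5`, `p_bond2 = 1.0`, `p_break = 5e-4`,
`sweep_interval = 25`) were calibrated once so that the desk-scale system
reaches a stationary census with most dumbbells doubly bound — the regime the
reference study reports (roughly 2000–2400 of 2500 linkers engaged) — while
bonds keep forming and breaking throughout a production run.

### Desk-scale study conditions

The full published composition is 300 + 300 chains of 40 beads plus 2500
dumbbells in a periodic box of edge 100 (29 000 particles, number density
0.029). The desk-scale configuration used by the tests and the acceptance
script keeps the composition *ratios* (40-bead chains, ~4.2 dumbbells per
chain, equal species) and the number density, at 12 + 12 chains and 100
dumbbells (1160 particles, box edge ~34). Production runs are 4e5 steps
after 2e4 equilibration steps, sampled every 20 steps; persistence lengths
and order parameters are measured from step 1.5e5 onward, after the census
has plateaued and the freshly formed network has relaxed. These sizes were
chosen as the smallest at which the cross-linked versus free comparison is
statistically resolvable (per-chain persistence lengths need long time
averages before the chain-to-chain spread stops being sampling noise); the
full-composition runs of the reference study are three orders of magnitude
more expensive and are deliberately out of scope, so printed full-scale
values (e.g. the cross-linked persistence length 14.33) are approached only
in ordering, not magnitude, at desk scale.

## Trajectory estimators

*Persistence length* uses the bond-angle route `lp = -<l_bond>/ln<cos theta>`
per chain, with the cosine averaged over all adjacent bond pairs and frames
first, then the ratio, then mean ± sd across chains. The freely-rotating
prediction `-l / ln(coth(k_theta/T) - T/k_theta)` (≈ 19.50 bond lengths at
`k_theta = 20`) serves as an independent oracle for un-cross-linked chains.
`<cos theta> <= 0` raises (the estimator is undefined); a perfectly straight
chain is flagged infinite.

*Local nematic order* `S(r)` is the second-Legendre average over ordered
pairs of backbone bonds whose anchor monomers (first monomer of each bond)
lie within `r` under minimum image, with the `1/(2 N_r)` prefactor that makes
perfect alignment give exactly 1; adjacent bonds of one chain count like any
other pair (only `i = j` is excluded).

*S(q, omega)* is estimated from collective density modes on the reciprocal
lattice of the box (`q = 2 pi n / L`, one representative per ±q pair), a
periodogram over time per mode, spherical averaging over shells of width
`2 pi / L`, and per-particle normalisation chosen so that summing over
frequency recovers the static structure factor (a discrete Parseval identity,
exact without a taper; a Hann taper is available but off by default, and no
omega averaging is applied). Dense outer shells may be represented by a
deterministic random subset of lattice vectors (`max_vectors_per_shell`) —
an unbiased spherical average at much lower cost. For line-shape fits a
second grouping mode assigns shells by exact `|q|` (`shell_mode = "exact"`):
the smallest width-shell otherwise mixes lattice vectors whose relaxation
rates differ by a factor two, visibly broadening a fitted width. For free
Brownian particles the estimate converges to the analytic Lorentzian with
half-width `D q^2`, which cross-validates both the estimator and the
thermostat's Einstein relation; the validation starts from a uniform
(structureless) configuration — the rejection-packed builder imprints weak
short-range order whose relaxation contaminates collective modes — and fits
only the diffusive band `|omega| <= 10 D q^2`, outside which the inertial
`1/omega^4` tail of the underdamped Langevin spectrum is not Lorentzian.

*Cross-link census* summaries report post-burn-in mean/sd/range per class and
a stationarity diagnostic (first-half vs second-half mean difference in sd
units; 0 for a constant series).

## What the desk-scale comparisons do and do not show

Passing tests demonstrate: the analytic formulas are internally consistent
(Hessian and matrix-inverse identities, sum rules, symmetry and zero-density
limits); the simulator reproduces exact statistical-mechanics baselines
(equipartition, Einstein diffusion, the freely-rotating persistence length,
energy conservation without the thermostat); and the cross-linked versus free
comparison reproduces the reference orderings (census rise-then-plateau,
lower local order at every radius, reduced persistence length, lower/broader
small-q diffusive peaks with enhanced large-q weight). They do not establish
quantitative transferability to the full 29 000-particle composition, do not
include hydrodynamics or entanglement, and the analytic model remains a
flexible-chain theory compared against semi-flexible simulations — only
qualitative shapes are comparable by construction.

## Known limitations

- The strong-linking approximation is baked into the potentials; there is no
  adaptive weak-linking branch, and preconditions (`C > P`, `C > rho`) are
  enforced by errors rather than crossovers.
- The inter-species potentials carry no k-dependence (the pre-averaged
  extension enters the intra-species channel only), so the combined potential
  set is a `k = 0` object by construction.
- The reaction scheme is a model of the (unpublished) original templates, not
  a reimplementation; only its stationary-census character is matched.
- Periodogram estimates of S(q, omega) are noisy per frequency bin (no omega
  averaging by default, mirroring the reference post-processing) and show
  finite-window leakage at low omega.
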