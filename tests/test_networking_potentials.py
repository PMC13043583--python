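"""Saddle points, effective networking potentials and their free-energy oracles.

The central check: every coupling equals minus the corresponding second
derivative of the saddle free-energy density at the background densities.
The oracle is an independent transcription of the printed free-energy
integrands differentiated by high-precision central finite differences
(mpmath at 50 digits), never the closed forms under test.
"""

import math

import mpmath as mp
import pytest
from hypothesis import given, settings, strategies as st

from xlinkdyn.linker_model import LinkerParams
from xlinkdyn.networking_potentials import (
    CollapseError,
    NetworkModel,
    combine_potentials,
    crosslink_count_inter,
    crosslink_count_intra,
    free_energy_density_inter,
    free_energy_density_intra,
    inter_potentials,
    intra_cross_coupling_printed,
    intra_potentials,
    network_potentials,
    saddle_inter,
    saddle_intra,
)

# enough digits that the tiny strong-limit cross couplings (~1e-22) survive
# the cancellation in the second differences
mp.mp.dps = 80
LINKER = LinkerParams(1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# independent free-energy transcriptions (mpmath)
# ---------------------------------------------------------------------------

def f_intra_mp(C, rho0, mu, alpha, tau):
    """Strong intra-species saddle free-energy density, endpoint density P = 2 rho0."""
    C, rho0, mu, alpha, tau = map(mp.mpf, (C, rho0, mu, alpha, tau))
    P = 2 * rho0
    s = (alpha * tau) ** 2
    return (C * mp.log(C / (C - P)) + P * mp.log(1 + (C - P) * mp.e**mu / s) - P) / tau


def f_inter_mp(CA, CB, rho, eps, alpha, tau):
    CA, CB, rho, eps, alpha, tau = map(mp.mpf, (CA, CB, rho, eps, alpha, tau))
    s = (alpha * tau) ** 2
    return (
        CA * mp.log(CA / (CA - rho))
        + CB * mp.log(CB / (CB - rho))
        + rho * mp.log(1 + (CA - rho) * (CB - rho) * mp.e**eps / s)
        - 2 * rho
    ) / tau


def hessian_fd(f, x0, y0, h="1e-10"):
    """Central-difference Hessian of f(x, y) at (x0, y0) in extended precision."""
    h = mp.mpf(h)
    x0, y0 = mp.mpf(x0), mp.mpf(y0)
    fxx = (f(x0 + h, y0) - 2 * f(x0, y0) + f(x0 - h, y0)) / h**2
    fyy = (f(x0, y0 + h) - 2 * f(x0, y0) + f(x0, y0 - h)) / h**2
    fxy = (
        f(x0 + h, y0 + h) - f(x0 + h, y0 - h) - f(x0 - h, y0 + h) + f(x0 - h, y0 - h)
    ) / (4 * h**2)
    return fxx, fyy, fxy


# ---------------------------------------------------------------------------
# saddle points
# ---------------------------------------------------------------------------

class TestSaddles:
    def test_intra_values(self):
        s = saddle_intra(1.0, 0.5, 1.0, 1.0)
        assert (s.phi_bar, s.phi_star_bar) == (0.5, 1.0)
        s = saddle_intra(2.0, 0.0, 1.0, 1.0)
        assert (s.phi_bar, s.phi_star_bar) == (2.0, 0.0)

    def test_intra_residuals(self):
        """The solutions satisfy the strong-linking stationarity equations."""
        C, P, alpha, tau, mu = 1.0, 0.5, 1.0, 1.0, 50.0
        s = saddle_intra(C, P, alpha, tau)
        r1 = C / (alpha * tau * (1.0 + s.phi_star_bar)) - s.phi_bar
        # second equation with 1 + phi e^mu ~ phi e^mu
        r2 = P / (alpha * tau * s.phi_bar) - s.phi_star_bar
        assert abs(r1) <= 1e-12 and abs(r2) <= 1e-12

    def test_inter_values_and_residuals(self):
        s = saddle_inter(1.0, 1.0, 0.25, 1.0, 1.0)
        assert (s.phi_bar, s.psi_bar) == (0.75, 0.75)
        assert s.phi_star_bar == pytest.approx(1.0 / 3.0)
        assert s.psi_star_bar == pytest.approx(1.0 / 3.0)
        # back-substitution into the four strong-linking equations
        CA = CB = 1.0
        rho, alpha, tau = 0.25, 1.0, 1.0
        assert s.phi_bar == pytest.approx(CA / (alpha * tau * (1 + s.phi_star_bar)))
        assert s.psi_bar == pytest.approx(CB / (alpha * tau * (1 + s.psi_star_bar)))
        assert s.phi_star_bar == pytest.approx(rho / (alpha * tau * s.phi_bar))
        assert s.psi_star_bar == pytest.approx(rho / (alpha * tau * s.psi_bar))

    def test_no_linker_limit(self):
        s = saddle_inter(1.3, 0.8, 0.0, 1.0, 1.0)
        assert (s.phi_star_bar, s.psi_star_bar) == (0.0, 0.0)

    def test_collapse(self):
        with pytest.raises(CollapseError):
            saddle_intra(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(CollapseError):
            saddle_inter(1.0, 0.2, 0.25, 1.0, 1.0)


# ---------------------------------------------------------------------------
# potentials vs Hessian oracle
# ---------------------------------------------------------------------------

INTER_POINTS = [
    dict(C_A_bar=1.0, C_B_bar=1.0, rho_bar=0.25, eps=50.0, alpha=1.0, tau=1.0),
    dict(C_A_bar=1.4, C_B_bar=0.9, rho_bar=0.3, eps=50.0, alpha=0.8, tau=1.3),
    dict(C_A_bar=2.0, C_B_bar=1.1, rho_bar=0.05, eps=6.0, alpha=1.0, tau=1.0),
    dict(C_A_bar=0.9, C_B_bar=0.8, rho_bar=0.4, eps=9.0, alpha=1.0, tau=1.0),
]


@pytest.mark.parametrize("pt", INTER_POINTS)
def test_inter_potentials_match_hessian(pt):
    """Couplings equal minus the second derivatives of the free energy."""
    m = NetworkModel(mu_A=50.0, mu_B=50.0, linker=LINKER, **pt)
    pots = inter_potentials(m)
    args = (pt["eps"], pt["alpha"], pt["tau"])
    rho = pt["rho_bar"]

    fxx, fyy, fxy = hessian_fd(
        lambda x, y: f_inter_mp(x, y, rho, *args), pt["C_A_bar"], pt["C_B_bar"]
    )
    assert pots.w_A == pytest.approx(float(-fxx), rel=1e-6)
    assert pots.w_B == pytest.approx(float(-fyy), rel=1e-6)
    assert pots.v_AB == pytest.approx(float(-fxy), rel=1e-6)

    fxx, fyy, fxy = hessian_fd(
        lambda x, y: f_inter_mp(x, pt["C_B_bar"], y, *args), pt["C_A_bar"], rho
    )
    assert pots.v_Arho == pytest.approx(float(-fxy), rel=1e-6)
    fxx, fyy, fxy = hessian_fd(
        lambda x, y: f_inter_mp(pt["C_A_bar"], x, y, *args), pt["C_B_bar"], rho
    )
    assert pots.v_Brho == pytest.approx(float(-fxy), rel=1e-6)
    assert pots.w_rho == pytest.approx(float(-fyy), rel=1e-6)


INTRA_POINTS = [
    dict(mu=50.0, rho0_bar=0.25, C_bar=1.0, alpha=1.0, tau=1.0),
    dict(mu=40.0, rho0_bar=0.2, C_bar=1.5, alpha=1.0, tau=1.0),
    dict(mu=8.0, rho0_bar=0.1, C_bar=0.9, alpha=1.0, tau=1.0),
]


@pytest.mark.parametrize("pt", INTRA_POINTS)
def test_intra_potentials_match_hessian_at_k0(pt):
    ip = intra_potentials(0.0, linker=LINKER, **pt)
    fxx, fyy, fxy = hessian_fd(
        lambda C, r0: f_intra_mp(C, r0, pt["mu"], pt["alpha"], pt["tau"]),
        pt["C_bar"],
        pt["rho0_bar"],
    )
    assert ip.w_C == pytest.approx(float(-fxx), rel=1e-6)
    assert ip.w_rho == pytest.approx(float(-fyy), rel=1e-6)
    assert ip.v_Crho == pytest.approx(float(-fxy), rel=1e-6)


def test_intra_reference_point_values():
    """k = 0 reference point: w_C = 1, w_rho = 8, v_Crho = -4."""
    ip = intra_potentials(0.0, 50.0, 0.25, 1.0, 1.0, 1.0, LINKER)
    assert ip.w_C == pytest.approx(1.0, rel=1e-9)
    assert ip.w_rho == pytest.approx(8.0, rel=1e-9)
    assert ip.v_Crho == pytest.approx(-4.0, rel=1e-9)


def test_published_cross_coupling_form_disagrees_with_free_energy():
    """The published closed form of v_Crho is inconsistent with the free energy
    it is derived from (14 vs -4 at the reference point); the package keeps it
    only as a reference and uses the corrected derivative."""
    printed = intra_cross_coupling_printed(0.0, 50.0, 0.25, 1.0, 1.0, 1.0, LINKER)
    assert printed == pytest.approx(14.0, rel=1e-9)
    _, _, fxy = hessian_fd(lambda C, r0: f_intra_mp(C, r0, 50.0, 1.0, 1.0), 1.0, 0.25)
    assert abs(printed - float(-fxy)) > 1.0


def test_gamma_factor_reference():
    """Gamma(0) = -8 for unit linker constants."""
    from xlinkdyn.networking_potentials import _gamma_factor

    assert _gamma_factor(0.0, LINKER) == pytest.approx(-8.0)


# ---------------------------------------------------------------------------
# structural limits and symmetries
# ---------------------------------------------------------------------------

def test_zero_linker_density_zeroes_rho_prefixed_couplings():
    m = NetworkModel(rho_bar=0.0, linker=LINKER)
    pots = inter_potentials(m)
    assert pots.w_A == 0.0 and pots.w_B == 0.0 and pots.v_AB == 0.0
    ip = intra_potentials(0.0, 50.0, 0.0, 1.0, 1.0, 1.0, LINKER)
    assert ip.w_C == 0.0


@given(
    CA=st.floats(0.8, 2.0),
    CB=st.floats(0.8, 2.0),
    rho=st.floats(0.0, 0.5),
    eps=st.floats(3.0, 60.0),
)
@settings(max_examples=60, deadline=None)
def test_inter_species_relabelling_symmetry(CA, CB, rho, eps):
    """Swapping the species exchanges w_A <-> w_B and v_Arho <-> v_Brho exactly."""
    a = inter_potentials(NetworkModel(C_A_bar=CA, C_B_bar=CB, rho_bar=rho, eps=eps))
    b = inter_potentials(NetworkModel(C_A_bar=CB, C_B_bar=CA, rho_bar=rho, eps=eps))
    tol = dict(rel=1e-13, abs=1e-300)
    assert a.w_A == pytest.approx(b.w_B, **tol)
    assert a.w_B == pytest.approx(b.w_A, **tol)
    assert a.v_Arho == pytest.approx(b.v_Brho, **tol)
    assert a.v_Brho == pytest.approx(b.v_Arho, **tol)
    assert a.w_rho == pytest.approx(b.w_rho, **tol)
    assert a.v_AB == b.v_AB


def test_vab_large_eps_asymptote():
    """|v_AB| follows -rho e^-eps / ((C_A-rho)^2 (C_B-rho)^2) deep in the strong limit."""
    m = NetworkModel(eps=50.0)
    pots = inter_potentials(m)
    expected = -0.25 * math.exp(-50.0) / (0.75**2 * 0.75**2) ** 2 * (0.75 * 0.75) ** 2
    # equivalently -rho e^-eps / (a b)^2 with a = b = 0.75
    expected = -0.25 * math.exp(-50.0) / (0.75 * 0.75) ** 2
    assert pots.v_AB == pytest.approx(expected, rel=1e-10)
    assert pots.v_AB == pytest.approx(-1.52e-22, rel=0.01)


def test_vab_magnitude_decreasing_in_eps():
    vals = [
        abs(inter_potentials(NetworkModel(eps=e)).v_AB) for e in (10, 20, 30, 40, 50)
    ]
    assert all(a > b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# combination and counts
# ---------------------------------------------------------------------------

def test_combination_structure():
    m = NetworkModel()
    inter = inter_potentials(m)
    ia = intra_potentials(0.0, m.mu_A, m.rho_bar, m.C_A_bar, m.alpha, m.tau, m.linker)
    ib = intra_potentials(0.0, m.mu_B, m.rho_bar, m.C_B_bar, m.alpha, m.tau, m.linker)
    full = combine_potentials(ia, ib, inter)
    assert full.v_AB == inter.v_AB  # inter channel only
    assert full.w_A == pytest.approx(inter.w_A + ia.w_C)
    assert full.w_rho == pytest.approx(inter.w_rho + ia.w_rho + ib.w_rho)
    assert full.v_Arho == pytest.approx(inter.v_Arho + ia.v_Crho)
    # network_potentials is exactly this composition
    assert network_potentials(m).as_dict() == pytest.approx(full.as_dict())


def test_combination_with_zero_intra_reduces_to_inter():
    from xlinkdyn.networking_potentials import IntraPotentials

    zero = IntraPotentials(0.0, 0.0, 0.0)
    inter = inter_potentials(NetworkModel())
    assert combine_potentials(zero, zero, inter).as_dict() == inter.as_dict()


def test_mismatched_tags_rejected():
    from xlinkdyn.networking_potentials import IntraPotentials, PotentialSet

    a = IntraPotentials(0.0, 0.0, 0.0, tag="set1")
    b = IntraPotentials(0.0, 0.0, 0.0, tag="set2")
    inter = PotentialSet(0, 0, 0, 0, 0, 0, tag="set1")
    with pytest.raises(ValueError):
        combine_potentials(a, b, inter)


@pytest.mark.parametrize(
    "P, alpha, tau, expected", [(10.0, 1.0, 1.0, 10.0), (0.0, 2.0, 3.0, 0.0), (10.0, 1.0, 2.0, 2.5)]
)
def test_crosslink_count_intra(P, alpha, tau, expected):
    assert crosslink_count_intra(P, alpha, tau) == pytest.approx(expected)


@pytest.mark.parametrize(
    "M, tau, T, expected", [(2500, 1.0, 1.0, 2500.0), (0, 1.0, 5.0, 0.0), (2500, 2.0, 1.0, 1250.0)]
)
def test_crosslink_count_inter(M, tau, T, expected):
    assert crosslink_count_inter(M, tau, T) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# free-energy densities
# ---------------------------------------------------------------------------

def test_free_energy_examples():
    # C=1, P=0.5, mu=50: ln 2 + 0.5 ln(1 + 0.5 e^50) - 0.5
    val = free_energy_density_intra(1.0, 0.5, 50.0, 1.0, 1.0)
    expected = math.log(2.0) + 0.5 * (50.0 + math.log(0.5)) - 0.5
    assert val == pytest.approx(expected, rel=1e-10)
    assert val == pytest.approx(24.8466, abs=5e-4)
    assert free_energy_density_intra(1.0, 0.0, 50.0, 1.0, 1.0) == 0.0
    assert free_energy_density_inter(1.0, 1.2, 0.0, 50.0, 1.0, 1.0) == 0.0


def test_free_energy_inter_symmetric():
    a = free_energy_density_inter(1.3, 0.9, 0.2, 12.0, 1.0, 1.0)
    b = free_energy_density_inter(0.9, 1.3, 0.2, 12.0, 1.0, 1.0)
    assert a == pytest.approx(b, rel=1e-14)


def test_free_energy_log_domain():
    with pytest.raises(CollapseError):
        free_energy_density_intra(1.0, 1.5, 50.0, 1.0, 1.0)
    with pytest.raises(CollapseError):
        free_energy_density_inter(1.0, 0.1, 0.2, 50.0, 1.0, 1.0)
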