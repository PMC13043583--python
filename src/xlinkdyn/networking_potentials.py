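"""Effective networking potentials in the strong cross-linking limit.

Reversible binding of dumbbell cross-linkers to two polymer species is encoded
by Gaussian networking fields; evaluating the field integrals at their saddle
point and expanding the resulting free energy to second order in density
fluctuations yields quadratic effective couplings between the three density
fields: the two attachment-point densities ``C_A``, ``C_B`` and the
cross-linker centre-of-mass density ``rho``.

Two limits are tractable and are combined additively:

* intra-species networking (both linker endpoints on the same species, with
  statistical advantage ``exp(mu)``), giving k-dependent couplings
  ``w_C(k)``, ``w_rho(k)``, ``v_Crho(k)``;
* inter-species networking (one endpoint on each species, advantage
  ``exp(eps)``), giving k-independent couplings ``w_A, w_B, w_rho, v_Arho,
  v_Brho, v_AB``.

Each coupling equals minus the corresponding second derivative (Hessian entry)
of the saddle-point free-energy density at the background densities; the
free-energy densities themselves are exposed so that tests can verify the
closed forms against brute-force differentiation.

Large advantage exponents (``mu``, ``eps`` of order 50) are handled by
cancelling the dominant exponential analytically: every ratio is evaluated in
terms of ``exp(-mu)`` / ``exp(-eps)``, so nothing overflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .linker_model import LinkerParams

__all__ = [
    "CollapseError",
    "NetworkModel",
    "SaddleSolution",
    "IntraPotentials",
    "PotentialSet",
    "saddle_intra",
    "saddle_inter",
    "intra_potentials",
    "intra_cross_coupling_printed",
    "inter_potentials",
    "combine_potentials",
    "network_potentials",
    "crosslink_count_intra",
    "crosslink_count_inter",
    "free_energy_density_intra",
    "free_energy_density_inter",
]


class CollapseError(ValueError):
    """A density denominator vanished: the strong-linking saddle collapses."""


@dataclass(frozen=True)
class NetworkModel:
    """Background densities and networking constants of the two-species system.

    ``alpha`` is the field-damping coefficient of the networking functional,
    ``tau`` the networking time interval, ``eps`` the inter-species advantage
    exponent and ``mu_A`` / ``mu_B`` the intra-species ones.  ``C_A_bar`` and
    ``C_B_bar`` are the background attachment-point densities and ``rho_bar``
    the background cross-linker centre-of-mass density (one density field
    serves both the intra- and inter-species formulas; the endpoint density is
    ``2 rho_bar`` at zero wavenumber).
    """

    alpha: float = 1.0
    tau: float = 1.0
    eps: float = 50.0
    mu_A: float = 50.0
    mu_B: float = 50.0
    C_A_bar: float = 1.0
    C_B_bar: float = 1.0
    rho_bar: float = 0.25
    linker: LinkerParams = field(default_factory=LinkerParams)

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.tau > 0):
            raise ValueError("alpha and tau must be strictly positive")
        if not self.rho_bar >= 0:
            raise ValueError("rho_bar must be nonnegative")
        if not (self.C_A_bar > self.rho_bar and self.C_B_bar > self.rho_bar):
            raise CollapseError(
                "saddle solutions require C_bar > rho_bar for both species"
            )


@dataclass(frozen=True)
class SaddleSolution:
    """Stationary networking-field values (psi pair unset for intra-species)."""

    phi_bar: float
    phi_star_bar: float
    psi_bar: float | None = None
    psi_star_bar: float | None = None


@dataclass(frozen=True)
class IntraPotentials:
    """Couplings from strong intra-species networking at one wavenumber."""

    w_C: float
    w_rho: float
    v_Crho: float
    tag: str | None = None


@dataclass(frozen=True)
class PotentialSet:
    """The six effective couplings of the combined two-species system."""

    w_A: float
    w_B: float
    w_rho: float
    v_AB: float
    v_Arho: float
    v_Brho: float
    tag: str | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "w_A": self.w_A,
            "w_B": self.w_B,
            "w_rho": self.w_rho,
            "v_AB": self.v_AB,
            "v_Arho": self.v_Arho,
            "v_Brho": self.v_Brho,
        }


# ---------------------------------------------------------------------------
# saddle points
# ---------------------------------------------------------------------------

def saddle_intra(C: float, P: float, alpha: float, tau: float) -> SaddleSolution:
    """Strong-linking saddle of the single-species networking fields.

    ``phi_bar = (C - P) / (alpha tau)`` and ``phi_star_bar = P / (C - P)`` for
    attachment density ``C`` and endpoint density ``P``.
    """
    if not P >= 0:
        raise ValueError("endpoint density P must be nonnegative")
    if not C > P:
        raise CollapseError(f"saddle denominator C - P = {C - P} is nonpositive")
    return SaddleSolution(phi_bar=(C - P) / (alpha * tau), phi_star_bar=P / (C - P))


def saddle_inter(
    C_A: float, C_B: float, rho: float, alpha: float, tau: float
) -> SaddleSolution:
    """Strong-linking saddle of the two-species networking fields."""
    if not rho >= 0:
        raise ValueError("rho must be nonnegative")
    if not (C_A > rho and C_B > rho):
        raise CollapseError("saddle denominators C - rho must be positive")
    return SaddleSolution(
        phi_bar=(C_A - rho) / (alpha * tau),
        psi_bar=(C_B - rho) / (alpha * tau),
        phi_star_bar=rho / (C_A - rho),
        psi_star_bar=rho / (C_B - rho),
    )


# ---------------------------------------------------------------------------
# intra-species potentials
# ---------------------------------------------------------------------------

def _gamma_factor(k: float, linker: LinkerParams) -> float:
    """Gamma(k) = k^2 lambda_y - 8 gamma_y kappa (negative at small k)."""
    return k**2 * linker.lambda_y - 8.0 * linker.gamma_y * linker.kappa


def intra_potentials(
    k: float,
    mu: float,
    rho0_bar: float,
    C_bar: float,
    alpha: float,
    tau: float,
    linker: LinkerParams,
    tag: str | None = None,
) -> IntraPotentials:
    """Effective couplings from strong intra-species networking.

    The diagonal couplings follow the printed closed forms; the cross coupling
    ``v_Crho`` is the analytic mixed second derivative of the saddle
    free-energy density with the pre-averaged endpoint factor (the published
    closed form for this one entry is inconsistent with the free energy it is
    derived from; see :func:`intra_cross_coupling_printed`).
    """
    g, ka, la = linker.gamma_y, linker.kappa, linker.lambda_y
    G = _gamma_factor(k, linker)
    big = 4.0 * g * ka * C_bar - 8.0 * g * ka * rho0_bar + la * k**2 * rho0_bar
    if big <= 0.0:
        raise CollapseError(
            f"intra-species factor 4*gamma*kappa*C - 8*gamma*kappa*rho0 "
            f"+ lambda*k^2*rho0 = {big} is nonpositive (C_bar <= 2 rho0_bar)"
        )
    em = math.exp(-mu)  # dominant exp(mu) cancelled analytically
    d1 = 4.0 * alpha * g * ka * tau * em + big  # = e^-mu (4 a g k t + e^mu big)

    if rho0_bar == 0.0:
        w_C = 0.0
    else:
        w_C = -(rho0_bar / tau) * (
            4.0 * g * ka * G / d1**2 + rho0_bar * G**2 / (C_bar * big**2)
        )

    num = (
        -64.0 * alpha**2 * g**3 * C_bar * ka**3 * tau**2 * em**2
        + 8.0 * alpha * g * ka * rho0_bar * tau * G * big * em
        + big**3
    )
    w_rho = G**2 * num / (4.0 * g * ka * tau * big**2 * d1**2)

    # corrected cross coupling: -(c / tau) d^2 f / dC dP with P = c rho0,
    # c(k) = -Gamma(k) / (4 gamma kappa) and C - P = big / (4 gamma kappa)
    c = -G / (4.0 * g * ka)
    P = c * rho0_bar
    CmP = big / (4.0 * g * ka)
    d2 = alpha * tau * em + CmP
    v_Crho = -(c / tau) * (-P / CmP**2 + 1.0 / d2 + P / d2**2)

    return IntraPotentials(w_C=w_C, w_rho=w_rho, v_Crho=v_Crho, tag=tag)


def intra_cross_coupling_printed(
    k: float,
    mu: float,
    rho0_bar: float,
    C_bar: float,
    alpha: float,
    tau: float,
    linker: LinkerParams,
) -> float:
    """The published closed form of the intra-species cross coupling.

    Kept verbatim for reference: it does not equal the mixed Hessian of the
    saddle free-energy density (e.g. it gives 14 where the free energy gives
    -4 at the reference parameter point), so :func:`intra_potentials` uses the
    corrected derivative instead.
    """
    g, ka, la = linker.gamma_y, linker.kappa, linker.lambda_y
    G = _gamma_factor(k, linker)
    big = 4.0 * g * ka * C_bar - 8.0 * g * ka * rho0_bar + la * k**2 * rho0_bar
    if big <= 0.0:
        raise CollapseError("nonpositive intra-species density factor")
    big2 = 8.0 * g * ka * C_bar - 8.0 * g * ka * rho0_bar + la * k**2 * rho0_bar
    em = math.exp(-mu)
    d1 = 4.0 * alpha * g * ka * tau * em + big
    term1 = rho0_bar * G / d1**2
    term2 = -2.0 * rho0_bar * G**2 / big**2
    term3 = -G * (8.0 * alpha * g * ka * tau * em + big2) / d1**2
    return -(G / (2.0 * tau)) * (term1 + term2 + term3)


# ---------------------------------------------------------------------------
# inter-species potentials
# ---------------------------------------------------------------------------

def inter_potentials(model: NetworkModel, tag: str | None = None) -> PotentialSet:
    """Effective couplings from strong inter-species networking (k = 0).

    Evaluates the printed second-order expansion of the two-species saddle
    free energy.  All couplings carrying an overall ``rho_bar`` factor vanish
    exactly at ``rho_bar = 0``, and the set is symmetric under exchanging the
    two species.
    """
    CA, CB, rho = model.C_A_bar, model.C_B_bar, model.rho_bar
    tau = model.tau
    a = CA - rho
    b = CB - rho
    if a <= 0.0 or b <= 0.0:
        raise CollapseError("C_bar - rho_bar must be positive for both species")
    s = model.alpha**2 * tau**2
    E = math.exp(-model.eps)  # dominant exp(eps) cancelled analytically
    D = (s * E + a * b) ** 2

    w_A = rho * (-(s**2) * rho * E**2 - 2.0 * s * rho * a * b * E + a**3 * b**2) / (
        CA * tau * a**2 * D
    )
    w_B = rho * (-(s**2) * rho * E**2 - 2.0 * s * rho * a * b * E + a**2 * b**3) / (
        CB * tau * b**2 * D
    )
    Q = CA**2 + CB**2 + CA * CB - 3.0 * rho * (CA + CB) + 3.0 * rho**2
    R = rho**2 * (CA + CB) - 4.0 * CA * CB * rho + CA * CB * (CA + CB)
    w_rho = (
        -2.0 * s * rho * a * b * E * Q
        - s**2 * E**2 * R
        + a**3 * b**3 * (CA + CB - 2.0 * rho)
    ) / (tau * a**2 * b**2 * D)
    v_Arho = (
        s**2 * rho * E**2
        + s * E * (rho - CA) * (CA * (CB - 2.0 * rho) + rho * (4.0 * rho - 3.0 * CB))
        - a**3 * b**2
    ) / (tau * a**2 * D)
    v_Brho = (
        s**2 * rho * E**2
        + s * E * (rho - CB) * (CA * (CB - 3.0 * rho) - 2.0 * rho * (CB - 2.0 * rho))
        - a**2 * b**3
    ) / (tau * b**2 * D)
    v_AB = -(model.alpha**2) * tau * rho * E / D

    if rho == 0.0:
        # the overall rho factors make these vanish identically; enforce exactly
        w_A = w_B = v_AB = 0.0
    return PotentialSet(
        w_A=w_A, w_B=w_B, w_rho=w_rho, v_AB=v_AB, v_Arho=v_Arho, v_Brho=v_Brho, tag=tag
    )


# ---------------------------------------------------------------------------
# combination and cross-link counts
# ---------------------------------------------------------------------------

def combine_potentials(
    intra_A: IntraPotentials, intra_B: IntraPotentials, inter: PotentialSet
) -> PotentialSet:
    """Sum the k = 0 contributions of the three networking channels.

    The inter-species channel alone carries the A-B coupling; each diagonal
    and linker-cross coupling adds the matching intra-species contribution,
    and the linker diagonal collects both.
    """
    tags = {t for t in (intra_A.tag, intra_B.tag, inter.tag) if t is not None}
    if len(tags) > 1:
        raise ValueError(f"mismatched parameter sets in combination: {sorted(tags)}")
    return PotentialSet(
        w_A=inter.w_A + intra_A.w_C,
        w_B=inter.w_B + intra_B.w_C,
        w_rho=inter.w_rho + intra_A.w_rho + intra_B.w_rho,
        v_AB=inter.v_AB,
        v_Arho=inter.v_Arho + intra_A.v_Crho,
        v_Brho=inter.v_Brho + intra_B.v_Crho,
        tag=tags.pop() if tags else None,
    )


def network_potentials(model: NetworkModel) -> PotentialSet:
    """Full combined potential set of a :class:`NetworkModel` at k = 0."""
    intra_A = intra_potentials(
        0.0, model.mu_A, model.rho_bar, model.C_A_bar, model.alpha, model.tau,
        model.linker,
    )
    intra_B = intra_potentials(
        0.0, model.mu_B, model.rho_bar, model.C_B_bar, model.alpha, model.tau,
        model.linker,
    )
    return combine_potentials(intra_A, intra_B, inter_potentials(model))


def crosslink_count_intra(P_integral: float, alpha: float, tau: float) -> float:
    """Intra-species cross-link count: time-integrated endpoint density / (alpha tau^2)."""
    if P_integral < 0:
        raise ValueError("P_integral must be nonnegative")
    return P_integral / (alpha * tau**2)


def crosslink_count_inter(M: float, tau: float, T_obs: float) -> float:
    """Inter-species cross-link count: M * T_obs / tau for M cross-linkers."""
    if M < 0:
        raise ValueError("M must be nonnegative")
    return M * T_obs / tau


# ---------------------------------------------------------------------------
# saddle free-energy densities (Hessian oracles)
# ---------------------------------------------------------------------------

def free_energy_density_intra(
    C: float, P: float, mu: float, alpha: float, tau: float
) -> float:
    """Saddle-point free-energy density of strong intra-species networking.

    ``(1/tau) [C ln(C/(C-P)) + P ln(1 + (C-P) e^mu / (alpha tau)^2) - P]``
    with ``P`` the endpoint density (twice the centre-of-mass density at zero
    wavenumber).  The log of the large exponential is expanded analytically so
    ``mu`` of order 50 is exact.
    """
    if P == 0.0:
        return 0.0
    if not C > P:
        raise CollapseError("log-domain violation: requires C > P")
    s = (alpha * tau) ** 2
    # ln(1 + (C-P) e^mu / s) = mu + ln(e^-mu + (C-P)/s)
    big_log = mu + math.log(math.exp(-mu) + (C - P) / s)
    return (C * math.log(C / (C - P)) + P * big_log - P) / tau


def free_energy_density_inter(
    C_A: float, C_B: float, rho: float, eps: float, alpha: float, tau: float
) -> float:
    """Saddle-point free-energy density of strong inter-species networking.

    Symmetric under exchanging the two species; vanishes at ``rho = 0``.
    """
    if rho == 0.0:
        return 0.0
    a = C_A - rho
    b = C_B - rho
    if a <= 0.0 or b <= 0.0:
        raise CollapseError("log-domain violation: requires C_A, C_B > rho")
    s = (alpha * tau) ** 2
    big_log = eps + math.log(math.exp(-eps) + a * b / s)
    return (
        C_A * math.log(C_A / a) + C_B * math.log(C_B / b) + rho * big_log - 2.0 * rho
    ) / tau
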