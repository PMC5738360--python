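"""Closed-form steady-state algebra of both reporter models.

Two models live here:

* the dox-induction cascade (dox -> effector C -> reporter G), whose steady
  state is a Hill function of the dox dose, and
* the receptor-cleavage (ChaCha) system, whose reporter steady state factors
  into a product of a ligand occupancy term and an adaptor term,
  ``G = G_max * L/(L+K_L) * A^n/(K_A+A^n)``.

The coupled fixed point of the full five-state rate system reduces to a single
scalar equation in the adaptor steady state, which is bracketed on
``(0, alpha_A/beta_A]`` — cleavage can only deplete the adaptor below its
no-ligand level — and solved with Brent's method.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .params import ChaChaRateParams, DoxInductionParams, SteadyStateParams

__all__ = [
    "dox_steady_state_gfp",
    "chacha_steady_state_gfp",
    "derive_steady_state_params",
    "solve_coupled_steady_state",
    "SteadyStateConvergenceError",
]


class SteadyStateConvergenceError(RuntimeError):
    """Raised when the coupled fixed point cannot be located to tolerance."""

    def __init__(self, message: str, residuals: dict[str, float] | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


def dox_steady_state_gfp(D, p: DoxInductionParams):
    """Steady-state reporter level under constant dox concentration ``D``.

    Returns ``kappa2 * C_ss**m`` with ``C_ss = kappa1 * D^n/(K_D + D^n)``;
    for the default m = 1 this is the familiar Hill form
    ``kappa1*kappa2 * D^n/(K_D + D^n)``. Accepts scalars or arrays.
    """
    D = _check_nonnegative("D", D)
    Dn = np.power(D, p.n_hill)
    c_ss = p.kappa1 * Dn / (p.K_D + Dn)
    out = p.kappa2 * np.power(c_ss, p.m)
    return out if out.ndim else float(out)


def chacha_steady_state_gfp(L, A_ss, p: SteadyStateParams):
    """Steady-state reporter level at ligand ``L`` and adaptor level ``A_ss``.

    Evaluates ``G_max * L/(L + K_L) * A^n/(K_A + A^n)``; monotone
    nondecreasing in both arguments. Accepts scalars or broadcastable arrays.
    """
    L = _check_nonnegative("L", L)
    A = _check_nonnegative("A_ss", A_ss)
    An = np.power(A, p.n_stoich)
    out = p.G_max * (L / (L + p.K_L)) * (An / (p.K_A + An))
    return out if out.ndim else float(out)


def derive_steady_state_params(p: ChaChaRateParams) -> SteadyStateParams:
    """Lump the mass-action rate constants into the steady-state surface.

    G_max = (gamma_G/beta_G) * alpha_R/(gamma_G + beta_C);
    K_L = beta_R/alpha_Rstar;  K_A = beta_Rstar/gamma_C;  n carried over.
    """
    return SteadyStateParams(
        G_max=(p.gamma_G / p.beta_G) * (p.alpha_R / (p.gamma_G + p.beta_C)),
        K_L=p.beta_R / p.alpha_Rstar,
        K_A=p.beta_Rstar / p.gamma_C,
        n_stoich=p.n_stoich,
    )


def chacha_rhs(state: np.ndarray, L: float, p: ChaChaRateParams) -> np.ndarray:
    """Right-hand side of the five-state rate system (R, R*, A, C, G)."""
    R, Rstar, A, C, G = state
    # A can transiently graze tiny negative values inside an implicit solver
    # step; the real power A^n requires clipping at 0.
    An = np.power(max(A, 0.0), p.n_stoich)
    cleave = p.gamma_C * Rstar * An
    return np.array(
        [
            p.alpha_R - p.alpha_Rstar * R * L - p.beta_R * R,
            p.alpha_Rstar * R * L - p.beta_Rstar * Rstar - cleave,
            p.alpha_A - p.beta_A * A - cleave,
            cleave - p.gamma_G * C - p.beta_C * C,
            p.gamma_G * C - p.beta_G * G,
        ]
    )


def _states_from_adaptor(A: float, L: float, p: ChaChaRateParams) -> dict[str, float]:
    R = p.alpha_R / (p.alpha_Rstar * L + p.beta_R)
    An = A**p.n_stoich
    Rstar = p.alpha_Rstar * R * L / (p.beta_Rstar + p.gamma_C * An)
    C = p.gamma_C * Rstar * An / (p.gamma_G + p.beta_C)
    G = (p.gamma_G / p.beta_G) * C
    return {"R_ss": R, "Rstar_ss": Rstar, "A_ss": A, "C_ss": C, "G_ss": G}


def _relative_residuals(
    sol: dict[str, float], L: float, p: ChaChaRateParams
) -> dict[str, float]:
    state = np.array(
        [sol["R_ss"], sol["Rstar_ss"], sol["A_ss"], sol["C_ss"], sol["G_ss"]]
    )
    rhs = chacha_rhs(state, L, p)
    # scale each balance by the largest constituent flux so the check is
    # relative, not absolute
    R, Rstar, A, C, G = state
    An = np.power(A, p.n_stoich)
    cleave = p.gamma_C * Rstar * An
    scales = np.array(
        [
            max(p.alpha_R, p.alpha_Rstar * R * L, p.beta_R * R),
            max(p.alpha_Rstar * R * L, p.beta_Rstar * Rstar, cleave, 1e-300),
            max(p.alpha_A, p.beta_A * A, cleave),
            max(cleave, (p.gamma_G + p.beta_C) * C, 1e-300),
            max(p.gamma_G * C, p.beta_G * G, 1e-300),
        ]
    )
    names = ("R", "Rstar", "A", "C", "G")
    return {name: abs(r) / s for name, r, s in zip(names, rhs, scales)}


def solve_coupled_steady_state(
    p: ChaChaRateParams, L: float, rtol: float = 1e-8
) -> dict[str, float]:
    """Solve the coupled fixed point of the five-state system at ligand ``L``.

    Substituting the receptor and active-receptor balances into the adaptor
    balance leaves one scalar equation in the adaptor steady state A:

        f(A) = alpha_A - beta_A*A - gamma_C*R*(A)*A^n = 0,

    with f(0+) = alpha_A > 0 and f(alpha_A/beta_A) <= 0, so a bracketing root
    find on (0, alpha_A/beta_A] is guaranteed. Returns the five steady levels
    and verifies every balance to a relative residual below ``rtol``
    (raising :class:`SteadyStateConvergenceError` with a residual report
    otherwise).
    """
    if L < 0:
        raise ValueError("L must be nonnegative")
    A0 = p.alpha_A / p.beta_A
    if L == 0:
        sol = {
            "R_ss": p.alpha_R / p.beta_R,
            "Rstar_ss": 0.0,
            "A_ss": A0,
            "C_ss": 0.0,
            "G_ss": 0.0,
        }
        return sol

    R = p.alpha_R / (p.alpha_Rstar * L + p.beta_R)
    activation = p.alpha_Rstar * R * L  # flux into the active receptor pool

    def f(A: float) -> float:
        An = A**p.n_stoich
        Rstar = activation / (p.beta_Rstar + p.gamma_C * An)
        return p.alpha_A - p.beta_A * A - p.gamma_C * Rstar * An

    lo = A0 * 1e-14
    try:
        A = brentq(f, lo, A0, xtol=1e-300, rtol=4 * np.finfo(float).eps)
    except ValueError as exc:  # pragma: no cover - bracketing is structural
        raise SteadyStateConvergenceError(
            f"bracketing failed on ({lo!r}, {A0!r}): {exc}"
        ) from exc

    sol = _states_from_adaptor(A, L, p)
    residuals = _relative_residuals(sol, L, p)
    worst = max(residuals.values())
    if not worst < rtol:
        raise SteadyStateConvergenceError(
            f"fixed point residuals exceed rtol={rtol:g}: {residuals}", residuals
        )
    return sol
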