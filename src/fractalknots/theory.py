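"""Analytical theory of the knotting length of fractal ring polymers.

The beta model prescribes Gaussian Fourier modes with eigenvalues
``lambda_q = 4 k sin(pi q / N)**chi`` and spectral exponent
``chi = 1 + 2/d_f``.  Topological excluded volume swells the ring on
scales above the knotting length ``N0``, where the mode spectrum crosses
over to a steeper exponent ``gamma`` obtained from a generalized Flory
argument.  Feeding this two-regime spectrum into the exact derivative of
the unknot probability with respect to ``chi`` yields a linear ODE for
``mu(d_f) = ln N0(d_f)``,

    d mu / d d_f = f1(d_f) * mu + f2(d_f),

whose frozen-coefficient solution is the double exponential

    mu(d_f) = c1 * exp(c2 * d_f) + c3,      c2 = f1,  c3 = -f2 / f1.

This module evaluates chi, gamma, the algebraic coefficient functions
f1/f2, the two-regime mode-amplitude model, the ODE, and the closed
form.  The Flory estimate for gamma is only trusted for d_f above
``TRUST_DF_MIN``; values computed below that threshold are flagged as
extrapolated rather than refused.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FIG_GRID",
    "TRUST_DF_MIN",
    "TheoryParams",
    "chi_of",
    "gamma_flory",
    "delta_exponent",
    "f_functions",
    "representative_constants",
    "theory_params",
    "mode_amplitude_model",
    "solve_mu_ode",
    "mu_closed_form",
]

#: The twelve fractal dimensions of the simulation campaign.
FIG_GRID = (6 / 5, 3 / 2, 5 / 3, 9 / 5, 2, 11 / 5, 5 / 2, 3, 7 / 2, 4, 9 / 2, 5)

#: Below this fractal dimension the Flory exponent is not trusted
#: (a self-avoiding ring already has d_f ~ 1.7; the Flory gamma would
#: fall below chi, which excluded volume cannot do).
TRUST_DF_MIN = 1.7

LN_PI_2 = math.log(math.pi / 2)


def chi_of(d_f):
    """Spectral exponent chi = 1 + 2/d_f of the beta model."""
    d_f = np.asarray(d_f, dtype=float)
    if np.any(d_f <= 0):
        raise ValueError("fractal dimension must be positive")
    return 1.0 + 2.0 / d_f


def gamma_flory(d_f, d: int = 3):
    """Swollen-ring spectral exponent from the generalized Flory argument.

    Balancing a two-body interaction term ``v N^2 / R^d`` against the
    entropic elasticity ``R^2 / N^(2/d_f)`` of an ideal fractal chain and
    minimizing over the ring size R gives the swelling exponent
    ``nu = 2 (1 + 1/d_f) / (d + 2)`` and hence ``gamma = 1 + 2 nu``.
    For d = 3 and d_f = 2 this is the familiar nu = 3/5, gamma = 11/5;
    at d_f = 3/2 gamma equals chi exactly.
    """
    d_f = np.asarray(d_f, dtype=float)
    if np.any(d_f <= 1):
        raise ValueError("fractal dimension must exceed 1")
    if d not in (2, 3):
        raise ValueError("spatial dimension must be 2 or 3")
    nu = 2.0 * (1.0 + 1.0 / d_f) / (d + 2)
    return 1.0 + 2.0 * nu


def delta_exponent(d_f, d: int = 3):
    """Spectral-exponent gap delta = gamma - chi between swollen and ideal regimes."""
    return gamma_flory(d_f, d) - chi_of(d_f)


def _check_range(d_f) -> None:
    d_f = np.asarray(d_f, dtype=float)
    if np.any(d_f < 6 / 5) or np.any(d_f > 5):
        warnings.warn(
            "f1/f2 evaluated outside the studied range 6/5 <= d_f <= 5; "
            "the theory is untested there",
            stacklevel=3,
        )


def f_functions(d_f, d: int = 3):
    """Coefficient functions (f1, f2) of the knotting-length ODE.

    With delta(d_f) = gamma - chi and x = d_f, carrying the crossover
    sums to the continuum limit gives, in three dimensions,

        f1(x) = -2 (2x - 3) / (x^2 (x + 6))
        f2(x) = -f1(x) * [ln(pi/2) - 6 (x + 1) / (x + 6)]

    The general-d forms below reduce to these; the only model-dependent
    ingredient is the ln(pi/2) constant inherited from the crossover
    mode location q = N / (2 N0).
    """
    _check_range(d_f)
    x = np.asarray(d_f, dtype=float)
    dl = delta_exponent(x, d)
    jac = -2.0 / x**2  # d(chi)/d(d_f)
    a = dl / (1.0 - dl)  # integral of x^-delta - 1 over (0, 1]
    b_over_a = -(2.0 - dl) / (1.0 - dl)  # log-weighted integral, relative to a
    f1 = 0.5 * jac * a
    f2 = -f1 * (LN_PI_2 + b_over_a)
    if np.ndim(d_f) == 0:
        return float(f1), float(f2)
    return f1, f2


def representative_constants(
    grid=FIG_GRID, d: int = 3, d_f_min: float = TRUST_DF_MIN
) -> tuple[float, float]:
    """Representative (f1, -f2/f1) = (c2, c3) over the campaign grid.

    The coefficient functions are roughly constant only where the Flory
    estimate for gamma holds (d_f > ``d_f_min``); f1 changes sign at
    d_f = 3/2 so including smaller values would be meaningless.  Returns
    the arithmetic means of f1 and of -f2/f1 over the trusted grid
    points.
    """
    pts = np.array([x for x in grid if x > d_f_min], dtype=float)
    if pts.size == 0:
        raise ValueError("no grid points in the trusted range")
    f1, f2 = f_functions(pts, d)
    return float(np.mean(f1)), float(np.mean(-f2 / f1))


@dataclass(frozen=True)
class TheoryParams:
    """Analytical constants of the knotting-length theory at one d_f."""

    d_f: float
    d: int
    chi: float
    gamma: float
    delta: float
    f1: float
    f2: float
    c2: float
    c3: float
    extrapolated: bool


def theory_params(d_f: float, d: int = 3) -> TheoryParams:
    """Bundle chi, gamma, delta, f1, f2 and derived constants at one d_f."""
    f1, f2 = f_functions(d_f, d)
    return TheoryParams(
        d_f=float(d_f),
        d=d,
        chi=float(chi_of(d_f)),
        gamma=float(gamma_flory(d_f, d)),
        delta=float(delta_exponent(d_f, d)),
        f1=f1,
        f2=f2,
        c2=f1,
        c3=-f2 / f1 if f1 != 0 else math.nan,
        extrapolated=bool(d_f <= TRUST_DF_MIN),
    )


def mode_amplitude_model(q_prime, N: int, N0: float, d_f: float, d: int = 3):
    """Two-regime postulate for the constrained mean-squared mode amplitude.

    Modes describe structure on the scale of N/2q' segments.  Below the
    crossover q' = N/(2 N0) (scales larger than the knotting length) the
    unknotted ring is swollen and follows the gamma spectrum; above it
    the unconstrained chi spectrum is untouched.  The prefactor
    ``sin(pi/(2 N0))**delta`` makes the two branches meet continuously
    at the crossover.  Returns <|X_q|^2> for a d-component mode vector.
    """
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    q_prime = np.asarray(q_prime, dtype=float)
    if np.any(q_prime < 1) or np.any(q_prime > N / 2):
        raise ValueError("q' must lie in [1, N/2]")
    chi = float(chi_of(d_f))
    gamma = float(gamma_flory(d_f, d))
    k = float(d)
    s = np.sin(np.pi * q_prime / N)
    q_star = N / (2.0 * N0)
    prefactor = np.sin(np.pi * q_star / N) ** (gamma - chi)
    unconstrained = d / (4.0 * k * s**chi)
    swollen = prefactor * d / (4.0 * k * s**gamma)
    out = np.where(q_prime > q_star, unconstrained, swollen)
    if np.ndim(out) == 0:
        return float(out)
    return out


def solve_mu_ode(
    d_f_grid,
    mu_initial: tuple[float, float],
    d: int = 3,
    frozen: tuple[float, float] | None = None,
    rtol: float = 1e-8,
):
    """Integrate d mu/d d_f = f1 mu + f2 along a grid of fractal dimensions.

    Parameters
    ----------
    d_f_grid : array-like
        Strictly increasing evaluation points.
    mu_initial : (d_f0, mu0)
        Initial condition; the theory fixes the ODE but not its constant
        of integration, which in practice comes from fitting data.
    frozen : (f1, f2), optional
        Freeze the coefficients at constants, in which case the solution
        coincides with the closed-form double exponential.
    """
    grid = np.asarray(d_f_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("d_f_grid must be strictly increasing with >= 2 points")
    df0, mu0 = mu_initial

    if frozen is not None:
        f1c, f2c = frozen

        def rhs(x, y):
            return f1c * y[0] + f2c
    else:

        def rhs(x, y):
            f1, f2 = f_functions(x, d)
            return f1 * y[0] + f2

    lo, hi = min(df0, grid[0]), max(df0, grid[-1])
    out = np.empty_like(grid)
    for span, sel in (
        ((df0, hi), grid >= df0),
        ((df0, lo), grid < df0),
    ):
        if span[0] == span[1]:
            if np.any(sel):
                out[sel] = mu0
            continue
        pts = grid[sel]
        if pts.size == 0:
            continue
        order = np.argsort(pts) if span[1] > span[0] else np.argsort(-pts)
        sol = solve_ivp(
            rhs,
            span,
            [mu0],
            t_eval=pts[order],
            rtol=rtol,
            atol=1e-12,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        tmp = np.empty(pts.size)
        tmp[order] = sol.y[0]
        out[sel] = tmp
    return out


def mu_closed_form(d_f, c1: float, c2: float, c3: float):
    """Double-exponential knotting-length law mu = c1 exp(c2 d_f) + c3."""
    d_f = np.asarray(d_f, dtype=float)
    out = c1 * np.exp(c2 * d_f) + c3
    if np.ndim(d_f) == 0:
        return float(out)
    return out
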