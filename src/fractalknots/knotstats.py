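"""From Monte-Carlo knot calls to knotting lengths and their d_f dependence.

The unknot probability of a self-similar ring decays exponentially,

    P0(N) = C exp(-N / N0),

so a weighted log-linear fit of the per-N unknot fractions yields the
knotting length N0 and mu = ln N0.  Collecting mu over a grid of fractal
dimensions gives the mu(d_f) curve, which the analytical theory predicts
to be double-exponential, mu = c1 exp(c2 d_f) + c3, and which simple
scaling arguments would instead render logarithmic,
mu = c1 ln(d_f + c2) + c3.  Both forms are fit here by weighted
nonlinear least squares and compared by a small-sample-corrected
information criterion plus a residual runs test.

The module also implements the thermodynamic estimator for
d(ln P0)/d chi: since the Boltzmann weight is Gaussian in the modes, the
derivative of ln P0 with respect to the spectral exponent equals the
difference between the unconstrained (analytic) and unknotted-ensemble
averages of (1/2) sum_q (d lambda_q / d chi) |X_q|^2.  This identity is
exact at every N and is converted to d mu / d d_f via the chain rule
d chi/d d_f = -2/d_f^2 and the exponential law above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from fractalknots.beta_model import ModeSpectrum, ring_to_modes

__all__ = [
    "FitDegenerate",
    "KnottingCurve",
    "ExponentialFit",
    "MuCurve",
    "MuFit",
    "estimate_p0",
    "wilson_interval",
    "fit_exponential",
    "build_mu_curve",
    "fit_mu",
    "runs_test_pvalue",
    "derivative_estimator",
    "generate_bernoulli_curve",
]


class FitDegenerate(RuntimeError):
    """Raised when a knotting-curve fit has no decaying-exponential solution."""


# ---------------------------------------------------------------------------
# P0 estimation
# ---------------------------------------------------------------------------


def wilson_interval(count: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    res = stats.binomtest(count, trials).proportion_ci(
        confidence_level=level, method="wilson"
    )
    return float(res.low), float(res.high)


def estimate_p0(trials: int, unknot_count: int) -> tuple[float, tuple[float, float]]:
    """Point estimate and Wilson 95% interval for the unknot probability."""
    if trials < 1:
        raise ValueError("at least one trial is required")
    if not 0 <= unknot_count <= trials:
        raise ValueError("unknot_count must lie in [0, trials]")
    return unknot_count / trials, wilson_interval(unknot_count, trials)


@dataclass(frozen=True)
class KnottingCurve:
    """Per-N unknot statistics at one fractal dimension."""

    data: pd.DataFrame  # columns: N, trials, unknot, p0, ci_lo, ci_hi
    d_f: float
    d: int = 3
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_counts(cls, N, trials, unknot, d_f: float, d: int = 3, **meta):
        N = np.asarray(N, dtype=int)
        trials = np.broadcast_to(np.asarray(trials, dtype=int), N.shape)
        unknot = np.asarray(unknot, dtype=int)
        if np.any(unknot < 0) or np.any(unknot > trials):
            raise ValueError("unknot counts must lie in [0, trials]")
        rows = []
        for n_i, t_i, u_i in zip(N, trials, unknot):
            p, (lo, hi) = estimate_p0(int(t_i), int(u_i))
            rows.append((n_i, t_i, u_i, p, lo, hi))
        df = pd.DataFrame(
            rows, columns=["N", "trials", "unknot", "p0", "ci_lo", "ci_hi"]
        )
        return cls(data=df, d_f=float(d_f), d=int(d), meta=dict(meta))


@dataclass(frozen=True)
class ExponentialFit:
    """Weighted log-linear fit of P0(N) = C exp(-N/N0)."""

    N0: float
    mu: float
    mu_stderr: float
    prefactor: float
    slope: float
    slope_stderr: float
    chi2_reduced: float
    window: tuple
    n_points: int
    d_f: float


def fit_exponential(
    curve: KnottingCurve,
    p_floor: float = 0.01,
    p_ceil: float = 0.99,
) -> ExponentialFit:
    """Fit the exponential unknotting law by weighted least squares.

    Regresses ln p0 on N with delta-method weights
    ``trials * p0 / (1 - p0)`` (inverse variance of ln p0-hat).  Points
    with no unknots, or with p0 outside (p_floor, p_ceil) where the
    asymptotic law carries no slope information, are excluded.  The
    slope is -1/N0; a non-negative slope raises :class:`FitDegenerate`.
    """
    df = curve.data
    usable = (df["unknot"] > 0) & (df["p0"] > p_floor) & (df["p0"] < p_ceil)
    sub = df[usable]
    if len(sub) < 3:
        raise FitDegenerate(
            f"only {len(sub)} usable points (need >= 3) for d_f={curve.d_f}"
        )
    x = sub["N"].to_numpy(dtype=float)
    y = np.log(sub["p0"].to_numpy(dtype=float))
    p = sub["p0"].to_numpy(dtype=float)
    w = sub["trials"].to_numpy(dtype=float) * p / (1.0 - p)
    A = np.vstack([x, np.ones_like(x)]).T
    cov = np.linalg.inv(A.T @ (w[:, None] * A))
    beta = cov @ (A.T @ (w * y))
    slope, intercept = float(beta[0]), float(beta[1])
    resid = y - A @ beta
    chi2 = float(resid @ (w * resid))
    dof = max(len(sub) - 2, 1)
    slope_err = float(np.sqrt(cov[0, 0]))
    if slope >= 0:
        raise FitDegenerate(
            f"non-decaying P0(N) (slope {slope:.3g} >= 0) at d_f={curve.d_f}"
        )
    N0 = -1.0 / slope
    mu = math.log(N0)
    mu_err = slope_err / abs(slope)
    return ExponentialFit(
        N0=N0,
        mu=mu,
        mu_stderr=mu_err,
        prefactor=math.exp(intercept),
        slope=slope,
        slope_stderr=slope_err,
        chi2_reduced=chi2 / dof,
        window=(float(x.min()), float(x.max())),
        n_points=len(sub),
        d_f=curve.d_f,
    )


# ---------------------------------------------------------------------------
# mu(d_f) curve and model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MuCurve:
    """ln N0 versus fractal dimension, with propagated standard errors."""

    data: pd.DataFrame  # columns: d_f, mu, mu_stderr


def build_mu_curve(fits) -> MuCurve:
    """Assemble mu(d_f) from per-d_f exponential fits (>= 4 required)."""
    items = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if len(items) < 4:
        raise ValueError("need fits at >= 4 fractal dimensions")
    dfs = [f.d_f for f in items]
    if len(set(dfs)) != len(dfs):
        raise ValueError("duplicate fractal dimensions in mu curve")
    df = pd.DataFrame(
        {
            "d_f": dfs,
            "mu": [f.mu for f in items],
            "mu_stderr": [f.mu_stderr for f in items],
        }
    ).sort_values("d_f", ignore_index=True)
    return MuCurve(data=df)


@dataclass(frozen=True)
class MuFit:
    """Weighted nonlinear fit of mu(d_f) for one functional form."""

    model: str  # "double_exponential" or "logarithmic"
    c1: float
    c2: float
    c3: float
    residuals: np.ndarray
    chi2: float
    aicc: float
    runs_pvalue: float


def _model_funcs(model: str):
    if model == "double_exponential":

        def f(x, c1, c2, c3):
            return c1 * np.exp(c2 * np.asarray(x, dtype=float)) + c3

        return f
    if model == "logarithmic":

        def f(x, c1, c2, c3):
            arg = np.asarray(x, dtype=float) + c2
            if np.any(arg <= 0):
                return np.full(np.shape(arg), 1e6)
            return c1 * np.log(arg) + c3

        return f
    raise ValueError(f"unknown model {model!r}")


def runs_test_pvalue(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs test on residual signs (normal approximation).

    Small p-values indicate structured (non-random) residuals, i.e. a
    systematically wrong functional form.
    """
    signs = np.sign(np.asarray(residuals, dtype=float))
    signs = signs[signs != 0]
    n = signs.size
    if n < 2:
        return 1.0
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mean = 1.0 + 2.0 * n_pos * n_neg / n
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mean) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _aicc_from_chi2(chi2: float, n: int, k: int) -> float:
    """Small-sample-corrected information criterion for weighted LS."""
    aic = chi2 + 2.0 * k
    if n - k - 1 > 0:
        return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    return math.inf


def _starts(model: str, x: np.ndarray, y: np.ndarray):
    """16 deterministic starting points spanning sign combinations."""
    span = max(float(y.max() - y.min()), 1e-3)
    base = float(y.min())
    if model == "double_exponential":
        for c1_mag in (span, 10.0 * span):
            for c2 in (-2.0, -1.0, -0.3, 0.3):
                for sign in (1.0, -1.0):
                    yield (sign * c1_mag, c2, base)
    else:
        for c1 in (-span, span, -2.0 * span, 2.0 * span):
            for c2 in (-float(x.min()) + 0.5, 0.0, 1.0, 5.0):
                yield (c1, c2, base)


def fit_mu(
    curve: MuCurve, model: str = "double_exponential", weighted: bool = True
) -> MuFit:
    """Fit one functional form to the mu(d_f) curve.

    Weighted nonlinear least squares with 16 deterministic starting
    points spanning sign combinations; the best converged fit by
    objective wins (ties broken by smallest |c2|).  Raises RuntimeError
    when no start converges.
    """
    df = curve.data
    if len(df) < 4:
        raise ValueError("need >= 4 points to fit mu(d_f)")
    x = df["d_f"].to_numpy(dtype=float)
    y = df["mu"].to_numpy(dtype=float)
    err = df["mu_stderr"].to_numpy(dtype=float)
    if weighted:
        if not np.all(np.isfinite(err)) or np.any(err <= 0):
            raise ValueError("finite positive errors required for weighted fit")
        sigma = err
    else:
        sigma = np.ones_like(y)
    f = _model_funcs(model)
    best = None
    for p0 in _starts(model, x, y):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    f, x, y, p0=p0, sigma=sigma, absolute_sigma=True, maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        resid = (y - f(x, *popt)) / sigma
        chi2 = float(resid @ resid)
        if not math.isfinite(chi2):
            continue
        key = (chi2, abs(popt[1]))
        if best is None or key < best[0]:
            best = (key, popt, resid)
    if best is None:
        raise RuntimeError(f"no converged {model} fit from any start")
    _, popt, resid = best
    chi2 = float(resid @ resid)
    return MuFit(
        model=model,
        c1=float(popt[0]),
        c2=float(popt[1]),
        c3=float(popt[2]),
        residuals=resid,
        chi2=chi2,
        aicc=_aicc_from_chi2(chi2, len(x), 3),
        runs_pvalue=runs_test_pvalue(resid),
    )


# ---------------------------------------------------------------------------
# Thermodynamic derivative estimator
# ---------------------------------------------------------------------------


def derivative_estimator(
    positions: np.ndarray,
    is_unknotted: np.ndarray | None,
    spectrum: ModeSpectrum,
    N0: float,
    constrained: bool = True,
) -> tuple[float, float]:
    """Estimate d mu / d d_f from classified conformations at one (N, d_f).

    Exact Gaussian identity: with effective energy
    ``H = (1/2) sum_q lambda_q |X_q|^2`` and
    ``d lambda_q / d chi = lambda_q ln sin(pi q / N)``,

        d ln P0 / d chi = <dH/dchi> - <dH/dchi>_0,

    where <.>_0 averages over the unknotted subset and the unconstrained
    average is analytic by equipartition, <|X_q|^2> = d / lambda_q.  The
    exponential law P0 = C exp(-N/N0) turns this into
    ``d mu / d chi = (N0/N) d ln P0 / d chi``, and the chain rule
    ``d chi / d d_f = -2/d_f**2`` gives the returned derivative.
    Returns (estimate, stderr).

    With ``constrained=False`` the topological constraint is switched
    off: every sample enters the "unknotted" average, which then
    coincides with the unconstrained ensemble, and the estimate is zero
    up to Monte-Carlo error (a useful null check).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3:
        raise ValueError("positions must be (n_samples, N, d)")
    if not constrained:
        mask = np.ones(pos.shape[0], dtype=bool)
    else:
        mask = np.asarray(is_unknotted, dtype=bool)
        if mask.shape[0] != pos.shape[0]:
            raise ValueError("mask length must match sample count")
        n_sel = int(mask.sum())
        if n_sel == 0 or n_sel == mask.size:
            raise ValueError(
                "need both knotted and unknotted samples to constrain the ensemble"
            )
    n_un = int(mask.sum())
    N = spectrum.N
    if pos.shape[1] != N or pos.shape[2] != spectrum.d:
        raise ValueError("spectrum does not match sample shape")
    q = np.arange(1, N)
    log_sin = np.log(np.sin(np.pi * q / N))
    lam = spectrum.eigenvalues
    modes = ring_to_modes(pos[mask])
    amp2 = np.sum(modes**2, axis=-1)  # |X_q|^2 per sample, (n_un, N-1)
    per_sample = 0.5 * amp2 @ (lam * log_sin)
    constrained = float(per_sample.mean())
    constrained_err = (
        float(per_sample.std(ddof=1) / math.sqrt(n_un)) if n_un > 1 else math.nan
    )
    unconstrained = 0.5 * spectrum.d * float(np.sum(log_sin))
    dlnp0_dchi = unconstrained - constrained
    jac = (N0 / N) * (-2.0 / spectrum.d_f**2)
    return jac * dlnp0_dchi, abs(jac) * constrained_err


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def generate_bernoulli_curve(
    N0_true: float,
    N_grid,
    trials,
    rng: np.random.Generator,
    prefactor: float = 1.0,
    d_f: float = math.nan,
) -> KnottingCurve:
    """Binomial draws from an exact exponential law, for fit validation."""
    if N0_true <= 0:
        raise ValueError("N0 must be positive")
    N_grid = np.asarray(N_grid, dtype=int)
    trials = np.broadcast_to(np.asarray(trials, dtype=int), N_grid.shape)
    p0 = np.minimum(1.0, prefactor * np.exp(-N_grid / N0_true))
    unknot = rng.binomial(trials, p0)
    return KnottingCurve.from_counts(
        N_grid, trials, unknot, d_f=d_f, N0_true=N0_true
    )
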