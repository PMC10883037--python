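"""Predict the occupied fraction <theta_SA> from K and system parameters.

Three families of predictions are provided, in increasing faithfulness to
small closed systems:

* the macroscopic Langmuir isotherm theta = Kc/(c_std + Kc), either fed a
  measured equilibrium free-adsorbate concentration or solved
  self-consistently with the closed-system mass balance;
* the fluctuation-corrected equation, which restores the two-body average
  <N_SA^2> = <N_SA>^2 (1 + l) inside the correlation-aware
  equilibrium-constant expression:

      K * [N_A N_S - (N_A + N_S) <N_SA> + <N_SA>^2 (1 + l)] = V c_std <N_SA>

  with l = l(N_SA, N_SA) approximated by an interpolation between the two
  exactly solvable regimes (a single molecule or site, and the thermodynamic
  limit);
* the two-state special case N_A = N_S = 1, where occupancy is Bernoulli and
  K = p/(1-p) * V * c_std — the single-molecule (e.g. nanovesicle FRET)
  estimator.

Isotherm fitting treats V*c_std/K as a single parameter, which together with
N_S_total reduces a titration fit to two parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model_core import C_STD

LambdaRule = Literal["eq20_previous", "eq21_new", "exact_min1", "none"]


@dataclass
class PredictionRequest:
    K: float
    N_A_total: int
    N_S_total: int
    V: float
    c_std: float = C_STD
    lambda_rule: LambdaRule = "eq21_new"

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.lambda_rule != "none" and (self.N_A_total < 1 or self.N_S_total < 1):
            raise ValueError("fluctuation rules require counts >= 1")


def langmuir_theta(K: float, c_A: float, c_std: float = C_STD) -> float:
    """Macroscopic Langmuir isotherm fed a free-adsorbate concentration.

    Note that for small closed systems the relevant input is the *measured*
    equilibrium <c_A> of that system; feeding the total concentration, or
    solving self-consistently (see closed_system_langmuir), gives different
    numbers once depletion matters.
    """
    if c_A < 0:
        raise ValueError("c_A must be >= 0")
    x = K * c_A / c_std
    return x / (1.0 + x)


def closed_system_langmuir(
    K: float, N_A_total: int, N_S_total: int, V: float, c_std: float = C_STD
) -> float:
    """Langmuir isotherm combined with the closed-system mass balance.

    Solves theta = K c_A / (c_std + K c_A) with c_A = (N_A - theta*N_S)/V.
    Unique root of the resulting quadratic in [0, min(1, N_A/N_S)], selected
    as the branch continuous with theta(K -> 0) = 0.  Equivalent to the
    fluctuation-corrected equation with l = 0.
    """
    return predict_theta_eq17(
        PredictionRequest(K, N_A_total, N_S_total, V, c_std, lambda_rule="none")
    )


def _lambda_factor(rule: LambdaRule, n_x: float, n_y: float, t: float) -> float:
    """Interpolation factor lambda multiplying the exact min-count-1 form.

    Both rules reduce to 1 when the scarcer species has a single particle
    (where l = c_std*V/(K*N_X) is exact) and vanish in the thermodynamic
    limit.  The dilute endpoint lambda -> 1/N_Y is exact for every system
    (only the i = 0, 1 states carry weight); the previous rule (eq20) keeps
    that constant value.  The improved rule (eq21) also restores the exact
    saturation endpoint lambda -> N_X/(N_Y*(N_X-N_Y+1)) (a single-vacancy
    fluctuation) and interpolates between the two with the occupied fraction
    t = <N_SA>/N_Y of the scarcer species:

        lambda = lambda_0 + (lambda_inf - lambda_0) * w,
        w = t**k * (1 - 0.15*(1 - t)),   k = 1 + (N_Y - 1)*N_Y/N_X

    with the exponent and mid-range damping calibrated against the
    enumerated pmf (see docs).  In the thermodynamic limit k diverges, so
    w -> 0 and lambda -> 1/N_Y -> 0.
    """
    if rule == "eq20_previous":
        return 1.0 / n_y
    if rule == "eq21_new":
        lam0 = 1.0 / n_y
        lam_inf = n_x / (n_y * (n_x - n_y + 1.0))
        t = min(max(t, 0.0), 1.0)
        k = 1.0 + (n_y - 1.0) * n_y / n_x
        w = t**k * (1.0 - 0.15 * (1.0 - t))
        w = min(max(w, 0.0), 1.0)
        return lam0 + (lam_inf - lam0) * w
    if rule == "exact_min1":
        if n_y != 1:
            raise ValueError("exact_min1 rule requires min(N_A, N_S) = 1")
        return 1.0
    raise ValueError(f"unknown lambda rule: {rule!r}")


def l_interp(request: PredictionRequest, mean_guess: float | None = None) -> float:
    """Approximate l(N_SA, N_SA) for the requested system.

    The base expression c_std*V/(K*N_X) (X the more abundant species) is the
    exact relative fluctuation when min(N_A, N_S) = 1; the lambda factor
    interpolates it across particle numbers and occupancies.  ``mean_guess``
    is the current estimate of <N_SA> used by the occupancy-dependent rule;
    when omitted, the zero-fluctuation (closed-system Langmuir) mean is used.
    """
    if request.lambda_rule == "none":
        return 0.0
    if request.N_A_total < 1 or request.N_S_total < 1:
        raise ValueError("counts must be >= 1 for fluctuation rules")
    if request.K <= 0:
        raise ZeroDivisionError("l diverges as K -> 0; use the l=0 rule instead")
    n_x = max(request.N_A_total, request.N_S_total)
    n_y = min(request.N_A_total, request.N_S_total)
    if mean_guess is None:
        z = request.K / (request.c_std * request.V)
        mean_guess = _solve_mean_quadratic(
            z, request.N_A_total, request.N_S_total, 0.0
        )
    base = request.c_std * request.V / (request.K * n_x)
    return _lambda_factor(request.lambda_rule, n_x, n_y, mean_guess / n_y) * base


def _solve_mean_quadratic(z: float, n_a: int, n_s: int, ell: float) -> float:
    """Root of z(1+l)m^2 - (z(N_A+N_S)+1)m + z*N_A*N_S = 0 in [0, N_SA_max].

    The physical branch is continuous with m(z -> 0) = 0, i.e. the smaller
    root, evaluated in the numerically stable 2c/(b+sqrt(disc)) form.
    """
    if z == 0.0:
        return 0.0
    a = z * (1.0 + ell)
    b = z * (n_a + n_s) + 1.0
    c = z * n_a * n_s
    disc = b * b - 4.0 * a * c
    if disc < 0:
        if disc > -1e-9 * b * b:
            disc = 0.0
        else:
            raise ArithmeticError("no real root: inconsistent fluctuation input")
    m = 2.0 * c / (b + np.sqrt(disc))
    return float(min(max(m, 0.0), min(n_a, n_s)))


def predict_theta_eq17(
    request: PredictionRequest,
    l_value: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Occupied fraction from the fluctuation-corrected equation.

    Solves the quadratic self-consistently with the l approximation (damped
    fixed point on (<N_SA>, l)); with ``l_value`` given, that value is used
    directly (e.g. an exact l from the enumerated pmf, which reproduces the
    exact mean to machine precision).  With the ``none`` rule this is
    algebraically identical to the closed-system Langmuir solve.
    """
    n_a, n_s = request.N_A_total, request.N_S_total
    if request.K == 0.0:
        return 0.0
    z = request.K / (request.c_std * request.V)
    if l_value is not None:
        m = _solve_mean_quadratic(z, n_a, n_s, l_value)
        return m / n_s
    if request.lambda_rule == "none":
        m = _solve_mean_quadratic(z, n_a, n_s, 0.0)
        return m / n_s
    m = _solve_mean_quadratic(z, n_a, n_s, 0.0)
    for _ in range(max_iter):
        ell = l_interp(request, mean_guess=m)
        m_new = _solve_mean_quadratic(z, n_a, n_s, ell)
        if abs(m_new - m) < tol:
            return m_new / n_s
        m = 0.5 * (m + m_new)
    raise RuntimeError(
        f"fixed point did not converge after {max_iter} iterations "
        f"(K={request.K}, N_A={n_a}, N_S={n_s}, last m={m})"
    )


def two_state_K(p_bound: float, V: float, c_std: float = C_STD) -> float:
    """Single-molecule/single-site estimator K = p/(1-p) * V * c_std.

    ``p_bound`` is the fraction of time the one site is occupied — e.g. the
    bound-state dwell fraction of a FRET trace from a nanovesicle enclosing
    one ligand and one receptor.
    """
    if not (0.0 < p_bound < 1.0):
        raise ValueError("p_bound must lie strictly inside (0, 1)")
    return p_bound / (1.0 - p_bound) * V * c_std


@dataclass
class IsothermFit:
    """Result of a two-parameter titration fit."""

    g: float  # V*c_std/K, the single combined affinity-volume parameter
    N_S_total: float
    g_stderr: float
    N_S_stderr: float
    residuals: np.ndarray
    covariance: np.ndarray
    lambda_rule: LambdaRule
    dof: int = 1

    def confidence_interval(self, level: float = 0.95):
        """Per-parameter confidence intervals using the Student-t quantile
        appropriate for the residual degrees of freedom."""
        from scipy.stats import t as t_dist

        q = float(t_dist.ppf(0.5 + level / 2.0, max(self.dof, 1)))
        return (
            (self.g - q * self.g_stderr, self.g + q * self.g_stderr),
            (
                self.N_S_total - q * self.N_S_stderr,
                self.N_S_total + q * self.N_S_stderr,
            ),
        )


def _model_mean_nsa(g: float, n_s: float, n_a_values: np.ndarray, rule: LambdaRule) -> np.ndarray:
    """Predicted <N_SA> over a titration, parameterized by g = V*c_std/K.

    The prediction depends on V and K only through g, which is what makes the
    two-parameter fit possible; n_s is treated as continuous during the fit.
    """
    z = 1.0 / g
    out = np.empty(len(n_a_values))
    n_s_c = max(n_s, 1e-6)
    for j, n_a in enumerate(n_a_values):
        n_x = max(n_a, n_s_c)
        n_y = min(n_a, n_s_c)
        m = _solve_mean_quadratic_cont(z, n_a, n_s_c, 0.0)
        if rule != "none":
            for _ in range(200):
                ell = _lambda_factor(rule, n_x, n_y, m / n_y) * g / n_x
                m_new = _solve_mean_quadratic_cont(z, n_a, n_s_c, ell)
                if abs(m_new - m) < 1e-12:
                    m = m_new
                    break
                m = 0.5 * (m + m_new)
        out[j] = m
    return out


def _solve_mean_quadratic_cont(z: float, n_a: float, n_s: float, ell: float) -> float:
    a = z * (1.0 + ell)
    b = z * (n_a + n_s) + 1.0
    c = z * n_a * n_s
    disc = max(b * b - 4.0 * a * c, 0.0)
    return 2.0 * c / (b + np.sqrt(disc))


def fit_isotherm(
    data: Sequence[tuple[float, float]],
    known_N_S_total: float | None = None,
    lambda_rule: LambdaRule = "eq21_new",
) -> IsothermFit:
    """Fit (V*c_std/K, N_S_total) to a titration of (N_A_total, <N_SA>).

    Nonlinear least squares of the fluctuation-corrected prediction with
    relative-error weighting (occupancies span decades across a titration).
    Requires at least 3 points spanning sub- and near-saturation occupancy.
    """
    data = list(data)
    if len(data) < 3:
        raise ValueError("need at least 3 titration points")
    n_a_values = np.array([d[0] for d in data], dtype=float)
    y = np.array([d[1] for d in data], dtype=float)
    if np.any(y <= 0):
        raise ValueError("observed <N_SA> values must be positive")
    if np.ptp(y) < 1e-9 * y.mean():
        raise ValueError("degenerate (flat) titration data; fit is unconstrained")

    fit_ns = known_N_S_total is None

    def resid(params):
        log_g = params[0]
        n_s = np.exp(params[1]) if fit_ns else known_N_S_total
        pred = _model_mean_nsa(np.exp(log_g), n_s, n_a_values, lambda_rule)
        return (pred - y) / y

    # crude starts: N_S from the largest observed occupancy, g from midpoint
    ns0 = known_N_S_total if not fit_ns else max(y.max() * 1.2, 1.0)
    g0 = 1.0
    x0 = [np.log(g0), np.log(ns0)] if fit_ns else [np.log(g0)]
    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(f"isotherm fit failed: {sol.message}")

    # covariance of the log-parameters from the Gauss-Newton approximation
    dof = max(len(y) - len(sol.x), 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov_log = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("isotherm fit failed: singular Jacobian") from exc

    g = float(np.exp(sol.x[0]))
    g_err = g * float(np.sqrt(cov_log[0, 0]))
    if fit_ns:
        n_s = float(np.exp(sol.x[1]))
        ns_err = n_s * float(np.sqrt(cov_log[1, 1]))
    else:
        n_s, ns_err = float(known_N_S_total), 0.0
    return IsothermFit(
        g=g,
        N_S_total=n_s,
        g_stderr=g_err,
        N_S_stderr=ns_err,
        residuals=sol.fun * y,
        covariance=cov_log,
        lambda_rule=lambda_rule,
        dof=dof,
    )
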