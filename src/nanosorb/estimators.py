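"""Equilibrium averages, relative fluctuations and equilibrium constants
from occupancy time series.

The central objects are the relative fluctuation

    l(zeta, eta) = <(zeta - <zeta>)(eta - <eta>)> / (<zeta> <eta>)

and the two equilibrium-constant estimators

    K  = (<N_SA> / <N_A * N_S>) * V * c_std      (correlation-aware)
    K' = (<N_SA> / (<N_A> <N_S>)) * V * c_std    (conventional, textbook)

The two-body average <N_A*N_S> is accumulated per configuration from integer
counts — never reconstructed from marginal means.  K is invariant with system
size; K' is not, and K'/K - 1 = l(N_A, N_S) identically on the same samples.

A fluctuation identity of the ideal model predicts the mean composition from
spreads alone:

    <N_SA> = 1 / ( l(N_SA, N_SA) - l(N_SA, N_A*N_S) )

which is exact on the enumerated occupancy distribution (see exact_oracle)
and holds within sampling error on simulation traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .model_core import C_STD, nm3_to_molar

if TYPE_CHECKING:  # pragma: no cover
    from .mc_engine import ObservableTrace


class UndefinedFluctuationError(ZeroDivisionError):
    """A relative fluctuation is undefined because a mean vanishes."""


def rel_fluct(zeta: np.ndarray, eta: np.ndarray) -> float:
    """Relative cross-fluctuation l(zeta, eta), population (1/N) normalization."""
    zeta = np.asarray(zeta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    mz = zeta.mean()
    me = eta.mean()
    if mz == 0.0 or me == 0.0:
        raise UndefinedFluctuationError(
            "l(zeta,eta) undefined: a series has zero mean "
            "(species never/always present)"
        )
    cov = np.mean(zeta * eta) - mz * me
    return float(cov / (mz * me))


def K_eq14(
    mean_n_sa: float, mean_prod_as: float, V: float, c_std: float = C_STD
) -> float:
    """Correlation-aware equilibrium constant from <N_SA> and <N_A*N_S>."""
    if mean_n_sa == 0.0:
        return 0.0
    if mean_prod_as <= 0.0:
        raise ZeroDivisionError(
            "K undefined: <N_A*N_S> = 0 (complete conversion on every sample)"
        )
    return mean_n_sa / mean_prod_as * V * c_std


def Kprime_eq15(
    mean_n_sa: float,
    mean_n_a: float,
    mean_n_s: float,
    V: float,
    c_std: float = C_STD,
) -> float:
    """Conventional equilibrium constant from marginal means only."""
    if mean_n_sa == 0.0:
        return 0.0
    if mean_n_a * mean_n_s <= 0.0:
        raise ZeroDivisionError("K' undefined: <N_A><N_S> = 0")
    return mean_n_sa / (mean_n_a * mean_n_s) * V * c_std


def eq16_prediction(
    n_sa: np.ndarray, prod_as: np.ndarray | None = None, n_a=None, n_s=None
) -> float:
    """Predict <N_SA> from fluctuations alone.

    Evaluates 1 / (l(N_SA,N_SA) - l(N_SA, N_A*N_S)) on the sample series.
    ``prod_as`` is the per-sample product N_A*N_S; it may alternatively be
    supplied through the ``n_a``/``n_s`` series.
    """
    n_sa = np.asarray(n_sa, dtype=float)
    if prod_as is None:
        if n_a is None or n_s is None:
            raise ValueError("supply prod_as or both n_a and n_s")
        prod_as = np.asarray(n_a, dtype=float) * np.asarray(n_s, dtype=float)
    diff = rel_fluct(n_sa, n_sa) - rel_fluct(n_sa, prod_as)
    return 1.0 / diff


def eq16_prediction_from_pmf(dist) -> float:
    """Evaluate the fluctuation identity on an exact OccupancyDistribution."""
    i = dist.support.astype(float)
    prod = (dist.N_A_total - i) * (dist.N_S_total - i)
    m_i = dist.mean()
    m_p = float(np.dot(prod, dist.pmf))
    if m_i == 0 or m_p == 0:
        raise UndefinedFluctuationError("identity undefined at degenerate pmf")
    l_ii = dist.var() / (m_i * m_i)
    cov_ip = float(np.dot(i * prod, dist.pmf)) - m_i * m_p
    l_ip = cov_ip / (m_i * m_p)
    return 1.0 / (l_ii - l_ip)


def block_average(series: np.ndarray, n_blocks: int = 20) -> tuple[float, float]:
    """Mean and standard error of the mean from contiguous block means."""
    series = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if series.size < n_blocks:
        raise ValueError(
            f"series of length {series.size} too short for {n_blocks} blocks"
        )
    usable = (series.size // n_blocks) * n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    mean = float(blocks.mean())
    stderr = float(blocks.std(ddof=1) / np.sqrt(n_blocks))
    return mean, stderr


def _jackknife_ratio(num: np.ndarray, den: np.ndarray, n_blocks: int) -> tuple[float, float]:
    """Delete-one-block jackknife for a ratio of means (ratio of means,
    not mean of ratios)."""
    usable = (num.size // n_blocks) * n_blocks
    nb = num[:usable].reshape(n_blocks, -1).mean(axis=1)
    db = den[:usable].reshape(n_blocks, -1).mean(axis=1)
    full = nb.mean() / db.mean()
    loo = np.array(
        [
            (nb.sum() - nb[j]) / (db.sum() - db[j])
            for j in range(n_blocks)
        ]
    )
    var = (n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)
    return float(full), float(np.sqrt(var))


@dataclass
class EquilibriumSummary:
    """Means, fluctuation functionals and equilibrium constants of one trace."""

    mean_n_sa: float
    mean_n_a: float
    mean_n_s: float
    mean_prod_as: float
    theta_sa: float
    c_a_nm3: float
    c_a_molar: float
    l_sa_sa: float | None
    l_a_s: float | None
    l_a_sa: float | None
    l_s_sa: float | None
    l_a_a: float | None
    l_s_s: float | None
    K: float
    Kprime: float
    K_stderr: float
    Kprime_stderr: float
    n_sa_stderr: float
    eq16_mean: float | None
    n_samples: int
    V: float
    c_std: float

    @property
    def Kprime_over_K_minus_1(self) -> float:
        return self.Kprime / self.K - 1.0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["Kprime_over_K_minus_1"] = (
            self.Kprime_over_K_minus_1 if self.K > 0 else None
        )
        return d


def summarize(trace: "ObservableTrace", n_blocks: int = 20) -> EquilibriumSummary:
    """Aggregate a trace into an EquilibriumSummary with block errors.

    Fluctuation functionals that are undefined for the trace (a species never
    or always present) are reported as None rather than raising, so that
    strongly converted or empty-occupancy systems still summarize.
    """
    n_sa = trace.n_sa.astype(float)
    n_a = trace.n_a.astype(float)
    n_s = trace.n_s.astype(float)
    if n_sa.size == 0:
        raise ValueError("cannot summarize an empty trace")
    prod = trace.prod_as.astype(float)
    V = trace.volume
    c_std = trace.c_std

    def safe_l(x, y):
        try:
            return rel_fluct(x, y)
        except UndefinedFluctuationError:
            return None

    mean_n_sa, n_sa_stderr = block_average(n_sa, n_blocks)
    mean_n_a = float(n_a.mean())
    mean_n_s = float(n_s.mean())
    mean_prod = float(prod.mean())

    K, K_err = (0.0, 0.0)
    if mean_n_sa > 0 and mean_prod > 0:
        K, K_err = _jackknife_ratio(n_sa, prod, n_blocks)
        K *= V * c_std
        K_err *= V * c_std
    elif mean_prod <= 0:
        raise ZeroDivisionError("K unreachable: <N_A*N_S> = 0 on every sample")

    Kp, Kp_err = (0.0, 0.0)
    if mean_n_sa > 0 and mean_n_a * mean_n_s > 0:
        # delete-one-block jackknife on the ratio <N_SA>/(<N_A><N_S>)
        usable = (n_sa.size // n_blocks) * n_blocks
        nb = n_sa[:usable].reshape(n_blocks, -1).mean(axis=1)
        ab = n_a[:usable].reshape(n_blocks, -1).mean(axis=1)
        sb = n_s[:usable].reshape(n_blocks, -1).mean(axis=1)
        m = n_blocks - 1
        loo = np.array(
            [
                ((nb.sum() - nb[j]) / m)
                / (((ab.sum() - ab[j]) / m) * ((sb.sum() - sb[j]) / m))
                for j in range(n_blocks)
            ]
        )
        Kp = mean_n_sa / (mean_n_a * mean_n_s) * V * c_std
        var = m / n_blocks * np.sum((loo - loo.mean()) ** 2)
        Kp_err = float(np.sqrt(var)) * V * c_std

    try:
        eq16 = eq16_prediction(n_sa, prod)
    except (UndefinedFluctuationError, ZeroDivisionError):
        eq16 = None

    c_a = mean_n_a / V
    return EquilibriumSummary(
        mean_n_sa=mean_n_sa,
        mean_n_a=mean_n_a,
        mean_n_s=mean_n_s,
        mean_prod_as=mean_prod,
        theta_sa=mean_n_sa / trace.N_S_total if trace.N_S_total else float("nan"),
        c_a_nm3=c_a,
        c_a_molar=nm3_to_molar(c_a),
        l_sa_sa=safe_l(n_sa, n_sa),
        l_a_s=safe_l(n_a, n_s),
        l_a_sa=safe_l(n_a, n_sa),
        l_s_sa=safe_l(n_s, n_sa),
        l_a_a=safe_l(n_a, n_a),
        l_s_s=safe_l(n_s, n_s),
        K=K,
        Kprime=Kp,
        K_stderr=K_err,
        Kprime_stderr=Kp_err,
        n_sa_stderr=n_sa_stderr,
        eq16_mean=eq16,
        n_samples=int(n_sa.size),
        V=V,
        c_std=c_std,
    )
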