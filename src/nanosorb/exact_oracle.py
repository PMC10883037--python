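"""Exact enumeration of the finite-system occupancy distribution.

For the ideal adsorption model (non-interacting single-occupancy sites,
ideal adsorbate gas) the canonical partition function is a binding
polynomial over the number of occupied sites i:

    p(i)  proportional to  C(N_A, i) * C(N_S, i) * i! * z**i

where the dimensionless site affinity z = K / (c_std * V) is the only
surviving combination of the single- and pair-particle partition functions.
The first combinatorial factor counts the choice of i adsorbate molecules
out of N_A_total, the second times i! counts ordered placements onto the
N_S_total distinguishable sites.

This module is the package's ground truth: the correlation-aware
equilibrium-constant estimator evaluated on this pmf returns z*V*c_std to
machine precision for every (N_A_total, N_S_total, z) — the identity that
makes K size-invariant in small closed systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .model_core import C_STD

#: pmf support is truncated where the log-weight falls this far below the max.
_LOG_TRUNC = 60.0


@dataclass
class OccupancyDistribution:
    """Exact pmf over the number of occupied sites for given (N_A, N_S, z)."""

    N_A_total: int
    N_S_total: int
    z: float
    support: np.ndarray = field(repr=False)
    pmf: np.ndarray = field(repr=False)

    @property
    def n_sa_max(self) -> int:
        return min(self.N_A_total, self.N_S_total)

    # -- moments -----------------------------------------------------------
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def mean_sq(self) -> float:
        return float(np.dot(self.support.astype(float) ** 2, self.pmf))

    def var(self) -> float:
        m = self.mean()
        return self.mean_sq() - m * m

    def mean_free_A(self) -> float:
        return self.N_A_total - self.mean()

    def mean_vacant_S(self) -> float:
        return self.N_S_total - self.mean()

    def mean_product_AS(self) -> float:
        """<N_A * N_S> = <(N_A_total - i)(N_S_total - i)>, the two-body average."""
        i = self.support.astype(float)
        return float(
            np.dot((self.N_A_total - i) * (self.N_S_total - i), self.pmf)
        )

    def theta_mean(self) -> float:
        return self.mean() / self.N_S_total

    def rel_fluct_occupancy(self) -> float:
        """l(N_SA, N_SA) = var(i)/<i>^2 evaluated on the exact pmf."""
        m = self.mean()
        if m == 0:
            raise ZeroDivisionError("l(N_SA,N_SA) undefined: <N_SA> = 0")
        return self.var() / (m * m)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n iid occupancy counts from the pmf."""
        return rng.choice(self.support, size=n, p=self.pmf)

    def to_dict(self) -> dict:
        return {
            "N_A_total": self.N_A_total,
            "N_S_total": self.N_S_total,
            "z": self.z,
            "support": self.support.tolist(),
            "pmf": self.pmf.tolist(),
        }


def occupancy_pmf(N_A_total: int, N_S_total: int, z: float) -> OccupancyDistribution:
    """Enumerate the occupancy pmf in log space.

    Log-gamma-based binomials keep particle numbers up to ~1e4 and affinities
    up to ~1e8 enumerable without overflow; the support is truncated where the
    log-weight falls 60 nats below the maximum.
    """
    if z < 0:
        raise ValueError(f"site affinity z must be >= 0, got {z}")
    if N_A_total < 0 or N_S_total < 0:
        raise ValueError("particle counts must be non-negative")
    imax = min(N_A_total, N_S_total)
    i = np.arange(imax + 1)
    if z == 0.0:
        pmf = np.zeros(imax + 1)
        pmf[0] = 1.0
        return OccupancyDistribution(N_A_total, N_S_total, z, i, pmf)
    logw = (
        gammaln(N_A_total + 1)
        - gammaln(i + 1)
        - gammaln(N_A_total - i + 1)
        + gammaln(N_S_total + 1)
        - gammaln(N_S_total - i + 1)
        + i * np.log(z)
    )
    logw -= logsumexp(logw)
    keep = logw > logw.max() - _LOG_TRUNC
    pmf = np.zeros(imax + 1)
    pmf[keep] = np.exp(logw[keep])
    pmf /= pmf.sum()
    return OccupancyDistribution(N_A_total, N_S_total, z, i, pmf)


def z_from_K(K: float, V: float, c_std: float = C_STD) -> float:
    """Convert an equilibrium constant to the dimensionless site affinity."""
    return K / (c_std * V)


def K_from_z(z: float, V: float, c_std: float = C_STD) -> float:
    return z * c_std * V


def oracle_K_recovery(dist: OccupancyDistribution, V: float, c_std: float = C_STD) -> float:
    """Evaluate the correlation-aware K estimator on the exact distribution.

    Returns (<i> / <(N_A-i)(N_S-i)>) * V * c_std, which equals z*V*c_std to
    machine precision — the self-consistency identity between the binding
    polynomial and the equilibrium-constant expression.
    """
    denom = dist.mean_product_AS()
    if denom <= 0:
        raise ZeroDivisionError(
            "K recovery undefined: <N_A*N_S> = 0 (complete conversion)"
        )
    return dist.mean() / denom * V * c_std


def invert_for_z(target_mean: float, N_A_total: int, N_S_total: int) -> float:
    """Find z such that the exact pmf has <N_SA> = target_mean.

    <i>(z) is strictly increasing in z, so a bracketing root-find on log(z)
    converges to relative tolerance 1e-12.
    """
    imax = min(N_A_total, N_S_total)
    if not (0.0 < target_mean < imax):
        raise ValueError(
            f"target mean must lie strictly inside (0, {imax}), got {target_mean}"
        )

    def f(logz: float) -> float:
        return occupancy_pmf(N_A_total, N_S_total, np.exp(logz)).mean() - target_mean

    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo -= 8.0
        if lo < -700:
            raise RuntimeError("bracketing failed on the low side")
    while f(hi) < 0:
        hi += 8.0
        if hi > 700:
            raise RuntimeError("bracketing failed on the high side")
    logz = brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)
    return float(np.exp(logz))


def langmuir_limit_check(
    K: float,
    n_A: int,
    n_S: int,
    v: float,
    scales: list[int] | np.ndarray,
    c_std: float = C_STD,
) -> np.ndarray:
    """Occupied fraction of m replicated subsystems merged into one system.

    Scales (n_A, n_S, v) by each factor m at fixed concentrations and fixed K
    and returns the exact <theta_SA>(m).  As m grows, the sequence converges
    to the closed-system Langmuir solution with the same K — the macroscopic
    limit in which cross-correlations between particle numbers vanish.
    """
    out = np.empty(len(scales))
    for j, m in enumerate(scales):
        if m < 1:
            raise ValueError("scale factors must be >= 1")
        z = z_from_K(K, v * m, c_std)
        out[j] = occupancy_pmf(n_A * m, n_S * m, z).theta_mean()
    return out
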