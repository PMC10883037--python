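"""Canonical-ensemble Metropolis Monte Carlo with rigid-body molecule moves.

One trial move selects a molecule at random, displaces it uniformly within
+/- 0.4 nm along each Cartesian axis and rotates it rigidly about its
binding atom (uniform increments of +/- 0.1 in cos(theta), reflected at the
poles, and +/- 0.314 rad in phi).  Acceptance follows
min(1, exp(-dU/(R*T))) with per-mole energies.  Lennard-Jones interactions
are truncated (not shifted) at 2.0 nm with the minimum-image convention in
all three axes; sites never interact with each other.

The hot loop is compiled with numba; thin pure-Python references of each
piece (pair energy, molecule energy, occupancy counting, trial moves) are
exposed for testing and for the insertion routine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_core import C_STD, R_GAS, SystemSpec, spec_to_dict, validate_spec
from .system_builder import (
    AdsorbateConfiguration,
    SiteLattice,
    build_site_lattice,
    random_insert_adsorbates,
)

# ---------------------------------------------------------------------------
# Pure-Python reference pieces


def lj_pair_energy(r: float, sigma: float, epsilon: float, r_cut: float) -> float:
    """Truncated (unshifted) Lennard-Jones pair energy in kJ/mol."""
    if r <= 0:
        raise ValueError("pair distance must be positive (overlap)")
    if r >= r_cut:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _pair_e(p1, p2, sigma, eps, r_cut, box):
    r = float(np.linalg.norm(_min_image(p1 - p2, box)))
    return lj_pair_energy(r, sigma, eps, r_cut) if r > 0 else np.inf


def molecule_energy_brute(
    config: AdsorbateConfiguration, lattice: SiteLattice, i: int, spec: SystemSpec
) -> float:
    """Energy of molecule i with all sites and all other molecules (kJ/mol)."""
    lj = spec.effective_lj()
    box = np.array([spec.L_x, spec.L_y, spec.L_z])
    rc = lj.r_cut
    s_sa, e_sa = lj.sigma_eps("s", "a")
    s_sh, e_sh = lj.sigma_eps("s", "h")
    s_ah, e_ah = lj.sigma_eps("a", "h")
    s_hh, e_hh = lj.sigma_eps("h", "h")
    s_aa, e_aa = lj.sigma_eps("a", "a")
    a_i = config.a_xyz[i]
    h_i = config.h_xyz[i]
    e = 0.0
    for m in range(lattice.n_sites):
        s_m, hs_m = lattice.s_xyz[m], lattice.h_xyz[m]
        e += _pair_e(a_i, s_m, s_sa, e_sa, rc, box)
        e += _pair_e(a_i, hs_m, s_ah, e_ah, rc, box)
        e += _pair_e(h_i, s_m, s_sh, e_sh, rc, box)
        e += _pair_e(h_i, hs_m, s_hh, e_hh, rc, box)
    for j in range(config.n_molecules):
        if j == i:
            continue
        a_j, h_j = config.a_xyz[j], config.h_xyz[j]
        e += _pair_e(a_i, a_j, s_aa, e_aa, rc, box)
        e += _pair_e(a_i, h_j, s_ah, e_ah, rc, box)
        e += _pair_e(h_i, a_j, s_ah, e_ah, rc, box)
        e += _pair_e(h_i, h_j, s_hh, e_hh, rc, box)
    return e


def total_energy_brute(
    config: AdsorbateConfiguration, lattice: SiteLattice, spec: SystemSpec
) -> float:
    """Total configurational energy; intermolecular pairs counted once."""
    e_site = sum(
        _site_energy_brute(config, lattice, i, spec)
        for i in range(config.n_molecules)
    )
    e_inter = 0.0
    for i in range(config.n_molecules):
        e_inter += molecule_energy_brute(config, lattice, i, spec)
        e_inter -= _site_energy_brute(config, lattice, i, spec)
    return e_site + e_inter / 2.0


def _site_energy_brute(config, lattice, i, spec):
    empty = AdsorbateConfiguration(
        a_xyz=config.a_xyz[i : i + 1],
        u=config.u[i : i + 1],
        bond_length=config.bond_length,
    )
    return molecule_energy_brute(empty, lattice, 0, spec)


def metropolis_accept(dU: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dU/(R*T)))."""
    if dU <= 0.0:
        return True
    w = -dU / (R_GAS * T)
    if w < -700.0:
        return False
    return bool(rng.random() < np.exp(w))


def trial_move(
    config: AdsorbateConfiguration, i: int, spec: SystemSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Propose a combined displacement + rigid rotation for molecule i.

    Returns the proposed (a_position, orientation).  The a-atom is the
    rotation pivot; cos(theta) increments are reflected at +/-1 so the
    orientation proposal stays symmetric and uniform on the sphere.
    """
    box = np.array([spec.L_x, spec.L_y, spec.L_z])
    disp = rng.uniform(-spec.move_max_displacement, spec.move_max_displacement, 3)
    a_new = (config.a_xyz[i] + disp) % box
    u = config.u[i]
    ct = u[2] + rng.uniform(-spec.move_max_dcos_theta, spec.move_max_dcos_theta)
    if ct > 1.0:
        ct = 2.0 - ct
    elif ct < -1.0:
        ct = -2.0 - ct
    phi = np.arctan2(u[1], u[0]) + rng.uniform(-spec.move_max_dphi, spec.move_max_dphi)
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    u_new = np.array([st * np.cos(phi), st * np.sin(phi), ct])
    return a_new, u_new


def count_occupancy(
    config: AdsorbateConfiguration,
    lattice: SiteLattice,
    bound_cutoff: float,
    box: np.ndarray,
) -> tuple[int, int, int, int]:
    """(N_SA, N_A, N_S, double_occupancy_count) for one configuration.

    A site is occupied iff at least one a-atom lies within the cutoff of its
    s-atom (minimum image); a molecule is bound iff within the cutoff of at
    least one site.  Sites hosting two or more molecules are counted once in
    N_SA and increment the double-occupancy counter.
    """
    if config.n_molecules == 0 or lattice.n_sites == 0:
        return 0, config.n_molecules, lattice.n_sites, 0
    d = config.a_xyz[:, None, :] - lattice.s_xyz[None, :, :]
    d -= box * np.round(d / box)
    r2 = np.sum(d * d, axis=2)
    within = r2 < bound_cutoff**2
    per_site = within.sum(axis=0)
    n_sa = int((per_site >= 1).sum())
    double = int((per_site >= 2).sum())
    bound_mols = int((within.sum(axis=1) >= 1).sum())
    return n_sa, config.n_molecules - bound_mols, lattice.n_sites - n_sa, double


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True, fastmath=True)
def _lj(r2, s6, e4, rcut2):
    if r2 >= rcut2:
        return 0.0
    inv6 = s6 / (r2 * r2 * r2)
    return e4 * (inv6 * inv6 - inv6)


@njit(cache=True, fastmath=True)
def _d2(x1, y1, z1, x2, y2, z2, lx, ly, lz):
    dx = x1 - x2
    dy = y1 - y2
    dz = z1 - z2
    dx -= lx * np.floor(dx / lx + 0.5)
    dy -= ly * np.floor(dy / ly + 0.5)
    dz -= lz * np.floor(dz / lz + 0.5)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, fastmath=True)
def _mol_energy(
    k, ax, ay, az, hx, hy, hz, A, H, S, HS, lx, ly, lz,
    s6_aa, e4_aa, s6_ah, e4_ah, s6_hh, e4_hh, s6_sa, e4_sa, s6_sh, e4_sh, rcut2,
):
    e = 0.0
    for m in range(S.shape[0]):
        e += _lj(_d2(ax, ay, az, S[m, 0], S[m, 1], S[m, 2], lx, ly, lz), s6_sa, e4_sa, rcut2)
        e += _lj(_d2(ax, ay, az, HS[m, 0], HS[m, 1], HS[m, 2], lx, ly, lz), s6_ah, e4_ah, rcut2)
        e += _lj(_d2(hx, hy, hz, S[m, 0], S[m, 1], S[m, 2], lx, ly, lz), s6_sh, e4_sh, rcut2)
        e += _lj(_d2(hx, hy, hz, HS[m, 0], HS[m, 1], HS[m, 2], lx, ly, lz), s6_hh, e4_hh, rcut2)
    for j in range(A.shape[0]):
        if j == k:
            continue
        e += _lj(_d2(ax, ay, az, A[j, 0], A[j, 1], A[j, 2], lx, ly, lz), s6_aa, e4_aa, rcut2)
        e += _lj(_d2(ax, ay, az, H[j, 0], H[j, 1], H[j, 2], lx, ly, lz), s6_ah, e4_ah, rcut2)
        e += _lj(_d2(hx, hy, hz, A[j, 0], A[j, 1], A[j, 2], lx, ly, lz), s6_ah, e4_ah, rcut2)
        e += _lj(_d2(hx, hy, hz, H[j, 0], H[j, 1], H[j, 2], lx, ly, lz), s6_hh, e4_hh, rcut2)
    return e


@njit(cache=True, fastmath=True)
def _total_energy(
    A, H, S, HS, lx, ly, lz,
    s6_aa, e4_aa, s6_ah, e4_ah, s6_hh, e4_hh, s6_sa, e4_sa, s6_sh, e4_sh, rcut2,
):
    e = 0.0
    for k in range(A.shape[0]):
        for m in range(S.shape[0]):
            e += _lj(_d2(A[k, 0], A[k, 1], A[k, 2], S[m, 0], S[m, 1], S[m, 2], lx, ly, lz), s6_sa, e4_sa, rcut2)
            e += _lj(_d2(A[k, 0], A[k, 1], A[k, 2], HS[m, 0], HS[m, 1], HS[m, 2], lx, ly, lz), s6_ah, e4_ah, rcut2)
            e += _lj(_d2(H[k, 0], H[k, 1], H[k, 2], S[m, 0], S[m, 1], S[m, 2], lx, ly, lz), s6_sh, e4_sh, rcut2)
            e += _lj(_d2(H[k, 0], H[k, 1], H[k, 2], HS[m, 0], HS[m, 1], HS[m, 2], lx, ly, lz), s6_hh, e4_hh, rcut2)
        for j in range(k + 1, A.shape[0]):
            e += _lj(_d2(A[k, 0], A[k, 1], A[k, 2], A[j, 0], A[j, 1], A[j, 2], lx, ly, lz), s6_aa, e4_aa, rcut2)
            e += _lj(_d2(A[k, 0], A[k, 1], A[k, 2], H[j, 0], H[j, 1], H[j, 2], lx, ly, lz), s6_ah, e4_ah, rcut2)
            e += _lj(_d2(H[k, 0], H[k, 1], H[k, 2], A[j, 0], A[j, 1], A[j, 2], lx, ly, lz), s6_ah, e4_ah, rcut2)
            e += _lj(_d2(H[k, 0], H[k, 1], H[k, 2], H[j, 0], H[j, 1], H[j, 2], lx, ly, lz), s6_hh, e4_hh, rcut2)
    return e


@njit(cache=True, fastmath=True)
def _run_mc(
    A, H, U, S, HS, lx, ly, lz, beta, bond,
    s6_aa, e4_aa, s6_ah, e4_ah, s6_hh, e4_hh, s6_sa, e4_sa, s6_sh, e4_sh, rcut2,
    dmax, dcosmax, dphimax, bcut2,
    n_equil, n_prod, sample_interval,
    n_sa_out, n_a_out, n_s_out, e_out,
    site_occ,  # int32 scratch, length M
    gsa_counts, gsa_dr,  # histogram of s-a distances; empty array disables
    seed,
):
    np.random.seed(seed)
    N = A.shape[0]
    M = S.shape[0]
    e_tot = _total_energy(
        A, H, S, HS, lx, ly, lz,
        s6_aa, e4_aa, s6_ah, e4_ah, s6_hh, e4_hh, s6_sa, e4_sa, s6_sh, e4_sh, rcut2,
    )
    gsa_nbins = gsa_counts.shape[0]
    gsa_rmax2 = (gsa_nbins * gsa_dr) ** 2
    accepted = 0
    trials = 0
    n_samp = 0
    double_occ = 0
    n_total = n_equil + n_prod
    for step in range(n_total):
        if N > 0:
            k = np.random.randint(N)
            e_old = _mol_energy(
                k, A[k, 0], A[k, 1], A[k, 2], H[k, 0], H[k, 1], H[k, 2],
                A, H, S, HS, lx, ly, lz,
                s6_aa, e4_aa, s6_ah, e4_ah, s6_hh, e4_hh, s6_sa, e4_sa, s6_sh, e4_sh, rcut2,
            )
            nax = A[k, 0] + (np.random.random() * 2.0 - 1.0) * dmax
            nay = A[k, 1] + (np.random.random() * 2.0 - 1.0) * dmax
            naz = A[k, 2] + (np.random.random() * 2.0 - 1.0) * dmax
            nax -= lx * np.floor(nax / lx)
            nay -= ly * np.floor(nay / ly)
            naz -= lz * np.floor(naz / lz)
            ct = U[k, 2] + (np.random.random() * 2.0 - 1.0) * dcosmax
            if ct > 1.0:
                ct = 2.0 - ct
            elif ct < -1.0:
                ct = -2.0 - ct
            phi = np.arctan2(U[k, 1], U[k, 0]) + (np.random.random() * 2.0 - 1.0) * dphimax
            st = np.sqrt(max(0.0, 1.0 - ct * ct))
            nux = st * np.cos(phi)
            nuy = st * np.sin(phi)
            nuz = ct
            nhx = nax + bond * nux
            nhy = nay + bond * nuy
            nhz = naz + bond * nuz
            e_new = _mol_energy(
                k, nax, nay, naz, nhx, nhy, nhz,
                A, H, S, HS, lx, ly, lz,
                s6_aa, e4_aa, s6_ah, e4_ah, s6_hh, e4_hh, s6_sa, e4_sa, s6_sh, e4_sh, rcut2,
            )
            du = e_new - e_old
            acc = False
            if du <= 0.0:
                acc = True
            else:
                w = -beta * du
                if w > -700.0 and np.random.random() < np.exp(w):
                    acc = True
            if step >= n_equil:
                trials += 1
                if acc:
                    accepted += 1
            if acc:
                A[k, 0] = nax
                A[k, 1] = nay
                A[k, 2] = naz
                H[k, 0] = nhx
                H[k, 1] = nhy
                H[k, 2] = nhz
                U[k, 0] = nux
                U[k, 1] = nuy
                U[k, 2] = nuz
                e_tot += du
        if step >= n_equil and (step - n_equil + 1) % sample_interval == 0:
            if n_samp < n_sa_out.shape[0]:
                for m in range(M):
                    site_occ[m] = 0
                bound_mols = 0
                for j in range(N):
                    mol_bound = False
                    for m in range(M):
                        r2 = _d2(
                            A[j, 0], A[j, 1], A[j, 2],
                            S[m, 0], S[m, 1], S[m, 2], lx, ly, lz,
                        )
                        if r2 < bcut2:
                            site_occ[m] += 1
                            mol_bound = True
                        if gsa_nbins > 0 and r2 < gsa_rmax2:
                            gsa_counts[int(np.sqrt(r2) / gsa_dr)] += 1
                    if mol_bound:
                        bound_mols += 1
                nsa = 0
                for m in range(M):
                    if site_occ[m] >= 1:
                        nsa += 1
                    if site_occ[m] >= 2:
                        double_occ += 1
                n_sa_out[n_samp] = nsa
                n_a_out[n_samp] = N - bound_mols
                n_s_out[n_samp] = M - nsa
                e_out[n_samp] = e_tot
                n_samp += 1
                if not np.isfinite(e_tot):
                    return accepted, trials, n_samp, double_occ, e_tot, -1
    return accepted, trials, n_samp, double_occ, e_tot, 0


# ---------------------------------------------------------------------------
# Trace container and driver


@dataclass
class ObservableTrace:
    """Per-sample observables of one run plus global counters."""

    spec: SystemSpec
    n_sa: np.ndarray
    n_a: np.ndarray
    n_s: np.ndarray
    energy: np.ndarray
    trials: int
    accepted: int
    double_occupancy: int
    seed: int
    final_config: AdsorbateConfiguration | None = None
    lattice: SiteLattice | None = None
    gsa_counts: np.ndarray | None = field(default=None, repr=False)
    gsa_bin_width: float | None = None

    @property
    def prod_as(self) -> np.ndarray:
        """Per-sample two-body product N_A * N_S."""
        return self.n_a.astype(np.int64) * self.n_s.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return int(self.n_sa.size)

    @property
    def acceptance_ratio(self) -> float:
        return self.accepted / self.trials if self.trials else float("nan")

    @property
    def volume(self) -> float:
        return self.spec.volume

    @property
    def c_std(self) -> float:
        return C_STD

    @property
    def N_A_total(self) -> int:
        return self.spec.N_A_total

    @property
    def N_S_total(self) -> int:
        return self.spec.N_S_total

    @property
    def double_occupancy_rate(self) -> float:
        """Double-occupancy incidents per sample."""
        return self.double_occupancy / self.n_samples if self.n_samples else 0.0

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "move_index": (np.arange(self.n_samples) + 1) * self.spec.sample_interval,
                "N_SA": self.n_sa,
                "N_A": self.n_a,
                "N_S": self.n_s,
                "N_A*N_S": self.prod_as,
                "energy": self.energy,
            }
        )
        df.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "spec": spec_to_dict(self.spec),
            "seed": self.seed,
            "trials": self.trials,
            "accepted": self.accepted,
            "acceptance_ratio": self.acceptance_ratio,
            "double_occupancy": self.double_occupancy,
            "n_samples": self.n_samples,
        }

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def trace_from_series(
    n_sa, n_a, n_s, spec: SystemSpec, energy=None
) -> ObservableTrace:
    """Wrap external occupancy series (e.g. experimental) as a trace."""
    n_sa = np.asarray(n_sa)
    if energy is None:
        energy = np.zeros(n_sa.size)
    return ObservableTrace(
        spec=spec,
        n_sa=n_sa,
        n_a=np.asarray(n_a),
        n_s=np.asarray(n_s),
        energy=np.asarray(energy),
        trials=0,
        accepted=0,
        double_occupancy=0,
        seed=spec.seed,
    )


def load_trace_csv(path, spec: SystemSpec) -> ObservableTrace:
    """Read a trace CSV (columns N_SA, N_A, N_S at minimum)."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("N_SA", "N_A", "N_S"):
        if col not in df.columns:
            raise ValueError(f"trace file {path} is missing column {col!r}")
    energy = df["energy"].to_numpy() if "energy" in df.columns else None
    return trace_from_series(
        df["N_SA"].to_numpy(), df["N_A"].to_numpy(), df["N_S"].to_numpy(), spec, energy
    )


def run_simulation(
    spec: SystemSpec,
    collect_gsa: bool = False,
    gsa_bin_width: float = 0.003,
    gsa_rmax: float = 1.5,
) -> ObservableTrace:
    """Run one canonical MC simulation; deterministic given spec.seed.

    Equilibration moves are discarded; observables are recorded every
    ``sample_interval`` production moves.  With ``collect_gsa`` the s-a
    distance histogram is accumulated at each sample for g_sa(r).
    """
    validate_spec(spec)
    lattice = build_site_lattice(spec.N_S_total, spec) if spec.N_S_total else SiteLattice(
        s_xyz=np.empty((0, 3)), h_xyz=np.empty((0, 3))
    )
    rng = np.random.default_rng(spec.seed)
    config = random_insert_adsorbates(spec.N_A_total, lattice, spec, rng)

    lj = spec.effective_lj()
    s_aa, e_aa = lj.sigma_eps("a", "a")
    s_ah, e_ah = lj.sigma_eps("a", "h")
    s_hh, e_hh = lj.sigma_eps("h", "h")
    s_sa, e_sa = lj.sigma_eps("s", "a")
    s_sh, e_sh = lj.sigma_eps("s", "h")

    n_samples = spec.n_production // spec.sample_interval
    n_sa = np.zeros(n_samples, dtype=np.int32)
    n_a = np.zeros(n_samples, dtype=np.int32)
    n_s = np.zeros(n_samples, dtype=np.int32)
    energy = np.zeros(n_samples, dtype=np.float64)
    site_occ = np.zeros(max(lattice.n_sites, 1), dtype=np.int32)
    if collect_gsa:
        gsa_counts = np.zeros(int(np.ceil(gsa_rmax / gsa_bin_width)), dtype=np.int64)
    else:
        gsa_counts = np.zeros(0, dtype=np.int64)

    A = np.ascontiguousarray(config.a_xyz, dtype=np.float64)
    U = np.ascontiguousarray(config.u, dtype=np.float64)
    H = A + spec.bond_length * U
    kernel_seed = int(np.random.SeedSequence(spec.seed).generate_state(1)[0] % (2**31))

    accepted, trials, n_samp, double_occ, e_final, status = _run_mc(
        A, H, U,
        np.ascontiguousarray(lattice.s_xyz), np.ascontiguousarray(lattice.h_xyz),
        spec.L_x, spec.L_y, spec.L_z,
        1.0 / (R_GAS * spec.T), spec.bond_length,
        s_aa**6, 4.0 * e_aa, s_ah**6, 4.0 * e_ah, s_hh**6, 4.0 * e_hh,
        s_sa**6, 4.0 * e_sa, s_sh**6, 4.0 * e_sh, lj.r_cut**2,
        spec.move_max_displacement, spec.move_max_dcos_theta, spec.move_max_dphi,
        spec.bound_cutoff**2,
        spec.n_equilibration, spec.n_production, spec.sample_interval,
        n_sa, n_a, n_s, energy, site_occ,
        gsa_counts, gsa_bin_width,
        kernel_seed,
    )
    if status != 0:
        raise ArithmeticError(
            f"non-finite total energy encountered (E={e_final}); "
            "check for overlapping particles or a corrupt configuration"
        )
    final = AdsorbateConfiguration(a_xyz=A, u=U, bond_length=spec.bond_length)
    return ObservableTrace(
        spec=spec,
        n_sa=n_sa[:n_samp],
        n_a=n_a[:n_samp],
        n_s=n_s[:n_samp],
        energy=energy[:n_samp],
        trials=trials,
        accepted=accepted,
        double_occupancy=double_occ,
        seed=spec.seed,
        final_config=final,
        lattice=lattice,
        gsa_counts=gsa_counts if collect_gsa else None,
        gsa_bin_width=gsa_bin_width if collect_gsa else None,
    )


# ---------------------------------------------------------------------------
# Radial distribution


def radial_distribution_sa(trace: ObservableTrace) -> tuple[np.ndarray, np.ndarray]:
    """g_sa(r) from the histogram accumulated during a run.

    Standard pair-distribution normalization for the s-a pair in the periodic
    box: counts divided by n_samples * N_s * N_a * 4 pi r^2 dr / V.
    """
    if trace.gsa_counts is None or trace.n_samples == 0:
        raise ValueError("trace carries no g_sa histogram (run with collect_gsa=True)")
    dr = trace.gsa_bin_width
    counts = trace.gsa_counts.astype(float)
    r = (np.arange(counts.size) + 0.5) * dr
    npairs = trace.N_A_total * trace.N_S_total
    shell = 4.0 * np.pi * r**2 * dr / trace.volume
    g = counts / (trace.n_samples * npairs * shell)
    return r, g


def radial_distribution_sa_from_configs(
    configs: list[AdsorbateConfiguration],
    lattice: SiteLattice,
    spec: SystemSpec,
    bin_width: float = 0.003,
    r_max: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """g_sa(r) from explicit configuration snapshots."""
    if not configs:
        raise ValueError("need at least one snapshot")
    box = np.array([spec.L_x, spec.L_y, spec.L_z])
    nbins = int(np.ceil(r_max / bin_width))
    counts = np.zeros(nbins)
    for cfg in configs:
        d = cfg.a_xyz[:, None, :] - lattice.s_xyz[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt(np.sum(d * d, axis=2)).ravel()
        hist, _ = np.histogram(r, bins=nbins, range=(0.0, nbins * bin_width))
        counts += hist
    r = (np.arange(nbins) + 0.5) * bin_width
    shell = 4.0 * np.pi * r**2 * bin_width / spec.volume
    npairs = configs[0].n_molecules * lattice.n_sites
    g = counts / (len(configs) * npairs * shell)
    return r, g
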