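"""Build immobile site lattices, series boxes and initial adsorbate configurations.

Adsorbing sites form a two-dimensional equilateral triangular lattice with a
nearest-neighbour distance of 3.5 nm, centred in the box xy-midplane.  Each
site is a vertical s-h dimer: the binding atom s at z = 2.50 nm and the
protecting atom h 0.14 nm above it, which sterically blocks a second
adsorbate from binding the same site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import SystemSpec, validate_spec

# Row patterns transcribed as near-square triangular patches for the particle
# numbers used in the simulation series.  Equilibrium quantities of the ideal
# model are insensitive to the patch shape (sites do not interact), so any
# patch with the correct count and 3.5 nm spacing is equivalent.
_ROW_LAYOUTS: dict[int, tuple[int, ...]] = {
    1: (1,),
    2: (2,),
    3: (2, 1),
    4: (2, 2),
    5: (3, 2),
    6: (3, 3),
    7: (2, 3, 2),
    8: (3, 2, 3),
    9: (3, 3, 3),
    10: (3, 4, 3),
    11: (4, 3, 4),
    12: (4, 4, 4),
    13: (4, 5, 4),
    14: (4, 3, 4, 3),
    30: (5, 5, 5, 5, 5, 5),
    68: (8, 7, 8, 7, 8, 7, 8, 7, 8),
    120: (10,) * 12,
}

#: concentration targets (nm^-3) of the simulation series
SERIES_CONC = {"R1": 0.008, "R2": 0.015, "R3": 0.015, "R4": 0.008}


@dataclass
class SiteLattice:
    """Immobile adsorbing sites: s positions and h positions, one row each."""

    s_xyz: np.ndarray  # (M, 3)
    h_xyz: np.ndarray  # (M, 3)

    @property
    def n_sites(self) -> int:
        return self.s_xyz.shape[0]


@dataclass
class AdsorbateConfiguration:
    """Rigid diatomic adsorbates: binding-atom positions and unit orientations."""

    a_xyz: np.ndarray  # (N, 3), wrapped into the primary box
    u: np.ndarray  # (N, 3) unit vectors
    bond_length: float = 0.14

    @property
    def n_molecules(self) -> int:
        return self.a_xyz.shape[0]

    @property
    def h_xyz(self) -> np.ndarray:
        return self.a_xyz + self.bond_length * self.u


def _row_layout(n: int) -> tuple[int, ...]:
    if n in _ROW_LAYOUTS:
        return _ROW_LAYOUTS[n]
    # nearest-to-square patch: choose a row count that balances the x extent
    # (3.5 nm per column) against the y extent (3.5*sqrt(3)/2 per row)
    n_rows = max(1, round(np.sqrt(n * 2 / np.sqrt(3))))
    base, extra = divmod(n, n_rows)
    rows = tuple(base + (1 if j < extra else 0) for j in range(n_rows))
    return tuple(r for r in rows if r > 0)


def build_site_lattice(N_S_total: int, spec: SystemSpec) -> SiteLattice:
    """Triangular site patch centred in the box, exact 3.5 nm spacing.

    Raises if the patch cannot keep its nearest-neighbour spacing inside the
    box, or if periodic images would approach closely enough to make the
    bound-state assignment ambiguous.  Image gaps below the lattice constant
    are physically inert (sites are mutually non-interacting) and only warn.
    """
    if N_S_total < 1:
        raise ValueError("N_S_total must be >= 1")
    d = spec.nn_distance
    rows = _row_layout(N_S_total)
    dy = d * np.sqrt(3.0) / 2.0
    xs, ys = [], []
    for j, count in enumerate(rows):
        x0 = (j % 2) * d / 2.0
        for i in range(count):
            xs.append(x0 + i * d)
            ys.append(j * dy)
    xy = np.column_stack([xs, ys])
    xy -= (xy.min(axis=0) + xy.max(axis=0)) / 2.0  # centre patch at origin
    xy += np.array([spec.L_x / 2.0, spec.L_y / 2.0])

    extent = xy.max(axis=0) - xy.min(axis=0)
    if extent[0] >= spec.L_x or extent[1] >= spec.L_y:
        raise ValueError(
            f"site lattice for N_S={N_S_total} (extent {extent}) does not fit "
            f"in box {spec.L_x} x {spec.L_y} nm"
        )
    if N_S_total > 1:
        dmin = _min_site_distance(xy, spec.L_x, spec.L_y)
        if dmin < d - 1e-9:
            limit = 2.0 * spec.bound_cutoff + 0.5
            if dmin < limit:
                raise ValueError(
                    f"periodic site images approach to {dmin:.3f} nm "
                    f"(< {limit:.2f} nm); bound-state assignment is ambiguous"
                )
            warnings.warn(
                f"site images across the periodic boundary are {dmin:.2f} nm "
                f"apart (< lattice constant {d} nm); harmless for "
                "non-interacting sites",
                stacklevel=2,
            )

    s = np.column_stack([xy, np.full(len(xy), spec.z_s)])
    h = np.column_stack([xy, np.full(len(xy), spec.z_h)])
    return SiteLattice(s_xyz=s, h_xyz=h)


def _min_site_distance(xy: np.ndarray, lx: float, ly: float) -> float:
    """Minimum pairwise in-plane distance under the periodic minimum image."""
    dx = xy[:, None, 0] - xy[None, :, 0]
    dy = xy[:, None, 1] - xy[None, :, 1]
    dx -= lx * np.round(dx / lx)
    dy -= ly * np.round(dy / ly)
    dist = np.sqrt(dx**2 + dy**2)
    dist[np.diag_indices_from(dist)] = np.inf
    return float(dist.min())


def box_for_series(series: str, N_A_total: int, N_S_total: int) -> tuple[float, float, float]:
    """Box lengths (L_x, L_y, L_z) for a preset series, L_z fixed at 5 nm.

    R1 and R4 keep c_A_total = 0.008 nm^-3; R2 and R3 keep the most abundant
    species at 0.015 nm^-3.  L_x = L_y = sqrt(V / L_z).
    """
    series = series.upper()
    if series not in SERIES_CONC:
        raise ValueError(f"unknown series {series!r}; expected R1-R4")
    if N_A_total < 1 or N_S_total < 1:
        raise ValueError("series boxes require at least one particle of each species")
    c = SERIES_CONC[series]
    n_target = N_A_total if series in ("R1", "R4") else max(N_A_total, N_S_total)
    V = n_target / c
    L = float(np.sqrt(V / 5.0))
    return (L, L, 5.0)


def random_insert_adsorbates(
    N_A_total: int,
    lattice: SiteLattice,
    spec: SystemSpec,
    rng: np.random.Generator,
    overlap_energy: float = 100.0,
    max_retries: int = 1000,
) -> AdsorbateConfiguration:
    """Insert adsorbates uniformly at random with random orientations.

    A candidate whose interaction energy with the already-placed system
    exceeds ``overlap_energy`` (kJ/mol) is resampled, preventing pathological
    initial energies; the threshold is irrelevant after equilibration.
    """
    from .mc_engine import molecule_energy_brute  # local import, avoids cycle

    box = np.array([spec.L_x, spec.L_y, spec.L_z])
    a_list: list[np.ndarray] = []
    u_list: list[np.ndarray] = []
    for _ in range(N_A_total):
        for _attempt in range(max_retries):
            a = rng.random(3) * box
            u = _random_unit_vector(rng)
            cfg = AdsorbateConfiguration(
                a_xyz=np.array(a_list + [a]),
                u=np.array(u_list + [u]),
                bond_length=spec.bond_length,
            )
            e = molecule_energy_brute(cfg, lattice, cfg.n_molecules - 1, spec)
            if e <= overlap_energy:
                a_list.append(a)
                u_list.append(u)
                break
        else:
            raise RuntimeError(
                f"could not place molecule {len(a_list)} below "
                f"{overlap_energy} kJ/mol after {max_retries} retries"
            )
    if N_A_total == 0:
        return AdsorbateConfiguration(
            a_xyz=np.empty((0, 3)), u=np.empty((0, 3)), bond_length=spec.bond_length
        )
    return AdsorbateConfiguration(
        a_xyz=np.array(a_list), u=np.array(u_list), bond_length=spec.bond_length
    )


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the sphere (uniform cos(theta), uniform phi)."""
    ct = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    st = np.sqrt(1.0 - ct * ct)
    return np.array([st * np.cos(phi), st * np.sin(phi), ct])


def spec_for_series(
    series: str,
    N_A_total: int,
    N_S_total: int,
    seed: int = 0,
    epsilon_sa: float | None = None,
    **overrides,
) -> SystemSpec:
    """Convenience constructor: series box + defaults + optional overrides."""
    lx, ly, lz = box_for_series(series, N_A_total, N_S_total)
    spec = SystemSpec(
        N_A_total=N_A_total,
        N_S_total=N_S_total,
        L_x=lx,
        L_y=ly,
        L_z=lz,
        seed=seed,
        epsilon_sa_override=epsilon_sa,
        **overrides,
    )
    return validate_spec(spec)


def write_xyz(
    path,
    lattice: SiteLattice,
    config: AdsorbateConfiguration | None = None,
    comment: str = "",
    angstrom: bool = False,
) -> None:
    """Export lattice (+ optional adsorbates) as an XYZ file.

    Coordinates are written in nm by default, or in Angstrom with
    ``angstrom=True`` (flagged in the comment line).
    """
    scale = 10.0 if angstrom else 1.0
    unit = "angstrom" if angstrom else "nm"
    lines = []
    atoms: list[tuple[str, np.ndarray]] = []
    for p in lattice.s_xyz:
        atoms.append(("s", p))
    for p in lattice.h_xyz:
        atoms.append(("h", p))
    if config is not None:
        for p in config.a_xyz:
            atoms.append(("a", p))
        for p in config.h_xyz:
            atoms.append(("h", p))
    lines.append(str(len(atoms)))
    lines.append(f"{comment} units={unit}".strip())
    for name, p in atoms:
        x, y, z = p * scale
        lines.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
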