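"""Domain types, physical constants and configuration schema.

Units are fixed globally: lengths in nm, energies in kJ/mol, temperature in K.
Concentrations are number densities in nm^-3; molar values are derived through
the standard concentration ``C_STD`` (1 mol/L).  The Boltzmann constant is
expressed in kJ mol^-1 K^-1, so Lennard-Jones well depths are per-mole
quantities and the Metropolis criterion uses exp(-dU/(R*T)).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

import yaml

#: Boltzmann constant, kJ mol^-1 K^-1 (energies are per mole of particles).
K_B = 0.0083145
#: Gas constant, kJ mol^-1 K^-1 (numerically identical to K_B in these units).
R_GAS = 0.0083145
#: Standard (reference) concentration c-standard = 1 mol/L as a number density, nm^-3.
C_STD = 0.602214

#: Avogadro-based conversion: 1 mol/L expressed in molecules nm^-3.
_NM3_PER_MOLAR = 0.602214


def molar_to_nm3(c_molar: float) -> float:
    """Convert a molar concentration (mol/L) to a number density (nm^-3)."""
    return c_molar * _NM3_PER_MOLAR


def nm3_to_molar(c_nm3: float) -> float:
    """Convert a number density (nm^-3) to a molar concentration (mol/L)."""
    return c_nm3 / _NM3_PER_MOLAR


def concentration(N: int, V: float) -> float:
    """Number density N/V in nm^-3 for N particles in a volume V (nm^3).

    The molar value follows as ``nm3_to_molar(concentration(N, V))``.
    """
    if V <= 0:
        raise ValueError(f"volume must be positive, got V={V}")
    if N < 0:
        raise ValueError(f"particle count must be non-negative, got N={N}")
    return N / V


# Atom types: 'a' (adsorbate binding atom), 'h' (protecting/head atom, present
# on both the adsorbate molecule and the site), 's' (surface binding atom).
PairKey = Tuple[str, str]


def _pair(a: str, b: str) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class LJTable:
    """Lennard-Jones parameter table over unordered atom-type pairs.

    The default table carries exactly the five interacting pairs of the model:
    all pairs are mildly repulsive (eps = 0.1 kJ/mol) except the deep s-a
    attraction that produces adsorption.  s-s pairs never interact: adsorbing
    sites are immobile and mutually inert.
    """

    pairs: Dict[PairKey, Tuple[float, float]] = field(
        default_factory=lambda: {
            _pair("a", "a"): (0.75, 0.1),
            _pair("h", "h"): (0.50, 0.1),
            _pair("s", "h"): (0.35, 0.1),
            _pair("a", "h"): (0.35, 0.1),
            _pair("s", "a"): (0.18, 35.0),
        }
    )
    r_cut: float = 2.0  # nm, truncation distance (truncated, not shifted)

    def sigma_eps(self, a: str, b: str) -> Tuple[float, float]:
        return self.pairs[_pair(a, b)]

    def with_eps_sa(self, eps_sa: float) -> "LJTable":
        """Copy of the table with the s-a well depth replaced (R4 series)."""
        pairs = dict(self.pairs)
        sigma, _ = pairs[_pair("s", "a")]
        pairs[_pair("s", "a")] = (sigma, eps_sa)
        return LJTable(pairs=pairs, r_cut=self.r_cut)

    def validate(self) -> None:
        for (a, b), (sigma, eps) in self.pairs.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be positive for pair {a}-{b}")
            if eps <= 0:
                raise ValueError(f"epsilon must be positive for pair {a}-{b}")
        if self.r_cut <= max(s for s, _ in self.pairs.values()):
            raise ValueError("r_cut must exceed the largest sigma")


@dataclass
class SystemSpec:
    """Full parameterization of one canonical-ensemble simulation.

    Defaults are the model's reference values: rigid a-h bond of 0.14 nm,
    site plane at z = 2.50 nm with protecting atoms at 2.64 nm, triangular
    site lattice with 3.5 nm nearest-neighbour spacing, binding cutoff
    r_sa < 0.37 nm, and the standard trial-move maxima (0.4 nm per axis,
    0.1 in cos(theta), 0.314 rad in phi).
    """

    N_A_total: int
    N_S_total: int
    L_x: float
    L_y: float
    L_z: float = 5.0
    T: float = 300.0
    lj: LJTable = field(default_factory=LJTable)
    epsilon_sa_override: float | None = None
    bond_length: float = 0.14
    z_s: float = 2.50
    z_h: float = 2.64
    nn_distance: float = 3.5
    bound_cutoff: float = 0.37
    move_max_displacement: float = 0.4
    move_max_dcos_theta: float = 0.1
    move_max_dphi: float = 0.314
    n_equilibration: int = 1_000_000
    n_production: int = 10_000_000
    sample_interval: int = 50
    seed: int = 0

    @property
    def volume(self) -> float:
        return self.L_x * self.L_y * self.L_z

    def effective_lj(self) -> LJTable:
        """LJ table with any s-a override applied."""
        if self.epsilon_sa_override is None:
            return self.lj
        return self.lj.with_eps_sa(self.epsilon_sa_override)


def validate_spec(spec: SystemSpec) -> SystemSpec:
    """Validate a SystemSpec, raising a ValueError naming the offending field."""
    if spec.N_A_total < 0:
        raise ValueError(f"N_A_total must be >= 0, got {spec.N_A_total}")
    if spec.N_S_total < 0:
        raise ValueError(f"N_S_total must be >= 0, got {spec.N_S_total}")
    for name in ("L_x", "L_y", "L_z", "bond_length", "nn_distance", "bound_cutoff"):
        value = getattr(spec, name)
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
    if spec.T <= 0:
        raise ValueError(f"T must be positive, got {spec.T}")
    if spec.bound_cutoff >= spec.nn_distance / 2:
        raise ValueError(
            "bound_cutoff must be smaller than nn_distance/2 so that a bound "
            f"adsorbate is unambiguously assigned to one site "
            f"(bound_cutoff={spec.bound_cutoff}, nn_distance={spec.nn_distance})"
        )
    if not (0 < spec.z_s < spec.L_z and 0 < spec.z_h < spec.L_z):
        raise ValueError("z_s and z_h must lie inside the box along z")
    if spec.epsilon_sa_override is not None and spec.epsilon_sa_override <= 0:
        raise ValueError("epsilon_sa_override must be positive")
    for name in ("move_max_displacement", "move_max_dcos_theta", "move_max_dphi"):
        if getattr(spec, name) <= 0:
            raise ValueError(f"{name} must be positive")
    if spec.move_max_dcos_theta > 1.0:
        raise ValueError("move_max_dcos_theta must be <= 1")
    for name in ("n_equilibration", "n_production"):
        if getattr(spec, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    if spec.sample_interval < 1:
        raise ValueError("sample_interval must be >= 1")
    spec.lj.validate()
    return spec


# ---------------------------------------------------------------------------
# YAML (de)serialization — one file per simulation, lossless round trip.

def spec_to_dict(spec: SystemSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["lj"] = {
        "r_cut": spec.lj.r_cut,
        "pairs": {f"{a}{b}": list(v) for (a, b), v in spec.lj.pairs.items()},
    }
    return d


def spec_from_dict(d: dict) -> SystemSpec:
    d = dict(d)
    lj_d = d.pop("lj", None)
    if lj_d is not None:
        pairs = {
            _pair(k[0], k[1]): (float(v[0]), float(v[1]))
            for k, v in lj_d["pairs"].items()
        }
        lj = LJTable(pairs=pairs, r_cut=float(lj_d.get("r_cut", 2.0)))
    else:
        lj = LJTable()
    return SystemSpec(lj=lj, **d)


def save_spec(spec: SystemSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> SystemSpec:
    with open(path) as fh:
        return validate_spec(spec_from_dict(yaml.safe_load(fh)))
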