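"""Preset simulation series.

R1: N_A_total = N_S_total in {1,...,120} at c_A_total = 0.008 nm^-3.
R2: N_S_total = 4 fixed, N_A_total varied, most abundant species at 0.015 nm^-3.
R3: N_A_total = 4 fixed, N_S_total varied, most abundant species at 0.015 nm^-3.
R4: N_A_total = N_S_total = 2 at 0.008 nm^-3, s-a well depth 15..50 kJ/mol in
    steps of 5.

The reference sampling schedule used 5e9 equilibration moves and 1.2e10-1e12
production moves per system; the preset default is a desk-scale schedule
(1e6 equilibration, 1e7 production) tunable through the ``scale`` factor,
with production moves inversely proportional-ish to system size left to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import SystemSpec
from .system_builder import spec_for_series

R1_COUNTS = (1, 2, 3, 4, 5, 6, 8, 10, 14, 30, 68, 120)
R2_NA_VALUES = (1, 2, 3, 4, 5, 6, 8, 10, 14, 30, 68, 120)
R3_NS_VALUES = (1, 2, 3, 4, 5, 6, 8, 10, 14, 30, 68, 120)
R4_EPS_VALUES = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)

_DESK_EQUIL = 1_000_000
_DESK_PROD = 10_000_000


@dataclass
class SeriesPreset:
    series: str
    specs: list[SystemSpec]

    def __iter__(self):
        return iter(self.specs)

    def __len__(self):
        return len(self.specs)


def _sched(scale: float) -> dict:
    return {
        "n_equilibration": max(int(_DESK_EQUIL * scale), 1000),
        "n_production": max(int(_DESK_PROD * scale), 1000),
    }


def build_preset(series: str, seed: int = 0, scale: float = 1.0) -> SeriesPreset:
    """Expand a series id into a list of validated SystemSpecs."""
    series = series.upper()
    specs: list[SystemSpec] = []
    if series == "R1":
        for j, n in enumerate(R1_COUNTS):
            specs.append(spec_for_series("R1", n, n, seed=seed + j, **_sched(scale)))
    elif series == "R2":
        for j, n_a in enumerate(R2_NA_VALUES):
            specs.append(spec_for_series("R2", n_a, 4, seed=seed + j, **_sched(scale)))
    elif series == "R3":
        for j, n_s in enumerate(R3_NS_VALUES):
            specs.append(spec_for_series("R3", 4, n_s, seed=seed + j, **_sched(scale)))
    elif series == "R4":
        for j, eps in enumerate(R4_EPS_VALUES):
            specs.append(
                spec_for_series(
                    "R4", 2, 2, seed=seed + j, epsilon_sa=eps, **_sched(scale)
                )
            )
    else:
        raise ValueError(f"unknown preset series {series!r}; expected r1/r2/r3/r4")
    return SeriesPreset(series=series, specs=specs)
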