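"""Reference parameter sets for the three studied permeation cases.

Each case is a three-layer Franz-cell configuration (donor chamber | skin |
receptor chamber) with the estimated skin diffusivity, partition
coefficients P1 (donor/skin) and P2 (skin/receptor), mass-transfer
coefficients K1 and K2, a 5 mg/mL donor load, and the experiment horizon.
"""
from __future__ import annotations

from dataclasses import dataclass

from .specs import CellGeometry, InterfaceSpec, LayerSpec, Orientation

__all__ = [
    "CaseConfig",
    "CASE_IDS",
    "make_case_config",
    "CHAMBER_DIFFUSIVITY",
    "DONOR_CONCENTRATION",
    "SC_DEPTH_BOUNDS_CM",
]

#: diffusivity assigned to the stirred chambers so their profiles stay flat
#: (three to four orders of magnitude above the skin diffusivities), cm^2/h
CHAMBER_DIFFUSIVITY = 10.0

#: donor loading concentration, mg/cm^3
DONOR_CONCENTRATION = 5.0

#: total depth stripped by 70 tape strips under the thin (0.5 um) and thick
#: (1.0 um) per-strip assumptions, cm
SC_DEPTH_BOUNDS_CM = (0.0035, 0.0070)

_CASES: dict[str, dict[str, float]] = {
    # diclofenac sodium, room temperature
    "diclofenac_RT": dict(
        skin_thickness=0.07, diffusivity=1.2e-3,
        P1=8.0, P2=25.0, K1=0.08, K2=0.04, end_time=47.0,
    ),
    # diclofenac sodium, 32 C
    "diclofenac_32C": dict(
        skin_thickness=0.1, diffusivity=1.8e-3,
        P1=5.0, P2=10.0, K1=0.12, K2=0.10, end_time=51.5,
    ),
    # caffeine, 32 C
    "caffeine_32C": dict(
        skin_thickness=0.1, diffusivity=5.0e-3,
        P1=8.0, P2=23.0, K1=0.11, K2=0.08, end_time=53.0,
    ),
}

CASE_IDS = tuple(_CASES)


@dataclass(frozen=True)
class CaseConfig:
    """A complete forward-model configuration for one study case."""

    name: str
    layers: tuple[LayerSpec, LayerSpec, LayerSpec]
    interfaces: tuple[InterfaceSpec, InterfaceSpec]
    geometry: CellGeometry
    end_time: float

    @property
    def truth(self) -> dict[str, float]:
        """Ground-truth parameter dictionary (D, P1, P2, K1, K2)."""
        return {
            "D": self.layers[1].diffusivity,
            "P1": self.interfaces[0].partition,
            "P2": self.interfaces[1].partition,
            "K1": self.interfaces[0].mass_transfer,
            "K2": self.interfaces[1].mass_transfer,
        }


def make_case_config(
    case_id: str,
    *,
    chamber_diffusivity: float = CHAMBER_DIFFUSIVITY,
    donor_concentration: float = DONOR_CONCENTRATION,
    geometry: CellGeometry | None = None,
) -> CaseConfig:
    """Return the published parameter set for one of the three cases.

    Parameters
    ----------
    case_id:
        One of ``"diclofenac_RT"``, ``"diclofenac_32C"``, ``"caffeine_32C"``.
    chamber_diffusivity:
        Diffusivity of the donor and receptor layers (large, so they behave
        as well-stirred compartments).
    donor_concentration:
        Initial donor concentration in mg/cm^3.
    geometry:
        Franz-cell geometry; the standard cell by default.
    """
    try:
        p = _CASES[case_id]
    except KeyError:
        raise ValueError(
            f"unknown case_id {case_id!r}; expected one of {CASE_IDS}"
        ) from None
    geom = geometry if geometry is not None else CellGeometry()
    layers = (
        LayerSpec("donor", geom.donor_thickness, chamber_diffusivity,
                  donor_concentration),
        LayerSpec("skin", p["skin_thickness"], p["diffusivity"], 0.0),
        LayerSpec("receptor", geom.receptor_thickness, chamber_diffusivity,
                  0.0),
    )
    interfaces = (
        InterfaceSpec(p["P1"], p["K1"], Orientation.SKIN_DOWNSTREAM),
        InterfaceSpec(p["P2"], p["K2"], Orientation.SKIN_UPSTREAM),
    )
    return CaseConfig(case_id, layers, interfaces, geom, p["end_time"])
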