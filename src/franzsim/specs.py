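"""Parameter containers for the three-layer Franz-cell diffusion model.

Units are fixed throughout the package: lengths in cm, times in hours,
concentrations in mg/cm^3 (equivalently mg/mL), diffusivities in cm^2/h,
mass-transfer coefficients in cm/h, amounts in mg.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Orientation",
    "LayerSpec",
    "InterfaceSpec",
    "CellGeometry",
    "Discretization",
    "ExperimentProtocol",
    "MICRON_CM",
]

#: one micrometre in centimetres
MICRON_CM = 1e-4


class Orientation(str, Enum):
    """Which side of an interlayer boundary is the skin (partitioning) phase.

    The partition coefficient P is always reported as the equilibrium ratio
    C_skin / C_fluid across the boundary.  ``SKIN_DOWNSTREAM`` means the skin
    is the layer with the larger x coordinate (e.g. the donor/skin boundary,
    with the donor on top); ``SKIN_UPSTREAM`` means the skin comes first
    (e.g. the skin/receptor boundary).
    """

    SKIN_DOWNSTREAM = "skin_downstream"
    SKIN_UPSTREAM = "skin_upstream"


@dataclass(frozen=True)
class LayerSpec:
    """One diffusion layer of the 1-D multilayer domain.

    Parameters
    ----------
    name:
        Text label ("donor", "skin", "receptor", ...).
    thickness:
        Layer thickness in cm (> 0).  For the well-stirred chambers this is
        the effective thickness volume / exposure area.
    diffusivity:
        Fickian diffusion coefficient in cm^2/h (> 0).
    initial_concentration:
        Uniform initial concentration in mg/cm^3 (>= 0).
    """

    name: str
    thickness: float
    diffusivity: float
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if not self.diffusivity > 0:
            raise ValueError(f"layer {self.name!r}: diffusivity must be > 0")
        if self.initial_concentration < 0:
            raise ValueError(
                f"layer {self.name!r}: initial_concentration must be >= 0"
            )


@dataclass(frozen=True)
class InterfaceSpec:
    """Partition / mass-transfer condition at one interlayer boundary.

    The interfacial flux law (positive flux in the +x direction, from the
    upstream layer i into the downstream layer i+1) is

        J = K * (C_i - rho * C_{i+1})

    where ``rho`` is the equilibrium ratio C_i / C_{i+1}.  The partition
    coefficient ``partition`` is reported the way the field reports it: as
    the skin-to-fluid concentration ratio at equilibrium, so

        rho = 1 / partition   if the skin is downstream (fluid on top),
        rho = partition       if the skin is upstream  (fluid below).

    Either way the concentration in the skin settles at ``partition`` times
    the adjacent fluid concentration once the flux vanishes.  ``mass_transfer``
    (cm/h) sets how quickly that interfacial equilibrium is approached; K = 0
    is an impermeable barrier.
    """

    partition: float
    mass_transfer: float
    orientation: Orientation = Orientation.SKIN_DOWNSTREAM

    def __post_init__(self) -> None:
        if not self.partition > 0:
            raise ValueError("partition must be > 0")
        if self.mass_transfer < 0:
            raise ValueError("mass_transfer must be >= 0")
        object.__setattr__(self, "orientation", Orientation(self.orientation))

    @property
    def upstream_ratio(self) -> float:
        """Equilibrium ratio C_upstream / C_downstream implied by the law."""
        if self.orientation is Orientation.SKIN_DOWNSTREAM:
            return 1.0 / self.partition
        return self.partition

    def flux(self, c_up: float, c_down: float) -> float:
        """Interfacial flux J in mg/(cm^2 h), positive toward +x."""
        return self.mass_transfer * (c_up - self.upstream_ratio * c_down)


@dataclass(frozen=True)
class CellGeometry:
    """Franz-cell geometry: orifice area and chamber volumes.

    Defaults are the unjacketed cell used throughout: 0.636 cm^2 exposure,
    1 mL donor and 12 mL receptor chamber.
    """

    exposure_area: float = 0.636  # cm^2
    donor_volume: float = 1.0  # cm^3
    receptor_volume: float = 12.0  # cm^3

    def __post_init__(self) -> None:
        for name in ("exposure_area", "donor_volume", "receptor_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def donor_thickness(self) -> float:
        """Effective donor layer thickness (volume / area), cm."""
        return self.donor_volume / self.exposure_area

    @property
    def receptor_thickness(self) -> float:
        """Effective receptor layer thickness (volume / area), cm."""
        return self.receptor_volume / self.exposure_area


@dataclass(frozen=True)
class Discretization:
    """Spatial/temporal resolution of the finite-element solver.

    ``nodes_per_layer`` is either a single integer applied to every layer or
    one integer per layer (>= 3 each); ``time_step`` is the implicit-Euler
    step in hours.
    """

    nodes_per_layer: int | tuple[int, ...] = (50, 200, 50)
    time_step: float = 0.01

    def __post_init__(self) -> None:
        npl = self.nodes_per_layer
        if isinstance(npl, Sequence) and not isinstance(npl, (str, bytes)):
            npl = tuple(int(n) for n in npl)
            object.__setattr__(self, "nodes_per_layer", npl)
            counts = npl
        else:
            counts = (int(npl),)
        if any(n < 3 for n in counts):
            raise ValueError("nodes_per_layer must be >= 3 for every layer")
        if not self.time_step > 0:
            raise ValueError("time_step must be > 0")

    def nodes_for(self, n_layers: int) -> tuple[int, ...]:
        """Per-layer node counts for a domain with ``n_layers`` layers."""
        npl = self.nodes_per_layer
        if isinstance(npl, tuple):
            if len(npl) != n_layers:
                raise ValueError(
                    f"nodes_per_layer has {len(npl)} entries for "
                    f"{n_layers} layers"
                )
            return npl
        return (int(npl),) * n_layers


#: receptor sampling schedule of the in-vitro protocol, hours
DEFAULT_SAMPLING_TIMES: tuple[float, ...] = (
    1, 2, 3, 4.5, 6, 8, 10, 12, 23, 26, 29, 32, 35, 48,
)


@dataclass(frozen=True)
class ExperimentProtocol:
    """Sampling protocol and noise model for (synthetic) experiments.

    Mirrors the laboratory procedure: receptor fluid sampled at the listed
    times (200 uL withdrawn and replaced with fresh buffer), four replicate
    cells, and 70 sequential tape strips (0.5-1 um each, two strips per
    microtube) taken at the end of the run.
    """

    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    sample_volume: float = 0.2  # cm^3 withdrawn and replaced
    replicates: int = 4
    noise_cv: float = 0.05
    seed: int = 0
    strip_thickness_um: float = 0.75  # nominal per-strip thickness, um
    strip_thickness_bounds_um: tuple[float, float] = (0.5, 1.0)
    n_strips: int = 70
    strips_per_tube: int = 2
    model_sampling: bool = False

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sampling_times)
        object.__setattr__(self, "sampling_times", times)
        arr = np.asarray(times)
        if arr.size == 0 or np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
            raise ValueError("sampling_times must be strictly increasing and > 0")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must satisfy 0 <= cv < 1")
        if self.sample_volume < 0:
            raise ValueError("sample_volume must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        lo, hi = self.strip_thickness_bounds_um
        if not (0 < lo <= hi):
            raise ValueError("strip_thickness_bounds_um must be 0 < lo <= hi")
        if not lo <= self.strip_thickness_um <= hi:
            raise ValueError("strip_thickness_um must lie within its bounds")
        if self.n_strips % self.strips_per_tube:
            raise ValueError("n_strips must be a multiple of strips_per_tube")

    @property
    def n_tubes(self) -> int:
        return self.n_strips // self.strips_per_tube

    @property
    def strip_thickness_cm(self) -> float:
        return self.strip_thickness_um * MICRON_CM
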