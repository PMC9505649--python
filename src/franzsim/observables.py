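"""Derived quantities: release curves, layer amounts and stratum-corneum
depth-window amounts.

All amounts are in mg, concentrations in mg/cm^3, depths in cm measured
into the skin from its donor-facing surface (the surface tape strips remove
first).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cases import SC_DEPTH_BOUNDS_CM
from .model import SimulationResult
from .specs import CellGeometry

__all__ = [
    "ReleaseCurve",
    "release_curve",
    "layer_mean_concentration",
    "depth_window_amount",
    "sc_window_estimate",
    "layer_amounts",
]


@dataclass(frozen=True)
class ReleaseCurve:
    """Receptor-chamber concentration versus time.

    ``concentration`` is the mean over replicates when ``replicates`` (a
    (n_replicates, n_times) array) is present.
    """

    times: np.ndarray
    concentration: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and concentration must be 1-D and aligned")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentration", c)


def layer_mean_concentration(result: SimulationResult,
                             layer: int | str) -> np.ndarray:
    """Volume-averaged concentration of one layer at every output time."""
    i = result.layer_number(layer)
    sl = result.grid.layer_slices[i]
    xs = result.positions[sl]
    return np.trapezoid(result.concentrations[:, sl], xs, axis=1) / (
        xs[-1] - xs[0]
    )


def release_curve(result: SimulationResult,
                  layer: int | str = "receptor") -> ReleaseCurve:
    """Receptor-layer mean concentration at the recorded output times."""
    return ReleaseCurve(result.times,
                        layer_mean_concentration(result, layer))


def _skin_layer(result: SimulationResult) -> int:
    if "skin" in result.layer_names:
        return result.layer_names.index("skin")
    return 1  # middle layer of the standard three-layer cell


def depth_window_amount(
    result: SimulationResult,
    t: float,
    depth: float,
    area: float | None = None,
    *,
    layer: int | str | None = None,
) -> float:
    """Drug amount (mg) in the skin between the surface and ``depth``.

    Trapezoidal integral of the skin concentration profile from the
    donor-facing surface down to ``depth``, times the exposure area; this
    is the amount a stack of tape strips of that total thickness removes.
    Sub-node depths are handled by linear interpolation, which is exact for
    the piecewise-linear FEM field.
    """
    i = result.layer_number(layer) if layer is not None else _skin_layer(result)
    xs, cs = result.layer_field(i, t)
    x_rel = xs - xs[0]
    if not 0 <= depth <= x_rel[-1] * (1 + 1e-12):
        raise ValueError(
            f"depth {depth} cm outside the skin layer (0..{x_rel[-1]:.4g} cm)"
        )
    if area is None:
        if result.geometry is None:
            raise ValueError("no area given and result has no geometry")
        area = result.geometry.exposure_area
    depth = min(depth, x_rel[-1])
    if depth == 0:
        return 0.0
    inside = x_rel < depth
    grid_x = np.concatenate([x_rel[inside], [depth]])
    grid_c = np.concatenate([cs[inside], [np.interp(depth, x_rel, cs)]])
    return float(area * np.trapezoid(grid_c, grid_x))


def sc_window_estimate(
    result: SimulationResult,
    t: float,
    area: float | None = None,
    depth_bounds: tuple[float, float] = SC_DEPTH_BOUNDS_CM,
) -> float:
    """Model estimate (mg) of the drug removed by the 70-strip protocol.

    The 70 strips remove 0.0035 cm (all strips 0.5 um) to 0.0070 cm (all
    1 um); the estimate is the mean of the depth-window amounts at those
    two bounds.
    """
    lo, hi = depth_bounds
    return 0.5 * (
        depth_window_amount(result, t, lo, area)
        + depth_window_amount(result, t, hi, area)
    )


def layer_amounts(
    result: SimulationResult,
    t: float,
    geometry: CellGeometry | None = None,
) -> np.ndarray:
    """Drug amount (mg) in each layer at time ``t``; sums to total mass."""
    geom = geometry if geometry is not None else result.geometry
    area = geom.exposure_area if geom is not None else 1.0
    field = result.field_at(t)
    return np.array([
        area * np.trapezoid(field[sl], result.positions[sl])
        for sl in result.grid.layer_slices
    ])
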