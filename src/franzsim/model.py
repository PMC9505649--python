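"""Finite-element solver for multilayer Fickian diffusion with
partition/mass-transfer interface conditions.

Within each layer the concentration obeys Fick's second law,
dC/dt = d/dx (D dC/dx).  At every interlayer boundary the concentration is
allowed to jump; the two sides exchange mass through the interfacial flux
law J = K (C_up - rho C_down) (see :class:`franzsim.specs.InterfaceSpec`),
which also equals -D dC/dx on either side.  The outer boundaries carry zero
flux (sealed cell).

Space is discretised with linear finite elements on a per-layer uniform
grid, with a doubled node at every interface so the jump is representable;
time integration is implicit Euler.  The semi-discrete system
M dc/dt = A c conserves total mass exactly (columns of A sum to zero), and
implicit Euler preserves that identity step by step, so any drift measured
by :func:`mass_balance` is pure linear-algebra round-off.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .specs import CellGeometry, Discretization, InterfaceSpec, LayerSpec

__all__ = [
    "Grid",
    "SimulationResult",
    "build_grid",
    "assemble_system",
    "simulate",
    "simulate_case",
    "interface_flux",
    "mass_balance",
    "equilibrium_state",
    "compartment_oracle",
]

# the consistent-mass FEM scheme can undershoot slightly on coarse grids
# (time steps below a layer's critical h^2/6D); undershoots within this
# relative tolerance are clipped to zero, anything worse raises
_NEGATIVE_TOL = 1e-6


@dataclass(frozen=True)
class Grid:
    """Node layout of the multilayer domain.

    ``positions`` is strictly nondecreasing with exactly one duplicated
    value per interface (the upstream and downstream trace of the jump);
    ``layer_index`` maps each node to its layer; ``interface_nodes`` holds
    the (upstream node, downstream node) pair of every interface.
    """

    positions: np.ndarray
    layer_index: np.ndarray
    layer_slices: tuple[slice, ...]
    interface_nodes: tuple[tuple[int, int], ...]

    @property
    def n_nodes(self) -> int:
        return self.positions.size

    @property
    def n_layers(self) -> int:
        return len(self.layer_slices)


def build_grid(
    layers: Sequence[LayerSpec], discretization: Discretization
) -> Grid:
    """Lay out per-layer uniform nodes with doubled interface nodes."""
    if len(layers) < 1:
        raise ValueError("at least one layer is required")
    counts = discretization.nodes_for(len(layers))
    positions: list[np.ndarray] = []
    layer_index: list[np.ndarray] = []
    slices: list[slice] = []
    interface_nodes: list[tuple[int, int]] = []
    x0 = 0.0
    offset = 0
    for i, (layer, n) in enumerate(zip(layers, counts)):
        xs = x0 + np.linspace(0.0, layer.thickness, n)
        positions.append(xs)
        layer_index.append(np.full(n, i))
        slices.append(slice(offset, offset + n))
        if i > 0:
            interface_nodes.append((offset - 1, offset))
        offset += n
        x0 += layer.thickness
    return Grid(
        positions=np.concatenate(positions),
        layer_index=np.concatenate(layer_index),
        layer_slices=tuple(slices),
        interface_nodes=tuple(interface_nodes),
    )


def assemble_system(
    grid: Grid,
    layers: Sequence[LayerSpec],
    interfaces: Sequence[InterfaceSpec],
) -> tuple[sp.csc_matrix, sp.csc_matrix]:
    """Assemble the consistent mass matrix M and system matrix A.

    The semi-discrete problem is M dc/dt = A c with A = -S + E, where S is
    the per-layer stiffness matrix and E couples the doubled interface
    nodes through the flux law.  Both matrices are tridiagonal in the
    sequential node numbering.
    """
    if len(interfaces) != len(grid.interface_nodes):
        raise ValueError(
            f"{len(grid.interface_nodes)} interfaces in grid but "
            f"{len(interfaces)} InterfaceSpec(s) given"
        )
    n = grid.n_nodes
    main_m = np.zeros(n)
    off_m = np.zeros(n - 1)
    main_a = np.zeros(n)
    off_lo = np.zeros(n - 1)  # A[i+1, i]
    off_hi = np.zeros(n - 1)  # A[i, i+1]
    for layer, sl in zip(layers, grid.layer_slices):
        i0, i1 = sl.start, sl.stop
        h = np.diff(grid.positions[i0:i1])
        # consistent mass matrix, element h/6 [[2,1],[1,2]]
        main_m[i0:i1 - 1] += h / 3.0
        main_m[i0 + 1:i1] += h / 3.0
        off_m[i0:i1 - 1] += h / 6.0
        # stiffness, element D/h [[1,-1],[-1,1]]; A -= S
        w = layer.diffusivity / h
        main_a[i0:i1 - 1] -= w
        main_a[i0 + 1:i1] -= w
        off_lo[i0:i1 - 1] += w
        off_hi[i0:i1 - 1] += w
    for itf, (a, b) in zip(interfaces, grid.interface_nodes):
        k = itf.mass_transfer
        rho = itf.upstream_ratio
        # node a loses J, node b gains J; J = k (c_a - rho c_b)
        main_a[a] -= k
        off_hi[a] += k * rho  # A[a, b]
        off_lo[a] += k  # A[b, a]
        main_a[b] -= k * rho
    mass = sp.diags([off_m, main_m, off_m], [-1, 0, 1], format="csc")
    amat = sp.diags([off_lo, main_a, off_hi], [-1, 0, 1], format="csc")
    return mass, amat


@dataclass
class SimulationResult:
    """Concentration field C(x, t) of one forward simulation.

    ``concentrations`` has shape (n_times, n_nodes); ``times`` always starts
    at 0 with the initial field in the first row.  Interface jumps live on
    the duplicated grid nodes.
    """

    grid: Grid
    times: np.ndarray
    concentrations: np.ndarray
    layers: tuple[LayerSpec, ...]
    interfaces: tuple[InterfaceSpec, ...]
    geometry: CellGeometry | None = None

    @property
    def positions(self) -> np.ndarray:
        return self.grid.positions

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(layer.name for layer in self.layers)

    def time_index(self, t: float, *, rtol: float = 1e-9, atol: float = 1e-9) -> int:
        """Index of output time ``t`` (must be one of ``times``)."""
        idx = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[idx], t, rtol=rtol, atol=atol):
            raise ValueError(f"t={t} is not an output time")
        return idx

    def field_at(self, t: float) -> np.ndarray:
        return self.concentrations[self.time_index(t)]

    def layer_field(self, layer: int | str, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(positions, concentrations) restricted to one layer at time t."""
        sl = self.grid.layer_slices[self.layer_number(layer)]
        return self.positions[sl], self.field_at(t)[sl]

    def layer_number(self, layer: int | str) -> int:
        if isinstance(layer, str):
            try:
                return self.layer_names.index(layer)
            except ValueError:
                raise KeyError(f"no layer named {layer!r}") from None
        return range(len(self.layers))[layer]


def _initial_field(grid: Grid, layers: Sequence[LayerSpec]) -> np.ndarray:
    c0 = np.empty(grid.n_nodes)
    for layer, sl in zip(layers, grid.layer_slices):
        c0[sl] = layer.initial_concentration
    return c0


def simulate(
    layers: Sequence[LayerSpec],
    interfaces: Sequence[InterfaceSpec],
    geometry: CellGeometry | None,
    discretization: Discretization,
    output_times: Sequence[float],
    *,
    sampling_times: Sequence[float] | None = None,
    sample_volume: float = 0.0,
    negative_tol: float = _NEGATIVE_TOL,
) -> SimulationResult:
    """Run the implicit-Euler FEM simulation.

    Parameters
    ----------
    output_times:
        Times (h) at which the field is recorded; t = 0 is always included.
    sampling_times, sample_volume:
        Optional receptor-sampling events: at each listed time
        ``sample_volume`` cm^3 of receptor fluid is withdrawn and replaced
        with blank buffer, uniformly diluting the receptor layer by
        (1 - V_sample/V_receptor).  Fields recorded at a sampling time are
        the pre-replacement state (what the syringe sees).
    negative_tol:
        Relative undershoot tolerance: nodal values in
        (-negative_tol * max C, 0) are clipped to zero (consistent-mass
        FEM wiggle on coarse grids); anything below raises.
    """
    out = np.atleast_1d(np.asarray(output_times, dtype=float))
    if out.size == 0:
        raise ValueError("output_times must not be empty")
    if np.any(out < 0) or np.any(np.diff(np.sort(out)) <= 0):
        raise ValueError("output_times must be distinct and >= 0")
    out = np.sort(out)
    if out[0] > 0:
        out = np.concatenate([[0.0], out])
    dt0 = discretization.time_step

    events: np.ndarray
    if sampling_times is not None and sample_volume > 0:
        if geometry is None:
            raise ValueError("sampling events require a CellGeometry")
        if sample_volume >= geometry.receptor_volume:
            raise ValueError("sample_volume must be < receptor volume")
        events = np.asarray(sampling_times, dtype=float)
        events = events[(events > 0) & (events <= out[-1])]
    else:
        events = np.empty(0)

    grid = build_grid(layers, discretization)
    mass, amat = assemble_system(grid, layers, interfaces)
    c = _initial_field(grid, layers)

    checkpoints = np.unique(np.concatenate([out, events]))
    checkpoints = checkpoints[checkpoints > 0]
    out_set = {round(t, 12) for t in out}
    event_set = {round(t, 12) for t in events}

    recorded = [c.copy()]
    lu_cache: dict[float, object] = {}
    t_prev = 0.0
    dilution = 1.0 - sample_volume / geometry.receptor_volume if events.size else 1.0
    receptor_slice = grid.layer_slices[-1]
    for t_next in checkpoints:
        span = t_next - t_prev
        n_steps = max(1, int(np.ceil(span / dt0 - 1e-12)))
        dt = span / n_steps
        key = round(dt, 14)
        lu = lu_cache.get(key)
        if lu is None:
            lu = splu((mass - dt * amat).tocsc())
            lu_cache[key] = lu
        for _ in range(n_steps):
            c = lu.solve(mass @ c)
        t_prev = t_next
        tkey = round(t_next, 12)
        if tkey in out_set:
            recorded.append(c.copy())
        if tkey in event_set:
            c[receptor_slice] *= dilution
    conc = np.asarray(recorded)

    floor = -negative_tol * max(conc.max(), 1e-300)
    if conc.min() < floor:
        raise ArithmeticError(
            f"simulation produced significantly negative concentrations "
            f"(min {conc.min():.3e}); refine the discretization"
        )
    np.clip(conc, 0.0, None, out=conc)

    return SimulationResult(
        grid=grid,
        times=out,
        concentrations=conc,
        layers=tuple(layers),
        interfaces=tuple(interfaces),
        geometry=geometry,
    )


def simulate_case(case, discretization: Discretization | None = None,
                  output_times: Sequence[float] | None = None,
                  **kwargs) -> SimulationResult:
    """Convenience wrapper: simulate a :class:`~franzsim.cases.CaseConfig`."""
    disc = discretization if discretization is not None else Discretization()
    times = output_times if output_times is not None else [case.end_time]
    return simulate(case.layers, case.interfaces, case.geometry, disc,
                    times, **kwargs)


def interface_flux(result: SimulationResult, interface_index: int,
                   t: float) -> float:
    """Interfacial flux J (mg/(cm^2 h), positive toward the receptor).

    Evaluates the flux law at the doubled interface nodes of the recorded
    field; equals -D dC/dx on either side up to discretisation error.
    """
    try:
        a, b = result.grid.interface_nodes[interface_index]
        itf = result.interfaces[interface_index]
    except IndexError:
        raise IndexError(
            f"interface_index {interface_index} out of range"
        ) from None
    field = result.field_at(t)
    return itf.flux(field[a], field[b])


def mass_balance(result: SimulationResult,
                 geometry: CellGeometry | None = None) -> float:
    """Maximum relative drift of total drug mass over the recorded times."""
    geom = geometry if geometry is not None else result.geometry
    area = geom.exposure_area if geom is not None else 1.0
    masses = area * np.trapezoid(result.concentrations, result.positions,
                                 axis=1)
    m0 = masses[0]
    if m0 == 0:
        return float(np.max(np.abs(masses)))
    return float(np.max(np.abs(masses - m0)) / m0)


def equilibrium_state(
    layers: Sequence[LayerSpec],
    interfaces: Sequence[InterfaceSpec],
    geometry: CellGeometry,
) -> np.ndarray:
    """Closed-form t -> infinity state of the sealed cell, mg/cm^3 per layer.

    At equilibrium every interfacial flux vanishes, so adjacent layers sit
    at the equilibrium ratio of their interface (skin = P x fluid), and the
    common scale is fixed by conservation of the initial mass.
    """
    rel = np.empty(len(layers))
    rel[0] = 1.0
    for i, itf in enumerate(interfaces):
        rel[i + 1] = rel[i] / itf.upstream_ratio
    volumes = geometry.exposure_area * np.array(
        [layer.thickness for layer in layers]
    )
    total_mass = float(np.dot(volumes, [l.initial_concentration for l in layers]))
    return rel * total_mass / float(np.dot(volumes, rel))


def compartment_oracle(
    interfaces: Sequence[InterfaceSpec],
    geometry: CellGeometry,
    skin_volume: float,
    initial_concentrations: Sequence[float],
    times: Sequence[float],
) -> np.ndarray:
    """Exact well-mixed three-compartment solution, shape (n_times, 3).

    In the limit of large chamber and skin diffusivities each layer is
    uniform and the cell reduces to the linear ODE system
    V_i dc_i/dt = A (J_in - J_out) with the same interfacial flux laws as
    the PDE.  Solved exactly with the matrix exponential; useful as an
    independent check of the FEM solver in the large-D limit.
    """
    if len(interfaces) != 2 or len(initial_concentrations) != 3:
        raise ValueError("compartment oracle is defined for 3 layers")
    if skin_volume <= 0:
        raise ValueError("skin_volume must be > 0")
    volumes = np.array([
        geometry.donor_volume, skin_volume, geometry.receptor_volume,
    ])
    area = geometry.exposure_area
    gmat = np.zeros((3, 3))
    for i, itf in enumerate(interfaces):
        k, rho = itf.mass_transfer, itf.upstream_ratio
        gmat[i, i] -= k
        gmat[i, i + 1] += k * rho
        gmat[i + 1, i] += k
        gmat[i + 1, i + 1] -= k * rho
    bmat = area * gmat / volumes[:, None]
    c0 = np.asarray(initial_concentrations, dtype=float)
    return np.array([
        scipy.linalg.expm(bmat * t) @ c0 for t in np.asarray(times, float)
    ])
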