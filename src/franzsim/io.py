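"""File plumbing: CSV/JSON/TOML readers and writers for the pipeline.

CSV schemas (headers carry units):

* simulation field (long): time_h, position_cm, layer, concentration_mg_per_cm3
* release curve: time_h, concentration_mg_per_ml[, replicate]
* tape strips: replicate, tube_index, amount_mg
* depth profile: tube_index, depth_lower_cm, depth_upper_cm, amount_mg
"""
from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .model import SimulationResult
from .observables import ReleaseCurve
from .specs import (
    CellGeometry,
    Discretization,
    InterfaceSpec,
    LayerSpec,
)

__all__ = [
    "result_to_frame",
    "release_to_frame",
    "release_curve_from_frame",
    "read_release_csv",
    "write_json",
    "load_run_config",
]


def result_to_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format concentration field."""
    nt, nn = result.concentrations.shape
    names = np.array(result.layer_names)[result.grid.layer_index]
    return pd.DataFrame({
        "time_h": np.repeat(result.times, nn),
        "position_cm": np.tile(result.positions, nt),
        "layer": np.tile(names, nt),
        "concentration_mg_per_cm3": result.concentrations.ravel(),
    })


def release_to_frame(curve: ReleaseCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "time_h": curve.times,
        "concentration_mg_per_ml": curve.concentration,
    })


def release_curve_from_frame(df: pd.DataFrame) -> ReleaseCurve:
    """Build a (replicate-mean) ReleaseCurve from a release table."""
    if "replicate" in df.columns and df["replicate"].nunique() > 1:
        wide = df.pivot_table(index="time_h",
                              columns="replicate",
                              values="concentration_mg_per_ml")
        return ReleaseCurve(
            times=wide.index.to_numpy(dtype=float),
            concentration=wide.mean(axis=1).to_numpy(),
            replicates=wide.to_numpy().T,
        )
    g = df.sort_values("time_h")
    return ReleaseCurve(g["time_h"].to_numpy(dtype=float),
                        g["concentration_mg_per_ml"].to_numpy(dtype=float))


def read_release_csv(path: str | Path) -> ReleaseCurve:
    return release_curve_from_frame(pd.read_csv(path))


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _parse_layers(blocks: list[dict]) -> tuple[LayerSpec, ...]:
    return tuple(
        LayerSpec(
            name=b["name"],
            thickness=float(b["thickness_cm"]),
            diffusivity=float(b["diffusivity_cm2_per_h"]),
            initial_concentration=float(b.get("initial_concentration_mg_per_cm3", 0.0)),
        )
        for b in blocks
    )


def _parse_interfaces(blocks: list[dict]) -> tuple[InterfaceSpec, ...]:
    return tuple(
        InterfaceSpec(
            partition=float(b["partition"]),
            mass_transfer=float(b["mass_transfer_cm_per_h"]),
            orientation=b.get("orientation", "skin_downstream"),
        )
        for b in blocks
    )


def load_run_config(path: str | Path) -> dict:
    """Parse a TOML (or JSON) run configuration into model objects.

    Recognised blocks: ``[[layers]]``, ``[[interfaces]]``, ``[geometry]``,
    ``[discretization]``, plus top-level ``output_times`` / ``end_time`` /
    ``seed``.  Chamber layers may omit ``thickness_cm``, in which case it
    is derived from the geometry (volume / exposure area).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)

    geom_block = raw.get("geometry", {})
    geometry = CellGeometry(
        exposure_area=float(geom_block.get("exposure_area_cm2", 0.636)),
        donor_volume=float(geom_block.get("donor_volume_ml", 1.0)),
        receptor_volume=float(geom_block.get("receptor_volume_ml", 12.0)),
    )
    layer_blocks = raw.get("layers", [])
    for b in layer_blocks:
        if "thickness_cm" not in b:
            if b.get("name") == "donor":
                b["thickness_cm"] = geometry.donor_thickness
            elif b.get("name") == "receptor":
                b["thickness_cm"] = geometry.receptor_thickness
    disc_block = raw.get("discretization", {})
    discretization = Discretization(
        nodes_per_layer=tuple(disc_block["nodes_per_layer"])
        if "nodes_per_layer" in disc_block else Discretization().nodes_per_layer,
        time_step=float(disc_block.get("time_step_h", 0.01)),
    )
    return {
        "layers": _parse_layers(layer_blocks) if layer_blocks else None,
        "interfaces": (_parse_interfaces(raw["interfaces"])
                       if "interfaces" in raw else None),
        "geometry": geometry,
        "discretization": discretization,
        "output_times": raw.get("output_times"),
        "end_time": raw.get("end_time"),
        "seed": raw.get("seed"),
        "case": raw.get("case"),
    }
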