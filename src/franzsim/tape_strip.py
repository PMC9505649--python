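"""Tape-strip dataset handling: totals and depth profiles.

The assay strips the stratum corneum 70 times per skin sample; strips go
pairwise into 35 microtubes (tube 1 holds strips 1-2 from the very surface,
tube 35 holds strips 69-70) and each tube's extract is assayed for drug.
Each strip removes 0.5-1 um, so the full series removes 0.0035-0.0070 cm
and tube k spans cumulative depths 2k x (0.5, 1.0) um.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .specs import MICRON_CM

__all__ = [
    "TapeStripDataset",
    "StripTotal",
    "DepthProfile",
    "validate_and_total",
    "depth_profile",
]

#: per-strip thickness bounds, um
STRIP_THICKNESS_BOUNDS_UM = (0.5, 1.0)
N_TUBES = 35
STRIPS_PER_TUBE = 2


@dataclass(frozen=True)
class TapeStripDataset:
    """Per-microtube drug amounts, possibly over several replicates.

    ``data`` columns: replicate (id), tube_index (1..n_tubes, contiguous
    within each replicate), amount_mg (>= 0).
    """

    data: pd.DataFrame
    strip_thickness_bounds_um: tuple[float, float] = STRIP_THICKNESS_BOUNDS_UM
    strips_per_tube: int = STRIPS_PER_TUBE

    def __post_init__(self) -> None:
        df = self.data
        required = {"replicate", "tube_index", "amount_mg"}
        if not required.issubset(df.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        if (df["amount_mg"] < 0).any():
            raise ValueError("strip amounts must be >= 0")
        for rep, grp in df.groupby("replicate"):
            tubes = np.sort(grp["tube_index"].to_numpy())
            if len(tubes) != len(set(tubes)):
                raise ValueError(f"replicate {rep!r}: duplicate tube indices")
            if tubes[0] != 1 or np.any(np.diff(tubes) != 1):
                raise ValueError(
                    f"replicate {rep!r}: tube indices must be contiguous from 1"
                )
        lo, hi = self.strip_thickness_bounds_um
        if not 0 < lo <= hi:
            raise ValueError("strip thickness bounds must be 0 < lo <= hi")

    @property
    def n_tubes(self) -> int:
        return int(self.data["tube_index"].max())

    @property
    def replicates(self) -> tuple:
        return tuple(pd.unique(self.data["replicate"]))

    @classmethod
    def from_amounts(cls, amounts, replicate=1, **kwargs) -> "TapeStripDataset":
        """Build a single-replicate dataset from a per-tube amount vector."""
        amounts = np.asarray(amounts, dtype=float)
        df = pd.DataFrame({
            "replicate": replicate,
            "tube_index": np.arange(1, amounts.size + 1),
            "amount_mg": amounts,
        })
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "TapeStripDataset":
        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False,
                         columns=["replicate", "tube_index", "amount_mg"])


@dataclass(frozen=True)
class StripTotal:
    """Total drug retained in the strips: mean over replicates +/- SD."""

    total_mg: float
    sd_mg: float
    n_replicates: int


@dataclass(frozen=True)
class DepthProfile:
    """Amount per tube with cumulative depth bounds (thin/thick strips)."""

    tube_index: np.ndarray
    depth_lower_cm: np.ndarray
    depth_upper_cm: np.ndarray
    amount_mg: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tube_index": self.tube_index,
            "depth_lower_cm": self.depth_lower_cm,
            "depth_upper_cm": self.depth_upper_cm,
            "amount_mg": self.amount_mg,
        })


def validate_and_total(dataset: TapeStripDataset) -> StripTotal:
    """Total retained amount: per-replicate sums, averaged across replicates."""
    sums = dataset.data.groupby("replicate")["amount_mg"].sum()
    return StripTotal(
        total_mg=float(sums.mean()),
        sd_mg=float(sums.std(ddof=1)) if len(sums) > 1 else 0.0,
        n_replicates=len(sums),
    )


def depth_profile(dataset: TapeStripDataset) -> DepthProfile:
    """Replicate-mean amount per tube with its cumulative depth bounds."""
    means = (
        dataset.data.groupby("tube_index")["amount_mg"].mean().sort_index()
    )
    tubes = means.index.to_numpy()
    lo, hi = dataset.strip_thickness_bounds_um
    strips = tubes * dataset.strips_per_tube
    return DepthProfile(
        tube_index=tubes,
        depth_lower_cm=strips * lo * MICRON_CM,
        depth_upper_cm=strips * hi * MICRON_CM,
        amount_mg=means.to_numpy(),
    )
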