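"""Cell biovolume, population percentiles, and biomass partitioning.

Converts microscopy cell measurements (shape, length, width in micrometres)
into biovolumes, summarizes populations by 5th/50th/95th volume percentiles,
and partitions community biomass: a population's biomass share is its share
of total biovolume (constant cell density assumed), and the
biomass-to-abundance ratio is that share divided by its share of cell
counts — algebraically identical to mean focal volume over mean community
volume.

Biovolume model: rods and ovoids are cylinders with hemispherical caps,
``V = (pi/4) * w^2 * (l - w/3)``; spheres are ``V = (pi/6) * d^3``. The rod
formula degenerates continuously to the sphere formula at l = w.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SHAPES = ("rod", "sphere", "ovoid")


@dataclass
class PopulationBiomass:
    """Abundance vs biomass summary for a focal population."""

    population: str
    abundance_pct: float
    biomass_pct: float
    ratio: float
    volume_median: float
    volume_p5: float
    volume_p95: float
    n_cells: int


def cell_volume(shape: str, length_um: float, width_um: float) -> float:
    """Biovolume (um^3) of one cell from its shape model."""
    if length_um <= 0 or width_um <= 0:
        raise ValueError("cell dimensions must be positive")
    if shape == "sphere":
        if not math.isclose(length_um, width_um, rel_tol=1e-9):
            raise ValueError("sphere requires length == width (diameter)")
        return math.pi / 6.0 * width_um ** 3
    if shape in ("rod", "ovoid"):
        if width_um > length_um:
            raise ValueError("rod/ovoid requires length >= width")
        return math.pi / 4.0 * width_um ** 2 * (length_um - width_um / 3.0)
    raise ValueError(f"unknown shape {shape!r}")


def add_volumes(cells: pd.DataFrame) -> pd.DataFrame:
    """Vectorized volume column for a cell-measurement table.

    Expects columns shape, length_um, width_um; returns a copy with a
    ``volume_um3`` column.
    """
    length = cells["length_um"].to_numpy(float)
    width = cells["width_um"].to_numpy(float)
    shape = cells["shape"].to_numpy()
    if (length <= 0).any() or (width <= 0).any():
        raise ValueError("cell dimensions must be positive")
    unknown = set(shape) - set(SHAPES)
    if unknown:
        raise ValueError(f"unknown shapes: {sorted(unknown)}")
    is_sphere = shape == "sphere"
    if (width[~is_sphere] > length[~is_sphere]).any():
        raise ValueError("rod/ovoid requires length >= width")
    if not np.allclose(length[is_sphere], width[is_sphere], rtol=1e-9):
        raise ValueError("sphere requires length == width")
    vol = np.where(is_sphere,
                   math.pi / 6.0 * width ** 3,
                   math.pi / 4.0 * width ** 2 * (length - width / 3.0))
    out = cells.copy()
    out["volume_um3"] = vol
    return out


def population_summary(cells: pd.DataFrame, population: str) -> dict[str, float] | None:
    """Volume percentiles (p5, median, p95) of one population.

    Percentiles use linear interpolation between order statistics. Returns
    None for an empty population (explicit empty result).
    """
    table = add_volumes(cells)
    vols = table.loc[table["population"] == population, "volume_um3"].to_numpy()
    if vols.size == 0:
        return None
    p5, med, p95 = np.percentile(vols, [5, 50, 95], method="linear")
    return {"n_cells": int(vols.size), "volume_p5": float(p5),
            "volume_median": float(med), "volume_p95": float(p95)}


def biomass_share(cells: pd.DataFrame, focal: str) -> PopulationBiomass:
    """Abundance %, biomass %, and their ratio for a focal population.

    Biomass is proxied by biovolume (constant density; no carbon-conversion
    exponent). Requires the table to contain both focal and non-focal cells.
    """
    table = add_volumes(cells)
    if len(table) == 0:
        raise ValueError("empty cell table")
    is_focal = table["population"] == focal
    n_focal = int(is_focal.sum())
    if n_focal == 0:
        raise ValueError(f"no cells in focal population {focal!r}")
    if n_focal == len(table):
        # degenerate but well-defined: the focal population is the community
        pass
    focal_vols = table.loc[is_focal, "volume_um3"].to_numpy()
    abundance_pct = 100.0 * n_focal / len(table)
    biomass_pct = 100.0 * focal_vols.sum() / table["volume_um3"].sum()
    p5, med, p95 = np.percentile(focal_vols, [5, 50, 95], method="linear")
    return PopulationBiomass(
        population=focal, abundance_pct=abundance_pct,
        biomass_pct=biomass_pct, ratio=biomass_pct / abundance_pct,
        volume_median=float(med), volume_p5=float(p5), volume_p95=float(p95),
        n_cells=n_focal)


def carbon_content_fg(volume_um3: float, *, a: float = 218.0,
                      d: float = 0.86) -> float:
    """Optional allometric carbon conversion ``C = a * V^d`` (fg C per cell).

    Off by default everywhere; biomass shares use raw biovolume.
    """
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return a * volume_um3 ** d
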