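"""Virtual head-and-neck tumors T1-T4.

The reference tumor T1 is *grown* with the tumor response model: a single
cell seeded at the lattice center proliferates, spreads by cell exchange,
and progressively crushes and outgrows its host vasculature, so that by the
time the tumor holds 3888 voxels (side 1.124 mm, ~2 cm sphere) it has an
emergent hypoxic core of about 1 cm diameter (vascular fraction near the
floor) surrounded by a better-oxygenated rim, with the cell density falling
from the maximum density toward roughly half of it at the border.

Three variants probe which heterogeneity drives dose painting:

==  ====================  =====================
id  cell density profile  vascular fraction
==  ====================  =====================
T1  non-uniform (grown)   non-uniform (grown)
T2  uniform               uniform (6%)
T3  uniform               non-uniform (grown)
T4  non-uniform (grown)   uniform (6%)
==  ====================  =====================

All four hold exactly the same total number of tumor cells; the uniform
density is the T1 total divided by the 3888 tumor voxels, and the uniform
vascular fraction of 6% is representative of well-oxygenated tumors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oxygenation import OxygenLookup, weighted_median
from .tumor_model import (BioParams, TumorGrid, angiogenesis, exchange_cells,
                          proliferate, update_oxygenation, HOURS_PER_DAY)

TARGET_VOXELS = 3888
VOXEL_SIDE_MM = 1.124
LATTICE_SIDE = 23  # odd, so a single seeded cell sits in a center voxel
HOST_VF = 0.06     # vascular fraction of normal host tissue


class GenerationError(RuntimeError):
    """Tumor growth did not reach its target size."""


@dataclass(frozen=True)
class TumorSpec:
    """Selector for one of the four virtual tumors."""

    density_profile: str = "nonuniform"   # {nonuniform, uniform}
    vf_profile: str = "nonuniform"        # {nonuniform, uniform}
    uniform_vf: float = HOST_VF
    diameter_cm: float = 2.0
    core_diameter_cm: float = 1.0
    rim_width_cm: float = 0.5
    target_voxels: int = TARGET_VOXELS

    def __post_init__(self) -> None:
        if self.density_profile not in ("nonuniform", "uniform"):
            raise ValueError(f"unknown density_profile {self.density_profile!r}")
        if self.vf_profile not in ("nonuniform", "uniform"):
            raise ValueError(f"unknown vf_profile {self.vf_profile!r}")
        if not 0 < self.uniform_vf <= 0.2:
            raise ValueError("uniform_vf must be in (0, 0.2]")
        if abs(self.diameter_cm - self.core_diameter_cm - 2 * self.rim_width_cm) > 1e-9:
            raise ValueError("diameter must equal core_diameter + 2*rim_width")


TUMOR_SPECS = {
    "T1": TumorSpec("nonuniform", "nonuniform"),
    "T2": TumorSpec("uniform", "uniform"),
    "T3": TumorSpec("uniform", "nonuniform"),
    "T4": TumorSpec("nonuniform", "uniform"),
}


def grow_reference_tumor(bio: BioParams, lookup: OxygenLookup,
                         spec: TumorSpec | None = None,
                         max_days: int = 2000) -> TumorGrid:
    """Grow the reference tumor T1 from a single seeded cell.

    The untreated growth phase runs the daily model loop (proliferation,
    angiogenesis, exchange, oxygenation) with the fast pre-treatment doubling
    time ``bio.growth_tp`` and no irradiation, until ``target_voxels`` voxels
    are at least half full of tumor cells.  Those voxels, ranked by tumor
    cell count, become the fixed tumor mask (planned target volume); the
    clock is then reset to treatment day 0.

    Growth is deterministic (no stochastic process is involved), so the same
    parameters always reproduce the same tumor bit for bit.
    """
    spec = spec or TUMOR_SPECS["T1"]
    grid = TumorGrid((LATTICE_SIDE,) * 3, VOXEL_SIDE_MM, bio.mu, batch=1)
    # intact host tissue: loosely packed, with the host vascular fraction
    grid.capillary[:] = bio.host_vf * bio.host_occupancy * grid.capacity
    grid.normal[:] = (1.0 - bio.host_vf) * bio.host_occupancy * grid.capacity
    c = LATTICE_SIDE // 2
    grid.viable[0, c, c, c] = 1.0
    # the target volume is the sphere of target_voxels voxels around the
    # center; growth stops when the tumor front reaches its surface, i.e.
    # when the outermost shell's density reaches half the packing density
    dist = _radius_lattice(grid)
    order = np.argsort(dist.ravel(), kind="stable")
    mask = np.zeros(dist.size, dtype=bool)
    mask[order[:spec.target_voxels]] = True
    mask = mask.reshape(dist.shape)
    surface = mask & (dist >= dist[mask].max() - grid.voxel_side)
    half = 0.5 * grid.capacity
    for _ in range(max_days):
        proliferate(grid, HOURS_PER_DAY, bio, tp_hours=bio.growth_tp)
        angiogenesis(grid, HOURS_PER_DAY, bio, lookup)
        exchange_cells(grid, bio)
        if float(grid.viable[0][surface].mean()) >= half:
            break
    else:
        raise GenerationError(
            f"tumor did not reach {spec.target_voxels} voxels in {max_days} days")
    grid.tumor_mask = mask
    grid.time_days = 0.0
    update_oxygenation(grid, lookup)
    return grid


def _radius_lattice(grid: TumorGrid) -> np.ndarray:
    """Distance (mm) of each voxel center from the lattice center."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * grid.voxel_side for n in grid.shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(X * X + Y * Y + Z * Z)


def core_mask(grid: TumorGrid, core_diameter_cm: float = 1.0) -> np.ndarray:
    """Voxels of the central tumor core (default: 1 cm diameter sphere)."""
    return (_radius_lattice(grid) <= 5.0 * core_diameter_cm) & grid.tumor_mask


def make_variant(t1: TumorGrid, spec: TumorSpec) -> TumorGrid:
    """Derive a variant tumor from the grown reference T1.

    Uniform-density variants concentrate the *entire* T1 tumor-cell burden
    evenly over the 3888 mask voxels (cells in the growth front outside the
    mask are folded in, so totals match exactly).  Uniform-vf variants set
    every mask voxel's capillaries to the 6% representative value.  With both
    profiles "nonuniform" the reference is returned unchanged (a copy).
    """
    grid = t1.copy()
    mask = grid.tumor_mask
    if spec.density_profile == "uniform":
        total = float(grid.viable.sum())
        n_mask = int(mask.sum())
        grid.viable[:] = 0.0
        grid.viable[:, mask] = total / n_mask
    if spec.vf_profile == "uniform":
        # capillaries such that the vf of the occupied tissue equals uniform_vf
        other = (grid.viable + grid.dead + grid.normal)[:, mask]
        grid.capillary[:, mask] = spec.uniform_vf / (1.0 - spec.uniform_vf) * other
    return grid


def make_tumor_set(bio: BioParams, lookup: OxygenLookup) -> dict[str, TumorGrid]:
    """Grow T1 and derive T2-T4."""
    t1 = grow_reference_tumor(bio, lookup, TUMOR_SPECS["T1"])
    out = {"T1": t1}
    for name in ("T2", "T3", "T4"):
        out[name] = make_variant(t1, TUMOR_SPECS[name])
    return out


def radial_profile(grid: TumorGrid, quantity: str = "density",
                   lookup: OxygenLookup | None = None) -> pd.DataFrame:
    """Shell-averaged radial profile over the tumor mask (batch member 0).

    quantity : {"density", "vf", "median_po2"}; density is viable cells/mm^3.
    Returns a DataFrame with columns radius_mm, value, n_voxels.
    """
    r = _radius_lattice(grid)[grid.tumor_mask]
    if quantity == "density":
        values = grid.viable[0][grid.tumor_mask] / grid.voxel_side**3
    elif quantity == "vf":
        values = grid.vf[0][grid.tumor_mask]
    elif quantity == "median_po2":
        if lookup is None:
            raise ValueError("median_po2 profile needs an oxygen lookup")
        w = lookup.interp_weights(grid.vf[0][grid.tumor_mask],
                                  grid.consumption_scale[0][grid.tumor_mask])
        values = weighted_median(w, lookup.bin_centers)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    shell = np.floor(r / grid.voxel_side).astype(int)
    df = pd.DataFrame({"shell": shell, "value": values})
    agg = df.groupby("shell")["value"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame({
        "radius_mm": (agg["shell"] + 0.5) * grid.voxel_side,
        "value": agg["mean"],
        "n_voxels": agg["size"],
    })
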