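"""Voxel-based tumor response model (growth and radiation response).

The tumor is a 3-D lattice of cubic voxels.  Each voxel holds four cell
compartments -- viable tumor cells, dead tumor cells, capillary
(endothelial) cells and normal host cells.  All cell types share the same
volume, so a voxel of side ``s`` holds at most ``mu * s^3`` cells (``mu`` =
maximum packing density).  Host tissue occupies a fraction
``host_occupancy`` of that capacity (normal tissue is less densely packed
than tumor); a growing tumor fills the rest and destroys the resident
normal cells under proliferation pressure.

The vascular fraction seen by the oxygenation model is the capillary share
of the *occupied* tissue, ``vf = capillary / (viable + dead + capillary +
normal)``: when radiation clears tumor mass from a voxel, the surviving
capillaries perfuse what remains and the voxel reoxygenates -- this is the
shrinkage-driven reoxygenation channel.  The oxygen consumption scale is
the viable fraction of the tumor cells, ``viable / (viable + dead)`` (dead
cells do not consume but still occupy space until resorbed), so a freshly
irradiated voxel reoxygenates transiently and re-hypoxifies as dead cells
clear -- unless its vasculature has caught up through angiogenesis.

Six processes are iterated once per simulated day:

1. irradiation (if a fraction is scheduled): oxygen-dependent LQ kill per
   histogram bin, stochastic (multinomial partition + binomial kill) once a
   voxel drops below ``stochastic_threshold`` viable cells, expected-value
   above it;
2. proliferation with doubling time ``tp`` (switched to the accelerated
   value two weeks into treatment), suppressed in voxels at capacity, where
   the confined growth pressure instead crushes capillaries (down to a
   vascular floor) and atrophies normal cells -- this is what dilutes the
   vasculature of a growing tumor core;
3. hypoxia-induced angiogenesis: capillaries double with time ``ta`` in
   voxels whose histogram median pO2 is below a threshold;
4. resorption of dead cells with half-time ``tr``;
5. spatial cell exchange: above-capacity voxels push their excess into
   neighbor headroom, plus occupancy-gradient diffusion from fuller to
   emptier voxels, both moving all four compartments proportionally (tumor
   growth outward, consolidation of shrinking tumors inward);
6. oxygenation update: histograms re-interpolated from the oxygen lookup at
   the current (vf, consumption scale).

State arrays carry a leading batch axis so that an entire TCP population
(e.g. 30 virtual patients) is stepped in one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import diffusion_exchange, stochastic_survivors, survivors_lookup
from .oxygenation import OxygenLookup
from .radiobiology import LQParams, OERParams, lq_coefficients

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class BioParams:
    """Biological parameters of the tumor response model (head-and-neck defaults).

    tp_initial : h, tumor-cell doubling time at treatment start (1200)
    tp_accelerated : h, doubling time after the accelerated-repopulation
        switch (120)
    accel_switch_day : days from treatment start at which repopulation
        accelerates (14)
    ta : h, capillary-cell doubling time for angiogenesis (612)
    tr : h, half-time of dead-cell resorption (168)
    mu : cells/mm^3, maximum voxel packing density (1e6)
    growth_tp : h, doubling time used while growing a virtual tumor before
        any treatment (120; untreated microscopic tumors proliferate fast)
    hypoxia_threshold : mmHg, histogram-median pO2 below which angiogenesis
        is triggered (5)
    vf_floor : minimum vascular fraction (of capacity) that survives
        proliferation pressure (0.005)
    crush_efficiency : fraction of a capillary halving caused by one
        suppressed tumor-cell doubling in an at-capacity voxel (0.5); sets
        how fast a growing tumor core dilutes its vasculature
    host_occupancy : fraction of the packing capacity occupied by intact
        host tissue (0.8); normal tissue is looser than packed tumor
    host_vf : vascular fraction of intact host tissue (0.06)
    normal_atrophy_time : h, halving time of normal cells at full tumor
        pressure (96); tumor invasion destroys host tissue at rate
        proportional to the local tumor occupancy
    exchange_rate : 1/day, diffusive cell-exchange coefficient between
        face-neighbor voxels per unit occupancy difference (0.3)
    stochastic_threshold : viable-cell count below which radiation kill is
        sampled binomially instead of taking the expected value (1e4)
    """

    tp_initial: float = 1200.0
    tp_accelerated: float = 120.0
    accel_switch_day: float = 14.0
    ta: float = 612.0
    tr: float = 168.0
    mu: float = 1.0e6
    growth_tp: float = 120.0
    hypoxia_threshold: float = 5.0
    vf_floor: float = 0.005
    crush_efficiency: float = 0.5
    host_occupancy: float = 0.8
    host_vf: float = 0.06
    normal_atrophy_time: float = 96.0
    exchange_rate: float = 0.3
    stochastic_threshold: float = 1.0e4

    def __post_init__(self) -> None:
        for name in ("tp_initial", "tp_accelerated", "ta", "tr", "mu", "growth_tp",
                     "normal_atrophy_time"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.tp_accelerated > self.tp_initial:
            raise ValueError("tp_accelerated must be <= tp_initial")
        if not 0 <= self.vf_floor < 0.5:
            raise ValueError("vf_floor must be in [0, 0.5)")
        if not 0 < self.host_occupancy <= 1:
            raise ValueError("host_occupancy must be in (0, 1]")

    def tp_effective(self, time_days: float) -> float:
        """Doubling time in effect at a given treatment day (repopulation switch)."""
        return self.tp_accelerated if time_days >= self.accel_switch_day else self.tp_initial


class TumorGrid:
    """Batched 3-D voxel lattice of tumor state.

    Attributes
    ----------
    viable, dead, capillary, normal : (B, nx, ny, nz) float arrays, cells
        per voxel.
    tumor_mask : (nx, ny, nz) bool, the planned target volume (fixed over a
        treatment; dose plans are defined on these voxels).
    voxel_side : mm.
    time_days : days since treatment start.
    """

    def __init__(self, shape, voxel_side: float, mu: float, batch: int = 1):
        self.shape = tuple(shape)
        self.voxel_side = float(voxel_side)
        self.capacity = float(mu * voxel_side**3)
        # compartments live in one contiguous stack so the exchange kernel
        # operates in place; viable/dead/capillary/normal are views into it
        self._cells = np.zeros((4, batch, *self.shape))
        self.tumor_mask = np.zeros(self.shape, dtype=bool)
        self.time_days = 0.0

    # -- compartment views (setters accept in-place augmented assignment) ----
    @property
    def viable(self) -> np.ndarray:
        return self._cells[0]

    @viable.setter
    def viable(self, value) -> None:
        if value is not self._cells[0]:
            self._cells[0][:] = value

    @property
    def dead(self) -> np.ndarray:
        return self._cells[1]

    @dead.setter
    def dead(self, value) -> None:
        if value is not self._cells[1]:
            self._cells[1][:] = value

    @property
    def capillary(self) -> np.ndarray:
        return self._cells[2]

    @capillary.setter
    def capillary(self, value) -> None:
        if value is not self._cells[2]:
            self._cells[2][:] = value

    @property
    def normal(self) -> np.ndarray:
        return self._cells[3]

    @normal.setter
    def normal(self, value) -> None:
        if value is not self._cells[3]:
            self._cells[3][:] = value

    # -- derived quantities -------------------------------------------------
    @property
    def batch(self) -> int:
        return self._cells.shape[1]

    @property
    def tracked(self) -> np.ndarray:
        return self.viable + self.dead + self.capillary + self.normal

    @property
    def vf(self) -> np.ndarray:
        """Vascular fraction of the occupied tissue (0 where empty)."""
        tracked = self.tracked
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tracked > 0, self.capillary / tracked, 0.0)

    @property
    def consumption_scale(self) -> np.ndarray:
        """Viable fraction of the tumor cells: the oxygen-consumption scale."""
        cells = self.viable + self.dead
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cells > 0, self.viable / cells, 0.0)

    def total_viable(self) -> np.ndarray:
        """(B,) total viable cells per batch member."""
        return self.viable.sum(axis=(1, 2, 3))

    def mask_view(self, arr: np.ndarray) -> np.ndarray:
        """(B, N) view of a batched lattice array on the tumor mask."""
        return arr[:, self.tumor_mask]

    def histogram_weights(self, lookup: OxygenLookup) -> np.ndarray:
        """(B, N, 16) pO2-histogram weights of the tumor-mask voxels."""
        _, vf, cons = self.mask_quantities()
        return lookup.interp_weights(vf, cons)

    def mask_quantities(self) -> tuple:
        """(viable, vf, consumption) as (B, N) arrays on the tumor mask."""
        v = self._cells[0][:, self.tumor_mask]
        d = self._cells[1][:, self.tumor_mask]
        c = self._cells[2][:, self.tumor_mask]
        n = self._cells[3][:, self.tumor_mask]
        tracked = v + d + c + n
        cells = v + d
        with np.errstate(invalid="ignore", divide="ignore"):
            vf = np.where(tracked > 0, c / tracked, 0.0)
            cons = np.where(cells > 0, v / cells, 0.0)
        return v, vf, cons

    def copy(self) -> "TumorGrid":
        out = TumorGrid.__new__(TumorGrid)
        out.shape = self.shape
        out.voxel_side = self.voxel_side
        out.capacity = self.capacity
        out._cells = self._cells.copy()
        out.tumor_mask = self.tumor_mask.copy()
        out.time_days = self.time_days
        return out

    def tile(self, batch: int) -> "TumorGrid":
        """Replicate a single-batch grid into a batch of identical tumors."""
        if self.batch != 1:
            raise ValueError("tile() requires a single-batch grid")
        out = self.copy()
        out._cells = np.tile(self._cells, (1, batch, 1, 1, 1))
        return out

    @property
    def compartments(self) -> tuple:
        return (self.viable, self.dead, self.capillary, self.normal)


# ---------------------------------------------------------------------------
# biological process steps (each mutates the grid in place and returns it)
# ---------------------------------------------------------------------------

def proliferate(grid: TumorGrid, dt_hours: float, bio: BioParams,
                tp_hours: float | None = None) -> TumorGrid:
    """Exponential viable-cell growth, suppressed at capacity.

    Voxels below capacity grow freely (they may overshoot within one step;
    the exchange step redistributes the excess).  In voxels at capacity the
    confined proliferation pressure crushes capillaries at
    ``crush_efficiency`` times the suppressed growth rate (never below the
    vascular floor).  Normal cells co-located with tumor cells atrophy at a
    rate proportional to the tumor occupancy (invasion destroys host
    tissue); they are not regenerated.
    """
    if dt_hours < 0:
        raise ValueError("dt must be >= 0")
    if dt_hours == 0:
        return grid
    tp = bio.tp_effective(grid.time_days) if tp_hours is None else tp_hours
    factor = 2.0 ** (dt_hours / tp)
    at_capacity = grid.tracked >= grid.capacity * (1.0 - 1e-12)
    has_tumor = grid.viable > 0
    grid.viable *= np.where(has_tumor & ~at_capacity, factor, 1.0)
    # proliferation pressure: crush vasculature in packed tumor voxels
    crush = at_capacity & has_tumor
    if np.any(crush):
        occ = grid.viable[crush] / grid.capacity
        floor = bio.vf_floor * grid.capacity
        crushed = grid.capillary[crush] * 2.0 ** (
            -bio.crush_efficiency * dt_hours * occ / tp)
        grid.capillary[crush] = np.maximum(crushed, np.minimum(grid.capillary[crush], floor))
    # tumor pressure atrophies resident normal cells
    pressure = (grid.viable + grid.dead) / grid.capacity
    grid.normal *= 2.0 ** (-dt_hours * pressure / bio.normal_atrophy_time)
    return grid


def angiogenesis(grid: TumorGrid, dt_hours: float, bio: BioParams,
                 lookup: OxygenLookup) -> TumorGrid:
    """Hypoxia-induced capillary growth (doubling time ``ta``).

    Triggered in voxels holding tumor cells whose histogram median pO2 is
    below ``bio.hypoxia_threshold``; well-oxygenated voxels are unchanged.
    """
    if dt_hours < 0:
        raise ValueError("dt must be >= 0")
    if dt_hours == 0:
        return grid
    cons_grid, vf_star = lookup.hypoxia_vf_threshold(bio.hypoxia_threshold)
    idx = np.where(grid.viable > 0)
    if idx[0].size == 0:
        return grid
    v = grid.viable[idx]
    d = grid.dead[idx]
    c = grid.capillary[idx]
    n = grid.normal[idx]
    cons = v / (v + d)
    vf = np.where(v + d + c + n > 0, c / (v + d + c + n), 0.0)
    critical = np.interp(cons, cons_grid, vf_star)
    grid.capillary[idx] = np.where(vf < critical,
                                   c * 2.0 ** (dt_hours / bio.ta), c)
    return grid


def resorb_dead(grid: TumorGrid, dt_hours: float, bio: BioParams) -> TumorGrid:
    """First-order clearance of dead cells with half-time ``tr``."""
    if dt_hours < 0:
        raise ValueError("dt must be >= 0")
    grid.dead *= 2.0 ** (-dt_hours / bio.tr)
    return grid


def irradiate(grid: TumorGrid, doses: np.ndarray, lq: LQParams, oer: OERParams,
              lookup: OxygenLookup, rng: np.random.Generator | None = None,
              bio: BioParams | None = None, alpha: np.ndarray | None = None,
              margin_dose: float | None = None) -> TumorGrid:
    """Deliver one fraction: oxygen-dependent LQ kill, viable -> dead.

    Parameters
    ----------
    doses : (N,) Gy on the tumor-mask voxels.  Tumor cells that migrated
        outside the planned mask receive ``margin_dose`` (default: the mean
        of the plan, i.e. the uniform margin dose).
    rng : if given, voxels below the stochastic threshold realize survivors
        as binomial draws per histogram bin (integerized kill); otherwise
        the expected value is used everywhere (deterministic mode).
    alpha : optional (B,) per-patient alpha values; beta stays fixed.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any((doses < 0) | (doses > 10.0)):
        raise ValueError("per-voxel dose outside the sane range [0, 10] Gy")
    bio = bio or BioParams()
    mask = grid.tumor_mask
    n_mask = int(mask.sum())
    if doses.shape != (n_mask,):
        raise ValueError("dose plan does not cover the tumor mask")
    if margin_dose is None:
        margin_dose = float(doses.mean()) if n_mask else 0.0

    a_bins, b_bins = lq_coefficients(lookup.bin_centers, lq, oer)  # (J,)
    if alpha is not None:
        alpha_scale = np.asarray(alpha, dtype=float) / lq.alpha  # (B,)
    else:
        alpha_scale = np.ones(grid.batch)

    def kill(viable, vf, cons, d):
        """viable/vf/cons: (B, N); d: (N,) -> survivors (B, N)."""
        expected = survivors_lookup(
            np.ascontiguousarray(viable), np.ascontiguousarray(vf),
            np.ascontiguousarray(cons), np.ascontiguousarray(d),
            lookup.vf_grid, lookup.consumption_grid, lookup.weights,
            a_bins, b_bins, alpha_scale)
        if rng is None:
            return expected
        survivors = expected
        small = viable < bio.stochastic_threshold
        if np.any(small):
            survivors = survivors.copy()
            # below half a cell the integerized count is zero: no draw needed
            survivors[small & (viable < 0.5)] = 0.0
            idx = np.where(small & (viable >= 0.5))
            if idx[0].size:
                seed = int(rng.integers(0, 2**31 - 1))
                survivors[idx] = stochastic_survivors(
                    np.ascontiguousarray(viable[idx]),
                    np.ascontiguousarray(vf[idx]),
                    np.ascontiguousarray(cons[idx]),
                    np.ascontiguousarray(d[idx[1]]),
                    lookup.vf_grid, lookup.consumption_grid, lookup.weights,
                    a_bins, b_bins,
                    np.ascontiguousarray(alpha_scale[idx[0]]), seed)
        return survivors

    # planned target volume
    viable_m, vf_m, cons_m = grid.mask_quantities()
    surv_m = kill(viable_m, vf_m, cons_m, doses)
    grid.dead[:, mask] += viable_m - surv_m
    grid.viable[:, mask] = surv_m

    # tumor cells outside the planned mask get the uniform margin dose
    outside_occupied = ~mask & (grid.viable > 0).any(axis=0)
    if margin_dose > 0 and np.any(outside_occupied):
        v_o = grid.viable[:, outside_occupied]
        d_o = grid.dead[:, outside_occupied]
        c_o = grid.capillary[:, outside_occupied]
        n_o = grid.normal[:, outside_occupied]
        tracked_o = v_o + d_o + c_o + n_o
        cells_o = v_o + d_o
        with np.errstate(invalid="ignore", divide="ignore"):
            vf_o = np.where(tracked_o > 0, c_o / tracked_o, 0.0)
            cons_o = np.where(cells_o > 0, v_o / cells_o, 0.0)
        surv_o = kill(v_o, vf_o, cons_o, np.full(v_o.shape[1], margin_dose))
        grid.dead[:, outside_occupied] += v_o - surv_o
        grid.viable[:, outside_occupied] = surv_o
    return grid


def _neighbor_sum(arr: np.ndarray) -> np.ndarray:
    """Sum of the 6 face neighbors with zero-flux (no outside neighbor) edges."""
    out = np.zeros_like(arr)
    for axis in (1, 2, 3):
        for shift in (1, -1):
            out += _shift(arr, shift, axis)
    return out


def _shift(arr: np.ndarray, shift: int, axis: int) -> np.ndarray:
    """np.roll with zero fill instead of wrap-around."""
    out = np.roll(arr, shift, axis=axis)
    idx = [slice(None)] * arr.ndim
    idx[axis] = 0 if shift == 1 else -1
    out[tuple(idx)] = 0.0
    return out


def exchange_cells(grid: TumorGrid, bio: BioParams, dt_days: float = 1.0) -> TumorGrid:
    """Spatial cell exchange: capacity-overflow push plus occupancy diffusion.

    Two conservative transport mechanisms, both moving all four compartments
    in proportion to the source voxel's composition:

    * voxels above capacity push their excess into the headroom of their six
      face neighbors, split proportionally to the available headroom (a
      receiver may accept a small overfill, ``overfill_tolerance`` of the
      capacity, so that a growth front can invade still-full host tissue);
    * a diffusive flux ``exchange_rate/6 * capacity * (occ_i - occ_j)`` per
      day flows across every face from the fuller to the emptier voxel,
      limited by the headroom of the receiver.

    Lattice-wide totals of every compartment are conserved exactly (no flux
    through the lattice boundary).
    """
    cap = grid.capacity
    overfill = 1.05  # receivers accept up to 5% above capacity

    # --- overflow push (repeat a few times in case receivers overflow) ----
    for _ in range(6):
        tracked = grid.tracked
        excess = np.maximum(tracked - cap, 0.0)
        if not np.any(excess > 1e-9 * cap):
            break
        headroom = np.maximum(overfill * cap - tracked, 0.0)
        nbr_headroom = _neighbor_sum(headroom)
        send_total = np.minimum(excess, nbr_headroom)
        with np.errstate(invalid="ignore", divide="ignore"):
            out_frac = np.where(tracked > 0, send_total / tracked, 0.0)
            per_headroom = np.where(nbr_headroom > 0, send_total / nbr_headroom, 0.0)
        for comp in grid.compartments:
            outgoing = comp * out_frac
            comp -= outgoing
            with np.errstate(invalid="ignore", divide="ignore"):
                dens = np.where(send_total > 0, outgoing / send_total, 0.0)
            # receiver r gets sum over senders s of send_s * headroom_r/nbr_headroom_s
            comp += headroom * _neighbor_sum(per_headroom * dens)

    # --- diffusive occupancy-gradient exchange -----------------------------
    rate = bio.exchange_rate * dt_days
    if rate > 0:
        diffusion_exchange(grid._cells, cap, rate, overfill)
    np.clip(grid._cells, 0.0, None, out=grid._cells)
    return grid


def update_oxygenation(grid: TumorGrid, lookup: OxygenLookup) -> TumorGrid:
    """No persistent histogram state is kept: histograms are derived from
    (vf, consumption scale) on demand via ``grid.histogram_weights``.
    Provided for pipeline symmetry; validates that the lookup is usable."""
    _ = lookup.interp_weights(grid.mask_view(grid.vf)[:, :1],
                              grid.mask_view(grid.consumption_scale)[:, :1])
    return grid


def step_day(grid: TumorGrid, doses: np.ndarray | None, bio: BioParams,
             lq: LQParams, oer: OERParams, lookup: OxygenLookup,
             rng: np.random.Generator | None = None,
             alpha: np.ndarray | None = None) -> TumorGrid:
    """Advance the model by one calendar day.

    Order: irradiate (if a fraction is scheduled) -> proliferate ->
    angiogenesis -> resorb dead cells -> exchange -> oxygenation update;
    then the clock advances by 24 h.
    """
    if doses is not None:
        irradiate(grid, doses, lq, oer, lookup, rng=rng, bio=bio, alpha=alpha)
    proliferate(grid, HOURS_PER_DAY, bio)
    angiogenesis(grid, HOURS_PER_DAY, bio, lookup)
    resorb_dead(grid, HOURS_PER_DAY, bio)
    exchange_cells(grid, bio)
    update_oxygenation(grid, lookup)
    grid.time_days += 1.0
    return grid
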