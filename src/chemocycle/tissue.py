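"""2-D tissue domain: tumor disc embedded in normal tissue on a regular grid.

The domain is a square, cell-centered grid carrying boolean tumor/normal
masks and per-cell transport parameter fields filled from per-region
parameter sets.  A discrete vascular network is mapped onto the grid by
distributing each segment's wall area over the cells its centerline
crosses.  After a treatment cycle the tumor radius is rescaled by the
cube-root of the cell-count ratio (the planar grid represents the mid-plane
slice of a spherical tumor whose cell number tracks its volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RegionParams",
    "TissueParams",
    "TissueGrid",
    "build_domain",
    "map_vessel_sources",
    "rasterize_segments",
    "update_geometry_after_cycle",
]


@dataclass
class RegionParams:
    """Transport parameters of one tissue region (tumor or normal).

    L_p    : vessel-wall hydraulic conductivity, m/(Pa·s)
    kappa  : interstitial hydraulic conductivity (Darcy), m^2/(Pa·s)
    sv_nominal : nominal vessel surface area per volume, 1/m (used when no
                 discrete network is mapped)
    lymph_coeff : lymphatic filtration coefficient L_PL (S/V)_L, 1/(Pa·s)
    pi_b, pi_i : capillary / interstitial osmotic pressure, Pa
    sigma_s : osmotic reflection coefficient for plasma proteins
    p_L    : lymphatic hydrostatic pressure, Pa
    drug_perm_factor : multiplier on the drug's vessel-wall permeability in
                 this region (normal vessels are far less leaky than
                 angiogenic tumor vessels)
    receptor_factor : multiplier on the drug's binding-site density in this
                 region; healthy tissue carries ~0.2x the tumor's cell (and
                 hence binding-site) density
    """

    L_p: float
    kappa: float
    sv_nominal: float
    lymph_coeff: float
    pi_b: float = 2660.0
    pi_i: float = 2000.0
    sigma_s: float = 0.82
    p_L: float = 0.0
    drug_perm_factor: float = 1.0
    receptor_factor: float = 1.0


def default_tumor_params() -> RegionParams:
    # Baxter–Jain-style tumor values; lymphatics non-functional in tumor
    return RegionParams(
        L_p=2.1e-11, kappa=3.1e-14, sv_nominal=20000.0, lymph_coeff=0.0,
        pi_b=2660.0, pi_i=2000.0, sigma_s=0.82, p_L=0.0, drug_perm_factor=1.0,
        receptor_factor=1.0,
    )


def default_normal_params() -> RegionParams:
    return RegionParams(
        L_p=2.7e-12, kappa=6.4e-15, sv_nominal=7000.0, lymph_coeff=1.042e-6,
        pi_b=2660.0, pi_i=1330.0, sigma_s=0.91, p_L=0.0, drug_perm_factor=0.1,
        receptor_factor=0.2,
    )


@dataclass
class TissueParams:
    tumor: RegionParams = field(default_factory=default_tumor_params)
    normal: RegionParams = field(default_factory=default_normal_params)


_FIELD_NAMES = (
    "L_p", "kappa", "lymph_coeff", "pi_b", "pi_i", "sigma_s", "p_L",
    "drug_perm_factor", "receptor_factor",
)


@dataclass
class TissueGrid:
    """Cell-centered square grid with region masks and parameter fields.

    Arrays are indexed ``[ix, iy]`` with the origin at the lower-left;
    cell centers sit at ``(i + 1/2) h``.  ``sv`` is the realized vessel
    surface density field (1/m), either nominal per region or mapped from a
    discrete network.
    """

    extent: float
    h: float
    tumor_radius: float
    tumor_center: tuple[float, float]
    params: TissueParams
    tumor_mask: np.ndarray = field(init=False)
    sv: np.ndarray = field(init=False)

    def __post_init__(self):
        n = self.n
        cc = self.cell_centers()
        r2 = (cc[0] - self.tumor_center[0]) ** 2 + (cc[1] - self.tumor_center[1]) ** 2
        self.tumor_mask = r2 <= self.tumor_radius**2
        if not self.tumor_mask.any():
            raise ValueError("tumor mask is empty: tumor radius below grid resolution")
        for name in _FIELD_NAMES:
            setattr(self, name, self.region_field(name))
        self.sv = self.region_field("sv_nominal")

    @property
    def n(self) -> int:
        return int(round(self.extent / self.h))

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    def cell_centers(self):
        x = (np.arange(self.n) + 0.5) * self.h
        return np.meshgrid(x, x, indexing="ij")

    def region_field(self, attr: str) -> np.ndarray:
        """Per-cell field filled with tumor/normal values of ``attr``."""
        return np.where(
            self.tumor_mask,
            getattr(self.params.tumor, attr),
            getattr(self.params.normal, attr),
        ).astype(float)

    def normal_mask(self) -> np.ndarray:
        return ~self.tumor_mask

    def cell_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices containing the given (k, 2) points (clipped to grid)."""
        idx = np.clip((points / self.h).astype(int), 0, self.n - 1)
        return idx[..., 0], idx[..., 1]


def build_domain(
    tumor_radius: float,
    extent: float,
    h: float,
    params: Optional[TissueParams] = None,
    tumor_center: Optional[tuple[float, float]] = None,
) -> TissueGrid:
    """Build the tissue grid with a centered tumor disc.

    ``h`` must divide ``extent`` and the tumor must fit strictly inside the
    domain (radius < extent/2) and be resolved (radius >= h).
    """
    if h <= 0 or extent <= 0:
        raise ValueError("spacing and extent must be positive")
    n = round(extent / h)
    if n < 2 or abs(n * h - extent) > 1e-9 * extent:
        raise ValueError("grid spacing must divide the domain extent")
    if tumor_radius <= 0:
        raise ValueError("tumor radius must be positive")
    if tumor_radius >= extent / 2:
        raise ValueError("tumor must fit strictly inside the domain (R < extent/2)")
    if tumor_radius < h:
        raise ValueError("tumor radius below grid resolution")
    if params is None:
        params = TissueParams()
    if tumor_center is None:
        tumor_center = (extent / 2.0, extent / 2.0)
    return TissueGrid(
        extent=extent, h=h, tumor_radius=tumor_radius,
        tumor_center=tumor_center, params=params,
    )


def rasterize_segments(grid: TissueGrid, positions: np.ndarray, edges: np.ndarray):
    """Clip straight segments against the grid.

    Returns ``(seg_idx, ix, iy, length)`` flat arrays: for every
    (segment, cell) intersection, the segment id, the cell indices, and the
    intersected centerline length (m).  Lengths are exact, so per-segment
    sums equal the segment lengths to round-off.
    """
    h = grid.h
    n = grid.n
    seg_out, ix_out, iy_out, len_out = [], [], [], []
    for k in range(edges.shape[0]):
        a = positions[edges[k, 0]]
        b = positions[edges[k, 1]]
        d = b - a
        seg_len = float(np.hypot(d[0], d[1]))
        if seg_len == 0.0:
            continue
        ts = [0.0, 1.0]
        for dim in range(2):
            if d[dim] != 0.0:
                lo = int(np.ceil(min(a[dim], b[dim]) / h))
                hi = int(np.floor(max(a[dim], b[dim]) / h))
                for g in range(lo, hi + 1):
                    t = (g * h - a[dim]) / d[dim]
                    if 0.0 < t < 1.0:
                        ts.append(t)
        ts = np.unique(np.asarray(ts))
        mids = a[None, :] + np.diff(ts)[:, None] / 2 * d[None, :] \
            + ts[:-1, None] * 0  # placeholder, replaced below
        mids = a[None, :] + (ts[:-1, None] + np.diff(ts)[:, None] / 2.0) * d[None, :]
        pieces = np.diff(ts) * seg_len
        ci = np.clip((mids / h).astype(int), 0, n - 1)
        for p, (cx, cy) in zip(pieces, ci):
            if p > 0:
                seg_out.append(k)
                ix_out.append(cx)
                iy_out.append(cy)
                len_out.append(p)
    return (
        np.asarray(seg_out, dtype=np.int64),
        np.asarray(ix_out, dtype=np.int64),
        np.asarray(iy_out, dtype=np.int64),
        np.asarray(len_out, dtype=float),
    )


def map_vessel_sources(network, grid: TissueGrid, depth: Optional[float] = None,
                       raster=None) -> np.ndarray:
    """Map a discrete network to a per-cell surface density field S/V (1/m).

    Each segment's wall area pi*D*L is distributed over the cells its
    centerline crosses, proportional to the intersected length; the total
    wall area is conserved exactly.  ``depth`` is the slab thickness of the
    cell volume ``h^2 * depth``; it defaults to the network's own depth.

    The result is stored on ``grid.sv`` and returned.
    """
    pos = network.positions
    if np.any(pos < -1e-12) or np.any(pos > grid.extent * (1 + 1e-12)):
        raise ValueError("network lies outside the grid extent")
    if depth is None:
        depth = network.depth
    if raster is None:
        raster = rasterize_segments(grid, pos, network.edges)
    seg, ix, iy, ln = raster
    area = np.pi * network.diam_um[seg] * 1e-6 * ln
    sv = np.zeros((grid.n, grid.n))
    np.add.at(sv, (ix, iy), area)
    sv /= grid.cell_area * depth
    grid.sv = sv
    return sv


def update_geometry_after_cycle(grid: TissueGrid, n_new: float, n_old: float) -> TissueGrid:
    """Rescale the tumor radius by (N_new/N_old)^(1/3) and rebuild the grid.

    The cell count is taken proportional to tumor volume; shrinkage after a
    kill and regrowth during a break both pass through here.  Parameter
    fields are rebuilt from the region masks; a mapped vessel-density field
    must be re-mapped by the caller (the network structure itself is held
    fixed across cycles).
    """
    if n_new <= 0 or n_old <= 0:
        raise ValueError("cell counts must be positive")
    r_new = grid.tumor_radius * (n_new / n_old) ** (1.0 / 3.0)
    return build_domain(
        tumor_radius=max(r_new, grid.h),  # keep the core resolved
        extent=grid.extent,
        h=grid.h,
        params=grid.params,
        tumor_center=grid.tumor_center,
    )
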