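"""Sparse spot-to-voxel dose and LET influence matrices.

``D[i, j]`` is the dose (Gy per MU) that unit-weight spot ``j`` deposits
in voxel ``i``; ``L[i, j]`` is the dose-averaged LET (keV/um) of that
spot's contribution at the voxel.  Per-voxel dose and dose-averaged LET
for a weight vector ``w`` are

    dose_i = sum_j D_ij w_j
    letd_i = sum_j L_ij D_ij w_j / sum_j D_ij w_j   (0 where dose_i = 0)

Matrices are stored spot-major (CSC, columns = spots) because the
optimizer iterates over weight vectors.  Rows are restricted to a scoring
mask (default: body voxels); air dose is irrelevant to planning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from ._errors import ContractViolation
from .beam_physics import BeamModel, Spot, WEPLGrid
from .phantoms import VoxelPhantom

log = logging.getLogger(__name__)


@dataclass
class InfluencePair:
    """Matched sparse dose (Gy/MU) and LET (keV/um) matrices, voxels x spots."""

    D: sparse.csc_matrix
    L: sparse.csc_matrix
    voxel_index: np.ndarray  # flat C-order phantom indices of the rows
    shape: tuple[int, int, int]  # phantom grid shape
    dl: sparse.csc_matrix = field(init=False)  # elementwise L*D, cached

    def __post_init__(self) -> None:
        if self.D.shape != self.L.shape:
            raise ContractViolation("D and L must share dimensions")
        if self.D.shape[0] != self.voxel_index.size:
            raise ContractViolation("row count must match the voxel index map")
        self.dl = self.D.multiply(self.L).tocsc()

    @property
    def n_voxels(self) -> int:
        return self.D.shape[0]

    @property
    def n_spots(self) -> int:
        return self.D.shape[1]

    def rows_for_mask(self, mask: np.ndarray) -> np.ndarray:
        """Row indices corresponding to a boolean phantom mask."""
        lookup = np.full(int(np.prod(self.shape)), -1, dtype=np.int64)
        lookup[self.voxel_index] = np.arange(self.n_voxels)
        rows = lookup[np.flatnonzero(mask.ravel())]
        return rows[rows >= 0]


@dataclass
class DoseMap:
    """Per-voxel dose (Gy) on the scoring voxels of an influence pair."""

    values: np.ndarray
    voxel_index: np.ndarray
    shape: tuple[int, int, int]

    def to_grid(self) -> np.ndarray:
        grid = np.zeros(int(np.prod(self.shape)))
        grid[self.voxel_index] = self.values
        return grid.reshape(self.shape)


@dataclass
class LETMap(DoseMap):
    """Per-voxel dose-averaged LET (keV/um); zero where the dose is zero."""


def compute_influence(
    phantom: VoxelPhantom,
    spots: Sequence[Spot],
    cp_angles_deg: Sequence[float],
    model: BeamModel,
    cutoff: float = 1e-4,
    scoring_mask: np.ndarray | None = None,
    sigma_reach: float = 3.0,
) -> InfluencePair:
    """Assemble the influence pair for a spot set.

    Parameters
    ----------
    spots
        Spot list; ``spot.cp_index`` indexes into ``cp_angles_deg``.
    cutoff
        Entries below ``cutoff * column max`` are dropped (sparsification).
    scoring_mask
        Boolean phantom mask of voxels to score; defaults to body voxels.
    sigma_reach
        Lateral truncation of the spot Gaussian, in sigmas.
    """
    if len(spots) == 0:
        raise ContractViolation("spot list must be non-empty")
    if not (0.0 <= cutoff < 1.0):
        raise ContractViolation("cutoff fraction must lie in [0, 1)")
    if scoring_mask is None:
        scoring_mask = phantom.body_mask()
    voxel_index = np.flatnonzero(scoring_mask.ravel())
    pts = phantom.voxel_centers_mm()[voxel_index]

    angles = np.asarray(cp_angles_deg, dtype=float)
    rows_all: list[np.ndarray] = []
    cols_all: list[np.ndarray] = []
    dvals_all: list[np.ndarray] = []
    lvals_all: list[np.ndarray] = []

    # group spots by control point so each WEPL grid is built once
    by_cp: dict[int, list[int]] = {}
    for j, s in enumerate(spots):
        by_cp.setdefault(s.cp_index, []).append(j)

    for cp, jlist in sorted(by_cp.items()):
        wg = WEPLGrid(phantom, angles[cp])
        a_v, z_v, _ = wg.bev_coords(pts)
        w_v = wg.wepl_cm(pts)
        sigma_v = model.lateral_sigma_mm(w_v)
        curve_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        for j in jlist:
            s = spots[j]
            e = s.energy_mev
            if e not in curve_cache:
                curve_cache[e] = (
                    np.asarray(model.depth_dose(e, w_v)),
                    np.asarray(model.depth_let(e, w_v)),
                )
            dcurve, lcurve = curve_cache[e]
            reach = sigma_reach * float(
                model.lateral_sigma_mm(model.range_cm(e))
            )
            da = a_v - s.x_mm
            dz = z_v - s.y_mm
            sel = (np.abs(da) < reach) & (np.abs(dz) < reach) & (dcurve > 0)
            if not sel.any():
                log.warning(
                    "spot %d (cp %d, E=%.0f MeV) misses the phantom", j, cp, e
                )
                continue
            sig = sigma_v[sel]
            gauss = np.exp(
                -0.5 * (da[sel] ** 2 + dz[sel] ** 2) / sig**2
            ) / (2.0 * np.pi * sig**2)
            dose = dcurve[sel] * gauss
            keep = dose >= cutoff * dose.max()
            idx = np.flatnonzero(sel)[keep]
            rows_all.append(idx)
            cols_all.append(np.full(idx.size, j, dtype=np.int64))
            dvals_all.append(dose[keep])
            lvals_all.append(lcurve[idx])

    n_vox, n_spots = pts.shape[0], len(spots)
    if rows_all:
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        dv = np.concatenate(dvals_all)
        lv = np.concatenate(lvals_all)
    else:
        rows = cols = np.zeros(0, dtype=np.int64)
        dv = lv = np.zeros(0)
    D = sparse.csc_matrix((dv, (rows, cols)), shape=(n_vox, n_spots))
    L = sparse.csc_matrix((lv, (rows, cols)), shape=(n_vox, n_spots))
    pair = InfluencePair(D, L, voxel_index, phantom.shape)
    log.info(
        "influence assembled: %d voxels x %d spots, %.2f M nonzeros",
        n_vox, n_spots, D.nnz / 1e6,
    )
    return pair


def _check_weights(inf: InfluencePair, weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (inf.n_spots,):
        raise ContractViolation(
            f"weights length {w.shape} != spot count {inf.n_spots}"
        )
    if np.any(w < 0):
        raise ContractViolation("weights must be >= 0")
    return w


def accumulate_dose(inf: InfluencePair, weights) -> DoseMap:
    """Per-voxel dose: the weighted column sum ``D @ w`` (exact, linear)."""
    w = _check_weights(inf, weights)
    return DoseMap(inf.D @ w, inf.voxel_index, inf.shape)


def accumulate_letd(inf: InfluencePair, weights) -> LETMap:
    """Per-voxel dose-averaged LET: dose-weighted LET sum over dose sum.

    Voxels receiving zero dose are assigned LET 0 by convention.  The
    result is invariant under uniform scaling of the weights.
    """
    w = _check_weights(inf, weights)
    den = inf.D @ w
    num = inf.dl @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    return LETMap(vals, inf.voxel_index, inf.shape)


def save_influence(path, inf: InfluencePair) -> None:
    """Persist an influence pair to a compressed ``.npz`` container."""
    np.savez_compressed(
        path,
        d_data=inf.D.data, d_indices=inf.D.indices, d_indptr=inf.D.indptr,
        l_data=inf.L.data,
        shape_mat=np.array(inf.D.shape), shape_grid=np.array(inf.shape),
        voxel_index=inf.voxel_index,
    )


def load_influence(path) -> InfluencePair:
    with np.load(path) as z:
        shape_mat = tuple(z["shape_mat"])
        D = sparse.csc_matrix(
            (z["d_data"], z["d_indices"], z["d_indptr"]), shape=shape_mat
        )
        L = sparse.csc_matrix(
            (z["l_data"], z["d_indices"].copy(), z["d_indptr"].copy()),
            shape=shape_mat,
        )
        return InfluencePair(D, L, z["voxel_index"], tuple(z["shape_grid"]))
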