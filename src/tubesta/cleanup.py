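"""Particle-set hygiene: duplicate removal by distance-thresholded CC
competition, cross-correlation cutoff filtering, and tomogram-edge exclusion.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CleanupReport:
    n_input: int
    n_after_dedup: int | None = None
    n_after_cc_cut: int | None = None
    n_after_edge: int | None = None
    cc_cutoff_used: float | None = None

    def __post_init__(self) -> None:
        counts = [self.n_input, self.n_after_dedup, self.n_after_cc_cut,
                  self.n_after_edge]
        counts = [c for c in counts if c is not None]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValidationError("cleanup counts must be non-increasing")


def remove_duplicates(
    table: pd.DataFrame, distance_A: float, voxel_size_A: float
) -> tuple[pd.DataFrame, CleanupReport]:
    """Greedy duplicate removal: walk particles by descending cc_score
    (particle_id breaks ties) and accept one only if no already-accepted
    particle of the same tomogram lies within ``distance_A``.

    This resolves the oversampling of the initial surface seeding once
    particles have converged onto lattice positions.
    """
    if not distance_A > 0:
        raise ValidationError("distance_A must be positive")
    if table["cc_score"].isna().any():
        raise ValidationError("remove_duplicates requires cc_score on all records")
    report = CleanupReport(n_input=len(table))
    order = table.sort_values(
        ["cc_score", "particle_id"], ascending=[False, True]
    ).index
    r_vox = distance_A / voxel_size_A
    accepted_idx = []
    accepted_by_tomo: dict[int, list[np.ndarray]] = {}
    for idx in order:
        rec = table.loc[idx]
        pos = rec[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float)
        tomo = int(rec["tomo_id"])
        kept = accepted_by_tomo.get(tomo, [])
        if kept:
            d = np.linalg.norm(np.asarray(kept) - pos, axis=1)
            if (d < r_vox).any():
                continue
        accepted_idx.append(idx)
        accepted_by_tomo.setdefault(tomo, []).append(pos)
    out = table.loc[sorted(accepted_idx, key=lambda i: table.loc[i, "particle_id"])]
    report.n_after_dedup = len(out)
    return out.copy(), report


def apply_cc_cutoff(
    table: pd.DataFrame, cutoff="auto"
) -> tuple[pd.DataFrame, CleanupReport]:
    """Drop records with cc_score below ``cutoff``.

    ``cutoff='auto'`` replaces the interactive histogram inspection with a
    reproducible surrogate: Otsu's threshold on the CC-score histogram.
    """
    report = CleanupReport(n_input=len(table))
    scores = table["cc_score"].to_numpy(dtype=float)
    if cutoff == "auto" or cutoff == "interactive-histogram":
        finite = scores[np.isfinite(scores)]
        if len(finite) < 2 or np.ptp(finite) < 1e-12:
            cut = -1.0
        else:
            cut = float(threshold_otsu(finite))
        logger.info("automatic CC cutoff (Otsu): %.4f", cut)
    else:
        cut = float(cutoff)
        if not -1.0 <= cut <= 1.0:
            raise ValidationError("cc cutoff must lie in [-1, 1]")
    keep = np.isfinite(scores) & (scores >= cut)
    out = table.loc[keep].copy()
    report.n_after_cc_cut = len(out)
    report.cc_cutoff_used = cut
    return out, report


def exclude_edge_particles(
    table: pd.DataFrame, tomo_dims_vox: dict, box: int
) -> tuple[pd.DataFrame, CleanupReport]:
    """Drop particles whose box (after applying shifts) extends outside the
    tomogram.  ``tomo_dims_vox`` maps tomo_id to (nx, ny, nz)."""
    report = CleanupReport(n_input=len(table))
    half = box / 2.0
    keep = []
    for idx in table.index:
        rec = table.loc[idx]
        dims = np.asarray(tomo_dims_vox[int(rec["tomo_id"])], dtype=float)
        pos = rec[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float) + rec[
            ["shift_x", "shift_y", "shift_z"]
        ].to_numpy(dtype=float)
        center = np.round(pos)
        if ((center - half) >= 0).all() and ((center + half) <= dims).all():
            keep.append(idx)
    out = table.loc[keep].copy()
    report.n_after_edge = len(out)
    return out, report


def neighbor_free(table: pd.DataFrame, distance_A: float, voxel_size_A: float):
    """Particle ids that have no same-tomogram neighbor within the threshold
    (these can never be removed by deduplication)."""
    free = []
    for tomo, sub in table.groupby("tomo_id"):
        pos = sub[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float)
        tree = cKDTree(pos)
        pairs = tree.query_pairs(distance_A / voxel_size_A)
        has_neighbor = set()
        for i, j in pairs:
            has_neighbor.add(i)
            has_neighbor.add(j)
        for k, pid in enumerate(sub["particle_id"]):
            if k not in has_neighbor:
                free.append(int(pid))
    return free
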