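"""3D classification by PCA of wedge-masked difference maps (WMDs).

A WMD compares each aligned particle with the reference *as the particle saw
it*: the reference is rotated into the particle's frame and filtered by that
particle's Fourier sampling mask before subtraction, so missing-wedge
artefacts do not masquerade as structural variability.  The difference maps,
flattened under a shared real mask, feed a principal components analysis and
k-means clustering in the leading component space.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import fft as sfft
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .align_average import normalize_under_mask
from .errors import ValidationError
from .fourier_filters import FourierMask
from .geometry import EulerTriplet, euler_to_matrix, invert_pose, rotate_array
from .io_formats import DensityVolume

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class WMDStack:
    """Per-particle wedge-masked difference volumes plus provenance."""

    diffs: np.ndarray  # (n_particles, box, box, box), reference frame
    particle_ids: np.ndarray
    real_mask: np.ndarray
    reference_id: str = ""


def wedge_masked_difference(
    subtomo: DensityVolume,
    reference: DensityVolume,
    record,
    particle_mask: FourierMask,
    real_mask: np.ndarray,
) -> np.ndarray:
    """Difference between one aligned particle and the wedge-filtered reference.

    The reference is rotated to the particle frame and filtered by the
    particle's own Fourier mask; both volumes are intensity-normalized under
    the real mask; the difference (particle - filtered reference) is returned
    in the reference frame.
    """
    if pd.isna(record["cc_score"]):
        raise ValidationError("wedge_masked_difference requires an aligned particle")
    r = euler_to_matrix(EulerTriplet(record["phi"], record["theta"], record["psi"]))
    t = np.array([record["shift_x"], record["shift_y"], record["shift_z"]], dtype=float)
    box = subtomo.data.shape[0]
    ref_rot = rotate_array(reference.data.astype(np.float64), r, t)
    ref_filt = sfft.irfftn(
        sfft.rfftn(ref_rot) * particle_mask.rfft_weights(), s=ref_rot.shape
    )
    # normalize in the particle frame under the particle-frame real mask
    mask_p = np.clip(rotate_array(real_mask.astype(np.float64), r, cval=0.0), 0, 1)
    sub_n = normalize_under_mask(subtomo.data.astype(np.float64), mask_p)
    ref_n = normalize_under_mask(ref_filt, mask_p)
    diff_particle_frame = (sub_n - ref_n) * mask_p
    rinv, tinv = invert_pose(r, t)
    diff_ref_frame = rotate_array(diff_particle_frame, rinv, tinv, cval=0.0)
    assert diff_ref_frame.shape == (box,) * 3
    return diff_ref_frame


def build_wmd_stack(
    table: pd.DataFrame,
    source,
    reference: DensityVolume,
    real_mask: np.ndarray,
    reference_id: str = "",
) -> WMDStack:
    """Wedge-masked difference maps for every particle in the table."""
    diffs = []
    pids = []
    for idx in table.sort_values("particle_id").index:
        rec = table.loc[idx]
        vol, _ = source.get(rec)
        d = wedge_masked_difference(vol, reference, rec, source.mask(rec), real_mask)
        diffs.append(d.astype(np.float32))
        pids.append(int(rec["particle_id"]))
    return WMDStack(np.stack(diffs), np.asarray(pids), real_mask, reference_id)


@dataclasses.dataclass
class ClassificationResult:
    labels: pd.Series  # particle_id -> class_id
    eigenvolumes: np.ndarray  # (n_components, box, box, box)
    explained_variance: np.ndarray
    coordinates: np.ndarray  # (n_particles, n_components)


def pca_classify(
    stack: WMDStack, n_components: int, k_classes: int, seed: int = 0
) -> ClassificationResult:
    """PCA of mask-flattened difference vectors + k-means in component space.

    Deterministic for a fixed seed.  Raises for k < 2 or too few particles.
    """
    n = len(stack.diffs)
    if k_classes < 2:
        raise ValidationError("k_classes must be at least 2")
    if n < k_classes:
        raise ValidationError("need at least k_classes particles")
    if n_components > n:
        raise ValidationError("n_components cannot exceed the stack length")
    sel = stack.real_mask > 0.5
    x = stack.diffs[:, sel].astype(np.float64)
    pca = PCA(n_components=n_components, random_state=seed, svd_solver="full")
    coords = pca.fit_transform(x)
    km = KMeans(n_clusters=k_classes, random_state=seed, n_init=10)
    labels = km.fit_predict(coords)
    box = stack.diffs.shape[1]
    eig = np.zeros((n_components, box, box, box), dtype=np.float32)
    eig[:, sel] = pca.components_.astype(np.float32)
    return ClassificationResult(
        labels=pd.Series(labels, index=stack.particle_ids, name="class_id"),
        eigenvolumes=eig,
        explained_variance=pca.explained_variance_.copy(),
        coordinates=coords,
    )


def total_masked_variance(stack: WMDStack) -> float:
    """Total variance of the mask-flattened difference vectors (the quantity
    a complete principal decomposition must account for)."""
    sel = stack.real_mask > 0.5
    x = stack.diffs[:, sel].astype(np.float64)
    return float(((x - x.mean(axis=0)) ** 2).sum() / (len(x) - 1))


def scree_is_flat(explained_variance: np.ndarray, ratio: float = 3.0) -> bool:
    """'No classes' diagnostic: no component explains more than ``ratio``
    times the variance of its successor."""
    ev = np.asarray(explained_variance, dtype=float)
    if len(ev) < 2:
        return True
    return bool(np.all(ev[:-1] <= ratio * np.maximum(ev[1:], 1e-300)))


def class_purity(labels: pd.Series, truth: pd.Series) -> float:
    """Best-permutation agreement between predicted and true labels."""
    from itertools import permutations

    pred = labels.to_numpy()
    true = truth.loc[labels.index].to_numpy()
    classes = np.unique(pred)
    best = 0.0
    for perm in permutations(np.unique(true), len(classes)):
        mapping = dict(zip(classes, perm))
        acc = float(np.mean([mapping[p] == t for p, t in zip(pred, true)]))
        best = max(best, acc)
    return best
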