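"""Spatial similarity of task activation maps.

Operations on group-level z-statistic volumes sharing one voxel grid:
thresholding into positive-activation masks, pairwise mask intersection,
masked Pearson spatial correlation, assembly of the task-pair correlation
matrix, eigenvalue repair to positive definiteness, and per-domain
conjunction masks.

All maps live in 0-based voxel-index space on a common grid; no resampling
is performed here (inputs are assumed spatially normalized upstream).
Negative activations are ignored throughout: masks keep voxels whose
z-statistic strictly exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
import json

import numpy as np
import nibabel as nib
from scipy import ndimage

__all__ = [
    "StatMap",
    "BetaMap",
    "ActivationMask",
    "PairCorrelationMatrix",
    "GridMismatchError",
    "UndefinedCorrelationError",
    "threshold_mask",
    "intersection_mask",
    "spatial_correlation",
    "pairwise_matrix",
    "nearest_pd_repair",
    "domain_conjunction_mask",
    "load_stat_map",
    "save_map",
    "save_mask",
    "save_pair_matrix",
    "load_pair_matrix",
]

#: default z threshold for positive activation
DEFAULT_Z = 2.3
#: minimum intersection size for a pair correlation to be defined
DEFAULT_N_MIN = 10


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class UndefinedCorrelationError(ValueError):
    """A masked correlation cannot be computed (too few voxels or zero variance)."""


@dataclass(frozen=True)
class StatMap:
    """A 3D volume of group-level z-statistics for one task."""

    values: np.ndarray
    task_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in map {self.task_id!r}")
        object.__setattr__(self, "values", v)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class BetaMap:
    """A 3D volume of subject-level parameter estimates for one task."""

    values: np.ndarray
    subject_id: str = ""
    task_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class ActivationMask:
    """A boolean voxel mask derived from thresholding one or more z-maps."""

    values: np.ndarray
    threshold: float | None = None
    source_tasks: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=bool))

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class PairCorrelationMatrix:
    """Symmetric matrix of masked spatial correlations between task maps.

    ``r[i, j]`` is the Pearson correlation of task i's and task j's
    z-statistics over the intersection of their positive-activation masks;
    ``n_voxels[i, j]`` is the size of that intersection.
    """

    tasks: list[str]
    r: np.ndarray
    n_voxels: np.ndarray
    threshold: float = DEFAULT_Z
    repaired: bool = False

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        p = len(self.tasks)
        if self.r.shape != (p, p):
            raise ValueError("correlation matrix shape does not match task list")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_pairs(self) -> int:
        """Number of unordered off-diagonal task pairs, p(p-1)/2."""
        p = self.n_tasks
        return p * (p - 1) // 2

    @property
    def n_unique_values(self) -> int:
        """Unique entries including the diagonal, p(p+1)/2 (78 for 12 tasks)."""
        p = self.n_tasks
        return p * (p + 1) // 2


def _check_same_grid(*shapes):
    first = shapes[0]
    for s in shapes[1:]:
        if s != first:
            raise GridMismatchError(f"grid shapes differ: {first} vs {s}")


def threshold_mask(stat_map: StatMap, z: float = DEFAULT_Z,
                   min_cluster: int = 0) -> ActivationMask:
    """Positive-activation mask: voxels with z-statistic strictly above ``z``.

    ``min_cluster`` > 0 additionally removes connected components (26-neighbor
    connectivity) smaller than that many voxels, a crude stand-in for
    cluster-extent inference; default 0 leaves the voxelwise mask untouched.
    """
    mask = stat_map.values > z
    if min_cluster > 0 and mask.any():
        labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        counts = np.bincount(labels.ravel())
        keep = counts >= min_cluster
        keep[0] = False
        mask = keep[labels]
    return ActivationMask(mask, threshold=z, source_tasks=(stat_map.task_id,))


def intersection_mask(a: ActivationMask, b: ActivationMask) -> ActivationMask:
    """Voxelwise AND of two activation masks on the same grid."""
    _check_same_grid(a.grid_shape, b.grid_shape)
    thr = a.threshold if a.threshold == b.threshold else None
    return ActivationMask(a.values & b.values, threshold=thr,
                          source_tasks=a.source_tasks + b.source_tasks)


def spatial_correlation(a: StatMap, b: StatMap, mask: ActivationMask,
                        n_min: int = DEFAULT_N_MIN) -> tuple[float, int]:
    """Pearson correlation of two maps' values over the masked voxels.

    Returns ``(r, n)`` where n is the mask size. Raises
    :class:`UndefinedCorrelationError` when fewer than ``n_min`` voxels are
    available or either map is constant within the mask.
    """
    _check_same_grid(a.grid_shape, b.grid_shape, mask.grid_shape)
    n = mask.voxel_count
    if n < n_min:
        raise UndefinedCorrelationError(
            f"only {n} voxels in mask for ({a.task_id}, {b.task_id}); "
            f"need at least {n_min}")
    x = a.values[mask.values]
    y = b.values[mask.values]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            f"zero variance within mask for ({a.task_id}, {b.task_id})")
    r = float(np.dot(x - x.mean(), y - y.mean()) / (n * sx * sy))
    return min(1.0, max(-1.0, r)), n


def pairwise_matrix(maps: list[StatMap], z: float = DEFAULT_Z,
                    n_min: int = DEFAULT_N_MIN,
                    min_cluster: int = 0) -> PairCorrelationMatrix:
    """Masked spatial correlations for every unordered task pair.

    Each pair's correlation is computed over the intersection of the two
    tasks' own positive-activation masks, so every entry has its own voxel
    support; ``n_voxels`` records it. Raises if any pair is undefined,
    listing the failing pairs.
    """
    p = len(maps)
    if p < 2:
        raise ValueError("need at least two maps")
    _check_same_grid(*[m.grid_shape for m in maps])
    masks = [threshold_mask(m, z=z, min_cluster=min_cluster) for m in maps]
    r = np.eye(p)
    n_vox = np.zeros((p, p), dtype=int)
    for i in range(p):
        n_vox[i, i] = masks[i].voxel_count
    failures = []
    for i, j in combinations(range(p), 2):
        inter = intersection_mask(masks[i], masks[j])
        try:
            rij, nij = spatial_correlation(maps[i], maps[j], inter, n_min=n_min)
        except UndefinedCorrelationError as exc:
            failures.append(f"({maps[i].task_id}, {maps[j].task_id}): {exc}")
            continue
        r[i, j] = r[j, i] = rij
        n_vox[i, j] = n_vox[j, i] = nij
    if failures:
        raise UndefinedCorrelationError(
            "undefined correlation for pairs:\n  " + "\n  ".join(failures))
    return PairCorrelationMatrix([m.task_id for m in maps], r, n_vox, threshold=z)


def clip_rescale_pd(matrix: np.ndarray, eig_floor: float = 1e-6,
                    max_iter: int = 200) -> tuple[np.ndarray, bool]:
    """Alternate eigenvalue clipping (to >= ``eig_floor``) with rescaling to
    unit diagonal until a symmetric matrix is both PD and a correlation
    matrix. Returns ``(repaired, touched)``; untouched inputs come back
    unmodified."""
    m = 0.5 * (np.asarray(matrix, dtype=float) + np.asarray(matrix).T)
    touched = False
    for _ in range(max_iter):
        w, v = np.linalg.eigh(m)
        if w.min() >= eig_floor * (1 - 1e-9):
            break
        touched = True
        m = (v * np.maximum(w, eig_floor)) @ v.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        np.fill_diagonal(m, 1.0)
        m = 0.5 * (m + m.T)
    return m, touched


def nearest_pd_repair(matrix: PairCorrelationMatrix,
                      eig_floor: float = 1e-6,
                      max_iter: int = 200) -> PairCorrelationMatrix:
    """Repair an indefinite pair-correlation matrix to positive definiteness.

    Because every entry is computed over its own voxel support, the assembled
    matrix need not be positive semidefinite. This alternates eigenvalue
    clipping (to >= ``eig_floor``) with rescaling back to unit diagonal until
    both properties hold. The ``repaired`` flag is set iff any clipping
    occurred; a matrix that is already PD is returned unchanged.
    """
    m, touched = clip_rescale_pd(matrix.r, eig_floor=eig_floor, max_iter=max_iter)
    if not touched:
        return matrix
    return replace(matrix, r=m, repaired=True)


def domain_conjunction_mask(masks: list[ActivationMask]) -> ActivationMask:
    """Conjunction (voxelwise AND) of a domain's three task activation masks."""
    if len(masks) != 3:
        raise ValueError(f"a domain conjunction takes exactly 3 masks, got {len(masks)}")
    out = masks[0]
    for m in masks[1:]:
        out = intersection_mask(out, m)
    return out


# ---------------------------------------------------------------------------
# NIfTI / tabular I/O

def load_stat_map(path: str | Path, task_id: str | None = None) -> StatMap:
    img = nib.load(str(path))
    if task_id is None:
        name = Path(path).name
        task_id = name.split("_")[0].removeprefix("task-")
    return StatMap(np.asarray(img.get_fdata(), dtype=float), task_id=task_id)


def save_map(values: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), np.eye(4)), str(path))


def save_mask(mask: ActivationMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), np.eye(4)), str(path))


def save_pair_matrix(matrix: PairCorrelationMatrix, prefix: str | Path) -> None:
    """Write the correlation matrix as TSV plus a JSON sidecar."""
    prefix = Path(prefix)
    import pandas as pd

    pd.DataFrame(matrix.r, index=matrix.tasks, columns=matrix.tasks).to_csv(
        prefix.with_suffix(".tsv"), sep="\t")
    sidecar = {
        "tasks": matrix.tasks,
        "n_voxels": matrix.n_voxels.tolist(),
        "threshold": matrix.threshold,
        "repaired": matrix.repaired,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_pair_matrix(prefix: str | Path) -> PairCorrelationMatrix:
    prefix = Path(prefix)
    import pandas as pd

    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return PairCorrelationMatrix(
        tasks=list(df.columns), r=df.to_numpy(),
        n_voxels=np.asarray(meta["n_voxels"], dtype=int),
        threshold=float(meta["threshold"]), repaired=bool(meta["repaired"]))
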