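"""Searchlight neural representational plasticity (NRP) maps.

NRP quantifies how much a local multivoxel activation pattern changed between
a pre- and a post-training scan.  Within a sphere (default radius 6 mm)
centered at each gray-matter voxel, the spatial Pearson correlation r between
the pre and post t-score patterns is computed, Fisher transformed,
Z = 0.5 * ln((1 + r) / (1 - r)) = atanh(r), and negated:

    NRP = -Z = -atanh(r).

Stable local representations (r near 1) give strongly negative NRP; changed
representations give NRP near or above zero.  The searchlight repeats this at
every voxel of the mask to produce a whole-brain map.

Conventions: voxel indices are 0-based; sphere membership is decided by
center-to-center Euclidean distance in world mm through the volume affine
(anisotropic voxels supported) and includes the center voxel; spheres are
truncated at the mask; neighborhoods smaller than ``min_neighborhood`` voxels
are marked invalid, as are neighborhoods with a constant pre or post patch.
Correlations are clamped to +/-(1 - 1e-7) before atanh so the map stays
finite and order preserving at |r| = 1.

The upstream t-maps are expected to be estimated from correctly solved trials
only; this module consumes them as given and cannot verify that restriction.

The module also houses the subject-level fMRI quality-control filters: run
exclusion on head motion summaries and cohort-level image-intensity outlier
flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "ActivationMapPair",
    "NRPMap",
    "R_CLAMP_EPS",
    "MIN_NEIGHBORHOOD",
    "sphere_offsets",
    "sphere_neighborhood",
    "nrp_at_voxel",
    "Searchlight",
    "searchlight_nrp",
    "qc_motion_exclude",
    "qc_intensity_outlier",
]

R_CLAMP_EPS = 1e-7
MIN_NEIGHBORHOOD = 10


@dataclass
class ActivationMapPair:
    """Paired pre/post 3D t-score volumes with a shared mask and affine."""

    pre: np.ndarray
    post: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0]))

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if not (self.pre.shape == self.post.shape == self.mask.shape):
            raise ValueError("pre, post and mask must share dimensions")
        if self.pre.ndim != 3:
            raise ValueError("volumes must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def from_nifti(cls, pre_path, post_path, mask_path) -> "ActivationMapPair":
        pre_img = nib.load(str(pre_path))
        post_img = nib.load(str(post_path))
        mask_img = nib.load(str(mask_path))
        for other in (post_img, mask_img):
            if other.shape != pre_img.shape or not np.allclose(other.affine, pre_img.affine):
                raise ValueError("pre, post and mask images must share shape and affine")
        return cls(
            pre=np.asanyarray(pre_img.dataobj, dtype=float),
            post=np.asanyarray(post_img.dataobj, dtype=float),
            mask=np.asanyarray(mask_img.dataobj) > 0,
            affine=pre_img.affine,
        )


@dataclass
class NRPMap:
    """A voxel-wise NRP volume; NaN (and ``valid`` False) where not computable."""

    nrp: np.ndarray
    valid: np.ndarray
    affine: np.ndarray

    def masked_values(self) -> np.ndarray:
        """NRP values at valid voxels, in C order of the volume."""
        return self.nrp[self.valid]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.nrp.astype(np.float64), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path) -> "NRPMap":
        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj, dtype=float)
        return cls(nrp=vol, valid=np.isfinite(vol), affine=img.affine)


def sphere_offsets(radius_mm: float, affine: np.ndarray) -> np.ndarray:
    """Integer voxel offsets whose world-space length is <= radius_mm.

    Offsets are enumerated in lexicographic order and include (0, 0, 0).
    World displacement for offset o is ``affine[:3, :3] @ o``.
    """
    A = np.asarray(affine, dtype=float)[:3, :3]
    vox = np.sqrt((A ** 2).sum(axis=0))
    r = np.maximum(np.floor(radius_mm / vox).astype(int), 0)
    axes = [np.arange(-r[i], r[i] + 1) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((grid @ A.T) ** 2).sum(axis=1)
    return grid[d2 <= radius_mm ** 2 + 1e-9]


def sphere_neighborhood(
    center: Sequence[int],
    radius_mm: float,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
) -> np.ndarray:
    """In-mask voxel indices within radius_mm of ``center`` (center included).

    Distances are center-to-center in world mm via the affine (2 mm isotropic
    voxels assumed if no affine is given).  Returns an (m, 3) index array in
    lexicographic offset order.
    """
    mask = np.asarray(mask).astype(bool)
    center = np.asarray(center, dtype=int)
    if not mask[tuple(center)]:
        raise ValueError(f"center {center.tolist()} is outside the mask")
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
    pts = center + sphere_offsets(radius_mm, affine)
    ok = np.all((pts >= 0) & (pts < mask.shape), axis=1)
    pts = pts[ok]
    return pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]


def nrp_at_voxel(pre_patch: np.ndarray, post_patch: np.ndarray) -> float:
    """NRP for one searchlight patch: -atanh(clamped Pearson r).

    Patches must have equal length >= ``MIN_NEIGHBORHOOD``; a constant patch
    has no defined correlation and returns NaN.
    """
    x = np.asarray(pre_patch, dtype=float)
    y = np.asarray(post_patch, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("patches must be 1D and of equal length")
    m = x.size
    if m < MIN_NEIGHBORHOOD:
        raise ValueError(f"patch of {m} voxels is below the minimum of {MIN_NEIGHBORHOOD}")
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    sxy = (x * y).sum()
    vx = sxx - sx * sx / m
    vy = syy - sy * sy / m
    if vx <= 0 or vy <= 0:
        return float("nan")
    r = (sxy - sx * sy / m) / np.sqrt(vx * vy)
    r = np.clip(r, -(1 - R_CLAMP_EPS), 1 - R_CLAMP_EPS)
    return float(-np.arctanh(r))


class Searchlight:
    """Reusable searchlight engine for one (mask, affine, radius) geometry.

    Precomputes the per-center neighbor table (the expensive part) once, so a
    cohort of subjects sharing a mask can be mapped cheaply.  ``centers`` may
    restrict the searchlight to a boolean sub-volume when only part of the
    map is needed (e.g. an effect region during simulation studies).
    """

    def __init__(
        self,
        mask: np.ndarray,
        affine: np.ndarray | None = None,
        radius_mm: float = 6.0,
        min_neighborhood: int = MIN_NEIGHBORHOOD,
        centers: np.ndarray | None = None,
    ) -> None:
        if radius_mm <= 0:
            raise ValueError("radius must be positive")
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("mask is empty")
        if affine is None:
            affine = np.diag([2.0, 2.0, 2.0, 1.0])
        self.mask = mask
        self.affine = np.asarray(affine, dtype=float)
        self.radius_mm = radius_mm
        self.min_neighborhood = min_neighborhood
        shape = mask.shape
        coords = np.argwhere(mask)  # lexicographic order
        V = coords.shape[0]
        pos = -np.ones(shape, dtype=np.int64)
        pos[mask] = np.arange(V)
        if centers is None:
            center_rows = np.arange(V)
        else:
            centers = np.asarray(centers).astype(bool)
            if centers.shape != shape:
                raise ValueError("centers must match the volume shape")
            center_rows = pos[centers & mask]
        offs = sphere_offsets(radius_mm, self.affine)
        ccoords = coords[center_rows]
        n_c = ccoords.shape[0]
        nb = np.full((n_c, offs.shape[0]), -1, dtype=np.int64)
        for j, o in enumerate(offs):
            p = ccoords + o
            ok = np.all((p >= 0) & (p < shape), axis=1)
            q = p[ok]
            nb[ok, j] = pos[q[:, 0], q[:, 1], q[:, 2]]
        valid_nb = nb >= 0
        counts = valid_nb.sum(axis=1)
        self._ccoords = ccoords
        # per-neighborhood-size row groups with dense (rows, m) index blocks
        self._groups: list[tuple[int, np.ndarray, np.ndarray]] = []
        for m in np.unique(counts):
            rows = np.flatnonzero(counts == m)
            if m < min_neighborhood:
                continue
            idx = nb[rows][valid_nb[rows]].reshape(rows.size, m)
            self._groups.append((int(m), rows, idx))

    def map(self, pair: ActivationMapPair) -> NRPMap:
        """Searchlight NRP map for one subject's pre/post pair."""
        if pair.mask.shape != self.mask.shape or not np.array_equal(pair.mask, self.mask):
            raise ValueError("pair mask does not match the engine mask")
        pre_v = pair.pre[self.mask]
        post_v = pair.post[self.mask]
        n_c = self._ccoords.shape[0]
        nrp_vals = np.full(n_c, np.nan)
        for m, rows, idx in self._groups:
            x = pre_v[idx]
            y = post_v[idx]
            sx = x.sum(axis=1)
            sy = y.sum(axis=1)
            sxx = (x * x).sum(axis=1)
            syy = (y * y).sum(axis=1)
            sxy = (x * y).sum(axis=1)
            vx = sxx - sx * sx / m
            vy = syy - sy * sy / m
            good = (vx > 0) & (vy > 0)
            r = np.full(rows.size, np.nan)
            r[good] = (sxy[good] - sx[good] * sy[good] / m) / np.sqrt(vx[good] * vy[good])
            r = np.clip(r, -(1 - R_CLAMP_EPS), 1 - R_CLAMP_EPS)
            nrp_vals[rows] = -np.arctanh(r)
        vol = np.full(self.mask.shape, np.nan)
        vol[tuple(self._ccoords.T)] = nrp_vals
        return NRPMap(nrp=vol, valid=np.isfinite(vol), affine=self.affine.copy())


def searchlight_nrp(
    pair: ActivationMapPair,
    radius_mm: float = 6.0,
    min_neighborhood: int = MIN_NEIGHBORHOOD,
    centers: np.ndarray | None = None,
) -> NRPMap:
    """Whole-mask searchlight NRP map.

    At every mask voxel (or only at ``centers``, a boolean sub-volume, when a
    restricted map suffices) the pre/post patterns over the in-mask sphere are
    correlated and transformed to NRP.  Voxels whose truncated neighborhood
    falls below ``min_neighborhood`` voxels, or whose patch is constant, are
    marked invalid (NaN).

    The computation is vectorized by grouping searchlight centers by
    neighborhood size and reducing along the patch axis, which reproduces a
    naive per-voxel loop (lexicographic neighbor order, textbook sum formula
    for r) bit for bit.  When mapping many subjects on one mask, build a
    :class:`Searchlight` engine once instead.
    """
    return Searchlight(pair.mask, pair.affine, radius_mm, min_neighborhood, centers).map(pair)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_motion_exclude(
    translations_mm: np.ndarray,
    rotations_deg: np.ndarray,
    mean_fwd_mm: Sequence[float],
    max_translation_mm: float = 10.0,
    max_rotation_deg: float = 10.0,
    max_mean_fwd_mm: float = 0.5,
) -> tuple[bool, np.ndarray]:
    """Subject-level head-motion exclusion from per-run motion summaries.

    A run is excessive when any translation exceeds 10 mm, any rotation
    exceeds 10 degrees, or mean framewise displacement exceeds 0.5 mm.  The
    subject is dropped only when excessive motion occurs in *more than half*
    of runs (exactly half keeps the subject).

    ``translations_mm`` and ``rotations_deg`` are (n_runs, k) peak absolute
    values per direction (k may be 1 for a precomputed per-run maximum);
    ``mean_fwd_mm`` is one value per run.  Returns ``(keep, bad_run_flags)``.
    """
    tr = np.atleast_2d(np.asarray(translations_mm, dtype=float))
    ro = np.atleast_2d(np.asarray(rotations_deg, dtype=float))
    fwd = np.asarray(mean_fwd_mm, dtype=float)
    n_runs = fwd.size
    if tr.shape[0] != n_runs or ro.shape[0] != n_runs:
        raise ValueError("per-run motion summaries have inconsistent run counts")
    if n_runs == 0 or not (np.all(np.isfinite(tr)) and np.all(np.isfinite(ro)) and np.all(np.isfinite(fwd))):
        raise ValueError("missing run summaries")
    bad = (
        (np.abs(tr) > max_translation_mm).any(axis=1)
        | (np.abs(ro) > max_rotation_deg).any(axis=1)
        | (fwd > max_mean_fwd_mm)
    )
    keep = bad.sum() <= n_runs / 2
    return bool(keep), bad


def qc_intensity_outlier(intensity_summaries: Sequence[float]) -> np.ndarray:
    """Flag subjects whose image intensity lies > 3 SD from the cohort mean.

    Each subject is compared against the leave-one-out mean and sample SD of
    the remaining cohort, so a single extreme value cannot mask itself.  A
    zero-variance remainder yields no flag for that subject; needs >= 3
    subjects.
    """
    x = np.asarray(intensity_summaries, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects for outlier detection")
    total, total2 = x.sum(), (x ** 2).sum()
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        m = (total - x[i]) / (n - 1)
        var = (total2 - x[i] ** 2 - (n - 1) * m ** 2) / (n - 2)
        sd = np.sqrt(max(var, 0.0))
        if sd > 0:
            flags[i] = abs(x[i] - m) > 3 * sd
    return flags
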