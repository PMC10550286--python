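"""Voxel-wise group inference on NRP maps.

Two complementary questions are addressed at every gray-matter voxel:

* do the groups differ in mean NRP? (two-sample t map), and
* does the NRP-learning-gain slope differ by group? (OLS with group, gain
  and their interaction; the interaction t map is the primary output).

Multiple comparisons are handled by cluster-extent correction: voxels are
thresholded at an uncorrected height threshold (two-sided p < 0.005 by
default), connected components are formed separately for positive and
negative suprathreshold voxels (26-connectivity by default), and each
cluster's family-wise-error-corrected p is its extent's tail probability
under the permutation distribution of the *maximum* cluster extent (group
labels are permuted for the group term; residualized maps are sign-flipped,
Freedman-Lane style, for regression terms).  Permutation replaces the
Gaussian-random-field correction used in much of the parametric literature:
it is exact under exchangeability and requires no smoothness estimation.

Design coding: group enters as an indicator (reference group coded 0), and
the gain covariate is mean-centered before the product is formed, so the
group coefficient is the group difference at average gain.

ROI summaries (mean NRP over a sphere around a peak, or over a supplied
anatomical mask) support a priori region analyses; no atlas is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .nrp import NRPMap

__all__ = [
    "GroupModelResult",
    "ClusterResult",
    "PlasticityGLM",
    "stack_nrp_maps",
    "two_sample_nrp_map",
    "find_clusters",
    "cohens_f",
    "roi_extract",
    "sphere_roi_mask",
]


def stack_nrp_maps(maps: Sequence[NRPMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack subject NRP maps into an (n_subjects, V) matrix.

    The analysis mask is the intersection of the subjects' valid voxels (and
    their geometry must agree).  Returns ``(Y, mask, affine)``.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    ref = maps[0]
    for m in maps[1:]:
        if m.nrp.shape != ref.nrp.shape or not np.allclose(m.affine, ref.affine):
            raise ValueError("NRP maps have mismatched geometry")
    mask = np.logical_and.reduce([m.valid for m in maps])
    if not mask.any():
        raise ValueError("no voxel is valid in every subject")
    Y = np.stack([m.nrp[mask] for m in maps])
    return Y, mask, ref.affine.copy()


@dataclass
class ClusterResult:
    """One suprathreshold connected component of a statistic volume."""

    cluster_id: int
    member_voxels: np.ndarray  # (m, 3) voxel indices
    peak_voxel: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    extent: int
    peak_t: float
    corrected_p: float = float("nan")


def _label_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def find_clusters(
    t_vol: np.ndarray,
    threshold: float,
    affine: np.ndarray,
    connectivity: int = 26,
) -> list[ClusterResult]:
    """Connected components with |t| above ``threshold``, split by sign."""
    structure = _label_structure(connectivity)
    out: list[ClusterResult] = []
    cid = 0
    for sign in (1.0, -1.0):
        supra = np.nan_to_num(sign * t_vol) > threshold
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            members = np.argwhere(labels == lab)
            tvals = t_vol[tuple(members.T)]
            k = int(np.argmax(sign * tvals))
            peak = tuple(int(v) for v in members[k])
            peak_mm = tuple((affine @ np.array([*peak, 1.0]))[:3])
            out.append(ClusterResult(
                cluster_id=cid, member_voxels=members, peak_voxel=peak,
                peak_mm=peak_mm, extent=members.shape[0], peak_t=float(tvals[k]),
            ))
            cid += 1
    out.sort(key=lambda c: -c.extent)
    for i, c in enumerate(out):
        c.cluster_id = i
    return out


def _max_extent(t_vol: np.ndarray, threshold: float, structure: np.ndarray) -> int:
    mx = 0
    for sign in (1.0, -1.0):
        supra = np.nan_to_num(sign * t_vol) > threshold
        labels, n = ndimage.label(supra, structure=structure)
        if n:
            mx = max(mx, int(np.bincount(labels.ravel())[1:].max()))
    return mx


@dataclass
class GroupModelResult:
    """Voxel-wise model fit: per-term coefficient, t and uncorrected-p volumes.

    ``terms`` preserves the design ordering.  ``df`` is the residual degrees
    of freedom shared by every voxel; p volumes are two-sided.  Cluster
    correction hangs off this object and uses the permutation engine supplied
    by the model that produced it.
    """

    terms: list[str]
    beta: dict[str, np.ndarray]
    t: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    df: int
    mask: np.ndarray
    affine: np.ndarray
    n_per_group: dict[str, int]
    _perm_engines: dict[str, Callable[[np.random.Generator], np.ndarray]] = field(
        default_factory=dict, repr=False)
    _extra: dict = field(default_factory=dict, repr=False)

    def summary(self) -> pd.DataFrame:
        rows = []
        for term in self.terms:
            tv = self.t[term][self.mask]
            rows.append({
                "term": term,
                "df": self.df,
                "peak_|t|": float(np.nanmax(np.abs(tv))),
                "n_p<0.005": int((self.p[term][self.mask] < 0.005).sum()),
                "n_voxels": int(self.mask.sum()),
            })
        return pd.DataFrame(rows).set_index("term")

    def height_threshold(self, height_p: float) -> float:
        """t value whose two-sided p equals ``height_p`` at this df."""
        return float(stats.t.ppf(1 - height_p / 2, self.df))

    def clusters(self, term: str, height_p: float = 0.005,
                 connectivity: int = 26) -> list[ClusterResult]:
        return find_clusters(self.t[term], self.height_threshold(height_p),
                             self.affine, connectivity)

    def cluster_correct(
        self,
        term: str,
        height_p: float = 0.005,
        alpha: float = 0.05,
        n_perm: int = 1000,
        seed: int | None = None,
        connectivity: int = 26,
        return_all: bool = False,
    ) -> list[ClusterResult]:
        """Cluster-extent FWE correction by max-extent permutation.

        Corrected p for a cluster of extent k is (1 + #{permutation max
        extent >= k}) / (n_perm + 1); clusters with corrected p < ``alpha``
        are returned (all clusters when ``return_all``).  An empty list (no
        suprathreshold voxels or none surviving) is a valid outcome, not an
        error.
        """
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 for a usable null distribution")
        if term not in self._perm_engines:
            raise ValueError(f"no permutation scheme available for term {term!r}")
        if seed is None:
            raise ValueError("a seed is required for the permutation null")
        thr = self.height_threshold(height_p)
        observed = find_clusters(self.t[term], thr, self.affine, connectivity)
        if not observed:
            return []
        rng = np.random.default_rng(seed)
        structure = _label_structure(connectivity)
        engine = self._perm_engines[term]
        null_max = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            null_max[i] = _max_extent(engine(rng), thr, structure)
        for c in observed:
            c.corrected_p = float((1 + (null_max >= c.extent).sum()) / (n_perm + 1))
        if return_all:
            return observed
        return [c for c in observed if c.corrected_p < alpha]

    def cluster_table(self, clusters: Sequence[ClusterResult]) -> pd.DataFrame:
        return pd.DataFrame([
            {"cluster_id": c.cluster_id, "peak_x_mm": c.peak_mm[0],
             "peak_y_mm": c.peak_mm[1], "peak_z_mm": c.peak_mm[2],
             "extent": c.extent, "peak_t": c.peak_t, "corrected_p": c.corrected_p}
            for c in clusters
        ])


def _scatter(mask: np.ndarray, values: np.ndarray) -> np.ndarray:
    vol = np.full(mask.shape, np.nan)
    vol[mask] = values
    return vol


def _pooled_t(Y: np.ndarray, is_a: np.ndarray, welch: bool = False) -> tuple[np.ndarray, float]:
    na, nb = int(is_a.sum()), int((~is_a).sum())
    A, B = Y[is_a], Y[~is_a]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = float(np.median(se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
    return t, df


def two_sample_nrp_map(
    nrp_a: Sequence[NRPMap],
    nrp_b: Sequence[NRPMap],
    labels: tuple[str, str] = ("ASD", "TD"),
    welch: bool = False,
) -> GroupModelResult:
    """Voxel-wise two-sample t comparison of group mean NRP (A minus B)."""
    if len(nrp_a) < 2 or len(nrp_b) < 2:
        raise ValueError("each group needs >= 2 subjects")
    Y, mask, affine = stack_nrp_maps(list(nrp_a) + list(nrp_b))
    is_a = np.zeros(Y.shape[0], dtype=bool)
    is_a[: len(nrp_a)] = True
    t, df = _pooled_t(Y, is_a, welch=welch)
    p = 2 * stats.t.sf(np.abs(t), df)

    def perm_engine(rng: np.random.Generator) -> np.ndarray:
        perm = rng.permutation(is_a)
        tp, _ = _pooled_t(Y, perm, welch=welch)
        return _scatter(mask, tp)

    beta = Y[is_a].mean(axis=0) - Y[~is_a].mean(axis=0)
    return GroupModelResult(
        terms=["group"],
        beta={"group": _scatter(mask, beta)},
        t={"group": _scatter(mask, t)},
        p={"group": _scatter(mask, p)},
        df=int(round(df)), mask=mask, affine=affine,
        n_per_group={labels[0]: len(nrp_a), labels[1]: len(nrp_b)},
        _perm_engines={"group": perm_engine},
    )


class PlasticityGLM:
    """Voxel-wise OLS of NRP on group, learning gain, and their interaction.

    ``group`` labels are coded as an indicator (``reference`` group = 0) and
    ``gain`` is mean-centered before the product is formed.  ``fit`` returns
    a :class:`GroupModelResult` with terms ``intercept``, ``group``, ``gain``
    and ``group:gain``; the interaction t map is the primary output, and
    group-specific simple slopes are available from the results.
    """

    def __init__(
        self,
        nrp_maps: Sequence[NRPMap],
        group: Sequence[str],
        gain: Sequence[float],
        reference: str | None = None,
    ) -> None:
        group = np.asarray(group)
        gain = np.asarray(gain, dtype=float)
        if len(nrp_maps) != group.size or group.size != gain.size:
            raise ValueError("nrp_maps, group and gain must align")
        if not np.all(np.isfinite(gain)):
            raise ValueError("gain must be finite for all subjects")
        levels = np.unique(group)
        if levels.size != 2:
            raise ValueError(f"exactly two groups required, got {levels.tolist()}")
        self.reference = reference if reference is not None else ("TD" if "TD" in levels else levels[0])
        if self.reference not in levels:
            raise ValueError(f"reference {self.reference!r} not among groups")
        self.coded_group = levels[levels != self.reference][0]
        for g in levels:
            if np.std(gain[group == g]) == 0:
                raise ValueError(
                    f"zero gain variance within group {g!r}: the gain and "
                    f"group:gain terms are degenerate")
        self.nrp_maps = list(nrp_maps)
        self.group = group
        self.gain = gain

    def _design(self) -> np.ndarray:
        g = (self.group == self.coded_group).astype(float)
        gc = self.gain - self.gain.mean()
        return np.column_stack([np.ones_like(gc), g, gc, g * gc])

    def fit(self) -> GroupModelResult:
        Y, mask, affine = stack_nrp_maps(self.nrp_maps)
        X = self._design()
        n, k = X.shape
        if n <= k:
            raise ValueError(f"need more than {k} subjects to fit {k} terms")
        XtX = X.T @ X
        if np.linalg.cond(XtX) > 1e10:
            raise ValueError("rank-deficient design (group x gain collinear)")
        XtX_inv = np.linalg.inv(XtX)
        P = XtX_inv @ X.T
        B = P @ Y
        resid = Y - X @ B
        df = n - k
        sigma2 = (resid ** 2).sum(axis=0) / df
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        tmat = B / se
        pmat = 2 * stats.t.sf(np.abs(tmat), df)
        terms = ["intercept", "group", "gain", "group:gain"]

        engines = {}
        for j, term in enumerate(terms[1:], start=1):
            engines[term] = self._freedman_lane_engine(Y, X, j, mask)
        res = GroupModelResult(
            terms=terms,
            beta={t: _scatter(mask, B[i]) for i, t in enumerate(terms)},
            t={t: _scatter(mask, tmat[i]) for i, t in enumerate(terms)},
            p={t: _scatter(mask, pmat[i]) for i, t in enumerate(terms)},
            df=df, mask=mask, affine=affine,
            n_per_group={str(g): int((self.group == g).sum()) for g in np.unique(self.group)},
            _perm_engines=engines,
            _extra={"coded_group": self.coded_group, "reference": self.reference},
        )
        return res

    def _freedman_lane_engine(self, Y, X, term_idx, mask):
        """Sign-flip permutation of residualized maps for one design term.

        The reduced model excludes the term; its residuals are sign-flipped
        per subject, added back to the reduced fit, and the full-model t for
        the term is recomputed (Freedman-Lane).
        """
        n, k = X.shape
        Z = np.delete(X, term_idx, axis=1)
        Bz = np.linalg.lstsq(Z, Y, rcond=None)[0]
        fitted = Z @ Bz
        resid = Y - fitted
        XtX_inv = np.linalg.inv(X.T @ X)
        P = XtX_inv @ X.T
        cjj = XtX_inv[term_idx, term_idx]
        df = n - k

        def engine(rng: np.random.Generator) -> np.ndarray:
            s = rng.choice([-1.0, 1.0], size=n)
            Ystar = fitted + s[:, None] * resid
            Bs = P @ Ystar
            rss = ((Ystar - X @ Bs) ** 2).sum(axis=0)
            t = Bs[term_idx] / np.sqrt(cjj * rss / df)
            return _scatter(mask, t)

        return engine

    def simple_slopes(self, result: GroupModelResult) -> dict[str, np.ndarray]:
        """Per-group NRP-gain slope volumes implied by the fitted model."""
        ref_slope = result.beta["gain"]
        coded_slope = result.beta["gain"] + result.beta["group:gain"]
        return {self.reference: ref_slope, str(self.coded_group): coded_slope}


def cohens_f(eta_sq_partial: float) -> float:
    """Cohen's f from partial eta squared: f = sqrt(np2 / (1 - np2))."""
    if not 0 <= eta_sq_partial < 1:
        raise ValueError("partial eta squared must lie in [0, 1)")
    return float(np.sqrt(eta_sq_partial / (1 - eta_sq_partial)))


def sphere_roi_mask(
    shape: Sequence[int],
    affine: np.ndarray,
    center_mm: Sequence[float],
    radius_mm: float = 6.0,
) -> np.ndarray:
    """Boolean volume of voxels whose world-mm center lies within the sphere."""
    idx = np.indices(shape).reshape(3, -1)
    world = (np.asarray(affine)[:3, :3] @ idx).T + np.asarray(affine)[:3, 3]
    d2 = ((world - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=1)
    return (d2 <= radius_mm ** 2).reshape(shape)


def roi_extract(
    nrp_map: NRPMap,
    center_mm: Sequence[float] | None = None,
    roi_mask: np.ndarray | None = None,
    radius_mm: float = 6.0,
) -> float:
    """Mean NRP over valid voxels in a peak sphere or a supplied ROI mask."""
    if (center_mm is None) == (roi_mask is None):
        raise ValueError("give exactly one of center_mm or roi_mask")
    if roi_mask is None:
        roi_mask = sphere_roi_mask(nrp_map.nrp.shape, nrp_map.affine, center_mm, radius_mm)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if roi_mask.shape != nrp_map.nrp.shape:
        raise ValueError("ROI mask shape does not match the map")
    sel = roi_mask & nrp_map.valid
    if not sel.any():
        raise ValueError("ROI does not intersect any valid voxel")
    return float(nrp_map.nrp[sel].mean())
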