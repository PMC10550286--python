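"""Synthetic cohorts with known ground truth for every downstream stage.

The generator emulates the structure of a two-group pre/post training study:
children with autism (ASD) and typically developing (TD) children complete
five days of arithmetic training (daily accuracy / reaction time, hence a
declining inverse efficiency score), pre- and post-training verification and
production tasks on 14 trained and 14 untrained problems, per-problem
strategy reports, clinical RRIB subscores, and paired pre/post activation
volumes whose local pattern stability is coupled to each child's learning
gain with a group-dependent sign.

Behavioral side (:class:`CohortSpec`, :func:`generate_behavior`)
    Daily IES follows a linear decline with Gaussian noise; task gains are
    Gaussian around group means; strategy codes are drawn per problem as
    Bernoulli(memory probability), where the post-training memory probability
    is high (0.85) or low (0.15) according to a subject-level dominance
    indicator drawn with the group's strategy-shift probability - so dominant
    strategy emerges from problem counts while its population rate tracks the
    specified probability.

Imaging side (:class:`PlasticitySpec`, :func:`generate_map_pair`)
    Each subject's pre map is a Gaussian i.i.d. t-score field (optionally
    smoothed); the post map is constructed as

        post = rho * pre + sqrt(1 - rho^2) * eps

    with an independent field eps, so the population voxel-wise correlation
    equals rho exactly.  rho is ``stability_base`` everywhere except inside
    spherical effect regions, where it varies linearly with the subject's
    group-centered learning gain (then clipped to +/-0.99), giving the
    searchlight NRP statistic a known gain coupling of known sign per group.

All outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .nrp import ActivationMapPair

__all__ = [
    "CohortSpec",
    "EffectRegion",
    "PlasticitySpec",
    "BehavioralDataset",
    "generate_behavior",
    "generate_map_pair",
    "ellipsoid_mask",
    "simulate_moderation_cohort",
]

#: per-problem memory-strategy probability for subjects whose dominant
#: strategy is (resp. is not) memory-based; majority at p=0.85 over 14
#: problems occurs with probability 0.996, so the population dominance rate
#: tracks the subject-level indicator probability.
_P_MEM_DOMINANT = 0.85
_P_MEM_NONDOMINANT = 0.15


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic behavioral cohort.

    Defaults mirror the study conditions: 35 ASD / 28 TD children, 5 training
    days, 14 problems per condition; a day-1 IES around 6000 ms declining by
    800 ms/day (children this age need several seconds per problem early in
    training); comparable accuracy gains (ASD 0.05, TD 0.07, SD 0.15) and
    large reaction-time speed-ups (-0.35, SD 0.15) in both groups; most TD
    children (0.8) but only about half of ASD children (0.5) shifting to a
    memory-based dominant strategy for trained problems after training.
    """

    n_asd: int = 35
    n_td: int = 28
    n_days: int = 5
    n_problems_per_condition: int = 14
    ies_day1_mean: float = 6000.0
    ies_daily_decline: float = 800.0
    ies_noise_sd: float = 400.0
    acc_gain_mean_by_group: dict = field(
        default_factory=lambda: {"ASD": 0.05, "TD": 0.07})
    rt_gain_mean_by_group: dict = field(
        default_factory=lambda: {"ASD": -0.35, "TD": -0.35})
    acc_gain_sd: float = 0.15
    rt_gain_sd: float = 0.15
    memory_shift_prob_td: float = 0.8
    memory_shift_prob_asd: float = 0.5
    pre_memory_prob: float = 0.35
    is_score_range: tuple[int, int] = (0, 10)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_asd", "n_td", "n_days", "n_problems_per_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("memory_shift_prob_td", "memory_shift_prob_asd", "pre_memory_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        lo, hi = self.is_score_range
        if hi < lo:
            raise ValueError("is_score_range must be (low, high) with high >= low")
        for g in ("ASD", "TD"):
            if g not in self.acc_gain_mean_by_group or g not in self.rt_gain_mean_by_group:
                raise ValueError(f"gain means must be given for group {g!r}")


@dataclass
class BehavioralDataset:
    """Synthetic behavioral tables.

    ``subjects``: one row per child (group, RRIB subscores, pre/post accuracy
    and RT per condition).  ``training``: one row per child per training day
    (accuracy, mean correct RT in ms, IES in ms).  ``strategies``: one row per
    child x condition x phase x problem with correctness and, for correct
    problems, the strategy code (retrieval / counting / decomposition).
    """

    subjects: pd.DataFrame
    training: pd.DataFrame
    strategies: pd.DataFrame

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("subjects", "training", "strategies"):
            getattr(self, name).to_csv(d / f"{name}.tsv", sep="\t", index=False)


def generate_behavior(spec: CohortSpec) -> BehavioralDataset:
    """Draw a full synthetic behavioral cohort from ``spec`` (deterministic)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_asd + spec.n_td
    groups = np.array(["ASD"] * spec.n_asd + ["TD"] * spec.n_td)
    sid = np.array([f"s{i:03d}" for i in range(n)])
    is_asd = groups == "ASD"

    # --- training table: declining IES with plausible accuracy trajectory
    days = np.arange(1, spec.n_days + 1)
    ies = (spec.ies_day1_mean
           - spec.ies_daily_decline * (days - 1)[None, :]
           + spec.ies_noise_sd * rng.standard_normal((n, spec.n_days)))
    ies = np.maximum(ies, 200.0)
    acc_day = np.clip(
        0.75 + 0.04 * (days - 1)[None, :] + 0.05 * rng.standard_normal((n, spec.n_days)),
        0.05, 1.0)
    training = pd.DataFrame({
        "subject_id": np.repeat(sid, spec.n_days),
        "day": np.tile(days, n),
        "accuracy": acc_day.ravel(),
        "mean_rt": (ies * acc_day).ravel(),
        "ies": ies.ravel(),
    })

    # --- pre/post task performance per condition
    acc_gain_mean = np.where(is_asd, spec.acc_gain_mean_by_group["ASD"],
                             spec.acc_gain_mean_by_group["TD"])
    rt_gain_mean = np.where(is_asd, spec.rt_gain_mean_by_group["ASD"],
                            spec.rt_gain_mean_by_group["TD"])
    acc_pre_tr = np.clip(rng.normal(0.80, 0.08, n), 0.4, 0.98)
    acc_gain = rng.normal(acc_gain_mean, spec.acc_gain_sd)
    acc_post_tr = np.clip(acc_pre_tr * (1 + acc_gain), 0.05, 1.0)
    acc_pre_un = np.clip(rng.normal(0.80, 0.08, n), 0.4, 0.98)
    acc_post_un = np.clip(acc_pre_un * (1 + rng.normal(0.0, spec.acc_gain_sd, n)), 0.05, 1.0)
    rt_pre_tr = np.clip(rng.normal(5000.0, 900.0, n), 1000, None)
    rt_post_tr = rt_pre_tr * (1 + rng.normal(rt_gain_mean, spec.rt_gain_sd))
    rt_pre_un = np.clip(rng.normal(5000.0, 900.0, n), 1000, None)
    rt_post_un = rt_pre_un * (1 + rng.normal(0.0, spec.rt_gain_sd, n))
    rt_post_tr = np.clip(rt_post_tr, 500, None)
    rt_post_un = np.clip(rt_post_un, 500, None)

    lo, hi = spec.is_score_range
    subjects = pd.DataFrame({
        "subject_id": sid,
        "group": groups,
        "is_score": rng.integers(lo, hi + 1, n),
        "ci_score": rng.integers(lo, hi + 1, n),
        "rmb_score": rng.integers(lo, hi + 1, n),
        "acc_pre_trained": acc_pre_tr, "acc_post_trained": acc_post_tr,
        "acc_pre_untrained": acc_pre_un, "acc_post_untrained": acc_post_un,
        "rt_pre_trained": rt_pre_tr, "rt_post_trained": rt_post_tr,
        "rt_pre_untrained": rt_pre_un, "rt_post_untrained": rt_post_un,
    })

    # --- strategy codes: subject-level dominance indicator, then per-problem
    # Bernoulli draws; codes exist only for correctly solved problems.
    shift_prob = np.where(is_asd, spec.memory_shift_prob_asd, spec.memory_shift_prob_td)
    p_mem = {}  # (condition, phase) -> per-subject memory probability
    p_mem[("trained", "pre")] = np.full(n, spec.pre_memory_prob)
    p_mem[("untrained", "pre")] = np.full(n, spec.pre_memory_prob)
    dom_tr = rng.random(n) < shift_prob
    p_mem[("trained", "post")] = np.where(dom_tr, _P_MEM_DOMINANT, _P_MEM_NONDOMINANT)
    # post-training untrained problems: ASD children keep strategy use similar
    # across problem types; TD children stay near their pre-training mix.
    dom_un = rng.random(n) < np.where(is_asd, spec.memory_shift_prob_asd, spec.pre_memory_prob)
    p_mem[("untrained", "post")] = np.where(dom_un, _P_MEM_DOMINANT, _P_MEM_NONDOMINANT)

    acc_for = {("trained", "pre"): acc_pre_tr, ("trained", "post"): acc_post_tr,
               ("untrained", "pre"): acc_pre_un, ("untrained", "post"): acc_post_un}
    k = spec.n_problems_per_condition
    frames = []
    for (cond, phase), p in p_mem.items():
        correct = rng.random((n, k)) < acc_for[(cond, phase)][:, None]
        mem = rng.random((n, k)) < p[:, None]
        ruleword = rng.random((n, k)) < 0.5
        code = np.where(mem, "retrieval", np.where(ruleword, "counting", "decomposition"))
        code = np.where(correct, code, None)
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(sid, k),
            "condition": cond,
            "phase": phase,
            "problem": np.tile(np.arange(k), n),
            "correct": correct.ravel(),
            "strategy": code.ravel(),
        }))
    strategies = pd.concat(frames, ignore_index=True)
    return BehavioralDataset(subjects=subjects, training=training, strategies=strategies)


# ---------------------------------------------------------------------------
# paired activation volumes
# ---------------------------------------------------------------------------

def ellipsoid_mask(shape: Sequence[int] = (32, 32, 32),
                   semi_axes: Sequence[float] | None = None) -> np.ndarray:
    """Centered ellipsoidal binary mask (default semi-axes dim/2 - 3)."""
    shape = tuple(int(s) for s in shape)
    if semi_axes is None:
        semi_axes = [s / 2 - 3 for s in shape]
    c = [(s - 1) / 2 for s in shape]
    g = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d = sum(((gi - ci) / ai) ** 2 for gi, ci, ai in zip(g, c, semi_axes))
    return d <= 1.0


@dataclass(frozen=True)
class EffectRegion:
    """A spherical region where local stability is coupled to learning gain.

    ``coupling_by_group`` maps group label to the NRP-direction coupling c:
    inside the region rho = stability_base - c * (gain - group mean gain), so
    a positive c makes higher-gaining subjects show *more* plasticity (lower
    pre/post correlation, higher NRP).
    """

    center: tuple[int, int, int]
    radius_mm: float
    coupling_by_group: dict

    def voxels(self, shape: Sequence[int], voxel_size_mm: float) -> np.ndarray:
        c = np.asarray(self.center)
        g = np.ogrid[: shape[0], : shape[1], : shape[2]]
        d2 = sum(((gi - ci) * voxel_size_mm) ** 2 for gi, ci in zip(g, c))
        return d2 <= self.radius_mm ** 2


@dataclass(frozen=True)
class PlasticitySpec:
    """Generative parameters for paired pre/post activation volumes."""

    gain_vector: np.ndarray
    groups: np.ndarray
    grid_dims: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    mask: np.ndarray | None = None
    stability_base: float = 0.5
    effect_regions: tuple = ()
    noise_sd: float = 1.0
    smooth_fwhm_mm: float | None = None
    seed: int = 0

    def resolved_mask(self) -> np.ndarray:
        m = ellipsoid_mask(self.grid_dims) if self.mask is None else np.asarray(self.mask).astype(bool)
        if m.shape != tuple(self.grid_dims):
            raise ValueError("mask shape does not match grid_dims")
        if not m.any():
            raise ValueError("mask is empty")
        return m

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    def centered_gains(self) -> np.ndarray:
        """Learning gains centered within group (so coupling is pure slope)."""
        gains = np.asarray(self.gain_vector, dtype=float)
        groups = np.asarray(self.groups)
        if gains.shape != groups.shape:
            raise ValueError("gain_vector and groups must align")
        out = gains.copy()
        for g in np.unique(groups):
            sel = groups == g
            out[sel] -= gains[sel].mean()
        return out

    def validate(self) -> None:
        if not -1 < self.stability_base < 1:
            raise ValueError("stability_base must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        cg = self.centered_gains()
        groups = np.asarray(self.groups)
        for region in self.effect_regions:
            worst = 0.0
            for g in np.unique(groups):
                c = region.coupling_by_group.get(str(g), region.coupling_by_group.get(g, 0.0))
                sel = groups == g
                if sel.any():
                    worst = max(worst, np.abs(c * cg[sel]).max())
            if abs(self.stability_base) + worst >= 1.0:
                raise ValueError(
                    f"effect region centered at {region.center} drives |rho| >= 1 "
                    f"(base {self.stability_base}, max coupling excursion {worst:.3f})"
                )


def _rho_volume(spec: PlasticitySpec, subject_index: int, mask: np.ndarray) -> np.ndarray:
    cg = spec.centered_gains()
    group = str(np.asarray(spec.groups)[subject_index])
    rho = np.full(spec.grid_dims, spec.stability_base)
    for region in spec.effect_regions:
        c = region.coupling_by_group.get(group, 0.0)
        sel = region.voxels(spec.grid_dims, spec.voxel_size_mm)
        rho[sel] = spec.stability_base - c * cg[subject_index]
    rho = np.clip(rho, -0.99, 0.99)
    rho[~mask] = np.nan
    return rho


def generate_map_pair(
    spec: PlasticitySpec, subject_index: int
) -> tuple[ActivationMapPair, np.ndarray]:
    """One subject's paired pre/post volumes plus the ground-truth rho volume.

    Outside-mask voxels are NaN in all three volumes.  The draw depends only
    on ``(spec.seed, subject_index)``, so cohorts can be generated in any
    order or in parallel.
    """
    spec.validate()
    n = len(np.asarray(spec.gain_vector))
    if not 0 <= subject_index < n:
        raise IndexError(f"subject_index {subject_index} outside 0..{n - 1}")
    mask = spec.resolved_mask()
    rho = _rho_volume(spec, subject_index, mask)

    rng = np.random.default_rng([spec.seed, subject_index])
    pre = rng.standard_normal(spec.grid_dims)
    eps = rng.standard_normal(spec.grid_dims)
    if spec.smooth_fwhm_mm:
        from scipy.ndimage import gaussian_filter

        sigma = spec.smooth_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / spec.voxel_size_mm
        pre = gaussian_filter(pre, sigma)
        eps = gaussian_filter(eps, sigma)
        pre /= pre.std()
        eps /= eps.std()
    pre = spec.noise_sd * pre
    eps = spec.noise_sd * eps
    post = np.where(mask, rho * pre + np.sqrt(1 - rho ** 2) * eps, np.nan)
    pre = np.where(mask, pre, np.nan)
    pair = ActivationMapPair(pre=pre, post=post, mask=mask, affine=spec.affine)
    return pair, rho


def simulate_moderation_cohort(
    n: int = 19,
    b: float = -0.8,
    noise_sd: float = 0.8,
    seed: int = 0,
    rois: Sequence[str] = ("MTL", "IPS", "V1", "wholebrain"),
    moderators: Sequence[str] = ("IS", "circumscribed", "motor"),
    effect_cell: tuple[str, str] = ("IS", "MTL"),
) -> pd.DataFrame:
    """Synthetic subject table for moderation analysis with one causal cell.

    ROI-mean NRP values and moderator scores are independent standard normal
    draws; the learning gain is ``b`` times the centered product of the
    ``effect_cell`` pair plus Gaussian noise.  The default noise SD 0.8 was
    calibrated by simulation to give about 80% power for detecting b = -0.8
    at n = 19 and alpha = 0.05 (the random, heavy-tailed product regressor
    makes the analytic noncentral-t power calculation optimistic here).
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"nrp_{r}": rng.standard_normal(n) for r in rois})
    for m in moderators:
        df[m] = rng.standard_normal(n)
    mod, roi = effect_cell
    x = df[f"nrp_{roi}"] - df[f"nrp_{roi}"].mean()
    z = df[mod] - df[mod].mean()
    df["gain"] = b * x * z + noise_sd * rng.standard_normal(n)
    return df
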