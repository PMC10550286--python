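"""Moderation of the brain-behavior (NRP-learning) relation by clinical scores.

The model asks whether a restricted-and-repetitive-interests/behaviors (RRIB)
subscore - chiefly insistence on sameness (IS) - changes the strength or sign
of the coupling between regional neural representational plasticity (NRP) and
learning gain.  With mean-centered predictors,

    gain_i = b0 + b1 * NRP_i + b2 * M_i + b3 * (NRP_i * M_i) + e_i,

the interaction coefficient b3 is the headline result; its t statistic is
b3/se exactly, with n - 4 residual degrees of freedom.  Simple slopes of gain
on NRP are reported at moderator values of mean +/- 1 SD, and a median split
of the moderator supports the high/low group illustrations common in
reporting (ties at the median go to the low group, deterministically).

A specificity scan refits the model over a moderator x ROI grid (e.g. the
three RRIB components crossed with MTL, IPS, a visual control region, and the
whole brain) to check that moderation is confined to the hypothesized cell.
No multiple-testing correction is applied across the grid by default (a
Bonferroni option is available).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModerationResult",
    "ModerationModel",
    "moderation_fit",
    "median_split",
    "specificity_scan",
]


@dataclass
class ModerationResult:
    """Headline interaction row of a fitted moderation model."""

    b: float
    se: float
    t: float
    p_value: float
    df: int
    n: int
    coefficients: pd.DataFrame
    simple_slopes: pd.DataFrame
    moderator_name: str = "moderator"
    roi_name: str = "nrp"

    def summary(self) -> str:
        lines = [
            f"Moderation of gain ~ {self.roi_name} by {self.moderator_name} "
            f"(n={self.n}, df={self.df})",
            f"  interaction: b={self.b:.4f}, se={self.se:.4f}, "
            f"t={self.t:.3f}, p={self.p_value:.4f}",
            "  coefficients:",
            self.coefficients.to_string(),
            "  simple slopes (gain on NRP at moderator mean +/- 1 SD):",
            self.simple_slopes.to_string(index=False),
        ]
        return "\n".join(lines)

    def plot(self, gain, nrp, moderator, ax=None):  # pragma: no cover - visual
        """Scatter of gain vs NRP colored by median-split moderator group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = median_split(moderator)
        for lab, color in (("low", "tab:blue"), ("high", "tab:red")):
            sel = labels == lab
            ax.scatter(np.asarray(nrp)[sel], np.asarray(gain)[sel],
                       label=f"{lab} {self.moderator_name}", color=color)
            if sel.sum() >= 2:
                z = np.polyfit(np.asarray(nrp)[sel], np.asarray(gain)[sel], 1)
                xs = np.linspace(np.min(nrp), np.max(nrp), 20)
                ax.plot(xs, np.polyval(z, xs), color=color)
        ax.set_xlabel(f"NRP ({self.roi_name})")
        ax.set_ylabel("learning gain")
        ax.legend()
        return ax


class ModerationModel:
    """OLS moderation model of learning gain on ROI NRP x moderator."""

    def __init__(
        self,
        gain: Sequence[float],
        nrp: Sequence[float],
        moderator: Sequence[float],
        moderator_name: str = "moderator",
        roi_name: str = "nrp",
    ) -> None:
        gain = np.asarray(gain, dtype=float)
        nrp = np.asarray(nrp, dtype=float)
        moderator = np.asarray(moderator, dtype=float)
        if not gain.shape == nrp.shape == moderator.shape:
            raise ValueError("gain, nrp and moderator must align")
        n = gain.size
        if n < 8:
            raise ValueError(f"need n >= 8 subjects, got {n}")
        if not (np.all(np.isfinite(gain)) and np.all(np.isfinite(nrp))
                and np.all(np.isfinite(moderator))):
            raise ValueError("all values must be finite")
        if moderator.std() == 0:
            raise ValueError("moderator has zero variance")
        if nrp.std() == 0:
            raise ValueError("NRP predictor has zero variance")
        self.gain, self.nrp, self.moderator = gain, nrp, moderator
        self.moderator_name, self.roi_name = moderator_name, roi_name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gain: str = "gain",
                       nrp: str = "nrp", moderator: str = "moderator") -> "ModerationModel":
        return cls(df[gain], df[nrp], df[moderator],
                   moderator_name=moderator, roi_name=nrp)

    def fit(self) -> ModerationResult:
        x = self.nrp - self.nrp.mean()
        z = self.moderator - self.moderator.mean()
        X = np.column_stack([np.ones_like(x), x, z, x * z])
        cond = np.linalg.cond(X)
        if cond > 1e8:
            raise ValueError(f"collinear predictors (condition number {cond:.2e})")
        names = ["intercept", self.roi_name, self.moderator_name, "interaction"]
        res = sm.OLS(self.gain, X).fit()
        coefs = pd.DataFrame({
            "b": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
        }, index=names)
        sd = z.std(ddof=1)
        slopes = []
        cov = res.cov_params()
        for label, zval in (("low (-1 SD)", -sd), ("high (+1 SD)", sd)):
            slope = res.params[1] + res.params[3] * zval
            var = cov[1, 1] + zval ** 2 * cov[3, 3] + 2 * zval * cov[1, 3]
            slopes.append({"moderator": label, "slope": slope, "se": np.sqrt(var)})
        return ModerationResult(
            b=float(res.params[3]), se=float(res.bse[3]), t=float(res.tvalues[3]),
            p_value=float(res.pvalues[3]), df=int(res.df_resid), n=self.gain.size,
            coefficients=coefs, simple_slopes=pd.DataFrame(slopes),
            moderator_name=self.moderator_name, roi_name=self.roi_name,
        )


def moderation_fit(gain, nrp, moderator, **names) -> ModerationResult:
    """Functional wrapper: fit the moderation model in one call."""
    return ModerationModel(gain, nrp, moderator, **names).fit()


def median_split(scores: Sequence[float]) -> np.ndarray:
    """Label each subject "high" or "low" relative to the sample median.

    Values strictly above the median are "high"; values at or below it are
    "low" (at-median ties go to the low group, deterministically).  Rejects
    fewer than 2 subjects or an all-constant vector.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.all(x == x[0]):
        raise ValueError("all scores identical: median split undefined")
    med = np.median(x)
    return np.where(x > med, "high", "low")


def specificity_scan(
    gain: Sequence[float],
    nrp_by_roi: dict[str, Sequence[float]],
    moderators: dict[str, Sequence[float]],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Full moderator x ROI grid of moderation fits on the same subjects.

    Returns a tidy frame with one row per (moderator, roi) cell carrying the
    interaction b, se, t and p (optionally Bonferroni-adjusted across the
    grid) plus the fitted :class:`ModerationResult` object.
    """
    gain = np.asarray(gain, dtype=float)
    n_cells = len(nrp_by_roi) * len(moderators)
    rows = []
    for mod_name, roi_name in itertools.product(moderators, nrp_by_roi):
        res = ModerationModel(
            gain, nrp_by_roi[roi_name], moderators[mod_name],
            moderator_name=mod_name, roi_name=roi_name,
        ).fit()
        p = min(res.p_value * n_cells, 1.0) if bonferroni else res.p_value
        rows.append({
            "moderator": mod_name, "roi": roi_name, "b": res.b, "se": res.se,
            "t": res.t, "p": p, "result": res,
        })
    return pd.DataFrame(rows)
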