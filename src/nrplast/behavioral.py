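"""Behavioral learning metrics and the statistical battery for a two-group
pre/post training study.

The measures implemented here summarize how children learn a set of practiced
arithmetic problems over five tutoring days and how performance and
problem-solving strategy change between pre- and post-training sessions:

* inverse efficiency score (IES): mean correct-trial reaction time divided by
  accuracy, in ms; lower is better.  Daily IES across training days yields a
  per-child learning rate (OLS slope, ms/day).
* learning gain: proportional pre-to-post change, (post - pre) / pre, applied
  to accuracy (verification task) or reaction time (production task).
* dominant strategy: modal strategy across correctly solved problems, after
  collapsing counting and decomposition into "rule-based" versus memory-based
  "retrieval"; the dominant strategy rate divides the modal count by the full
  problem-set size.

Inference uses classical mixed-design ANOVA (between factor: group; within
factor: session/time) with partial eta squared, two-sample / paired t tests
with Cohen's d, Pearson chi-square on 2x2 strategy tables with the phi
coefficient, and default-prior (JZS) Bayes factors for t designs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "StatResult",
    "inverse_efficiency",
    "learning_rate",
    "percent_gain",
    "dominant_strategy",
    "run_is_valid",
    "mixed_anova",
    "MixedAnovaResults",
    "cohens_d_from_t",
    "partial_eta_squared",
    "chi2_2x2",
    "jzs_bayes_factor",
    "classify_bf",
]

RULE_BASED = frozenset({"counting", "decomposition"})
MEMORY_BASED = frozenset({"retrieval"})


@dataclass(frozen=True)
class StatResult:
    """A single test statistic with df, p, an effect size, and a Bayes factor.

    ``effect_size_name`` is one of ``d`` (t tests), ``np2`` (ANOVA partial eta
    squared) or ``phi`` (2x2 chi-square).  ``bf10`` may be NaN when no Bayes
    factor is defined for the design.
    """

    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float
    effect_size_name: str
    bf10: float = float("nan")

    @property
    def evidence(self) -> str:
        return classify_bf(self.bf10) if np.isfinite(self.bf10) else "unavailable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        dfs = ",".join(f"{d:g}" for d in self.df)
        out = (f"{self.name}: stat({dfs})={self.statistic:.3f}, "
               f"p={self.p_value:.4f}, {self.effect_size_name}={self.effect_size:.3f}")
        if np.isfinite(self.bf10):
            out += f", BF10={self.bf10:.3f} ({self.evidence})"
        return out


def inverse_efficiency(mean_correct_rt: float, accuracy: float) -> float:
    """IES in ms: mean correct-trial RT divided by accuracy.

    Returns NaN (with a warning) when accuracy is zero, in which case the
    subject-day should be excluded upstream.
    """
    if accuracy < 0 or accuracy > 1:
        raise ValueError(f"accuracy must lie in [0, 1], got {accuracy}")
    if mean_correct_rt <= 0:
        raise ValueError(f"mean RT must be positive, got {mean_correct_rt}")
    if accuracy == 0:
        warnings.warn("accuracy is 0: inverse efficiency undefined; flagging as NaN")
        return float("nan")
    return mean_correct_rt / accuracy


def learning_rate(ies_by_day: Sequence[float]) -> float:
    """OLS slope (ms/day) of daily IES on day index 1..n.

    NaN entries are treated as missing days.  Fewer than two valid days gives
    NaN with a warning.
    """
    y = np.asarray(ies_by_day, dtype=float)
    days = np.arange(1, y.size + 1, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        warnings.warn("fewer than 2 valid training days: learning rate undefined")
        return float("nan")
    x, y = days[ok], y[ok]
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def percent_gain(pre: float, post: float) -> float:
    """Proportional change (post - pre) / pre.

    For reaction times a negative gain is a speed-up.  ``pre == 0`` is
    undefined and returns NaN with a warning.
    """
    if pre == 0:
        warnings.warn("pre-training value is 0: percent gain undefined; flagging as NaN")
        return float("nan")
    return (post - pre) / pre


def dominant_strategy(
    codes: Sequence[str],
    n_possible: int = 14,
    tie_rule: Literal["memory", "flag"] = "memory",
) -> tuple[str | None, float]:
    """Modal strategy category over correctly solved problems, and its rate.

    ``codes`` are per-problem strategy labels for correctly solved problems
    only, drawn from {retrieval, counting, decomposition}.  Counting and
    decomposition collapse into "rule-based"; retrieval is "memory-based".
    The rate divides the modal-category count by ``n_possible`` (the full
    problem-set size, 14 per condition by default), not by the number of
    correct problems.

    Ties go to memory-based by default (deterministic); ``tie_rule="flag"``
    returns ``(None, nan)`` instead.  Zero correct problems always returns
    ``(None, nan)`` with a warning.
    """
    known = RULE_BASED | MEMORY_BASED
    bad = set(codes) - known
    if bad:
        raise ValueError(f"unknown strategy codes: {sorted(bad)}")
    if n_possible <= 0:
        raise ValueError("n_possible must be positive")
    if len(codes) > n_possible:
        raise ValueError("more strategy codes than possible problems")
    if len(codes) == 0:
        warnings.warn("no correctly solved problems: dominant strategy undefined")
        return None, float("nan")
    n_mem = sum(c in MEMORY_BASED for c in codes)
    n_rule = len(codes) - n_mem
    if n_mem == n_rule and tie_rule == "flag":
        warnings.warn("tie between memory- and rule-based strategies: flagged")
        return None, float("nan")
    label = "memory-based" if n_mem >= n_rule else "rule-based"
    rate = max(n_mem, n_rule) / n_possible
    return label, rate


def run_is_valid(
    accuracy: float,
    nonresponse_rate: float,
    rule: Literal["any", "all"] = "any",
) -> bool:
    """Task-run validity filter: chance-level accuracy and non-responding.

    A run is invalid when accuracy falls below chance (50%) or when 30% or
    more of trials received no response.  ``rule="any"`` (default) invalidates
    on either criterion; ``rule="all"`` requires both simultaneously.
    """
    bad_acc = accuracy < 0.5
    bad_nr = nonresponse_rate >= 0.3
    return not (bad_acc or bad_nr) if rule == "any" else not (bad_acc and bad_nr)


# ---------------------------------------------------------------------------
# mixed-design ANOVA
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaResults:
    """Per-term results of a two-factor mixed-design ANOVA.

    Terms are the between-subject factor (``group``), the within-subject
    factor (``session``) and their interaction.  Effect sizes are partial eta
    squared from the classical sums-of-squares decomposition.
    """

    terms: dict[str, StatResult] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, term: str) -> StatResult:
        return self.terms[term]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "term": k,
                "F": r.statistic,
                "df1": r.df[0],
                "df2": r.df[1],
                "p": r.p_value,
                "np2": r.effect_size,
            }
            for k, r in self.terms.items()
        ]
        return pd.DataFrame(rows).set_index("term")


def mixed_anova(values: np.ndarray, group: Sequence[str]) -> MixedAnovaResults:
    """Classical mixed-design ANOVA on a complete subjects x sessions matrix.

    ``values`` has one row per subject and one column per within-subject
    session; ``group`` assigns each row to one of exactly two groups.  F tests
    use the classical sums-of-squares decomposition: the group term is tested
    against subjects-within-groups, the session and session-by-group terms
    against the subject-within-group x session error.  Degenerate inputs with
    a zero error term yield F = 0 when the effect is also zero and F = inf
    (p = 0) when it is not.

    Rejects incomplete data and singleton groups; the design must be complete
    within subjects (every subject observed at every session).
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("values must be a subjects x sessions matrix with >= 2 sessions")
    if not np.all(np.isfinite(values)):
        raise ValueError("incomplete data: the mixed ANOVA requires complete cases")
    labels, counts = np.unique(group, return_counts=True)
    if labels.size != 2:
        raise ValueError(f"exactly two groups required, got {labels.tolist()}")
    if counts.min() < 2:
        raise ValueError("singleton group: each group needs >= 2 subjects")

    n, k = values.shape
    grand = values.mean()
    subj_mean = values.mean(axis=1)
    sess_mean = values.mean(axis=0)
    ga, gb = labels
    sel_a = group == ga
    cell_a = values[sel_a].mean(axis=0)
    cell_b = values[~sel_a].mean(axis=0)
    na, nb = counts

    ss_between_subj = k * ((subj_mean - grand) ** 2).sum()
    ss_group = k * (na * (values[sel_a].mean() - grand) ** 2
                    + nb * (values[~sel_a].mean() - grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_session = n * ((sess_mean - grand) ** 2).sum()
    ss_inter = (na * ((cell_a - sess_mean - values[sel_a].mean() + grand) ** 2).sum()
                + nb * ((cell_b - sess_mean - values[~sel_a].mean() + grand) ** 2).sum())
    ss_error = ((values - grand) ** 2).sum() - ss_between_subj - ss_session - ss_inter

    df_group, df_sess = 1, k - 1
    df_subj_within = n - 2
    df_error = df_subj_within * df_sess

    def f_test(term, ss_effect, df1, ss_err, df2):
        ms_err = ss_err / df2
        if ms_err == 0:
            F = 0.0 if ss_effect / df1 == 0 else float("inf")
        else:
            F = (ss_effect / df1) / ms_err
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        np2 = partial_eta_squared(F, df1, df2) if np.isfinite(F) else 1.0
        return StatResult(name=term, statistic=F, df=(float(df1), float(df2)),
                          p_value=p, effect_size=np2, effect_size_name="np2")

    res = MixedAnovaResults(n_per_group=dict(zip(labels.tolist(), counts.tolist())))
    res.terms["group"] = f_test("group", ss_group, df_group, ss_subj_within, df_subj_within)
    res.terms["session"] = f_test("session", ss_session, df_sess, ss_error, df_error)
    res.terms["session*group"] = f_test(
        "session*group", ss_inter, df_group * df_sess, ss_error, df_error)
    return res


# ---------------------------------------------------------------------------
# effect sizes and their identities
# ---------------------------------------------------------------------------

def cohens_d_from_t(t: float, n: int, design: Literal["paired", "one-sample"] = "paired") -> float:
    """Cohen's d from a paired/one-sample t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if design not in ("paired", "one-sample"):
        raise ValueError(f"unknown design {design!r}")
    return t / math.sqrt(n)


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be nonnegative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


def chi2_2x2(table: np.ndarray, correction: bool = False) -> StatResult:
    """Pearson chi-square on a 2x2 contingency table with phi = sqrt(chi2/N).

    Continuity (Yates) correction is off by default.  A zero row or column
    margin leaves the test undefined (raises).
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must contain nonnegative integer counts")
    N = int(table.sum())
    if N == 0:
        raise ValueError("empty table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined for this table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return StatResult(
        name="chi2_2x2", statistic=float(chi2), df=(float(dof),), p_value=float(p),
        effect_size=math.sqrt(chi2 / N), effect_size_name="phi",
    )


# ---------------------------------------------------------------------------
# default (JZS) Bayes factors
# ---------------------------------------------------------------------------

def jzs_bayes_factor(
    t: float,
    n1: int,
    n2: int | None = None,
    rscale: float = math.sqrt(2) / 2,
) -> float:
    """Default-prior (JZS) Bayes factor BF10 for a t statistic.

    The alternative places a Cauchy(0, ``rscale``) prior on the standardized
    effect size delta.  The marginal likelihood under H1 is the noncentral-t
    density integrated over the prior,

        p(t | H1) = \\int nct(t; df, delta * sqrt(n_eff)) Cauchy(delta; rscale) d delta,

    and BF10 = p(t | H1) / t(t; df).  For a one-sample or paired design
    (``n2 is None``) df = n1 - 1 and n_eff = n1; for an independent-samples
    design df = n1 + n2 - 2 and n_eff = n1*n2/(n1+n2).

    Values above 1 favor the effect; see :func:`classify_bf` for the
    conventional evidence bands.
    """
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("group sizes must be >= 2")
    if rscale <= 0:
        raise ValueError("prior scale must be positive")
    if n2 is None:
        df, n_eff = n1 - 1, float(n1)
    else:
        df, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    root_n = math.sqrt(n_eff)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, nc=delta * root_n) * stats.cauchy.pdf(delta, 0.0, rscale)

    num, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    if num <= 0 or not np.isfinite(num) or (num > 0 and err / num > 1e-6):
        raise RuntimeError(
            f"JZS quadrature failed to converge (value={num}, abs err={err}, rel tol 1e-6)"
        )
    return num / stats.t.pdf(t, df)


_BF_BANDS = (
    (10.0, "strong H1"),
    (3.0, "moderate H1"),
    (1 / 3, "insufficient"),
    (0.10, "moderate H0"),
)


def classify_bf(bf10: float) -> str:
    """Conventional evidence band for a Bayes factor BF10.

    >10 strong evidence for H1; 3-10 moderate H1; 0.33-3 insufficient;
    0.10-0.33 moderate evidence of absence; <0.10 strong evidence of absence.
    """
    if not (bf10 > 0):
        raise ValueError("BF10 must be positive")
    for cut, label in _BF_BANDS:
        if bf10 > cut:
            return label
    return "strong H0"
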