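"""Independent reference implementations used only as test oracles.

These deliberately use the most transparent formulation available (explicit
loops, textbook sums-of-squares, alternative integral forms) and stay
independent of the package's optimized code paths.
"""

import numpy as np
from scipy import integrate, special

from nrplast.nrp import MIN_NEIGHBORHOOD, nrp_at_voxel, sphere_neighborhood


def naive_searchlight(pre, post, mask, affine, radius_mm=6.0):
    """Triple-loop searchlight: per-voxel neighborhood gather + patch NRP."""
    out = np.full(mask.shape, np.nan)
    for idx in np.ndindex(*mask.shape):
        if not mask[idx]:
            continue
        nb = sphere_neighborhood(idx, radius_mm, mask, affine)
        if nb.shape[0] < MIN_NEIGHBORHOOD:
            continue
        sel = tuple(nb.T)
        out[idx] = nrp_at_voxel(pre[sel], post[sel])
    return out


def mixed_anova_ss(values, group):
    """Textbook sums-of-squares decomposition for a two-factor mixed design.

    Returns F statistics (group, session, interaction).  Group uses the
    between-subject error (subjects within groups); session and interaction
    use the subject-within-group x session error.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    n, k = values.shape
    grand = values.mean()
    subj_m = values.mean(axis=1)
    sess_m = values.mean(axis=0)
    groups = np.unique(group)
    grp_m = {g: values[group == g].mean() for g in groups}
    ng = {g: int((group == g).sum()) for g in groups}

    ss_between_subj = k * ((subj_m - grand) ** 2).sum()
    ss_group = k * sum(ng[g] * (grp_m[g] - grand) ** 2 for g in groups)
    ss_subj_within = ss_between_subj - ss_group
    ss_sess = n * ((sess_m - grand) ** 2).sum()
    cell = {g: values[group == g].mean(axis=0) for g in groups}
    ss_inter = sum(
        ng[g] * ((cell[g] - sess_m - grp_m[g] + grand) ** 2).sum() for g in groups)
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_sess - ss_inter

    df_g, df_s = len(groups) - 1, k - 1
    df_sw = n - len(groups)
    df_err = df_sw * df_s
    F_group = (ss_group / df_g) / (ss_subj_within / df_sw)
    F_sess = (ss_sess / df_s) / (ss_err / df_err)
    F_inter = (ss_inter / (df_g * df_s)) / (ss_err / df_err)
    return F_group, F_sess, F_inter


def jzs_bf_g_integral(t, n1, n2=None, rscale=np.sqrt(2) / 2):
    """JZS BF10 via the variance-inflation (g-prior) integral.

    Integrates over the auxiliary scale g with delta | g ~ N(0, g), g ~
    InverseGamma(1/2, rscale^2/2), the classical alternative route to the
    same Bayes factor (the package integrates the Cauchy prior directly).
    """
    if n2 is None:
        df, neff = n1 - 1, float(n1)
    else:
        df, neff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    r2 = rscale ** 2

    def h1_density(g):
        # marginal density of t under H1 given g, times the IG(1/2, r2/2) prior
        c = 1.0 / np.sqrt(1 + neff * g)
        kern = (1 + t * t * c * c / df) ** (-(df + 1) / 2)
        prior = (r2 / 2) ** 0.5 / special.gamma(0.5) * g ** (-1.5) * np.exp(-r2 / (2 * g))
        return c * kern * prior

    num, _ = integrate.quad(h1_density, 0, np.inf, limit=300)
    den = (1 + t * t / df) ** (-(df + 1) / 2)
    return num / den
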