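"""Outlier detection for temporal signal and per-branch model fit.

Three complementary checks run before/after dating:

* root-to-tip regression of tip divergence on sampling date, with a 95%
  expected envelope (Poisson around the fitted line) flagging aberrant tips;
* a date-randomization permutation test of the temporal signal; and
* a per-branch test comparing each observed substitution count with its
  distribution under the fitted clock model (two-sided tail probability,
  Benjamini-Hochberg corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clock import branch_cdf
from .phylo import ValidationError, match_branches, matched_branch_values

__all__ = [
    "RTTFit",
    "EnvelopeReport",
    "OutlierReport",
    "root_to_tip_regression",
    "rtt_envelope",
    "date_randomization_test",
    "branch_outlier_test",
]


@dataclass
class RTTFit:
    """Ordinary least squares of root-to-tip distance on sampling date."""

    slope: float  # substitutions per year
    intercept: float
    r2: float
    x_intercept: float  # implied root date
    tip_labels: list
    dates: np.ndarray
    distances: np.ndarray


@dataclass
class EnvelopeReport:
    """Central expected interval of root-to-tip distance for each tip."""

    level: float
    lower: np.ndarray
    upper: np.ndarray
    flags: np.ndarray  # boolean per tip

    @property
    def flagged_tips(self):
        return list(np.flatnonzero(self.flags))


@dataclass
class OutlierReport:
    """Per-unit raw p-values and BH-adjusted q-values with flags at q < alpha."""

    branch: np.ndarray  # child node index in D
    tip_label: list  # tip label for terminal branches, else None
    pvalue: np.ndarray
    qvalue: np.ndarray
    alpha: float = 0.05

    @property
    def flags(self):
        return self.qvalue < self.alpha

    @property
    def flagged_tips(self):
        return [lab for lab, f in zip(self.tip_label, self.flags) if f and lab]


def root_to_tip_regression(L, dates):
    """Fit distance-to-root against sampling date for every tip of ``L``."""
    if L.n_tips < 3:
        raise ValidationError("root-to-tip regression needs at least 3 tips")
    missing = [lab for lab in L.tip_labels if lab not in dates]
    if missing:
        raise ValidationError(f"missing dates for tips: {missing[:5]}")
    x = np.array([dates[lab] for lab in L.tip_labels])
    if np.ptp(x) == 0:
        raise ValidationError("all sampling dates identical: no temporal signal testable")
    y = L.depths()[: L.n_tips]
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    x_int = -intercept / slope if slope > 0 else np.nan
    return RTTFit(
        slope=slope,
        intercept=intercept,
        r2=float(fit.rvalue**2),
        x_intercept=x_int,
        tip_labels=list(L.tip_labels),
        dates=x,
        distances=y,
    )


def rtt_envelope(fit, level=0.95):
    """Expected envelope of root-to-tip distances around the regression line.

    The envelope is the central ``level`` interval of a Poisson with mean
    ``slope * (date - x_intercept)`` (the strict-clock expectation); tips
    whose observed distance falls outside are flagged.
    """
    if not fit.slope > 0:
        raise ValidationError("envelope requires a positive fitted slope")
    mu = np.maximum(fit.slope * (fit.dates - fit.x_intercept), 0.0)
    a = (1.0 - level) / 2.0
    lower = stats.poisson.ppf(a, mu)
    upper = stats.poisson.ppf(1.0 - a, mu)
    lower = np.where(mu > 0, lower, 0.0)
    flags = (fit.distances < lower) | (fit.distances > upper)
    return EnvelopeReport(level=level, lower=lower, upper=upper, flags=flags)


def date_randomization_test(L, dates, n_permutations=10000, rng=None, statistic="r2"):
    """Permutation test of temporal signal by shuffling tip dates.

    ``p = (1 + #{permuted stat >= observed stat}) / (B + 1)`` where the
    statistic is the regression R-squared (or the slope with
    ``statistic='slope'``).
    """
    if n_permutations < 100:
        raise ValidationError("need at least 100 permutations")
    if rng is None:
        rng = np.random.default_rng()
    fit = root_to_tip_regression(L, dates)
    y = fit.distances - fit.distances.mean()
    x = fit.dates
    perms = rng.permuted(np.tile(x, (n_permutations, 1)), axis=1)
    perms = perms - perms.mean(axis=1, keepdims=True)
    ny = np.sqrt((y**2).sum())
    nx = np.sqrt((perms**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (perms @ y) / (nx * ny)
    r = np.nan_to_num(r)
    if statistic == "r2":
        obs, sim = fit.r2, r**2
    elif statistic == "slope":
        obs = fit.slope
        sim = r * ny / nx
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")
    if not np.isfinite(obs):
        obs = 0.0
    return float((1 + np.sum(sim >= obs)) / (n_permutations + 1))


def branch_outlier_test(D, L, m, alpha=0.05, correspondence=None):
    """Two-sided per-branch tail test of substitution counts under ``m``.

    Discrete families use ``p = 2 min(P(L <= l), P(L >= l))``; continuous
    (and root-split non-integer) values use ``2 min(F(l), 1 - F(l))``.
    q-values are Benjamini-Hochberg adjusted; flags are at q < ``alpha``.
    """
    corr = correspondence if correspondence is not None else match_branches(D, L)
    d_nodes, d_vals, l_vals = matched_branch_values(D, L, corr)
    is_int = np.isclose(l_vals, np.round(l_vals), atol=1e-9)
    p = np.empty(len(l_vals))
    if m.discrete:
        lo = branch_cdf(m, l_vals, d_vals)
        ge = 1.0 - branch_cdf(m, l_vals - 1.0, d_vals)
        p_disc = 2.0 * np.minimum(lo, ge)
        mc = m.continuous_counterpart()
        F = branch_cdf(mc, l_vals, d_vals)
        p_cont = 2.0 * np.minimum(F, 1.0 - F)
        p = np.where(is_int, p_disc, p_cont)
    else:
        F = branch_cdf(m, l_vals, d_vals)
        p = 2.0 * np.minimum(F, 1.0 - F)
    p = np.minimum(p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    labels = [D.tip_labels[v] if D.is_tip(v) else None for v in d_nodes]
    return OutlierReport(branch=d_nodes, tip_label=labels, pvalue=p, qvalue=q, alpha=alpha)
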