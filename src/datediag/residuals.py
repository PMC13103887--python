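"""Per-branch residuals of a dated phylogeny and the Anderson-Darling test.

Given a dated tree D (branch durations ``d_i``), the undated tree L it was
inferred from (substitutions ``l_i``), and the clock model used for the
inference, each branch yields a *uniform residual*

    u_i = F_i(l_i) = P(L_i <= l_i | d_i),

which is Uniform(0,1) when the model is correct (probability integral
transform).  For the discrete clock models the transform is randomized:
u_i is drawn uniformly on the probability interval of the observed count,

    u_i ~ Uniform(P(L_i <= l_i - 1), P(L_i <= l_i)),

which restores exact uniformity.  The *normal residual* is
``n_i = ndtri(u_i)``, standard normal under a correct model, and normality is
assessed with the Anderson-Darling simple-hypothesis test against N(0,1)
(equivalently, of the u_i against Uniform(0,1)); the p-value uses the
asymptotic null distribution of Marsaglia & Marsaglia (2004).

The substitutions on the branch spanning the root of L are divided between
the two root-adjacent branches of D in proportion to their durations before
residuals are computed; the resulting (generally non-integer) values are
scored under the same-moment continuous model.

Because the dated tree is usually a posterior sample, the whole analysis is
repeated for every retained draw, giving a posterior distribution of
p-values summarized by its median and the proportion below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .clock import branch_cdf
from .phylo import ValidationError, match_branches, matched_branch_values

__all__ = [
    "ResidualSet",
    "PosteriorPvalues",
    "uniform_residual",
    "normal_residual",
    "tree_residuals",
    "ad_statistic",
    "ad_test_normal01",
    "posterior_residual_pvalues",
]

_CLIP = 1e-12


@dataclass
class ResidualSet:
    """Per-branch uniform and normal residuals with the AD test result."""

    branch: np.ndarray  # child-node index in D of each branch
    u: np.ndarray
    n: np.ndarray
    A2: float
    pvalue: float

    def __len__(self):
        return len(self.u)


@dataclass
class PosteriorPvalues:
    """AD p-values across posterior draws with the two reported summaries."""

    pvalues: np.ndarray

    @property
    def median(self):
        return float(np.median(self.pvalues))

    @property
    def prop_below_05(self):
        return float(np.mean(self.pvalues < 0.05))


def uniform_residual(m, l, d, rng):
    """Randomized-PIT uniform residuals; vectorized over branches.

    Continuous families return F(l) directly; discrete families draw
    uniformly on (F(l-1), F(l)).  Values are clipped away from 0 and 1 so the
    normal quantile stays finite.
    """
    l = np.asarray(l, dtype=float)
    d = np.asarray(d, dtype=float)
    l, d = np.broadcast_arrays(l, d)
    scalar = l.ndim == 0
    l, d = np.atleast_1d(l), np.atleast_1d(d)
    u = np.empty(l.shape)
    is_int = np.isclose(l, np.round(l), atol=1e-9)
    if m.discrete:
        disc = is_int
        if np.any(disc):
            hi = branch_cdf(m, l[disc], d[disc])
            lo = branch_cdf(m, l[disc] - 1.0, d[disc])
            u[disc] = lo + rng.uniform(size=int(disc.sum())) * (hi - lo)
        if np.any(~disc):
            mc = m.continuous_counterpart()
            u[~disc] = branch_cdf(mc, l[~disc], d[~disc])
    else:
        u[:] = branch_cdf(m, l, d)
        # continuous model, zero duration: degenerate at l = 0 -> randomize
        zero = (d == 0) & (l == 0)
        if np.any(zero):
            u[zero] = rng.uniform(size=int(zero.sum()))
    u = np.clip(u, _CLIP, 1.0 - _CLIP)
    return float(u[0]) if scalar else u


def normal_residual(u):
    """Standard-normal quantile of a uniform residual."""
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValidationError("uniform residuals must lie strictly in (0, 1)")
    out = special.ndtri(u)
    return float(out) if out.ndim == 0 else out


def tree_residuals(D, L, m, rng, correspondence=None):
    """Residuals for every branch of D against the matched branches of L."""
    corr = correspondence if correspondence is not None else match_branches(D, L)
    d_nodes, d_vals, l_vals = matched_branch_values(D, L, corr)
    u = uniform_residual(m, l_vals, d_vals, rng)
    n = normal_residual(u)
    A2, p = ad_test_normal01(n)
    return ResidualSet(branch=d_nodes, u=u, n=n, A2=A2, pvalue=p)


# ---------------------------------------------------------------------------
# Anderson-Darling simple-hypothesis test
# ---------------------------------------------------------------------------

def _adinf(z):
    """Asymptotic CDF of the Anderson-Darling statistic under the null
    (Marsaglia & Marsaglia 2004, without the finite-n correction)."""
    if z <= 0:
        return 0.0
    if z < 2.0:
        return (
            z ** -0.5
            * np.exp(-1.2337141 / z)
            * (
                2.00012
                + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z) * z) * z) * z) * z
            )
        )
    return np.exp(
        -np.exp(1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z) * z)
    )


def ad_statistic(z):
    """A-squared of sorted probabilities ``z`` against Uniform(0,1)."""
    z = np.sort(np.clip(np.asarray(z, dtype=float), _CLIP, 1.0 - _CLIP))
    k = len(z)
    i = np.arange(1, k + 1)
    return float(-k - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1]))))


def ad_test_normal01(n):
    """Anderson-Darling test of residuals ``n`` against Normal(0,1).

    Returns ``(A2, p)``.  Identical to testing the uniform residuals
    ``u = Phi(n)`` against Uniform(0,1).  Small samples (< 8) are allowed but
    the asymptotic p-value is then only indicative.
    """
    n = np.asarray(n, dtype=float)
    if len(n) < 1:
        raise ValidationError("need at least one residual")
    z = special.ndtr(n)
    A2 = ad_statistic(z)
    p = float(np.clip(1.0 - _adinf(A2), 0.0, 1.0))
    return A2, p


def plot_residual_diagnostics(res, path_prefix):
    """Histogram of normal residuals against N(0,1) and a QQ plot.

    Writes ``<prefix>.hist.png`` and ``<prefix>.qq.png``; returns the paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist_path = f"{path_prefix}.hist.png"
    qq_path = f"{path_prefix}.qq.png"
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(res.n, bins=30, density=True, color="#7fa6c9", edgecolor="white")
    grid = np.linspace(-4, 4, 200)
    ax.plot(grid, np.exp(-grid**2 / 2) / np.sqrt(2 * np.pi), "k-", lw=1.5)
    ax.set_xlabel("normal residual")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(hist_path, dpi=120)
    plt.close(fig)

    k = len(res.n)
    theo = special.ndtri((np.arange(1, k + 1) - 0.5) / k)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(theo, np.sort(res.n), "o", ms=3, color="#7fa6c9")
    lim = [min(theo.min(), res.n.min()), max(theo.max(), res.n.max())]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel("theoretical N(0,1) quantiles")
    ax.set_ylabel("observed residual quantiles")
    fig.tight_layout()
    fig.savefig(qq_path, dpi=120)
    plt.close(fig)
    return hist_path, qq_path


def posterior_residual_pvalues(posterior, L, rng, max_draws=1000, correspondence=None):
    """AD residual p-value for every posterior draw.

    Each draw's own dated tree and clock parameters are used, with an
    independent randomization of the discrete residuals, giving the posterior
    distribution of p-values.  At most ``max_draws`` draws are used
    (subsampled evenly).
    """
    post = posterior.subsample(max_draws)
    corr = correspondence
    if corr is None:
        corr = match_branches(post.trees[0], L)
    pvals = np.empty(len(post))
    for i, tree in enumerate(post.trees):
        res = tree_residuals(tree, L, post.model(i), rng, correspondence=corr)
        pvals[i] = res.pvalue
    return PosteriorPvalues(pvalues=pvals)
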