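"""Bayesian dating of a phylogeny and pseudo-posterior sampling.

A minimal Metropolis-Hastings engine that, given a rooted undated tree (branch
lengths in substitutions) and tip sampling dates, samples dated trees together
with the clock rate ``mu``, relaxation ``omega`` (relaxed models) and the
coalescent population-size parameter ``Ne`` from

    posterior  ∝  coalescent(D | Ne) × clock(L | D, mu, omega) × priors.

The tree prior is the heterochronous coalescent with constant population
size: with ``k`` lineages active on an inter-event interval of length ``dt``
the log-density contributes ``-k(k-1) dt / (2 Ne)``, and each of the ``n-1``
coalescences contributes ``-log Ne``.

The module also provides closed-form estimators (``mu_hat = sum l / sum d``;
the coalescent-rate estimator from the lineage-count curve), DIC model
comparison, an ML-style dating routine, the conjugate
Gamma-Poisson toy model that motivates pseudo-posterior sampling, and the
pseudo-posterior sampler itself: a short constrained MCMC over node dates
centered on a point-estimate dated tree, which restores the dispersion that
residual diagnostics need when only a point estimate is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .clock import ClockModel, branch_logprob
from .outliers import root_to_tip_regression
from .phylo import (
    DatedTree,
    UndatedTree,
    ValidationError,
    match_branches,
    matched_branch_values,
)
from .posterior import PosteriorSample

__all__ = [
    "LineageCountCurve",
    "coalescent_loglik",
    "clock_loglik",
    "mcmc_date",
    "dic",
    "mle_mu",
    "mle_alpha",
    "alpha_posterior_sample",
    "ml_date",
    "pseudo_posterior",
    "conjugate_toy",
]


# ---------------------------------------------------------------------------
# Coalescent prior
# ---------------------------------------------------------------------------

@dataclass
class LineageCountCurve:
    """Sorted node dates of a dated tree and the lineage count per interval.

    ``times`` is sorted most-recent-first; ``counts[i]`` is the number of
    lineages on the interval ``(times[i+1], times[i])``.  ``pair_time`` is
    ``sum_i counts_i (counts_i - 1) (times_i - times_{i+1})``, the total
    coalescent opportunity that drives both the likelihood and the
    estimator of the coalescent rate.
    """

    times: np.ndarray
    counts: np.ndarray
    n_tips: int

    @property
    def pair_time(self):
        dt = -np.diff(self.times)
        k = self.counts[:-1].astype(float)
        return float(np.sum(k * (k - 1.0) * dt))

    @classmethod
    def from_tree(cls, D):
        return cls.from_dates(D.dates, D.n_tips)

    @classmethod
    def from_dates(cls, dates, n_tips):
        dates = np.asarray(dates, dtype=float)
        is_tip = np.zeros(len(dates), dtype=bool)
        is_tip[:n_tips] = True
        order = np.argsort(-dates, kind="stable")
        step = np.where(is_tip[order], 1, -1)
        counts = np.cumsum(step)
        return cls(times=dates[order], counts=counts, n_tips=n_tips)


def _pair_time(dates, n_tips):
    return LineageCountCurve.from_dates(dates, n_tips).pair_time


def coalescent_loglik(D_or_dates, ne, n_tips=None):
    """Log-density of a dated tree under the constant-Ne heterochronous
    coalescent: ``-pair_time/(2 Ne) - (n-1) log Ne``."""
    if not ne > 0:
        raise ValidationError("Ne must be positive")
    if isinstance(D_or_dates, DatedTree):
        dates, n_tips = D_or_dates.dates, D_or_dates.n_tips
    else:
        dates = np.asarray(D_or_dates, dtype=float)
        if n_tips is None:
            raise ValidationError("n_tips required when passing raw dates")
    I = _pair_time(dates, n_tips)
    return -I / (2.0 * ne) - (n_tips - 1) * math.log(ne)


def mle_alpha(D):
    """Maximum-likelihood coalescent rate ``pair_time / (2(n-1))``."""
    if D.n_tips < 2:
        raise ValidationError("need at least 2 tips")
    return LineageCountCurve.from_tree(D).pair_time / (2.0 * (D.n_tips - 1))


def alpha_posterior_sample(D, rng, size=None):
    """Posterior draws of the coalescent rate under the improper InvGamma
    prior: ``1/alpha ~ Gamma(shape n-1, rate pair_time/2)``."""
    if D.n_tips < 2:
        raise ValidationError("need at least 2 tips")
    rate = LineageCountCurve.from_tree(D).pair_time / 2.0
    g = rng.gamma(shape=D.n_tips - 1, scale=1.0 / rate, size=size)
    return 1.0 / g


# ---------------------------------------------------------------------------
# Clock likelihood
# ---------------------------------------------------------------------------

def clock_loglik(D, L, m, correspondence=None):
    """Sum of branch log-probabilities over all matched branches of D.

    The root-spanning substitutions of L are split proportionally between the
    two root-adjacent branches of D before evaluation.
    """
    _, d_vals, l_vals = matched_branch_values(D, L, correspondence)
    return float(np.sum(branch_logprob(m, l_vals, d_vals)))


class _ClockEval:
    """Fast repeated clock-likelihood evaluation on a fixed tree pair.

    Branch substitution values are fixed; durations, ``mu`` and ``omega``
    vary across MCMC proposals.  The two root-adjacent branches carry the
    proportional split of the root-spanning substitutions (scored by the
    discrete mass when the split is integer, e.g. a zero root count, and by
    the same-moment continuous density otherwise).
    """

    def __init__(self, L, corr, family, censor_below=None):
        self.family = family
        self.a, self.b = corr.root_a, corr.root_b
        self.l_x = corr.root_x_subs
        self.d_nodes = np.array([p[0] for p in corr.pairs], dtype=np.int64)
        self.l_nodes = np.array([p[1] for p in corr.pairs], dtype=np.int64)
        self.l = L.lengths[self.l_nodes]
        self.l_int = np.isclose(self.l, np.round(self.l), atol=1e-9)
        self.l_round = np.round(self.l)
        self.lgam_l1 = special.gammaln(self.l_round + 1.0)
        # continuous-model branches below this value are left-censored at it
        # (an exact zero has zero density for any positive duration)
        self.censor_below = censor_below
        self.cens = (
            self.l < censor_below if censor_below is not None else np.zeros(len(self.l), bool)
        )

    def loglik(self, dates, parent, mu, omega):
        d = dates[self.d_nodes] - dates[parent[self.d_nodes]]
        d_a = dates[self.a] - dates[parent[self.a]]
        d_b = dates[self.b] - dates[parent[self.b]]
        tot = d_a + d_b
        if tot > 0:
            la = self.l_x * d_a / tot
            lb = self.l_x - la
        else:
            la = lb = 0.5 * self.l_x
        fam = self.family
        if fam == "negbin" and omega == 0:
            fam = "poisson"
        if fam == "argamma" and omega == 0:
            fam = "gamma"
        root = _root_logprob(fam, (la, lb), (d_a, d_b), mu, omega)
        if fam == "poisson":
            lam = d * mu
            main = special.xlogy(self.l_round, lam) - lam - self.lgam_l1
            bad = ~self.l_int
            if np.any(bad):
                main[bad] = _gamma_logpdf(self.l[bad], d[bad] * mu, 1.0)
        elif fam == "negbin":
            r = d * mu / omega
            p = 1.0 / (1.0 + omega)
            with np.errstate(divide="ignore", invalid="ignore"):
                main = (
                    special.gammaln(self.l_round + r)
                    - special.gammaln(r)
                    - self.lgam_l1
                    + r * math.log(p)
                    + self.l_round * math.log(omega * p)
                )
            main[(d <= 0) & (self.l_round == 0)] = 0.0
            main[(d <= 0) & (self.l_round > 0)] = -np.inf
            bad = ~self.l_int
            if np.any(bad):
                main[bad] = _gamma_logpdf(
                    self.l[bad], d[bad] * mu / (1.0 + omega), 1.0 + omega
                )
        elif fam == "gamma":
            main = _gamma_logpdf(self.l, d * mu, 1.0)
            if np.any(self.cens):
                # zero-count branches carry the discrete counterpart's
                # point mass at zero: exp(-d mu)
                main[self.cens] = -d[self.cens] * mu
        else:  # argamma
            s = 1.0 + omega
            main = _gamma_logpdf(self.l, d * mu / s, s)
            if np.any(self.cens):
                main[self.cens] = -(d[self.cens] * mu / omega) * math.log(s)
        return float(main.sum() + root.sum())


def _root_logprob(fam, lr, dr, mu, omega):
    """Log-probability of the two root-adjacent branches given the split
    values; integer splits under a discrete family (notably a zero
    root-spanning count) use the discrete mass, others the same-moment
    continuous density."""
    out = np.empty(2)
    for i in range(2):
        l, d = float(lr[i]), float(dr[i])
        if d <= 0:
            out[i] = 0.0 if l == 0 else -np.inf
            continue
        k = round(l)
        if fam in ("poisson", "negbin") and abs(l - k) < 1e-9:
            if fam == "poisson":
                out[i] = float(
                    special.xlogy(k, d * mu) - d * mu - special.gammaln(k + 1)
                )
            else:
                r = d * mu / omega
                p = 1.0 / (1.0 + omega)
                out[i] = float(
                    special.gammaln(k + r)
                    - special.gammaln(r)
                    - special.gammaln(k + 1)
                    + r * math.log(p)
                    + k * math.log(omega * p)
                )
        elif fam in ("poisson", "gamma"):
            out[i] = _gamma_logpdf(np.array([l]), d * mu, 1.0)[0]
        else:
            s = 1.0 + omega
            out[i] = _gamma_logpdf(np.array([l]), d * mu / s, s)[0]
    return out


def _gamma_logpdf(l, shape, scale):
    """Gamma(shape, scale) log-density; point mass at 0 when shape == 0."""
    l = np.asarray(l, dtype=float)
    shape = np.broadcast_to(np.asarray(shape, dtype=float), l.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            special.xlogy(shape - 1.0, l)
            - l / scale
            - shape * math.log(scale)
            - special.gammaln(shape)
        )
    zero_shape = shape <= 0
    if np.any(zero_shape):
        out = np.where(zero_shape & (l == 0), 0.0, out)
        out = np.where(zero_shape & (l > 0), -np.inf, out)
    return out


# ---------------------------------------------------------------------------
# Closed-form estimators and the conjugate toy model
# ---------------------------------------------------------------------------

def mle_mu(L, D, correspondence=None):
    """Clock-rate estimator ``sum_i l_i / sum_i d_i`` over matched branches."""
    _, d_vals, l_vals = matched_branch_values(D, L, correspondence)
    tot_d = d_vals.sum()
    if not tot_d > 0:
        raise ValidationError("total branch duration is zero")
    return float(l_vals.sum() / tot_d)


def conjugate_toy(k, theta, mu, l):
    """Posterior of a branch duration in the i.i.d. Gamma-Poisson toy model.

    Prior ``d ~ Gamma(k, theta)``, likelihood ``l ~ Poisson(d mu)``; the
    posterior is ``Gamma(k + l, theta / (1 + theta mu))`` (shape, scale).
    """
    if not (k > 0 and theta > 0 and mu > 0):
        raise ValidationError("k, theta, mu must be positive")
    if l < 0 or l != int(l):
        raise ValidationError("l must be a non-negative integer")
    return k + l, theta / (1.0 + theta * mu)


# ---------------------------------------------------------------------------
# MCMC engine
# ---------------------------------------------------------------------------

def _apply_fixed_root(L, state_dates, t_root):
    """Pin the root date and move every internal date strictly inside its
    feasible interval (parent date, youngest tip below it)."""
    state_dates[L.root] = t_root
    sub_min = np.full(L.n_nodes, np.inf)
    for v in L.postorder():
        if L.is_tip(v):
            sub_min[v] = state_dates[v]
        else:
            sub_min[v] = min(sub_min[c] for c in L.children[v])
    for v in reversed(L.postorder()):  # preorder
        if L.is_tip(v) or L.parent[v] < 0:
            continue
        lo, hi = state_dates[L.parent[v]], sub_min[v]
        if not (lo < state_dates[v] < hi):
            state_dates[v] = lo + 0.05 * (hi - lo)


def _init_dates(L, tip_dates, mu0):
    """Initial node dates: each internal node slightly older than the dates
    its children's substitution counts imply at rate ``mu0``."""
    n = L.n_nodes
    dates = np.empty(n)
    dates[: L.n_tips] = tip_dates
    for v in L.postorder():
        if not L.is_tip(v):
            dates[v] = min(
                dates[c] - max(L.lengths[c], 0.5) / mu0 for c in L.children[v]
            )
    return dates


def mcmc_date(
    L,
    dates,
    model,
    iters=200_000,
    burnin=None,
    thin_to=1000,
    rng=None,
    fixed=None,
    init_dates=None,
    p_node=0.9,
    censor_below=None,
):
    """Sample dated trees and parameters by Metropolis-Hastings.

    Parameters
    ----------
    L : UndatedTree
        Rooted tree with substitution-scaled branch lengths; the topology is
        fixed throughout.
    dates : dict
        Tip label -> sampling date (decimal years).
    model : ClockModel
        Clock family for the likelihood; its ``mu``/``omega`` serve as
        starting values when not estimated from the data.
    iters : int
        Total number of single-variable proposals.
    burnin : int
        Discarded prefix (default ``iters // 2``).
    thin_to : int
        Maximum number of retained draws (evenly spaced).
    fixed : dict
        Any of ``root_date``, ``mu``, ``omega``, ``ne`` mapped to the value
        at which to hold them.
    init_dates : array, optional
        Starting node dates (e.g. from a point estimate).

    Priors: ``mu ~ Exponential(mean = root-to-tip slope)``,
    ``omega ~ Exponential(1)``, improper ``1/Ne`` on ``Ne``.  Proposal step
    sizes adapt toward ~25% acceptance during burn-in and are frozen after.
    """
    if rng is None:
        rng = np.random.default_rng()
    fixed = dict(fixed or {})
    burnin = iters // 2 if burnin is None else burnin
    n = L.n_nodes
    tip_dates = np.array([dates[lab] for lab in L.tip_labels])

    # initialization
    try:
        slope = root_to_tip_regression(L, dates).slope
    except ValidationError:
        slope = np.nan
    mu0 = slope if np.isfinite(slope) and slope > 1e-6 else max(
        L.lengths[np.flatnonzero(L.parent >= 0)].mean(), 1e-6
    )
    mu_prior_mean = max(mu0, 1e-6)
    state_dates = (
        np.asarray(init_dates, dtype=float).copy()
        if init_dates is not None
        else _init_dates(L, tip_dates, mu0)
    )
    parent = L.parent
    children = L.children
    root = L.root
    if "root_date" in fixed:
        t_root = float(fixed["root_date"])
        if t_root >= tip_dates.min():
            raise ValidationError("fixed root date must predate all tip dates")
        _apply_fixed_root(L, state_dates, t_root)

    D0 = DatedTree(parent, state_dates, L.tip_labels)
    corr = match_branches(D0, L)
    ev = _ClockEval(L, corr, model.family, censor_below=censor_below)

    mu = float(fixed.get("mu", model.mu if model.mu else mu0))
    if "mu" not in fixed:
        # moment-matched start from the initialized tree
        tot_d = np.sum(state_dates[parent >= 0] - state_dates[parent[parent >= 0]])
        tot_l = np.sum(L.lengths[parent >= 0])
        if tot_d > 0 and tot_l > 0:
            mu = tot_l / tot_d
    relaxed = model.relaxed
    omega = float(fixed.get("omega", model.omega if relaxed else 0.0)) if relaxed else 0.0
    if relaxed and "omega" not in fixed and (model.omega is None or model.omega == 0):
        omega = 1.0
    ne = float(fixed.get("ne", _pair_time(state_dates, L.n_tips) / (2.0 * (L.n_tips - 1))))
    ne = max(ne, 1e-9)

    def log_prior(mu_, omega_, ne_):
        lp = -mu_ / mu_prior_mean - math.log(mu_prior_mean)
        if relaxed:
            lp += -omega_
        lp += -math.log(ne_)
        return lp

    clock_ll = ev.loglik(state_dates, parent, mu, omega)
    I = _pair_time(state_dates, L.n_tips)
    attempts = 0
    while not np.isfinite(clock_ll):
        attempts += 1
        if attempts > 100:
            raise ValidationError("could not find a finite starting likelihood")
        mu0 *= 2.0
        state_dates = _init_dates(L, tip_dates, mu0)
        if "root_date" in fixed:
            _apply_fixed_root(L, state_dates, float(fixed["root_date"]))
        clock_ll = ev.loglik(state_dates, parent, mu, omega)
        I = _pair_time(state_dates, L.n_tips)

    def coal_ll(I_, ne_):
        return -I_ / (2.0 * ne_) - (L.n_tips - 1) * math.log(ne_)

    internal = [v for v in range(n) if not L.is_tip(v)]
    if "root_date" in fixed:
        movable = [v for v in internal if v != root]
    else:
        movable = internal
    movable = np.array(movable, dtype=np.int64)
    free_params = [
        p
        for p in (["mu"] if "mu" not in fixed else [])
        + (["omega"] if relaxed and "omega" not in fixed else [])
        + (["ne"] if "ne" not in fixed else [])
    ]

    span = max(tip_dates.max() - state_dates[root], 1.0)
    sigma = {"node": 0.2 * span / max(len(internal), 1) ** 0.5, "mu": 0.3, "omega": 0.5, "ne": 0.5}
    acc = {k: [0, 0] for k in sigma}

    keep_every = max(1, (iters - burnin) // max(thin_to, 1))
    kept_dates, kept_mu, kept_omega, kept_ne, kept_ll, kept_iter = [], [], [], [], [], []

    uni = rng.random(iters)
    which = rng.random(iters)
    for it in range(iters):
        if which[it] < p_node or not free_params:
            if len(movable) == 0:
                pass
            else:
                v = movable[rng.integers(len(movable))]
                t_old = state_dates[v]
                t_new = t_old + sigma["node"] * rng.standard_normal()
                lo = state_dates[parent[v]] if parent[v] >= 0 else -np.inf
                hi = min(state_dates[c] for c in children[v])
                acc["node"][1] += 1
                if lo <= t_new <= hi:
                    state_dates[v] = t_new
                    new_clock = ev.loglik(state_dates, parent, mu, omega)
                    new_I = _pair_time(state_dates, L.n_tips)
                    delta = (new_clock - clock_ll) + (coal_ll(new_I, ne) - coal_ll(I, ne))
                    if delta >= 0 or uni[it] < math.exp(max(delta, -700)):
                        clock_ll, I = new_clock, new_I
                        acc["node"][0] += 1
                    else:
                        state_dates[v] = t_old
        else:
            name = free_params[rng.integers(len(free_params))]
            s = sigma[name]
            if name == "mu":
                mu_new = mu * math.exp(s * rng.standard_normal())
                new_clock = ev.loglik(state_dates, parent, mu_new, omega)
                delta = (
                    new_clock
                    - clock_ll
                    + log_prior(mu_new, omega, ne)
                    - log_prior(mu, omega, ne)
                    + math.log(mu_new / mu)
                )
                acc["mu"][1] += 1
                if delta >= 0 or uni[it] < math.exp(max(delta, -700)):
                    mu, clock_ll = mu_new, new_clock
                    acc["mu"][0] += 1
            elif name == "omega":
                om_new = omega * math.exp(s * rng.standard_normal()) if omega > 0 else 0.1
                new_clock = ev.loglik(state_dates, parent, mu, om_new)
                delta = (
                    new_clock
                    - clock_ll
                    + log_prior(mu, om_new, ne)
                    - log_prior(mu, omega, ne)
                    + (math.log(om_new / omega) if omega > 0 else 0.0)
                )
                acc["omega"][1] += 1
                if delta >= 0 or uni[it] < math.exp(max(delta, -700)):
                    omega, clock_ll = om_new, new_clock
                    acc["omega"][0] += 1
            else:  # ne
                ne_new = ne * math.exp(s * rng.standard_normal())
                delta = (
                    coal_ll(I, ne_new)
                    - coal_ll(I, ne)
                    + log_prior(mu, omega, ne_new)
                    - log_prior(mu, omega, ne)
                    + math.log(ne_new / ne)
                )
                acc["ne"][1] += 1
                if delta >= 0 or uni[it] < math.exp(max(delta, -700)):
                    ne = ne_new
                    acc["ne"][0] += 1

        # adapt step sizes during burn-in
        if it < burnin and (it + 1) % 200 == 0:
            for k, (a, t) in acc.items():
                if t >= 20:
                    rate = a / t
                    sigma[k] = max(sigma[k] * math.exp((rate - 0.25) * 0.5), 1e-8)
                acc[k] = [0, 0]

        if it >= burnin and (it - burnin) % keep_every == 0:
            kept_dates.append(state_dates.copy())
            kept_mu.append(mu)
            kept_omega.append(omega)
            kept_ne.append(ne)
            kept_ll.append(clock_ll)
            kept_iter.append(it)

    trees = [DatedTree(parent, d, L.tip_labels) for d in kept_dates]
    return PosteriorSample(
        trees=trees,
        mu=np.array(kept_mu),
        ne=np.array(kept_ne),
        loglik=np.array(kept_ll),
        family=model.family,
        omega=np.array(kept_omega) if relaxed else None,
        iteration=np.array(kept_iter),
    )


def dic(posterior, min_draws=50):
    """Deviance information criterion from stored clock log-likelihoods:
    ``DIC = mean(deviance) + var(deviance)/2`` with deviance ``-2 log L``."""
    if len(posterior) < min_draws:
        raise ValidationError(f"need at least {min_draws} posterior draws for DIC")
    dev = -2.0 * posterior.loglik
    return float(dev.mean() + 0.5 * dev.var(ddof=1))


# ---------------------------------------------------------------------------
# ML-style dating and the pseudo-posterior
# ---------------------------------------------------------------------------

def _branch_dll_dd(m, l, d):
    """Derivative of the branch log-probability with respect to duration."""
    fam = m.effective_family
    is_int = np.isclose(l, np.round(l), atol=1e-9)
    out = np.empty(l.shape)
    if fam == "poisson":
        out = np.where(is_int, l / d - m.mu, m.mu * np.log(np.maximum(l, 1e-300)) - m.mu * special.digamma(d * m.mu))
    elif fam == "gamma":
        out = m.mu * np.log(np.maximum(l, 1e-300)) - m.mu * special.digamma(d * m.mu)
    elif fam == "negbin":
        r = d * m.mu / m.omega
        p = 1.0 / (1.0 + m.omega)
        disc = (m.mu / m.omega) * (special.digamma(l + r) - special.digamma(r) + math.log(p))
        s = 1.0 + m.omega
        cont = (m.mu / s) * (np.log(np.maximum(l, 1e-300)) - math.log(s) - special.digamma(d * m.mu / s))
        out = np.where(is_int, disc, cont)
    else:  # argamma
        s = 1.0 + m.omega
        out = (m.mu / s) * (np.log(np.maximum(l, 1e-300)) - math.log(s) - special.digamma(d * m.mu / s))
    return out


def ml_date(L, dates, model, mu=None, max_rounds=20, mu_tol=1e-5):
    """Point-estimate dating: maximize the clock likelihood over node dates
    and the clock rate.

    Starting from the root-to-tip regression slope (or ``mu`` if given), the
    routine alternates two ascent steps until the rate is stationary: the
    node dates are optimized at fixed rate (a convex problem with linear
    ordering constraints, solved by SLSQP with analytic gradients), and the
    rate is updated to its closed-form maximizer ``sum l / sum d``.  Like
    any maximum-likelihood dating, the result is overfitted: branch
    durations track the observed substitution counts too closely, which is
    exactly the residual distortion the pseudo-posterior corrects.
    """
    tip_dates = np.array([dates[lab] for lab in L.tip_labels])
    if mu is None:
        try:
            slope = root_to_tip_regression(L, dates).slope
        except ValidationError:
            slope = np.nan
        mu = slope if np.isfinite(slope) and slope > 1e-6 else 1.0
    D = None
    for _ in range(max_rounds):
        D, m = _ml_date_fixed_mu(L, tip_dates, model, mu)
        mu_new = mle_mu(L, D)
        if abs(mu_new - mu) <= mu_tol * mu:
            mu = mu_new
            break
        mu = mu_new
    return D, model.with_params(mu=mu)


def _ml_date_fixed_mu(L, tip_dates, model, mu):
    m = model.with_params(mu=mu)
    parent = L.parent
    node_dates = _init_dates(L, tip_dates, mu)
    internal = np.array([v for v in range(L.n_nodes) if not L.is_tip(v)], dtype=np.int64)
    pos = {int(v): i for i, v in enumerate(internal)}
    nonroot = np.flatnonzero(parent >= 0)
    l_all = L.lengths[nonroot]

    full = node_dates.copy()

    def set_x(x):
        full[internal] = x
        return full

    def negll(x):
        dd = set_x(x)
        d = np.maximum(dd[nonroot] - dd[parent[nonroot]], 1e-9)
        return -float(np.sum(branch_logprob(m, l_all, d)))

    def grad(x):
        dd = set_x(x)
        d = np.maximum(dd[nonroot] - dd[parent[nonroot]], 1e-9)
        g_edge = _branch_dll_dd(m, l_all, d)
        g = np.zeros(len(internal))
        for e, v in enumerate(nonroot):
            if not L.is_tip(v):
                g[pos[int(v)]] += g_edge[e]
            g[pos[int(parent[v])]] -= g_edge[e]
        return -g

    # linear ordering constraints: child date - parent date >= 0
    A = np.zeros((len(nonroot), len(internal)))
    b = np.zeros(len(nonroot))
    for e, v in enumerate(nonroot):
        if L.is_tip(v):
            b[e] = tip_dates[v]
        else:
            A[e, pos[int(v)]] = 1.0
        A[e, pos[int(parent[v])]] -= 1.0
    cons = {"type": "ineq", "fun": lambda x: A @ x + b, "jac": lambda x: A}
    res = optimize.minimize(
        negll,
        node_dates[internal],
        jac=grad,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-10},
    )
    out = node_dates.copy()
    out[internal] = res.x
    # project tiny constraint violations left by the optimizer
    for v in L.postorder():
        if not L.is_tip(v):
            out[v] = min([out[v]] + [out[c] for c in L.children[v]])
    D = DatedTree(parent, out, L.tip_labels)
    return D, m


def pseudo_posterior(
    D_hat,
    L,
    model=None,
    mu_hat=None,
    alpha_hat=None,
    iters=100_000,
    thin_to=500,
    rng=None,
):
    """Approximate posterior sample centered on a point-estimate dated tree.

    The input tree for the short MCMC has branch lengths equal to the
    point-estimate durations times ``mu_hat``; inference runs under the
    continuous strict clock with ``mu`` fixed at ``mu_hat`` and the
    coalescent rate fixed at ``alpha_hat`` (their closed-form estimates by
    default), sampling node dates only.  The returned sample carries the
    original inference model's family and parameters so residual diagnostics
    can be applied to it exactly as to a real posterior sample.
    """
    if rng is None:
        rng = np.random.default_rng()
    corr = match_branches(D_hat, L)
    if mu_hat is None:
        # the rate consistent with the point-estimate tree (sum l / sum d);
        # using any other rate would shift every residual systematically
        mu_hat = mle_mu(L, D_hat, corr)
    if alpha_hat is None:
        alpha_hat = mle_alpha(D_hat)
    if model is None:
        model = ClockModel("poisson", mu_hat)
    nonroot = D_hat.parent >= 0
    scaled = np.where(nonroot, D_hat.lengths * mu_hat, np.nan)
    R = UndatedTree(D_hat.parent, scaled, D_hat.tip_labels)
    dates = {lab: float(D_hat.dates[i]) for i, lab in enumerate(D_hat.tip_labels)}
    sample = mcmc_date(
        R,
        dates,
        ClockModel("gamma", mu_hat),
        iters=iters,
        thin_to=thin_to,
        rng=rng,
        fixed={"mu": mu_hat, "ne": alpha_hat},
        init_dates=D_hat.dates,
        # branches estimated at under half a substitution are left-censored:
        # an exact zero would have zero density for every positive duration
        censor_below=0.5,
    )
    return PosteriorSample(
        trees=sample.trees,
        mu=np.full(len(sample), mu_hat),
        ne=sample.ne,
        loglik=sample.loglik,
        family=model.family,
        omega=None if model.omega is None else np.full(len(sample), model.omega),
        iteration=sample.iteration,
    )
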