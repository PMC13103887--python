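"""Simulation of dated phylogenies and substitution data.

Genealogies are drawn from the heterochronous coalescent, going backward in
time: with ``k`` active lineages the waiting time to the next coalescence has
hazard ``k(k-1)/(2 N(t))``, interleaved with the (fixed) sampling events.
Constant and time-varying population sizes are supported; the time-varying
sampler uses time-rescaling, inverting the integrated hazard on each
inter-event interval.  A logistic clonal-expansion trajectory

    N(t) = M (t-s)^2 / (h^2 + (t-s)^2)   for t >= s, else 0

starts at zero at time ``s``, reaches ``M/2`` at ``s + h`` and saturates at
``M``.  Structured datasets join independently simulated population
components at specified divergence dates, which (with one sampling year per
component) reproduces the date-structure confounding that distorts
root-to-tip regressions.  Substitution data are laid on branches by the
clock models, and artificial outliers can be injected on terminal branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .clock import ClockModel, apply_clock
from .phylo import DatedTree, UndatedTree, ValidationError

__all__ = [
    "ConstantPop",
    "LogisticPop",
    "logistic_N",
    "uniform_dates",
    "sim_coalescent_constant",
    "sim_coalescent_nt",
    "coalescent_nt_loglik",
    "sim_structured",
    "inject_outliers",
    "simulate_dataset",
]


def uniform_dates(n, t_min, t_max, rng):
    """``n`` sampling dates uniformly distributed on [t_min, t_max]."""
    if n < 2:
        raise ValidationError("need at least 2 tips")
    return np.sort(rng.uniform(t_min, t_max, size=n))[::-1]


# ---------------------------------------------------------------------------
# Population trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantPop:
    """Constant effective population size ``Ne`` (in years, Ne*generation)."""

    ne: float

    def __post_init__(self):
        if not self.ne > 0:
            raise ValidationError("Ne must be positive")

    earliest = -np.inf

    def size(self, t):
        return self.ne

    def inv_integral(self, a, b):
        """Integral of 1/N(u) du over [a, b]."""
        return (b - a) / self.ne

    def solve_back(self, t, target):
        """The time tau < t with ``integral_{tau}^{t} du/N(u) = target``."""
        return t - target * self.ne


@dataclass(frozen=True)
class LogisticPop:
    """Clonal-expansion trajectory: zero before ``s``, logistic growth to ``M``."""

    M: float
    s: float
    h: float

    def __post_init__(self):
        if not (self.M > 0 and self.h > 0):
            raise ValidationError("M and h must be positive")

    @property
    def earliest(self):
        return self.s

    def size(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(
            t >= self.s, self.M * (t - self.s) ** 2 / (self.h**2 + (t - self.s) ** 2), 0.0
        )
        return float(out) if out.ndim == 0 else out

    def inv_integral(self, a, b):
        # 1/N(u) = (1/M) (1 + h^2/(u-s)^2); diverges as a -> s+
        if b <= a:
            return 0.0
        if a <= self.s:
            return np.inf
        return ((b - a) + self.h**2 * (1.0 / (a - self.s) - 1.0 / (b - self.s))) / self.M

    def solve_back(self, t, target):
        lo = self.s + 1e-12 * max(abs(self.s), 1.0)
        if self.inv_integral(lo, t) <= target:
            # hazard diverges at s; only numerically possible with tiny target
            return lo
        return optimize.brentq(
            lambda tau: self.inv_integral(tau, t) - target, lo, t, xtol=1e-12, rtol=1e-12
        )


class CallablePop:
    """Arbitrary ``N(t)`` given as a callable; integrals done by quadrature."""

    earliest = -np.inf

    def __init__(self, fn):
        self.fn = fn

    def size(self, t):
        return self.fn(t)

    def inv_integral(self, a, b):
        val, _ = integrate.quad(lambda u: 1.0 / self.fn(u), a, b, limit=200)
        return val

    def solve_back(self, t, target, max_span=1e6):
        lo = t - 1.0
        while self.inv_integral(lo, t) < target:
            lo = t - 2.0 * (t - lo)
            if t - lo > max_span:
                raise ValidationError("could not bracket the next coalescence time")
        return optimize.brentq(lambda tau: self.inv_integral(tau, t) - target, lo, t)


# ---------------------------------------------------------------------------
# Coalescent simulators
# ---------------------------------------------------------------------------

def logistic_N(t, M, s, h):
    """Population size of the logistic clonal-expansion model at time ``t``."""
    return LogisticPop(M, s, h).size(t)


def _simulate_genealogy(tip_dates, pop, rng, labels=None):
    """Backward-in-time heterochronous coalescent under trajectory ``pop``.

    Returns parent array, node dates, labels; tips are 0..n-1 in the order of
    ``labels`` and internal nodes are appended as they coalesce (root last).
    """
    tip_dates = np.asarray(tip_dates, dtype=float)
    n = len(tip_dates)
    if n < 2:
        raise ValidationError("need at least 2 tips")
    if labels is None:
        labels = [f"t{i+1}" for i in range(n)]
    order = np.argsort(-tip_dates, kind="stable")  # most recent first
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_dates = np.empty(n_nodes)
    node_dates[:n] = tip_dates
    active = []
    next_internal = n
    i = 0
    t = tip_dates[order[0]]
    while next_internal < n_nodes:
        # add all tips sampled at the current time
        while i < n and tip_dates[order[i]] >= t - 1e-15:
            active.append(int(order[i]))
            i += 1
        k = len(active)
        next_samp = tip_dates[order[i]] if i < n else -np.inf
        if k < 2:
            t = next_samp
            continue
        target = rng.exponential() * 2.0 / (k * (k - 1))
        budget = pop.inv_integral(next_samp, t) if np.isfinite(next_samp) else np.inf
        if target < budget:
            t = pop.solve_back(t, target)
            c1 = active.pop(rng.integers(k))
            c2 = active.pop(rng.integers(k - 1))
            parent[c1] = parent[c2] = next_internal
            node_dates[next_internal] = t
            active.append(next_internal)
            next_internal += 1
        else:
            if not np.isfinite(next_samp):
                raise ValidationError("coalescent simulation failed to terminate")
            t = next_samp
    return parent, node_dates, list(labels)


def sim_coalescent_constant(tip_dates, ne, rng, labels=None):
    """Heterochronous coalescent genealogy with constant ``Ne``."""
    parent, node_dates, labels = _simulate_genealogy(tip_dates, ConstantPop(ne), rng, labels)
    return DatedTree(parent, node_dates, labels)


def sim_coalescent_nt(tip_dates, pop, rng, labels=None):
    """Coalescent genealogy under a time-varying population size trajectory."""
    if callable(pop):
        pop = CallablePop(pop)
    parent, node_dates, labels = _simulate_genealogy(tip_dates, pop, rng, labels)
    return DatedTree(parent, node_dates, labels)


def coalescent_nt_loglik(D, pop):
    """Log-density of a dated genealogy under trajectory ``pop``:
    ``-∫ A(t)(A(t)-1)/(2N(t)) dt - sum_coalescences log N(c)``."""
    if callable(pop) and not hasattr(pop, "inv_integral"):
        pop = CallablePop(pop)
    dates = D.dates
    is_tip = np.zeros(D.n_nodes, dtype=bool)
    is_tip[: D.n_tips] = True
    order = np.argsort(-dates, kind="stable")
    t_sorted = dates[order]
    k = np.cumsum(np.where(is_tip[order], 1, -1))
    ll = 0.0
    for j in range(len(t_sorted) - 1):
        kk = k[j]
        if kk >= 2:
            ll -= kk * (kk - 1) / 2.0 * pop.inv_integral(t_sorted[j + 1], t_sorted[j])
    for v in order:
        if not is_tip[v]:
            ll -= math.log(pop.size(dates[v]))
    return ll


# ---------------------------------------------------------------------------
# Structured populations
# ---------------------------------------------------------------------------

def sim_structured(components, join_dates, rng):
    """Join independently simulated population components into one tree.

    ``components`` is a list of ``(tip_dates, pop, label_prefix)`` triples;
    each component genealogy is simulated with its own trajectory.  The
    component root lineages are then merged in order at ``join_dates``
    (decreasing; the last one is the root of the combined tree).  Every join
    date must be older than the MRCAs it joins.
    """
    if len(components) == 0:
        raise ValidationError("need at least one component")
    if len(components) == 1:
        tip_dates, pop, prefix = components[0]
        labels = [f"{prefix}_{i+1}" for i in range(len(tip_dates))]
        return sim_coalescent_nt(tip_dates, pop, rng, labels=labels)
    join_dates = sorted(join_dates, reverse=True)
    if len(join_dates) != len(components) - 1:
        raise ValidationError("need exactly n_components - 1 join dates")
    parts = []
    for ci, (tip_dates, pop, prefix) in enumerate(components):
        labels = [f"{prefix}_{i+1}" for i in range(len(tip_dates))]
        parent, node_dates, labels = _simulate_genealogy(tip_dates, pop, rng, labels)
        parts.append((parent, node_dates, labels))
    # merge arrays: tips of all components first, then internals, then joins
    n_tips_tot = sum(len(p[2]) for p in parts)
    tip_off, int_off = 0, n_tips_tot
    maps, labels_all = [], []
    n_nodes_tot = sum(len(p[0]) for p in parts) + len(join_dates)
    parent_all = np.full(n_nodes_tot, -1, dtype=np.int64)
    dates_all = np.empty(n_nodes_tot)
    roots = []
    for parent, node_dates, labels in parts:
        n = len(labels)
        idx = np.concatenate(
            [np.arange(tip_off, tip_off + n), np.arange(int_off, int_off + n - 1)]
        )
        for v in range(len(parent)):
            dates_all[idx[v]] = node_dates[v]
            if parent[v] >= 0:
                parent_all[idx[v]] = idx[parent[v]]
            else:
                roots.append(int(idx[v]))
        labels_all.extend(labels)
        tip_off += n
        int_off += n - 1
    join_ids = list(range(n_nodes_tot - len(join_dates), n_nodes_tot))
    current = roots[0]
    for j, (jid, jdate) in enumerate(zip(join_ids, join_dates)):
        other = roots[j + 1]
        if jdate >= min(dates_all[current], dates_all[other]):
            raise ValidationError(
                f"join date {jdate} is not older than the lineages it joins"
            )
        parent_all[current] = jid
        parent_all[other] = jid
        dates_all[jid] = jdate
        current = jid
    return DatedTree(parent_all, dates_all, labels_all)


def inject_outliers(L, tips, extra, rng=None):
    """Add ``extra`` substitutions to the terminal branches of selected tips.

    ``tips`` is either a list of tip labels or an integer count of tips to
    select at random (requires ``rng``).
    """
    if extra < 0:
        raise ValidationError("extra must be non-negative")
    if isinstance(tips, (int, np.integer)):
        if rng is None:
            raise ValidationError("random tip selection requires an rng")
        idx = rng.choice(L.n_tips, size=int(tips), replace=False)
        tips = [L.tip_labels[i] for i in idx]
    out = L.copy()
    for lab in tips:
        if lab not in L.tip_labels:
            raise ValidationError(f"unknown tip {lab!r}")
        out.lengths[L.tip_labels.index(lab)] += extra
    return UndatedTree(out.parent, out.lengths, out.tip_labels), list(tips)


# ---------------------------------------------------------------------------
# Ready-made scenarios
# ---------------------------------------------------------------------------

def simulate_dataset(
    scenario,
    rng,
    n=100,
    t_min=2010.0,
    t_max=2020.0,
    ne=1.0,
    mu=10.0,
    omega=5.0,
    n_outliers=5,
    extra=20.0,
    clock_family=None,
):
    """Simulate a complete dataset (dated tree, undated tree, dates, truth).

    Scenarios: ``constant`` (strict clock on a constant-Ne coalescent),
    ``relaxed`` (additive relaxed clock), ``outliers`` (strict clock plus
    injected terminal-branch outliers), ``structured`` (three components
    sampled in different years, logistic growth, strict clock) and
    ``logistic`` (single logistic-growth component, strict clock).
    """
    truth = {"scenario": scenario, "mu": mu, "ne": ne}
    if scenario in ("constant", "relaxed", "outliers"):
        dates = uniform_dates(n, t_min, t_max, rng)
        D = sim_coalescent_constant(dates, ne, rng)
        if scenario == "relaxed":
            m = ClockModel(clock_family or "negbin", mu, omega)
            truth["omega"] = omega
        else:
            m = ClockModel(clock_family or "poisson", mu)
        L = apply_clock(D, m, rng)
        if scenario == "outliers":
            L, chosen = inject_outliers(L, n_outliers, extra, rng)
            truth["outlier_tips"] = chosen
            truth["extra"] = extra
    elif scenario in ("structured", "logistic"):
        m = ClockModel(clock_family or "poisson", mu)
        if scenario == "logistic":
            dates = uniform_dates(n, t_min, t_max, rng)
            D = sim_coalescent_nt(dates, LogisticPop(M=ne, s=t_min - 20.0, h=3.0), rng)
        else:
            years = [2000.0, 2010.0, 2020.0]
            per = max(n // 3, 2)
            comps = [
                (
                    np.full(per, yr),
                    LogisticPop(M=2.0, s=yr - 10.0, h=3.0),
                    f"c{j+1}",
                )
                for j, yr in enumerate(years)
            ]
            D = sim_structured(comps, join_dates=[1948.0, 1946.0], rng=rng)
            truth["root_date"] = 1946.0
        L = apply_clock(D, m, rng)
    else:
        raise ValidationError(f"unknown scenario {scenario!r}")
    truth.setdefault("root_date", float(D.dates[D.root]))
    truth["clock_family"] = m.family
    date_map = {lab: float(D.dates[i]) for i, lab in enumerate(D.tip_labels)}
    return {"dated": D, "undated": L, "dates": date_map, "truth": truth, "model": m}
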