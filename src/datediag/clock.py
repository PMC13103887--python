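"""Molecular clock models: distributions of substitutions given branch durations.

Four models are supported, one for each combination of strict/relaxed and
discrete/continuous.  Writing ``d`` for the branch duration (years) and ``mu``
for the (mean) clock rate in substitutions per year:

* ``poisson``  — strict clock, discrete:    l ~ Poisson(d*mu)
* ``gamma``    — strict clock, continuous:  l ~ Gamma(shape d*mu, scale 1)
* ``negbin``   — additive relaxed clock, discrete:
                 l ~ NegBinomial(r = d*mu/omega, p = 1/(1+omega))
* ``argamma``  — additive relaxed clock, continuous:
                 l ~ Gamma(shape d*mu/(1+omega), scale 1+omega)

All four have mean ``d*mu``; the variance is ``d*mu`` for the strict models
and ``d*mu*(1+omega)`` for the relaxed models, so ``omega >= 0`` measures the
overdispersion of substitution counts relative to a Poisson process.  The
relaxed models with ``omega = 0`` reduce to their strict counterparts.

A non-integer substitution amount presented to a discrete model (which arises
when the root-spanning substitutions are divided proportionally between the
two root-adjacent branches) is evaluated under the continuous model with the
same mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .phylo import DatedTree, UndatedTree, ValidationError

__all__ = [
    "ClockModel",
    "branch_logprob",
    "branch_cdf",
    "simulate_branch",
    "apply_clock",
    "FAMILIES",
]

FAMILIES = ("poisson", "gamma", "negbin", "argamma")
_DISCRETE = ("poisson", "negbin")
_RELAXED = ("negbin", "argamma")


@dataclass(frozen=True)
class ClockModel:
    """A molecular clock model ``family`` with rate ``mu`` and relaxation ``omega``."""

    family: str
    mu: float
    omega: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown clock family {self.family!r}")
        if not self.mu > 0:
            raise ValidationError("clock rate mu must be positive")
        if self.relaxed:
            if self.omega is None or self.omega < 0:
                raise ValidationError("relaxed models require omega >= 0")
        elif self.omega is not None:
            raise ValidationError("strict models take no omega")

    @property
    def discrete(self):
        return self.family in _DISCRETE

    @property
    def relaxed(self):
        return self.family in _RELAXED

    @property
    def effective_family(self):
        """Family after collapsing an omega=0 relaxed model to its strict limit."""
        if self.relaxed and self.omega == 0:
            return "poisson" if self.family == "negbin" else "gamma"
        return self.family

    def strict_counterpart(self):
        return ClockModel("poisson" if self.discrete else "gamma", self.mu)

    def continuous_counterpart(self):
        """Same-moment Gamma model (identity for continuous families)."""
        if self.family == "poisson":
            return ClockModel("gamma", self.mu)
        if self.family == "negbin":
            return ClockModel("argamma", self.mu, self.omega)
        return self

    def with_params(self, mu=None, omega=None):
        return ClockModel(
            self.family,
            self.mu if mu is None else mu,
            (self.omega if omega is None else omega) if self.relaxed else None,
        )


def _gamma_params(m, d):
    """Shape and scale of the continuous model matching m's moments."""
    d = np.asarray(d, dtype=float)
    if m.effective_family in ("poisson", "gamma"):
        return d * m.mu, 1.0
    return d * m.mu / (1.0 + m.omega), 1.0 + m.omega


def branch_logprob(m, l, d):
    """Log mass/density of ``l`` substitutions on a branch of duration ``d``.

    Vectorized over ``l`` and ``d``.  A branch of zero duration carries
    probability one at ``l = 0`` and zero elsewhere.  Non-integer ``l`` under
    a discrete family is scored by the same-moment continuous model.
    """
    l = np.asarray(l, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(l < 0) or np.any(d < 0):
        raise ValidationError("l and d must be non-negative")
    l, d = np.broadcast_arrays(l, d)
    out = np.full(l.shape, -np.inf)
    fam = m.effective_family
    pos = d > 0
    if fam in ("gamma", "argamma"):
        shape, scale = _gamma_params(m, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = (
                special.xlogy(shape - 1.0, l)
                - l / scale
                - shape * np.log(scale)
                - special.gammaln(shape)
            )
        out[pos] = val[pos]
    else:
        is_int = np.isclose(l, np.round(l), atol=1e-9)
        if fam == "poisson":
            mlam = d * m.mu
            val = special.xlogy(np.round(l), mlam) - mlam - special.gammaln(np.round(l) + 1)
        else:  # negbin
            r = d * m.mu / m.omega
            p = 1.0 / (1.0 + m.omega)
            k = np.round(l)
            val = (
                special.gammaln(k + r)
                - special.gammaln(r)
                - special.gammaln(k + 1)
                + r * np.log(p)
                + k * np.log(m.omega / (1.0 + m.omega))
            )
        mask = pos & is_int
        out[mask] = val[mask]
        if np.any(pos & ~is_int):
            cont = np.asarray(branch_logprob(m.continuous_counterpart(), l, d))
            mask = pos & ~is_int
            out[mask] = cont[mask]
    # zero-duration branches: point mass at l = 0
    out[~pos & (l == 0)] = 0.0
    if out.ndim == 0:
        return float(out)
    return out


def branch_cdf(m, l, d):
    """P(L <= l) for a branch of duration ``d``; vectorized.

    For discrete families the CDF is evaluated at ``floor(l)``; negative ``l``
    gives 0.  A zero-duration branch has all its mass at zero.
    """
    l = np.asarray(l, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("d must be non-negative")
    l, d = np.broadcast_arrays(l, d)
    out = np.zeros(l.shape)
    fam = m.effective_family
    pos = d > 0
    nonneg = l >= 0
    if fam in ("gamma", "argamma"):
        shape, scale = _gamma_params(m, d)
        with np.errstate(invalid="ignore"):
            val = special.gammainc(np.where(shape > 0, shape, 1.0), np.maximum(l, 0) / scale)
        mask = pos & nonneg
        out[mask] = val[mask]
    elif fam == "poisson":
        k = np.floor(l)
        val = special.gammaincc(np.maximum(k, 0) + 1.0, d * m.mu)
        mask = pos & (k >= 0)
        out[mask] = val[mask]
    else:  # negbin
        r = d * m.mu / m.omega
        p = 1.0 / (1.0 + m.omega)
        k = np.floor(l)
        with np.errstate(invalid="ignore"):
            val = special.betainc(np.where(r > 0, r, 1.0), np.maximum(k, 0) + 1.0, p)
        mask = pos & (k >= 0)
        out[mask] = val[mask]
    out[~pos & nonneg] = 1.0  # d = 0: point mass at zero
    if out.ndim == 0:
        return float(out)
    return out


def simulate_branch(m, d, rng):
    """Draw substitution amounts for branches of duration ``d``; vectorized."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("d must be non-negative")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.zeros(d.shape)
    pos = d > 0
    fam = m.effective_family
    if np.any(pos):
        dp = d[pos]
        if fam == "poisson":
            out[pos] = rng.poisson(dp * m.mu)
        elif fam == "gamma":
            out[pos] = rng.gamma(shape=dp * m.mu, scale=1.0)
        elif fam == "negbin":
            r = dp * m.mu / m.omega
            p = 1.0 / (1.0 + m.omega)
            # Gamma-Poisson mixture: NB(r, p) = Poisson(Gamma(r, (1-p)/p))
            out[pos] = rng.poisson(rng.gamma(shape=r, scale=(1.0 - p) / p))
        else:
            shape, scale = d * m.mu / (1.0 + m.omega), 1.0 + m.omega
            out[pos] = rng.gamma(shape=shape[pos], scale=scale)
    return float(out[0]) if scalar else out


def apply_clock(D, m, rng):
    """Simulate an undated tree by drawing substitutions on every branch of D."""
    if not isinstance(D, DatedTree):
        raise ValidationError("apply_clock requires a DatedTree")
    subs = np.full(D.n_nodes, np.nan)
    nonroot = np.flatnonzero(D.parent >= 0)
    subs[nonroot] = simulate_branch(m, D.lengths[nonroot], rng)
    return UndatedTree(D.parent, subs, D.tip_labels)
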