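"""Container for posterior (or pseudo-posterior) samples of dated trees.

A sample holds, for each retained draw, a dated tree plus the clock and
coalescent parameters of that draw.  On disk a sample is a multi-tree Newick
file (one tree per line) with a companion CSV trace with header
``iteration,mu,omega,ne,loglik``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import ClockModel
from .phylo import ValidationError, attach_dates, parse_newick, write_newick

__all__ = ["PosteriorSample"]


@dataclass
class PosteriorSample:
    """A sequence of (dated tree, mu, omega, Ne, log-likelihood) draws."""

    trees: list
    mu: np.ndarray
    ne: np.ndarray
    loglik: np.ndarray
    family: str = "poisson"
    omega: np.ndarray | None = None
    iteration: np.ndarray | None = None

    def __post_init__(self):
        if len(self.trees) < 1:
            raise ValidationError("posterior sample must contain at least one draw")
        self.mu = np.asarray(self.mu, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float)
        if self.iteration is None:
            self.iteration = np.arange(len(self.trees))

    def __len__(self):
        return len(self.trees)

    def model(self, i):
        """Clock model of draw ``i``."""
        omega = None if self.omega is None else float(self.omega[i])
        return ClockModel(self.family, float(self.mu[i]), omega)

    def subsample(self, max_draws):
        """Evenly thin to at most ``max_draws`` draws."""
        n = len(self)
        if n <= max_draws:
            return self
        idx = np.unique(np.linspace(0, n - 1, max_draws).round().astype(int))
        return PosteriorSample(
            trees=[self.trees[i] for i in idx],
            mu=self.mu[idx],
            ne=self.ne[idx],
            loglik=self.loglik[idx],
            family=self.family,
            omega=None if self.omega is None else self.omega[idx],
            iteration=self.iteration[idx],
        )

    @classmethod
    def point_estimate(cls, tree, model, ne=np.nan, loglik=np.nan):
        """Wrap a single dated tree + parameters as a size-1 'posterior'."""
        return cls(
            trees=[tree],
            mu=[model.mu],
            ne=[ne],
            loglik=[loglik],
            family=model.family,
            omega=None if model.omega is None else [model.omega],
        )

    # -- I/O ---------------------------------------------------------------

    def write(self, trees_path, trace_path):
        with open(trees_path, "w") as fh:
            for t in self.trees:
                t2 = t.copy()
                t2.tip_labels = [
                    lab if "|" in lab else f"{lab}|{t.dates[i]:.8f}"
                    for i, lab in enumerate(t.tip_labels)
                ]
                fh.write(write_newick(t2) + "\n")
        pd.DataFrame(
            {
                "iteration": self.iteration,
                "mu": self.mu,
                "omega": np.full(len(self), np.nan) if self.omega is None else self.omega,
                "ne": self.ne,
                "loglik": self.loglik,
            }
        ).to_csv(trace_path, index=False)

    @classmethod
    def read(cls, trees_path, trace_path, family="poisson"):
        trace = pd.read_csv(trace_path)
        trees = []
        with open(trees_path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                t = parse_newick(line, unit="years")
                dates = {
                    lab: float(lab.rsplit("|", 1)[1]) if "|" in lab else None
                    for lab in t.tip_labels
                }
                if any(v is None for v in dates.values()):
                    raise ValidationError(
                        "posterior tree tips must embed dates as 'label|date'"
                    )
                dated = attach_dates(t, dates)
                dated.tip_labels = [lab.rsplit("|", 1)[0] for lab in dated.tip_labels]
                trees.append(dated)
        if len(trees) != len(trace):
            raise ValidationError("trace and trees files have different lengths")
        omega = trace["omega"].to_numpy()
        if np.all(np.isnan(omega)):
            omega = None
        return cls(
            trees=trees,
            mu=trace["mu"].to_numpy(),
            ne=trace["ne"].to_numpy(),
            loglik=trace["loglik"].to_numpy(),
            family=family,
            omega=omega,
            iteration=trace["iteration"].to_numpy(),
        )
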