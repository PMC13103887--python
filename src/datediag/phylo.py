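"""Rooted tree containers, Newick and date I/O, branch matching, summary statistics.

Two kinds of trees are distinguished throughout the package:

* a *dated* tree, whose branch lengths are calendar durations (decimal years)
  and whose nodes carry dates, with tips at their sampling dates; and
* an *undated* tree with the same topology, whose branch lengths are numbers
  of substitutions (integer counts for discrete clock models, non-negative
  reals otherwise).

Trees are stored as flat parent arrays (tips first, then internal nodes) so
that the numerical routines can operate on vectors.  Newick reading and
writing is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "RootedTree",
    "DatedTree",
    "UndatedTree",
    "BranchCorrespondence",
    "DatediagError",
    "NewickParseError",
    "ValidationError",
    "TopologyMismatchError",
    "parse_newick",
    "write_newick",
    "read_dates_csv",
    "dates_from_labels",
    "attach_dates",
    "match_branches",
    "split_root_substitutions",
    "tree_summary_stats",
]


class DatediagError(Exception):
    """Base class for all package errors."""


class NewickParseError(DatediagError):
    """Raised when a Newick string cannot be parsed."""


class ValidationError(DatediagError):
    """Raised when an input violates a structural invariant."""


class TopologyMismatchError(DatediagError):
    """Raised when dated and undated trees disagree topologically."""

    def __init__(self, message, bipartitions=()):
        super().__init__(message)
        self.bipartitions = list(bipartitions)


class RootedTree:
    """A rooted phylogeny stored as parent/child arrays.

    Nodes are indexed ``0 .. n_nodes-1`` with tips occupying ``0 .. n_tips-1``.
    ``lengths[i]`` is the length of the branch above node ``i`` (NaN for the
    root).  ``unit`` records whether lengths are calendar years or
    substitutions.
    """

    def __init__(self, parent, lengths, tip_labels, unit="substitutions"):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        self.unit = unit
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValidationError("tip labels must be unique")
        nonroot = np.flatnonzero(self.parent >= 0)
        if np.any(self.lengths[nonroot] < 0):
            raise ValidationError("negative branch lengths are not allowed")
        self.children = [[] for _ in range(self.n_nodes)]
        for i in nonroot:
            self.children[self.parent[i]].append(int(i))

    @property
    def n_nodes(self):
        return len(self.parent)

    @property
    def n_tips(self):
        return len(self.tip_labels)

    def is_tip(self, i):
        return i < self.n_tips

    def postorder(self):
        """Node indices, every child before its parent."""
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def depths(self):
        """Path length from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in reversed(self.postorder()):  # preorder
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def leafsets(self):
        """Bit mask of tips below each node (tips indexed by position)."""
        masks = [0] * self.n_nodes
        for v in self.postorder():
            if self.is_tip(v):
                masks[v] = 1 << v
            else:
                m = 0
                for c in self.children[v]:
                    m |= masks[c]
                masks[v] = m
        return masks

    def copy(self):
        t = object.__new__(type(self))
        t.parent = self.parent.copy()
        t.lengths = self.lengths.copy()
        t.tip_labels = list(self.tip_labels)
        t.unit = self.unit
        t.root = self.root
        t.children = [list(c) for c in self.children]
        for attr in ("dates",):
            if hasattr(self, attr):
                setattr(t, attr, getattr(self, attr).copy())
        return t


class DatedTree(RootedTree):
    """Rooted tree with a calendar date (decimal years) on every node.

    Branch lengths are the durations ``date(child) - date(parent)`` and must
    be non-negative.
    """

    def __init__(self, parent, dates, tip_labels):
        dates = np.asarray(dates, dtype=float)
        parent = np.asarray(parent, dtype=np.int64)
        lengths = np.full(len(parent), np.nan)
        nonroot = np.flatnonzero(parent >= 0)
        lengths[nonroot] = dates[nonroot] - dates[parent[nonroot]]
        if np.any(lengths[nonroot] < -1e-9):
            raise ValidationError("child dated before its parent")
        lengths[nonroot] = np.maximum(lengths[nonroot], 0.0)
        super().__init__(parent, lengths, tip_labels, unit="years")
        self.dates = dates

    def durations(self):
        """Per-branch durations in years (NaN above the root)."""
        return self.lengths


class UndatedTree(RootedTree):
    """Rooted tree whose branch lengths are substitution counts/amounts."""

    def __init__(self, parent, subs, tip_labels):
        super().__init__(parent, subs, tip_labels, unit="substitutions")

    @property
    def subs(self):
        return self.lengths


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------

def parse_newick(text, unit="substitutions"):
    """Parse a rooted Newick string into a :class:`RootedTree`.

    Branch lengths are required on all non-root edges and must be
    non-negative; the tree is treated as rooted as written.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    dnodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in dnodes if nd.is_leaf()]
    internals = [nd for nd in dnodes if not nd.is_leaf()]
    if len(tips) < 2:
        raise NewickParseError("tree must have at least 2 tips")
    index = {}
    labels = []
    for i, nd in enumerate(tips):
        index[id(nd)] = i
        labels.append(nd.taxon.label if nd.taxon else (nd.label or f"t{i}"))
    for j, nd in enumerate(internals):
        index[id(nd)] = len(tips) + j
    n = len(tips) + len(internals)
    parent = np.full(n, -1, dtype=np.int64)
    lengths = np.full(n, np.nan)
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickParseError("branch lengths are required")
            if nd.edge.length < 0:
                raise ValidationError("negative branch length in Newick input")
            lengths[i] = nd.edge.length
    if unit == "substitutions":
        return UndatedTree(parent, lengths, labels)
    return RootedTree(parent, lengths, labels, unit=unit)


def write_newick(tree, precision=12):
    """Serialize a tree back to a one-line Newick string."""
    fmt = f"%.{precision}g"
    parts = [""] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_tip(v):
            s = tree.tip_labels[v]
        else:
            s = "(" + ",".join(parts[c] for c in tree.children[v]) + ")"
        if tree.parent[v] >= 0:
            s += ":" + (fmt % tree.lengths[v])
        parts[v] = s
    return parts[tree.root] + ";"


def read_dates_csv(path_or_buffer):
    """Read tip sampling dates from a CSV with header ``tip,date``."""
    df = pd.read_csv(path_or_buffer)
    if not {"tip", "date"} <= set(df.columns):
        raise ValidationError("dates CSV must have columns 'tip' and 'date'")
    return dict(zip(df["tip"].astype(str), df["date"].astype(float)))


def write_dates_csv(dates, path):
    pd.DataFrame({"tip": list(dates), "date": list(dates.values())}).to_csv(
        path, index=False
    )


def dates_from_labels(labels):
    """Extract decimal-year dates embedded after the final ``|`` of tip labels."""
    out = {}
    for lab in labels:
        if "|" in lab:
            try:
                out[lab] = float(lab.rsplit("|", 1)[1])
            except ValueError as exc:
                raise ValidationError(f"cannot parse date from label {lab!r}") from exc
    return out


def attach_dates(tree, dates, tol=1e-6):
    """Turn a year-unit :class:`RootedTree` into a :class:`DatedTree`.

    The root date is implied by ``tip date - root-to-tip path length`` and
    must be consistent across all tips (to within ``tol`` years).
    """
    if tree.unit != "years":
        raise ValidationError("attach_dates requires branch lengths in years")
    missing = [lab for lab in tree.tip_labels if lab not in dates]
    if missing:
        raise ValidationError(f"missing dates for tips: {missing[:5]}")
    depth = tree.depths()
    tip_dates = np.array([dates[lab] for lab in tree.tip_labels])
    root_dates = tip_dates - depth[: tree.n_tips]
    if root_dates.max() - root_dates.min() > tol:
        raise ValidationError(
            "tip dates inconsistent with branch lengths: implied root dates span "
            f"{root_dates.min():.6f}..{root_dates.max():.6f}"
        )
    node_dates = root_dates.mean() + depth
    node_dates[: tree.n_tips] = tip_dates
    return DatedTree(tree.parent, node_dates, tree.tip_labels)


# ---------------------------------------------------------------------------
# Branch correspondence
# ---------------------------------------------------------------------------

@dataclass
class BranchCorrespondence:
    """Mapping between branches of a dated tree D and an undated tree L.

    ``pairs`` maps each non-root-adjacent branch of D (identified by its child
    node) to the branch of L subtending the same set of tips.  The two
    branches incident to the root of D jointly correspond to the root split of
    L; their combined substitution amount ``root_x_subs`` is divided between
    them in proportion to their durations (see
    :func:`split_root_substitutions`).
    """

    pairs: list  # list of (d_child_node, l_child_node)
    root_a: int  # child node of D's root
    root_b: int
    root_x_subs: float  # total substitutions across L's root split

    @property
    def n_branches(self):
        return len(self.pairs) + 2


def _leafset_map(tree, label_to_bit):
    masks = [0] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_tip(v):
            masks[v] = label_to_bit[tree.tip_labels[v]]
        else:
            m = 0
            for c in tree.children[v]:
                m |= masks[c]
            masks[v] = m
    return masks


def match_branches(D, L):
    """Match every branch of D to the branch of L separating the same tips.

    Raises :class:`TopologyMismatchError` if any bipartition of D is absent
    from L, listing the offending tip sets.
    """
    if set(D.tip_labels) != set(L.tip_labels):
        raise TopologyMismatchError("leaf label sets differ")
    if len(D.children[D.root]) != 2:
        raise ValidationError("dated tree must be binary at the root")
    label_to_bit = {lab: 1 << i for i, lab in enumerate(sorted(D.tip_labels))}
    dm = _leafset_map(D, label_to_bit)
    lm = _leafset_map(L, label_to_bit)
    l_lookup = {}
    l_root_children = set(L.children[L.root])
    for v in range(L.n_nodes):
        if L.parent[v] >= 0 and v not in l_root_children:
            l_lookup[lm[v]] = v
    a, b = D.children[D.root]
    pairs, bad = [], []
    for v in range(D.n_nodes):
        if D.parent[v] < 0 or v in (a, b):
            continue
        if dm[v] in l_lookup:
            pairs.append((v, l_lookup[dm[v]]))
        else:
            bad.append(frozenset(lab for lab, bit in label_to_bit.items() if dm[v] & bit))
    # root split of D must coincide with the root split of L
    l_root_masks = {lm[c] for c in l_root_children}
    if dm[a] not in l_root_masks or dm[b] not in l_root_masks:
        bad.append(frozenset(lab for lab, bit in label_to_bit.items() if dm[a] & bit))
    if bad:
        raise TopologyMismatchError(
            f"{len(bad)} bipartition(s) of the dated tree absent from the undated tree",
            bipartitions=bad,
        )
    x_subs = float(sum(L.lengths[c] for c in l_root_children))
    return BranchCorrespondence(pairs=pairs, root_a=a, root_b=b, root_x_subs=x_subs)


def split_root_substitutions(l_x, d_a, d_b):
    """Divide the substitutions on the root-spanning branch between the two
    root-adjacent branches, proportionally to their durations.

    When both durations are zero the split is 50/50.
    """
    if l_x < 0 or d_a < 0 or d_b < 0:
        raise ValidationError("split_root_substitutions requires non-negative inputs")
    tot = d_a + d_b
    if tot == 0:
        return 0.5 * l_x, 0.5 * l_x
    l_a = l_x * d_a / tot
    return l_a, max(l_x - l_a, 0.0)


def matched_branch_values(D, L, correspondence=None):
    """Durations and substitution amounts for every branch of D.

    Returns ``(d_nodes, d_vals, l_vals)`` with one entry per branch of D
    (identified by its child node); the last two entries are the
    root-adjacent branches, whose substitutions come from the proportional
    split of L's root-spanning branch.
    """
    corr = correspondence if correspondence is not None else match_branches(D, L)
    d_nodes = np.array([p[0] for p in corr.pairs] + [corr.root_a, corr.root_b])
    l_vals = np.array([L.lengths[p[1]] for p in corr.pairs] + [0.0, 0.0])
    l_vals[-2], l_vals[-1] = split_root_substitutions(
        corr.root_x_subs, D.lengths[corr.root_a], D.lengths[corr.root_b]
    )
    return d_nodes, D.lengths[d_nodes], l_vals


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def tree_summary_stats(tree):
    """Mean, sample variance, maximum of branch lengths, and stemminess.

    Stemminess is the total internal branch length divided by the total
    branch length; the two root-adjacent branches count as internal when
    their child is an internal node.
    """
    nonroot = np.flatnonzero(tree.parent >= 0)
    if len(nonroot) < 2:
        raise ValidationError("need at least 2 branches for summary statistics")
    lens = tree.lengths[nonroot]
    total = lens.sum()
    if total == 0:
        raise ValidationError("stemminess undefined: total branch length is zero")
    internal = lens[[not tree.is_tip(v) for v in nonroot]].sum()
    return {
        "mean": float(lens.mean()),
        "variance": float(lens.var(ddof=1)),
        "max": float(lens.max()),
        "stemminess": float(internal / total),
    }
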