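"""Ancestral reconstruction of continuous traits and per-node relative change.

Two reconstruction routes are provided, mirroring how transcriptome-wide and
C4-specific quantities are treated differently in the analysis:

* :func:`bm_ancestral_ml` — maximum-likelihood ancestral states under Brownian
  motion.  Under BM the joint density of all node states is a Gaussian Markov
  random field whose precision is the tree's graph Laplacian weighted by
  inverse branch lengths, so the ML internal states solve one sparse linear
  system (no iterative optimiser) and the conditional variances are the
  diagonal of the inverse internal-block Laplacian scaled by the ML rate.
* :func:`assign_descendant_values` — the descendant-assignment shortcut used
  for C4-related expression, protein and physiology values: every internal
  node inherits the value of its most recent derived species, i.e. the
  nearest tip hanging off the node away from the backbone.

Per-node relative change is ``(N − N_pre) / N_pre`` where ``N_pre`` is the
value at the nearest preceding internal node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from c4evo.tree import Node, PhyloTree, preceding_node, _n_index

__all__ = [
    "NodeChangeProfile",
    "bm_ancestral_ml",
    "bm_ancestral_batch",
    "assign_descendant_values",
    "relative_change_continuous",
]


@dataclass
class NodeChangeProfile:
    """Per-internal-node relative change for one feature class."""

    feature_class: str
    changes: dict[str, float] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    def argmax_abs(self) -> str:
        """Node with the largest absolute relative change."""
        if not self.changes:
            raise ValueError("empty change profile")
        return max(self.changes, key=lambda k: abs(self.changes[k]))

    def as_series(self):
        import pandas as pd

        return pd.Series(self.changes, name=self.feature_class)


def _check_branch_lengths(tree: PhyloTree) -> None:
    for node in tree.preorder():
        if node is not tree.root and node.length <= 0:
            raise ValueError(
                f"branch into {node.label!r} has non-positive length; "
                "BM reconstruction requires strictly positive branch lengths"
            )


def bm_ancestral_ml(
    tree: PhyloTree, tip_values: Mapping[str, float]
) -> dict[str, tuple[float, float]]:
    """ML ancestral states under Brownian motion with conditional variances.

    Parameters
    ----------
    tree
        Rooted tree with labelled internal nodes and strictly positive
        branch lengths.
    tip_values
        Finite trait value for every tip.

    Returns
    -------
    dict
        ``{internal_label: (estimate, variance)}``.  The root estimate is the
        phylogenetically (GLS) weighted mean of the tips; every estimate lies
        within ``[min(tips), max(tips)]``; the variance is the conditional
        variance of the node state given the tips at the ML rate ``σ²``.
    """
    _check_branch_lengths(tree)
    tips = tree.tips()
    internals = tree.internal_nodes()
    for tip in tips:
        if tip.label not in tip_values:
            raise KeyError(f"missing trait value for tip {tip.label!r}")
        if not np.isfinite(tip_values[tip.label]):
            raise ValueError(f"non-finite trait value for tip {tip.label!r}")

    nodes = internals + tips
    idx = {id(n): i for i, n in enumerate(nodes)}
    m, n = len(internals), len(tips)

    # graph Laplacian weighted by 1/branch length over all nodes
    lap = np.zeros((m + n, m + n))
    for node in tree.preorder():
        if node is tree.root:
            continue
        w = 1.0 / node.length
        i, j = idx[id(node)], idx[id(node.parent)]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w

    x_tip = np.array([float(tip_values[t.label]) for t in tips])
    l_ii = lap[:m, :m]
    l_it = lap[:m, m:]
    l_ii_inv = np.linalg.inv(l_ii)
    estimates = l_ii_inv @ (-l_it @ x_tip)

    sigma2 = _bm_sigma2_ml(tree, tips, x_tip)
    variances = sigma2 * np.diag(l_ii_inv)
    return {
        node.label: (float(est), float(var))
        for node, est, var in zip(internals, estimates, variances)
    }


def bm_ancestral_batch(tree: PhyloTree, tip_matrix) -> "object":
    """ML ancestral estimates for many traits sharing one tree.

    ``tip_matrix`` is a DataFrame with species rows and one column per
    trait/gene; the Laplacian solve is factored once, so reconstruction is a
    single matrix product.  Returns a DataFrame (internal labels × columns)
    of estimates (no variances; use :func:`bm_ancestral_ml` per trait for
    those).
    """
    import pandas as pd

    _check_branch_lengths(tree)
    tips = tree.tips()
    internals = tree.internal_nodes()
    missing = [t.label for t in tips if t.label not in tip_matrix.index]
    if missing:
        raise KeyError(f"missing trait rows for tips {missing}")
    nodes = internals + tips
    idx = {id(n): i for i, n in enumerate(nodes)}
    m = len(internals)
    lap = np.zeros((len(nodes), len(nodes)))
    for node in tree.preorder():
        if node is tree.root:
            continue
        w = 1.0 / node.length
        i, j = idx[id(node)], idx[id(node.parent)]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
    weights = np.linalg.solve(lap[:m, :m], -lap[:m, m:])
    x = tip_matrix.loc[[t.label for t in tips]].to_numpy(dtype=float)
    est = weights @ x
    return pd.DataFrame(est, index=[n.label for n in internals], columns=tip_matrix.columns)


def _bm_sigma2_ml(tree: PhyloTree, tips: list[Node], x: np.ndarray) -> float:
    """ML Brownian rate from the tip likelihood (GLS with the tree covariance)."""
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node is not tree.root:
            depth[id(node)] = depth[id(node.parent)] + node.length
    n = len(tips)
    cov = np.empty((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i <= j:
                anc = tree.mrca([a.label, b.label])
                cov[i, j] = cov[j, i] = depth[id(anc)]
    # guard: a pure cherry-at-root tree can give cov with zero rows off-diagonal
    cinv = np.linalg.pinv(cov)
    ones = np.ones(n)
    denom = ones @ cinv @ ones
    mu = (ones @ cinv @ x) / denom
    resid = x - mu
    return float(resid @ cinv @ resid) / n


def _designated_tip(node: Node) -> Node | None:
    """Most recent derived species of an internal node.

    The tip reached through a child branch that is off the backbone (the
    backbone child is the internal child with the lowest N-number, where the
    numbering continues); nearest tip by edge count, name order on ties.
    """
    internal_children = [c for c in node.children if not c.is_tip]
    backbone = None
    if internal_children:
        indexed = [(c, _n_index(c.label)) for c in internal_children]
        indexed = [(c, i) for c, i in indexed if i is not None]
        if indexed:
            backbone = min(indexed, key=lambda ci: ci[1])[0]
        else:
            backbone = internal_children[0]
    candidates: list[tuple[int, str, Node]] = []
    for child in node.children:
        if child is backbone:
            continue
        queue = [(child, 1)]
        while queue:
            cur, dist = queue.pop(0)
            if cur.is_tip:
                candidates.append((dist, cur.label, cur))
            else:
                queue.extend((c, dist + 1) for c in cur.children)
    if not candidates:
        return None
    return min(candidates)[2]


def assign_descendant_values(
    tree: PhyloTree, trait: Mapping[str, float]
) -> dict[str, float]:
    """Assign each internal node the trait value of its most recent derived tip.

    Tips map to themselves.  Nodes whose designated tip lacks the trait are
    omitted from the result and reported in a warning, never filled with 0.
    """
    out: dict[str, float] = {}
    missing: list[str] = []
    for tip in tree.tips():
        if tip.label in trait and trait[tip.label] is not None:
            val = float(trait[tip.label])
            if np.isfinite(val):
                out[tip.label] = val
    for node in tree.internal_nodes():
        tip = _designated_tip(node)
        if tip is not None and tip.label in out:
            out[node.label] = out[tip.label]
        else:
            missing.append(node.label)
    if missing:
        warnings.warn(
            f"no valued descendant for nodes {missing}; values flagged missing",
            stacklevel=2,
        )
    return out


def relative_change_continuous(
    node_values: Mapping[str, float],
    overrides: Mapping[str, str] | None = None,
    feature_class: str = "trait",
) -> NodeChangeProfile:
    """Per-node relative change ``(N − N_pre) / N_pre``.

    ``node_values`` maps internal labels (N1..Nm, tips ignored) to positive
    values; ``overrides`` carries the preceding-node exceptions.  A zero
    predecessor value makes the change undefined (flagged missing); negative
    values are refused — shift or recode the trait first.
    """
    labels = sorted(
        (lab for lab in node_values if _n_index(lab) is not None),
        key=lambda lab: _n_index(lab),
    )
    for lab in labels:
        if node_values[lab] < 0:
            raise ValueError(
                f"negative value at {lab}; relative change requires positive "
                "traits — shift or recode before calling"
            )
    profile = NodeChangeProfile(feature_class=feature_class)
    for lab in labels:
        if _n_index(lab) == 1:
            continue
        pre = preceding_node(lab, dict(overrides) if overrides else None)
        if pre not in node_values:
            profile.missing.append(lab)
            continue
        base = node_values[pre]
        if base == 0:
            profile.missing.append(lab)
            warnings.warn(
                f"predecessor value of {lab} is 0; relative change undefined",
                stacklevel=2,
            )
            continue
        profile.changes[lab] = (node_values[lab] - base) / base
    return profile
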