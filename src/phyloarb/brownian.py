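"""Continuous-trait ancestral states under Brownian motion (BM).

Under BM with rate sigma^2, trait values at the tips are jointly normal
with covariance sigma^2 * C, where C[i, j] is the shared root-to-MRCA
path length of tips i and j. The ML root state is the GLS estimate

    a_hat = (1' C^-1 1)^-1 1' C^-1 x

and sigma^2 is estimated by ML (residual quadratic form divided by n,
not n-1). The state at any internal node is the GLS root estimate of
the tree re-rooted at that node; its variance is
sigma_hat^2 * (1' C_r^-1 1)^-1 with C_r the re-rooted covariance, and
the 95% CI uses the normal multiplier 1.959964. The mean of the
per-node variances is the relative goodness-of-fit score used to
arbitrate between rival trees for continuous traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .tree import Tree
from .mk import _is_missing

__all__ = [
    "BmFit", "ContinuousAsr",
    "phylo_covariance", "fit_bm", "ancestral_estimates", "mean_node_variance",
]

CI95_MULTIPLIER = 1.959964


def phylo_covariance(tree: Tree, order: Sequence[str] | None = None) -> pd.DataFrame:
    """BM covariance structure: shared root-to-MRCA path lengths."""
    clamped = tree.clamped()
    labels = list(order) if order is not None else clamped.leaf_labels()
    pos = {lb: i for i, lb in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depth = clamped.depths()
    for lb in labels:
        C[pos[lb], pos[lb]] = depth[clamped.find(lb).id]
    below: dict[int, list] = {}
    for node in clamped.postorder():
        if node.is_leaf:
            below[node.id] = [node.label]
            continue
        kids = [below[c.id] for c in node.children]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for a in kids[i]:
                    for b in kids[j]:
                        C[pos[a], pos[b]] = C[pos[b], pos[a]] = depth[node.id]
        below[node.id] = [lb for k in kids for lb in k]
    return pd.DataFrame(C, index=labels, columns=labels)


def _gls_root(tree: Tree, x: np.ndarray, labels: Sequence[str]):
    """GLS root estimate and (1'C^-1 1)^-1 on the given tree."""
    C = phylo_covariance(tree, labels).to_numpy()
    factor = cho_factor(C)
    ones = np.ones(len(labels))
    Cinv_1 = cho_solve(factor, ones)
    Cinv_x = cho_solve(factor, x)
    denom = float(ones @ Cinv_1)
    a_hat = float(ones @ Cinv_x) / denom
    return a_hat, 1.0 / denom, factor


def _clean(tree: Tree, x: Mapping[str, float], missing: str):
    if not tree.is_binary():
        raise ValueError("BM machinery requires a strictly binary rooted tree")
    labels = tree.leaf_labels()
    absent = [lb for lb in labels if lb not in x or _is_missing(x[lb])]
    if absent:
        if missing == "strict":
            raise ValueError(f"missing values for leaves: {sorted(absent)}")
        keep = [lb for lb in labels if lb not in set(absent)]
        if len(keep) < 2:
            raise ValueError("fewer than 2 leaves with observed values")
        tree = tree.prune_to(keep)
        labels = keep
    values = {lb: float(x[lb]) for lb in labels}
    return tree, values


@dataclass
class BmFit:
    """ML Brownian-motion fit: rate and root state."""

    sigma2: float
    root_estimate: float
    tree: Tree = field(repr=False)
    values: dict[str, float] = field(repr=False)

    def to_record(self) -> dict:
        return {"sigma2": self.sigma2, "root_estimate": self.root_estimate,
                "n_taxa": self.tree.n_leaves}


def fit_bm(tree: Tree, x: Mapping[str, float], missing: str = "prune") -> BmFit:
    """ML estimates of the BM rate and the root state.

    sigma2 = (x - a 1)' C^-1 (x - a 1) / n  (ML, division by n).
    """
    tree, values = _clean(tree, x, missing)
    labels = tree.leaf_labels()
    xv = np.array([values[lb] for lb in labels])
    a_hat, _, factor = _gls_root(tree, xv, labels)
    resid = xv - a_hat
    sigma2 = float(resid @ cho_solve(factor, resid)) / len(xv)
    return BmFit(sigma2, a_hat, tree, values)


@dataclass
class ContinuousAsr:
    """Per-internal-node BM estimate, variance, and 95% CI."""

    tree: Tree = field(repr=False)
    estimates: dict[int, float] = field(repr=False)
    variances: dict[int, float] = field(repr=False)
    fit: BmFit = field(repr=False)

    def at_mrca(self, labels) -> tuple[float, float]:
        nid = self.tree.mrca(labels).id
        return self.estimates[nid], self.variances[nid]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.tree.postorder():
            if node.is_leaf:
                continue
            est, var = self.estimates[node.id], self.variances[node.id]
            half = CI95_MULTIPLIER * np.sqrt(var)
            rows.append({"node": node.id, "label": node.label or f"node{node.id}",
                         "estimate": est, "variance": var,
                         "ci_low": est - half, "ci_high": est + half})
        return pd.DataFrame(rows).set_index("node")


def ancestral_estimates(tree: Tree, x: Mapping[str, float], fit: BmFit | None = None,
                        missing: str = "prune") -> ContinuousAsr:
    """ML ancestral states for every internal node, with variances.

    Each internal node's estimate is the GLS root estimate of the tree
    re-rooted at that node; under BM with a flat prior on the root value
    this equals the conditional expectation of the node's state given the
    tips. The root entry coincides with ``fit.root_estimate``.
    """
    if fit is None:
        fit = fit_bm(tree, x, missing=missing)
    work_tree, values = _clean(tree, x, missing)
    if set(work_tree.leaf_labels()) != set(fit.tree.leaf_labels()):
        raise ValueError("fit was obtained on a different leaf set than tree/x")
    labels = work_tree.leaf_labels()
    xv = np.array([values[lb] for lb in labels])
    estimates: dict[int, float] = {}
    variances: dict[int, float] = {}
    for node in work_tree.internal_nodes():
        t = work_tree if node is work_tree.root else work_tree.reroot_at(node.id)
        # the leaf order of a re-rooted tree can change; keep a fixed order
        a_hat, inv_quad, _ = _gls_root(t, xv, labels)
        estimates[node.id] = a_hat
        variances[node.id] = fit.sigma2 * inv_quad
    return ContinuousAsr(work_tree, estimates, variances, fit)


def mean_node_variance(asr: ContinuousAsr) -> float:
    """Arithmetic mean of the ancestral-state variances over all interior
    nodes — the relative tree-fit score for a continuous trait."""
    if not asr.variances:
        raise ValueError("no interior nodes")
    return float(np.mean(list(asr.variances.values())))
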