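"""Independent oracles used by the test suite.

Everything here deliberately avoids the code paths it is used to check:
Mk marginals come from exhaustive enumeration of internal-state
assignments, BM conditional means/variances from the joint-normal
closed form on the tip covariance (flat-root-prior limit via
Sherman-Morrison), transition probabilities from a dense matrix
exponential, and Robinson-Foulds distances from dendropy.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
from scipy.linalg import expm

from phyloarb.tree import Tree, BRANCH_EPSILON


def er_rate_matrix(q: float) -> np.ndarray:
    return np.array([[-q, q], [q, -q]])


def transition_matrix_expm(q: float, t: float) -> np.ndarray:
    return expm(er_rate_matrix(q) * t)


def enumeration_mk(tree: Tree, tips: dict[str, int], model) -> tuple[dict[int, np.ndarray], float]:
    """Exact marginal posteriors and log-likelihood by summing the joint
    probability over every assignment of states to internal nodes."""
    from phyloarb.mk import transition_matrix

    internals = tree.internal_nodes()
    prior = model.prior
    post = {n.id: np.zeros(2) for n in internals}
    total = 0.0
    edge_p = {}
    for node in tree.preorder():
        if node is not tree.root:
            edge_p[node.id] = transition_matrix(model, max(node.length or 0.0, BRANCH_EPSILON))
    for assign in itertools.product((0, 1), repeat=len(internals)):
        states = {n.id: s for n, s in zip(internals, assign)}
        for leaf in tree.leaves():
            states[leaf.id] = tips[leaf.label]
        p = prior[states[tree.root.id]]
        for node in tree.preorder():
            if node is not tree.root:
                p *= edge_p[node.id][states[node.parent.id], states[node.id]]
        total += p
        for n in internals:
            post[n.id][states[n.id]] += p
    return {k: v / total for k, v in post.items()}, float(np.log(total))


def bm_conditional_oracle(tree: Tree, x: dict[str, float]):
    """Conditional mean and variance of each internal node's state given
    the tips under BM with a flat (improper) prior on the root value.

    Uses only the tip covariance C and the node-to-tip shared paths c_a;
    the flat-prior limit is taken analytically:

        E[a|x]   = c_a' W x + (1 - c_a' W 1) (1' W x) / (1' W 1)
        Var[a|x] = sigma2 [ d_a - c_a' W c_a + (1 - c_a' W 1)^2 / (1' W 1) ]

    with W = C^{-1} and d_a the node's root-to-node depth.
    """
    ct = tree.clamped()
    labels = ct.leaf_labels()
    depth = ct.depths()
    clades = ct.clades()
    n = len(labels)
    pos = {lb: i for i, lb in enumerate(labels)}

    def shared_depth(node_a, node_b):
        # depth of the MRCA of two nodes
        anc = set()
        cur = node_a
        while cur is not None:
            anc.add(cur.id)
            cur = cur.parent
        cur = node_b
        while cur.id not in anc:
            cur = cur.parent
        return depth[cur.id]

    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            C[i, j] = depth[ct.find(a).id] if i == j else shared_depth(ct.find(a), ct.find(b))
    W = np.linalg.inv(C)
    ones = np.ones(n)
    xv = np.array([x[lb] for lb in labels])
    W1, Wx = W @ ones, W @ xv
    s11, s1x = ones @ W1, ones @ Wx

    means: dict[int, float] = {}
    var_shapes: dict[int, float] = {}
    for node in ct.internal_nodes():
        c_a = np.array([shared_depth(node, ct.find(lb)) for lb in labels])
        h = 1.0 - c_a @ W1
        means[node.id] = float(c_a @ Wx + h * s1x / s11)
        var_shapes[node.id] = float(depth[node.id] - c_a @ W @ c_a + h * h / s11)
    return means, var_shapes


def dendropy_rf(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds symmetric difference via dendropy."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


def random_binary_tree(n: int, rng: np.random.Generator) -> Tree:
    """Random topology by sequential random attachment, unit-ish branch
    lengths; independent of the package's Yule simulator."""
    from phyloarb.tree import Node

    root = Node()
    a, b = Node("L1", 1.0), Node("L2", 1.0)
    root.add_child(a)
    root.add_child(b)
    leaves = [a, b]
    for k in range(3, n + 1):
        target = leaves[rng.integers(len(leaves))]
        # split the target's edge and hang a new leaf off the midpoint
        mid = Node(length=float(rng.uniform(0.2, 1.0)))
        new_leaf = Node(f"L{k}", float(rng.uniform(0.2, 1.0)))
        parent = target.parent
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        target.length = float(rng.uniform(0.2, 1.0))
        mid.add_child(target)
        mid.add_child(new_leaf)
        leaves.append(new_leaf)
    return Tree(root)


def nni_once(tree: Tree, rng: np.random.Generator) -> Tree:
    """One nearest-neighbour-interchange on a random internal edge of a
    rooted binary tree: swap a child of an internal node with its sibling.
    Alters exactly one non-trivial split when the trees are binary."""
    new = tree.copy()
    # the parent must not be the (degree-2) root: swapping across the root
    # edge only rotates children around one unrooted node, a topological no-op
    candidates = [nd for nd in new.internal_nodes()
                  if nd is not new.root and nd.parent is not None
                  and nd.parent is not new.root and not nd.is_leaf]
    # exclude edges whose swap would produce a trivial (identical) split
    rng.shuffle(candidates)
    for v in candidates:
        parent = v.parent
        siblings = [c for c in parent.children if c is not v]
        if not siblings:
            continue
        sib = siblings[0]
        child = v.children[rng.integers(len(v.children))]
        # swap sib <-> child
        parent.children[parent.children.index(sib)] = child
        v.children[v.children.index(child)] = sib
        child.parent, sib.parent = parent, v
        return Tree(new.root)
    raise ValueError("no NNI possible")
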