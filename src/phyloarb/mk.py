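"""Binary-trait Mk model: pruning likelihood, ML rate fitting, and
marginal ancestral state reconstruction by the re-rooting method.

The Mk model is a continuous-time Markov chain on states {0, 1} running
along the branches of a rooted tree. Two parameterisations are offered:

* ``ER`` (equal rates): a single rate ``q`` in both directions. The
  transition probability over a branch of length ``t`` has the closed
  form P(stay) = (1 + exp(-2 q t)) / 2.
* ``ARD`` (all rates different): forward and backward rates ``q01``,
  ``q10`` with stationary distribution (q10, q01) / (q01 + q10).

The total log-likelihood of the tip states is computed with the pruning
algorithm (post-order conditional likelihoods with per-node scaling) and
maximised over the rate(s) on a bounded log scale. The marginal state
distribution at an internal node is obtained by re-rooting the tree at
that node and normalising the prior-weighted root conditional
likelihoods — the marginal log-likelihood at the root doubles as the
goodness-of-fit score used to arbitrate between rival trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import BRANCH_EPSILON, Tree

__all__ = [
    "MkModel", "MkFit", "DiscreteAsr",
    "transition_matrix", "mk_loglik", "fit_mk", "marginal_asr",
]

LOG_RATE_BOUNDS = (np.log(1e-6), np.log(1e3))
#: Values in a tip-state mapping treated as "not observed".
MISSING_TOKENS = {None, "", "?", "-", "NA", "nan"}


def _is_missing(value) -> bool:
    if value in MISSING_TOKENS:
        return True
    try:
        return bool(np.isnan(value))
    except TypeError:
        return False


@dataclass(frozen=True)
class MkModel:
    """Binary Mk model: rates per unit branch length plus a root prior."""

    model_class: str = "ER"                      # "ER" | "ARD"
    rates: tuple[float, ...] = (1.0,)            # (q,) or (q01, q10)
    root_prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        if self.model_class not in ("ER", "ARD"):
            raise ValueError(f"unknown model class {self.model_class!r}")
        expected = 1 if self.model_class == "ER" else 2
        if len(self.rates) != expected:
            raise ValueError(f"{self.model_class} needs {expected} rate(s)")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be > 0")
        if abs(sum(self.root_prior) - 1.0) > 1e-12 or min(self.root_prior) < 0:
            raise ValueError("root prior must be a probability vector")

    @property
    def stationary(self) -> np.ndarray:
        if self.model_class == "ER":
            return np.array([0.5, 0.5])
        q01, q10 = self.rates
        return np.array([q10, q01]) / (q01 + q10)

    @property
    def prior(self) -> np.ndarray:
        return np.asarray(self.root_prior, dtype=float)


def _resolve_prior(root_prior, model_class: str, rates) -> tuple[float, float]:
    if root_prior == "flat" or root_prior is None:
        return (0.5, 0.5)
    if root_prior == "stationary":
        if model_class == "ER":
            return (0.5, 0.5)
        q01, q10 = rates
        s = q01 + q10
        return (q10 / s, q01 / s)
    p = tuple(float(v) for v in root_prior)
    return p


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """2x2 stochastic matrix P(t) = expm(Q t) in closed form."""
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    if model.model_class == "ER":
        (q,) = model.rates
        stay = 0.5 * (1.0 + np.exp(-2.0 * q * t))
        return np.array([[stay, 1 - stay], [1 - stay, stay]])
    q01, q10 = model.rates
    s = q01 + q10
    pi = np.array([q10, q01]) / s
    decay = np.exp(-s * t)
    stationary_rows = np.tile(pi, (2, 1))
    return stationary_rows + decay * (np.eye(2) - stationary_rows)


# --------------------------------------------------------------------------
# Flattened tree representation for fast, trait-vectorised pruning.

class _TreeIndex:
    """Post-order arrays for one tree: for each node its children ids and
    the (clamped) length of the edge above it."""

    def __init__(self, tree: Tree):
        self.tree = tree
        nodes = list(tree.postorder())
        self.index = {node.id: i for i, node in enumerate(nodes)}
        self.nodes = nodes
        self.n = len(nodes)
        self.lengths = np.array(
            [max(nd.length or 0.0, BRANCH_EPSILON) if nd is not tree.root else 0.0
             for nd in nodes])
        self.children = [[self.index[c.id] for c in nd.children] for nd in nodes]
        self.leaf_rows = {nd.label: i for i, nd in enumerate(nodes) if nd.is_leaf}
        self.root_row = self.index[tree.root.id]


def _tip_matrix(idx: _TreeIndex, tip_states: Mapping[str, int],
                n_traits: int = 1) -> np.ndarray:
    """Initial conditional likelihoods, shape (nodes, traits, 2)."""
    L = np.ones((idx.n, n_traits, 2))
    for label, row in idx.leaf_rows.items():
        if label not in tip_states:
            raise KeyError(f"no state for leaf {label!r}")
        state = tip_states[label]
        states = state if isinstance(state, (list, tuple, np.ndarray)) else [state] * n_traits
        for trait_i, s in enumerate(states):
            s = int(s)
            if s not in (0, 1):
                raise ValueError(f"tip state must be 0 or 1, got {s!r} for {label!r}")
            L[row, trait_i, :] = 0.0
            L[row, trait_i, s] = 1.0
    return L


def _pruning_loglik_er(idx: _TreeIndex, tips: np.ndarray, q,
                       prior: np.ndarray, return_root_conditionals=False):
    """ER pruning, vectorised over traits. ``q`` is scalar or (traits,).

    Returns per-trait log-likelihoods (and optionally the scaled root
    conditional likelihood vectors, whose prior-weighted normalisation is
    the root marginal posterior).
    """
    n_traits = tips.shape[1]
    q = np.broadcast_to(np.asarray(q, dtype=float), (n_traits,))
    L = tips.copy()
    logscale = np.zeros(n_traits)
    for i, kids in enumerate(idx.children):
        if not kids:
            continue
        acc = np.ones((n_traits, 2))
        for k in kids:
            stay = 0.5 * (1.0 + np.exp(-2.0 * q * idx.lengths[k]))  # (traits,)
            Lk = L[k]
            acc *= stay[:, None] * Lk + (1.0 - stay)[:, None] * Lk[:, ::-1]
        scale = acc.max(axis=1)
        scale = np.where(scale > 0, scale, 1.0)
        L[i] = acc / scale[:, None]
        logscale += np.log(scale)
    root_cond = L[idx.root_row]
    lik = root_cond @ prior
    loglik = np.where(lik > 0, np.log(np.maximum(lik, 1e-300)), -np.inf) + logscale
    if return_root_conditionals:
        return loglik, root_cond
    return loglik


def _pruning_loglik_general(idx: _TreeIndex, tips: np.ndarray, model: MkModel,
                            return_root_conditionals=False):
    """Single-trait pruning for any model class (used for ARD)."""
    L = tips[:, 0, :].copy()
    logscale = 0.0
    for i, kids in enumerate(idx.children):
        if not kids:
            continue
        acc = np.ones(2)
        for k in kids:
            P = transition_matrix(model, idx.lengths[k])
            acc *= P @ L[k]
        scale = acc.max()
        if scale > 0:
            L[i] = acc / scale
            logscale += np.log(scale)
        else:
            L[i] = acc
    root_cond = L[idx.root_row]
    lik = float(root_cond @ model.prior)
    loglik = (np.log(lik) if lik > 0 else -np.inf) + logscale
    if return_root_conditionals:
        return loglik, root_cond
    return loglik


def _is_binaryish(tree: Tree) -> bool:
    # strictly binary, except that the root may be trifurcating — the
    # natural shape of a re-rooted (unrooted-style) binary tree
    return all(len(n.children) == 2 for n in tree.internal_nodes()
               if n is not tree.root) and len(tree.root.children) in (2, 3)


def _prepare(tree: Tree, tip_states: Mapping[str, object], missing: str):
    """Apply the missing-data policy and return (tree, clean state map)."""
    if not _is_binaryish(tree):
        raise ValueError("Mk machinery requires a strictly binary rooted tree "
                         "(polytomies are not supported)")
    labels = tree.leaf_labels()
    absent = [lb for lb in labels if lb not in tip_states or _is_missing(tip_states[lb])]
    if absent:
        if missing == "strict":
            raise ValueError(f"missing states for leaves: {sorted(absent)}")
        if missing != "prune":
            raise ValueError(f"unknown missing policy {missing!r}")
        keep = [lb for lb in labels if lb not in set(absent)]
        if len(keep) < 2:
            raise ValueError("fewer than 2 leaves with observed states")
        tree = tree.prune_to(keep)
        labels = keep
    states = {lb: int(tip_states[lb]) for lb in labels}
    return tree, states


def mk_loglik(tree: Tree, tip_states: Mapping[str, object], model: MkModel,
              missing: str = "prune") -> float:
    """Total log-likelihood of the tip states under ``model``.

    Equals log sum_s pi_s L_s with L_s the root conditional likelihoods
    from the pruning algorithm; computed with per-node scaling so that
    55-taxon trees do not underflow.
    """
    tree, states = _prepare(tree, tip_states, missing)
    idx = _TreeIndex(tree)
    tips = _tip_matrix(idx, states)
    if model.model_class == "ER":
        return float(_pruning_loglik_er(idx, tips, model.rates[0], model.prior)[0])
    return float(_pruning_loglik_general(idx, tips, model))


@dataclass
class MkFit:
    """Maximum-likelihood Mk fit for one trait on one tree."""

    model: MkModel
    log_likelihood: float
    at_bound: bool                       # rate pinned at a search bound
    tree: Tree = field(repr=False)       # tree actually used (pruned to observed taxa)
    tip_states: dict = field(repr=False)

    def to_record(self) -> dict:
        return {
            "model_class": self.model.model_class,
            "rates": list(self.model.rates),
            "root_prior": list(self.model.root_prior),
            "log_likelihood": self.log_likelihood,
            "at_bound": self.at_bound,
            "n_taxa": self.tree.n_leaves,
        }


def _golden_max(f, lo: np.ndarray, hi: np.ndarray, iters: int = 70):
    """Vectorised golden-section maximisation on per-trait brackets."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.astype(float).copy(), hi.astype(float).copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        choose_left = fc >= fd
        b = np.where(choose_left, d, b)
        a = np.where(choose_left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    x = np.where(fc >= fd, c, d)
    return x, np.maximum(fc, fd)


def _fit_er_many(idx: _TreeIndex, tips: np.ndarray,
                 prior: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the ER rate independently for each trait column.

    Deterministic: a 33-point log-spaced scan locates the basin for every
    trait (guarding against flat-likelihood plateaus), then golden-section
    refinement converges well below 1e-8 in log-likelihood.
    """
    lo, hi = LOG_RATE_BOUNDS
    n_traits = tips.shape[1]
    grid = np.linspace(lo, hi, 33)
    scores = np.stack([_pruning_loglik_er(idx, tips, np.exp(g), prior) for g in grid])
    best = scores.argmax(axis=0)
    bracket_lo = grid[np.maximum(best - 1, 0)]
    bracket_hi = grid[np.minimum(best + 1, len(grid) - 1)]

    def objective(logq):
        return _pruning_loglik_er(idx, tips, np.exp(logq), prior)

    logq, logl = _golden_max(objective, bracket_lo, bracket_hi)
    at_bound = (logq - lo < 1e-4) | (hi - logq < 1e-4)
    # a trait at the bound keeps the bound value (boundary fit, not an error)
    logq = np.clip(logq, lo, hi)
    return np.exp(logq), logl, at_bound


def fit_mk(tree: Tree, tip_states: Mapping[str, object], model_class: str = "ER",
           root_prior="flat", missing: str = "prune") -> MkFit:
    """Maximise the Mk log-likelihood over the transition rate(s).

    The search is on log-rate within ``LOG_RATE_BOUNDS``. Degenerate data
    (all observed tips identical) drives the rate to the lower bound and
    is reported through ``at_bound`` rather than raising.
    """
    tree, states = _prepare(tree, tip_states, missing)
    idx = _TreeIndex(tree)
    tips = _tip_matrix(idx, states)
    if model_class == "ER":
        prior = np.asarray(_resolve_prior(root_prior, "ER", None))
        rates, logl, at_bound = _fit_er_many(idx, tips, prior)
        model = MkModel("ER", (float(rates[0]),), tuple(prior))
        return MkFit(model, float(logl[0]), bool(at_bound[0]), tree, states)
    if model_class != "ARD":
        raise ValueError(f"unknown model class {model_class!r}")

    from scipy.optimize import minimize

    lo, hi = LOG_RATE_BOUNDS

    def neg(params):
        q01, q10 = np.exp(params)
        pr = np.asarray(_resolve_prior(root_prior, "ARD", (q01, q10)))
        model = MkModel("ARD", (q01, q10), tuple(pr))
        return -_pruning_loglik_general(idx, tips, model)

    starts = [(np.log(0.1), np.log(0.1)), (0.0, 0.0), (np.log(0.01), np.log(1.0))]
    best = None
    for s in starts:
        res = minimize(neg, s, method="L-BFGS-B",
                       bounds=[(lo, hi), (lo, hi)],
                       options={"ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    q01, q10 = np.exp(best.x)
    prior = _resolve_prior(root_prior, "ARD", (q01, q10))
    model = MkModel("ARD", (float(q01), float(q10)), tuple(prior))
    at_bound = bool(np.any(best.x - lo < 1e-4) or np.any(hi - best.x < 1e-4))
    return MkFit(model, -float(best.fun), at_bound, tree, states)


def fit_er_rates(tree: Tree, state_matrix: pd.DataFrame | np.ndarray,
                 root_prior="flat") -> pd.DataFrame:
    """Batch ER fit: one rate/log-likelihood per trait column.

    ``state_matrix`` is (taxa x traits) with index = leaf labels; no
    missing values (use :func:`fit_mk` per trait for missing-data traits).
    Vectorising the pruning over hundreds of traits is what makes the
    simulation-based parameter-recovery checks cheap.
    """
    if isinstance(state_matrix, np.ndarray):
        state_matrix = pd.DataFrame(state_matrix, index=tree.leaf_labels())
    if not tree.is_binary():
        raise ValueError("requires a strictly binary rooted tree")
    idx = _TreeIndex(tree)
    states = {lb: state_matrix.loc[lb].to_numpy() for lb in tree.leaf_labels()}
    tips = _tip_matrix(idx, states, n_traits=state_matrix.shape[1])
    prior = np.asarray(_resolve_prior(root_prior, "ER", None))
    rates, logl, at_bound = _fit_er_many(idx, tips, prior)
    return pd.DataFrame({"rate": rates, "log_likelihood": logl, "at_bound": at_bound},
                        index=state_matrix.columns)


@dataclass
class DiscreteAsr:
    """Marginal posterior state probabilities at every internal node.

    ``posteriors`` maps node id (of :attr:`tree`, which is the fitted —
    possibly pruned — tree) to a length-2 probability vector.
    """

    tree: Tree = field(repr=False)
    posteriors: dict[int, np.ndarray] = field(repr=False)
    fit: MkFit = field(repr=False)

    def __getitem__(self, node_id: int) -> np.ndarray:
        return self.posteriors[node_id]

    def at_mrca(self, labels) -> np.ndarray:
        """Posterior at the most recent common ancestor of given leaves."""
        return self.posteriors[self.tree.mrca(labels).id]

    @property
    def root_posterior(self) -> np.ndarray:
        return self.posteriors[self.tree.root.id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.tree.postorder():
            if node.is_leaf:
                continue
            p = self.posteriors[node.id]
            rows.append({"node": node.id, "label": node.label or f"node{node.id}",
                         "p_state0": p[0], "p_state1": p[1]})
        return pd.DataFrame(rows).set_index("node")

    def __iter__(self) -> Iterator[int]:
        return iter(self.posteriors)


def marginal_asr(tree: Tree, tip_states: Mapping[str, object], fit: MkFit | None = None,
                 missing: str = "prune", **fit_kwargs) -> DiscreteAsr:
    """Marginal ancestral states by the re-rooting method.

    Each internal node in turn is made the root (the original degree-2
    root being suppressed), the pruning algorithm is run on the re-rooted
    tree, and the node's marginal distribution is the normalised
    prior-weighted vector of root conditional likelihoods. For a
    time-reversible model with its matching prior this equals the exact
    marginal posterior obtained by summing over all other nodes' states.
    """
    if fit is None:
        fit = fit_mk(tree, tip_states, missing=missing, **fit_kwargs)
    work_tree, states = _prepare(tree, tip_states, missing)
    if set(work_tree.leaf_labels()) != set(fit.tree.leaf_labels()):
        raise ValueError("fit was obtained on a different leaf set than tree/tip_states")
    model = fit.model
    prior = model.prior

    def root_posterior_of(t: Tree) -> np.ndarray:
        idx = _TreeIndex(t)
        tips = _tip_matrix(idx, states)
        if model.model_class == "ER":
            _, cond = _pruning_loglik_er(idx, tips, model.rates[0], prior,
                                         return_root_conditionals=True)
            cond = cond[0]
        else:
            _, cond = _pruning_loglik_general(idx, tips, model,
                                              return_root_conditionals=True)
        weighted = prior * cond
        return weighted / weighted.sum()

    posteriors: dict[int, np.ndarray] = {}
    for node in work_tree.internal_nodes():
        if node is work_tree.root:
            posteriors[node.id] = root_posterior_of(work_tree)
        else:
            posteriors[node.id] = root_posterior_of(work_tree.reroot_at(node.id))
    return DiscreteAsr(work_tree, posteriors, fit)
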