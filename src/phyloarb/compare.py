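"""Topology concordance: non-consensual node counts and marker tallies.

A "non-consensual node" of a test tree relative to a reference topology
is an internal node whose bipartition (split) of the shared leaf set is
absent from the reference tree's split set. The comparison is unrooted
and outgroup-agnostic; for fully binary trees the count equals half the
Robinson-Foulds distance, so a count of 0 means the test tree reproduces
the reference exactly. Poorly resolved test trees (polytomies) are not
penalised for what they leave unresolved: only splits the test tree
actually asserts can conflict, and the number of reference splits it
fails to assert is reported separately.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .tree import Tree

__all__ = ["TopologyComparison", "MarkerEval", "compare_topologies",
           "nonconsensual_count", "tally_markers"]


@dataclass(frozen=True)
class TopologyComparison:
    nonconsensual: int      # test splits conflicting with the reference
    unresolved: int         # reference splits the test tree does not assert
    shared_leaves: int


def compare_topologies(test: Tree, reference: Tree) -> TopologyComparison:
    """Count conflicting and missing splits of ``test`` against
    ``reference`` on their shared leaf set.

    Both trees are restricted to the leaf-set intersection first; fewer
    than 4 shared leaves leave no non-trivial splits to compare and raise.
    """
    shared = set(test.leaf_labels()) & set(reference.leaf_labels())
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared leaves; need >= 4 to compare topologies")
    if shared != set(test.leaf_labels()):
        test = test.prune_to(shared)
    if shared != set(reference.leaf_labels()):
        reference = reference.prune_to(shared)
    test_splits = test.split_set()
    ref_splits = reference.split_set()
    return TopologyComparison(
        nonconsensual=len(test_splits - ref_splits),
        unresolved=len(ref_splits - test_splits),
        shared_leaves=len(shared),
    )


def nonconsensual_count(test: Tree, reference: Tree) -> int:
    """Number of internal nodes of ``test`` whose split conflicts with
    ``reference``; equals RF/2 when both trees are fully binary."""
    return compare_topologies(test, reference).nonconsensual


@dataclass(frozen=True)
class MarkerEval:
    """Concordance record for one phylogenetic marker (gene/protein)."""

    name: str
    aligned_positions: int
    non_consensual_nodes: int
    unresolved: int = 0


def tally_markers(evals: Iterable[MarkerEval]) -> dict[int, list[str]]:
    """Histogram of markers keyed by non-consensual node count, the
    layout used to rank candidate marker genes."""
    out: dict[int, list[str]] = defaultdict(list)
    for ev in evals:
        out[ev.non_consensual_nodes].append(ev.name)
    return {k: sorted(v) for k, v in sorted(out.items())}
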