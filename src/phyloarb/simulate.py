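"""Study-shaped synthetic data: rival trees, traits, and toy alignments.

The generator emulates the input shape of a Dictyostelia-style trait
arbitration: ~52 ingroup taxa plus a small outgroup, partitioned into
four major groups with group 4 sampled most densely; two rival rooted
binary trees over the same leaf set — one with roughly uniform branch
lengths (the multi-protein-like tree) and one rate-heterogeneous version
of the same group structure (the SSU-rDNA-like tree: a long stem
isolating group 1 and 50-fold shortened branches inside group 4); 13
binary and 12 continuous traits with clade-structured signal; and six
short coding-sequence fragments whose per-taxon G/C content follows
clade targets spanning 0.27 (lowest, in group 4) to 0.61 (highest, in
group 2).

All randomness flows through one seeded numpy Generator, so a fixed seed
yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .tree import Node, Tree
from .seqstats import Alignment
from .validity import TraitTable

__all__ = [
    "FixtureSpec", "FixtureBundle",
    "simulate_yule", "distort_branch_lengths",
    "simulate_mk_trait", "simulate_bm_trait",
    "make_study_fixture",
]


def _rng_of(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule(n: int, birth_rate: float = 1.0, seed=0) -> Tree:
    """Rooted binary ultrametric tree under a pure-birth (Yule) process.

    Starts from two lineages at the root; each of k extant lineages
    splits at total rate ``k * birth_rate``; after the n-th lineage is
    born one further exponential interval runs to the present, and all
    pending edges are extended to it (ultrametric by construction).
    """
    if n < 2:
        raise ValueError("need n >= 2 leaves")
    rng = _rng_of(seed)
    root = Node()
    t = 0.0
    # (node, birth time of its pending edge)
    active: list[tuple[Node, float]] = [(root.add_child(Node()), 0.0),
                                        (root.add_child(Node()), 0.0)]
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        node, born = active[i]
        node.length = t - born
        active[i] = (node.add_child(Node()), t)
        active.append((node.add_child(Node()), t))
    present = t + rng.exponential(1.0 / (birth_rate * n))
    for k, (node, born) in enumerate(active):
        node.length = present - born
        node.label = f"t{k + 1}"
    return Tree(root)


def distort_branch_lengths(tree: Tree, clade_scalers: Mapping[frozenset | tuple, float],
                           stem_scalers: Mapping[frozenset | tuple, float] | None = None) -> Tree:
    """Rescale branch lengths clade-by-clade, keeping the topology.

    ``clade_scalers`` maps a leaf subset (which must be exactly the leaf
    set of one clade) to a positive factor applied to every edge strictly
    inside that clade. ``stem_scalers`` optionally rescales the single
    edge subtending a clade (the "stem"). Path lengths between leaves
    outside every scaled clade are untouched.
    """
    new = tree.copy()
    clades = new.clades()

    def clade_root(leafset: frozenset) -> Node:
        for node in new.postorder():
            if clades[node.id] == leafset:
                if node.is_leaf and len(leafset) > 1:
                    continue
                return node
        raise ValueError(f"leaf set is not a clade of the tree: {sorted(leafset)}")

    for leaves, factor in (clade_scalers or {}).items():
        if factor <= 0:
            raise ValueError("scale factors must be > 0")
        top = clade_root(frozenset(leaves))
        stack = list(top.children)
        while stack:
            node = stack.pop()
            node.length = (node.length or 0.0) * factor
            stack.extend(node.children)
    for leaves, factor in (stem_scalers or {}).items():
        if factor <= 0:
            raise ValueError("scale factors must be > 0")
        top = clade_root(frozenset(leaves))
        if top is new.root:
            raise ValueError("the root has no stem edge")
        top.length = (top.length or 0.0) * factor
    return new


def simulate_mk_trait(tree: Tree, q: float, root_state: int = 0, seed=0) -> dict[str, int]:
    """Evolve a binary trait root-to-tip under the ER Mk model.

    The state flips over a branch of length t with probability
    (1 - exp(-2 q t)) / 2. Returns leaf label -> state.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    rng = _rng_of(seed)
    states = {tree.root.id: int(root_state)}
    out: dict[str, int] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.length or 0.0
        p_flip = 0.5 * (1.0 - np.exp(-2.0 * q * t))
        s = states[node.parent.id]
        if rng.random() < p_flip:
            s = 1 - s
        states[node.id] = s
        if node.is_leaf:
            out[node.label] = s
    return out


def simulate_bm_trait(tree: Tree, sigma2: float, root_value: float = 0.0,
                      seed=0) -> dict[str, float]:
    """Evolve a continuous trait under Brownian motion: independent
    normal increments of variance sigma2 * t per branch."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = _rng_of(seed)
    values = {tree.root.id: float(root_value)}
    out: dict[str, float] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.length or 0.0
        v = values[node.parent.id]
        if sigma2 > 0 and t > 0:
            v += rng.normal(0.0, np.sqrt(sigma2 * t))
        values[node.id] = v
        if node.is_leaf:
            out[node.label] = v
    return out


# --------------------------------------------------------------------------

GROUP_NAMES = ("group1", "group2", "group3", "group4")

#: Per-clade G/C targets for the toy coding fragments. Branch II
#: (groups 3 + 4) runs AT-rich, branch I (groups 1 + 2) GC-rich; the
#: designated extreme taxa sit at exactly 0.27 and 0.61.
GC_BASE = {"outgroup": 0.45, "group1": 0.50, "group2": 0.57,
           "group3": 0.35, "group4": 0.30}
GC_JITTER = 0.02
GC_MIN_TARGET = 0.27   # first group-4 taxon
GC_MAX_TARGET = 0.61   # first group-2 taxon

FRAGMENT_NAMES = ("agl", "amdA", "purD", "purL", "rpaA", "smdA")
FRAGMENT_LENGTHS = (600, 450, 780, 1300, 520, 400)   # 0.4-1.6 kb PCR-sized


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and rates of the synthetic study bundle.

    Group sizes (3, 6, 12, 31) plus a 3-taxon outgroup mirror the
    sampling emphasis of the real data (group 4 by far the densest);
    ``group4_shorten`` and the stem/other factors create the
    rate-heterogeneous rival tree from the uniform one.
    """

    seed: int = 0
    n_outgroup: int = 3
    group_sizes: tuple[int, ...] = (3, 6, 12, 31)
    n_discrete: int = 13
    n_continuous: int = 12
    mk_rate: float = 0.5          # changes per unit branch length
    bm_sigma2: float = 1.0        # squared trait units per unit branch length
    missing_fraction: float = 0.05
    group4_shorten: float = 0.02  # 50-fold shortening inside group 4
    other_lengthen: float = 5.0   # branch stretch inside groups 1-3
    group1_stem_stretch: float = 8.0  # the long deep branch isolating group 1

    def __post_init__(self):
        if self.n_outgroup + sum(self.group_sizes) < 8:
            raise ValueError("fixture needs at least 8 taxa")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    tree_uniform: Tree
    tree_heterogeneous: Tree
    traits: TraitTable
    groups: dict[str, list[str]]        # group name -> taxon labels
    fragments: list[Alignment]          # nucleotide, one per marker
    gc_targets: dict[str, float]

    def write(self, out_dir) -> dict[str, Path]:
        """Write the bundle as newick / TSV / YAML / FASTA files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree_a": out / "treeA.nwk",
            "tree_b": out / "treeB.nwk",
            "traits": out / "traits.tsv",
            "rules": out / "rules.yaml",
            "manifest": out / "manifest.json",
        }
        self.tree_uniform.write(paths["tree_a"])
        self.tree_heterogeneous.write(paths["tree_b"])
        with open(paths["traits"], "w") as fh:
            fh.write(f"# synthetic trait table (seed={self.spec.seed})\n")
            self.traits.data.to_csv(fh, sep="\t", index_label="taxon",
                                    float_format="%.6f")
        rules_doc = {
            "seed": self.spec.seed,
            "discrete": {tr: (dict(self.traits.rules[tr])
                              if tr in self.traits.rules else None)
                         for tr in self.traits.discrete},
            "continuous": list(self.traits.continuous),
        }
        with open(paths["rules"], "w") as fh:
            fh.write(f"# synthetic binarization rules (seed={self.spec.seed})\n")
            yaml.safe_dump(rules_doc, fh, sort_keys=True)
        frag_dir = out / "fragments"
        frag_dir.mkdir(exist_ok=True)
        for aln in self.fragments:
            path = frag_dir / f"{aln.name}.fasta"
            aln.to_fasta(path)
            paths[f"fragment:{aln.name}"] = path
        with open(paths["manifest"], "w") as fh:
            json.dump({"seed": self.spec.seed,
                       "groups": {g: sorted(t) for g, t in self.groups.items()},
                       "gc_targets": self.gc_targets,
                       "fragments": [a.name for a in self.fragments]},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _scaled_subtree(rng: np.random.Generator, n: int, prefix: str,
                    depth: float) -> Tree:
    """Yule subtree rescaled to a fixed root-to-tip depth with relabelled
    leaves; single taxa become a bare leaf handled by the caller."""
    sub = simulate_yule(n, 1.0, rng)
    current = sub.depths()[sub.leaves()[0].id]   # ultrametric: any leaf
    factor = depth / current
    for node in sub.preorder():
        if node is not sub.root:
            node.length *= factor
    for k, leaf in enumerate(sub.leaves()):
        leaf.label = f"{prefix}_{k + 1:02d}"
    return sub


def make_study_fixture(spec: FixtureSpec = FixtureSpec()) -> FixtureBundle:
    """Build the full synthetic bundle for one seed."""
    rng = np.random.default_rng(spec.seed)

    # ---- the uniform-rate tree: fixed backbone, Yule groups -------------
    group_depth, stem = 0.4, 0.15
    subtrees = {}
    for name, size in zip(GROUP_NAMES, spec.group_sizes):
        subtrees[name] = _scaled_subtree(rng, size, name.replace("group", "g"), group_depth)
    og = _scaled_subtree(rng, spec.n_outgroup, "og", 0.3)

    def attach(parent: Node, sub: Tree, stem_len: float) -> None:
        sub.root.length = stem_len
        parent.add_child(sub.root)

    root = Node()
    og_node = og.root
    og_node.length = 0.3
    root.add_child(og_node)
    ingroup = root.add_child(Node(length=0.2))
    branch_i = ingroup.add_child(Node(length=0.15))
    branch_ii = ingroup.add_child(Node(length=0.15))
    attach(branch_i, subtrees["group1"], stem)
    attach(branch_i, subtrees["group2"], stem)
    attach(branch_ii, subtrees["group3"], stem)
    attach(branch_ii, subtrees["group4"], stem)
    # subtree node ids collide across independently built subtrees; renumber
    stack = [root]
    while stack:
        node = stack.pop()
        node.id = None
        stack.extend(node.children)
    tree_uniform = Tree(root)

    prefix_of = dict(zip(GROUP_NAMES, ("g1", "g2", "g3", "g4")))
    groups = {name: sorted(lb for lb in tree_uniform.leaf_labels()
                           if lb.startswith(prefix_of[name] + "_"))
              for name in GROUP_NAMES}
    groups["outgroup"] = sorted(lb for lb in tree_uniform.leaf_labels()
                                if lb.startswith("og_"))

    # ---- the rate-heterogeneous rival tree ------------------------------
    # the whole group-4 region (stem included) is compressed, as in an
    # SSU-rDNA-style tree where those species are barely separated
    tree_heterogeneous = distort_branch_lengths(
        tree_uniform,
        clade_scalers={
            frozenset(groups["group4"]): spec.group4_shorten,
            frozenset(groups["group1"]): spec.other_lengthen,
            frozenset(groups["group2"]): spec.other_lengthen,
            frozenset(groups["group3"]): spec.other_lengthen,
        },
        stem_scalers={frozenset(groups["group4"]): spec.group4_shorten,
                      frozenset(groups["group1"]): spec.group1_stem_stretch},
    )

    # ---- traits ---------------------------------------------------------
    taxa = tree_uniform.leaf_labels()
    group4 = set(groups["group4"])
    data: dict[str, dict] = {}
    rules: dict[str, Mapping] = {}
    discrete_names, continuous_names = [], []

    for j in range(spec.n_discrete):
        name = f"d{j + 1:02d}_binary"
        if j == 0:
            # clade-diagnostic trait ("stalk support" pattern): present only
            # within group 4, with a few scattered absences inside the clade
            # — as with real presence/absence traits, the boundary is not
            # perfectly clean, and those within-clade changes are what the
            # compressed branches of the rate-heterogeneous tree distort
            g4_sorted = sorted(group4)
            step = max(1, len(g4_sorted) // 3)
            losses = set(g4_sorted[::step][:3])
            states = {t: int(t in group4 and t not in losses) for t in taxa}
            name = "d01_group4_diagnostic"
        elif j == 1:
            sub4 = sorted(group4)[: len(group4) // 2]
            states = {t: int(t in set(sub4)) for t in taxa}
            name = "d02_group4_subclade"
        else:
            states = simulate_mk_trait(tree_uniform, spec.mk_rate,
                                       root_state=int(rng.random() < 0.5), seed=rng)
        if j % 3 == 2:
            # raw categorical encoding exercised through binarization rules
            data[name] = {t: ("present" if s else "absent") for t, s in states.items()}
            rules[name] = {"present": 1, "absent": 0}
        else:
            data[name] = dict(states)
        discrete_names.append(name)

    for j in range(spec.n_continuous):
        name = f"c{j + 1:02d}_bm"
        values = simulate_bm_trait(tree_uniform, spec.bm_sigma2,
                                   root_value=0.0, seed=rng)
        if j < 3:
            # clade shift: group 4 runs larger, the size-increase pattern
            values = {t: v + (2.0 if t in group4 else 0.0) for t, v in values.items()}
            name = f"c{j + 1:02d}_bm_shifted"
        data[name] = values
        continuous_names.append(name)

    frame = pd.DataFrame(data, index=taxa)
    if spec.missing_fraction > 0:
        mask = rng.random(frame.shape) < spec.missing_fraction
        # keep the diagnostic trait complete so deep-node queries always resolve
        mask[:, 0] = False
        frame = frame.mask(mask)
    table = TraitTable(frame, discrete_names, continuous_names, rules)

    # ---- coding fragments with clade G/C targets ------------------------
    gc_targets: dict[str, float] = {}
    for gname in ("outgroup",) + GROUP_NAMES:
        base = GC_BASE[gname]
        for t in groups[gname]:
            gc_targets[t] = float(np.clip(base + rng.uniform(-GC_JITTER, GC_JITTER),
                                          0.28, 0.60))
    gc_targets[groups["group4"][0]] = GC_MIN_TARGET
    gc_targets[groups["group2"][0]] = GC_MAX_TARGET

    fragments: list[Alignment] = []
    protected = {groups["group4"][0], groups["group2"][0]}
    for fname, flen in zip(FRAGMENT_NAMES, FRAGMENT_LENGTHS):
        records: dict[str, str] = {}
        for t in taxa:
            # a few taxa miss a fragment, as with failed amplifications
            if t not in protected and rng.random() < 0.08:
                continue
            gc = gc_targets[t]
            bases = rng.choice(np.array(list("GCAT")), size=flen,
                               p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
            records[t] = "".join(bases)
        fragments.append(Alignment(records, name=fname))

    return FixtureBundle(spec, tree_uniform, tree_heterogeneous, table,
                         groups, fragments, gc_targets)
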