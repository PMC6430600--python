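"""Tree arbitration by trait fit: the two-tree validity pipeline.

Rival phylogenies over the same taxa can be arbitrated by asking on
which tree the observed traits have the more likely evolutionary
history. For a binary trait the score is the root marginal
log-likelihood of the fitted Mk model; for a continuous trait, where no
such marginal exists, the score is the averaged variance of the
Brownian-motion ancestral estimates over all interior nodes (smaller =
tighter reconstruction = better fit), compared between trees as a
ratio. The summary reports, per tree, how many traits favour it and the
mean log-likelihood advantage among those traits, plus the grand mean
of the continuous variance ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .tree import Tree
from . import mk, brownian

__all__ = [
    "TraitTable", "binarize",
    "DiscreteComparison", "ContinuousComparison", "ValiditySummary", "ValidityReport",
    "compare_discrete", "compare_continuous", "variance_ratio",
    "summarize", "tree_validity",
    "load_published_loglik_table", "load_published_variance_ratios",
]

TIE_TOLERANCE = 1e-6


def binarize(column: pd.Series, rule: Mapping | None) -> pd.Series:
    """Map a raw categorical trait column onto {0, 1}, preserving missing.

    ``rule`` maps every raw category to 0 or 1; a ``None`` rule demands an
    already-binary column. An uncovered raw value is an error naming it.
    """
    out = {}
    for taxon, raw in column.items():
        if mk._is_missing(raw):
            out[taxon] = np.nan
            continue
        if rule is None:
            value = raw
        else:
            key = raw
            if key not in rule and isinstance(raw, float) and raw.is_integer():
                key = int(raw)
            if key not in rule and str(raw) in rule:
                key = str(raw)
            if key not in rule:
                raise ValueError(
                    f"trait {column.name!r}: raw value {raw!r} (taxon {taxon!r}) "
                    f"not covered by binarization rule {dict(rule)!r}")
            value = rule[key]
        value = int(value)
        if value not in (0, 1):
            raise ValueError(f"trait {column.name!r}: binarized value must be 0/1, got {value!r}")
        out[taxon] = value
    return pd.Series(out, name=column.name)


@dataclass
class TraitTable:
    """Taxon x trait matrix with binary and continuous trait columns.

    ``rules`` holds the per-trait binarization maps (raw category ->
    {0, 1}) for discrete traits whose raw encoding is not already binary.
    """

    data: pd.DataFrame
    discrete: list[str]
    continuous: list[str]
    rules: dict[str, Mapping] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dupes = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise ValueError(f"duplicate taxa in trait table: {dupes}")
        unknown = (set(self.discrete) | set(self.continuous)) - set(self.data.columns)
        if unknown:
            raise KeyError(f"traits not in table: {sorted(unknown)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def binary(self, trait: str) -> pd.Series:
        """The binarized column for a discrete trait."""
        if trait not in self.discrete:
            raise KeyError(f"{trait!r} is not a discrete trait")
        return binarize(self.data[trait], self.rules.get(trait))

    def values(self, trait: str, log10: bool = False) -> pd.Series:
        """The numeric column for a continuous trait."""
        if trait not in self.continuous:
            raise KeyError(f"{trait!r} is not a continuous trait")
        col = pd.to_numeric(self.data[trait], errors="coerce")
        if log10:
            if (col.dropna() <= 0).any():
                raise ValueError(f"trait {trait!r}: log10 transform needs positive values")
            col = np.log10(col)
        return col

    @classmethod
    def from_files(cls, traits_tsv, rules_yaml=None) -> "TraitTable":
        """Load a TSV (first column = taxon) plus a YAML sidecar declaring
        which columns are discrete/continuous and any binarization rules."""
        data = pd.read_csv(traits_tsv, sep="\t", index_col=0, comment="#")
        rules: dict = {}
        discrete: list[str] = []
        continuous: list[str] = []
        if rules_yaml is not None:
            with open(rules_yaml) as fh:
                cfg = yaml.safe_load(fh) or {}
            extra = set(cfg) - {"discrete", "continuous", "seed"}
            if extra:
                raise ValueError(f"unknown keys in rules file: {sorted(extra)}")
            disc = cfg.get("discrete", {})
            if isinstance(disc, dict):
                discrete = list(disc)
                rules = {k: v for k, v in disc.items() if v is not None}
            else:
                discrete = list(disc)
            continuous = list(cfg.get("continuous", []))
        else:
            discrete = [c for c in data.columns
                        if set(data[c].dropna().unique()) <= {0, 1, "0", "1"}]
            continuous = [c for c in data.columns if c not in discrete]
        return cls(data, discrete, continuous, rules)


@dataclass(frozen=True)
class DiscreteComparison:
    trait: str
    logl_a: float
    logl_b: float
    favoured: str           # "A" | "B" | "tie"
    n_taxa: int = 0


@dataclass(frozen=True)
class ContinuousComparison:
    trait: str
    mean_variance_a: float
    mean_variance_b: float
    ratio: float            # A over B
    n_taxa: int = 0


def _favoured(logl_a: float, logl_b: float, tie_tolerance: float = TIE_TOLERANCE) -> str:
    if abs(logl_a - logl_b) < tie_tolerance:
        return "tie"
    return "A" if logl_a > logl_b else "B"


def _common_taxa(tree_a: Tree, tree_b: Tree, observed: Iterable[str]) -> list[str]:
    common = set(tree_a.leaf_labels()) & set(tree_b.leaf_labels()) & set(observed)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} taxa shared by both trees and the trait")
    return sorted(common)


def compare_discrete(tree_a: Tree, tree_b: Tree, states: Mapping[str, object] | pd.Series,
                     model_class: str = "ER", root_prior="flat",
                     tie_tolerance: float = TIE_TOLERANCE,
                     trait: str = "") -> DiscreteComparison:
    """Fit the Mk model to one binary trait on each tree independently and
    report which tree gives the higher marginal log-likelihood.

    Both trees are pruned to the same set of taxa (those present on both
    trees with an observed state) so the two log-likelihoods describe the
    same data and are commensurable.
    """
    if isinstance(states, pd.Series):
        trait = trait or str(states.name)
        states = states.to_dict()
    observed = [t for t, v in states.items() if not mk._is_missing(v)]
    common = _common_taxa(tree_a, tree_b, observed)
    sub = {t: states[t] for t in common}
    fit_a = mk.fit_mk(tree_a.prune_to(common), sub, model_class, root_prior)
    fit_b = mk.fit_mk(tree_b.prune_to(common), sub, model_class, root_prior)
    return DiscreteComparison(trait, fit_a.log_likelihood, fit_b.log_likelihood,
                              _favoured(fit_a.log_likelihood, fit_b.log_likelihood,
                                        tie_tolerance), len(common))


def variance_ratio(asr_a: brownian.ContinuousAsr, asr_b: brownian.ContinuousAsr) -> float:
    """Ratio of mean interior-node variances, tree A over tree B."""
    denom = brownian.mean_node_variance(asr_b)
    if denom == 0:
        raise ZeroDivisionError("tree B mean node variance is zero")
    return brownian.mean_node_variance(asr_a) / denom


def compare_continuous(tree_a: Tree, tree_b: Tree, values: Mapping[str, float] | pd.Series,
                       trait: str = "") -> ContinuousComparison:
    """BM ancestral reconstruction of one continuous trait on each tree;
    the fit score is the mean interior-node variance (smaller is better)."""
    if isinstance(values, pd.Series):
        trait = trait or str(values.name)
        values = values.to_dict()
    observed = [t for t, v in values.items() if not mk._is_missing(v)]
    common = _common_taxa(tree_a, tree_b, observed)
    sub = {t: values[t] for t in common}
    asr_a = brownian.ancestral_estimates(tree_a.prune_to(common), sub)
    asr_b = brownian.ancestral_estimates(tree_b.prune_to(common), sub)
    mean_a = brownian.mean_node_variance(asr_a)
    mean_b = brownian.mean_node_variance(asr_b)
    return ContinuousComparison(trait, mean_a, mean_b, variance_ratio(asr_a, asr_b),
                                len(common))


@dataclass(frozen=True)
class ValiditySummary:
    favoured_a: int
    favoured_b: int
    ties: int
    mean_advantage_a: float     # mean |delta logL| among traits favouring A
    mean_advantage_b: float
    mean_variance_ratio: float  # grand mean of continuous A/B ratios (nan if none)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("favoured_a", "favoured_b", "ties",
                 "mean_advantage_a", "mean_advantage_b", "mean_variance_ratio")}


def summarize(discrete: Sequence, ratios: Sequence[float] = (),
              tie_tolerance: float = TIE_TOLERANCE) -> ValiditySummary:
    """Aggregate per-trait two-tree comparisons.

    ``discrete`` entries are either (logl_a, logl_b) pairs or
    :class:`DiscreteComparison` objects. Ties fall in neither favoured
    count and are excluded from the mean-advantage denominators.
    """
    adv_a, adv_b, ties = [], [], 0
    for entry in discrete:
        if isinstance(entry, DiscreteComparison):
            la, lb = entry.logl_a, entry.logl_b
        else:
            la, lb = float(entry[0]), float(entry[1])
        side = _favoured(la, lb, tie_tolerance)
        if side == "tie":
            ties += 1
        elif side == "A":
            adv_a.append(la - lb)
        else:
            adv_b.append(lb - la)
    ratios = [float(r) for r in ratios]
    return ValiditySummary(
        favoured_a=len(adv_a),
        favoured_b=len(adv_b),
        ties=ties,
        mean_advantage_a=float(np.mean(adv_a)) if adv_a else math.nan,
        mean_advantage_b=float(np.mean(adv_b)) if adv_b else math.nan,
        mean_variance_ratio=float(np.mean(ratios)) if ratios else math.nan,
    )


@dataclass
class ValidityReport:
    """Full two-tree arbitration: per-trait rows plus the summary."""

    discrete: list[DiscreteComparison]
    continuous: list[ContinuousComparison]
    summary: ValiditySummary
    tree_a_name: str = "tree_a"
    tree_b_name: str = "tree_b"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.discrete:
            rows.append({"trait": d.trait, "kind": "discrete",
                         "logl_a": d.logl_a, "logl_b": d.logl_b,
                         "favoured": d.favoured, "ratio_a_over_b": np.nan,
                         "n_taxa": d.n_taxa})
        for c in self.continuous:
            rows.append({"trait": c.trait, "kind": "continuous",
                         "logl_a": np.nan, "logl_b": np.nan,
                         "favoured": "A" if c.ratio < 1 else ("B" if c.ratio > 1 else "tie"),
                         "ratio_a_over_b": c.ratio, "n_taxa": c.n_taxa})
        return pd.DataFrame(rows)


def tree_validity(tree_a: Tree, tree_b: Tree, table: TraitTable,
                  model_class: str = "ER", root_prior="flat",
                  log10_traits: Sequence[str] = (),
                  tie_tolerance: float = TIE_TOLERANCE) -> ValidityReport:
    """Run the whole arbitration: every discrete trait through the Mk
    comparison, every continuous trait through the BM variance ratio."""
    discrete = [compare_discrete(tree_a, tree_b, table.binary(tr),
                                 model_class, root_prior, tie_tolerance, trait=tr)
                for tr in table.discrete]
    continuous = [compare_continuous(tree_a, tree_b,
                                     table.values(tr, log10=tr in set(log10_traits)),
                                     trait=tr)
                  for tr in table.continuous]
    summary = summarize(discrete, [c.ratio for c in continuous], tie_tolerance)
    return ValidityReport(discrete, continuous, summary)


# --------------------------------------------------------------------------
# Published Dictyostelia arbitration statistics, shipped as reference data.

def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("phyloarb.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_published_loglik_table() -> pd.DataFrame:
    """The 13 published binary-trait log-likelihood pairs (AAPPRS vs SSU
    rDNA trees of Dictyostelia)."""
    return _read_packaged("dictyostelia_discrete_loglik.tsv")


def load_published_variance_ratios() -> pd.DataFrame:
    """The 12 published continuous-trait mean-variance ratios (AAPPRS
    over SSU rDNA)."""
    return _read_packaged("dictyostelia_variance_ratios.tsv")
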