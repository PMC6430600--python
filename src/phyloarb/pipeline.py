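"""File-level orchestration: configs in, TSV/JSON reports out.

Everything here is a thin, reproducible wrapper over the library: a flat
YAML config (unknown keys are errors) is hashed, every output carries
the hash and seed, and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd
import yaml

from .tree import Tree
from . import mk, brownian, validity, compare

__all__ = ["RunConfig", "run_validity", "run_marker_eval"]

logger = logging.getLogger("phyloarb")


@dataclass
class RunConfig:
    """Flat run configuration for the validity and marker pipelines."""

    tree_a: str = ""
    tree_b: str = ""
    traits: str = ""
    rules: str | None = None
    reference: str = ""        # marker evaluation
    markers_dir: str = ""
    out_dir: str = "phyloarb_out"
    model_class: str = "ER"
    root_prior: str = "flat"
    log10_traits: list = field(default_factory=list)
    tie_tolerance: float = 1e-6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @property
    def digest(self) -> str:
        """Hash of everything that determines the results (the output
        location itself does not)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(yaml.safe_dump(payload, sort_keys=True)
                              .encode()).hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path: Path, config: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={config.digest} seed={config.seed}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.6f")


def _write_json(payload: dict, path: Path, config: RunConfig) -> None:
    payload = {"config": config.digest, "seed": config.seed, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def run_validity(config: RunConfig) -> dict[str, Path]:
    """Two-tree trait arbitration from files; writes the per-trait table,
    the JSON summary, and per-trait per-node ancestral-state tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree_a = Tree.from_file(config.tree_a)
    tree_b = Tree.from_file(config.tree_b)
    table = validity.TraitTable.from_files(config.traits, config.rules)
    logger.info("validity run: %d discrete, %d continuous traits on %d/%d-leaf trees",
                len(table.discrete), len(table.continuous),
                tree_a.n_leaves, tree_b.n_leaves)

    report = validity.tree_validity(tree_a, tree_b, table,
                                    model_class=config.model_class,
                                    root_prior=config.root_prior,
                                    log10_traits=config.log10_traits,
                                    tie_tolerance=config.tie_tolerance)
    paths = {"report": out / "validity_report.tsv", "summary": out / "summary.json"}
    _write_tsv(report.to_frame(), paths["report"], config)
    _write_json({"summary": report.summary.to_dict()}, paths["summary"], config)

    asr_dir = out / "asr"
    asr_dir.mkdir(exist_ok=True)
    fit_records: dict[str, dict] = {}
    for label, tree in (("treeA", tree_a), ("treeB", tree_b)):
        for trait in table.discrete:
            states = table.binary(trait).dropna()
            pruned = sorted(set(tree.leaf_labels()) - set(states.index))
            if pruned:
                logger.info("%s/%s: pruned taxa without data: %s", label, trait, pruned)
            asr = mk.marginal_asr(tree, states.to_dict(),
                                  model_class=config.model_class,
                                  root_prior=config.root_prior)
            path = asr_dir / f"{trait}__{label}.tsv"
            _write_tsv(asr.to_frame(), path, config, index=True)
            paths[f"asr:{trait}:{label}"] = path
            fit_records[f"{trait}:{label}"] = asr.fit.to_record()
        for trait in table.continuous:
            values = table.values(trait, log10=trait in set(config.log10_traits)).dropna()
            casr = brownian.ancestral_estimates(tree, values.to_dict())
            path = asr_dir / f"{trait}__{label}.tsv"
            _write_tsv(casr.to_frame(), path, config, index=True)
            paths[f"asr:{trait}:{label}"] = path
            fit_records[f"{trait}:{label}"] = casr.fit.to_record()
    paths["fits"] = out / "fits.json"
    _write_json({"fits": fit_records}, paths["fits"], config)
    return paths


def run_marker_eval(config: RunConfig) -> dict[str, Path]:
    """Compare every tree in ``markers_dir`` against the reference and
    tally markers by non-consensual node count."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = Tree.from_file(config.reference)
    marker_paths = sorted(Path(config.markers_dir).glob("*.nwk"))
    if not marker_paths:
        raise FileNotFoundError(f"no .nwk trees in {config.markers_dir}")
    evals, skipped = [], []
    for path in marker_paths:
        try:
            test = Tree.from_file(path)
            cmp_ = compare.compare_topologies(test, reference)
        except Exception as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append(path.name)
            continue
        evals.append(compare.MarkerEval(path.stem, 0, cmp_.nonconsensual, cmp_.unresolved))
    frame = pd.DataFrame([{"marker": e.name,
                           "nonconsensual": e.non_consensual_nodes,
                           "unresolved": e.unresolved} for e in evals])
    histogram = {str(k): v for k, v in compare.tally_markers(evals).items()}
    paths = {"markers": out / "markers.tsv", "histogram": out / "marker_histogram.json"}
    _write_tsv(frame, paths["markers"], config)
    _write_json({"histogram": histogram, "skipped": skipped}, paths["histogram"], config)
    if skipped:
        logger.warning("%d marker tree(s) skipped", len(skipped))
    return paths
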