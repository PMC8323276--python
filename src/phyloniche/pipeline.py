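"""Configuration-driven orchestration of the full analysis.

A run executes, in order: input loading (or simulation) -> species
reconciliation -> per-dimension niche reduction -> PCA ordination -> KDE
occupancy regions -> hypervolume null-model test -> functional-group
classification -> group/family summaries -> PSV permutation test ->
phylogenetic fuzzy weighting -> PCPS. Every stage writes a machine-readable
report under the output directory, and the run manifest records seeds,
input digests and per-stage runtimes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from phyloniche import __version__ as _pkg_version
from phyloniche.errors import InvalidParameterError, StageError
from phyloniche.groups import classify, group_summary, write_group_assignment
from phyloniche.hypervolume import NULL_MODELS, hypervolume_test
from phyloniche.io import (
    read_ecology_table,
    read_trait_table,
    read_tree,
    reconcile,
    write_ecology_table,
    write_trait_table,
    write_tree,
)
from phyloniche.phylo import (
    fuzzy_weighting,
    pcps,
    phylo_correlation,
    psv_permutation_test,
)
from phyloniche.reduction import build_functional_variables, kde_regions, pca_functional
from phyloniche.simulate import (
    SimulationConfig,
    simulate_ecology,
    simulate_phylogeny,
    simulate_traits,
    substream,
)


@dataclass
class PipelineConfig:
    """Either file inputs or a simulation block, plus stage parameters."""

    outdir: str = "results/run"
    seed: int = 0
    traits_path: str | None = None
    traits_meta_path: str | None = None
    tree_path: str | None = None
    ecology_path: str | None = None
    simulation: SimulationConfig | None = None
    null_models: tuple[str, ...] = NULL_MODELS
    replicates: int = 999
    psv_replicates: int = 1000
    alpha: float = 0.05
    kde_levels: tuple[float, ...] = (50.0, 95.0, 99.0)
    retain_threshold: float = 10.0

    def __post_init__(self) -> None:
        has_paths = any(
            p is not None
            for p in (self.traits_path, self.tree_path, self.ecology_path)
        )
        if has_paths and self.simulation is not None:
            raise InvalidParameterError(
                "config must give either input paths or a simulation block, not both"
            )
        if not has_paths and self.simulation is None:
            raise InvalidParameterError(
                "config must give input paths or a simulation block"
            )
        if has_paths:
            missing = [
                name
                for name, p in (
                    ("traits_path", self.traits_path),
                    ("traits_meta_path", self.traits_meta_path),
                    ("tree_path", self.tree_path),
                    ("ecology_path", self.ecology_path),
                )
                if p is None
            ]
            if missing:
                raise InvalidParameterError(
                    f"file-input config is missing: {missing}"
                )
        for m in self.null_models:
            if m not in NULL_MODELS:
                raise InvalidParameterError(f"unknown null model {m!r}")
        if self.replicates < 1 or self.psv_replicates < 1:
            raise InvalidParameterError("replicate counts must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if any(not 0.0 < l < 100.0 for l in self.kde_levels):
            raise InvalidParameterError("KDE levels must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = dict(raw)
        if sim is not None:
            cfg["simulation"] = SimulationConfig(**sim)
        for key in ("null_models", "kde_levels"):
            if key in cfg and cfg[key] is not None:
                cfg[key] = tuple(cfg[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    Any stage failure raises :class:`StageError` naming the stage and a
    reproduction command.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "stages": [],
        "inputs": {},
    }

    def stage(name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(
                name,
                str(exc),
                repro=f"phyloniche run-all --config <config.yaml> --seed {config.seed}",
            ) from exc
        manifest["stages"].append(
            {"name": name, "runtime_s": round(time.perf_counter() - t0, 4)}
        )
        return result

    # ---- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(exist_ok=True)

        def _simulate():
            tree = simulate_phylogeny(sim)
            traits = simulate_traits(tree, sim)
            eco = simulate_ecology(tree, sim)
            write_tree(tree, inputs_dir / "tree.nwk")
            write_trait_table(
                traits, inputs_dir / "traits.csv", inputs_dir / "traits_meta.csv"
            )
            write_ecology_table(eco, inputs_dir / "ecology.csv")
            return traits, tree, eco

        traits, tree, eco = stage("simulate", _simulate)
        for name in ("tree.nwk", "traits.csv", "traits_meta.csv", "ecology.csv"):
            manifest["inputs"][name] = _digest(inputs_dir / name)
    else:
        def _load():
            return (
                read_trait_table(config.traits_path, config.traits_meta_path),
                read_tree(config.tree_path),
                read_ecology_table(config.ecology_path),
            )

        traits, tree, eco = stage("load", _load)
        for name, p in (
            ("traits", config.traits_path),
            ("traits_meta", config.traits_meta_path),
            ("tree", config.tree_path),
            ("ecology", config.ecology_path),
        ):
            manifest["inputs"][name] = _digest(Path(p))

    # ---- reconcile --------------------------------------------------------
    def _reconcile():
        t, tr, e, report = reconcile(traits, tree, eco)
        report.write(outdir / "reconcile.json")
        return t, tr, e

    traits, tree, eco = stage("reconcile", _reconcile)

    # ---- niche reduction --------------------------------------------------
    def _reduce():
        red = build_functional_variables(traits)
        red.variables.to_csv(outdir / "functional_variables.csv")
        red.dimension_variance.to_csv(outdir / "dimension_variance.csv")
        return red

    reduction = stage("reduce", _reduce)

    def _pca():
        res = pca_functional(reduction.variables)
        res.scores.to_csv(outdir / "pca_scores.csv")
        _write_json(res.to_dict(), outdir / "pca_report.json")
        return res

    pca_res = stage("pca", _pca)

    def _kde():
        k = min(3, pca_res.scores.shape[1])
        regions = kde_regions(pca_res.scores.iloc[:, :k], levels=config.kde_levels)
        _write_json(regions.summary(), outdir / "kde_report.json")
        regions.membership.to_csv(outdir / "kde_membership.csv")
        return regions

    stage("kde", _kde)

    # ---- hypervolume ------------------------------------------------------
    def _hull():
        report = hypervolume_test(
            reduction.variables,
            models=config.null_models,
            R=config.replicates,
            seed=int(substream(config.seed, "hypervolume").integers(2**31)),
        )
        _write_json(report.to_dict(), outdir / "hypervolume_report.json")
        return report

    stage("hypervolume", _hull)

    # ---- functional groups ------------------------------------------------
    def _classify():
        ga = classify(eco)
        write_group_assignment(ga, outdir / "group_assignment.csv")
        return ga

    ga = stage("classify", _classify)

    def _summary():
        summary = group_summary(ga)
        _write_json(summary, outdir / "group_summary.json")
        return summary

    stage("group_summary", _summary)

    # ---- phylogenetic structure -------------------------------------------
    corr = stage("phylo_correlation", phylo_correlation, tree)

    def _psv():
        report = psv_permutation_test(
            ga,
            corr,
            R=config.psv_replicates,
            alpha=config.alpha,
            seed=int(substream(config.seed, "psv").integers(2**31)),
        )
        _write_json(report.to_dict(), outdir / "psv_report.json")
        return report

    stage("psv", _psv)

    def _pcps():
        P = fuzzy_weighting(tree, ga)
        P.values.to_csv(outdir / "matrix_p.csv")
        result = pcps(P, retain_threshold=config.retain_threshold)
        result.scores.to_csv(outdir / "pcps_scores.csv")
        _write_json(result.to_dict(), outdir / "pcps_report.json")
        result.species_correlations.to_csv(outdir / "pcps_species_correlations.csv")
        return result

    stage("pcps", _pcps)

    _write_json(manifest, outdir / "manifest.json")
    return manifest
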