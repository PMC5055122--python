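"""End-to-end pipeline runs with config, manifests, and seeding.

``run_pipeline`` executes the stages of the analysis in dependency
order — QC, feature selection, biclustering, marker binarization, and
then any of the downstream analyses (proliferation, pseudotime,
prototype scoring) — writing each stage's artifacts into a run
directory together with a manifest recording the stage, the SHA-256 of
its inputs, the seed substream used, and the package version.  All
randomness flows from one master seed via named per-stage substreams,
so the same config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .matrix import ExpressionMatrix
from .synth import SyntheticSpec, make_clustered_counts
from .qc import QCThresholds, run_qc
from .features import fit_noise_model, select_variable_genes
from .backspin import BackspinParams, backspin
from .markers import (
    BinarizationThresholds,
    SamplerConfig,
    binarize_genes,
    fit_all_genes,
    map_expression_profiles,
)
from .proliferation import learn_cycle_score, score_proliferation, select_cycle_genes

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "input",
    "qc",
    "feature_selection",
    "backspin",
    "binarization",
    "proliferation",
}
_STAGES = ("qc", "feature_selection", "backspin", "binarization", "proliferation")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run"
    stages: list = field(default_factory=lambda: ["qc", "feature_selection",
                                                  "backspin", "binarization"])
    input: dict = field(default_factory=lambda: {"kind": "synthetic"})
    qc: dict = field(default_factory=dict)  # QCThresholds fields
    feature_selection: dict = field(default_factory=lambda: {"n_genes": 200})
    backspin: dict = field(default_factory=dict)  # BackspinParams fields
    binarization: dict = field(default_factory=lambda: {"n_genes": 40})
    proliferation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad = [s for s in d.get("stages", []) if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def run_pipeline(config: PipelineConfig | dict) -> Path:
    """Run the configured stages; returns the run directory."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=1))

    manifests = []

    def record(stage: str, outputs: list[Path], inputs: list[Path]) -> None:
        manifests.append(
            {
                "stage": stage,
                "seed": _stage_seed(config.seed, stage),
                "version": __version__,
                "inputs": {p.name: _hash_file(p) for p in inputs},
                "outputs": {p.name: _hash_file(p) for p in outputs},
            }
        )
        (out / "manifest.json").write_text(json.dumps(manifests, indent=1))

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as err:
            raise StageError(f"stage {stage!r} failed: {err}") from err

    # --- input -----------------------------------------------------------
    kind = config.input.get("kind", "synthetic")
    if kind == "synthetic":
        spec_kwargs = {k: v for k, v in config.input.items() if k != "kind"}
        spec = SyntheticSpec(**{"seed": _stage_seed(config.seed, "input"), **spec_kwargs})
        matrix, truth = make_clustered_counts(spec)
        truth.to_json(out / "ground_truth.json")
    elif kind == "mtx":
        matrix = ExpressionMatrix.read_mtx(config.input["path"])
    elif kind == "tsv":
        matrix = ExpressionMatrix.read_tsv(config.input["path"])
    else:
        raise ValueError(f"unknown input kind {kind!r}")
    matrix.write_mtx(out / "input")
    input_files = sorted((out / "input").iterdir())
    record("input", input_files, [])

    # --- qc --------------------------------------------------------------
    if "qc" in config.stages:
        def _qc():
            thr = QCThresholds(**config.qc) if config.qc else QCThresholds(
                min_molecules=1, max_molecules=10**9, min_gene_total=4
            )
            filtered, report = run_qc(matrix, thr)
            (out / "qc_report.json").write_text(json.dumps(report, indent=1))
            filtered.write_mtx(out / "qc")
            return filtered

        matrix = run_stage("qc", _qc)
        record("qc", sorted((out / "qc").iterdir()) + [out / "qc_report.json"],
               input_files)

    # --- feature selection ----------------------------------------------
    selected = None
    if "feature_selection" in config.stages:
        def _select():
            model = fit_noise_model(matrix)
            n = min(config.feature_selection.get("n_genes", 200), len(model.residuals))
            genes = select_variable_genes(matrix, model, n)
            (out / "selected_genes.txt").write_text("\n".join(genes) + "\n")
            return genes

        selected = run_stage("feature_selection", _select)
        record("feature_selection", [out / "selected_genes.txt"], input_files)

    # --- backspin --------------------------------------------------------
    labels = None
    if "backspin" in config.stages:
        def _cluster():
            params = BackspinParams(**config.backspin)
            tree = backspin(matrix, params, seed=_stage_seed(config.seed, "backspin"))
            (out / "tree.json").write_text(json.dumps(tree.to_dict(), indent=1))
            lab = tree.leaf_labels().reindex(matrix.cells)
            lab.rename("cluster").to_csv(out / "clusters.tsv", sep="\t",
                                         index_label="cell")
            return lab

        labels = run_stage("backspin", _cluster)
        record("backspin", [out / "tree.json", out / "clusters.tsv"], input_files)

    # --- binarization ----------------------------------------------------
    if "binarization" in config.stages:
        if labels is None:
            raise StageError("stage 'binarization' failed: requires backspin labels")

        def _binarize():
            n = config.binarization.get("n_genes", 40)
            model = fit_noise_model(matrix)
            genes = select_variable_genes(matrix, model, min(n, len(model.residuals)))
            sampler = SamplerConfig(
                **{k: v for k, v in config.binarization.items() if k != "n_genes"}
            )
            posts, design = fit_all_genes(
                matrix, labels, genes, sampler,
                seed=_stage_seed(config.seed, "binarization"),
            )
            binary = binarize_genes(posts, BinarizationThresholds())
            binary.to_csv(out / "binary_patterns.tsv", sep="\t")
            map_expression_profiles(posts, design).to_csv(out / "map_profiles.csv")
            return binary

        run_stage("binarization", _binarize)
        record("binarization",
               [out / "binary_patterns.tsv", out / "map_profiles.csv"],
               [out / "clusters.tsv"])

    # --- proliferation ---------------------------------------------------
    if "proliferation" in config.stages:
        def _proliferate():
            cfg = dict(config.proliferation)
            panel_genes = cfg.pop("annotation_genes")
            panel = select_cycle_genes(matrix, panel_genes, **cfg)
            model = learn_cycle_score(
                matrix, panel, seed=_stage_seed(config.seed, "proliferation")
            )
            scores = score_proliferation(model, matrix)
            scores.to_csv(out / "proliferation.csv")
            return scores

        run_stage("proliferation", _proliferate)
        record("proliferation", [out / "proliferation.csv"], input_files)

    return out
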