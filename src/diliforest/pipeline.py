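"""End-to-end workflows: train-on-everything prediction reports and the
config-driven pipeline runner.

``train_full_and_predict`` reproduces the proactive-screening use case:
fit a model on the whole labeled dataset and report, for each new
compound, the class probabilities, the assigned class and a confidence
score.  ``run_pipeline`` chains simulate/ingest -> preprocessing -> a
validation mode -> the confidence and descriptor-frequency analyses, and
writes every artifact plus a run manifest into a fresh result directory.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .analysis import build_confidence_profile, descriptor_frequency
from .decision_forest import fit_df, fit_mcdf, predict_2class, predict_3class
from .decision_tree import TreeParams
from .io_types import (
    DataError,
    DescriptorTable,
    LabeledDescriptorTable,
    THREE_CLASS,
    TWO_CLASS,
    join_labels,
    read_descriptor_table,
    read_label_file,
    remove_constant_descriptors,
    subset_two_class,
)
from .synthetic_data import GeneratorSpec, generate, generate_dilirank_null
from .validation import (
    ValidationConfig,
    ValidationResult,
    run_bootstrap_validation,
    run_cross_validation,
    run_permutation_tests,
    summarize,
)

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, command: str, config: dict, master_seed: int, inputs: list[Path]) -> None:
    """Record what produced a result directory: command, config echo, seed,
    software version and input digests."""
    manifest = {
        "command": command,
        "config": config,
        "master_seed": master_seed,
        "software_version": __version__,
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def make_result_dir(base: Path, stem: str) -> Path:
    """A fresh, never-overwritten result directory (suffixing on collision)."""
    base = Path(base)
    base.mkdir(parents=True, exist_ok=True)
    candidate = base / stem
    i = 1
    while candidate.exists():
        candidate = base / f"{stem}.{i}"
        i += 1
    candidate.mkdir()
    return candidate


# ---------------------------------------------------------------------------
# Application case: train on everything, predict new compounds
# ---------------------------------------------------------------------------

def train_full_and_predict(
    training: LabeledDescriptorTable,
    new_compounds: DescriptorTable,
    n_trees: int = 5,
    tree_params: TreeParams | None = None,
    tie_tol: float | None = None,
) -> pd.DataFrame:
    """Fit on the full training table and predict new compounds.

    Returns one report row per new compound: ID, per-class probabilities,
    assigned class (2-class or winner-takes-all 3-class with ``unknown``)
    and confidence.  An empty prediction set yields an empty report.
    """
    if training.scheme.n_classes == 2:
        model = fit_df(training, n_trees, tree_params)
        preds = predict_2class(model, new_compounds) if new_compounds.n else []
    else:
        model = fit_mcdf(training, n_trees, tree_params)
        preds = predict_3class(model, new_compounds, tie_tol) if new_compounds.n else []
    rows = []
    for p in preds:
        row = {"compound_id": p.compound_id}
        row.update({f"p_{cls}": prob for cls, prob in p.probabilities.items()})
        row["assigned"] = p.assigned_class
        row["confidence"] = p.confidence
        rows.append(row)
    columns = (
        ["compound_id"]
        + [f"p_{c}" for c in ([training.scheme.positive] if training.scheme.n_classes == 2 else training.scheme.classes)]
        + ["assigned", "confidence"]
    )
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

_RUNNERS = {
    "crossval": run_cross_validation,
    "permutation": run_permutation_tests,
    "bootstrapA": run_bootstrap_validation,
    "bootstrapB": run_bootstrap_validation,
}


def _load_table_from_config(cfg: dict) -> tuple[LabeledDescriptorTable, list[Path]]:
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        preset = sim.pop("preset", None)
        if preset == "dilirank-2class":
            return generate_dilirank_null("two_class", seed=sim.get("seed", 0)), []
        if preset == "dilirank-3class":
            return generate_dilirank_null("three_class", seed=sim.get("seed", 0)), []
        return generate(GeneratorSpec(**sim)).table, []
    if "input" in cfg:
        inp = cfg["input"]
        table = read_descriptor_table(inp["descriptors"], id_column=inp.get("id_column", "ID"))
        labels = read_label_file(inp["labels"])
        scheme = THREE_CLASS if inp.get("classes", 2) == 3 else TWO_CLASS
        labeled = join_labels(table, labels, scheme)
        return labeled, [Path(inp["descriptors"]), Path(inp["labels"])]
    raise DataError("pipeline config needs a 'simulate' or 'input' section")


def run_pipeline(config: dict | str | Path, out_base: Path | str = "results") -> Path:
    """Execute a full configured run and return the result directory.

    Stages: load/simulate data, drop constant descriptors, optionally
    reduce to the binary problem, run the configured validation mode, then
    write per-iteration metrics, pooled predictions, a JSON summary, the
    confidence profile and the descriptor-frequency table.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    stage = "load"
    try:
        table, inputs = _load_table_from_config(config)
        stage = "preprocess"
        table, removed = remove_constant_descriptors(table)
        if config.get("subset_two_class"):
            table = subset_two_class(table)
        stage = "validate"
        vcfg_raw = dict(config.get("validation", {}))
        tp = vcfg_raw.pop("tree_params", {})
        vcfg = ValidationConfig(tree_params=TreeParams(**tp), **vcfg_raw)
        result = _RUNNERS[vcfg.mode](table, vcfg)
        stage = "analyze"
        out_dir = make_result_dir(Path(out_base), time.strftime("run-%Y%m%d-%H%M%S"))
        _write_validation_outputs(result, out_dir)
        write_manifest(out_dir, "pipeline", config, vcfg.master_seed, inputs)
        return out_dir
    except Exception as exc:  # noqa: BLE001 - stage-named abort is the contract
        raise DataError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_validation_outputs(result: ValidationResult, out_dir: Path) -> None:
    metrics_rows = []
    for it in result.iterations:
        row = {"iteration": it.index}
        row.update(it.metrics.as_dict())
        metrics_rows.append(row)
    pd.DataFrame(metrics_rows).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    result.pooled_predictions().to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
    summary = summarize(result)
    if result.mode == "permutation":
        summary["note"] = "null-model (labels permuted)"
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    profile = build_confidence_profile(result)
    profile.as_frame().to_csv(out_dir / "confidence_profile.tsv", sep="\t", index=False)
    freq = descriptor_frequency(result)
    freq.frame.to_csv(out_dir / "descriptor_frequency.tsv", sep="\t", index=False)
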