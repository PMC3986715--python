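"""End-to-end workflow: design -> dissolution data -> sweep -> retrain -> optimize.

Mirrors the study protocol on synthetic data: a central composite design
defines the corpus, a hidden-node sweep picks the architecture, the chosen
network is retrained on the full corpus, and a brute-force grid search
selects the composition whose predicted profile best matches the
reference (highest f2).  Every stage writes its artifact to the output
directory so any stage can be rerun in isolation, and all randomness
derives deterministically from one global seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import DissolutionProfile, Formulation, FormulationDataset
from .doe import CCDSpec, generate_ccd
from .io import time_column_name, write_dataset
from .optimizer import OptimizationResult, SearchGrid, optimize
from .surrogate import (
    SplitSpec,
    TrainingLimits,
    _derive_seeds,
    node_sweep,
    retrain_full,
    save_model,
)
from .synthetic import ReleaseModelParams, generate_study, make_reference

__all__ = ["PipelineConfig", "PipelineError", "PipelineReport", "run_pipeline"]

log = logging.getLogger("dissopt.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the workflow needs, validated before any computation."""

    seed: int = 0
    ccd: CCDSpec = field(default_factory=CCDSpec)
    release: ReleaseModelParams = field(default_factory=ReleaseModelParams)
    split: SplitSpec = field(default_factory=SplitSpec)
    limits: TrainingLimits = field(default_factory=TrainingLimits)
    sweep_nodes: tuple[int, ...] = tuple(range(3, 11))
    sweep_repeats: int = 2
    grid: SearchGrid = field(default_factory=SearchGrid)
    reference_composition: Formulation = field(
        default_factory=lambda: Formulation(45.0, 30.0, 5.0, 10.0)
    )
    top_k: int = 10

    def __post_init__(self) -> None:
        if not self.sweep_nodes:
            raise ValueError("sweep_nodes must not be empty")
        if any(c < 1 for c in self.sweep_nodes):
            raise ValueError("sweep_nodes must be >= 1")
        if self.sweep_repeats < 1:
            raise ValueError("sweep_repeats must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        if "seed" in doc:
            kwargs["seed"] = int(doc["seed"])
        if "ccd" in doc:
            kwargs["ccd"] = CCDSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in doc["ccd"].items()
            })
        if "release" in doc:
            kwargs["release"] = ReleaseModelParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in doc["release"].items()
            })
        if "split" in doc:
            kwargs["split"] = SplitSpec(**doc["split"])
        if "limits" in doc:
            kwargs["limits"] = TrainingLimits(**doc["limits"])
        if "sweep_nodes" in doc:
            kwargs["sweep_nodes"] = tuple(int(c) for c in doc["sweep_nodes"])
        if "sweep_repeats" in doc:
            kwargs["sweep_repeats"] = int(doc["sweep_repeats"])
        if "grid" in doc:
            kwargs["grid"] = SearchGrid(**{
                k: tuple(v) for k, v in doc["grid"].items()
            })
        if "reference_composition" in doc:
            kwargs["reference_composition"] = Formulation(
                *doc["reference_composition"]
            )
        if "top_k" in doc:
            kwargs["top_k"] = int(doc["top_k"])
        return cls(**kwargs)


@dataclass(frozen=True)
class PipelineReport:
    """In-memory bundle of everything the pipeline produced."""

    design: list[Formulation]
    dataset: FormulationDataset
    sweep_table: "object"  # pandas DataFrame
    selected_nodes: int
    reference: DissolutionProfile
    optimization: OptimizationResult
    seeds: dict[str, int]


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # noqa: BLE001 — rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineReport:
    """Execute all stages, writing artifacts and a run log under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        data_seed, sweep_seed, retrain_seed = _derive_seeds(config.seed, 3)
        seeds = {
            "global": config.seed,
            "data": data_seed,
            "sweep": sweep_seed,
            "retrain": retrain_seed,
        }
        log.info("dissopt %s; seeds %s", __version__, seeds)

        design = _stage("design")(generate_ccd)(config.ccd)
        _write_design(design, out / "design.csv")
        log.info("design: %d runs -> design.csv", len(design))

        release = replace(config.release, seed=data_seed)
        dataset = _stage("simulate")(generate_study)(release, design)
        write_dataset(dataset, out / "dataset.csv")
        log.info("simulate: %d records -> dataset.csv", len(dataset))

        sweep_table, selected = _stage("sweep")(node_sweep)(
            dataset,
            config.sweep_nodes,
            repeats=config.sweep_repeats,
            seed=sweep_seed,
            limits=config.limits,
            split=config.split,
        )
        sweep_table.to_csv(out / "sweep.csv", index=False)
        log.info("sweep: selected %d hidden nodes -> sweep.csv", selected)

        net = _stage("retrain")(retrain_full)(
            dataset, selected, limits=config.limits, seed=retrain_seed
        )
        save_model(net, out / "model.json")
        log.info("retrain: full-corpus model -> model.json")

        reference = _stage("reference")(make_reference)(
            replace(config.release, noise_sd=0.0),
            config.reference_composition,
        )
        _write_profile(reference, "REFERENCE", out / "reference.csv")

        result = _stage("optimize")(optimize)(
            net, reference, config.grid, top_k=config.top_k
        )
        log.info(
            "optimize: best %s, f2=%.2f over %d candidates",
            result.best.as_tuple(), result.f2, result.n_evaluated,
        )
        _write_report(config, seeds, selected, reference, result, out / "report.json")
        return PipelineReport(
            design=design,
            dataset=dataset,
            sweep_table=sweep_table,
            selected_nodes=selected,
            reference=reference,
            optimization=result,
            seeds=seeds,
        )
    finally:
        log.removeHandler(fh)
        fh.close()


def _write_design(design: list[Formulation], path: Path) -> None:
    import pandas as pd

    from .core import FACTOR_NAMES

    rows = [
        {"id": f"SAL{i:03d}", **dict(zip(FACTOR_NAMES, f.as_tuple()))}
        for i, f in enumerate(design, start=1)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_profile(profile: DissolutionProfile, label: str, path: Path) -> None:
    cols = ["id"] + [time_column_name(t) for t in profile.times_h]
    vals = [label] + [f"{v:.10g}" for v in profile.release_pct]
    path.write_text(
        ",".join(cols) + "\n" + ",".join(str(v) for v in vals) + "\n",
        encoding="utf-8",
    )


def _write_report(config, seeds, selected, reference, result, path: Path) -> None:
    clipped = result.predicted_profile.clipped()
    doc = {
        "dissopt_version": __version__,
        "numpy_version": np.__version__,
        "seeds": seeds,
        "selected_hidden_nodes": selected,
        "reference_profile": {
            time_column_name(t): v
            for t, v in zip(reference.times_h, reference.release_pct)
        },
        "best_formulation": dict(
            zip(
                ("methocel_mg", "xanthan_mg", "carbopol_mg", "surelease_pct"),
                result.best.as_tuple(),
            )
        ),
        "filler": "Avicel PH101 as balance to tablet weight",
        "predicted_profile": {
            time_column_name(t): v
            for t, v in zip(clipped.times_h, clipped.release_pct)
        },
        "f2": result.f2,
        "n_evaluated": result.n_evaluated,
        "top_k": [
            {"formulation": f.as_tuple(), "f2": s} for f, s in result.top_k
        ],
    }
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
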