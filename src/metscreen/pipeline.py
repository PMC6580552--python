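"""End-to-end orchestration: load/synthesize -> simulate -> screen -> signatures.

Every run writes its tables plus a manifest that echoes all parameters and
seeds; re-running the same configuration reproduces the TSVs byte for byte
(numbers are formatted to 6 significant digits).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import synth as synthmod
from .network import MetabolicModel, load_model, model_summary
from .profiles import (
    Cohort,
    join_cohort,
    read_annotations,
    read_expression_matrix,
    read_ic50_table,
)
from .screen import StratifiedResult, stratified_run
from .simulate import SimulationConfig, simulate_cohort, write_simulation
from .synth import SyntheticSpec

logger = logging.getLogger("metscreen")

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """One fully-specified analysis run (real files XOR a synthetic spec)."""

    # real-mode inputs
    model_path: str | None = None
    expression_path: str | None = None
    ic50_path: str | None = None
    annotations_path: str | None = None
    # synthetic mode
    synthetic: SyntheticSpec | None = None
    n_planted: int = 5
    effect_size: float = 1.5
    # simulation & statistics
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    threshold: float = 0.15
    alpha: float = 0.05
    min_n: int = 10
    family_size: int | None = None
    aggregation: str = "mean"
    strata: tuple[str, ...] = ("all",)
    # bookkeeping
    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"
    write_sim_matrix: bool = True

    def __post_init__(self):
        real = any([self.model_path, self.expression_path, self.ic50_path])
        if real and self.synthetic is not None:
            raise ValueError("provide either real input paths or a synthetic spec, not both")
        if not real and self.synthetic is None:
            raise ValueError("provide real input paths or a synthetic spec")
        if real and not (self.model_path and self.expression_path and self.ic50_path):
            raise ValueError("real mode needs model_path, expression_path and ic50_path")
        if not (0 <= self.threshold <= 1):
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw:
            raw["sim"] = SimulationConfig(**raw["sim"])
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("cancer_types", "drugs"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticSpec(**syn)
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)

    def echo(self) -> dict:
        d = asdict(self)
        return d


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        spec = config.synthetic
        logger.info("generating synthetic network (%d components / %d reactions / %d pathways)",
                    spec.n_components, spec.n_reactions, spec.n_pathways)
        model = synthmod.generate_network(spec)
        profiles = synthmod.generate_cohort(model, spec)
        return model, profiles, spec
    logger.info("loading model from %s", config.model_path)
    model = load_model(config.model_path)
    profiles = read_expression_matrix(config.expression_path, aggregation=config.aggregation)
    return model, profiles, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    files: list[str] = ["run.log"]

    try:
        model, profiles, spec = _load_inputs(config)

        logger.info("simulating %d cell lines", len(profiles))
        sim_matrix, conv = simulate_cohort(model, profiles, config.sim, aggregation=config.aggregation)
        n_conv = sum(r.converged for r in conv)
        logger.info("convergence: %d/%d cell lines", n_conv, len(conv))
        converged_cells = [r.cell_line_id for r in conv if r.converged]

        if spec is not None:
            if spec.planted is None and config.n_planted > 0:
                spec = synthmod.make_planted_spec(
                    spec, model, sim_matrix, config.n_planted, config.effect_size
                )
            responses, truth = synthmod.generate_responses(model, profiles, sim_matrix, spec)
            annotations = synthmod.annotations_from_cohort(profiles)
            (out / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=1) + "\n")
            files.append("ground_truth.json")
        else:
            responses = read_ic50_table(config.ic50_path)
            annotations = read_annotations(config.annotations_path) if config.annotations_path else {}

        cohort = join_cohort(profiles, responses, annotations)

        if config.write_sim_matrix:
            write_simulation(sim_matrix, conv, out / "simulation_matrix.tsv")
            files += ["simulation_matrix.tsv", "simulation_matrix.tsv.convergence.tsv"]

        # non-converged cell lines are excluded from the correlation screen
        sim_cells = [c for c in cohort.cell_lines if c in set(converged_cells)]

        strata_info = {}
        for label in config.strata:
            cells = cohort.cells_of_type(label)
            cells = [c for c in cells if c in set(sim_cells)]
            result: StratifiedResult = stratified_run(
                sim_matrix,
                _restrict_cohort(cohort, cells),
                label,
                model,
                drugs=cohort.drugs,
                threshold=config.threshold,
                alpha=config.alpha,
                min_n=config.min_n,
                family_size=config.family_size,
            )
            suffix = "" if label == "all" else f"_{label}"
            corr_file = f"correlations{suffix}.tsv"
            result.screen.frame().to_csv(out / corr_file, sep="\t", index=False, float_format=FLOAT_FMT)
            summary_file = f"drug_summary{suffix}.tsv"
            _summary_frame(result).to_csv(out / summary_file, sep="\t", index=False, float_format=FLOAT_FMT)
            sig_file = f"signature_{label}.tsv"
            result.signature.frame().to_csv(out / sig_file, sep="\t", index=False, float_format=FLOAT_FMT)
            files += [corr_file, summary_file, sig_file]
            strata_info[label] = {
                "n_cell_lines": len(cells),
                "family_size": result.screen.family_size,
                "n_correlation_tests": result.screen.n_tests,
                "n_undefined": result.screen.n_undefined,
                "signature_size": len(result.signature.members),
            }
            logger.info(
                "stratum %s: %d cells, %d tests (family %d), signature size %d",
                label, len(cells), result.screen.n_tests, result.screen.family_size,
                len(result.signature.members),
            )

        summary = model_summary(model)
        manifest = {
            "parameters": config.echo(),
            "model": {
                "n_components": summary.n_components,
                "n_reactions": summary.n_reactions,
                "n_pathways": summary.n_pathways,
            },
            "convergence": {
                "n_cell_lines": len(conv),
                "n_converged": n_conv,
                "max_iterations_used": max((r.iterations for r in conv), default=0),
            },
            "strata": strata_info,
            "files": files + ["manifest.json"],
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")
        return manifest
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _restrict_cohort(cohort: Cohort, cells: Sequence[str]) -> Cohort:
    keep = set(cells)
    return Cohort(
        cell_lines=[c for c in cohort.cell_lines if c in keep],
        cancer_types={c: t for c, t in cohort.cancer_types.items() if c in keep},
        profiles=[p for p in cohort.profiles if p.cell_line_id in keep],
        responses=cohort.responses[[c for c in cohort.cell_lines if c in keep]],
        drugs=list(cohort.drugs),
        unmatched=cohort.unmatched,
    )


def _summary_frame(result: StratifiedResult) -> pd.DataFrame:
    rows = []
    for drug, s in result.summaries.items():
        rows.append(
            {
                "drug": drug,
                "n_significant_components": s.n_significant_components,
                "n_affected_pathways": len(s.affected_pathways),
                "affected_by_class": ";".join(f"{k}={v}" for k, v in sorted(s.affected_by_class.items())),
                "top_pathways": ";".join(f"{p}({c})" for p, c in s.top_pathways),
                "impact_score": s.impact_score,
            }
        )
    return pd.DataFrame(rows)
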