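"""End-to-end study workflow: traces → OPEA → flags → tables → reference interval.

``run_all`` wires the stages together, logs n-in/n-out at every stage, and
writes a machine-readable manifest alongside the result tables.  Outputs are
deterministic for a fixed config and seed (the manifest carries no wall-clock
information).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .io import read_calibration, read_cohort, read_lms_table, read_traces
from .kinetics import DEFAULT_R2_THRESHOLD, DEFAULT_WINDOW
from .normalize import build_opea_table, opea_table_to_frame
from .reference import run_reference_pipeline
from .spirometry import flag_cohort
from .stats import add_health_status, summarize_table2, table1_proportions, table2_to_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all"]


_VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A stage of the workflow failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and options for a full workflow run."""

    cohort: str
    outdir: str
    traces: str | None = None
    pairing: str | None = None
    calibration: str | None = None
    lms: str | None = None
    seed: int = 0
    window: tuple[float, float] = DEFAULT_WINDOW
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    replicate_agg: str = "mean"
    ratio_estimator: str = "ratio_of_means"
    tukey_k: float = 1.5
    n_bootstrap: int = 50
    equal_var: bool = True
    include_other: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)

    return _Ctx()


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the full workflow and write the artifact set.

    Returns a mapping of artifact name to path: opea table, the three result
    tables, and a run manifest (inputs, version, seed, per-stage counts).
    OPEA is computed from traces when ``traces`` and ``pairing`` are given;
    otherwise the cohort must already carry an ``opea`` column.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    with _stage("read-cohort"):
        cohort = read_cohort(config.cohort)
        counts["participants"] = len(cohort)

    outputs: dict[str, Path] = {}
    if config.traces is not None:
        with _stage("process-traces"):
            if config.pairing is None or config.calibration is None:
                raise ValueError("traces given but pairing or calibration missing")
            traces = read_traces(config.traces)
            counts["traces"] = len(traces)
            cal = read_calibration(config.calibration)
            with open(config.pairing, "r", encoding="utf-8") as fh:
                pairing_raw = json.load(fh)
            pairing = {pid: (v["exhaled"], v["ambient"]) for pid, v in pairing_raw.items()}
            records = build_opea_table(
                traces,
                cal,
                pairing,
                window=config.window,
                r2_threshold=config.r2_threshold,
                replicate_agg=config.replicate_agg,
                ratio_estimator=config.ratio_estimator,
            )
            opea_frame = opea_table_to_frame(records)
            counts["opea_defined"] = int(opea_frame["opea"].notna().sum())
            outputs["opea"] = outdir / "opea.csv"
            opea_frame.to_csv(outputs["opea"], index=False, float_format="%.10g")
            cohort = cohort.drop(columns=["opea"], errors="ignore").merge(
                opea_frame[["participant_id", "opea"]], on="participant_id", how="left"
            )
    elif "opea" not in cohort.columns:
        raise PipelineError("stage 'process-traces' failed: no traces given and cohort has no opea column")

    if config.lms is not None:
        with _stage("spirometry-flags"):
            lms = read_lms_table(config.lms)
            cohort = flag_cohort(cohort, lms)

    with _stage("health-status"):
        cohort = add_health_status(cohort, include_other=config.include_other)
        counts["healthy"] = int((cohort["health_status"] == "healthy").sum())

    with _stage("table1"):
        table1 = table1_proportions(cohort)
        outputs["table1"] = outdir / "table1.csv"
        table1.to_csv(outputs["table1"], index=False, float_format="%.10g")

    with _stage("table2"):
        table2 = table2_to_frame(summarize_table2(cohort, equal_var=config.equal_var))
        outputs["table2"] = outdir / "table2.csv"
        table2.to_csv(outputs["table2"], index=False, float_format="%.10g")

    with _stage("reference-interval"):
        interval, outliers = run_reference_pipeline(
            cohort, k=config.tukey_k, n_bootstrap=config.n_bootstrap, seed=config.seed
        )
        counts["reference_sample"] = interval.n_reference
        counts["outliers_removed"] = interval.n_outliers_removed
        table3 = {
            "n_reference": interval.n_reference,
            "n_outliers_removed": interval.n_outliers_removed,
            "mean": interval.mean,
            "sd": interval.sd,
            "lower": interval.lower,
            "upper": interval.upper,
            "lower_ci90": list(interval.lower_ci90),
            "upper_ci90": list(interval.upper_ci90),
            "n_bootstrap": interval.n_bootstrap,
            "seed": interval.seed,
            "tukey_k": outliers.k,
            "flagged_ids": [str(i) for i in outliers.flagged_ids],
        }
        outputs["table3"] = outdir / "table3.json"
        with open(outputs["table3"], "w", encoding="utf-8") as fh:
            json.dump(table3, fh, indent=1, sort_keys=True)

    with _stage("manifest"):
        manifest = {
            "version": _VERSION,
            "seed": config.seed,
            "inputs": {
                "cohort": str(config.cohort),
                "traces": str(config.traces) if config.traces else None,
                "pairing": str(config.pairing) if config.pairing else None,
                "calibration": str(config.calibration) if config.calibration else None,
                "lms": str(config.lms) if config.lms else None,
            },
            "options": {
                "window": list(config.window),
                "r2_threshold": config.r2_threshold,
                "replicate_agg": config.replicate_agg,
                "ratio_estimator": config.ratio_estimator,
                "tukey_k": config.tukey_k,
                "n_bootstrap": config.n_bootstrap,
                "equal_var": config.equal_var,
                "include_other": config.include_other,
            },
            "counts": counts,
        }
        outputs["manifest"] = outdir / "manifest.json"
        with open(outputs["manifest"], "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    logger.info("run complete: %s", {k: str(v) for k, v in outputs.items()})
    return outputs
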