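"""Dataset I/O and the end-to-end pipeline: enumerate, sweep, analyse, select.

A single YAML config drives one reproducible run.  One master seed fans out
deterministically to the data split, the per-architecture weight
initialisations, and (for synthetic presets) the data generator, so
re-running the same config reproduces ``results.csv`` bit-identically.  The
run directory collects ``design.csv``, ``results.csv``, ``anova.csv``,
``optimal.json``, ``timing.json`` (when several worker counts are given)
and a ``manifest.json`` sufficient to replay the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import BalanceError, anova_main_effects, select_optimal
from .design import (
    DesignTable,
    GroupDesign,
    G1_AS_ANALYSED_NHL_LEVELS,
    design_table_from_csv,
    enumerate_design,
    standard_group,
)
from .engine import ResultsTable, benchmark_sweep, run_sweep
from .mlp import Dataset, TrainConfig
from .synth import milk_defaults, generate

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineStageError",
    "PipelineConfig",
    "read_dataset",
    "write_dataset",
    "run_pipeline",
]

logger = logging.getLogger("mlpgrid")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DataError(ValueError):
    """Malformed dataset file."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Dataset CSV round-trip
# ---------------------------------------------------------------------------

def read_dataset(
    path, n_inputs: int = 3, n_outputs: int = 6
) -> Dataset:
    """Read a dataset CSV: header row, then ``n_inputs + n_outputs`` numeric columns.

    The first ``n_inputs`` columns are inputs, the rest targets.  Missing or
    non-numeric cells raise :class:`DataError` naming the offending row and
    column; a header-only file yields an empty dataset.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise DataError(f"cannot parse {path}: {exc}") from exc
    expected = n_inputs + n_outputs
    if len(frame.columns) != expected:
        raise DataError(
            f"{path}: expected {expected} columns ({n_inputs} inputs + "
            f"{n_outputs} outputs), found {len(frame.columns)}: "
            f"{list(frame.columns)}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r = int(bad.any(axis=1).idxmax())
        c = bad.columns[bad.loc[r].to_numpy().argmax()]
        raise DataError(
            f"{path}: missing or non-numeric value at row {r}, column {c!r}"
        )
    values = numeric.to_numpy(dtype=float)
    return Dataset(
        inputs=values[:, :n_inputs],
        targets=values[:, n_inputs:],
        input_names=tuple(frame.columns[:n_inputs]),
        target_names=tuple(frame.columns[n_inputs:]),
    )


def write_dataset(data: Dataset, path) -> None:
    """Write a dataset as CSV with the input columns first."""
    frame = pd.DataFrame(
        np.hstack([data.inputs, data.targets]),
        columns=list(data.input_names) + list(data.target_names),
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible run: design source, data source, training, workers."""

    design: dict                 # {"group": 1, ...} or {"csv": path} or {"preset": ...}
    data: dict                   # {"preset": "milk", ...} or {"csv": path}
    train: dict = field(default_factory=dict)
    workers: tuple = (1,)
    outdir: str = "run"
    seed: int = 0
    schema_version: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "workers",
            tuple(self.workers) if isinstance(self.workers, (list, tuple)) else (int(self.workers),),
        )
        if not self.workers or any(int(w) < 1 for w in self.workers):
            raise ConfigError("workers must be >= 1")
        design_keys = {"group", "csv", "preset"} & set(self.design)
        if len(design_keys) != 1:
            raise ConfigError(
                "design must give exactly one of 'group', 'csv', 'preset'"
            )
        data_keys = {"preset", "csv"} & set(self.data)
        if len(data_keys) != 1:
            raise ConfigError("data must give exactly one of 'preset', 'csv'")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "design": dict(self.design),
            "data": dict(self.data),
            "train": dict(self.train),
            "workers": list(self.workers),
            "outdir": str(self.outdir),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            return cls(
                design=dict(d["design"]),
                data=dict(d["data"]),
                train=dict(d.get("train", {})),
                workers=d.get("workers", [1]),
                outdir=str(d.get("outdir", "run")),
                seed=int(d.get("seed", 0)),
                schema_version=int(d.get("schema_version", 1)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except Exception as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


def _resolve_design(cfg: PipelineConfig) -> DesignTable:
    d = cfg.design
    if "csv" in d:
        return design_table_from_csv(d["csv"])
    if "preset" in d:
        if d["preset"] == "g1-as-analysed":
            return enumerate_design(
                standard_group(1, nhl_levels=G1_AS_ANALYSED_NHL_LEVELS)
            )
        raise ConfigError(f"unknown design preset {d['preset']!r}")
    group = standard_group(
        int(d["group"]),
        nhl_levels=d.get("nhl_levels"),
        af_levels=d.get("af_levels"),
    )
    return enumerate_design(group)


def _resolve_data(cfg: PipelineConfig) -> Dataset:
    d = cfg.data
    if "csv" in d:
        return read_dataset(
            d["csv"],
            n_inputs=int(d.get("n_inputs", 3)),
            n_outputs=int(d.get("n_outputs", 6)),
        )
    if d["preset"] != "milk":
        raise ConfigError(f"unknown data preset {d['preset']!r}")
    spec = milk_defaults(
        n_samples=int(d.get("n_samples", 252)),
        seed=int(d.get("seed", cfg.seed)),
        noise_sd=float(d.get("noise_sd", 0.1)),
    )
    return generate(spec)


def _train_config(cfg: PipelineConfig) -> TrainConfig:
    try:
        return TrainConfig(seed=cfg.seed, **cfg.train)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid train block: {exc}") from exc


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir=None) -> Path:
    """Execute enumerate -> sweep -> anova -> select (-> benchmark).

    Writes all stage outputs plus a replayable manifest into the run
    directory (``cfg.outdir`` unless overridden) and returns its path.
    Stage failures raise :class:`PipelineStageError`; outputs of earlier
    stages are left in place.
    """
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    train_cfg = _train_config(cfg)

    try:
        design = _resolve_design(cfg)
        design.to_csv(out / "design.csv")
    except (ConfigError,) as exc:
        raise
    except Exception as exc:
        raise PipelineStageError("enumerate", exc) from exc
    logger.info("design %s: %d architectures", design.design_name, len(design))

    try:
        data = _resolve_data(cfg)
    except DataError:
        raise
    except Exception as exc:
        raise PipelineStageError("data", exc) from exc

    try:
        results = run_sweep(design, data, train_cfg, n_workers=int(cfg.workers[0]))
        results.to_csv(out / "results.csv")
    except Exception as exc:
        raise PipelineStageError("sweep", exc) from exc

    frame = results.to_frame()
    finite = frame[np.isfinite(frame["sse"])]
    dropped = len(frame) - len(finite)
    if dropped:
        logger.warning("excluding %d diverged run(s) from the analysis", dropped)
    try:
        table = anova_main_effects(finite, factors=list(results.factor_names))
        table.to_csv(out / "anova.csv")
    except BalanceError as exc:
        raise PipelineStageError("anova", exc) from exc

    try:
        optimal = select_optimal(results)
        (out / "optimal.json").write_text(json.dumps(optimal.to_dict(), indent=2))
    except Exception as exc:
        raise PipelineStageError("select", exc) from exc

    timing = None
    if len(cfg.workers) > 1:
        try:
            reports = benchmark_sweep(
                design, data, train_cfg, [int(w) for w in cfg.workers]
            )
            timing = [r.to_dict() for r in reports]
            (out / "timing.json").write_text(json.dumps(timing, indent=2))
        except Exception as exc:
            raise PipelineStageError("benchmark", exc) from exc

    manifest = {
        "package": "mlpgrid",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "design_name": design.design_name,
        "n_architectures": len(design),
        "n_samples": data.n_samples,
        "n_diverged": dropped,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def replay_manifest(manifest_path, outdir) -> Path:
    """Re-run a pipeline from the config stored in a manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(cfg, outdir=outdir)
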