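"""Sweep execution: run every architecture of a design, serially or in parallel.

The parallel scheme is a static master-worker layout: the master splits the
design's rows into contiguous chunks whose sizes differ by at most one,
hands each chunk to a worker process, and merges the partial result lists
back into design order.  Because every task's randomness derives only from
the master seed and the task's design row index — never from worker identity
or completion order — sweep results are bit-identical for any worker count.

Speedup S = T0/Tn and efficiency eta = S/n summarise how well extra workers
convert into shorter wall time.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .design import ArchitectureSpec, DesignTable, design_table_from_frame
from .mlp import Dataset, EvaluationResult, TrainConfig, evaluate_architecture

__all__ = [
    "ResultsTable",
    "TimingReport",
    "balanced_partition",
    "run_sweep",
    "speedup",
    "efficiency",
    "benchmark_sweep",
]

logger = logging.getLogger("mlpgrid")


@dataclass
class ResultsTable:
    """Per-architecture SSE results for one complete sweep, in design order."""

    design_name: str
    results: list                # list[EvaluationResult], ordered by row_index
    factor_names: tuple
    n_workers: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.factor_names = tuple(self.factor_names)
        idx = [r.row_index for r in self.results]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("results must be unique and ordered by row_index")

    def __len__(self) -> int:
        return len(self.results)

    @property
    def sse(self) -> np.ndarray:
        return np.array([r.sse for r in self.results])

    @property
    def n_failed(self) -> int:
        return sum(r.failed for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.results:
            rec = {"design": self.design_name, "row_index": r.row_index}
            for i, v in enumerate(r.arch.nhl, start=1):
                rec[f"NHL{i}"] = v
            for i, v in enumerate(r.arch.af, start=1):
                rec[f"AF{i}"] = v
            rec["IN"] = r.arch.input_neurons
            rec["ON"] = r.arch.output_neurons
            rec["sse"] = r.sse
            rec["train_seconds"] = r.train_seconds
            rec["seed"] = r.seed
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResultsTable":
        design = design_table_from_frame(
            frame.drop(columns=["sse", "train_seconds", "seed"], errors="ignore")
        )
        results = [
            EvaluationResult(
                row_index=arch.row_index,
                arch=arch,
                sse=float(rec["sse"]),
                train_seconds=float(rec.get("train_seconds", 0.0)),
                seed=int(rec.get("seed", 0)),
                failed=not np.isfinite(rec["sse"]),
            )
            for arch, rec in zip(design.rows, frame.to_dict("records"))
        ]
        return cls(
            design_name=design.design_name,
            results=results,
            factor_names=design.factor_names,
        )

    @classmethod
    def from_csv(cls, path) -> "ResultsTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class TimingReport:
    """Wall-time, speedup, and efficiency of one worker-count configuration."""

    n: int
    T0: float
    Tn: float
    S: float
    eta: float

    def to_dict(self) -> dict:
        return {"n": self.n, "T0": self.T0, "Tn": self.Tn, "S": self.S, "eta": self.eta}


def balanced_partition(n_tasks: int, n_workers: int) -> list[range]:
    """Split ``range(n_tasks)`` into ``n_workers`` contiguous chunks.

    Chunk sizes differ by at most one, with the earlier workers taking the
    larger chunks; workers may receive empty ranges when tasks are scarce.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if n_tasks < 0:
        raise ValueError("n_tasks must be >= 0")
    base, extra = divmod(n_tasks, n_workers)
    ranges, start = [], 0
    for w in range(n_workers):
        size = base + (1 if w < extra else 0)
        ranges.append(range(start, start + size))
        start += size
    return ranges


def _evaluate_chunk(
    rows: list[ArchitectureSpec], data: Dataset, cfg: TrainConfig
) -> list[EvaluationResult]:
    return [evaluate_architecture(arch, data, cfg) for arch in rows]


def run_sweep(
    design: DesignTable,
    data: Dataset,
    cfg: TrainConfig,
    n_workers: int = 1,
) -> ResultsTable:
    """Evaluate every row of a design table and merge results in design order.

    With ``n_workers > 1`` the chunks run in separate worker processes; the
    per-architecture seeding depends only on ``(cfg.seed, row_index)``, so
    the merged table is identical whatever the worker count.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    chunks = balanced_partition(len(design), n_workers)
    logger.info(
        "sweep %s: %d architectures on %d worker(s), chunk sizes %s",
        design.design_name,
        len(design),
        n_workers,
        [len(c) for c in chunks],
    )
    if n_workers == 1:
        partials = [_evaluate_chunk(list(design.rows), data, cfg)]
    else:
        partials = Parallel(n_jobs=n_workers)(
            delayed(_evaluate_chunk)([design.rows[i] for i in chunk], data, cfg)
            for chunk in chunks
        )
    results: list[EvaluationResult] = []
    for part in partials:
        results.extend(part)
    results.sort(key=lambda r: r.row_index)
    n_failed = sum(r.failed for r in results)
    if n_failed:
        logger.warning("sweep %s: %d run(s) diverged", design.design_name, n_failed)
    return ResultsTable(
        design_name=design.design_name,
        results=results,
        factor_names=design.factor_names,
        n_workers=n_workers,
        master_seed=cfg.seed,
    )


def speedup(T0: float, Tn: float) -> float:
    """Speedup S = T0 / Tn of a parallel run against the sequential one."""
    if T0 <= 0 or Tn <= 0:
        raise ValueError("times must be positive")
    return T0 / Tn


def efficiency(S: float, n: int) -> float:
    """Efficiency eta = S / n: speedup normalised by the worker count."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if S <= 0:
        raise ValueError("speedup must be positive")
    return S / n


def benchmark_sweep(
    design: DesignTable,
    data: Dataset,
    cfg: TrainConfig,
    worker_counts: list[int],
) -> list[TimingReport]:
    """Time the same sweep at several worker counts and report S and eta.

    Wall time is measured around the sweep only.  The sequential reference
    T0 is the 1-worker run; if 1 is absent from ``worker_counts`` it is
    timed first anyway.
    """
    if not worker_counts or any(n < 1 for n in worker_counts):
        raise ValueError("worker_counts must be non-empty with entries >= 1")

    def timed(n: int) -> float:
        t0 = time.perf_counter()
        run_sweep(design, data, cfg, n_workers=n)
        return time.perf_counter() - t0

    times: dict[int, float] = {}
    if 1 not in worker_counts:
        times[1] = timed(1)
    for n in worker_counts:
        times[n] = timed(n)
    T0 = times[1]
    reports = []
    for n in worker_counts:
        S = speedup(T0, times[n])
        reports.append(TimingReport(n=n, T0=T0, Tn=times[n], S=S, eta=efficiency(S, n)))
    return reports
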