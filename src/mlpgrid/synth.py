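"""Synthetic datasets with the statistical shape of the milk-quality study.

The real study measured three physicochemical inputs — density (Dn),
oxidation-reduction potential (Rd), and pH — and six compositional outputs
(proteins, lactose, total solids, solids-fat, solids-non-fat, minerals) on
252 raw-milk samples.  The published per-variable summaries (min, max, mean,
standard deviation) are reproduced here so that the whole pipeline runs
without any download: inputs are drawn from truncated normals matching
those summaries, and outputs are a fixed, seeded smooth map of the inputs
(low-order polynomial plus sigmoid mixing) rescaled into each output's
printed range, with optional gaussian noise.

Note one anomaly carried over verbatim from the published summary: the
minerals variable prints mean 0.70 with range [0.41, 0.71] — a mean
essentially at the upper range edge.  The generator keeps the printed
values; truncation keeps sampling valid, but the realised mean of such an
edge-mean variable necessarily sits below the printed one.

A second generator plants a known ground-truth network: targets are the
outputs of a randomly initialised network of a chosen architecture (plus
noise), so that architecture-recovery behaviour is directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import ArchitectureSpec
from .mlp import (
    INPUT_NAMES,
    OUTPUT_NAMES,
    Dataset,
    TrainedNetwork,
    build_network,
    forward,
)

__all__ = [
    "VariableSpec",
    "SyntheticSpec",
    "milk_defaults",
    "generate",
    "generate_planted",
]

# Stream tags separating the substreams of one seed.
_INPUT_STREAM = 301
_MAP_STREAM = 302
_NOISE_STREAM = 303
_PLANT_STREAM = 304

#: Default sample count: the study's 252 milk samples.
MILK_N_SAMPLES = 252

#: Default output-noise scale, as a fraction of each output's nominal sd.
DEFAULT_NOISE_SD = 0.1


@dataclass(frozen=True)
class VariableSpec:
    """Summary statistics of one measured variable."""

    name: str
    unit: str
    vmin: float
    vmax: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.vmin <= self.mean <= self.vmax):
            raise ValueError(f"{self.name}: mean must lie within [min, max]")
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if self.vmax < self.vmin:
            raise ValueError(f"{self.name}: max must be >= min")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic dataset."""

    inputs: tuple
    outputs: tuple
    n_samples: int = MILK_N_SAMPLES
    seed: int = 0
    noise_sd: float = DEFAULT_NOISE_SD
    coupling: str = "smooth-map"

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.coupling not in ("smooth-map", "planted-network"):
            raise ValueError(f"unknown coupling {self.coupling!r}")


def milk_defaults(
    n_samples: int = MILK_N_SAMPLES,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SyntheticSpec:
    """The published per-variable summaries of the 252-sample milk dataset."""
    inputs = (
        VariableSpec("Dn", "g/ml", 1.026, 1.03, 1.028, 0.001),
        VariableSpec("Rd", "hours", 6.5, 6.79, 6.63, 0.049),
        VariableSpec("pH", "-", 6.0, 8.0, 6.5, 0.637),
    )
    outputs = (
        VariableSpec("Pr", "g/100 ml", 2.69, 3.33, 3.005, 0.14),
        VariableSpec("Lc", "g/100 ml", 4.31, 5.24, 4.85, 0.187),
        VariableSpec("St", "g/100 ml", 10.89, 13.14, 12.22, 0.433),
        VariableSpec("Sf", "g/100 ml", 3.0, 4.1, 3.62, 0.183),
        VariableSpec("Snf", "g/100 ml", 7.73, 9.27, 8.54, 0.31),
        VariableSpec("Mn", "g/100 ml", 0.41, 0.71, 0.7, 0.023),
    )
    return SyntheticSpec(
        inputs=inputs, outputs=outputs, n_samples=n_samples, seed=seed, noise_sd=noise_sd
    )


def truncated_moments(v: VariableSpec) -> tuple[float, float]:
    """Analytic mean and sd of the truncated normal a variable is drawn from."""
    if v.sd == 0:
        return v.mean, 0.0
    a = (v.vmin - v.mean) / v.sd
    b = (v.vmax - v.mean) / v.sd
    dist = stats.truncnorm(a, b, loc=v.mean, scale=v.sd)
    return float(dist.mean()), float(dist.std())


def _sample_inputs(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for v in spec.inputs:
        if v.sd == 0 or v.vmax == v.vmin:
            cols.append(np.full(spec.n_samples, v.mean))
            continue
        a = (v.vmin - v.mean) / v.sd
        b = (v.vmax - v.mean) / v.sd
        u = rng.random(spec.n_samples)
        cols.append(stats.truncnorm.ppf(u, a, b, loc=v.mean, scale=v.sd))
    return np.column_stack(cols) if cols else np.empty((spec.n_samples, 0))


def _smooth_map(z: np.ndarray, n_outputs: int, seed: int) -> np.ndarray:
    """Fixed seeded smooth coupling: linear + quadratic + tanh mixing, in (-1, 1)."""
    rng = np.random.default_rng(np.random.SeedSequence([_MAP_STREAM, int(seed)]))
    k = z.shape[1]
    A = rng.uniform(-1, 1, size=(n_outputs, k))
    Q = rng.uniform(-0.5, 0.5, size=(n_outputs, k))
    C = rng.uniform(-1, 1, size=(n_outputs, k))
    d = rng.uniform(-0.5, 0.5, size=n_outputs)
    u = z @ A.T + (z * z) @ Q.T + np.tanh(z @ C.T + d)
    return np.tanh(u)           # squash into (-1, 1) for range mapping


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw a synthetic dataset: truncated-normal inputs, smooth-map outputs.

    Outputs are the deterministic smooth map of the (standardised) inputs,
    affinely rescaled from (-1, 1) into each output variable's [min, max],
    plus gaussian noise of sd ``noise_sd`` times the variable's nominal sd;
    noisy values are re-clipped to the variable's range.  Fully determined
    by ``spec.seed``.
    """
    rng_in = np.random.default_rng(np.random.SeedSequence([_INPUT_STREAM, int(spec.seed)]))
    rng_noise = np.random.default_rng(
        np.random.SeedSequence([_NOISE_STREAM, int(spec.seed)])
    )
    X = _sample_inputs(spec, rng_in)
    n_out = len(spec.outputs)
    # standardise inputs so the coupling sees O(1) coordinates
    mu = np.array([v.mean for v in spec.inputs])
    sd = np.array([v.sd if v.sd > 0 else 1.0 for v in spec.inputs])
    z = (X - mu) / sd if spec.n_samples else X
    u = _smooth_map(z, n_out, spec.seed) if spec.n_samples else np.empty((0, n_out))
    lo = np.array([v.vmin for v in spec.outputs])
    hi = np.array([v.vmax for v in spec.outputs])
    Y = lo + (u + 1.0) / 2.0 * (hi - lo)
    if spec.noise_sd > 0 and spec.n_samples:
        Y = Y + rng_noise.standard_normal(Y.shape) * (
            spec.noise_sd * np.array([v.sd for v in spec.outputs])
        )
        Y = np.clip(Y, lo, hi)
    return Dataset(
        inputs=X,
        targets=Y,
        input_names=tuple(v.name for v in spec.inputs),
        target_names=tuple(v.name for v in spec.outputs),
    )


def generate_planted(
    arch: ArchitectureSpec,
    n_samples: int,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[Dataset, TrainedNetwork]:
    """Dataset generated by a known random network of the given architecture.

    Inputs are uniform in [-1, 1]; targets are the truth network's outputs
    plus gaussian noise of sd ``noise_sd``.  Returns the dataset and the
    ground-truth network, which achieves SSE 0 on its own noiseless data.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([_PLANT_STREAM, int(seed)]))
    truth = build_network(arch, init_scheme="small-random", seed=seed)
    X = rng.uniform(-1, 1, size=(n_samples, arch.input_neurons))
    Y = forward(truth, X) if n_samples else np.empty((0, arch.output_neurons))
    if noise_sd > 0 and n_samples:
        Y = Y + rng.standard_normal(Y.shape) * noise_sd
    names_in = tuple(f"x{i+1}" for i in range(arch.input_neurons))
    names_out = tuple(f"y{i+1}" for i in range(arch.output_neurons))
    data = Dataset(X, np.atleast_2d(Y), names_in, names_out)
    return data, truth
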