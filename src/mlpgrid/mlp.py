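"""Multilayer-perceptron construction, training, and SSE evaluation.

Networks are small fully connected feed-forward stacks: an affine map
followed by one of three activations per stage — hyperbolic-tangent sigmoid
(code 1), logistic sigmoid (code 2), or identity (code 3).  The objective
throughout is the sum of squared errors (SSE) over all samples and output
variables.

Training is full-batch gradient descent with classical momentum on the SSE,
via backpropagation.  The gradient is averaged over samples so that the
default learning rate behaves the same regardless of dataset size.  All
randomness (weight initialisation, train/validation split) is derived
deterministically from explicit seeds, and per-architecture initialisation
depends only on (master seed, design row index) so that results never depend
on execution order or worker count.

Inputs and targets are by default min-max normalised to [-1, 1]; SSE is
computed and reported on that normalised scale so scores are comparable
across output variables of very different magnitudes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .design import ACTIVATION_CODES, ArchitectureSpec

__all__ = [
    "Dataset",
    "TrainConfig",
    "TrainedNetwork",
    "TrainingRecord",
    "EvaluationResult",
    "TrainingDivergence",
    "activation",
    "activation_derivative",
    "build_network",
    "forward",
    "sse",
    "train",
    "split_indices",
    "evaluate_architecture",
]

#: Column names of the milk-composition dataset: 3 inputs, 6 outputs.
INPUT_NAMES = ("Dn", "Rd", "pH")
OUTPUT_NAMES = ("Pr", "Lc", "St", "Sf", "Snf", "Mn")

# Fixed stream tags so the split, init, and synthetic-data substreams of one
# master seed never collide.
_SPLIT_STREAM = 101
_INIT_STREAM = 202


class TrainingDivergence(RuntimeError):
    """SSE became non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite SSE) at epoch {epoch}")
        self.epoch = epoch


@dataclass
class Dataset:
    """Paired input/target observations."""

    inputs: np.ndarray          # (n_samples, n_inputs)
    targets: np.ndarray         # (n_samples, n_outputs)
    input_names: tuple = INPUT_NAMES
    target_names: tuple = OUTPUT_NAMES

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 2 or self.targets.ndim != 2:
            raise ValueError("inputs and targets must be 2-D arrays")
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must have equal sample counts")
        if np.isnan(self.inputs).any() or np.isnan(self.targets).any():
            raise ValueError("dataset contains missing values")
        self.input_names = tuple(self.input_names)
        self.target_names = tuple(self.target_names)
        if len(self.input_names) != self.inputs.shape[1]:
            raise ValueError("input_names length must match input columns")
        if len(self.target_names) != self.targets.shape[1]:
            raise ValueError("target_names length must match target columns")

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            self.inputs[idx], self.targets[idx], self.input_names, self.target_names
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training settings shared by every architecture in a sweep.

    The optimiser is full-batch gradient descent with momentum ("gdm"), the
    only identifier currently registered.  ``split_fraction`` is the share of
    samples used for training; the rest form the validation partition on
    which SSE is scored when ``eval_on="validation"``.  The split permutation
    derives only from ``seed`` and is therefore identical for every
    architecture, keeping SSE comparable across the sweep.
    """

    optimizer: str = "gdm"
    max_epochs: int = 500
    learning_rate: float = 0.01
    momentum: float = 0.9
    sse_tolerance: float = 1e-4
    init_scheme: str = "small-random"
    seed: int = 0
    normalize: bool = True
    split_fraction: float = 0.7
    eval_on: str = "validation"

    def __post_init__(self) -> None:
        if self.optimizer != "gdm":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.momentum < 0:
            raise ValueError("momentum must be >= 0")
        if self.sse_tolerance < 0:
            raise ValueError("sse_tolerance must be >= 0")
        if self.init_scheme not in ("small-random", "zero"):
            raise ValueError(f"unknown init_scheme {self.init_scheme!r}")
        if not (0 < self.split_fraction <= 1):
            raise ValueError("split_fraction must be in (0, 1]")
        if self.eval_on not in ("validation", "training"):
            raise ValueError(f"unknown eval_on {self.eval_on!r}")
        if self.split_fraction == 1.0 and self.eval_on == "validation":
            # no held-out samples exist; force training-set evaluation
            object.__setattr__(self, "eval_on", "training")


@dataclass
class TrainingRecord:
    """Epoch-indexed training-SSE trace and the reason training stopped."""

    sse_trace: np.ndarray
    stopping_reason: str        # "max_epochs" | "tolerance"
    elapsed_epochs: int


@dataclass
class TrainedNetwork:
    """Weights, biases, and activation codes of one perceptron.

    ``weights[l]`` has shape (size_{l+1}, size_l) following the convention
    that layer l computes ``act(W @ prev + b)``.  If normalisation bounds are
    attached, :func:`forward` min-max scales raw inputs into [-1, 1] and maps
    raw-scale predictions back out; the internal pass always operates on the
    normalised scale.
    """

    layer_sizes: tuple
    activations: tuple
    weights: list
    biases: list
    input_bounds: np.ndarray | None = None    # (2, n_inputs): min, max rows
    target_bounds: np.ndarray | None = None   # (2, n_outputs)

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        self.activations = tuple(int(a) for a in self.activations)
        if len(self.activations) != len(self.layer_sizes) - 1:
            raise ValueError("one activation required per weight layer")
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("one weight matrix required per layer transition")
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            want = (self.layer_sizes[l + 1], self.layer_sizes[l])
            if W.shape != want:
                raise ValueError(f"weight layer {l} has shape {W.shape}, want {want}")
            if b.shape != (self.layer_sizes[l + 1],):
                raise ValueError(f"bias layer {l} has wrong shape {b.shape}")

    @property
    def n_weight_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "TrainedNetwork":
        return TrainedNetwork(
            self.layer_sizes,
            self.activations,
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            None if self.input_bounds is None else self.input_bounds.copy(),
            None if self.target_bounds is None else self.target_bounds.copy(),
        )

    def to_dict(self) -> dict:
        d = {
            "layer_sizes": list(self.layer_sizes),
            "activations": list(self.activations),
            "weights": [W.ravel().tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        if self.input_bounds is not None:
            d["input_bounds"] = self.input_bounds.tolist()
        if self.target_bounds is not None:
            d["target_bounds"] = self.target_bounds.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedNetwork":
        sizes = tuple(d["layer_sizes"])
        weights = [
            np.asarray(w, dtype=float).reshape(sizes[l + 1], sizes[l])
            for l, w in enumerate(d["weights"])
        ]
        biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        return cls(
            sizes,
            tuple(d["activations"]),
            weights,
            biases,
            np.asarray(d["input_bounds"], dtype=float) if "input_bounds" in d else None,
            np.asarray(d["target_bounds"], dtype=float) if "target_bounds" in d else None,
        )


@dataclass
class EvaluationResult:
    """Outcome of building, training, and scoring one architecture."""

    row_index: int
    arch: ArchitectureSpec
    sse: float                  # NaN flags a diverged run
    train_seconds: float
    seed: int
    failed: bool = False


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

def activation(code: int, x):
    """Apply activation ``code`` elementwise: 1 tan-sig, 2 log-sig, 3 linear."""
    x = np.asarray(x, dtype=float)
    if code == 1:
        return np.tanh(x)       # == 2/(1+exp(-2x)) - 1, overflow-safe
    if code == 2:
        return expit(x)
    if code == 3:
        return x
    raise ValueError(f"unknown activation code {code!r}")


def activation_derivative(code: int, out):
    """Derivative of the activation expressed through its *output* value."""
    out = np.asarray(out, dtype=float)
    if code == 1:
        return 1.0 - out * out
    if code == 2:
        return out * (1.0 - out)
    if code == 3:
        return np.ones_like(out)
    raise ValueError(f"unknown activation code {code!r}")


# ---------------------------------------------------------------------------
# Construction and forward pass
# ---------------------------------------------------------------------------

def _init_rng(seed: int, row_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([_INIT_STREAM, int(seed), int(row_index)])
    )


def build_network(
    arch: ArchitectureSpec,
    init_scheme: str = "small-random",
    seed: int = 0,
) -> TrainedNetwork:
    """Instantiate a network for an architecture row.

    ``"small-random"`` draws every weight and bias uniformly from
    [-0.5, 0.5] using a generator seeded only by ``(seed, arch.row_index)``;
    ``"zero"`` sets all parameters to 0 exactly.  Zero initialisation leaves
    all hidden units of a layer permanently identical under gradient
    training, so it is available for fidelity but not the default.
    """
    sizes = arch.layer_sizes
    weights, biases = [], []
    if init_scheme == "small-random":
        rng = _init_rng(seed, arch.row_index)
        for l in range(len(sizes) - 1):
            weights.append(rng.uniform(-0.5, 0.5, size=(sizes[l + 1], sizes[l])))
            biases.append(rng.uniform(-0.5, 0.5, size=sizes[l + 1]))
    elif init_scheme == "zero":
        for l in range(len(sizes) - 1):
            weights.append(np.zeros((sizes[l + 1], sizes[l])))
            biases.append(np.zeros(sizes[l + 1]))
    else:
        raise ValueError(f"unknown init_scheme {init_scheme!r}")
    return TrainedNetwork(sizes, arch.af, weights, biases)


def _minmax_bounds(x: np.ndarray) -> np.ndarray:
    return np.vstack([x.min(axis=0), x.max(axis=0)])


def _normalize(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    lo, hi = bounds
    span = np.where(hi > lo, hi - lo, 1.0)  # constant columns map to -1
    return 2.0 * (x - lo) / span - 1.0


def _denormalize(z: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    lo, hi = bounds
    span = np.where(hi > lo, hi - lo, 1.0)
    return (z + 1.0) / 2.0 * span + lo


def _forward_core(net: TrainedNetwork, z: np.ndarray) -> np.ndarray:
    for W, b, code in zip(net.weights, net.biases, net.activations):
        z = activation(code, z @ W.T + b)
    return z


def forward(net: TrainedNetwork, inputs) -> np.ndarray:
    """Predict outputs for a batch of raw-scale inputs.

    Accepts a single sample (1-D) or a batch (2-D); returns the matching
    shape.  Stored normalisation bounds, if any, are applied on the way in
    and inverted on the way out.
    """
    x = np.asarray(inputs, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"input width {x.shape[1]} != network input size {net.layer_sizes[0]}"
        )
    z = _normalize(x, net.input_bounds) if net.input_bounds is not None else x
    y = _forward_core(net, z)
    if net.target_bounds is not None:
        y = _denormalize(y, net.target_bounds)
    return y[0] if single else y


def sse(targets, predictions) -> float:
    """Sum of squared errors over all samples and output variables."""
    t = np.asarray(targets, dtype=float)
    y = np.asarray(predictions, dtype=float)
    if t.shape != y.shape:
        raise ValueError(f"shape mismatch: targets {t.shape} vs predictions {y.shape}")
    d = t - y
    return float(np.sum(d * d))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _backprop_gradients(net, z_in, t):
    """Gradient of SSE w.r.t. every weight and bias, averaged over samples.

    Returns (grads_W, grads_b, batch_sse).  Averaging over samples makes the
    step size independent of dataset size; the reported SSE itself is the
    plain (unaveraged) sum.
    """
    n = z_in.shape[0]
    # forward with stored activations
    outs = [z_in]
    for W, b, code in zip(net.weights, net.biases, net.activations):
        outs.append(activation(code, outs[-1] @ W.T + b))
    y = outs[-1]
    resid = y - t
    batch_sse = float(np.sum(resid * resid))
    grads_W = [None] * net.n_weight_layers
    grads_b = [None] * net.n_weight_layers
    # delta at layer l: dSSE/d(pre-activation_l), averaged over samples
    delta = 2.0 * resid * activation_derivative(net.activations[-1], y)
    for l in range(net.n_weight_layers - 1, -1, -1):
        grads_W[l] = delta.T @ outs[l] / n
        grads_b[l] = delta.sum(axis=0) / n
        if l > 0:
            delta = (delta @ net.weights[l]) * activation_derivative(
                net.activations[l - 1], outs[l]
            )
    return grads_W, grads_b, batch_sse


def train(
    net: TrainedNetwork,
    data: Dataset,
    cfg: TrainConfig,
) -> tuple[TrainedNetwork, TrainingRecord]:
    """Fit a network by full-batch gradient descent with momentum on SSE.

    The input network is not mutated; a trained copy is returned together
    with the per-epoch training-SSE trace.  When ``cfg.normalize`` is set and
    the network carries no bounds yet, min-max bounds are computed from
    ``data`` and attached; training then runs on the normalised scale (as
    does the trace).  Stops after ``max_epochs`` epochs or as soon as the
    epoch SSE falls to ``sse_tolerance`` or below.  A non-finite SSE raises
    :class:`TrainingDivergence` carrying the epoch index.
    """
    if data.inputs.shape[1] != net.layer_sizes[0]:
        raise ValueError("dataset input width does not match network")
    if data.targets.shape[1] != net.layer_sizes[-1]:
        raise ValueError("dataset target width does not match network")

    net = net.copy()
    if cfg.normalize and net.input_bounds is None:
        net.input_bounds = _minmax_bounds(data.inputs)
        net.target_bounds = _minmax_bounds(data.targets)
    if net.input_bounds is not None:
        z = _normalize(data.inputs, net.input_bounds)
        t = _normalize(data.targets, net.target_bounds)
    else:
        z, t = data.inputs, data.targets

    vel_W = [np.zeros_like(W) for W in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    trace = []
    reason = "max_epochs"
    for epoch in range(cfg.max_epochs):
        grads_W, grads_b, batch_sse = _backprop_gradients(net, z, t)
        if not np.isfinite(batch_sse):
            raise TrainingDivergence(epoch)
        trace.append(batch_sse)
        if batch_sse <= cfg.sse_tolerance:
            reason = "tolerance"
            break
        for l in range(net.n_weight_layers):
            vel_W[l] = cfg.momentum * vel_W[l] - cfg.learning_rate * grads_W[l]
            vel_b[l] = cfg.momentum * vel_b[l] - cfg.learning_rate * grads_b[l]
            net.weights[l] += vel_W[l]
            net.biases[l] += vel_b[l]
    record = TrainingRecord(
        sse_trace=np.asarray(trace), stopping_reason=reason, elapsed_epochs=len(trace)
    )
    return net, record


def split_indices(n_samples: int, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/eval index split derived only from ``cfg.seed``.

    Every architecture in a sweep therefore sees the identical partition.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_SPLIT_STREAM, int(cfg.seed)]))
    perm = rng.permutation(n_samples)
    n_train = int(round(cfg.split_fraction * n_samples))
    n_train = max(1, min(n_samples, n_train)) if n_samples else 0
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def evaluate_architecture(
    arch: ArchitectureSpec, data: Dataset, cfg: TrainConfig
) -> EvaluationResult:
    """Build, train, and score one architecture.

    The score is the SSE on the evaluation partition, on the normalised
    scale when normalisation is active.  A diverged run is recorded with
    ``sse = NaN`` and ``failed = True`` instead of aborting the sweep.
    """
    t0 = time.perf_counter()
    train_idx, eval_idx = split_indices(data.n_samples, cfg)
    train_set = data.subset(train_idx)
    eval_set = train_set if cfg.eval_on == "training" else data.subset(eval_idx)

    init_seed = int(_init_rng(cfg.seed, arch.row_index).integers(0, 2**31))
    net = build_network(arch, cfg.init_scheme, cfg.seed)
    try:
        fitted, _ = train(net, train_set, cfg)
        if fitted.input_bounds is not None:
            z = _normalize(eval_set.inputs, fitted.input_bounds)
            t = _normalize(eval_set.targets, fitted.target_bounds)
            score = sse(t, _forward_core(fitted, z))
        else:
            score = sse(eval_set.targets, forward(fitted, eval_set.inputs))
        failed = not np.isfinite(score)
        score = score if np.isfinite(score) else float("nan")
    except TrainingDivergence:
        score, failed = float("nan"), True
    return EvaluationResult(
        row_index=arch.row_index,
        arch=arch,
        sse=score,
        train_seconds=time.perf_counter() - t0,
        seed=init_seed,
        failed=failed,
    )
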