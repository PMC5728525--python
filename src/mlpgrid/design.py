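"""Factorial design space of multilayer-perceptron architectures.

A *group* of architectures fixes the number of hidden layers (HL) and varies
two kinds of structural factors: the neuron count of each hidden layer
(NHL1..NHLk) and the activation function attached to each weight stage
(AF1..AF(k+1) — one per hidden layer plus one for the output layer).  The
full factorial enumeration of those factor levels is the search space over
which every architecture is trained and scored.

Enumeration order is fixed to mixed-radix with the rightmost factor varying
fastest (factor order NHL1..NHLk, AF1..AF(k+1)), so that tables are
byte-identical across runs and row indices can seed per-architecture
randomness deterministically.
"""

from __future__ import annotations

import io as _io
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

#: Valid activation-function codes: 1 = tan-sig, 2 = log-sig, 3 = linear.
ACTIVATION_CODES = (1, 2, 3)

#: Default neuron-count levels per hidden layer: 3, 6, ..., 27.
DEFAULT_NHL_LEVELS = tuple(range(3, 28, 3))

#: Default activation-function levels.
DEFAULT_AF_LEVELS = ACTIVATION_CODES

#: Reduced neuron-count levels (3..21 step 3) for the single-hidden-layer
#: group as it appears in the published analysis: the 63-treatment layout
#: (7 x 3 x 3) with 6 degrees of freedom for NHL1, rather than the 81
#: combinations the full 9-level grid would give.  Which seven levels were
#: actually analysed is not documented; this preset is the natural contiguous
#: choice that matches the printed degrees of freedom.
G1_AS_ANALYSED_NHL_LEVELS = tuple(range(3, 22, 3))

DEFAULT_INPUT_NEURONS = 3
DEFAULT_OUTPUT_NEURONS = 6


class DesignError(ValueError):
    """Invalid factor, group, or enumeration request."""


@dataclass(frozen=True)
class FactorSpec:
    """One structural factor: a named, ordered list of allowed levels.

    ``kind`` is ``"nhl"`` for neuron-count factors (positive-integer levels)
    or ``"af"`` for activation factors (levels drawn from
    :data:`ACTIVATION_CODES`).
    """

    name: str
    levels: tuple
    kind: str = "nhl"

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 1:
            raise DesignError(f"factor {self.name!r} needs at least one level")
        if len(set(self.levels)) != len(self.levels):
            raise DesignError(f"factor {self.name!r} has duplicate levels")
        if self.kind == "nhl":
            if not all(isinstance(v, (int,)) and v > 0 for v in self.levels):
                raise DesignError(
                    f"neuron-count factor {self.name!r} requires positive "
                    f"integer levels, got {self.levels}"
                )
        elif self.kind == "af":
            if not all(v in ACTIVATION_CODES for v in self.levels):
                raise DesignError(
                    f"activation factor {self.name!r} requires levels from "
                    f"{ACTIVATION_CODES}, got {self.levels}"
                )
        else:
            raise DesignError(f"unknown factor kind {self.kind!r}")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class GroupDesign:
    """A factorial design for one architecture group (fixed hidden-layer count)."""

    group_id: int
    nhl_factors: tuple
    af_factors: tuple
    input_neurons: int = DEFAULT_INPUT_NEURONS
    output_neurons: int = DEFAULT_OUTPUT_NEURONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "nhl_factors", tuple(self.nhl_factors))
        object.__setattr__(self, "af_factors", tuple(self.af_factors))
        hl = self.hidden_layer_count
        if hl < 1:
            raise DesignError("at least one hidden layer required")
        if len(self.af_factors) != hl + 1:
            raise DesignError(
                f"need {hl + 1} activation factors (one per hidden layer plus "
                f"the output layer), got {len(self.af_factors)}"
            )
        if self.input_neurons < 1 or self.output_neurons < 1:
            raise DesignError("input and output layers need at least one neuron")
        for f in self.nhl_factors:
            if f.kind != "nhl":
                raise DesignError(f"factor {f.name!r} is not a neuron-count factor")
        for f in self.af_factors:
            if f.kind != "af":
                raise DesignError(f"factor {f.name!r} is not an activation factor")

    @property
    def hidden_layer_count(self) -> int:
        return len(self.nhl_factors)

    @property
    def factors(self) -> tuple:
        """All factors in enumeration order: NHL1..NHLk, AF1..AF(k+1)."""
        return self.nhl_factors + self.af_factors

    @property
    def design_name(self) -> str:
        hl = self.hidden_layer_count
        return f"{hl}HL{hl + 1}AF"

    @property
    def n_combinations(self) -> int:
        return math.prod(f.n_levels for f in self.factors)


@dataclass(frozen=True)
class ArchitectureSpec:
    """One concrete perceptron structure — a single row of a design table."""

    group_id: int
    row_index: int
    nhl: tuple          # neurons per hidden layer
    af: tuple           # activation code per stage, length len(nhl) + 1
    input_neurons: int = DEFAULT_INPUT_NEURONS
    output_neurons: int = DEFAULT_OUTPUT_NEURONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "nhl", tuple(int(v) for v in self.nhl))
        object.__setattr__(self, "af", tuple(int(v) for v in self.af))
        if len(self.af) != len(self.nhl) + 1:
            raise DesignError(
                "need one activation per hidden layer plus the output layer"
            )
        if not all(v > 0 for v in self.nhl):
            raise DesignError("neuron counts must be positive")
        if not all(v in ACTIVATION_CODES for v in self.af):
            raise DesignError(f"activation codes must be in {ACTIVATION_CODES}")

    @property
    def layer_sizes(self) -> tuple:
        """Neuron counts of every layer: input, hidden..., output."""
        return (self.input_neurons,) + self.nhl + (self.output_neurons,)


@dataclass(frozen=True)
class DesignTable:
    """Ordered full-factorial enumeration of architectures for one group."""

    design_name: str
    rows: tuple
    factors: tuple
    input_neurons: int = DEFAULT_INPUT_NEURONS
    output_neurons: int = DEFAULT_OUTPUT_NEURONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "factors", tuple(self.factors))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i: int) -> ArchitectureSpec:
        return self.rows[i]

    @property
    def factor_names(self) -> tuple:
        return tuple(f.name for f in self.factors)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: design, row_index, NHL..., AF..., IN, ON."""
        records = []
        for r in self.rows:
            rec = {"design": self.design_name, "row_index": r.row_index}
            for i, v in enumerate(r.nhl, start=1):
                rec[f"NHL{i}"] = v
            for i, v in enumerate(r.af, start=1):
                rec[f"AF{i}"] = v
            rec["IN"] = r.input_neurons
            rec["ON"] = r.output_neurons
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def standard_group(
    group_id: int,
    nhl_levels: Sequence[int] | None = None,
    af_levels: Sequence[int] | None = None,
    input_neurons: int = DEFAULT_INPUT_NEURONS,
    output_neurons: int = DEFAULT_OUTPUT_NEURONS,
) -> GroupDesign:
    """Build the standard factorial design for group 1, 2, or 3.

    Group ``k`` has ``k`` hidden layers, ``k`` neuron-count factors (default
    levels 3..27 step 3) and ``k + 1`` activation factors (default levels
    1/2/3).  Pass explicit ``nhl_levels`` / ``af_levels`` to restrict the
    grid — e.g. ``nhl_levels=G1_AS_ANALYSED_NHL_LEVELS`` for the 63-treatment
    single-hidden-layer layout.
    """
    if group_id not in (1, 2, 3):
        raise DesignError(f"unknown group_id {group_id!r}; expected 1, 2 or 3")
    nhl_levels = tuple(nhl_levels) if nhl_levels is not None else DEFAULT_NHL_LEVELS
    af_levels = tuple(af_levels) if af_levels is not None else DEFAULT_AF_LEVELS
    if not nhl_levels or not af_levels:
        raise DesignError("level lists must be non-empty")
    hl = group_id
    nhl_factors = tuple(
        FactorSpec(f"NHL{i}", nhl_levels, kind="nhl") for i in range(1, hl + 1)
    )
    af_factors = tuple(
        FactorSpec(f"AF{i}", af_levels, kind="af") for i in range(1, hl + 2)
    )
    return GroupDesign(
        group_id=group_id,
        nhl_factors=nhl_factors,
        af_factors=af_factors,
        input_neurons=input_neurons,
        output_neurons=output_neurons,
    )


def group1_as_analysed() -> GroupDesign:
    """The single-hidden-layer design restricted to 7 NHL levels (63 runs)."""
    return standard_group(1, nhl_levels=G1_AS_ANALYSED_NHL_LEVELS)


def enumerate_design(design: GroupDesign) -> DesignTable:
    """Enumerate every factor-level combination of a group design.

    The cartesian product is emitted in mixed-radix order with the rightmost
    factor varying fastest; ``row_index`` is assigned contiguously from 0 in
    that order.
    """
    k = design.hidden_layer_count
    level_lists = [f.levels for f in design.factors]
    rows = []
    for idx, combo in enumerate(itertools.product(*level_lists)):
        rows.append(
            ArchitectureSpec(
                group_id=design.group_id,
                row_index=idx,
                nhl=combo[:k],
                af=combo[k:],
                input_neurons=design.input_neurons,
                output_neurons=design.output_neurons,
            )
        )
    return DesignTable(
        design_name=design.design_name,
        rows=tuple(rows),
        factors=design.factors,
        input_neurons=design.input_neurons,
        output_neurons=design.output_neurons,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def design_table_from_frame(frame: pd.DataFrame) -> DesignTable:
    """Rebuild a :class:`DesignTable` from its tabular form."""
    if len(frame) == 0:
        raise DesignError("empty design table")
    nhl_cols = sorted(
        (c for c in frame.columns if c.startswith("NHL")), key=lambda c: int(c[3:])
    )
    af_cols = sorted(
        (c for c in frame.columns if c.startswith("AF")), key=lambda c: int(c[2:])
    )
    if len(af_cols) != len(nhl_cols) + 1:
        raise DesignError(
            f"expected {len(nhl_cols) + 1} AF columns for {len(nhl_cols)} NHL "
            f"columns, found {len(af_cols)}"
        )
    design_name = str(frame["design"].iloc[0])
    inp = int(frame["IN"].iloc[0])
    out = int(frame["ON"].iloc[0])
    group_id = len(nhl_cols)
    factors = tuple(
        FactorSpec(c, tuple(dict.fromkeys(int(v) for v in frame[c])), kind="nhl")
        for c in nhl_cols
    ) + tuple(
        FactorSpec(c, tuple(dict.fromkeys(int(v) for v in frame[c])), kind="af")
        for c in af_cols
    )
    rows = tuple(
        ArchitectureSpec(
            group_id=group_id,
            row_index=int(rec["row_index"]),
            nhl=tuple(int(rec[c]) for c in nhl_cols),
            af=tuple(int(rec[c]) for c in af_cols),
            input_neurons=inp,
            output_neurons=out,
        )
        for rec in frame.to_dict("records")
    )
    return DesignTable(
        design_name=design_name,
        rows=rows,
        factors=factors,
        input_neurons=inp,
        output_neurons=out,
    )


def design_table_from_csv(path) -> DesignTable:
    return design_table_from_frame(pd.read_csv(path))


def group_to_dict(design: GroupDesign) -> dict:
    """Round-trippable plain-dict form of a group design (for YAML configs)."""
    return {
        "group_id": design.group_id,
        "input_neurons": design.input_neurons,
        "output_neurons": design.output_neurons,
        "nhl_levels": {f.name: list(f.levels) for f in design.nhl_factors},
        "af_levels": {f.name: list(f.levels) for f in design.af_factors},
    }


def group_from_dict(d: dict) -> GroupDesign:
    nhl_factors = tuple(
        FactorSpec(name, tuple(levels), kind="nhl")
        for name, levels in d["nhl_levels"].items()
    )
    af_factors = tuple(
        FactorSpec(name, tuple(levels), kind="af")
        for name, levels in d["af_levels"].items()
    )
    return GroupDesign(
        group_id=int(d["group_id"]),
        nhl_factors=nhl_factors,
        af_factors=af_factors,
        input_neurons=int(d.get("input_neurons", DEFAULT_INPUT_NEURONS)),
        output_neurons=int(d.get("output_neurons", DEFAULT_OUTPUT_NEURONS)),
    )


def group_to_yaml(design: GroupDesign, path) -> None:
    Path(path).write_text(yaml.safe_dump(group_to_dict(design), sort_keys=False))


def group_from_yaml(path) -> GroupDesign:
    return group_from_dict(yaml.safe_load(Path(path).read_text()))
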