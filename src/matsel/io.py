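"""Plain-text serialization of fitness sets and population states.

Fitness sets are written as CSV (offspring_i, offspring_j, mother_k, mother_l,
w) with 1-based allele indices in canonical order, plus a JSON sidecar
recording {n, seed, generator}.  Values are written as shortest round-trip
decimals, so read/write is bit-exact.  Population states are CSV rows
(i, j, x_ij) for i <= j.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import FitnessSet, PopulationState, enumerate_pairs
from .random_inputs import GENERATOR_NAME

__all__ = [
    "write_fitness_set",
    "read_fitness_set",
    "write_population_state",
    "read_population_state",
]


def write_fitness_set(path, fitness: FitnessSet, seed: Optional[int] = None) -> None:
    path = Path(path)
    pairs = enumerate_pairs(fitness.n)
    df = pd.DataFrame(
        {
            "offspring_i": [p.offspring.i + 1 for p in pairs],
            "offspring_j": [p.offspring.j + 1 for p in pairs],
            "mother_k": [p.mother.i + 1 for p in pairs],
            "mother_l": [p.mother.j + 1 for p in pairs],
            "w": [repr(float(v)) for v in fitness.w],
        }
    )
    df.to_csv(path, index=False)
    sidecar = {"n": fitness.n, "seed": seed, "generator": GENERATOR_NAME}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_fitness_set(path) -> FitnessSet:
    path = Path(path)
    df = pd.read_csv(path, dtype={"w": str})
    sidecar = path.with_suffix(path.suffix + ".json")
    n = json.loads(sidecar.read_text())["n"] if sidecar.exists() else int(df[["offspring_j"]].max().iloc[0])
    w = np.array([float(s) for s in df["w"]])
    # rows are written in canonical order; verify against the enumeration
    pairs = enumerate_pairs(n)
    expect = [(p.offspring.i + 1, p.offspring.j + 1, p.mother.i + 1, p.mother.j + 1) for p in pairs]
    got = list(zip(df.offspring_i, df.offspring_j, df.mother_k, df.mother_l))
    if got != expect:
        raise ValueError("fitness-set CSV rows are not in canonical enumeration order")
    return FitnessSet(n, w)


def write_population_state(path, state: PopulationState) -> None:
    rows = [
        (i + 1, j + 1, repr(float(state.x[i, j])))
        for i in range(state.n)
        for j in range(i, state.n)
    ]
    pd.DataFrame(rows, columns=["i", "j", "x_ij"]).to_csv(path, index=False)


def read_population_state(path) -> PopulationState:
    df = pd.read_csv(path, dtype={"x_ij": str})
    n = int(df["j"].max())
    x = np.zeros((n, n))
    for i, j, v in zip(df.i, df.j, df.x_ij):
        x[i - 1, j - 1] = x[j - 1, i - 1] = float(v)
    return PopulationState(x)
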