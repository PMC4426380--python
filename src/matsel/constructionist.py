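"""Constructing polymorphism by recurrent mutation and maternal selection.

Each replicate starts monomorphic (one allele, w_1111 = 0.5).  Every
generation a brand-new mutant allele enters at frequency 1e-5 (one resident
allele donates that frequency), the fitness set is extended with fresh U[0,1]
entries for the C(n+1) - C(n) = 3n^2 + 2n + 1 new offspring-mother
combinations, the population is iterated one generation of selection, and any
allele whose frequency has fallen below 1e-5 is removed as extinct.  After
10^4 generations the surviving fitness set and genotype frequencies are
recorded.  The per-generation allele count and mean fitness, and all
invasion/extinction events, are logged.

Within a generation the order is: mutation -> selection -> pruning ->
recording, so the recorded mean fitness is post-selection.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .model import (
    DegenerateStateError,
    FitnessSet,
    PopulationState,
    _new_positions,
    _embed_positions,
    _step_arrays,
    count_parameters,
)
from .random_inputs import RngConfig, _as_generator

__all__ = [
    "ConstructionConfig",
    "TrajectoryRecord",
    "NoEligibleDonorError",
    "expand_fitness_set",
    "introduce_mutant",
    "prune_extinct",
    "run_construction",
    "reiterate_without_mutation",
]


class NoEligibleDonorError(RuntimeError):
    """No resident allele has enough frequency to donate the mutant's share."""


@dataclass(frozen=True)
class ConstructionConfig:
    """Protocol parameters for one batch of constructionist replicates."""

    generations: int = 10_000
    mutant_frequency: float = 1e-5
    extinction_threshold: float = 1e-5
    initial_fitness: float = 0.5
    replicates: int = 1000
    rng: RngConfig = RngConfig(0)


@dataclass
class TrajectoryRecord:
    """Per-generation log plus final system of one constructionist replicate."""

    allele_counts: np.ndarray  # n_t after pruning, t = 1..generations
    mean_fitness: np.ndarray  # post-selection wbar_t
    events: list  # (generation, "invasion" | "extinction" | "skipped_mutation", allele id)
    final_state: PopulationState
    final_fitness: FitnessSet
    final_allele_ids: list  # global ids of surviving alleles
    replicate: int = 0

    @property
    def final_n(self) -> int:
        return len(self.final_allele_ids)


def expand_fitness_set(fitness: FitnessSet, rng) -> FitnessSet:
    """Extend an n-allele fitness set to n+1 alleles with fresh U[0,1] entries.

    Pre-existing entries are carried over bit-identically; the 3n^2 + 2n + 1
    new combinations receive independent draws assigned in the stable
    enumeration order of the (n+1)-allele pair list.
    """
    g = _as_generator(rng)
    n = fitness.n
    new_pos = _new_positions(n)
    w = np.empty(count_parameters(n + 1))
    w[_embed_positions(n, n + 1)] = fitness.w
    w[new_pos] = g.uniform(size=new_pos.size)
    return FitnessSet(n + 1, w)


def introduce_mutant(
    state: PopulationState, mutant_frequency: float, rng
) -> tuple[PopulationState, int]:
    """Add a new allele at exactly ``mutant_frequency``, donated by one resident.

    The donor allele d is chosen uniformly among alleles with p_d strictly
    above the mutant frequency; a fraction u = mutant_frequency / p_d of its
    copies is converted to the mutant, so x_dk -> (1-u) x_dk with u x_dk moved
    to the {k, mutant} heterozygote (and x_dd splitting (1-u)^2 / 2u(1-u) /
    u^2).  This reduces the donor's allele frequency by exactly the mutant
    frequency and leaves every other allele frequency unchanged to the last
    bit.  Returns (new state, donor index); raises
    :class:`NoEligibleDonorError` if no allele can donate.
    """
    if mutant_frequency <= 0:
        raise ValueError("mutant_frequency must be positive")
    g = _as_generator(rng)
    p = state.allele_frequencies()
    eligible = np.where(p > mutant_frequency)[0]
    if eligible.size == 0:
        raise NoEligibleDonorError("no resident allele exceeds the mutant frequency")
    donor = int(eligible[g.integers(eligible.size)])
    n = state.n
    u = mutant_frequency / p[donor]
    x = np.zeros((n + 1, n + 1))
    x[:n, :n] = state.x
    m = n
    xdd = state.x[donor, donor]
    for k in range(n):
        if k == donor:
            continue
        moved = u * state.x[donor, k]
        x[donor, k] -= moved
        x[k, donor] -= moved
        x[k, m] += moved
        x[m, k] += moved
    x[donor, donor] = (1.0 - u) ** 2 * xdd
    het = 2.0 * u * (1.0 - u) * xdd
    x[donor, m] += het
    x[m, donor] += het
    x[m, m] = u * u * xdd
    return PopulationState(x), donor


def prune_extinct(
    state: PopulationState, fitness: FitnessSet, threshold: float
) -> tuple[PopulationState, FitnessSet, list]:
    """Remove every allele with frequency strictly below ``threshold``.

    Removal and renormalization can push a surviving allele below threshold
    (its heterozygotes with the removed allele vanish), so the sweep repeats
    until stable.  Returns (state, fitness, removed allele indices relative to
    the input indexing).
    """
    if state.n != fitness.n:
        raise ValueError("state and fitness set must share n")
    labels = list(range(state.n))
    removed: list = []
    while True:
        p = state.allele_frequencies()
        low = np.where(p < threshold)[0]
        if low.size == 0:
            break
        if low.size == p.size:
            raise DegenerateStateError("every allele is below the extinction threshold")
        keep = [t for t in range(p.size) if t not in set(low.tolist())]
        removed.extend(labels[t] for t in low)
        labels = [labels[t] for t in keep]
        state = state.subset(keep)
        fitness = fitness.subset(keep)
    return state, fitness, removed


def run_construction(
    config: ConstructionConfig, replicate: int = 0, record_every: int = 1
) -> TrajectoryRecord:
    """One constructionist replicate; reproducible from (config.rng.seed, replicate)."""
    g = config.rng.child(replicate).generator()
    fitness = FitnessSet.constant(1, config.initial_fitness)
    state = PopulationState.monomorphic(1)
    allele_ids = [0]
    next_id = 1
    G = config.generations
    n_t = np.empty(G, dtype=np.int32)
    wbar_t = np.empty(G)
    events: list = []
    mutate = config.mutant_frequency > 0
    for gen in range(1, G + 1):
        if mutate:
            try:
                state, _donor = introduce_mutant(state, config.mutant_frequency, g)
            except NoEligibleDonorError:
                events.append((gen, "skipped_mutation", -1))
            else:
                fitness = expand_fitness_set(fitness, g)
                allele_ids.append(next_id)
                events.append((gen, "invasion", next_id))
                next_id += 1
        x_new, wbar = _step_arrays(state.x, fitness.tensor())
        if wbar <= 0.0:
            raise DegenerateStateError("mean fitness reached zero")
        state = PopulationState(x_new)
        state, fitness, removed = prune_extinct(state, fitness, config.extinction_threshold)
        for r in sorted(removed, reverse=True):
            events.append((gen, "extinction", allele_ids[r]))
            del allele_ids[r]
        n_t[gen - 1] = state.n
        wbar_t[gen - 1] = wbar
    if record_every > 1:
        idx = np.arange(record_every - 1, G, record_every)
        n_t, wbar_t = n_t[idx], wbar_t[idx]
    return TrajectoryRecord(
        allele_counts=n_t,
        mean_fitness=wbar_t,
        events=events,
        final_state=state,
        final_fitness=fitness,
        final_allele_ids=allele_ids,
        replicate=replicate,
    )


def reiterate_without_mutation(
    record: TrajectoryRecord, generations: int, threshold: float = 1e-5
) -> int:
    """Iterate a recorded final system further with no mutation; return surviving allele count."""
    state, fitness = record.final_state, record.final_fitness
    for _ in range(generations):
        x_new, wbar = _step_arrays(state.x, fitness.tensor())
        if wbar <= 0.0:
            raise DegenerateStateError("mean fitness reached zero")
        state = PopulationState(x_new)
        state, fitness, _ = prune_extinct(state, fitness, threshold)
    return state.n
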