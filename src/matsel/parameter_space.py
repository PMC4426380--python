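"""Estimating the potential for polymorphism by Monte-Carlo parameter-space sampling.

For a fixed allele number n, draw random fitness sets (each entry independent
U[0,1]) and, for each set, iterate the maternal-selection recursion from many
random initial conditions (broken-stick allele frequencies expanded to
Hardy-Weinberg genotype proportions).  A run "retains" its n alleles if no
allele frequency ever falls below the loss threshold before the run converges
or the generation horizon is reached; cycling n-allele runs count as retained.
A fitness set is "always" if every start retains all n alleles, "never" if no
start does, and "sometimes" otherwise.  The potential for polymorphism is the
pooled proportion of retaining runs, which decomposes exactly as

    potential = P(always) + P(sometimes) * retention-fraction-among-sometimes.

The heavy lifting is done by a batch engine that advances thousands of
independent populations per numpy call, retiring each run as soon as it loses
an allele or converges.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .model import (
    DegenerateStateError,
    FitnessSet,
    PopulationState,
    count_parameters,
)
from .random_inputs import GENERATOR_NAME, RngConfig, broken_stick_batch, _as_generator

__all__ = [
    "RunParams",
    "RunOutcome",
    "FitnessSetVerdict",
    "PotentialSummary",
    "run_to_outcome",
    "classify_fitness_set",
    "estimate_potential",
]


@dataclass(frozen=True)
class RunParams:
    """Stopping rules for a single deterministic iteration.

    convergence: max-norm allele-frequency change < ``convergence_tol`` for
    ``convergence_window`` consecutive generations.  Cycling: an unconverged
    run at the horizon whose allele-frequency vector recurs (within
    ``cycling_tol``, lag >= 2) inside a trailing ``cycling_window``-generation
    window, provided the window's amplitude exceeds ``cycling_min_amplitude``
    (which separates genuine cycles from slow monotone transients).
    """

    max_generations: int = 10_000
    loss_threshold: float = 1e-5
    convergence_tol: float = 1e-9
    convergence_window: int = 100
    cycling_window: int = 1000
    cycling_tol: float = 1e-6
    cycling_min_amplitude: float = 1e-4


@dataclass
class RunOutcome:
    """Result of iterating one (state, fitness set) pair to termination."""

    retained_alleles: int
    converged: bool
    cycling: bool
    final_state: PopulationState
    generations_run: int
    surviving_alleles: list


@dataclass
class FitnessSetVerdict:
    category: str  # "always" | "sometimes" | "never"
    fraction_polymorphic: float
    retained: np.ndarray
    cycling: np.ndarray


# ---------------------------------------------------------------------------
# batch engine


def _batch_step(X: np.ndarray, Vp: np.ndarray, d: np.ndarray):
    """Advance every population one generation.

    X:  (B, n, n) genotype matrices (total-heterozygote convention).
    Vp: (B, n, n, n) maternal tensor pre-transposed so Vp[b,j,i,k] = V[b,i,j,k].
    Returns (X_next, p_next, p_current, wbar).
    """
    B, n = X.shape[0], X.shape[1]
    T = 0.5 * X
    T[:, d, d] = X[:, d, d]
    p = T.sum(axis=2)
    # M[b,i,j] = sum_k V[b,i,j,k] T[b,j,k], via one batched matvec
    Mt = np.matmul(Vp.reshape(B * n, n, n), T.reshape(B * n, n, 1)).reshape(B, n, n)
    A = p[:, :, None] * Mt.transpose(0, 2, 1)
    wbar = A.sum(axis=(1, 2))
    if np.any(wbar <= 0.0):
        raise DegenerateStateError("mean fitness reached zero in a batch run")
    Y = A + A.transpose(0, 2, 1)
    Y[:, d, d] = A[:, d, d]
    X_next = Y / wbar[:, None, None]
    p_next = 0.5 * (A.sum(axis=2) + A.sum(axis=1)) / wbar[:, None]
    return X_next, p_next, p, wbar


def _cycling_diagnostic(Vp, X, params: RunParams, chunk: int = 2048):
    """Flag cycling among horizon survivors by a recurrence test.

    Each run is iterated ``cycling_window`` further generations; it is cycling
    if its final allele-frequency vector recurs (max-norm < cycling_tol) at
    lag >= 2 within the window and the window amplitude exceeds the floor.
    """
    m, n = X.shape[0], X.shape[1]
    d = np.arange(n)
    W = params.cycling_window
    out = np.zeros(m, dtype=bool)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        Xc = X[lo:hi].copy()
        Vc = np.ascontiguousarray(Vp[lo:hi])
        hist = np.empty((hi - lo, W, n))
        for t in range(W):
            Xc, p_next, _, _ = _batch_step(Xc, Vc, d)
            hist[:, t] = p_next
        final = hist[:, -1]
        amp = (hist.max(axis=1) - hist.min(axis=1)).max(axis=1)
        dist = np.abs(hist[:, :-2, :] - final[:, None, :]).max(axis=2).min(axis=1)
        out[lo:hi] = (dist < params.cycling_tol) & (amp > params.cycling_min_amplitude)
    return out


def _run_batch(V: np.ndarray, X0: np.ndarray, params: RunParams):
    """Iterate B independent (fitness, start) runs until loss/convergence/horizon.

    Returns boolean arrays (retained, converged, cycling) of length B.  A run
    is retired permanently the first time an allele drops below the loss
    threshold (not retained) or the convergence streak completes (retained);
    horizon survivors are retained and probed for cycling.
    """
    B, n = X0.shape[0], X0.shape[1]
    retained = np.zeros(B, dtype=bool)
    converged = np.zeros(B, dtype=bool)
    cycling = np.zeros(B, dtype=bool)
    d = np.arange(n)
    Vp = np.ascontiguousarray(V.transpose(0, 2, 1, 3))
    X = X0.astype(float, copy=True)
    ids = np.arange(B)
    streak = np.zeros(B, dtype=np.int32)
    status = np.zeros(B, dtype=np.int8)  # 0 running, 1 lost, 2 converged
    p_prev = 0.5 * (X.sum(axis=2) + X[:, d, d])
    gen = 0
    while gen < params.max_generations and ids.size:
        X, p_new, _, _ = _batch_step(X, Vp, d)
        gen += 1
        running = status == 0
        lost = running & (p_new.min(axis=1) < params.loss_threshold)
        close = np.abs(p_new - p_prev).max(axis=1) < params.convergence_tol
        streak = np.where(close, streak + 1, 0)
        conv = running & ~lost & (streak >= params.convergence_window)
        status[lost] = 1
        status[conv] = 2
        p_prev = p_new
        ndone = int((status != 0).sum())
        if ndone and (ndone > 0.25 * ids.size or gen % 256 == 0 or gen == params.max_generations):
            fin = status != 0
            sel = ids[fin]
            ok = status[fin] == 2
            retained[sel] = ok
            converged[sel] = ok
            keep = ~fin
            ids = ids[keep]
            X = np.ascontiguousarray(X[keep])
            Vp = np.ascontiguousarray(Vp[keep])
            streak = streak[keep]
            status = status[keep]
            p_prev = p_prev[keep]
    if ids.size:
        fin = status != 0
        sel = ids[fin]
        ok = status[fin] == 2
        retained[sel] = ok
        converged[sel] = ok
        surv = ~fin
        if surv.any():
            # unconverged with all alleles above threshold: counted as retained
            retained[ids[surv]] = True
            cyc = _cycling_diagnostic(
                np.ascontiguousarray(Vp[surv]), np.ascontiguousarray(X[surv]), params
            )
            cycling[ids[surv]] = cyc
    return retained, converged, cycling


# ---------------------------------------------------------------------------
# scalar run with allele removal


def run_to_outcome(
    state: PopulationState,
    fitness: FitnessSet,
    params: RunParams = RunParams(),
) -> RunOutcome:
    """Iterate one population, removing alleles as they are lost, to termination.

    When an allele frequency drops below the loss threshold the allele (and its
    genotypes and fitness entries) is removed, frequencies are renormalized and
    iteration continues on the reduced system, so ``retained_alleles`` is the
    number of alleles surviving at termination.
    """
    from .model import step  # local import keeps module load light

    if state.n != fitness.n:
        raise ValueError("state and fitness set must share n")
    alleles = list(range(state.n))
    window: deque = deque(maxlen=params.cycling_window)
    streak = 0
    converged = False
    p_prev: Optional[np.ndarray] = state.allele_frequencies()
    gen = 0
    while gen < params.max_generations:
        state, _ = step(state, fitness)
        gen += 1
        p = state.allele_frequencies()
        removed_any = False
        while np.any(p < params.loss_threshold):
            keep = [t for t in range(p.size) if p[t] >= params.loss_threshold]
            if not keep:
                raise DegenerateStateError("every allele fell below the loss threshold")
            state = state.subset(keep)
            fitness = fitness.subset(keep)
            alleles = [alleles[t] for t in keep]
            p = state.allele_frequencies()
            removed_any = True
        if removed_any:
            streak = 0
            window.clear()
        else:
            streak = streak + 1 if np.abs(p - p_prev).max() < params.convergence_tol else 0
        p_prev = p
        window.append(p.copy())
        if streak >= params.convergence_window:
            converged = True
            break
    cycling = False
    if not converged and len(window) > 2:
        arr = np.stack(tuple(window))
        amp = float((arr.max(axis=0) - arr.min(axis=0)).max())
        dist = float(np.abs(arr[:-2] - arr[-1]).max(axis=1).min())
        cycling = dist < params.cycling_tol and amp > params.cycling_min_amplitude
    return RunOutcome(
        retained_alleles=len(alleles),
        converged=converged,
        cycling=cycling,
        final_state=state,
        generations_run=gen,
        surviving_alleles=alleles,
    )


# ---------------------------------------------------------------------------
# classification and the potential estimate


def _initial_batch(n: int, n_starts: int, g: np.random.Generator) -> np.ndarray:
    """HW genotype matrices from broken-stick allele frequencies, as a batch."""
    P = broken_stick_batch(n, n_starts, g)
    X0 = 2.0 * P[:, :, None] * P[:, None, :]
    d = np.arange(n)
    X0[:, d, d] = P * P
    return X0


def classify_fitness_set(
    fitness: FitnessSet,
    n_starts: int,
    rng: RngConfig,
    params: RunParams = RunParams(),
) -> FitnessSetVerdict:
    """Run ``n_starts`` random initial conditions and categorize the fitness set."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    g = _as_generator(rng)
    n = fitness.n
    X0 = _initial_batch(n, n_starts, g)
    V = np.broadcast_to(fitness.tensor(), (n_starts, n, n, n)).copy()
    retained, _, cycling = _run_batch(V, X0, params)
    frac = float(retained.mean())
    category = "always" if frac == 1.0 else ("never" if frac == 0.0 else "sometimes")
    return FitnessSetVerdict(category, frac, retained, cycling)


@dataclass
class PotentialSummary:
    """Aggregate of a parameter-space experiment (one Table-1-style row)."""

    n: int
    n_sets: int
    n_starts: int
    fractions: np.ndarray  # per-set fraction of starts retaining all n alleles
    cycling_sets: int
    nonconverged_runs: int
    seed: int
    params: RunParams

    @property
    def always_count(self) -> int:
        return int(np.sum(self.fractions == 1.0))

    @property
    def never_count(self) -> int:
        return int(np.sum(self.fractions == 0.0))

    @property
    def sometimes_count(self) -> int:
        return self.n_sets - self.always_count - self.never_count

    @property
    def sometimes_retention(self) -> float:
        mask = (self.fractions > 0.0) & (self.fractions < 1.0)
        return float(self.fractions[mask].mean()) if mask.any() else float("nan")

    @property
    def potential(self) -> float:
        return float(self.fractions.mean())

    @property
    def potential_se(self) -> float:
        """Cluster (between-set) standard error of the pooled potential."""
        if self.n_sets < 2:
            return float("nan")
        return float(self.fractions.std(ddof=1) / np.sqrt(self.n_sets))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_sets": self.n_sets,
            "n_starts": self.n_starts,
            "always_count": self.always_count,
            "sometimes_count": self.sometimes_count,
            "never_count": self.never_count,
            "sometimes_retention": self.sometimes_retention,
            "potential": self.potential,
            "potential_se": self.potential_se,
            "cycling_sets": self.cycling_sets,
            "nonconverged_runs": self.nonconverged_runs,
            "seed": self.seed,
            "generator": GENERATOR_NAME,
            "stopping_rules": asdict(self.params),
        }


def estimate_potential(
    n: int,
    n_sets: int,
    n_starts: int,
    rng: RngConfig,
    params: RunParams = RunParams(),
    set_block: int = 5000,
) -> PotentialSummary:
    """Monte-Carlo estimate of the potential for polymorphism at allele number n.

    Fitness set s and its starts derive from the stream ``rng.child(s)``, so
    every replicate is a pure function of (seed, s).  Sets are processed in
    blocks of ``set_block`` to bound memory.
    """
    if n_sets < 1 or n_starts < 1:
        raise ValueError("n_sets and n_starts must be >= 1")
    C = count_parameters(n)
    fractions = np.empty(n_sets)
    cycling_sets = 0
    nonconverged = 0
    for lo in range(0, n_sets, set_block):
        hi = min(lo + set_block, n_sets)
        nb = hi - lo
        W = np.empty((nb, C))
        X0 = np.empty((nb * n_starts, n, n))
        for s in range(lo, hi):
            g = rng.child(s).generator()
            W[s - lo] = g.uniform(size=C)
            X0[(s - lo) * n_starts : (s - lo + 1) * n_starts] = _initial_batch(n, n_starts, g)
        from .model import _v_gather

        V = W[:, _v_gather(n).ravel()].reshape(nb, n, n, n)
        V = np.repeat(V, n_starts, axis=0)
        retained, converged, cycling = _run_batch(V, X0, params)
        fractions[lo:hi] = retained.reshape(nb, n_starts).mean(axis=1)
        cycling_sets += int(cycling.reshape(nb, n_starts).any(axis=1).sum())
        nonconverged += int((retained & ~converged).sum())
    return PotentialSummary(
        n=n,
        n_sets=n_sets,
        n_starts=n_starts,
        fractions=fractions,
        cycling_sets=cycling_sets,
        nonconverged_runs=nonconverged,
        seed=rng.seed,
        params=params,
    )
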