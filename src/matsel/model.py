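"""Core objects and the one-generation recursion of the n-allele maternal-selection model.

An individual's viability depends jointly on its own genotype A_iA_j and its
mother's genotype A_kA_l, parameterized by a relative fitness w_ijkl in [0, 1].
A mother is *compatible* with an offspring if she carries at least one of the
offspring's alleles (she must have transmitted one).  The number of distinct
compatible offspring-mother combinations, and hence of fitness parameters, is

    C(n) = n^2 + n(n-1)(2n-1)/2

(n^2 homozygote-offspring combinations plus the heterozygote-offspring ones).

Genotype frequencies x_ij (x_ij = x_ji, the *total* frequency of the unordered
heterozygote) evolve deterministically under random mating in an effectively
infinite dioecious population.  Writing p_i = x_ii + (1/2)Σ_{j≠i} x_ij for the
allele frequencies, the next generation satisfies

    wbar * x'_ii = p_i * ( w_iiii x_ii + (1/2) Σ_{k≠i} w_iiik x_ik )
    wbar * x'_ij = p_i * ( w_ijjj x_jj + (1/2) Σ_{k≠j} w_ijjk x_jk )
               + p_j * ( w_ijii x_ii + (1/2) Σ_{k≠i} w_ijik x_ik ),   i ≠ j,

where wbar, the population mean fitness, is the sum of all right-hand sides and
normalizes the frequencies to one.

Allele indices are stored 0-based internally and rendered 1-based (A_1...A_n)
in all I/O.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "OffspringMotherPair",
    "PairClass",
    "FitnessSet",
    "PopulationState",
    "DegenerateStateError",
    "count_parameters",
    "heterozygote_pair_count",
    "enumerate_pairs",
    "classify_pair",
    "allele_frequencies",
    "step",
]


class DegenerateStateError(RuntimeError):
    """Raised when the mean fitness of the unnormalized update is zero."""


class Genotype(NamedTuple):
    """Unordered diploid genotype A_iA_j, canonicalized so that i <= j."""

    i: int
    j: int

    @staticmethod
    def of(a: int, b: int) -> "Genotype":
        if a < 0 or b < 0:
            raise ValueError("allele indices must be non-negative")
        return Genotype(a, b) if a <= b else Genotype(b, a)

    @property
    def is_homozygote(self) -> bool:
        return self.i == self.j

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.i, self.j))

    def __str__(self) -> str:  # 1-based rendering
        return f"A{self.i + 1}A{self.j + 1}"


class OffspringMotherPair(NamedTuple):
    """A compatible (offspring, mother) genotype combination carrying one w_ijkl."""

    offspring: Genotype
    mother: Genotype

    @staticmethod
    def of(offspring: Genotype | tuple, mother: Genotype | tuple) -> "OffspringMotherPair":
        og = Genotype.of(*offspring)
        mg = Genotype.of(*mother)
        pair = OffspringMotherPair(og, mg)
        if not pair.is_compatible:
            raise ValueError(f"mother {mg} shares no allele with offspring {og}")
        return pair

    @property
    def is_compatible(self) -> bool:
        og, mg = self.offspring, self.mother
        return og.i in (mg.i, mg.j) or og.j in (mg.i, mg.j)

    def __str__(self) -> str:
        return f"({self.offspring}, {self.mother})"


class PairClass(enum.Enum):
    """The five classes of offspring-mother combinations.

    C_iiii: homozygote with homozygous (identical) mother
    C_iiij: homozygote with heterozygous mother
    C_ijii: heterozygote with homozygous mother
    C_ijij: heterozygote with identical heterozygous mother
    C_ijik: heterozygote with non-identical heterozygous mother
    """

    C_iiii = "C_iiii"
    C_iiij = "C_iiij"
    C_ijii = "C_ijii"
    C_ijij = "C_ijij"
    C_ijik = "C_ijik"


def count_parameters(n: int) -> int:
    """Number of distinct fitness parameters C(n) = n^2 + n(n-1)(2n-1)/2."""
    n = _check_n(n)
    return n * n + heterozygote_pair_count(n)


def heterozygote_pair_count(n: int) -> int:
    """Number of heterozygote-offspring/mother combinations, n(n-1)(2n-1)/2."""
    n = _check_n(n)
    return n * (n - 1) * (2 * n - 1) // 2


def _check_n(n: int) -> int:
    if int(n) != n or n < 1:
        raise ValueError(f"allele count n must be a positive integer, got {n!r}")
    return int(n)


@lru_cache(maxsize=None)
def enumerate_pairs(n: int) -> tuple[OffspringMotherPair, ...]:
    """All compatible canonical offspring-mother pairs for ``n`` alleles.

    The order (offspring lexicographic, then mother lexicographic) is fixed and
    used everywhere a fitness parameter vector is laid out, so seeded random
    assignment is reproducible.
    """
    n = _check_n(n)
    out = []
    for i in range(n):
        for j in range(i, n):
            og = Genotype(i, j)
            for k in range(n):
                for l in range(k, n):
                    mg = Genotype(k, l)
                    pair = OffspringMotherPair(og, mg)
                    if pair.is_compatible:
                        out.append(pair)
    return tuple(out)


@lru_cache(maxsize=None)
def _pair_index(n: int) -> dict:
    return {pair: t for t, pair in enumerate(enumerate_pairs(n))}


@lru_cache(maxsize=None)
def _v_gather(n: int) -> np.ndarray:
    """Index tensor G with G[i,j,k] = canonical index of ({i,j}, {j,k}).

    V = w[G] is the maternal-transmission tensor used by :func:`step`:
    V[i,j,k] is the fitness of an {i,j} offspring whose mother has genotype
    {j,k} and transmitted allele j.  Every (i,j,k) names a compatible pair.
    """
    idx = _pair_index(n)
    G = np.empty((n, n, n), dtype=np.intp)
    for i in range(n):
        for j in range(n):
            og = Genotype.of(i, j)
            for k in range(n):
                G[i, j, k] = idx[OffspringMotherPair(og, Genotype.of(j, k))]
    return G


def classify_pair(pair: OffspringMotherPair) -> PairClass:
    """Assign a compatible pair to exactly one of the five combination classes."""
    if not pair.is_compatible:
        raise ValueError(f"incompatible pair {pair}")
    og, mg = pair.offspring, pair.mother
    if og.is_homozygote:
        return PairClass.C_iiii if mg.is_homozygote else PairClass.C_iiij
    if mg.is_homozygote:
        return PairClass.C_ijii
    return PairClass.C_ijij if og == mg else PairClass.C_ijik


@lru_cache(maxsize=None)
def _class_codes(n: int) -> np.ndarray:
    """Per-parameter class membership, coded by PairClass ordinal."""
    order = list(PairClass)
    return np.array([order.index(classify_pair(p)) for p in enumerate_pairs(n)], dtype=np.int8)


@dataclass(frozen=True)
class FitnessSet:
    """A complete maternal-selection fitness set for ``n`` alleles.

    ``w`` holds one value per canonical pair, in :func:`enumerate_pairs` order.
    """

    n: int
    w: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        C = count_parameters(self.n)
        if self.w.shape != (C,):
            raise ValueError(f"fitness vector must have C({self.n}) = {C} entries, got {self.w.shape}")
        if np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("fitness values must lie in [0, 1]")

    @staticmethod
    def from_dict(n: int, values: dict) -> "FitnessSet":
        """Build from a {pair: fitness} mapping covering every canonical pair."""
        idx = _pair_index(n)
        w = np.empty(count_parameters(n))
        seen = 0
        for pair, value in values.items():
            if not isinstance(pair, OffspringMotherPair):
                pair = OffspringMotherPair.of(*pair)
            w[idx[pair]] = value
            seen += 1
        if seen != w.size:
            raise ValueError(f"expected {w.size} entries, got {seen}")
        return FitnessSet(n, w)

    @staticmethod
    def constant(n: int, value: float) -> "FitnessSet":
        return FitnessSet(n, np.full(count_parameters(n), float(value)))

    @staticmethod
    def mother_independent(v: np.ndarray) -> "FitnessSet":
        """Embed an ordinary viability matrix v[i,j] (offspring-only fitnesses)."""
        v = np.asarray(v, float)
        n = v.shape[0]
        w = np.empty(count_parameters(n))
        for t, pair in enumerate(enumerate_pairs(n)):
            w[t] = v[pair.offspring.i, pair.offspring.j]
        return FitnessSet(n, w)

    def __getitem__(self, pair) -> float:
        if not isinstance(pair, OffspringMotherPair):
            pair = OffspringMotherPair.of(*pair)
        return float(self.w[_pair_index(self.n)[pair]])

    def tensor(self) -> np.ndarray:
        """Dense maternal-transmission tensor V[i,j,k] (see :func:`_v_gather`)."""
        return self.w[_v_gather(self.n)]

    def subset(self, alleles: Sequence[int]) -> "FitnessSet":
        """Fitness set restricted to ``alleles`` (relabelled 0..m-1 in the given order)."""
        alleles = list(alleles)
        m = len(alleles)
        if m == 0:
            raise ValueError("cannot build a fitness set on zero alleles")
        if sorted(alleles) == list(range(m)) and alleles == sorted(alleles):
            # leading block: positions are cached
            return FitnessSet(m, self.w[_embed_positions(m, self.n)])
        idx = _pair_index(self.n)
        w = np.empty(count_parameters(m))
        for t, pair in enumerate(enumerate_pairs(m)):
            og = Genotype.of(alleles[pair.offspring.i], alleles[pair.offspring.j])
            mg = Genotype.of(alleles[pair.mother.i], alleles[pair.mother.j])
            w[t] = self.w[idx[OffspringMotherPair(og, mg)]]
        return FitnessSet(m, w)

    def permute(self, perm: Sequence[int]) -> "FitnessSet":
        """Relabel alleles: new allele a is old allele perm[a]."""
        if sorted(perm) != list(range(self.n)):
            raise ValueError("perm must be a permutation of range(n)")
        return self.subset(perm)

    def class_membership(self) -> np.ndarray:
        """PairClass ordinal (0..4) of each canonical parameter."""
        return _class_codes(self.n)


@lru_cache(maxsize=None)
def _embed_positions(m: int, n: int) -> np.ndarray:
    """Positions of the m-allele canonical pairs inside the n-allele enumeration (m <= n)."""
    idx = _pair_index(n)
    return np.array([idx[p] for p in enumerate_pairs(m)], dtype=np.intp)


@lru_cache(maxsize=None)
def _new_positions(n: int) -> np.ndarray:
    """Positions, within enumerate_pairs(n+1), of pairs involving the new allele n."""
    old = set(enumerate_pairs(n))
    return np.array(
        [t for t, p in enumerate(enumerate_pairs(n + 1)) if p not in old], dtype=np.intp
    )


@dataclass
class PopulationState:
    """Genotype frequencies of the population.

    ``x`` is a symmetric (n, n) matrix; the off-diagonal entry x[i, j] is the
    *total* frequency of the unordered heterozygote A_iA_j (stored in both
    cells for convenience), so that sum(diag) + sum(upper triangle) = 1.
    """

    x: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[0] != self.x.shape[1]:
            raise ValueError("genotype-frequency matrix must be square")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def total(self) -> float:
        return float(np.diag(self.x).sum() + np.triu(self.x, 1).sum())

    def validate(self, tol: float = 1e-8) -> "PopulationState":
        if not np.allclose(self.x, self.x.T, atol=1e-12, rtol=0):
            raise ValueError("genotype-frequency matrix must be symmetric")
        if np.any(self.x < -1e-12):
            raise ValueError("genotype frequencies must be non-negative")
        if abs(self.total() - 1.0) > tol:
            raise ValueError(f"genotype frequencies sum to {self.total()}, not 1")
        return self

    @staticmethod
    def monomorphic(n_total: int = 1) -> "PopulationState":
        x = np.zeros((n_total, n_total))
        x[0, 0] = 1.0
        return PopulationState(x)

    def allele_frequencies(self) -> np.ndarray:
        return allele_frequencies(self)

    def subset(self, alleles: Sequence[int]) -> "PopulationState":
        """Drop all genotypes carrying alleles outside ``alleles`` and renormalize."""
        sub = self.x[np.ix_(alleles, alleles)]
        tot = np.diag(sub).sum() + np.triu(sub, 1).sum()
        if tot <= 0:
            raise ValueError("no frequency mass left after restriction")
        return PopulationState(sub / tot)


def allele_frequencies(state: PopulationState) -> np.ndarray:
    """p_i = x_ii + (1/2) Σ_{j≠i} x_ij."""
    x = state.x
    d = np.diag(x)
    return 0.5 * (x.sum(axis=1) + d)


def hardy_weinberg_total(p: np.ndarray) -> np.ndarray:
    """HW genotype matrix in total-heterozygote-frequency convention."""
    p = np.asarray(p, float)
    x = 2.0 * np.outer(p, p)
    np.fill_diagonal(x, p * p)
    return x


def step(state: PopulationState, fitness: FitnessSet) -> tuple[PopulationState, float]:
    """One generation of maternal selection under random mating.

    Returns the next-generation state and the mean fitness wbar used to
    normalize it.  Raises :class:`DegenerateStateError` if wbar is zero.
    """
    if state.n != fitness.n:
        raise ValueError(f"state has {state.n} alleles but fitness set has {fitness.n}")
    V = fitness.tensor()
    x_new, wbar = _step_arrays(state.x, V)
    if wbar <= 0.0:
        raise DegenerateStateError("mean fitness of the unnormalized update is zero")
    # rounding guard: distinguish drift from logic errors
    tot = np.diag(x_new).sum() + np.triu(x_new, 1).sum()
    err = abs(tot - 1.0)
    if err > 1e-8:
        raise RuntimeError(f"genotype frequencies drifted from 1 by {err:.3e}")
    if err > 1e-12:
        x_new = x_new / tot
    return PopulationState(x_new), float(wbar)


def _step_arrays(x: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, float]:
    """Unchecked single-population update; shared by the public step()."""
    n = x.shape[0]
    # T[j,k]: probability a random mother has genotype {j,k} AND transmits j
    T = 0.5 * x.copy()
    d = np.arange(n)
    T[d, d] = x[d, d]
    p = T.sum(axis=1)
    # M[i,j] = Σ_k V[i,j,k] T[j,k]: chance an {i,j} child gets j maternally, weighted by w
    M = np.einsum("ijk,jk->ij", V, T)
    A = p[:, None] * M
    wbar = A.sum()
    if wbar <= 0.0:
        return x, 0.0
    Y = A + A.T
    Y[d, d] = A[d, d]
    return Y / wbar, wbar
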