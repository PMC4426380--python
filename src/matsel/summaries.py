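"""Summary statistics and report generation.

Covers the evenness statistic I = Σ(p_i - 1/n)^2 (squared distance of an
allele-frequency vector from the simplex centroid; 0 for equal frequencies,
1 - 1/n at a vertex), per-class mean fitnesses of the five offspring-mother
combination classes, Table-style aggregation of parameter-space experiments,
and histogram/mean summaries of constructionist experiments including an
internally generated broken-stick baseline for I.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import FitnessSet, PairClass, allele_frequencies
from .parameter_space import PotentialSummary
from .constructionist import TrajectoryRecord
from .random_inputs import RngConfig, broken_stick_batch

__all__ = [
    "ClassMeans",
    "evenness_statistic",
    "class_means",
    "summarize_experiment",
    "summarize_parameter_space",
    "summarize_construction",
]


@dataclass(frozen=True)
class ClassMeans:
    """Mean fitness per offspring-mother class; None flags an empty class.

    With one allele only C_iiii is populated; with two alleles C_ijik (a
    heterozygote with a non-identical heterozygous mother) does not exist.
    """

    c_iiii: Optional[float]
    c_iiij: Optional[float]
    c_ijii: Optional[float]
    c_ijij: Optional[float]
    c_ijik: Optional[float]

    def as_dict(self) -> dict:
        return {c.value: getattr(self, c.value.lower()) for c in PairClass}


def evenness_statistic(p) -> float:
    """I = Σ (p_i - 1/n)^2 for an allele-frequency vector on the simplex."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must be a frequency vector on the simplex")
    return float(np.sum((p - 1.0 / p.size) ** 2))


def class_means(fitness: FitnessSet) -> ClassMeans:
    """Arithmetic mean of the fitness entries within each combination class."""
    codes = fitness.class_membership()
    vals = {}
    for c, cls in enumerate(PairClass):
        mask = codes == c
        vals[cls.value.lower()] = float(fitness.w[mask].mean()) if mask.any() else None
    return ClassMeans(**vals)


def summarize_parameter_space(summary: PotentialSummary) -> dict:
    """Table-style row: always/sometimes counts, retention, potential, errors.

    Binomial standard errors accompany the set-level proportions; the pooled
    potential carries a cluster (between-set) standard error because runs
    sharing a fitness set are correlated.
    """
    ns = summary.n_sets
    p_always = summary.always_count / ns
    p_sometimes = summary.sometimes_count / ns
    out = summary.to_dict()
    out.update(
        {
            "always_proportion": p_always,
            "always_se": float(np.sqrt(p_always * (1 - p_always) / ns)),
            "sometimes_proportion": p_sometimes,
            "sometimes_se": float(np.sqrt(p_sometimes * (1 - p_sometimes) / ns)),
            "identity_check": p_always
            + p_sometimes * (0.0 if ns == 0 or summary.sometimes_count == 0 else summary.sometimes_retention),
        }
    )
    return out


def summarize_construction(
    records: Sequence[TrajectoryRecord],
    baseline_rng: Optional[RngConfig] = None,
    baseline_draws: int = 10_000,
    min_group: int = 10,
) -> dict:
    """Aggregate constructionist replicates.

    Reports the final allele-number histogram (with mode, mean and its
    standard error), per-final-n class means for groups with at least
    ``min_group`` replicates, final mean fitness per n, and evenness values I
    together with a broken-stick baseline distribution (unranked spacings)
    generated internally for every represented n.
    """
    records = list(records)
    if not records:
        return {"empty": True}
    final_n = np.array([r.final_n for r in records])
    counts = np.bincount(final_n)
    mean = float(final_n.mean())
    sem = float(final_n.std(ddof=1) / np.sqrt(final_n.size)) if final_n.size > 1 else float("nan")
    out: dict = {
        "replicates": len(records),
        "final_n_histogram": {int(n): int(c) for n, c in enumerate(counts) if c},
        "final_n_mode": int(np.argmax(counts)),
        "final_n_mean": mean,
        "final_n_sem": sem,
        "empty": False,
    }
    by_n: dict = {}
    for r in records:
        by_n.setdefault(r.final_n, []).append(r)
    cm_rows = {}
    wbar_rows = {}
    evenness: dict = {}
    for n, group in sorted(by_n.items()):
        i_vals = [evenness_statistic(allele_frequencies(r.final_state)) for r in group]
        evenness[int(n)] = i_vals
        wbar_rows[int(n)] = float(np.mean([r.mean_fitness[-1] for r in group]))
        if len(group) >= min_group:
            per_class: dict = {c.value: [] for c in PairClass}
            for r in group:
                for label, v in class_means(r.final_fitness).as_dict().items():
                    if v is not None:
                        per_class[label].append(v)
            cm_rows[int(n)] = {
                label: (float(np.mean(vs)) if vs else None) for label, vs in per_class.items()
            }
    out["class_means_by_final_n"] = cm_rows
    out["final_mean_fitness_by_n"] = wbar_rows
    out["evenness_by_final_n"] = evenness
    if baseline_rng is not None:
        baseline = {}
        for n in sorted(by_n):
            if n < 2:
                continue
            P = broken_stick_batch(n, baseline_draws, baseline_rng.child(n))
            baseline[int(n)] = np.sum((P - 1.0 / n) ** 2, axis=1).tolist()
        out["broken_stick_baseline_I"] = baseline
    return out


def summarize_experiment(records) -> dict:
    """Dispatch: a PotentialSummary or a collection of TrajectoryRecords."""
    if isinstance(records, PotentialSummary):
        return summarize_parameter_space(records)
    records = list(records)
    if not records:
        return {"empty": True}
    if all(isinstance(r, TrajectoryRecord) for r in records):
        return summarize_construction(records)
    raise TypeError("records must be a PotentialSummary or TrajectoryRecords")
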