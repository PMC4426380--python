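"""Optional figures (requires matplotlib); a data-identical CSV always
accompanies each figure so plots are cosmetic, never the record."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires the 'plots' extra (matplotlib)") from exc
    return plt


def plot_potential_curve(summaries: Sequence, out_prefix) -> None:
    """Potential for polymorphism and always-set proportion versus n."""
    rows = pd.DataFrame(
        {
            "n": [s.n for s in summaries],
            "potential": [s.potential for s in summaries],
            "always_proportion": [s.always_count / s.n_sets for s in summaries],
        }
    )
    out_prefix = Path(out_prefix)
    rows.to_csv(out_prefix.with_suffix(".csv"), index=False)
    plt = _pyplot()
    fig, ax = plt.subplots()
    ax.semilogy(rows.n, rows.potential, "o-", label="potential for polymorphism")
    ax.semilogy(rows.n, rows.always_proportion, "s-", label='"always" fitness sets')
    ax.set_xlabel("number of alleles n")
    ax.set_ylabel("proportion of parameter/state space")
    ax.legend()
    fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
    plt.close(fig)


def plot_final_allele_histogram(final_n: Sequence[int], out_prefix) -> None:
    """Bar chart of the number of alleles at the final generation."""
    final_n = np.asarray(final_n)
    counts = np.bincount(final_n)
    out_prefix = Path(out_prefix)
    pd.DataFrame({"n": np.arange(counts.size), "count": counts}).to_csv(
        out_prefix.with_suffix(".csv"), index=False
    )
    plt = _pyplot()
    fig, ax = plt.subplots()
    ax.bar(np.arange(counts.size), counts)
    ax.set_xlabel("alleles at final generation")
    ax.set_ylabel("replicates")
    fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
    plt.close(fig)


def plot_evenness_histograms(evenness_by_n: dict, baseline_by_n: dict, out_prefix) -> None:
    """Histograms of I = sum (p_i - 1/n)^2 against the broken-stick baseline."""
    out_prefix = Path(out_prefix)
    rows = []
    for n, vals in evenness_by_n.items():
        rows += [(n, "observed", v) for v in vals]
    for n, vals in baseline_by_n.items():
        rows += [(n, "broken_stick", v) for v in vals]
    pd.DataFrame(rows, columns=["n", "source", "I"]).to_csv(
        out_prefix.with_suffix(".csv"), index=False
    )
    plt = _pyplot()
    ns = sorted(set(evenness_by_n) & set(baseline_by_n))
    fig, axes = plt.subplots(1, max(len(ns), 1), figsize=(4 * max(len(ns), 1), 3))
    for ax, n in zip(np.atleast_1d(axes), ns):
        ax.hist(baseline_by_n[n], bins=30, density=True, histtype="step", label="broken stick")
        ax.hist(evenness_by_n[n], bins=30, density=True, histtype="step", label="observed")
        ax.set_title(f"n = {n}")
        ax.set_xlabel("I")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
    plt.close(fig)
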