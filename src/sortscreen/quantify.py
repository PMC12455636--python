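"""Genotype counting, abundance matrices, top-N tables and gate profiles.

Counts only full calls (reads spanning the whole amplicon with every grammar
slot recovered), tabulates them as a promoter x signal-peptide matrix per
(ORF library, gate) pool, and summarises enrichment across the low/medium/
high gates as a single rank score per genotype: the gate-weighted mean of its
per-gate fractions with weights low=0, medium=1, high=2. A genotype sorted
entirely into the high gate scores 2.0, entirely low scores 0.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .calling import FULL, GenotypeCall

GATE_WEIGHTS = {"low": 0.0, "medium": 1.0, "high": 2.0}

MIN_FULL_READS_DEFAULT = 1000


@dataclass
class AbundanceMatrix:
    """Genotype counts for one pool as a promoter x signal-peptide table."""

    counts: pd.DataFrame  # promoter rows, sp columns, integer counts
    pool: tuple[str, str]  # (orf library, gate)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_full_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def fractions(self) -> pd.DataFrame:
        n = self.n_full_reads
        if n == 0:
            return self.counts.astype(float)
        return self.counts / n


def count_genotypes(
    calls: Sequence[GenotypeCall],
    pool: tuple[str, str],
    promoter_order: Sequence[str],
    sp_order: Sequence[str],
    min_full_reads: int | None = None,
) -> AbundanceMatrix:
    """Count full genotype calls from one pool into a promoter x sp matrix.

    Only ``call_status == full`` contributes; rows and columns follow the
    fixed registry order. An empty pool yields an all-zero matrix with a
    warning, as does a pool below ``min_full_reads`` (analysis-depth floor).
    """
    counts = pd.DataFrame(0, index=list(promoter_order), columns=list(sp_order), dtype=int)
    n_full = 0
    for call in calls:
        if call.call_status != FULL:
            continue
        n_full += 1
        if call.promoter_id in counts.index and call.sp_id in counts.columns:
            counts.loc[call.promoter_id, call.sp_id] += 1
        else:
            raise ValueError(
                f"full call ({call.promoter_id}, {call.sp_id}) outside the registry axes"
            )
    if n_full == 0:
        warnings.warn(f"pool {pool}: no full calls", stacklevel=2)
    elif min_full_reads is not None and n_full < min_full_reads:
        warnings.warn(
            f"pool {pool}: only {n_full} full reads (floor {min_full_reads})", stacklevel=2
        )
    return AbundanceMatrix(counts=counts, pool=pool)


def top_n(matrix: AbundanceMatrix, n: int) -> list[tuple[tuple[str, str], float]]:
    """Top-N (promoter, sp) combinations by fraction, descending.

    Ties break lexicographically on (promoter, sp); only nonzero cells are
    returned, so the list may be shorter than ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    frac = matrix.fractions
    entries = [
        ((p, s), float(frac.loc[p, s]))
        for p in frac.index
        for s in frac.columns
        if frac.loc[p, s] > 0
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries[:n]


def enrichment_across_gates(
    matrices: Mapping[str, AbundanceMatrix],
) -> pd.DataFrame:
    """Per-genotype gate profile and secretion rank score for one ORF library.

    ``matrices`` maps gate -> AbundanceMatrix (low, medium, high; same axes).
    The score is sum(weight_g * fraction_g) / sum(fraction_g) with weights
    low=0, medium=1, high=2 — depth-invariant because it is fraction-based.
    Genotypes absent from every gate are omitted.
    """
    gates = list(GATE_WEIGHTS)
    missing = [g for g in gates if g not in matrices]
    if missing:
        raise ValueError(f"missing gate matrices: {missing}")
    axes = {(tuple(m.counts.index), tuple(m.counts.columns)) for m in matrices.values()}
    if len(axes) != 1:
        raise ValueError("gate matrices must share row/column order")

    rows = []
    ref = matrices[gates[0]].counts
    for p in ref.index:
        for s in ref.columns:
            fracs = {g: float(matrices[g].fractions.loc[p, s]) for g in gates}
            total = sum(fracs.values())
            if total == 0:
                continue
            score = sum(GATE_WEIGHTS[g] * fracs[g] for g in gates) / total
            rows.append(
                {"promoter": p, "sp": s,
                 **{f"frac_{g}": fracs[g] for g in gates},
                 "score": score}
            )
    return pd.DataFrame(rows)


def export_heatmap_table(
    matrix: AbundanceMatrix, path: str | Path, plot: str | Path | None = None
) -> None:
    """Write the fraction matrix as TSV (promoter rows, sp columns, fixed
    registry order); optionally render a basic heatmap alongside."""
    matrix.fractions.to_csv(path, sep="\t", index_label="promoter")
    if plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 6))
        data = matrix.fractions.to_numpy(dtype=float)
        im = ax.imshow(data, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(matrix.fractions.columns)), matrix.fractions.columns)
        ax.set_yticks(range(len(matrix.fractions.index)), matrix.fractions.index)
        ax.set_title(f"{matrix.pool[0]} / {matrix.pool[1]} (n={matrix.n_full_reads})")
        fig.colorbar(im, ax=ax, label="fraction of full reads")
        fig.tight_layout()
        fig.savefig(plot, dpi=120)
        plt.close(fig)


def import_heatmap_table(path: str | Path, pool: tuple[str, str]) -> pd.DataFrame:
    """Read back a TSV written by :func:`export_heatmap_table`."""
    return pd.read_csv(path, sep="\t", index_col="promoter")
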