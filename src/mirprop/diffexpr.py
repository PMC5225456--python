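"""Median normalization and the two-group fold-change filter.

Each array (column) is divided by its own median signal, then rescaled by
the grand mean of the original medians so the matrix keeps its overall
scale; this removes per-array multiplicative effects (labeling/scanning
intensity) before groups are compared.  A miRNA passes the screen when its
chronic-heroin / chronic-saline (CH/CS) mean ratio is at least the up
threshold (default 1.25) or at most the down threshold (default 0.75) —
the thresholds are asymmetric as stated, not reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix

GROUP_CONTROL = "CS"
GROUP_TREATED = "CH"


@dataclass(frozen=True)
class DifferentialRecord:
    mirna_id: str
    mean_cs: float
    mean_ch: float
    fold_change: float  # CH / CS
    direction: str  # "up" | "down" | "none"
    passes: bool


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each column by its median, rescale to the grand mean of the
    original medians.  Idempotent up to floating-point tolerance."""
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    medians = np.median(matrix.signals, axis=0)
    zero = np.flatnonzero(medians == 0)
    if zero.size:
        bad = [matrix.sample_ids[j] for j in zero]
        raise ValueError(f"zero median signal in sample(s) {bad}")
    out = matrix.copy()
    out.signals = matrix.signals / medians * medians.mean()
    out.normalized = True
    return out


def fold_changes(
    matrix: ExpressionMatrix,
    up_threshold: float = 1.25,
    down_threshold: float = 0.75,
    pseudocount: float = 0.0,
    summary: str = "mean",
) -> list[DifferentialRecord]:
    """Per-miRNA CH/CS fold change on normalized signals.

    *summary* is the per-group summary statistic ("mean" or "median").
    Records are sorted by |log fold change| descending, so the strongest
    alterations in either direction come first.
    """
    if not matrix.normalized:
        raise ValueError("median-normalize the matrix before fold changes")
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary {summary!r}")
    stat = np.mean if summary == "mean" else np.median
    cs_cols = matrix.columns_for(GROUP_CONTROL)
    ch_cols = matrix.columns_for(GROUP_TREATED)
    if not cs_cols or not ch_cols:
        raise ValueError("both CS and CH groups must be present")
    records = []
    for i, mirna in enumerate(matrix.mirna_ids):
        mean_cs = float(stat(matrix.signals[i, cs_cols]))
        mean_ch = float(stat(matrix.signals[i, ch_cols]))
        if mean_cs + pseudocount == 0:
            raise ValueError(f"zero CS signal (and pseudocount) for {mirna}")
        fc = (mean_ch + pseudocount) / (mean_cs + pseudocount)
        # inclusive thresholds, tolerant to rounding introduced by the
        # normalization arithmetic (a signal exactly at 1.25× must pass)
        if fc >= up_threshold * (1.0 - 1e-9):
            direction, passes = "up", True
        elif fc <= down_threshold * (1.0 + 1e-9):
            direction, passes = "down", True
        else:
            direction, passes = "none", False
        records.append(
            DifferentialRecord(mirna, mean_cs, mean_ch, fc, direction, passes)
        )
    # fold change 0 (all-zero treated signal) sorts as an infinite alteration
    records.sort(
        key=lambda r: (
            -abs(np.log(r.fold_change)) if r.fold_change > 0 else -np.inf,
            r.mirna_id,
        )
    )
    return records


def de_mirna_set(records: list[DifferentialRecord]) -> set[str]:
    """IDs of the miRNAs passing the fold-change filter."""
    return {r.mirna_id for r in records if r.passes}
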