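"""All-pairs group comparison matrices for external single-gene records.

Mirrors the published presentation for external neutrophil datasets: a
square table with mean fold differences in the upper triangle and
unadjusted t-test p-values in the lower triangle. The denominator
convention is fixed by group order: the group *earlier* in the order
(lower group number) is always the denominator, so ``fold[a][b] =
mean(group b) / mean(group a)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ComparisonMatrix, ExpressionMatrix, GroupDesign, Scale
from .stats import two_sample_t

__all__ = ["pairwise_comparison_matrix", "render_table3", "comparison_table_frame"]


def pairwise_comparison_matrix(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    ttest_flavor: str = "pooled",
) -> ComparisonMatrix:
    """Fold-difference / p-value matrix for a single-gene record.

    The record must carry exactly one gene. Declared-log2 input is
    exponentiated to the linear scale first; folds are ratios of arithmetic
    group means on the linear scale. Groups with fewer than two samples
    keep their folds but get NaN p-values (flagged undefined).
    """
    if len(matrix.gene_ids) != 1:
        raise ValueError(f"expected a single-gene record, got {len(matrix.gene_ids)} genes")
    if matrix.scale in (Scale.CT, Scale.MFI):
        raise ValueError("comparison matrices operate on linear or log2 expression records")
    linear = matrix.to_linear()
    design = design.subset(linear.sample_ids)
    groups = design.groups
    order = [g for g in design.group_order if g in groups]
    if len(order) < 2:
        raise ValueError("need at least two groups with samples")

    row = linear.data.iloc[0]
    values = {g: row[[s for s in members if s in row.index]].dropna().to_numpy()
              for g, members in groups.items()}
    n_per_group = {g: int(v.size) for g, v in values.items()}

    fold = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
    pvals = pd.DataFrame(np.full((len(order), len(order)), np.nan), index=order, columns=order)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i == j:
                continue
            fold.loc[a, b] = values[b].mean() / values[a].mean()
            if n_per_group[a] >= 2 and n_per_group[b] >= 2:
                pvals.loc[a, b] = two_sample_t(values[a], values[b], flavor=ttest_flavor).p_value
    return ComparisonMatrix(order, n_per_group, fold, pvals)


def _format_p(p: float) -> str:
    if np.isnan(p):
        return "NA"
    if p < 1e-3:
        return "<10^-3"
    return f"{p:.2f}"


def comparison_table_frame(cm: ComparisonMatrix) -> pd.DataFrame:
    """Rendered table as a DataFrame: folds above, p-values below diagonal."""
    k = len(cm.group_order)
    cells = [["" for _ in range(k)] for _ in range(k)]
    for i, a in enumerate(cm.group_order):
        for j, b in enumerate(cm.group_order):
            if i < j:
                cells[i][j] = f"{cm.fold.loc[a, b]:.2f}"
            elif i > j:
                cells[i][j] = _format_p(float(cm.pvals.loc[a, b]))
    labels = [
        f"{i + 1} {g} ({cm.n_per_group[g]})" for i, g in enumerate(cm.group_order)
    ]
    frame = pd.DataFrame(cells, columns=[str(i + 1) for i in range(k)])
    frame.insert(0, "comparison_group", labels)
    return frame


def render_table3(cm: ComparisonMatrix) -> str:
    """Fixed-width text rendering of the comparison matrix.

    Upper triangle: mean fold differences (2 decimals). Lower triangle:
    unadjusted t-test p-values (2 decimals, ``<10^-3`` below 0.001).
    """
    frame = comparison_table_frame(cm)
    widths = [max(len(str(v)) for v in [c, *frame[c]]) for c in frame.columns]
    lines = []
    header = "  ".join(str(c).ljust(w) for c, w in zip(frame.columns, widths))
    lines.append(header)
    lines.append("-" * len(header))
    for _, row in frame.iterrows():
        lines.append("  ".join(str(v).ljust(w) for v, w in zip(row, widths)))
    return "\n".join(lines) + "\n"
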