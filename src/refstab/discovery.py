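"""Two-step probabilistic selection of candidate reference genes.

The pipeline consumes a three-group matrix of normalized log2 intensities
and composes four filters in a fixed order:

1. **Nondiscrimination** — a gene is discarded as *discriminatory* when any
   of its three pairwise group comparisons is significant after FDR
   correction (BH, alpha = 0.05 by default).
2. **Low variability** — among nondiscriminatory genes, keep the
   ``n_lowvar`` genes with the lowest global standard deviation (sample sd
   over all samples of all groups pooled).
3. **Intensity window** — every group mean must lie inside a closed window
   of mean log2 intensity (default [4, 11]), excluding floor-compressed and
   saturating genes.
4. **Stability walk** — walking the surviving shortlist in ascending-sd
   order, collect genes whose three *unadjusted* pairwise t-test p-values
   all exceed ``stability_p`` (default 0.5), until ``k_candidates`` genes
   are found.

Genes whose p-values sit just below the stability threshold (default band
[0.45, 0.5)) while the rest clear it are flagged *borderline* and surfaced
in the report for manual adjudication; they are never auto-selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .core import DiscoveryConfig, ExpressionMatrix, GeneStats, GroupDesign
from .stats import TINY_P, bh_adjust, pairwise_t_pvalues

__all__ = [
    "CandidateReport",
    "nondiscriminatory_filter",
    "variability_rank",
    "intensity_window_filter",
    "stability_select",
    "run_discovery",
]

logger = logging.getLogger("refstab")


@dataclass
class CandidateReport:
    """Outcome of the discovery pipeline.

    ``table`` carries one row per gene that entered filter 1, with pooled
    sd, per-group means, raw and adjusted pairwise p-values and flags; it
    is the tabular analogue of the published selection figure.
    """

    table: pd.DataFrame
    shortlist: list[str]
    candidates: list[str]
    borderline: list[str]
    counts: dict[str, int]
    config: DiscoveryConfig
    excluded_genes: list[str] = field(default_factory=list)

    def gene_stats(self, gene_id: str) -> GeneStats:
        row = self.table.loc[gene_id]
        pairings = _pairings_from_columns(self.table.columns)
        return GeneStats(
            gene_id=gene_id,
            pooled_sd=float(row["sd"]),
            group_means={
                c[len("mean_"):]: float(row[c]) for c in self.table.columns if c.startswith("mean_")
            },
            pairwise_p_raw={p: float(row[f"p_{p[0]}_vs_{p[1]}"]) for p in pairings},
            pairwise_p_adj={p: float(row[f"padj_{p[0]}_vs_{p[1]}"]) for p in pairings},
            flags={f for f in str(row["flags"]).split(",") if f},
        )


def _pairings_from_columns(columns) -> list[tuple[str, str]]:
    out = []
    for c in columns:
        if c.startswith("p_") and "_vs_" in c:
            a, _, b = c[2:].partition("_vs_")
            out.append((a, b))
    return out


def _group_columns(matrix: ExpressionMatrix, design: GroupDesign) -> tuple[list[str], list[np.ndarray]]:
    col_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    order = [g for g in design.group_order if g in design.groups]
    cols = []
    for g in order:
        members = [s for s in design.groups[g] if s in col_index]
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples present in the matrix")
        cols.append(np.array([col_index[s] for s in members]))
    return order, cols


def nondiscriminatory_filter(
    matrix: ExpressionMatrix, design: GroupDesign, config: DiscoveryConfig | None = None
) -> pd.DataFrame:
    """Per-gene statistics with the discriminatory flag (filter 1).

    Requires exactly three groups with >= 2 samples each and complete rows
    (genes with missing values are excluded beforehand). Returns a
    DataFrame indexed by gene with columns ``sd``, ``mean_<group>``,
    ``p_<a>_vs_<b>`` (raw), ``padj_<a>_vs_<b>`` and ``discriminatory``.

    With ``fdr_scope='per_pairing'`` BH runs across genes separately within
    each pairing and a gene is discriminatory when any adjusted pairwise p
    is <= alpha. With ``fdr_scope='omnibus'`` the one-way ANOVA F-test p is
    BH-adjusted across genes instead (column ``panova_adj``); the pairwise
    adjusted columns are still reported.
    """
    config = config or DiscoveryConfig()
    matrix = matrix.complete_rows()
    order, cols = _group_columns(matrix, design)
    if len(order) != 3:
        raise ValueError(f"discovery requires exactly three groups, got {len(order)}: {order}")

    values = matrix.values
    df = pd.DataFrame(index=pd.Index(matrix.gene_ids, name="gene"))
    df["sd"] = values.std(axis=1, ddof=1)
    for g, c in zip(order, cols):
        df[f"mean_{g}"] = values[:, c].mean(axis=1)

    pairings = [(order[i], order[j]) for i in range(3) for j in range(i + 1, 3)]
    p_raw = pairwise_t_pvalues(values, cols, flavor=config.ttest_flavor)
    p_adj = np.column_stack([bh_adjust(p_raw[:, k]) for k in range(p_raw.shape[1])])
    for k, (a, b) in enumerate(pairings):
        df[f"p_{a}_vs_{b}"] = p_raw[:, k]
        df[f"padj_{a}_vs_{b}"] = p_adj[:, k]

    if config.fdr_scope == "per_pairing":
        df["discriminatory"] = (p_adj <= config.alpha).any(axis=1)
    else:
        f_stat, p_anova = _sps.f_oneway(*(values[:, c].T for c in cols))
        p_anova = np.clip(np.nan_to_num(p_anova, nan=1.0), TINY_P, 1.0)
        df["panova"] = p_anova
        df["panova_adj"] = bh_adjust(p_anova)
        df["discriminatory"] = df["panova_adj"] <= config.alpha
    return df


def variability_rank(stats_table: pd.DataFrame, eligible_genes=None) -> pd.DataFrame:
    """Order genes by ascending pooled sd (filter 2 ordering).

    Ties are broken lexicographically by gene id for reproducibility.
    """
    table = stats_table if eligible_genes is None else stats_table.loc[list(eligible_genes)]
    if table.empty:
        raise ValueError("no eligible genes to rank")
    # lexicographic index sort first, then a stable sd sort => sd ties break by gene id
    return table.sort_index(kind="stable").sort_values("sd", kind="stable")


def intensity_window_filter(stats_table: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    """Keep genes whose every group mean lies in the closed window (filter 3)."""
    lo, hi = window
    mean_cols = [c for c in stats_table.columns if c.startswith("mean_")]
    in_window = np.ones(len(stats_table), dtype=bool)
    for c in mean_cols:
        in_window &= (stats_table[c] >= lo) & (stats_table[c] <= hi)
    return stats_table.loc[in_window]


def stability_select(shortlist: pd.DataFrame, config: DiscoveryConfig) -> tuple[list[str], list[str]]:
    """Walk the sd-ascending shortlist collecting stable genes (filter 4).

    Returns (candidates, borderline). A candidate has all pairwise raw p >
    ``stability_p``; the walk stops after ``k_candidates``. A borderline
    gene has every p at or above the borderline band floor and at least one
    inside the band — flagged across the whole shortlist, not selected.
    """
    p_cols = [c for c in shortlist.columns if c.startswith("p_") and "_vs_" in c]
    if shortlist.empty:
        logger.warning("stability_select: empty shortlist, no candidates")
        return [], []
    pmat = shortlist[p_cols].to_numpy()
    stable = (pmat > config.stability_p).all(axis=1)
    band_lo, band_hi = config.borderline_band
    borderline = (
        (pmat >= band_lo).all(axis=1)
        & ((pmat >= band_lo) & (pmat < band_hi)).any(axis=1)
        & ~stable
    )
    candidates: list[str] = []
    for gene, ok in zip(shortlist.index, stable):
        if ok:
            candidates.append(gene)
            if len(candidates) >= config.k_candidates:
                break
    if len(candidates) < config.k_candidates:
        logger.warning(
            "stability_select: only %d of %d requested candidates found",
            len(candidates), config.k_candidates,
        )
    return candidates, list(shortlist.index[borderline])


def run_discovery(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    config: DiscoveryConfig | None = None,
    exclude_genes=(),
) -> CandidateReport:
    """Compose filters 1-4 and assemble the report.

    ``exclude_genes`` is an optional user-supplied list removed before the
    stability walk (e.g. genes without described function); the exclusion
    is recorded in the report rather than automated.
    """
    config = config or DiscoveryConfig()
    design.require_group_sizes(2)
    n_missing = int(matrix.missing_mask.sum())
    stats_table = nondiscriminatory_filter(matrix, design, config)
    stats_table = stats_table.reset_index().set_index("gene", drop=False)

    nondisc = stats_table.loc[~stats_table["discriminatory"]]
    ranked = variability_rank(nondisc)
    lowvar = ranked.iloc[: config.n_lowvar]
    windowed = intensity_window_filter(lowvar, config.intensity_window)

    excluded = [g for g in exclude_genes if g in windowed.index]
    shortlist = windowed.drop(index=excluded)
    candidates, borderline = stability_select(shortlist, config)

    flags = pd.Series("", index=stats_table.index, dtype=object)
    flags[stats_table["discriminatory"]] += "discriminatory,"
    flags[flags.index.isin(lowvar.index)] += "low_variability,"
    flags[flags.index.isin(windowed.index)] += "in_window,"
    flags[flags.index.isin(candidates)] += "stable,"
    flags[flags.index.isin(borderline)] += "borderline,"
    table = stats_table.drop(columns=["gene"]).copy()
    table["flags"] = flags.str.rstrip(",")
    # report rows in the walk order: ascending sd within the shortlist first
    table = table.reindex(list(shortlist.index) + [g for g in table.index if g not in set(shortlist.index)])

    counts = {
        "input_genes": len(matrix.gene_ids),
        "missing_excluded": n_missing,
        "tested": len(stats_table),
        "nondiscriminatory": len(nondisc),
        "low_variability": len(lowvar),
        "in_window": len(windowed),
        "user_excluded": len(excluded),
        "shortlist": len(shortlist),
        "candidates": len(candidates),
        "borderline": len(borderline),
    }
    return CandidateReport(
        table=table,
        shortlist=list(shortlist.index),
        candidates=candidates,
        borderline=borderline,
        counts=counts,
        config=config,
        excluded_genes=excluded,
    )
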