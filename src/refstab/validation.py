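"""Validation-stage analyses on targeted assays (RT-PCR Ct, branched-DNA MFI).

Technical replicates are always averaged per sample first; all group
statistics run on biological units (patients or donors). Fold-difference
semantics depend on scale:

* MFI is proportional to transcript quantity: fold = arithmetic group-mean
  ratio.
* Ct is inversely proportional to log2 transcript quantity: a difference of
  d cycles corresponds to a 2**d fold difference at amplification
  efficiency 2, so fold(num vs den) = 2**(mean Ct_den - mean Ct_num).

A candidate passes validation ("stable") when it is detectable, its group
fold difference lies inside a configured stability band and the rank-sum
test is non-significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Scale, TargetedAssayTable
from .stats import TestResult, wilcoxon_rank_sum, wilcoxon_signed_rank

__all__ = [
    "ValidationResult",
    "detectability_filter",
    "group_fold_difference",
    "paired_stimulation_analysis",
    "confirm_candidates",
]

logger = logging.getLogger("refstab")

#: default verdict band: folds in [2/3, 1.5] count as "highly similar"
DEFAULT_STABILITY_BAND = (2 / 3, 1.5)


@dataclass
class ValidationResult:
    gene_id: str
    group_summary: pd.DataFrame  # per group: mean, sd, n on the assay scale
    fold_difference: float | None
    fold_direction: tuple[str, str] | None  # (numerator group, denominator group)
    test: TestResult | None
    detectability: dict[str, float] = field(default_factory=dict)
    verdict: str = "stable"  # stable | unstable | undetectable | missing

    def __post_init__(self) -> None:
        if self.fold_difference is not None and not self.fold_difference > 0:
            raise ValueError("fold_difference must be positive")


def _per_sample_means(table: TargetedAssayTable) -> pd.DataFrame:
    return table.sample_means()


def detectability_filter(
    table: TargetedAssayTable,
    max_below_frac: float = 0.5,
    scope: str = "overall",
) -> pd.DataFrame:
    """Per-gene keep/drop decision from the limit of detection.

    A sample counts as *below* when its replicate-mean signal is at or
    under the LOD. A gene is dropped when the below fraction reaches
    ``max_below_frac`` (inclusive threshold: a gene detectable in only half
    the samples is dropped at the default 0.5). ``scope='per_group'`` drops
    a gene when any single group fails the rule.

    Returns a DataFrame indexed by gene with columns ``frac_below``,
    ``keep`` and one ``frac_below_<group>`` column per group.
    """
    if table.lod is None:
        raise ValueError(
            "detectability_filter needs a limit of detection: pass lod= when "
            "building the assay table, or skip this filter"
        )
    if scope not in ("overall", "per_group"):
        raise ValueError("scope must be 'overall' or 'per_group'")
    means = _per_sample_means(table)
    groups = table.design.groups
    out = pd.DataFrame(index=means.index)
    below = pd.DataFrame(index=means.index, columns=means.columns, dtype=float)
    for gene in means.index:
        lod = table.lod_for(gene)
        if lod is None:
            raise ValueError(f"no LOD available for gene {gene!r}")
        below.loc[gene] = (means.loc[gene] <= lod).astype(float)
    present = means.notna()
    out["frac_below"] = below[present].sum(axis=1) / present.sum(axis=1)
    for g, members in groups.items():
        cols = [s for s in members if s in means.columns]
        out[f"frac_below_{g}"] = below[present][cols].sum(axis=1) / present[cols].sum(axis=1)
    if scope == "overall":
        out["keep"] = out["frac_below"] < max_below_frac
    else:
        group_cols = [f"frac_below_{g}" for g in groups]
        out["keep"] = (out[group_cols] < max_below_frac).all(axis=1)
    return out


def group_fold_difference(
    table: TargetedAssayTable,
    gene: str,
    group_num: str,
    group_den: str,
    mfi_mean: str = "arithmetic",
) -> tuple[float, TestResult]:
    """Mean fold difference of ``group_num`` relative to ``group_den``.

    Replicates are averaged per sample; the rank-sum test runs on the
    per-sample values. Both groups need >= 2 samples with data.

    On the MFI scale the default fold is the ratio of arithmetic group
    means; ``mfi_mean='geometric'`` uses geometric means instead, which is
    the exact linear-scale counterpart of the Ct-scale fold (a Ct table
    converted to relative quantities 2**-Ct gives identical folds then).
    """
    means = _per_sample_means(table)
    if gene not in means.index:
        raise KeyError(f"gene {gene!r} not in assay table")
    groups = table.design.groups
    row = means.loc[gene]
    vals = {}
    for g in (group_num, group_den):
        if g not in groups:
            raise KeyError(f"group {g!r} not in design")
        v = row[[s for s in groups[g] if s in row.index]].dropna().to_numpy()
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples with data for {gene!r}")
        vals[g] = v

    if table.scale is Scale.CT:
        fold = float(2.0 ** (vals[group_den].mean() - vals[group_num].mean()))
    elif mfi_mean == "geometric":
        if np.any(vals[group_num] <= 0) or np.any(vals[group_den] <= 0):
            raise ValueError(f"geometric MFI fold needs positive signals for {gene!r}")
        fold = float(
            2.0 ** (np.log2(vals[group_num]).mean() - np.log2(vals[group_den]).mean())
        )
    elif mfi_mean == "arithmetic":
        den = vals[group_den].mean()
        if den == 0:
            raise ZeroDivisionError(
                f"zero denominator group mean for {gene!r} ({group_den!r}); degenerate MFI fold"
            )
        fold = float(vals[group_num].mean() / den)
    else:
        raise ValueError("mfi_mean must be 'arithmetic' or 'geometric'")
    test = wilcoxon_rank_sum(vals[group_num], vals[group_den])
    return fold, test


def _group_summary(table: TargetedAssayTable, gene: str) -> pd.DataFrame:
    means = _per_sample_means(table)
    rows = []
    for g, members in table.design.groups.items():
        v = means.loc[gene, [s for s in members if s in means.columns]].dropna()
        rows.append({"group": g, "mean": v.mean(), "sd": v.std(ddof=1), "n": int(v.size)})
    return pd.DataFrame(rows).set_index("group")


def paired_stimulation_analysis(
    table_before: TargetedAssayTable,
    table_after: TargetedAssayTable,
    stability_band: tuple[float, float] = DEFAULT_STABILITY_BAND,
    alpha: float = 0.05,
) -> list[ValidationResult]:
    """Per-gene paired before/after comparison across donors.

    Both tables must cover the same genes and the same donors (sample ids).
    On the Ct scale the per-gene mean fold change is 2**(mean over donors of
    (Ct_before - Ct_after)); on the MFI scale the geometric mean of the
    per-donor after/before ratios. The signed-rank test runs on the paired
    per-donor replicate means. Verdict: stable iff the fold lies inside
    ``stability_band`` and p >= ``alpha``.
    """
    genes_b, genes_a = set(table_before.gene_ids), set(table_after.gene_ids)
    if genes_b != genes_a:
        raise ValueError(f"gene sets differ between arms: {sorted(genes_b ^ genes_a)[:5]}")
    donors_b, donors_a = set(table_before.sample_ids), set(table_after.sample_ids)
    if donors_b != donors_a:
        raise ValueError(f"donor sets differ between arms: {sorted(donors_b ^ donors_a)[:5]}")
    if table_before.scale is not table_after.scale:
        raise ValueError("arms measured on different scales")
    donors = table_before.sample_ids
    mb = _per_sample_means(table_before)[donors]
    ma = _per_sample_means(table_after)[donors]

    results = []
    for gene in table_before.gene_ids:
        before, after = mb.loc[gene].to_numpy(), ma.loc[gene].to_numpy()
        if table_before.scale is Scale.CT:
            fold = float(2.0 ** np.mean(before - after))
        else:
            fold = float(2.0 ** np.mean(np.log2(after / before)))
        test = wilcoxon_signed_rank(before, after)
        stable = stability_band[0] <= fold <= stability_band[1] and test.p_value >= alpha
        summary = pd.DataFrame(
            {
                "mean": [before.mean(), after.mean()],
                "sd": [before.std(ddof=1), after.std(ddof=1)],
                "n": [len(before), len(after)],
            },
            index=["before", "after"],
        )
        results.append(
            ValidationResult(
                gene_id=gene,
                group_summary=summary,
                fold_difference=fold,
                fold_direction=("after", "before"),
                test=test,
                verdict="stable" if stable else "unstable",
            )
        )
    return results


def confirm_candidates(
    table: TargetedAssayTable,
    candidates,
    stability_band: tuple[float, float] = DEFAULT_STABILITY_BAND,
    alpha: float = 0.05,
    max_below_frac: float = 0.5,
    detectability_scope: str = "overall",
) -> list[ValidationResult]:
    """Validate discovery candidates on a two-group targeted assay.

    For each candidate, in list order: detectability (when an LOD is
    available), fold difference of the later group relative to the earlier
    group in the design order, rank-sum p, and a verdict — ``stable`` iff
    detectable, p >= alpha and fold inside the band. Candidates absent from
    the table get verdict ``missing``.
    """
    groups = [g for g in table.design.group_order if g in table.design.groups]
    if len(groups) != 2:
        raise ValueError(f"confirm_candidates expects two groups, got {groups}")
    group_den, group_num = groups  # earlier group is the denominator

    detect = None
    if table.lod is not None:
        detect = detectability_filter(table, max_below_frac, detectability_scope)

    results = []
    for gene in candidates:
        if gene not in set(table.gene_ids):
            logger.warning("confirm_candidates: %r missing from assay table", gene)
            results.append(
                ValidationResult(gene, pd.DataFrame(), None, None, None, verdict="missing")
            )
            continue
        detectability = {}
        if detect is not None:
            detectability = {
                g: 1 - float(detect.loc[gene, f"frac_below_{g}"]) for g in groups
            }
            if not bool(detect.loc[gene, "keep"]):
                results.append(
                    ValidationResult(
                        gene, _group_summary(table, gene), None, None, None,
                        detectability=detectability, verdict="undetectable",
                    )
                )
                continue
        fold, test = group_fold_difference(table, gene, group_num, group_den)
        stable = stability_band[0] <= fold <= stability_band[1] and test.p_value >= alpha
        results.append(
            ValidationResult(
                gene_id=gene,
                group_summary=_group_summary(table, gene),
                fold_difference=fold,
                fold_direction=(group_num, group_den),
                test=test,
                detectability=detectability,
                verdict="stable" if stable else "unstable",
            )
        )
    return results


def validation_frame(results: list[ValidationResult]) -> pd.DataFrame:
    """Tabular view of validation verdicts (one row per gene)."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene_id,
                "fold": r.fold_difference,
                "numerator": r.fold_direction[0] if r.fold_direction else None,
                "denominator": r.fold_direction[1] if r.fold_direction else None,
                "p_value": r.test.p_value if r.test else None,
                "test": r.test.method if r.test else None,
                "verdict": r.verdict,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
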