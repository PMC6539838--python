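"""Core domain types for grouped expression and targeted-assay data.

The pipeline moves three kinds of measurements through a common set of
containers:

* normalized log2 microarray intensities (discovery),
* RT-PCR threshold cycles (Ct; inversely proportional to log2 transcript
  quantity),
* branched-DNA assay median fluorescence intensities (MFI; proportional to
  transcript quantity per fixed number of lysed cells).

Scale is always declared explicitly, never inferred, because fold-change
semantics differ between scales.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "GroupDesign",
    "DiscoveryConfig",
    "GeneStats",
    "TargetedAssayTable",
    "ComparisonMatrix",
]


class Scale(str, enum.Enum):
    """Measurement scale of an expression container."""

    LOG2_INTENSITY = "log2_intensity"
    LINEAR = "linear"
    CT = "ct"
    MFI = "mfi"


def _as_scale(scale: "Scale | str") -> Scale:
    return scale if isinstance(scale, Scale) else Scale(str(scale))


class ExpressionMatrix:
    """Dense gene x sample matrix with a declared measurement scale.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with sample identifiers as
        columns. Missing values are allowed and carried as NaN; discovery
        excludes incomplete rows.
    scale
        One of :class:`Scale`. For ``ct`` and ``mfi`` all non-missing
        values must be non-negative.
    """

    def __init__(self, data: pd.DataFrame, scale: Scale | str = Scale.LOG2_INTENSITY):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genes x samples)")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        scale = _as_scale(scale)
        values = data.to_numpy(dtype=float)
        if scale in (Scale.CT, Scale.MFI):
            if np.nanmin(values, initial=np.inf) < 0:
                raise ValueError(f"negative values are invalid on scale {scale.value!r}")
        self.data = data.astype(float)
        self.scale = scale

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> pd.Series:
        """Per-gene flag: True when the row contains any missing value."""
        return self.data.isna().any(axis=1)

    def complete_rows(self) -> "ExpressionMatrix":
        """Matrix restricted to genes with no missing values."""
        return ExpressionMatrix(self.data.loc[~self.missing_mask], self.scale)

    def to_linear(self) -> "ExpressionMatrix":
        """Convert declared-log2 intensities to the linear scale.

        Linear-scale input is returned unchanged; Ct/MFI inputs are refused
        because their fold-change semantics are handled by the validation
        layer, not by naive exponentiation.
        """
        if self.scale is Scale.LINEAR:
            return self
        if self.scale is Scale.LOG2_INTENSITY:
            return ExpressionMatrix(np.exp2(self.data), Scale.LINEAR)
        raise ValueError(f"cannot convert scale {self.scale.value!r} to linear")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({len(self.gene_ids)} genes x "
            f"{len(self.sample_ids)} samples, scale={self.scale.value})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.scale == other.scale and self.data.equals(other.data)


@dataclass
class GroupDesign:
    """Sample-to-group assignment with an explicit group ordering.

    ``group_order`` fixes the canonical ordering used for pairwise
    comparisons and for fold-difference denominators (groups earlier in the
    order are denominators).
    """

    assignment: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty group assignment")
        seen: list[str] = []
        for g in self.assignment.values():
            if g not in seen:
                seen.append(g)
        if not self.group_order:
            self.group_order = seen
        else:
            missing = [g for g in seen if g not in self.group_order]
            if missing:
                raise ValueError(f"assigned groups not in group_order: {missing}")

    @property
    def groups(self) -> dict[str, list[str]]:
        """Ordered map group -> member sample ids (file order within group)."""
        out: dict[str, list[str]] = {g: [] for g in self.group_order}
        for s, g in self.assignment.items():
            out[g].append(s)
        return {g: m for g, m in out.items() if m}

    @property
    def n_per_group(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.groups.items()}

    def require_group_sizes(self, minimum: int = 2) -> None:
        small = {g: n for g, n in self.n_per_group.items() if n < minimum}
        if small:
            raise ValueError(
                f"each group needs >= {minimum} samples for testing; too small: {small}"
            )

    def subset(self, sample_ids: Sequence[str]) -> "GroupDesign":
        keep = {s: self.assignment[s] for s in sample_ids if s in self.assignment}
        if not keep:
            raise ValueError("no overlap between samples and group assignment")
        order = [g for g in self.group_order if g in set(keep.values())]
        return GroupDesign(keep, order)

    def pairings(self) -> list[tuple[str, str]]:
        """All group pairings in canonical order (earlier group first)."""
        order = [g for g in self.group_order if g in self.groups]
        return [(a, b) for i, a in enumerate(order) for b in order[i + 1 :]]


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds of the two-step candidate reference-gene selection.

    Defaults encode the published pipeline: FDR-corrected nondiscrimination
    at ``alpha`` = 0.05, retention of the ``n_lowvar`` = 5000 genes with the
    lowest global standard deviation, a closed mean-intensity window of
    [4, 11] log2 units, and a stability criterion of all three unadjusted
    pairwise t-test p-values > 0.5, walked in ascending-variability order
    until ``k_candidates`` = 5 genes are found.
    """

    alpha: float = 0.05
    n_lowvar: int = 5000
    intensity_window: tuple[float, float] = (4.0, 11.0)
    stability_p: float = 0.5
    k_candidates: int = 5
    borderline_band: tuple[float, float] = (0.45, 0.5)
    ttest_flavor: str = "pooled"  # or "welch"
    fdr_scope: str = "per_pairing"  # or "omnibus"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.stability_p < 1:
            raise ValueError("stability_p must lie in (0, 1)")
        if not self.n_lowvar >= self.k_candidates >= 1:
            raise ValueError("need n_lowvar >= k_candidates >= 1")
        lo, hi = self.intensity_window
        if not lo < hi:
            raise ValueError("intensity_window lower bound must be below upper bound")
        if self.ttest_flavor not in ("pooled", "welch"):
            raise ValueError("ttest_flavor must be 'pooled' or 'welch'")
        if self.fdr_scope not in ("per_pairing", "omnibus"):
            raise ValueError("fdr_scope must be 'per_pairing' or 'omnibus'")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_lowvar": self.n_lowvar,
            "intensity_window": list(self.intensity_window),
            "stability_p": self.stability_p,
            "k_candidates": self.k_candidates,
            "borderline_band": list(self.borderline_band),
            "ttest_flavor": self.ttest_flavor,
            "fdr_scope": self.fdr_scope,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DiscoveryConfig":
        kwargs = dict(d)
        for key in ("intensity_window", "borderline_band"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def updated(self, **kwargs) -> "DiscoveryConfig":
        return replace(self, **kwargs)


@dataclass
class GeneStats:
    """Per-gene discovery statistics.

    ``pooled_sd`` is the sample standard deviation (n-1 denominator) over
    all samples of all groups together — the global-variability estimator.
    """

    gene_id: str
    pooled_sd: float
    group_means: dict[str, float]
    pairwise_p_raw: dict[tuple[str, str], float]
    pairwise_p_adj: dict[tuple[str, str], float]
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pooled_sd < 0:
            raise ValueError("pooled_sd must be non-negative")
        for pairing, p_adj in self.pairwise_p_adj.items():
            p_raw = self.pairwise_p_raw[pairing]
            if not (0 < p_raw <= 1 and 0 < p_adj <= 1):
                raise ValueError(f"p-values out of (0, 1] for pairing {pairing}")
            if p_adj < p_raw - 1e-12:
                raise ValueError("adjusted p below raw p")


class TargetedAssayTable:
    """Replicate measurements per (gene, sample) on the Ct or MFI scale.

    Stored in long format: one row per technical replicate with columns
    ``gene``, ``sample``, ``replicate``, ``value``. ``lod`` may be a global
    number or a per-gene mapping on the measurement scale.
    """

    _COLUMNS = ("gene", "sample", "replicate", "value")

    def __init__(
        self,
        records: pd.DataFrame,
        scale: Scale | str,
        design: GroupDesign,
        lod: float | Mapping[str, float] | None = None,
    ):
        scale = _as_scale(scale)
        if scale not in (Scale.CT, Scale.MFI):
            raise ValueError("assay scale must be 'ct' or 'mfi'")
        missing = [c for c in self._COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"assay table missing columns: {missing}")
        records = records.loc[:, list(self._COLUMNS)].copy()
        records["value"] = records["value"].astype(float)
        vals = records["value"].to_numpy()
        if scale is Scale.CT:
            if np.any((vals <= 0) | (vals > 45)):
                raise ValueError("Ct replicates must lie in (0, 45]")
        else:
            if np.any(vals < 0):
                raise ValueError("MFI replicates must be non-negative")
        counts = records.groupby(["gene", "sample"]).size()
        if (counts < 1).any():  # pragma: no cover - groupby cannot produce 0
            raise ValueError("each (gene, sample) cell needs >= 1 replicate")
        unknown = set(records["sample"]) - set(design.assignment)
        if unknown:
            raise ValueError(f"samples not in design: {sorted(unknown)[:5]}")
        self.records = records
        self.scale = scale
        self.design = design
        self.lod = lod

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["gene"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample"]))

    def lod_for(self, gene: str) -> float | None:
        if self.lod is None:
            return None
        if isinstance(self.lod, Mapping):
            return self.lod.get(gene)
        return float(self.lod)

    def sample_means(self) -> pd.DataFrame:
        """Technical replicates averaged per (gene, sample) cell.

        Returns a gene x sample DataFrame of per-sample means — the
        biological units on which all group statistics run.
        """
        wide = self.records.groupby(["gene", "sample"])["value"].mean().unstack()
        return wide.reindex(index=self.gene_ids, columns=self.sample_ids)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TargetedAssayTable({len(self.gene_ids)} genes x "
            f"{len(self.sample_ids)} samples, scale={self.scale.value})"
        )


@dataclass
class ComparisonMatrix:
    """All-pairs group comparison: mean fold differences and t-test p-values.

    ``fold.loc[a, b]`` is mean(group b) / mean(group a): the group earlier
    in ``group_order`` is always the denominator, so the printed upper
    triangle reads as "column group relative to row group".
    """

    group_order: list[str]
    n_per_group: dict[str, int]
    fold: pd.DataFrame
    pvals: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.fold, self.pvals):
            if list(df.index) != self.group_order or list(df.columns) != self.group_order:
                raise ValueError("fold/pvals must be indexed by group_order on both axes")
        f = self.fold.to_numpy(dtype=float)
        if not np.allclose(np.diag(f), 1.0):
            raise ValueError("fold diagonal must be 1")
        with np.errstate(invalid="ignore"):
            recip = f * f.T
        if not np.allclose(recip[~np.isnan(recip)], 1.0, rtol=1e-9):
            raise ValueError("fold[a][b] * fold[b][a] must equal 1")
        p = self.pvals.to_numpy(dtype=float)
        mask = ~(np.isnan(p) | np.isnan(p.T))
        if not np.allclose(p[mask], p.T[mask]):
            raise ValueError("p-value matrix must be symmetric")
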