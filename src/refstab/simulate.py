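"""Seeded generators emulating the statistical structure of the study data.

Three generators cover the three assay worlds the pipeline consumes:

* :func:`generate_microarray` — three-group log2-normal expression
  matrices with a configurable differentially-expressed (DE) fraction and
  planted invariant genes inside the selection intensity window,
* :func:`generate_targeted_assay` — Ct-scale triplicate or MFI-scale
  duplicate tables with a multiplicative group effect and an LOD floor,
* :func:`generate_paired_stimulation` — paired before/after Ct tables over
  a small donor panel.

Every generator is a pure function of its parameters and a single integer
seed, and returns a :class:`SyntheticTruth` sufficient to score recovery.

Two scenario presets encode the study's two discovery worlds at desk scale
(5000 genes, 20% low-variability retention as in the full-size pipeline):
an NK-cell-like scenario (almost no DE, homogeneous variance) and a
granulocyte-like scenario (massive DE, a large unexpressed floor fraction
with compressed technical variance, and inflated biological variance of
expressed genes — the inter-patient heterogeneity reported for activated
granulocytes). The scenario constants are artifact conventions fixed so
the two worlds reproduce, in kind, the published contrast between a
thousands-strong and a nearly empty post-filter shortlist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DiscoveryConfig, ExpressionMatrix, GroupDesign, Scale, TargetedAssayTable

__all__ = [
    "SyntheticTruth",
    "generate_microarray",
    "generate_targeted_assay",
    "generate_paired_stimulation",
    "nk_like_scenario",
    "granulocyte_like_scenario",
]

DEFAULT_GROUPS = ("presurgical", "SIRS", "sepsis")


@dataclass
class SyntheticTruth:
    """Ground truth for scoring: one row per gene.

    ``class_`` partitions genes into ``invariant_in_window`` (planted),
    ``de``, ``invariant_out_window`` (nulls outside the intensity window)
    and ``high_variance_null`` (in-window nulls whose variability is not
    pinned to the planted reference-gene level). ``fold`` carries planted
    fold effects for targeted-assay genes.
    """

    table: pd.DataFrame

    @property
    def planted_invariants(self) -> list[str]:
        t = self.table
        return list(t.index[t["class_"] == "invariant_in_window"])

    @property
    def de_genes(self) -> list[str]:
        t = self.table
        return list(t.index[t["class_"] == "de"])

    def fold_for(self, gene: str) -> float:
        return float(self.table.loc[gene, "fold"])


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _sample_ids(n_per_group: Sequence[int], groups: Sequence[str]) -> GroupDesign:
    assignment = {}
    for g, n in zip(groups, n_per_group):
        for i in range(n):
            assignment[f"{g}_{i + 1:02d}"] = g
    return GroupDesign(assignment, list(groups))


def generate_microarray(
    n_genes: int = 5000,
    n_per_group: Sequence[int] = (19, 16, 10),
    frac_de: float = 0.005,
    de_effect_sd: float = 0.8,
    de_effect_min: float = 0.3,
    n_invariant: int = 20,
    invariant_sd: float = 0.10,
    intensity_range: tuple[float, float] = (2.0, 14.0),
    noise_sd_median: float = 0.25,
    noise_sd_sigma: float = 0.35,
    window: tuple[float, float] = (4.0, 11.0),
    floor_fraction: float | None = None,
    floor_sd_factor: float = 1.0,
    expressed_var_inflation: float = 1.0,
    group_labels: Sequence[str] = DEFAULT_GROUPS,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroupDesign, SyntheticTruth]:
    """Three-group log2 expression matrix with planted structure.

    Gene baselines are uniform over ``intensity_range``; when
    ``floor_fraction`` is given, that fraction of genes is instead drawn
    below the window floor (unexpressed genes at the detection floor) and
    their technical noise is compressed by ``floor_sd_factor``. DE genes
    are drawn among expressed genes (baseline at or above the window floor)
    and receive independent per-group offsets ~ Normal(0, ``de_effect_sd``)
    resampled to magnitude >= ``de_effect_min`` in the second and third
    group. Per-gene noise sd is log-normal with the given median and log
    sigma, times ``expressed_var_inflation`` for expressed genes; planted
    invariants sit inside the window with equal group means at
    ``invariant_sd``. Noise is Gaussian on the log2 scale.
    """
    if not 0 <= frac_de < 1:
        raise ValueError("frac_de must lie in [0, 1)")
    if n_invariant > n_genes:
        raise ValueError("n_invariant cannot exceed n_genes")
    if len(n_per_group) != len(group_labels):
        raise ValueError("n_per_group and group_labels lengths differ")
    rng = _rng(seed)
    lo, hi = intensity_range
    win_lo, win_hi = window
    n_groups = len(group_labels)

    genes = np.array([f"G{i + 1:05d}" for i in range(n_genes)])
    if floor_fraction is None:
        baseline = rng.uniform(lo, hi, size=n_genes)
    else:
        is_floor = rng.random(n_genes) < floor_fraction
        baseline = np.where(
            is_floor,
            rng.uniform(lo, min(win_lo, hi), size=n_genes),
            rng.uniform(win_lo, hi, size=n_genes),
        )

    # planted invariants: in-window with margin so sampled group means stay inside
    invariant_idx = rng.choice(n_genes, size=n_invariant, replace=False)
    baseline[invariant_idx] = rng.uniform(win_lo + 0.5, win_hi - 0.5, size=n_invariant)

    expressed = baseline >= win_lo
    de_pool = np.setdiff1d(np.flatnonzero(expressed), invariant_idx)
    n_de = min(int(round(frac_de * n_genes)), de_pool.size)
    de_idx = rng.choice(de_pool, size=n_de, replace=False) if n_de else np.array([], dtype=int)

    group_means = np.tile(baseline[:, None], (1, n_groups))
    offsets = rng.normal(0.0, de_effect_sd, size=(n_de, n_groups - 1))
    while True:
        small = np.abs(offsets) < de_effect_min
        if not small.any():
            break
        offsets[small] = rng.normal(0.0, de_effect_sd, size=int(small.sum()))
    if n_de:
        group_means[de_idx, 1:] += offsets

    noise_sd = rng.lognormal(np.log(noise_sd_median), noise_sd_sigma, size=n_genes)
    noise_sd[expressed] *= expressed_var_inflation
    noise_sd[~expressed] *= floor_sd_factor
    noise_sd[invariant_idx] = invariant_sd

    design = _sample_ids(n_per_group, group_labels)
    sample_groups = np.repeat(np.arange(n_groups), list(n_per_group))
    means = group_means[:, sample_groups]
    values = means + rng.normal(size=means.shape) * noise_sd[:, None]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=list(design.assignment)),
        Scale.LOG2_INTENSITY,
    )

    class_ = np.where(expressed, "high_variance_null", "invariant_out_window").astype(object)
    class_[baseline > win_hi] = "invariant_out_window"
    class_[de_idx] = "de"
    class_[invariant_idx] = "invariant_in_window"
    truth = pd.DataFrame(
        {
            "class_": class_,
            "baseline": baseline,
            "sd": noise_sd,
            "fold": np.ones(n_genes),
        },
        index=pd.Index(genes, name="gene"),
    )
    for k, g in enumerate(group_labels):
        truth[f"mean_{g}"] = group_means[:, k]
    return matrix, design, SyntheticTruth(truth)


def generate_targeted_assay(
    genes: Sequence[str],
    n_per_group: Sequence[int] = (22, 18),
    scale: Scale | str = Scale.MFI,
    planted_folds: Mapping[str, float] | None = None,
    noise_sd_log2: float = 0.25,
    lod: float | None = None,
    replicate_count: int | None = None,
    technical_sd_log2: float = 0.10,
    technical_sd_ct: float = 0.15,
    mfi_base_range: tuple[float, float] = (100.0, 2000.0),
    mfi_background: float = 15.0,
    ct_base_range: tuple[float, float] = (20.0, 30.0),
    group_labels: Sequence[str] = ("SIRS", "sepsis"),
    seed: int = 0,
) -> tuple[TargetedAssayTable, SyntheticTruth]:
    """Two-group targeted assay with multiplicative planted group effects.

    A planted fold ``f`` for a gene means the second group carries ``f``
    times the transcript level of the first. MFI: per-sample true levels
    are log-normal around the (fold-scaled) group mean, duplicates get
    multiplicative technical noise and are floored at ``mfi_background`` so
    LOD censoring occurs. Ct: the affected group's true Ct is shifted by
    ``-log2(f)``, triplicates get additive noise of ``technical_sd_ct``
    cycles.
    """
    scale = Scale(scale) if not isinstance(scale, Scale) else scale
    planted_folds = dict(planted_folds or {})
    bad = {g: f for g, f in planted_folds.items() if not f > 0}
    if bad:
        raise ValueError(f"planted folds must be positive: {bad}")
    if replicate_count is None:
        replicate_count = 3 if scale is Scale.CT else 2
    if replicate_count < 1:
        raise ValueError("replicate_count must be >= 1")
    rng = _rng(seed)
    design = _sample_ids(n_per_group, group_labels)
    samples = list(design.assignment)
    sample_group = np.array([group_labels.index(design.assignment[s]) for s in samples])

    rows = []
    truth_rows = []
    for gene in genes:
        fold = float(planted_folds.get(gene, 1.0))
        if scale is Scale.MFI:
            base = float(np.exp2(rng.uniform(*np.log2(mfi_base_range))))
            group_level = np.array([base, base * fold])
            level = group_level[sample_group] * np.exp2(
                rng.normal(0.0, noise_sd_log2, size=len(samples))
            )
            reps = level[:, None] * np.exp2(
                rng.normal(0.0, technical_sd_log2, size=(len(samples), replicate_count))
            )
            reps = np.maximum(reps, mfi_background)
            truth_rows.append({"gene": gene, "class_": "de" if fold != 1 else "null",
                               "fold": fold, "base": base})
        else:
            base = rng.uniform(*ct_base_range)
            group_ct = np.array([base, base - np.log2(fold)])
            ct = group_ct[sample_group] + rng.normal(0.0, noise_sd_log2, size=len(samples))
            reps = ct[:, None] + rng.normal(
                0.0, technical_sd_ct, size=(len(samples), replicate_count)
            )
            reps = np.clip(reps, 1.0, 45.0)
            truth_rows.append({"gene": gene, "class_": "de" if fold != 1 else "null",
                               "fold": fold, "base": base})
        for s_i, s in enumerate(samples):
            for r in range(replicate_count):
                rows.append((gene, s, r + 1, reps[s_i, r]))

    records = pd.DataFrame(rows, columns=["gene", "sample", "replicate", "value"])
    table = TargetedAssayTable(records, scale, design, lod=lod)
    truth = SyntheticTruth(pd.DataFrame(truth_rows).set_index("gene"))
    return table, truth


def generate_paired_stimulation(
    genes: Sequence[str],
    n_donors: int = 6,
    planted_folds: Mapping[str, float] | None = None,
    donor_baseline_sd: float = 0.5,
    donor_response_sd: float = 0.25,
    technical_sd_ct: float = 0.15,
    replicate_count: int = 3,
    ct_base_range: tuple[float, float] = (20.0, 30.0),
    seed: int = 0,
) -> tuple[TargetedAssayTable, TargetedAssayTable, SyntheticTruth]:
    """Paired before/after Ct tables over a healthy-donor panel.

    Donor baselines are shared between arms; the stimulated arm is shifted
    by ``-log2(fold)`` cycles plus per-donor response noise
    (``donor_response_sd`` cycles — the biological donor-to-donor spread of
    the response). Returns (before, after, truth).
    """
    if n_donors < 3:
        raise ValueError("need at least 3 donors for a paired design")
    planted_folds = dict(planted_folds or {})
    rng = _rng(seed)
    donors = [f"donor_{i + 1}" for i in range(n_donors)]
    design = GroupDesign({d: "donors" for d in donors}, ["donors"])

    rows_before, rows_after, truth_rows = [], [], []
    for gene in genes:
        fold = float(planted_folds.get(gene, 1.0))
        if not fold > 0:
            raise ValueError(f"planted fold for {gene!r} must be positive")
        base = rng.uniform(*ct_base_range)
        donor_base = base + rng.normal(0.0, donor_baseline_sd, size=n_donors)
        after_center = donor_base - np.log2(fold) + rng.normal(
            0.0, donor_response_sd, size=n_donors
        )
        before_reps = donor_base[:, None] + rng.normal(
            0.0, technical_sd_ct, size=(n_donors, replicate_count)
        )
        after_reps = after_center[:, None] + rng.normal(
            0.0, technical_sd_ct, size=(n_donors, replicate_count)
        )
        for d_i, d in enumerate(donors):
            for r in range(replicate_count):
                rows_before.append((gene, d, r + 1, np.clip(before_reps[d_i, r], 1.0, 45.0)))
                rows_after.append((gene, d, r + 1, np.clip(after_reps[d_i, r], 1.0, 45.0)))
        truth_rows.append({"gene": gene, "class_": "de" if fold != 1 else "null", "fold": fold})

    cols = ["gene", "sample", "replicate", "value"]
    before = TargetedAssayTable(pd.DataFrame(rows_before, columns=cols), Scale.CT, design)
    after = TargetedAssayTable(pd.DataFrame(rows_after, columns=cols), Scale.CT, design)
    truth = SyntheticTruth(pd.DataFrame(truth_rows).set_index("gene"))
    return before, after, truth


# ---------------------------------------------------------------------------
# scenario presets (desk-scale stand-ins for the two discovery datasets)
# ---------------------------------------------------------------------------

#: desk-scale low-variability retention: 20% of genes, as 5000 of ~25,000
DESK_SCALE_CONFIG = DiscoveryConfig(n_lowvar=1000)


def nk_like_scenario(seed: int = 0, n_genes: int = 5000):
    """NK-cell-like discovery world: ~0.5% DE, homogeneous variance.

    Returns (matrix, design, truth, config) with sample sizes 19/16/10 and
    20 planted invariant genes at sd 0.10.
    """
    matrix, design, truth = generate_microarray(
        n_genes=n_genes,
        n_per_group=(19, 16, 10),
        frac_de=0.005,
        n_invariant=20,
        seed=seed,
    )
    return matrix, design, truth, DESK_SCALE_CONFIG


def granulocyte_like_scenario(seed: int = 0, n_genes: int = 5000):
    """Granulocyte-like discovery world: 28% DE, floor-heavy, heterogeneous.

    Sample sizes 11/16/15. Forty percent of genes sit at the unexpressed
    floor with technical variance compressed to half; biological variance
    of expressed genes is inflated threefold (activated-granulocyte
    inter-patient heterogeneity). Four invariant genes are planted,
    mirroring the four candidates the granulocyte shortlist yielded.
    """
    matrix, design, truth = generate_microarray(
        n_genes=n_genes,
        n_per_group=(11, 16, 15),
        frac_de=0.28,
        n_invariant=4,
        floor_fraction=0.4,
        floor_sd_factor=0.5,
        expressed_var_inflation=3.0,
        seed=seed,
    )
    return matrix, design, truth, DESK_SCALE_CONFIG
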