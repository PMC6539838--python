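import numpy as np
import pandas as pd
import pytest

from refstab import ExpressionMatrix, GroupDesign, Scale, TargetedAssayTable


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 6 samples, two groups of three, log2 scale."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(7.0, 0.3, size=(3, 6)),
        index=["GENE_A", "GENE_B", "GENE_C"],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data, Scale.LOG2_INTENSITY)


@pytest.fixture
def three_group_design() -> GroupDesign:
    assignment = {}
    for g, n in zip(("presurgical", "SIRS", "sepsis"), (4, 4, 4)):
        for i in range(n):
            assignment[f"{g}_{i}"] = g
    return GroupDesign(assignment, ["presurgical", "SIRS", "sepsis"])


def make_assay(values_by_group: dict[str, list[float]], gene: str = "G1",
               scale=Scale.MFI, lod=None, replicates: int = 2) -> TargetedAssayTable:
    """Assay table with identical replicate values per sample (no technical noise)."""
    assignment, rows = {}, []
    for g, values in values_by_group.items():
        for i, v in enumerate(values):
            s = f"{g}_{i}"
            assignment[s] = g
            for r in range(replicates):
                rows.append((gene, s, r + 1, float(v)))
    design = GroupDesign(assignment, list(values_by_group))
    return TargetedAssayTable(
        pd.DataFrame(rows, columns=["gene", "sample", "replicate", "value"]),
        scale, design, lod=lod,
    )
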