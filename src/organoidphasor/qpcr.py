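"""Relative qPCR quantification by the double-delta-Ct method.

Per group and gene, replicate Ct values are averaged, normalized to the
housekeeping gene (dCt = mean Ct(gene) - mean Ct(housekeeping)), then to
the day-0 undifferentiated control group (ddCt = dCt(group) -
dCt(control)). Fold expression is 2^(-ddCt) under the perfect-doubling
efficiency assumption, and the heatmap matrix stores log2(fold expression)
= -ddCt. Wells with no detected amplification are assigned a ceiling Ct of
40 (the cycle count of the protocol) before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synth import QPCRTable

__all__ = [
    "FoldExpressionMatrix",
    "CT_CEILING",
    "impute_nondetect",
    "delta_delta_ct",
    "heatmap_matrix",
]

#: Ct assigned to non-detected wells: the amplification protocol runs 40
#: cycles, so 40 is the detection limit.
CT_CEILING = 40.0


@dataclass
class FoldExpressionMatrix:
    """Genes x groups matrix of log2 fold expression.

    The control group's own column is identically 0 by construction, and
    every entry is finite once non-detects have been imputed.
    """

    log2_fe: pd.DataFrame  # index: gene_id, columns: group_id
    replicate_counts: pd.DataFrame
    housekeeping_gene: str
    control_group: str
    n_imputed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_fe.to_numpy()).all():
            raise ValueError("log2 fold-expression matrix contains non-finite values")
        control = self.log2_fe[self.control_group]
        if not np.allclose(control, 0.0, atol=1e-9):
            raise ValueError("control-group column must be identically zero")


def impute_nondetect(table: QPCRTable, ct_ceiling: float = CT_CEILING) -> QPCRTable:
    """Assign the ceiling Ct to every non-detected well.

    Detected wells are untouched; the imputation count is recorded in the
    returned table's ``meta``. A ceiling at or below the largest detected
    Ct is suspicious (the floor would sit inside the data) and raises a
    warning, not an error.
    """
    detected = table.data["ct"].dropna()
    if len(detected) and ct_ceiling <= detected.max():
        warnings.warn(
            f"ct_ceiling={ct_ceiling} is not above the largest detected Ct "
            f"({detected.max():.2f})",
            stacklevel=2,
        )
    n = table.n_nondetected
    data = table.data.copy()
    data["ct"] = data["ct"].fillna(ct_ceiling)
    meta = dict(table.meta)
    meta["n_imputed"] = meta.get("n_imputed", 0) + n
    return QPCRTable(
        data=data,
        housekeeping_gene=table.housekeeping_gene,
        control_group=table.control_group,
        meta=meta,
    )


def delta_delta_ct(table: QPCRTable) -> FoldExpressionMatrix:
    """Compute the log2 fold-expression matrix from an imputed Ct table.

    Requires non-detects already imputed, the housekeeping gene in every
    group, and every gene present in the control group.
    """
    if table.data["ct"].isna().any():
        raise ValueError("table contains non-detected wells; impute first")
    df = table.data
    mean_ct = df.groupby(["group_id", "gene_id"], sort=False)["ct"].mean().unstack()
    counts = (
        df.groupby(["group_id", "gene_id"], sort=False)["ct"].count().unstack().fillna(0)
    )
    if table.housekeeping_gene not in mean_ct.columns or mean_ct[
        table.housekeeping_gene
    ].isna().any():
        raise ValueError("housekeeping gene missing from some group")
    if table.control_group not in mean_ct.index:
        raise ValueError("control group missing from table")
    missing_in_control = mean_ct.columns[mean_ct.loc[table.control_group].isna()]
    if len(missing_in_control):
        raise ValueError(
            f"genes absent from control group: {list(missing_in_control)}"
        )

    dct = mean_ct.sub(mean_ct[table.housekeeping_gene], axis=0)
    ddct = dct.sub(dct.loc[table.control_group], axis=1)
    log2_fe = (-ddct).T  # genes x groups; log2(2^-ddCt) = -ddCt

    if log2_fe.isna().any().any():
        raise ValueError("gene/group combinations missing from table")
    return FoldExpressionMatrix(
        log2_fe=log2_fe,
        replicate_counts=counts.T.astype(int),
        housekeeping_gene=table.housekeeping_gene,
        control_group=table.control_group,
        n_imputed=int(table.meta.get("n_imputed", 0)),
        meta=dict(table.meta),
    )


def heatmap_matrix(
    matrix: FoldExpressionMatrix,
    gene_order: list[str] | None = None,
    group_order: list[str] | None = None,
):
    """Reorder the matrix and render a diverging heatmap.

    Returns (ordered matrix, matplotlib Figure). The color scale is
    symmetric about zero so up- and down-regulation get equal visual
    weight.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    log2_fe = matrix.log2_fe
    if gene_order is not None:
        unknown = set(gene_order) - set(log2_fe.index)
        if unknown:
            raise ValueError(f"unknown genes in gene_order: {sorted(unknown)}")
        if set(gene_order) != set(log2_fe.index):
            raise ValueError("gene_order must be a permutation of the matrix genes")
        log2_fe = log2_fe.loc[gene_order]
    if group_order is not None:
        unknown = set(group_order) - set(log2_fe.columns)
        if unknown:
            raise ValueError(f"unknown groups in group_order: {sorted(unknown)}")
        if set(group_order) != set(log2_fe.columns):
            raise ValueError("group_order must be a permutation of the matrix groups")
        log2_fe = log2_fe[group_order]

    ordered = replace(matrix, log2_fe=log2_fe)
    vmax = max(float(np.abs(log2_fe.to_numpy()).max()), 1e-9)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.5 * log2_fe.shape[1], 1.0 + 0.35 * log2_fe.shape[0])
    )
    im = ax.imshow(log2_fe.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(log2_fe.shape[1]), log2_fe.columns, rotation=45, ha="right")
    ax.set_yticks(range(log2_fe.shape[0]), log2_fe.index)
    fig.colorbar(im, ax=ax, label=r"$\log_2$ fold expression")
    fig.tight_layout()
    return ordered, fig
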