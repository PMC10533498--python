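"""Per-cluster marker genes from labeled single-cell matrices.

Given a normalized (log1p-scale) genes x cells matrix with cluster labels,
markers of a cluster are genes whose expression differs between cells in
and out of the cluster by a two-sided Wilcoxon rank-sum test, Bonferroni
corrected over the total number of genes in the dataset. Marker tables for
an initial and a target cluster are then turned into an up/down transition
signature. Clustering itself (HVG selection, PCA, graph clustering) is out
of scope — labels are an input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MissingLabelError, ValidationError
from .signatures import TransitionSignature

__all__ = ["LabeledCellMatrix", "MarkerTable", "find_markers", "markers_to_signature"]

#: group size at or below which the exact rank-sum null is used (no ties)
EXACT_MAX_N = 25


@dataclass
class LabeledCellMatrix:
    """Genes x cells normalized expression with per-cell cluster labels."""

    values: pd.DataFrame
    cell_cluster: pd.Series

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("expression values must be finite and >= 0")
        self.cell_cluster = self.cell_cluster.reindex(self.values.columns)
        if self.cell_cluster.isna().any():
            raise ValidationError("cells without cluster label")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def clusters(self) -> list[str]:
        return sorted(set(self.cell_cluster))

    @classmethod
    def from_tsv(cls, path, clusters_path) -> "LabeledCellMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        lab = pd.read_csv(clusters_path, sep="\t", header=None, dtype=str)
        if lab.iloc[0, 0] in ("cell", "cell_id", "barcode"):
            lab = lab.iloc[1:]
        cl = pd.Series(lab.iloc[:, 1].to_numpy(), index=lab.iloc[:, 0].to_numpy())
        return cls(values=values.astype(float), cell_cluster=cl)

    @classmethod
    def from_mtx(cls, mtx_path, genes_path, barcodes_path, clusters_path) -> "LabeledCellMatrix":
        """Load a genes x cells MTX triplet (dense-ified) plus labels."""
        from scipy.io import mmread

        m = np.asarray(mmread(mtx_path).todense(), dtype=float)
        genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str)
        cells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str)
        values = pd.DataFrame(m, index=genes.to_numpy(), columns=cells.to_numpy())
        lab = pd.read_csv(clusters_path, sep="\t", header=None, dtype=str)
        cl = pd.Series(lab.iloc[:, 1].to_numpy(), index=lab.iloc[:, 0].to_numpy())
        return cls(values=values, cell_cluster=cl)


class MarkerTable(pd.DataFrame):
    """A marker table: (cluster, gene, log_fold_change, p_value, p_adjusted).

    Thin DataFrame subclass so the table round-trips through pandas I/O
    while keeping a domain name.
    """

    @property
    def _constructor(self):
        return MarkerTable

    def to_tsv(self, path) -> None:
        self.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"cluster": str, "gene": str}))


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null for small tie-free groups; normal approximation with tie
    and continuity correction otherwise.
    """
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def find_markers(
    mat: LabeledCellMatrix,
    cluster: str,
    *,
    min_cells: int = 3,
    p_adjusted_max: float = 0.05,
    min_abs_lfc: float = 0.25,
    filter_results: bool = True,
) -> MarkerTable:
    """Markers of ``cluster`` versus all other cells.

    Per gene: a two-sided Wilcoxon rank-sum p-value (in-cluster vs rest),
    the log2 fold change of de-logged means (input assumed log1p scale),
    and the Bonferroni-adjusted p-value ``min(1, p * G_total)`` over the
    total number of genes. Rows are sorted by adjusted p (ascending), then
    |log fold change| (descending), then gene id.
    """
    labels = mat.cell_cluster
    if cluster not in set(labels):
        raise MissingLabelError(f"cluster {cluster!r} not present")
    in_mask = (labels == cluster).to_numpy()
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < min_cells or n_out < min_cells:
        raise ValidationError(
            f"cluster {cluster!r} needs >= {min_cells} cells on both sides "
            f"(got {n_in} in, {n_out} out)"
        )
    arr = mat.values.to_numpy()
    x, y = arr[:, in_mask], arr[:, ~in_mask]
    g_total = mat.n_genes

    # log2 FC of de-logged means, pseudocount 1 (Seurat-style avg_log2FC)
    mean_in = np.expm1(x).mean(axis=1)
    mean_out = np.expm1(y).mean(axis=1)
    lfc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)

    pvals = np.array([_rank_sum_p(x[i], y[i]) for i in range(g_total)])
    padj = np.minimum(1.0, pvals * g_total)

    table = MarkerTable(
        {
            "cluster": cluster,
            "gene": mat.values.index.to_numpy(),
            "log_fold_change": lfc,
            "p_value": pvals,
            "p_adjusted": padj,
        }
    )
    if filter_results:
        keep = (table["p_adjusted"] < p_adjusted_max) & (
            table["log_fold_change"].abs() > min_abs_lfc
        )
        table = table[keep]
    table = table.assign(_abs=table["log_fold_change"].abs()).sort_values(
        ["p_adjusted", "_abs", "gene"], ascending=[True, False, True]
    )
    return MarkerTable(table.drop(columns="_abs").reset_index(drop=True))


def _top_genes(table: MarkerTable, n: int, *, positive: bool) -> list[str]:
    sub = table[table["log_fold_change"] > 0] if positive else table[table["log_fold_change"] < 0]
    return list(sub["gene"].head(n))


def markers_to_signature(
    up_table: MarkerTable,
    down_source: "MarkerTable | None",
    n_sig: int = 200,
) -> TransitionSignature:
    """Build a transition signature from marker tables.

    ``up`` takes the target cluster's positively enriched markers
    (``up_table``). ``down`` takes the initial cluster's positive markers
    when ``down_source`` is a second table, or the negative-LFC markers of
    ``up_table`` when ``down_source`` is None. Each side is truncated to
    ``n_sig`` (tables are already ordered by adjusted p, then |LFC|), and
    genes appearing on both sides are dropped from both.
    """
    if n_sig <= 0:
        raise ValidationError(f"n_sig must be positive, got {n_sig}")
    if len(up_table) == 0:
        raise ValidationError("up marker table is empty")
    up = _top_genes(up_table, n_sig, positive=True)
    if down_source is None:
        down = _top_genes(up_table, n_sig, positive=False)
    else:
        if len(down_source) == 0:
            raise ValidationError("down marker table is empty")
        down = _top_genes(down_source, n_sig, positive=True)
    clash = set(up) & set(down)
    up = [g for g in up if g not in clash]
    down = [g for g in down if g not in clash]
    if not up and not down:
        raise ValidationError("no marker genes left after truncation/disjointness")
    return TransitionSignature(up=tuple(up), down=tuple(down), n_sig=n_sig)
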