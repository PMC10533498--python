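"""Transition signatures from bulk expression contrasts.

A cell-fate transition is summarised by ranking genes on the mean
log-expression difference between the target and initial condition
(fold change on the log scale) and taking the top ``n_sig`` genes of each
tail as the up-/down-regulated signature sets. These disjoint sets are the
query of the connectivity screen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io
from .errors import (
    EmptyOverlapError,
    FateScreenWarning,
    MissingLabelError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RankedGeneList",
    "TransitionSignature",
    "HomologMap",
    "compute_fold_change",
    "extract_signature",
    "map_homologs",
    "signature_score",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples log-scale expression matrix with condition labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are unique gene ids, columns are sample ids; finite floats on
        a log scale (e.g. log2 normalized intensities or log-CPM).
    sample_condition : pandas.Series
        Condition label per sample (index must match ``values.columns``);
        typically ``initial`` / ``target`` but arbitrary time-point labels
        are allowed.
    """

    values: pd.DataFrame
    sample_condition: pd.Series

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values")
        self.sample_condition = self.sample_condition.reindex(self.values.columns)
        if self.sample_condition.isna().any():
            missing = list(self.sample_condition.index[self.sample_condition.isna()])
            raise ValidationError(f"samples without condition label: {missing}")

    @property
    def genes(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def samples_with(self, label: str) -> list[str]:
        mask = self.sample_condition == label
        return list(self.sample_condition.index[mask])

    @classmethod
    def from_tsv(cls, path, conditions_path) -> "ExpressionMatrix":
        """Load from a dense TSV (first column gene ids, header = samples)
        plus a two-column (sample, condition) TSV."""
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        cond = _read_condition_tsv(conditions_path)
        return cls(values=values.astype(float), sample_condition=cond)

    @classmethod
    def from_gct(cls, path, conditions_path) -> "ExpressionMatrix":
        values, _ = io.read_gct_frame(path)
        cond = _read_condition_tsv(conditions_path)
        return cls(values=values, sample_condition=cond)


def _read_condition_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError("condition file needs two columns: sample, condition")
    # tolerate an optional header row
    if df.iloc[0, 0] in ("sample", "sample_id"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by a differential statistic, best (highest) first.

    Ties in the statistic are broken by ascending gene id so rankings are
    bit-exactly reproducible. Construct with :meth:`from_stats` unless the
    arrays are already in ranked order.
    """

    genes: np.ndarray
    stats: np.ndarray

    def __post_init__(self):
        if len(self.genes) != len(self.stats):
            raise ValidationError("genes and stats length mismatch")

    @classmethod
    def from_stats(cls, genes: Sequence[str], stats: Sequence[float]) -> "RankedGeneList":
        genes = np.asarray(genes, dtype=object)
        stats = np.asarray(stats, dtype=float)
        if len(genes) == 0:
            raise ValidationError("cannot rank an empty gene list")
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate gene ids in ranked list")
        if not np.isfinite(stats).all():
            raise ValidationError("non-finite statistics in ranked list")
        order = np.lexsort((genes, -stats))
        return cls(genes=genes[order], stats=stats[order])

    @property
    def n_cell(self) -> int:
        """Length of the ranked list (N in the target-based score)."""
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return zip(self.genes, self.stats)

    def ranks(self) -> dict[str, int]:
        """1-based rank per gene (1 = highest statistic)."""
        return {g: i + 1 for i, g in enumerate(self.genes)}

    def stat_of(self) -> pd.Series:
        return pd.Series(self.stats, index=self.genes)

    def to_tsv(self, path) -> None:
        lines = ["gene\tstatistic"]
        lines += [f"{g}\t{float(s)!r}" for g, s in self]
        io.atomic_write_text(path, "\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t")
        return cls.from_stats(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))


@dataclass
class TransitionSignature:
    """Disjoint up/down gene sets describing a cell-fate transition."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    n_sig: int
    provenance: str = ""

    def __post_init__(self):
        self.up = tuple(self.up)
        self.down = tuple(self.down)
        if set(self.up) & set(self.down):
            raise ValidationError("up and down signature sets must be disjoint")
        if len(self.up) > self.n_sig or len(self.down) > self.n_sig:
            raise ValidationError("signature side larger than n_sig")

    def to_gmt(self, path, name: str = "signature") -> None:
        io.write_gmt(
            {f"{name}_UP": self.up, f"{name}_DN": self.down},
            path,
            descriptions={f"{name}_UP": self.provenance or "na",
                          f"{name}_DN": self.provenance or "na"},
        )

    @classmethod
    def from_gmt(cls, path, name: str | None = None) -> "TransitionSignature":
        sets = io.read_gmt(path)
        if name is None:
            ups = [k for k in sets if k.endswith("_UP")]
            if len(ups) != 1:
                raise ValidationError(
                    f"cannot infer signature name: {len(ups)} *_UP sets in file"
                )
            name = ups[0][: -len("_UP")]
        try:
            up, down = sets[f"{name}_UP"], sets[f"{name}_DN"]
        except KeyError as e:
            raise ValidationError(f"gene set {e.args[0]!r} missing from GMT") from None
        return cls(up=tuple(up), down=tuple(down),
                   n_sig=max(len(up), len(down), 1), provenance=name)

    def to_tsv(self, path) -> None:
        lines = ["gene\tdirection"]
        lines += [f"{g}\tup" for g in self.up]
        lines += [f"{g}\tdown" for g in self.down]
        io.atomic_write_text(path, "\n".join(lines) + "\n")


@dataclass
class HomologMap:
    """A source->target gene id translation (e.g. human->mouse symbols).

    Many-to-many input pairs are resolved by keeping the first pair per
    source id in file order.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "HomologMap":
        mapping: dict[str, str] = {}
        for src, tgt in pairs:
            mapping.setdefault(str(src), str(tgt))
        if not mapping:
            raise ValidationError("homolog map is empty")
        return cls(mapping=mapping)

    @classmethod
    def from_tsv(cls, path, source_col: int = 0, target_col: int = 1,
                 header: bool = False) -> "HomologMap":
        df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
        return cls.from_pairs(zip(df.iloc[:, source_col], df.iloc[:, target_col]))

    def __len__(self) -> int:
        return len(self.mapping)


def compute_fold_change(
    expr: ExpressionMatrix,
    initial_label: str = "initial",
    target_label: str = "target",
) -> RankedGeneList:
    """Rank genes by mean log-expression difference, target minus initial.

    Inputs are assumed log-transformed, so the difference of per-condition
    means is the fold change on the log scale. The result is sorted from
    most upregulated to most downregulated.
    """
    if len(expr.values) == 0:
        raise ValidationError("expression matrix has zero genes")
    for label in (initial_label, target_label):
        if not expr.samples_with(label):
            raise MissingLabelError(
                f"condition {label!r} has no samples; available: "
                f"{sorted(set(expr.sample_condition))}"
            )
    t = expr.values[expr.samples_with(target_label)].mean(axis=1)
    i = expr.values[expr.samples_with(initial_label)].mean(axis=1)
    diff = t - i
    return RankedGeneList.from_stats(diff.index.to_numpy(), diff.to_numpy())


def extract_signature(ranked: RankedGeneList, n_sig: int = 200) -> TransitionSignature:
    """Top up/down tails of a ranked list as a transition signature.

    ``up`` holds the (at most) ``n_sig`` genes with the largest positive
    statistics, ``down`` the most negative ones (most downregulated first).
    Genes with statistic exactly 0 belong to neither side.
    """
    if n_sig <= 0:
        raise ValidationError(f"n_sig must be positive, got {n_sig}")
    if len(ranked) == 0:
        raise ValidationError("ranked list is empty")
    pos = ranked.genes[ranked.stats > 0]
    up = tuple(pos[:n_sig])
    # down side mirrors the up-side tie-break: most negative statistic
    # first, ties by ascending gene id — so reversing the contrast swaps
    # the two sides exactly even with tied statistics
    neg_mask = ranked.stats < 0
    neg_genes, neg_stats = ranked.genes[neg_mask], ranked.stats[neg_mask]
    order = np.lexsort((neg_genes, neg_stats))
    down = tuple(neg_genes[order][:n_sig])
    if not up:
        warnings.warn("no positive statistics: up signature is empty", FateScreenWarning)
    if not down:
        warnings.warn("no negative statistics: down signature is empty", FateScreenWarning)
    return TransitionSignature(up=up, down=down, n_sig=n_sig)


def _map_ids(ids: Sequence[str], mapping: dict[str, str]) -> tuple[list[str], list[int]]:
    """Translate ids, dropping unmapped ones and (order-preserving)
    de-duplicating collisions. Returns mapped ids + kept positions."""
    seen: set[str] = set()
    mapped, kept = [], []
    for i, g in enumerate(ids):
        tgt = mapping.get(g)
        if tgt is None or tgt in seen:
            continue
        seen.add(tgt)
        mapped.append(tgt)
        kept.append(i)
    return mapped, kept


def map_homologs(obj, hmap: HomologMap):
    """Translate gene ids of a ranked list or signature across species.

    Unmapped genes are dropped (count logged); the relative order of a
    ranked list is preserved. When two sources map onto the same target id
    the first (better-ranked) occurrence wins.
    """
    if len(hmap) == 0:
        raise ValidationError("homolog map is empty")
    if isinstance(obj, RankedGeneList):
        mapped, kept = _map_ids(list(obj.genes), hmap.mapping)
        if not mapped:
            raise EmptyOverlapError("no ranked gene maps through the homolog table")
        n_dropped = len(obj) - len(mapped)
        if n_dropped:
            logger.info("map_homologs: dropped %d/%d ranked genes", n_dropped, len(obj))
        return RankedGeneList(
            genes=np.asarray(mapped, dtype=object), stats=obj.stats[kept]
        )
    if isinstance(obj, TransitionSignature):
        up, _ = _map_ids(obj.up, hmap.mapping)
        down, _ = _map_ids(obj.down, hmap.mapping)
        clash = set(up) & set(down)
        if clash:
            warnings.warn(
                f"{len(clash)} mapped genes landed in both directions; dropped from both",
                FateScreenWarning,
            )
            up = [g for g in up if g not in clash]
            down = [g for g in down if g not in clash]
        if not up and not down:
            raise EmptyOverlapError("no signature gene maps through the homolog table")
        n_dropped = (len(obj.up) - len(up)) + (len(obj.down) - len(down))
        if n_dropped:
            logger.info("map_homologs: dropped %d signature genes", n_dropped)
        return TransitionSignature(
            up=tuple(up), down=tuple(down), n_sig=obj.n_sig, provenance=obj.provenance
        )
    raise TypeError(f"cannot map homologs for {type(obj).__name__}")


def signature_score(ranked: RankedGeneList, gene_set: Iterable[str]) -> float:
    """Mean statistic (fold change) of the gene set's members present in
    the ranked list — a direction-aware summary of how strongly a set
    moves in the contrast."""
    gene_set = set(gene_set)
    mask = np.fromiter((g in gene_set for g in ranked.genes), bool, len(ranked))
    if not mask.any():
        raise EmptyOverlapError("gene set does not overlap the ranked list")
    return float(ranked.stats[mask].mean())
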