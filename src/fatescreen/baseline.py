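"""Target-based comparator score.

A conventional target-driven screen assumes that inhibiting genes which
are downregulated during the transition promotes it. For a molecule with
target set T, the score is the mean 1-based rank of its targets in the
fold-change-ranked gene list (rank 1 = most upregulated), divided by the
list length N::

    target_score = mean(R_m for m in T) / N      in (0, 1]

Targets near the bottom of the list (downregulated in the transition)
give scores near 1, so molecules are ranked by descending score: the
molecule whose targets are most downregulated is ranked first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable

import pandas as pd

from .errors import EmptyOverlapError, ValidationError
from .signatures import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = ["TargetAnnotation", "target_based_score", "rank_by_target_score"]


@dataclass
class TargetAnnotation:
    """molecule id -> set of target gene ids."""

    targets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        for mol, t in self.targets.items():
            if not t:
                raise ValidationError(f"molecule {mol!r} has an empty target set")
        self.targets = {m: frozenset(t) for m, t in self.targets.items()}

    def __len__(self) -> int:
        return len(self.targets)

    @classmethod
    def from_tsv(cls, path) -> "TargetAnnotation":
        """Long-format TSV: one (molecule_id, gene_id) pair per line."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValidationError("target table needs two columns: molecule, gene")
        if df.iloc[0, 0] in ("molecule", "molecule_id"):
            df = df.iloc[1:]
        targets: dict[str, set[str]] = {}
        for mol, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
            targets.setdefault(str(mol), set()).add(str(gene))
        return cls(targets={m: frozenset(t) for m, t in targets.items()})

    def to_tsv(self, path) -> None:
        rows = []
        for mol in sorted(self.targets):
            for g in sorted(self.targets[mol]):
                rows.append(f"{mol}\t{g}")
        from .io import atomic_write_text

        atomic_write_text(path, "\n".join(rows) + "\n")


def target_based_score(ranked: RankedGeneList, targets: Iterable[str]) -> float:
    """Mean 1-based rank of the molecule's targets, divided by list length.

    Targets absent from the ranked list are dropped with a logged count;
    if none remains an :class:`EmptyOverlapError` is raised.
    """
    targets = set(targets)
    rank_of = ranked.ranks()
    present = [rank_of[t] for t in targets if t in rank_of]
    if not present:
        raise EmptyOverlapError("no target gene present in the ranked list")
    dropped = len(targets) - len(present)
    if dropped:
        logger.debug("target_based_score: %d targets absent from ranked list", dropped)
    return float(sum(present) / len(present) / ranked.n_cell)


def rank_by_target_score(ranked: RankedGeneList, ann: TargetAnnotation) -> pd.DataFrame:
    """Score and rank all annotated molecules by the target-based score.

    Higher score = targets sit lower in the fold-change ranking (more
    downregulated) = stronger predicted inducer, so ranking is by
    descending score with competition ranking for ties. Molecules with no
    scoreable target are excluded with a logged warning. Returns a frame
    with columns (molecule, score, rank).
    """
    if len(ann) == 0:
        raise ValidationError("target annotation is empty")
    rows = []
    for mol in sorted(ann.targets):
        try:
            rows.append({"molecule": mol, "score": target_based_score(ranked, ann.targets[mol])})
        except EmptyOverlapError:
            logger.warning("molecule %s has no target in the ranked list; excluded", mol)
    if not rows:
        raise EmptyOverlapError("no molecule has a scoreable target")
    df = (
        pd.DataFrame(rows)
        .sort_values(["score", "molecule"], ascending=[False, True])
        .reset_index(drop=True)
    )
    df["rank"] = df["score"].rank(method="min", ascending=False).astype(int)
    return df
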