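"""Connectivity scoring: KS running-sum enrichment of signature genes in
ranked perturbation profiles.

For a ranked list of N genes and a signature side with G hits, a running
sum walks the list from top to bottom: a hit at position i adds
``w_i / sum(w_hits)`` (with ``w_i = |stat_i| ** weight_exponent``; the
default exponent 0 gives the classic unweighted Kolmogorov-Smirnov step
1/G) and a miss subtracts ``1/(N - G)``. The enrichment score (ES) is the
signed deviation of maximal absolute value, so ES lies in [-1, 1]: +1 when
the set sits entirely at the top of the list, -1 entirely at the bottom.

The similarity (connectivity) score of a molecule profile against a
transition signature is::

    similarity = (ES_up - ES_dn) / 2

which is +1 for a profile that drives the signature's up genes to the top
and its down genes to the bottom (a transition mimic) and -1 for the exact
opposite (a reverser). A molecule's screen score is the maximum over its
(cell line, dose) category profiles; molecules are ranked by that score
and the top 5% flagged as screen hits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, ValidationError
from .profiles import PerturbationProfile, ProfileKey, ProfileLibrary, rank_profile
from .signatures import RankedGeneList, TransitionSignature

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentScore",
    "ScreenResult",
    "enrichment_score",
    "similarity_score",
    "score_profile",
    "score_library",
    "score_ranked_profiles",
]


@dataclass(frozen=True)
class EnrichmentScore:
    """A signed KS enrichment score with the position of its extremum.

    ``tied`` marks the degenerate case where the positive and negative
    extrema have exactly equal magnitude; the positive one is reported.
    """

    value: float
    argmax_position: int  # 0-based index into the ranked list
    n_hits: int
    direction_set: str | None = None  # "up" / "down" when part of a signature
    tied: bool = False

    def __float__(self) -> float:
        return self.value


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = 0,
    min_overlap: int = 1,
    direction_set: str | None = None,
) -> EnrichmentScore:
    """KS running-sum enrichment of ``gene_set`` in ``ranked``.

    Signature genes absent from the ranked list are dropped (count
    logged). Raises :class:`EmptyOverlapError` when fewer than
    ``min_overlap`` genes remain, and :class:`ValidationError` when the
    set covers the whole list (the miss step would be undefined).
    """
    gene_set = set(gene_set)
    n = len(ranked)
    hits = np.fromiter((g in gene_set for g in ranked.genes), bool, n)
    g = int(hits.sum())
    dropped = len(gene_set) - g
    if dropped:
        logger.debug("enrichment_score: %d set genes absent from ranked list", dropped)
    if g < max(min_overlap, 1):
        raise EmptyOverlapError(
            f"gene set overlaps ranked list at {g} genes (< min_overlap {min_overlap})"
        )
    if g == n:
        raise ValidationError("gene set covers the entire ranked list")
    if weight_exponent == 0:
        # unweighted steps are +1/G and -1/(N-G): scale by G(N-G) and walk
        # in int64 so extrema and magnitude ties are exact, not subject to
        # float accumulation error
        rs = np.cumsum(np.where(hits, n - g, -g).astype(np.int64))
        scale = g * (n - g)
    else:
        w = np.abs(ranked.stats) ** weight_exponent
        denom = w[hits].sum()
        if denom == 0:  # degenerate all-zero hit statistics: fall back to equal steps
            hit_w = np.where(hits, 1.0 / g, 0.0)
        else:
            hit_w = np.where(hits, w / denom, 0.0)
        rs = np.cumsum(hit_w - np.where(hits, 0.0, 1.0 / (n - g)))
        scale = 1
    imax = int(np.argmax(rs))
    imin = int(np.argmin(rs))
    tied = bool(rs[imax] == -rs[imin])
    # positive extremum preferred on exact magnitude ties
    if rs[imax] >= -rs[imin]:
        value, pos = float(rs[imax]) / scale, imax
    else:
        value, pos = float(rs[imin]) / scale, imin
    return EnrichmentScore(value=value, argmax_position=pos, n_hits=g,
                           direction_set=direction_set, tied=tied)


def similarity_score(es_up: float, es_dn: float) -> float:
    """Combine the two directional enrichment scores: ``(ES_up - ES_dn)/2``."""
    es_up, es_dn = float(es_up), float(es_dn)
    for name, v in (("es_up", es_up), ("es_dn", es_dn)):
        if not -1.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v} outside [-1, 1]")
    return (es_up - es_dn) / 2.0


def score_profile(
    sig: TransitionSignature,
    p: PerturbationProfile,
    weight_exponent: float = 0,
    min_overlap: int = 1,
) -> float:
    """Similarity of one perturbation profile to a transition signature."""
    ranked = rank_profile(p)
    es_up = enrichment_score(ranked, sig.up, weight_exponent, min_overlap, "up")
    es_dn = enrichment_score(ranked, sig.down, weight_exponent, min_overlap, "down")
    return similarity_score(es_up.value, es_dn.value)


@dataclass
class ScreenResult:
    """Per-profile and per-molecule outcome of a connectivity screen.

    ``profile_scores`` has one row per scored (molecule, cell_line, dose)
    profile; ``molecule_scores`` one row per molecule with its max score,
    competition rank (ties share the minimum rank) and top-fraction flag.
    """

    profile_scores: pd.DataFrame
    molecule_scores: pd.DataFrame
    top_fraction: float
    skipped: list = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_scores)

    def rank_of(self, molecule: str) -> int:
        row = self.molecule_scores.loc[self.molecule_scores["molecule"] == molecule]
        if row.empty:
            raise KeyError(molecule)
        return int(row["rank"].iloc[0])

    def score_of(self, molecule: str) -> float:
        row = self.molecule_scores.loc[self.molecule_scores["molecule"] == molecule]
        if row.empty:
            raise KeyError(molecule)
        return float(row["score"].iloc[0])

    def ranks(self) -> dict[str, int]:
        return dict(zip(self.molecule_scores["molecule"], self.molecule_scores["rank"]))

    def to_frame(self) -> pd.DataFrame:
        """Flat per-profile table with molecule-level columns merged in."""
        mol = self.molecule_scores.rename(columns={"score": "molecule_score"})
        out = self.profile_scores.rename(columns={"score": "profile_score"}).merge(
            mol, on="molecule", how="left"
        )
        return out[
            ["molecule", "cell_line", "dose", "profile_score",
             "molecule_score", "rank", "top_flag"]
        ]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, top_fraction: float = 0.05) -> "ScreenResult":
        df = pd.read_csv(path, sep="\t", dtype={"molecule": str})
        prof = df[["molecule", "cell_line", "dose", "profile_score"]].rename(
            columns={"profile_score": "score"}
        )
        mol = (
            df[["molecule", "molecule_score", "rank", "top_flag"]]
            .drop_duplicates("molecule")
            .rename(columns={"molecule_score": "score"})
            .sort_values(["rank", "molecule"])
            .reset_index(drop=True)
        )
        return cls(profile_scores=prof, molecule_scores=mol, top_fraction=top_fraction)


def score_ranked_profiles(
    sig: TransitionSignature,
    items: Sequence[tuple[ProfileKey, RankedGeneList]],
    *,
    weight_exponent: float = 0,
    min_overlap: int = 1,
    top_fraction: float = 0.05,
) -> ScreenResult:
    """Score pre-ranked profiles (see :func:`score_library`).

    Exposed separately so callers that score the same ranked profiles
    against many signatures (e.g. the signature-size robustness analysis)
    can pay the ranking cost once.
    """
    rows, skipped = [], []
    for key, ranked in items:
        try:
            es_up = enrichment_score(ranked, sig.up, weight_exponent, min_overlap)
            es_dn = enrichment_score(ranked, sig.down, weight_exponent, min_overlap)
        except (EmptyOverlapError, ValidationError) as e:
            logger.warning("skipping profile %s: %s", key, e)
            skipped.append((key, str(e)))
            continue
        rows.append(
            {
                "molecule": key.molecule,
                "cell_line": key.cell_line,
                "dose": key.dose,
                "score": similarity_score(es_up.value, es_dn.value),
            }
        )
    if not rows:
        raise EmptyOverlapError("no profile could be scored against the signature")
    prof = pd.DataFrame(rows)
    mol = (
        prof.groupby("molecule", sort=True)["score"]
        .max()
        .reset_index()
        .sort_values(["score", "molecule"], ascending=[False, True])
        .reset_index(drop=True)
    )
    mol["rank"] = mol["score"].rank(method="min", ascending=False).astype(int)
    n_top = math.ceil(top_fraction * len(mol))
    mol["top_flag"] = mol["rank"] <= n_top
    return ScreenResult(
        profile_scores=prof,
        molecule_scores=mol,
        top_fraction=top_fraction,
        skipped=skipped,
    )


def score_library(
    sig: TransitionSignature,
    lib: ProfileLibrary,
    *,
    weight_exponent: float = 0,
    min_overlap: int = 1,
    top_fraction: float = 0.05,
) -> ScreenResult:
    """Screen a whole (aggregated) profile library against a signature.

    Profiles failing the overlap preconditions are skipped with a logged
    warning and recorded in ``ScreenResult.skipped``; the per-molecule
    score is the max over the molecule's scored category profiles.
    """
    items = [(p.key, rank_profile(p)) for p in lib]
    return score_ranked_profiles(
        sig,
        items,
        weight_exponent=weight_exponent,
        min_overlap=min_overlap,
        top_fraction=top_fraction,
    )
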