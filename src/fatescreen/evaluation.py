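"""Rank-based evaluation of a screen.

A screen is judged by where molecules with prior experimental evidence of
inducing the transition (the *query* molecules) land in the ranking: their
median rank, how many fall in the top fraction, and — for method
comparison — the paired ranks under the connectivity screen versus the
target-based baseline. A robustness analysis checks that per-molecule
score vectors correlate across signature sizes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ScreenResult, score_ranked_profiles
from .errors import FateScreenWarning, ValidationError
from .profiles import ProfileLibrary, rank_profile
from .signatures import RankedGeneList, extract_signature

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "ComparisonReport",
    "RobustnessReport",
    "median_rank",
    "compare_methods",
    "signature_size_robustness",
]

DEFAULT_SIZES = (50, 100, 150, 200, 250, 300)


def _ranks_from(result) -> tuple[dict[str, int], int, dict[str, bool]]:
    """Normalize a ScreenResult / rank frame / mapping to molecule->rank."""
    if isinstance(result, ScreenResult):
        ms = result.molecule_scores
        top = dict(zip(ms["molecule"], ms["top_flag"])) if "top_flag" in ms else {}
        return dict(zip(ms["molecule"], ms["rank"].astype(int))), len(ms), top
    if isinstance(result, pd.DataFrame):
        if not {"molecule", "rank"}.issubset(result.columns):
            raise ValidationError("rank frame needs 'molecule' and 'rank' columns")
        top = (
            dict(zip(result["molecule"], result["top_flag"]))
            if "top_flag" in result.columns
            else {}
        )
        return (
            dict(zip(result["molecule"].astype(str), result["rank"].astype(int))),
            result["molecule"].nunique(),
            top,
        )
    if isinstance(result, Mapping):
        ranks = {str(k): int(v) for k, v in result.items()}
        return ranks, len(ranks), {}
    raise TypeError(f"cannot extract ranks from {type(result).__name__}")


@dataclass
class EvaluationReport:
    """Ranks of the query molecules within one screen."""

    query_molecules: list[str]
    ranks: dict[str, int]
    median_rank: float
    n_total: int
    top_fraction_hits: int
    missing: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        from .io import atomic_write_text

        atomic_write_text(path, json.dumps(self.__dict__, indent=2, default=str) + "\n")


def median_rank(result, query: Sequence[str]) -> EvaluationReport:
    """Median screen rank of the query molecules (midpoint convention).

    Query molecules absent from the screen are reported in ``missing``,
    never imputed.
    """
    ranks, n_total, top = _ranks_from(result)
    query = [str(q) for q in query]
    present = {q: ranks[q] for q in query if q in ranks}
    missing = [q for q in query if q not in ranks]
    if not present:
        raise ValidationError("no query molecule present in the screen result")
    if missing:
        warnings.warn(
            f"{len(missing)} query molecules absent from the screen: {missing[:5]}",
            FateScreenWarning,
        )
    med = float(np.median(list(present.values())))
    hits = sum(1 for q in present if top.get(q, False))
    return EvaluationReport(
        query_molecules=query,
        ranks=present,
        median_rank=med,
        n_total=n_total,
        top_fraction_hits=hits,
        missing=missing,
    )


@dataclass
class ComparisonReport:
    """Paired per-molecule ranks under two screening methods."""

    paired: pd.DataFrame  # molecule, rank_connectivity, rank_baseline
    median_connectivity: float
    median_baseline: float


def compare_methods(connectivity_result, baseline_result, query: Sequence[str]) -> ComparisonReport:
    """Pair query-molecule ranks from the connectivity screen and the
    target-based baseline and report both medians. No significance test
    is attached — the comparison is descriptive."""
    c_ranks, _, _ = _ranks_from(connectivity_result)
    b_ranks, _, _ = _ranks_from(baseline_result)
    if not set(c_ranks) & set(b_ranks):
        raise ValidationError("connectivity and baseline results share no molecule")
    query = [str(q) for q in query]
    rows = [
        {"molecule": q, "rank_connectivity": c_ranks[q], "rank_baseline": b_ranks[q]}
        for q in query
        if q in c_ranks and q in b_ranks
    ]
    if not rows:
        raise ValidationError("no query molecule covered by both methods")
    paired = pd.DataFrame(rows)
    return ComparisonReport(
        paired=paired,
        median_connectivity=float(paired["rank_connectivity"].median()),
        median_baseline=float(paired["rank_baseline"].median()),
    )


@dataclass
class RobustnessReport:
    """Correlation of per-molecule score vectors across signature sizes."""

    correlations: pd.DataFrame  # size x size correlation matrix
    reference_size: int
    mean_reference_correlation: float
    sizes_used: list[int]
    sizes_skipped: list[int] = field(default_factory=list)


def signature_size_robustness(
    ranked: RankedGeneList,
    lib: ProfileLibrary,
    sizes: Sequence[int] = DEFAULT_SIZES,
    *,
    reference_size: int = 200,
    method: str = "spearman",
    weight_exponent: float = 0,
    min_overlap: int = 1,
) -> RobustnessReport:
    """Score the library with signatures of several sizes and correlate
    the per-molecule score vectors between every size pair.

    Sizes for which the ranked list lacks enough positive or negative
    genes are skipped with a warning. ``method`` is ``spearman`` (default;
    score scales differ across sizes) or ``pearson``.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    n_pos = int((ranked.stats > 0).sum())
    n_neg = int((ranked.stats < 0).sum())
    usable, skipped = [], []
    for s in dict.fromkeys(int(s) for s in sizes):  # dedupe, keep order
        if s <= min(n_pos, n_neg):
            usable.append(int(s))
        else:
            skipped.append(int(s))
            warnings.warn(
                f"signature size {s} exceeds available genes "
                f"({n_pos} up / {n_neg} down); skipped",
                FateScreenWarning,
            )
    if reference_size not in usable:
        raise ValidationError(
            f"reference size {reference_size} not usable with this ranked list"
        )
    preranked = [(p.key, rank_profile(p)) for p in lib]
    vectors = {}
    for s in usable:
        sig = extract_signature(ranked, n_sig=s)
        res = score_ranked_profiles(
            sig, preranked, weight_exponent=weight_exponent, min_overlap=min_overlap
        )
        vectors[s] = res.molecule_scores.set_index("molecule")["score"]
    mat = pd.DataFrame(vectors)  # molecules x sizes, aligned on molecule
    # Spearman = Pearson on (average-tie) ranks
    data = mat.rank().to_numpy() if method == "spearman" else mat.to_numpy()
    cmat = np.atleast_2d(np.corrcoef(data.T))
    corr = pd.DataFrame(cmat, index=usable, columns=usable)
    others = [s for s in usable if s != reference_size]
    mean_ref = float(corr.loc[reference_size, others].mean()) if others else 1.0
    return RobustnessReport(
        correlations=corr,
        reference_size=reference_size,
        mean_reference_correlation=mean_ref,
        sizes_used=usable,
        sizes_skipped=skipped,
    )
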