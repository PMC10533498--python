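"""Small-molecule perturbation profiles and their aggregation.

A perturbation profile is one differential-expression vector over a gene
universe (typically the ~978 directly measured landmark transcripts of an
L1000-style assay) for a (molecule, cell line, dose, replicate) treatment.
Replicates are averaged per (molecule, cell line, dose) category — or the
coarser (molecule, cell line) grouping — before scoring; each category is
screened independently and the per-molecule score is the max over its
categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io
from .errors import ParseError, ValidationError
from .signatures import RankedGeneList

__all__ = [
    "PerturbationProfile",
    "ProfileLibrary",
    "ProfileKey",
    "read_gct",
    "write_gct",
    "read_long_tsv",
    "write_long_tsv",
    "aggregate_replicates",
    "rank_profile",
]

#: field separator inside GCT column ids: molecule|cell_line|dose|replicate
_ID_SEP = "|"


class ProfileKey(NamedTuple):
    molecule: str
    cell_line: str | None = None
    dose: str | None = None


@dataclass
class PerturbationProfile:
    """One differential-expression vector for a treatment condition."""

    molecule: str
    stats: pd.Series  # index: gene ids
    cell_line: str | None = None
    dose: str | None = None
    replicate: str | None = None

    def __post_init__(self):
        if self.stats.index.has_duplicates:
            raise ValidationError(f"duplicate gene ids in profile {self.molecule!r}")
        if not np.isfinite(self.stats.to_numpy()).all():
            raise ValidationError(f"non-finite statistics in profile {self.molecule!r}")
        self.stats = self.stats.astype(float)

    @property
    def key(self) -> ProfileKey:
        return ProfileKey(self.molecule, self.cell_line, self.dose)

    @property
    def full_key(self) -> tuple:
        return (self.molecule, self.cell_line, self.dose, self.replicate)

    @property
    def genes(self) -> pd.Index:
        return self.stats.index

    def column_id(self) -> str:
        parts = [self.molecule, self.cell_line or "", self.dose or "", self.replicate or ""]
        for p in parts:
            if _ID_SEP in p:
                raise ValidationError(f"{_ID_SEP!r} not allowed inside profile fields: {p!r}")
        return _ID_SEP.join(parts).rstrip(_ID_SEP)


@dataclass
class ProfileLibrary:
    """A collection of perturbation profiles with unique condition keys."""

    profiles: list[PerturbationProfile] = field(default_factory=list)

    def __post_init__(self):
        keys = [p.full_key for p in self.profiles]
        if len(set(keys)) != len(keys):
            dupes = pd.Series(keys).value_counts()
            raise ValidationError(
                f"duplicate (molecule, cell_line, dose, replicate) keys: "
                f"{list(dupes[dupes > 1].index[:3])}"
            )

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def molecules(self) -> list[str]:
        return sorted({p.molecule for p in self.profiles})

    def gene_universe(self, policy: str = "intersection") -> pd.Index:
        """Common (``intersection``, default) or total (``union``) gene ids.

        Scoring requires a shared universe, so intersection is the policy
        the pipeline uses.
        """
        if not self.profiles:
            raise ValidationError("library is empty")
        idx = self.profiles[0].genes
        for p in self.profiles[1:]:
            idx = idx.intersection(p.genes) if policy == "intersection" else idx.union(p.genes)
        return idx


def _parse_column_id(col: str) -> tuple[str, str | None, str | None, str | None]:
    parts = col.split(_ID_SEP)
    parts += [""] * (4 - len(parts))
    mol, cl, dose, rep = parts[:4]
    return mol, cl or None, dose or None, rep or None


def read_gct(path) -> ProfileLibrary:
    """Read a profile library from GCT 1.2 text.

    Column ids encode the condition as ``molecule|cell_line|dose|replicate``
    (trailing empty fields may be omitted).
    """
    values, _ = io.read_gct_frame(path)
    profiles = []
    for col in values.columns:
        mol, cl, dose, rep = _parse_column_id(col)
        if not mol:
            raise ParseError(f"empty molecule id in column {col!r}", path=path)
        profiles.append(
            PerturbationProfile(
                molecule=mol, cell_line=cl, dose=dose, replicate=rep, stats=values[col]
            )
        )
    return ProfileLibrary(profiles=profiles)


def write_gct(lib: ProfileLibrary, path) -> None:
    if not lib.profiles:
        raise ValidationError("refusing to write an empty library")
    frame = pd.DataFrame({p.column_id(): p.stats for p in lib.profiles})
    # preserve gene order of the first profile; others must share it or be alignable
    frame = frame.reindex(lib.profiles[0].genes.union(frame.index, sort=False))
    if frame.isna().any().any():
        raise ValidationError(
            "profiles have unequal gene universes; GCT needs a rectangular matrix"
        )
    io.write_gct_frame(frame, path)


def read_long_tsv(path) -> ProfileLibrary:
    """Read a library from long TSV with columns
    (molecule, cell_line, dose, replicate, gene, stat)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene": str, "molecule": str},
        float_precision="round_trip",
    )
    required = {"molecule", "gene", "stat"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"long TSV needs columns {sorted(required)}; got {list(df.columns)}", path=path
        )
    for optional in ("cell_line", "dose", "replicate"):
        if optional not in df.columns:
            df[optional] = np.nan
    profiles = []
    for (mol, cl, dose, rep), grp in df.groupby(
        ["molecule", "cell_line", "dose", "replicate"], dropna=False, sort=True
    ):
        profiles.append(
            PerturbationProfile(
                molecule=str(mol),
                cell_line=None if pd.isna(cl) else str(cl),
                dose=None if pd.isna(dose) else str(dose),
                replicate=None if pd.isna(rep) else str(rep),
                stats=pd.Series(grp["stat"].to_numpy(), index=grp["gene"].to_numpy()),
            )
        )
    return ProfileLibrary(profiles=profiles)


def write_long_tsv(lib: ProfileLibrary, path) -> None:
    rows = ["molecule\tcell_line\tdose\treplicate\tgene\tstat"]
    for p in lib.profiles:
        cl, dose, rep = p.cell_line or "", p.dose or "", p.replicate or ""
        for g, v in p.stats.items():
            rows.append(f"{p.molecule}\t{cl}\t{dose}\t{rep}\t{g}\t{float(v)!r}")
    io.atomic_write_text(path, "\n".join(rows) + "\n")


def aggregate_replicates(
    lib: ProfileLibrary, keys: tuple[str, ...] = ("molecule", "cell_line", "dose")
) -> ProfileLibrary:
    """Average replicate profiles per condition category.

    ``keys`` selects the grouping — the default (molecule, cell_line, dose)
    or the coarser (molecule, cell_line). The aggregated statistic is the
    per-gene arithmetic mean over the intersection of the group's gene
    sets; the replicate id is cleared. Aggregating an already aggregated
    library is the identity.
    """
    if not lib.profiles:
        raise ValidationError("library is empty")
    allowed = {"molecule", "cell_line", "dose"}
    if not set(keys) <= allowed or "molecule" not in keys:
        raise ValidationError(f"keys must include 'molecule' and be among {sorted(allowed)}")
    groups: dict[tuple, list[PerturbationProfile]] = {}
    for p in lib.profiles:
        k = tuple(getattr(p, f) for f in keys)
        groups.setdefault(k, []).append(p)
    out = []
    for k in sorted(groups, key=lambda t: tuple("" if v is None else v for v in t)):
        members = groups[k]
        common = members[0].genes
        for m in members[1:]:
            common = common.intersection(m.genes)
        if len(common) == 0:
            raise ValidationError(
                f"non-overlapping gene sets within group {k}; cannot aggregate"
            )
        common = common.sort_values()
        mean = pd.concat([m.stats.reindex(common) for m in members], axis=1).mean(axis=1)
        fields = dict(zip(keys, k))
        out.append(
            PerturbationProfile(
                molecule=fields["molecule"],
                cell_line=fields.get("cell_line"),
                dose=fields.get("dose"),
                replicate=None,
                stats=mean,
            )
        )
    return ProfileLibrary(profiles=out)


def rank_profile(p: PerturbationProfile) -> RankedGeneList:
    """Order a profile's genes by statistic, descending, ties by gene id."""
    if len(p.stats) < 2:
        raise ValidationError("profile needs at least 2 genes to rank")
    return RankedGeneList.from_stats(
        p.stats.index.to_numpy(), p.stats.to_numpy()
    )


def subset_genes(lib: ProfileLibrary, genes: pd.Index) -> ProfileLibrary:
    """Restrict every profile to ``genes`` (used for universe policies)."""
    profiles = [replace(p, stats=p.stats.reindex(genes).dropna()) for p in lib.profiles]
    return ProfileLibrary(profiles=profiles)
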