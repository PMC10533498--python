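"""Seeded generators for offline, fully testable screening runs.

The generators emulate the study conditions of an L1000-style screen: a
978-gene landmark universe, a bulk transition matrix with planted
differentially expressed genes, a perturbation library in which a few
*planted mimic* molecules shift the planted signature genes in the
transition's direction while background molecules carry pure noise, a
target annotation (planted molecules target planted down genes), and a
labeled single-cell matrix with planted cluster markers.

Determinism: every generator derives its own RNG from ``(seed, stream)``
and each molecule/cluster gets a keyed child stream, so adding molecules
does not perturb earlier draws and identical specs give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .baseline import TargetAnnotation
from .errors import ValidationError
from .profiles import PerturbationProfile, ProfileLibrary
from .sc_markers import LabeledCellMatrix
from .signatures import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_transition",
    "generate_library",
    "generate_sc",
    "generate_score_battery",
]

# stream ids for the per-generator RNGs
_STREAM_TRANSITION = 0
_STREAM_LIBRARY = 1
_STREAM_SC = 2
_STREAM_BATTERY = 3


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the screening conditions the package is tested under:
    a 978-gene landmark universe, 200 planted DE genes per direction with
    a 2-noise-sd shift, and a 500-molecule library with 5 planted mimics
    replicated 3x over 2 cell lines at one dose.
    """

    seed: int = 0
    n_genes: int = 978
    n_samples: int = 3  # bulk samples per condition
    n_molecules: int = 500
    n_planted: int = 5
    n_replicates: int = 3
    n_cell_lines: int = 2
    n_doses: int = 1
    effect_size: float = 2.0  # mean shift of planted genes, in noise-sd units
    noise_sd: float = 1.0
    n_de: int = 200  # planted DE genes per direction
    n_clusters: int = 2
    n_cells_per_cluster: int = 50
    n_markers_per_cluster: int = 100
    n_targets_per_molecule: int = 3
    baseline_mean: float = 6.0  # log2-scale baseline expression
    baseline_sd: float = 1.0
    attenuation_range: tuple[float, float] = (0.5, 1.0)
    #: "down": planted molecules target planted down genes (informative
    #: annotation); "random": all molecules get random targets, for
    #: benchmarking the baseline against an uninformative annotation.
    planted_target_policy: str = "down"

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if not 0 <= self.n_planted <= self.n_molecules:
            raise ValidationError("need 0 <= n_planted <= n_molecules")
        if self.n_de * 2 > self.n_genes:
            raise ValidationError("n_de must be <= n_genes/2")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if min(self.n_samples, self.n_replicates, self.n_cell_lines, self.n_doses) < 1:
            raise ValidationError("sample/replicate/cell-line/dose counts must be >= 1")
        lo, hi = self.attenuation_range
        if not 0 < lo <= hi:
            raise ValidationError("attenuation_range must satisfy 0 < lo <= hi")
        if self.planted_target_policy not in ("down", "random"):
            raise ValidationError("planted_target_policy must be 'down' or 'random'")

    def gene_ids(self) -> np.ndarray:
        width = len(str(self.n_genes))
        return np.array([f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)], dtype=object)

    def molecule_ids(self) -> np.ndarray:
        width = len(str(self.n_molecules))
        return np.array(
            [f"M{i:0{width}d}" for i in range(1, self.n_molecules + 1)], dtype=object
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    planted_molecules: list[str] = field(default_factory=list)
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    cluster_markers: dict[str, list[str]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "planted_molecules": list(self.planted_molecules),
            "up_genes": list(self.up_genes),
            "down_genes": list(self.down_genes),
            "cluster_markers": {k: list(v) for k, v in self.cluster_markers.items()},
        }


def _rng(spec: SyntheticSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, *key))


def generate_transition(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Bulk initial/target expression with planted DE genes.

    Per gene, a baseline ~ Normal(baseline_mean, baseline_sd) is drawn;
    initial samples add Normal(0, noise_sd) noise, target samples
    additionally shift the planted up (+) / down (-) genes by
    ``effect_size * noise_sd``.

    Draw order: baseline, planted-gene choice, initial noise, target noise.
    """
    spec.validate()
    rng = _rng(spec, _STREAM_TRANSITION)
    genes = spec.gene_ids()
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    chosen = rng.choice(spec.n_genes, size=2 * spec.n_de, replace=False)
    up_idx, down_idx = chosen[: spec.n_de], chosen[spec.n_de :]
    shift = np.zeros(spec.n_genes)
    shift[up_idx] = spec.effect_size * spec.noise_sd
    shift[down_idx] = -spec.effect_size * spec.noise_sd

    initial = baseline[:, None] + rng.normal(0, spec.noise_sd, (spec.n_genes, spec.n_samples))
    target = (
        (baseline + shift)[:, None]
        + rng.normal(0, spec.noise_sd, (spec.n_genes, spec.n_samples))
    )
    cols = [f"initial_{i+1}" for i in range(spec.n_samples)] + [
        f"target_{i+1}" for i in range(spec.n_samples)
    ]
    values = pd.DataFrame(np.hstack([initial, target]), index=genes, columns=cols)
    cond = pd.Series(
        ["initial"] * spec.n_samples + ["target"] * spec.n_samples, index=cols
    )
    truth = GroundTruth(
        up_genes=sorted(genes[up_idx]), down_genes=sorted(genes[down_idx])
    )
    return ExpressionMatrix(values=values, sample_condition=cond), truth


def generate_library(
    spec: SyntheticSpec, truth: GroundTruth
) -> tuple[ProfileLibrary, TargetAnnotation]:
    """Perturbation library with planted transition mimics + targets.

    The first ``n_planted`` molecule ids are the mimics: their profiles
    shift the planted up genes by ``+effect_size*noise_sd`` and the down
    genes by the negative, scaled by a per-(cell line, dose) attenuation
    factor ~ U(attenuation_range), with fresh Normal(0, noise_sd) noise
    per replicate. Background molecules are pure noise. Planted molecules
    are annotated with targets drawn from the planted down genes;
    background molecules get random targets.

    Per-molecule draws use keyed child RNG streams, so the library is
    stable under changes to ``n_molecules`` for the molecules kept.
    """
    spec.validate()
    genes = spec.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    mols = spec.molecule_ids()
    planted = list(mols[: spec.n_planted])
    signal = np.zeros(spec.n_genes)
    amp = spec.effect_size * spec.noise_sd
    signal[[gene_pos[g] for g in truth.up_genes]] = amp
    signal[[gene_pos[g] for g in truth.down_genes]] = -amp

    lo, hi = spec.attenuation_range
    profiles: list[PerturbationProfile] = []
    targets: dict[str, frozenset[str]] = {}
    down_pool = np.asarray(truth.down_genes, dtype=object)
    for m_idx, mol in enumerate(mols):
        rng_m = _rng(spec, _STREAM_LIBRARY, m_idx)
        is_planted = mol in planted
        base = signal if is_planted else np.zeros(spec.n_genes)
        for c in range(spec.n_cell_lines):
            for d in range(spec.n_doses):
                atten = rng_m.uniform(lo, hi)
                for r in range(spec.n_replicates):
                    stats = atten * base + rng_m.normal(0, spec.noise_sd, spec.n_genes)
                    profiles.append(
                        PerturbationProfile(
                            molecule=mol,
                            cell_line=f"CL{c+1}",
                            dose=f"dose{d+1}",
                            replicate=f"rep{r+1}",
                            stats=pd.Series(stats, index=genes),
                        )
                    )
        n_t = min(spec.n_targets_per_molecule, spec.n_genes)
        informative = (
            is_planted
            and spec.planted_target_policy == "down"
            and len(down_pool) >= n_t
        )
        if informative:
            tset = rng_m.choice(down_pool, size=n_t, replace=False)
        else:
            tset = rng_m.choice(genes, size=n_t, replace=False)
        targets[mol] = frozenset(map(str, tset))
    lib = ProfileLibrary(profiles=profiles)
    truth.planted_molecules = planted
    return lib, TargetAnnotation(targets=targets)


def generate_sc(spec: SyntheticSpec) -> tuple[LabeledCellMatrix, GroundTruth]:
    """Labeled single-cell matrix with planted per-cluster markers.

    Counts are log-normal (log-scale mean 1, sd ``noise_sd``); marker
    genes of a cluster get a ``+effect_size*noise_sd`` log-scale shift in
    their own cluster. Emitted values are log1p(counts), i.e. normalized
    log expression >= 0.
    """
    spec.validate()
    if spec.n_clusters < 2:
        raise ValidationError("need >= 2 clusters for marker contrasts")
    if spec.n_clusters * spec.n_markers_per_cluster > spec.n_genes:
        raise ValidationError("too many markers for the gene universe")
    genes = spec.gene_ids()
    rng = _rng(spec, _STREAM_SC)
    marker_idx = rng.choice(
        spec.n_genes, size=spec.n_clusters * spec.n_markers_per_cluster, replace=False
    )
    clusters = [f"C{k}" for k in range(spec.n_clusters)]
    markers = {
        clusters[k]: marker_idx[
            k * spec.n_markers_per_cluster : (k + 1) * spec.n_markers_per_cluster
        ]
        for k in range(spec.n_clusters)
    }
    blocks, cell_ids, labels = [], [], []
    amp = spec.effect_size * spec.noise_sd
    for k, cl in enumerate(clusters):
        rng_k = _rng(spec, _STREAM_SC, k + 1)
        mu = np.ones(spec.n_genes)
        mu[markers[cl]] += amp
        latent = rng_k.normal(
            mu[:, None], spec.noise_sd, (spec.n_genes, spec.n_cells_per_cluster)
        )
        blocks.append(np.log1p(np.exp(latent)))
        cell_ids += [f"{cl}_cell{j+1}" for j in range(spec.n_cells_per_cluster)]
        labels += [cl] * spec.n_cells_per_cluster
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=cell_ids)
    truth = GroundTruth(
        cluster_markers={cl: sorted(genes[idx]) for cl, idx in markers.items()}
    )
    mat = LabeledCellMatrix(
        values=values, cell_cluster=pd.Series(labels, index=cell_ids)
    )
    return mat, truth


def generate_score_battery(
    spec: SyntheticSpec, n_pairs: int
):
    """Yield ``n_pairs`` random (signature, profile) pairs for stress
    testing the scoring pipeline: each pair draws a fresh Normal(0,
    noise_sd) profile over the gene universe and a random disjoint
    ``n_de``-up / ``n_de``-down signature."""
    from .signatures import TransitionSignature

    spec.validate()
    genes = spec.gene_ids()
    for i in range(n_pairs):
        rng = _rng(spec, _STREAM_BATTERY, i)
        stats = rng.normal(0, spec.noise_sd, spec.n_genes)
        perm = rng.permutation(spec.n_genes)
        sig = TransitionSignature(
            up=tuple(genes[perm[: spec.n_de]]),
            down=tuple(genes[perm[spec.n_de : 2 * spec.n_de]]),
            n_sig=spec.n_de,
        )
        profile = PerturbationProfile(
            molecule=f"B{i}", stats=pd.Series(stats, index=genes)
        )
        yield sig, profile
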