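# Methods

## Problem and model

`fatescreen` ranks small molecules by how closely their transcriptional
perturbation profiles mimic a desired cell-state transition
(reprogramming, differentiation, transdifferentiation). The premise is
the connectivity-map one: if a transition moves a characteristic set of
genes up and another set down, a molecule whose perturbation profile
moves the same genes in the same directions is a candidate inducer of
that transition.

The pipeline is a chain of deterministic transforms; nothing is fitted:

1. **Transition signature.** Genes are ranked by the difference of
   per-condition means of log-scale expression (fold change on the log
   scale), target minus initial. The signature is the top `n_sig` genes
   of each tail: `up` (most positive) and `down` (most negative), with
   zero-statistic genes assigned to neither side. Default
   `n_sig = 200` per direction, configurable 50–300 for the robustness
   analysis. Moderated/eBayes differential statistics are deliberately
   not used: only the fold-change ranking is consumed downstream, and the
   mean log-difference defines that ranking transparently.
2. **Profile library.** One differential-expression vector per
   (molecule, cell line, dose, replicate) over a common gene universe —
   typically the ~978 directly measured landmark transcripts of an
   L1000-style assay. Replicates are averaged per (molecule, cell line,
   dose) category (a coarser (molecule, cell line) grouping is available)
   on the intersection of their gene sets; enrichment over a partially
   shared universe is ill-defined, so the intersection policy is the one
   the scoring uses.
3. **Connectivity score.** For each aggregated profile, genes are ranked
   by the profile statistic and each signature side is scored with a
   Kolmogorov–Smirnov running sum: walking the ranked list, a hit adds
   `w_i / Σw_hits` and a miss subtracts `1/(N−G)`. With the default
   weight exponent 0 the hit step is `1/G` (classic unweighted KS); an
   exponent of 1 (statistic-weighted hits, fgsea-style) is available by
   flag. The enrichment score ES is the signed running-sum deviation of
   maximal absolute value, so ES ∈ [−1, 1]. The similarity of a profile
   to the signature is

   ```
   similarity = (ES_up − ES_dn) / 2        ∈ [−1, 1]
   ```

   +1 for a perfect mimic (up genes driven to the top, down genes to the
   bottom), −1 for a perfect reverser.
4. **Screen.** A molecule's score is the **max** over its category
   profiles; molecules are ranked by descending score (competition
   ranking: ties share the minimum rank) and the top 5 %
   (`rank ≤ ceil(0.05·n)`) are flagged as hits. No permutation p-values
   are attached: the screen ranks by score alone.
5. **Target-based comparator.** For a molecule with target set T, the
   score is `mean(rank of targets in the fold-change ranking) / N`
   (1-based ranks). Molecules are ranked by descending score: targets
   concentrated among transition-downregulated genes predict induction
   under the conventional "inhibit what goes down" assumption. The
   direction of that ranking is an inference from that premise, not a
   printed rule; the formula itself uses rank position only, so
   inhibitor/activator mechanism does not enter.
6. **Evaluation.** Median screen rank (midpoint convention for even
   counts) of query molecules with prior experimental evidence; paired
   rank comparison between the connectivity screen and the target-based
   comparator (descriptive, no significance test); and a signature-size
   robustness analysis correlating per-molecule score vectors across
   signature sizes (Spearman by default, Pearson available).

Single-cell inputs are handled by a marker path: with cluster labels
given (clustering itself — HVG selection, PCA, graph clustering — is out
of scope), markers of a cluster versus the rest are called per gene with
a two-sided Wilcoxon rank-sum test (exact null for tie-free groups of
≤ 25, normal approximation with tie/continuity correction otherwise;
`scipy.stats.mannwhitneyu` underneath), a Seurat-style
`log2((mean expm1 + 1) in) − log2((mean expm1 + 1) out)` fold change, and
Bonferroni correction over the **total** gene count. Defaults
`p_adjusted < 0.05`, `|log2FC| > 0.25`, ≥ 3 cells per side. Target- and
initial-cluster marker tables become the up/down signature sides
(truncated by ascending adjusted p, then descending |LFC|; genes marking
both sides are dropped from both). A user-supplied two-column homolog
table translates gene ids across species; many-to-many pairs resolve to
the first pair per source id, unmapped genes are dropped with a logged
count.

## Numerical choices

- **Deterministic ordering everywhere.** All rankings break statistic
  ties by ascending gene id, so results are bit-reproducible across runs
  and platforms. The down signature side mirrors the up side's tie-break
  (most negative first, ties by ascending gene id), which makes reversing
  the contrast swap the two sides exactly even with tied statistics.
- **Exact integer running sum.** With weight exponent 0 the KS steps are
  +1/G and −1/(N−G), so all partial sums lie on a 1/(G(N−G)) lattice and
  exact magnitude ties between the positive and negative extrema occur
  with non-negligible probability. The running sum is therefore
  accumulated in int64 (hit +(N−G), miss −G, rescaled at the end): the
  extremum and tie detection are exact rather than subject to float
  accumulation order. Ties resolve to the positive extremum and are
  flagged (`EnrichmentScore.tied`).
- **Tie rule vs antisymmetry.** Negating a profile's statistics reverses
  its ranking and negates both ES values and the similarity score —
  except at an exact extremum tie, where the positive-preference rule
  reports the positive value for both signs. This is an unavoidable
  consequence of preferring one sign at ties; the tests assert exact
  negation off ties and the deterministic tie behavior at them.
- **Degenerate inputs.** A gene set covering the whole ranked list, an
  empty overlap below `min_overlap` (default 1; ≥ 10 recommended for real
  libraries), a missing condition label, or a malformed GCT/GMT line all
  raise typed errors; profiles failing overlap during a library screen
  are skipped with a logged warning and recorded in
  `ScreenResult.skipped`, never silently. With exponent 1 and all-zero
  hit statistics the hit weights fall back to equal steps.
- **Formats.** GCT 1.2 and GMT writers print floats with Python `repr`,
  so read/write round trips are value-identical. Long-TSV reading uses
  pandas' round-trip float parser for the same reason.

## Synthetic study conditions

The generators emulate the screening conditions the package is tested
under; all are pure functions of `SyntheticSpec` (seed included), using
per-generator and per-molecule keyed RNG streams so adding molecules
does not perturb earlier draws.

- **Universe**: 978 genes, mirroring the landmark-transcript dimension.
- **Bulk transition**: per-gene baseline ~ Normal(6, 1) on a log2-like
  scale; 3 samples per condition with Normal(0, noise_sd) noise
  (noise_sd = 1); 200 planted DE genes per direction shifted by
  ±`effect_size`·noise_sd (effect 2) in the target condition. Three
  samples per condition is the small-replicate regime typical of the
  bulk time-course datasets this emulates.
- **Library**: 500 molecules, 5 planted mimics, 3 replicates × 2 cell
  lines × 1 dose. Planted profiles carry the ±effect shift on the
  planted genes scaled by a per-(cell line, dose) attenuation factor
  ~ U(0.5, 1) — categories respond with different strength, which is
  what the per-molecule max rule exploits — plus fresh per-replicate
  noise; background molecules are pure Normal(0, noise_sd) noise.
- **Targets**: 3 targets per molecule; planted molecules draw theirs
  from the planted down genes (policy `"down"`), or uniformly at random
  (policy `"random"`) for benchmarking against an uninformative
  annotation.
- **Single cell**: 2 clusters × 50 cells, 100 markers per cluster,
  log-normal counts (log-scale sd = noise_sd) with a +effect log-shift
  of a cluster's markers in that cluster, emitted as log1p values.

What the generators deliberately do **not** emulate: L1000 deconvolution
artifacts and heavy-tailed measurement noise, dose–response shapes,
correlated gene modules, and — importantly — transcriptional signal in
background molecules. Real perturbation profiles almost all carry *some*
reproducible signal; synthetic background profiles carry none. Passing
the planted-recovery tests therefore shows the scoring separates strong
mimics from noise, not that real libraries are this easy. The
signature-size robustness analysis is the one place this bites: for a
signal-free profile, scores at two signature sizes are correlated only
through the overlap of the nested signature sets, which caps the mean
Spearman correlation of size 200 versus {50…300} near 0.62 under these
conditions — Pearson, dominated by the concordant planted mimics,
exceeds 0.8. On real libraries, where per-molecule signal is stable
across signature sizes, rank correlations are far higher; the synthetic
figure is a floor, not an estimate of real-data behavior.

## Problem sizes used in tests and the acceptance script

The acceptance script scores a seeded battery of 10,000 random
signature/profile pairs (978 genes, 200 up/200 down) for the score-range
check, and six independently seeded 500-molecule transition/library
pairs for the robustness analysis; unit tests use 40–500-molecule
libraries and 100–500-gene universes. These sizes were chosen so the
full suite runs in well under a minute per analysis while keeping the
978-gene landmark dimension where it matters.

## Known limitations

- Bulk contrasts use plain mean log-differences; no variance moderation,
  no p-values, no time-course smoothing. Multi-time-point datasets are
  handled by letting the caller choose which labels to contrast.
- The screen assumes profile statistics are comparable within a library;
  cross-library harmonization is the caller's responsibility.
- GCT 1.2 text is the reference dialect; binary GCTX/HDF5 is not read.
- The target-based comparator ignores mechanism (inhibition vs
  activation) and target affinity by construction.
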