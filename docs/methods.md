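# Methods

This note documents the statistical procedures implemented in `sigmatch`,
the parameters that matter, the design decisions taken where the problem was
genuinely open, and what the synthetic test bed does and does not establish
about behaviour on real data.

## Signature formatting

Each dataset is reduced to one signed significance per gene,
`−log10(p) × sign(direction)`, so that heterogeneous platforms (microarray,
RNA-seq) become comparable. Practical details:

- **Cap.** |values| are capped at 320. −log10 of the smallest positive
  double is ≈ 323.6; the cap keeps stored values finite and gives
  underflowed p-values (passed as `Decimal`/`Fraction`) a well-defined
  image instead of an overflow. The cap only matters for astronomically
  significant genes, whose rank is unaffected.
- **Symbol harmonisation.** Symbols are stripped and uppercased, which maps
  most rodent symbols onto their human orthologs (Bdnf → BDNF). An explicit
  two-column ortholog map can override individual symbols; we deliberately
  keep all symbols that fail to map rather than dropping them — unmatched
  genes simply never intersect the reference universe.
- **Duplicates** collapse to the entry with the largest |value| (the most
  significant probe), with the larger signed value breaking exact-|value|
  ties; the collapse count is logged.
- **Zeros** (p = 1) carry no direction and belong to neither the up nor the
  down list.
- **Ties in ranking** are broken by ascending symbol everywhere, making
  every extraction deterministic across platforms and run orders.

## Quadrant congruence score

Both signatures are restricted to their shared gene universe (size N); each
contributes its top-n up and top-n down lists (default n = 1000 — large
enough to reflect meaningful biology, fixed so all datasets are treated
equally; lists are shorter when fewer signed genes exist). The four
directional overlaps A (up-up), B (up-down), C (down-up), D (down-down) are
scored with the hypergeometric upper tail −log10 P(X ≥ k) and combined as
score = A + D − B − C. Interpretation: the score is a log-scale evidence
balance, positive when the model moves the same genes in the same direction
as the reference, negative when it opposes it, and near zero under
independence (each quadrant's expected overlap is s₁s₂/N, where the tail
contributes almost nothing).

The quadrant outputs are uncorrected one-sided tails, a deliberate choice:
the score is a comparative index across models evaluated at one fixed
cutoff, not a per-gene inference, so a multiple-testing layer would only
rescale all models monotonically.

Models sharing fewer than `min_shared` genes (default 100) with the
reference are reported as `skipped` rather than scored from unstable tails.

### Numerical evaluation of the tail

Tails are computed in log space from a log-factorial table. When the
requested tail holds more than half the probability mass, it is evaluated
through the complementary tail with `log1p`/`expm1`: −log10 p then retains
full *relative* precision even at p = 1 − 10⁻³⁰, where direct summation
returns exactly 0. The list-size arguments are canonicalised (s₁ ≤ s₂)
so the floating-point path is identical under argument swap, which makes
RRHO transpose symmetry exact rather than approximate. The test suite and
the acceptance script verify agreement with an exact integer-arithmetic
oracle to better than 10⁻⁹ relative error, exhaustively for all
(k, s₁, s₂, N) with N ≤ 60, and against `scipy.stats.hypergeom` spot
values at larger N. scipy's tail is used only as a cross-check, never as
the implementation, because its generic discrete summation does not
guarantee relative precision near p = 1.

## RRHO heatmaps

For the stepped heatmap both signatures are ranked over the shared universe
by descending signed value; for every pair of rank thresholds (multiples of
`step`, default N//100, giving a ≈100×100 grid) the prefix overlap is
compared with its expectation i·j/N and reported as a signed value: +(upper
tail) when over-enriched, −(lower tail) when depleted. The reference is
conventionally the X axis. The grid of overlap counts is computed by a 2-D
rank histogram with cumulative sums, so cost is dominated by the per-cell
tail evaluations. Exported as TSV with threshold header lines; the
matplotlib rendering is cosmetic and untested.

## Consensus portraits

A portrait combines k ≥ 2 datasets of one condition. Per gene, with
`consistency` = largest fraction of nonzero entries sharing one sign
(∈ [0.5, 1]):

    consensus = mean(values) × (2 × consistency − 1)

Genes present in fewer than ⌈`min_presence_frac` × k⌉ datasets (default
frac 0.5) are omitted; zero entries count toward presence but not
direction. The formula rewards direction-consistent change, cancels 50/50
conflicts exactly, and is idempotent on identical copies. It is this
package's own reconstruction of a "consistent changes are highlighted"
aggregation — published consensus-portrait procedures differ in detail, and
no claim is made that this reproduces any specific one; the properties that
downstream stages rely on (idempotence, conflict cancellation, permutation
invariance, majority-sign consensus) are tested directly.

## Machine-learning ranking

Feature space: the top `n_features` (default 2000) portrait genes by
|consensus|; an explicit exclusion list supports dropping genes known to be
poorly represented in the model datasets. Signatures project by lookup with
0.0 for absent genes.

Two training constructions, both label-balanced by construction:

- **real_reversed** — each human dataset is a case; its elementwise
  negation is the matched control. With ≥ 2 datasets this is linearly
  separable in practice (cases and controls are antipodal), and ten-fold
  CV accuracy of 100% for the linear classifier is the expected, tested
  behaviour.
- **shuffled_reversed** — the portrait's top-gene values are randomly
  permuted across genes (`n_shuffles` times, default 20), preserving the
  multiset of signed values; each shuffle is a case, its negation a
  control. We implement the shuffle as a full permutation of the value
  vector: the per-gene assignment is destroyed but every sign survives in
  the multiset, and the constant direction Σv still separates cases from
  controls. A within-sign-group shuffle is the other defensible reading of
  "shuffled, sign unchanged"; the full permutation was chosen as the
  stronger null since it removes all gene identity.

Classifiers are injected through a `fit`/`predict_case_proba` contract; the
package ships a logistic-regression linear-margin classifier and a small
one-hidden-layer feed-forward network (32 units). These are the committee
members — which specific linear or neural implementation is used is not a
methodological claim. In practice the linear classifier also achieves 100%
CV on the shuffled construction (it finds the consistent Σv direction),
while the feed-forward network generalises worse across held-out shuffles
(any of many separating hyperplanes fits a training fold); its CV accuracy
on that construction is reported as measured, not asserted.

Per (training set × classifier) pair every model receives a case
probability; probabilities are converted to ranks (average on ties) and the
final ML rank is the re-ranked mean of per-pair ranks, ties broken by id.
Averaging **ranks** rather than probabilities keeps differently calibrated
committee members commensurable. Cross-validation uses stratified k-fold
(default 10) with a seeded shuffle and reports percent accuracy.

## Embedding

Models plus portrait are projected onto the top portrait genes and
flattened to 2-D. The backend is pluggable: UMAP (default; neighbour count
clipped to n−1, parameters recorded in the output metadata) or PCA (exact,
fast, used widely in the tests so that geometric assertions do not depend
on a neighbour-embedding's internals). Axes are arbitrary; the Euclidean
distance of each model to the embedded portrait point is reported, and on
synthetic suites high-congruence models sit significantly closer to the
portrait than anti-congruent ones (one-sided Mann–Whitney, tested).

## Synthetic test bed

`simulate` generates: a truth signature over `n_genes` (default 5000,
roughly a post-intersection universe) with `signal_fraction` (default 0.2)
signal genes — fair-coin sign, magnitude 1.3 + Exponential with mean
`effect_scale` = 3.0, so every planted effect is at least nominally
significant and top-1000 truncation bites; null genes are −log10 U(0,1]
with a random sign. Human replicates (default 29, the scale of a real
multi-study portrait) add N(0, `noise_sd` = 1.0) gene-wise noise to the
truth and flip null-gene signs with a per-dataset probability drawn from
U(0.25, 0.5), preventing spurious consensus on nulls. Models copy each
signal gene's truth direction with probability (1 + |c|)/2 — toward the
truth for planted congruence c ≥ 0, away for c < 0 — with magnitude
|truth| + noise; null genes are independent. c = 0 is exact independence,
and the score's null distribution is symmetric about zero by construction
(the calibration the acceptance suite measures).

What this establishes: order recovery (Spearman ≥ 0.9 over 50 models with
c graded across [−0.9, 0.9]), null calibration, ML/hypergeometric
agreement, and every algebraic invariant — under independent gene-wise
noise. What it does not establish: behaviour under gene–gene correlation,
platform batch structure, or region-specific covariance, none of which the
generator emulates. Passing tests therefore validate the machinery, not
the biology of any particular dataset.

## Pipeline and determinism

`run_full_ranking` (and `sigmatch run`) consumes a manifest (groups
`model`, `human`, optionally one prebuilt `portrait` used directly as the
reference), builds the portrait, ranks, attaches the ML committee and its
rank agreement, exports RRHO grids and congruent-gene lists for the top-k
models, embeds, and writes a provenance log with versions, configuration
and seeds — deliberately without timestamps, so a rerun with the same
inputs, configuration and seed is byte-identical (tested at file level).
All stochastic stages (simulation, shuffles, classifiers, CV folds,
embedding) consume explicit seeds derived from the single run seed.

Problem sizes used in the verification suite — 5000-gene universes,
29-dataset portraits, 50-model recovery suites, 200 null replicates,
exhaustive tail checking to N = 60 — are the package's chosen working
scale: large enough that the statistics are in their asymptotic regime,
small enough that the whole suite runs on a laptop in a couple of minutes.

## Known limitations

- The consensus-portrait formula is a documented reconstruction, not a
  reimplementation of any published aggregation.
- Quadrant evidence values are uncorrected tails; they are comparative
  scores, not calibrated per-comparison p-values.
- Uppercase-symbol ortholog mapping is approximate; genes with
  non-trivial orthology need an explicit map file.
- The RRHO grid omits the multiple-testing correction layer used by some
  published heatmap implementations; cell values are directly comparable
  within one grid, not across grids of different universe size.
- UMAP coordinates are only relationally meaningful; with seeds fixed they
  are reproducible on one platform but not guaranteed identical across
  library versions.
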