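# Methods

## The statistic

For one gene with expression vector `x` (length n, already-normalized units
such as log2(RSEM+1)) and a binary phenotype `y ∈ {0,1}`, the normalized
differential correlation is

    NDC(x, y) = ( MIC(x, y) − R²(x, y) − Thre_MIC ) / max(|R(x, y)|, ε)

with three ingredients:

**MIC for a binary label.** The maximal information coefficient normalizes
binned mutual information by `log2 min(k_x, k_y)`. With a binary y every
admissible grid has k_y = 2, so the normalizer is 1 and only the expression
axis is partitioned:

    MIC(x, y) = max over partitions of x into k bins of I(bin(x); y),
                2 ≤ k, k·2 < B(n), B(n) = n^0.6.

`mic_binary` computes this maximum exactly: samples are sorted by x, cut
points are allowed only between strictly different consecutive values (tied
samples are never split — bins are value intervals, not index intervals), and
for each admissible k a dynamic program over the last-cut position maximizes
the summed per-bin entropy contributions in O(k·c²) for c candidate cuts.
Because the DP consumes only the x-ordering and tie structure, MIC is exactly
invariant under strictly increasing transformations of x, and swapping the
class labels leaves it unchanged. A constant gene admits no cut and scores
MIC = 0 (reported with a single degenerate bin) rather than raising, so
whole-matrix scans never abort. `brute_force_mic` independently enumerates
every cut subset (n ≤ 30) and is required by the tests to agree with the DP
to 1e-12.

*Grid-budget edge case:* for 8 ≤ n ≤ 10 the strict bound `2k < n^0.6` admits
no grid at all; the single-cut family k = 2 is always allowed once n ≥ 8.
This is a deliberate relaxation so small inputs remain scoreable.

*Chi-square termination.* The estimator the score was designed around curbs
the finite-sample inflation of exhaustive grid search by stopping grid
refinement early. `MICConfig(termination="chi_square")` provides such a
variant: cuts are inserted greedily by information gain and insertion stops
when a Pearson chi-square test (df = 1) comparing the two new sub-bins' label
counts is non-significant at `chi_level` (default 0.05). The exact stopping
rule of the published ChiMIC estimator is not specified by our sources, so
this mode is an approximation flag; the exhaustive exact maximum is the
default everywhere.

**Linear terms.** R is the point-biserial correlation — the Pearson
correlation of x against the 0/1 label encoding (sample-SD convention; the
n vs n−1 choice cancels). R² is its square. For a constant gene the
correlation is undefined; the ranker assigns such genes a rank-last sentinel
instead of propagating NaN.

**Permutation threshold.** `Thre_MIC` is the finite-sample significance floor
of MIC: repeat n_perm times (default 1,000) — draw one gene uniformly at
random from the matrix (with replacement), shuffle its sample order, compute
MIC against the unshuffled labels — then take the nearest-rank 95% fractile
(1-based index ceil(0.95·n_perm) of the ascending sort, no interpolation).
Shuffling destroys any gene–label pairing, and for tie-free expression the
null MIC distribution depends only on n and the class sizes, so pooling draws
across genes is legitimate. Whether the original procedure draws genes with
or without replacement is not stated; with-replacement is used here.

**The ε floor.** The score divides by |R| with no published guard for
|R| → 0. A floor ε = 1e−8 (configurable) is applied: a genuinely nonlinear
gene has near-zero R with a *positive* numerator, so the floor preserves its
top rank instead of producing non-finite values, while null genes have a
negative numerator with ≈95% probability, which the floor amplifies
downwards. NDC is computed for every gene including strongly linear ones;
their large R² and |R| push them down without special-casing.

**Two-stage ranking.** Stage 1 sorts all genes by NDC descending (ties: MIC
descending, then gene ID); stage 2 re-sorts the first `top_pool` genes
(default 1,000) by MIC descending (ties: NDC descending, then gene ID).
Both orderings are reported (`rank_ndc`, `rank_final`) since either can be of
interest.

## Contingency and comparator statistics

The 2×2 contingency analyses (expression group vs. tumor grade, expression
pattern vs. vital status) use the Pearson chi-square with Yates continuity
correction, df = 1 — the corrected test reproduces both published p-values
(0.0084 and 0.002) from the published counts while the uncorrected test does
not, which pins the convention. The linear comparator is the Welch
unequal-variance t-test (Welch–Satterthwaite df; pooled-variance available by
flag); the original comparator's exact t-variant is unstated and only
rankings are consumed.

## Synthetic data

The generator emulates, on the log2 scale, four archetypes seen in paired
tumor/paracarcinoma cohorts (two samples per patient; sample IDs encode
patient and tissue, though the score itself uses only the labels):

| kind        | class 0 (paracarcinoma)                  | class 1 (tumor)                  |
|-------------|------------------------------------------|----------------------------------|
| null        | N(μ, σ)                                  | N(μ, σ)                          |
| linear_de   | N(μ, σ)                                  | N(μ + shift, σ)                  |
| bimodal     | ½N(μ−gap/2, σ) + ½N(μ+gap/2, σ)          | N(μ, σ)                          |
| stratified  | ½N(μ−gap/2, σ) + ½N(μ+gap/2, σ)          | ½N(μ−3gap/2, σ) + ½N(μ+3gap/2, σ)|

Defaults: μ = 8, σ = 0.5, shift = 1.5, gap = 4, mixture weight 0.5, values
clipped at 0. These are this package's constructions chosen to mimic the
qualitative patterns (a flanking low/high split around the other class's
single mode; four distinct strata); they are *not* a count-level RNA-seq
model — no library-size variation, no negative-binomial dispersion, no
gene–gene correlation, balanced classes by default. Passing recovery tests
therefore demonstrates the ranking logic under idealized Gaussian mixtures,
not performance on raw counts; real matrices should arrive normalized (or use
the `--log2p1` flag — MIC is monotone-invariant but R/R² are not, so the
transform must be explicit).

## Study conditions used by the tests and the acceptance script

Simulation checks run at n = 120 balanced samples (60 patients per class),
2,000 genes, n_perm = 1,000, seed 42 (the package default), chosen to keep
the full suite under a minute while leaving Monte-Carlo bands comfortably
narrow:

* **Null calibration** — on a fully null matrix the fraction of genes with
  MIC > Thre_MIC must lie in the 99% binomial band around 0.05
  (0.0374–0.0626 at 2,000 genes).
* **Recovery** — with 20 bimodal + 40 linear + 1,940 null genes planted,
  ≥ 90% of the bimodal genes must appear in the final top 40.
* **Disjointness** — the top-100 lists by NDC and by |t| should share ≤ 5
  genes.

## Known limitations

* **The disjointness bound is fragile at the default effect sizes, and the
  shipped benchmark does not meet it.** A planted linear gene with
  shift = 1.5, σ = 0.5 has R² ≈ 0.69 while its exhaustively maximized MIC at
  n = 120 is ≈ 0.92, so its NDC ≈ (0.92 − 0.69 − 0.27)/0.83 ≈ −0.05 — almost
  exactly the boundary separating it from the upper tail of null genes (whose
  scores are amplified by small |R| denominators to either clearly positive
  or clearly negative values). The count of positive-score nulls (~78
  expected of the ~80 needed to fill the top 100) then decides how many
  linear genes leak into the NDC top 100: across 20 seeds the overlap ranged
  8–32, and the chi-square termination narrows but does not close the gap
  (1–17). True top-list disjointness from the t-test requires linear effects
  strong enough that R² + Thre_MIC clearly exceeds MIC (as with the extreme
  effect sizes typical of real tumor/normal data); at moderate effect sizes
  partial overlap is the honest expectation. The corresponding test is left
  failing rather than weakening the bound or strengthening the generator.
* Exhaustive DP maximization inflates MIC under finite samples (that is what
  Thre_MIC corrects *on average*); per-gene inflation still adds variance to
  NDC near the decision boundary.
* Phenotypes must be binary; multi-class or continuous phenotypes are out of
  scope (R/R² are only meaningful for a binary class).
* No per-gene p-values are assigned to NDC — it is a ranking statistic.
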