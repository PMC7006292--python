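# ndc — nonlinear differential-expression gene ranking

Standard differential-expression statistics (t-test, edgeR/DESeq2-style
models) rank genes by a *mean shift* between two phenotype classes. They miss
genes whose expression separates the classes **nonlinearly** — for example a
gene that is unimodal in tumor tissue but splits into a low and a high mode in
adjacent non-tumor (paracarcinoma) tissue, giving near-zero correlation with
the class label despite carrying strong class information.

`ndc` implements the **normalized differential correlation** score for a
gene x against a binary phenotype y:

```
NDC(x, y) = ( MIC(x, y) − R²(x, y) − Thre_MIC ) / |R(x, y)|
```

* **MIC(x, y)** — the maximal information coefficient. With a binary y it
  reduces to the maximum, over partitions of the expression axis into
  2 ≤ k bins with 2k < n^0.6, of the mutual information between bin membership
  and the label; `ndc` computes this maximum *exactly* by dynamic programming
  over cut positions (a chi-square early-stopping variant is available as an
  approximation flag).
* **R(x, y)** — the point-biserial (Pearson) correlation; R² its square.
  These capture the linear part of the association.
* **Thre_MIC** — the 95% fractile of MIC scores obtained by repeatedly drawing
  a random gene from the matrix and shuffling its sample order (default 1,000
  permutations): the finite-sample significance floor for MIC.

A large positive NDC flags strong nonlinear but weak linear association.
Ranking is two-stage: all genes by NDC descending, then the top 1,000 re-sorted
by MIC descending.

The package also ships a synthetic-data generator that plants null, linearly
shifted, bimodal-nonlinear and four-level stratified genes with ground truth,
so the whole method is testable without any external download.

## Worked example

```bash
ndc simulate --patients 60 --seed 0 --out-prefix demo   # 2,000-gene benchmark
ndc rank --expr demo.matrix.tsv --labels demo.labels.tsv \
    --perms 1000 --seed 42 --out demo.ranked.tsv
head -6 demo.ranked.tsv
```

prints (abridged):

```
# ndc ranked gene list
# threshold = 0.272397
# n_perm = 1000, level = 0.95, seed = 42
# config: n_perm = 1000, seed = 42, alpha = 0.6, level = 0.95, eps = 1e-08, top_pool = 1000, log2p1 = False, termination = exhaustive, chi_level = 0.05, strict = False
gene	mic	r	r2	ndc	rank_ndc	rank_final	t_stat	t_p
bimodal_00008	1.000000	-0.012105	0.000147	60.093733	4	1	0.131508	0.895772
```

The first data row is a planted bimodal gene: MIC = 1 (a three-bin grid
separates the classes perfectly), |r| ≈ 0.01 (no linear signal, t-test p =
0.90), hence a large positive NDC and final rank 1. The `threshold` header is
Thre_MIC for this sample size; genes are ordered by the two-stage ranking and
every column needed to audit the score (mic, r, r², ndc, both ranks, t) is
present. `ndc chi2 16 10 10 29` and `ndc threshold`/`ndc mic` expose the
contingency test and the intermediate quantities individually.

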