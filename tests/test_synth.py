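"""Synthetic generator: shapes, determinism, planted-pattern statistics."""

import numpy as np
import pytest

from ndc.mic import MICConfig, SampleSeries, mic_binary
from ndc.stats import point_biserial
from ndc.synth import (
    PatternSpec,
    decode_sample_id,
    default_recovery_specs,
    generate,
    paired_layout,
)


class TestPatternSpec:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"kind": "wavy", "count": 1}, "kind"),
            ({"kind": "null", "count": -1}, "count"),
            ({"kind": "null", "count": 1, "base_sd": 0.0}, "base_sd"),
            ({"kind": "bimodal", "count": 1, "gap": -2}, "gap"),
            ({"kind": "bimodal", "count": 1, "mix_weight": 1.0}, "mix_weight"),
        ],
    )
    def test_validation_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            PatternSpec(**kwargs)


class TestGenerate:
    def test_dimensions_and_truth(self):
        specs = [PatternSpec("null", 7), PatternSpec("bimodal", 3),
                 PatternSpec("stratified", 2)]
        mat, labels, truth = generate(12, specs, seed=1)
        assert mat.values.shape == (12, 24)
        assert (labels == 0).sum() == (labels == 1).sum() == 12
        assert len(truth) == 12
        kinds = [t.kind for t in truth]
        assert kinds.count("null") == 7
        assert kinds.count("bimodal") == 3
        assert kinds.count("stratified") == 2
        assert len({t.gene_id for t in truth}) == 12

    def test_seed_determinism(self):
        specs = [PatternSpec("linear_de", 4)]
        a, la, ta = generate(15, specs, seed=7)
        b, lb, tb = generate(15, specs, seed=7)
        c, _, tc = generate(15, specs, seed=8)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(la, lb)
        assert [t.gene_id for t in ta] == [t.gene_id for t in tc]
        assert not np.array_equal(a.values, c.values)

    def test_values_clipped_nonnegative(self):
        mat, _, _ = generate(20, [PatternSpec("bimodal", 5, base_mean=1.0)], seed=2)
        assert mat.values.min() >= 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n_per_class"):
            generate(5, [PatternSpec("null", 1)])
        with pytest.raises(ValueError, match="at least one gene"):
            generate(10, [PatternSpec("null", 0)])

    def test_bimodal_gene_low_r_high_mic(self):
        # symmetric flanking mixture: population r = 0, but MIC well above null
        mat, labels, _ = generate(100, [PatternSpec("bimodal", 10)], seed=9)
        for row in mat.values:
            s = SampleSeries(row, labels)
            assert point_biserial(s).abs_r < 0.25
            assert mic_binary(s).mic > 0.5

    def test_linear_gene_shifts_class_means(self):
        mat, labels, _ = generate(50, [PatternSpec("linear_de", 5)], seed=10)
        diffs = mat.values[:, labels == 1].mean(1) - mat.values[:, labels == 0].mean(1)
        assert np.all(diffs > 0.8)

    def test_stratified_gene_four_levels(self):
        spec = PatternSpec("stratified", 1, base_mean=12.0)
        mat, labels, _ = generate(200, [spec], seed=11)
        x = mat.values[0]
        centers = [12 - 6, 12 - 2, 12 + 2, 12 + 6]
        counts = [np.sum(np.abs(x - c) < 1.5) for c in centers]  # 3 sd around each
        assert sum(counts) >= 395
        assert min(counts) > 50  # all four levels populated
        # inner levels come from class 0, outer from class 1 (up to rare tails)
        assert np.mean(np.abs(x[labels == 0] - 12) < 4) > 0.99
        assert np.mean(np.abs(x[labels == 1] - 12) > 4) > 0.99


class TestPairedLayout:
    @pytest.mark.parametrize("n_patients, total", [(51, 102), (72, 144)])
    def test_cohort_sizes(self, n_patients, total):
        ids, labels = paired_layout(n_patients, seed=0)
        assert len(ids) == total
        assert labels.count("tumor") == labels.count("paracarcinoma") == n_patients

    def test_ids_decode_round_trip(self):
        ids, labels = paired_layout(10, seed=3)
        patients = set()
        for sid, lab in zip(ids, labels):
            patient, tissue = decode_sample_id(sid)
            assert tissue == lab
            patients.add(patient)
        assert len(patients) == 10

    def test_bad_id_rejected(self):
        with pytest.raises(ValueError, match="format"):
            decode_sample_id("whatever")


class TestPlantedSeparation:
    def test_mean_ranks_cross_under_ndc_vs_t(self):
        # bimodal genes beat linear ones under NDC; the reverse under |t|
        from ndc.ranker import perm_threshold, score_all

        ndc_better, t_better = 0, 0
        for seed in range(5):
            mat, labels, truth = generate(
                30,
                [PatternSpec("bimodal", 5), PatternSpec("linear_de", 5),
                 PatternSpec("null", 90)],
                seed=seed,
            )
            null = perm_threshold(mat, labels, n_perm=200, seed=seed)
            scores = score_all(mat, labels, null)
            kind = {t.gene_id: t.kind for t in truth}
            by_t = sorted(scores, key=lambda s: -abs(s.t_stat))
            t_rank = {s.gene_id: i for i, s in enumerate(by_t)}
            bim = [s for s in scores if kind[s.gene_id] == "bimodal"]
            lin = [s for s in scores if kind[s.gene_id] == "linear_de"]
            if np.mean([s.rank_ndc for s in bim]) < np.mean(
                [s.rank_ndc for s in lin]
            ):
                ndc_better += 1
            if np.mean([t_rank[s.gene_id] for s in lin]) < np.mean(
                [t_rank[s.gene_id] for s in bim]
            ):
                t_better += 1
        assert ndc_better >= 4
        assert t_better >= 4
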