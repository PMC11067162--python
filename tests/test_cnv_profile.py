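"""CNV inference: smoothing oracle equivalence, reference centering, planted
segment detection, malignancy calling and sample-level event merging."""

import numpy as np
import pandas as pd
import pytest

from pdac_clonevo import (
    call_malignant,
    compare_event_frequencies,
    gene_cnv_score,
    generate_annotation,
    infer_cnv,
    merge_sample_cnv,
)
from pdac_clonevo.cnv_profile import CNVMatrix, _moving_average_block


def brute_force_moving_average(A, window):
    h = window // 2
    out = np.empty_like(A, dtype=float)
    for i in range(A.shape[1]):
        lo, hi = max(i - h, 0), min(i + h, A.shape[1] - 1)
        out[:, i] = A[:, lo : hi + 1].mean(axis=1)
    return out


def _nb_counts(rng, mu, theta=10.0):
    return rng.negative_binomial(theta, theta / (theta + np.maximum(mu, 1e-12)))


class TestSmoothing:
    @pytest.mark.parametrize("window", [3, 11, 101])
    def test_equals_brute_force_oracle(self, rng, window):
        A = rng.normal(size=(7, 200))
        assert np.allclose(_moving_average_block(A, window),
                           brute_force_moving_average(A, window), atol=1e-12)

    def test_window_larger_than_chromosome_is_full_span(self, rng):
        A = rng.normal(size=(4, 20))
        out = _moving_average_block(A, 101)
        assert np.allclose(out, A.mean(axis=1, keepdims=True), atol=1e-12)


class TestInferCNV:
    def test_parameter_validation(self, rng):
        annot = generate_annotation(50, 2, seed=0)
        X = rng.poisson(5.0, size=(10, 50))
        ids = [f"c{i}" for i in range(10)]
        import anndata as ad

        adata = ad.AnnData(X=X.astype(np.int32), obs=pd.DataFrame(index=ids), var=annot)
        with pytest.raises(ValueError, match="odd"):
            infer_cnv(adata, annot, ids[:5], window=4)
        with pytest.raises(ValueError, match="clip"):
            infer_cnv(adata, annot, ids[:5], window=5, clip=0.0)
        with pytest.raises(ValueError, match="reference"):
            infer_cnv(adata, annot, [], window=5)

    def test_identical_cells_give_flat_profiles(self, rng):
        annot = generate_annotation(100, 2, seed=1)
        row = rng.poisson(8.0, size=100)
        X = np.tile(row, (6, 1))
        cnv = infer_cnv(X, annot, pd.RangeIndex(6)[:3], window=11)
        assert np.abs(cnv.values).max() < 1e-10

    def test_reference_columns_center_near_zero(self, small_cnv):
        cnv, obs = small_cnv
        ridx = cnv.cell_ids.get_indexer(cnv.reference_cells)
        assert np.abs(cnv.values[ridx].mean(axis=0)).max() < 0.05

    def test_null_cells_stay_within_envelope(self, rng):
        """Cells statistically identical to the reference produce profiles
        inside +-0.2 nearly everywhere."""
        annot = generate_annotation(400, 2, seed=2)
        base = rng.lognormal(0.0, 1.0, 400)
        # envelope is depth-dependent: ~20 counts/gene keeps smoothed noise
        # well inside +-0.2
        mu = 8000 * base / base.sum()
        X = _nb_counts(rng, np.tile(mu, (120, 1)))
        cnv = infer_cnv(X, annot, pd.RangeIndex(120)[:60], window=101)
        targets = cnv.values[60:]
        assert (np.abs(targets) < 0.2).mean() > 0.99

    def test_planted_twofold_gain_detected(self, rng):
        """A 2-fold gain over 150 contiguous genes lifts the smoothed value of
        the segment's central 50 genes to >= 0.5 in carrier cells."""
        annot = generate_annotation(400, 1, seed=3)
        base = rng.lognormal(0.0, 1.0, 400)
        mu = 4000 * base / base.sum()
        ref = _nb_counts(rng, np.tile(mu, (100, 1)))
        mu_carrier = np.tile(mu, (80, 1))
        mu_carrier[:, 100:250] *= 2.0
        carrier = _nb_counts(rng, mu_carrier)
        X = np.vstack([ref, carrier])
        cnv = infer_cnv(X, annot, pd.RangeIndex(180)[:100], window=101)
        central = cnv.values[100:, 150:200]
        assert central.mean() >= 0.5
        # and nearly every carrier cell individually clears half that
        assert (central.mean(axis=1) >= 0.25).mean() > 0.99

    def test_gene_order_invariance(self, rng):
        annot = generate_annotation(60, 3, seed=4)
        X = rng.poisson(6.0, size=(12, 60))
        cnv = infer_cnv(X, annot, pd.RangeIndex(12)[:6], window=5)
        perm = rng.permutation(60)
        cnv_perm = infer_cnv(X[:, perm], annot.iloc[perm], pd.RangeIndex(12)[:6], window=5)
        assert np.allclose(cnv.values, cnv_perm.values, atol=1e-12)
        assert list(cnv.gene_order.index) == list(cnv_perm.gene_order.index)

    def test_all_zero_cell_flat_after_centering(self, rng):
        annot = generate_annotation(80, 1, seed=5)
        X = rng.poisson(5.0, size=(10, 80))
        X[9] = 0
        cnv = infer_cnv(X, annot, pd.RangeIndex(10)[:5], window=9)
        prof = cnv.values[9]
        assert np.abs(np.median(prof)) < 1e-10


class TestGeneScore:
    def test_accessor_returns_exact_column(self, small_cnv):
        cnv, obs = small_cnv
        gene = cnv.gene_order.index[37]
        scores, _ = gene_cnv_score(cnv, gene)
        assert np.array_equal(scores.to_numpy(), cnv.values[:, 37])

    def test_unknown_gene_lists_neighbours(self, small_cnv):
        cnv, _ = small_cnv
        with pytest.raises(KeyError, match="nearest"):
            gene_cnv_score(cnv, "g99999")

    def test_origin_comparison_on_planted_gain(self, small_cohort, small_cnv):
        """A gene inside an Lm truncal gain scores higher in Lm than in Pm1."""
        cnv, obs = small_cnv
        seg = small_cohort.truth.segment_table
        lm = seg[(seg["sample"].str.endswith("Lm")) & (seg.fold_change > 1) & seg.truncal]
        assert len(lm) > 0
        s = lm.iloc[0]
        gene = cnv.gene_order.index[(s.start_index + s.end_index) // 2]
        scores, summary = gene_cnv_score(cnv, gene, origins=obs["origin"].to_numpy(),
                                         compare=("Lm", "Pm1"))
        by_origin = summary["mean_by_origin"]
        carriers = obs["sample"] == s["sample"]
        assert scores[carriers.to_numpy()].mean() > 0.1


class TestMalignantCalls:
    def test_reference_cells_called_at_quantile_rate(self, small_cnv):
        cnv, obs = small_cnv
        calls, signal, thr = call_malignant(cnv, quantile=0.95)
        ridx = cnv.cell_ids.get_indexer(cnv.reference_cells)
        assert calls.to_numpy()[ridx].mean() == pytest.approx(0.05, abs=0.03)

    def test_segment_carriers_called(self, small_cnv):
        cnv, obs = small_cnv
        calls, _, _ = call_malignant(cnv)
        mal = obs["malignant"].to_numpy(bool)
        assert calls.to_numpy()[mal].mean() >= 0.90

    def test_few_reference_cells_warns_and_uses_null(self, small_cnv, caplog):
        cnv, _ = small_cnv
        import logging

        with caplog.at_level(logging.WARNING):
            calls, _, thr = call_malignant(cnv, reference_cells=cnv.reference_cells[:10])
        assert "reference" in caplog.text
        assert thr > 0

    def test_invalid_quantile(self, small_cnv):
        cnv, _ = small_cnv
        with pytest.raises(ValueError):
            call_malignant(cnv, quantile=1.5)


class TestSampleEvents:
    def _flat_cnv(self, rng, n_cells=20, n_genes=120):
        annot = generate_annotation(n_genes, 2, seed=9)
        order = annot.sort_values(["chromosome", "position"])
        return CNVMatrix(
            values=rng.normal(0.0, 0.01, size=(n_cells, n_genes)),
            cell_ids=pd.Index([f"c{i}" for i in range(n_cells)]),
            gene_order=order, window=11, clip=3.0,
            reference_cells=pd.Index([]),
        )

    def test_flat_cohort_has_zero_events(self, rng):
        cnv = self._flat_cnv(rng)
        table = merge_sample_cnv(cnv, np.repeat(["a", "b"], 10), np.ones(20, bool))
        assert len(table.events) == 0

    def test_threshold_above_clip_gives_zero_events(self, small_cnv):
        cnv, obs = small_cnv
        table = merge_sample_cnv(cnv, obs["sample"].to_numpy(),
                                 obs["malignant"].to_numpy(bool),
                                 event_threshold=cnv.clip + 1.0)
        assert len(table.events) == 0

    def test_sample_without_malignant_cells_excluded(self, rng):
        cnv = self._flat_cnv(rng)
        calls = np.array([True] * 10 + [False] * 10)
        table = merge_sample_cnv(cnv, np.repeat(["a", "b"], 10), calls)
        assert table.excluded_samples == ["b"]

    def test_lm_only_gain_frequency_and_fisher(self, rng):
        """A gain planted in all Lm samples and absent from Pm0 yields
        frequency 1 vs 0 and a significant Fisher test at 5 vs 5 samples."""
        cnv = self._flat_cnv(rng, n_cells=50, n_genes=120)
        samples = np.repeat([f"s{i}" for i in range(10)], 5)
        lm_cells = np.isin(samples, [f"s{i}" for i in range(5)])
        vals = cnv.values.copy()
        vals[lm_cells, 20:45] += 0.5
        cnv.values = vals
        table = merge_sample_cnv(cnv, samples, np.ones(50, bool),
                                 event_threshold=0.15, min_span=10)
        groups = pd.Series({f"s{i}": ("Lm" if i < 5 else "Pm0") for i in range(10)})
        freq = compare_event_frequencies(table, groups, "Lm", "Pm0")
        gains = freq[freq.direction == "gain"]
        assert len(gains) == 1
        assert gains["freq_Lm"].iloc[0] == 1.0
        assert gains["freq_Pm0"].iloc[0] == 0.0
        assert gains["fisher_p"].iloc[0] < 0.05

    def test_fold_change_monotonicity(self, rng):
        """A stronger planted fold change never yields a weaker smoothed
        segment mean (in expectation over cells)."""
        annot = generate_annotation(300, 1, seed=6)
        base = rng.lognormal(0.0, 1.0, 300)
        mu = 4000 * base / base.sum()
        ref = _nb_counts(rng, np.tile(mu, (80, 1)))
        means = []
        for fold in (1.5, 2.0):
            mu_c = np.tile(mu, (60, 1))
            mu_c[:, 100:200] *= fold
            X = np.vstack([ref, _nb_counts(rng, mu_c)])
            cnv = infer_cnv(X, annot, pd.RangeIndex(140)[:80], window=51)
            means.append(cnv.values[80:, 125:175].mean())
        assert means[1] > means[0]
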