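import numpy as np
import pandas as pd
import pytest

from multicnv import normalization as nz
from multicnv.targets_io import (DepthMatrix, ExonTarget, SampleMeta,
                                 build_flanked_targets)


def _depth_matrix(counts, lengths, totals):
    start, exons = 1000, []
    for i, L in enumerate(lengths):
        exons.append(ExonTarget("chr8", start, start + L, f"G{i}"))
        start += L + 5000
    regions = build_flanked_targets(exons, flank=0, merge_gap=0)
    sids = [f"s{i}" for i in range(len(totals))]
    meta = [SampleMeta(s, "CEU", "EUR", "BGI") for s in sids]
    df = pd.DataFrame(np.asarray(counts, dtype=float),
                      index=[r.region_id for r in regions], columns=sids)
    return DepthMatrix(regions, meta, df,
                       pd.Series(dict(zip(sids, map(float, totals)))))


class TestRpkm:
    @pytest.mark.parametrize("count,length,total,expected", [
        (100, 1000, 1e6, 100.0),   # unit case
        (0, 1000, 1e6, 0.0),
        (250, 500, 2e6, 250.0),    # 250 / (0.5 kb * 2 M reads)
    ])
    def test_rpkm_values(self, count, length, total, expected):
        dm = _depth_matrix([[count]], [length], [max(total, count)])
        dm.total_mapped_reads.iloc[0] = total
        rpkm = nz.compute_rpkm(dm)
        assert rpkm.values.iloc[0, 0] == pytest.approx(expected)

    def test_zero_total_reads_names_sample(self):
        dm = _depth_matrix([[0]], [1000], [1e6])
        dm.total_mapped_reads.iloc[0] = 0.0
        with pytest.raises(ValueError, match="s0"):
            nz.compute_rpkm(dm)


class TestLowCoverageFilter:
    def test_strict_threshold_semantics(self):
        vals = pd.DataFrame({"below": [49.99], "at": [50.0], "above": [100.0]})
        rpkm = nz.RpkmMatrix(vals, np.array([1000.0]))
        kept, discarded = nz.filter_low_coverage_samples(rpkm)
        assert discarded == ["below"]
        assert list(kept.values.columns) == ["at", "above"]

    def test_all_samples_discarded_is_an_error(self):
        rpkm = nz.RpkmMatrix(pd.DataFrame({"a": [1.0], "b": [2.0]}),
                             np.array([1000.0]))
        with pytest.raises(ValueError, match="below mean RPKM"):
            nz.filter_low_coverage_samples(rpkm)

    def test_qc_report_partitions_exhaustively(self):
        vals = pd.DataFrame({"a": [10.0], "b": [100.0]})
        report = nz.qc_report(nz.RpkmMatrix(vals, np.array([1000.0])))
        assert sorted(report["status"]) == ["discarded", "kept"]


class TestZrpkm:
    def test_median_location_and_sample_sd_scale(self):
        rpkm = nz.RpkmMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc")),
            np.array([1000.0]))
        z = nz.zrpkm(rpkm)
        assert z.values.values.tolist() == [[-1.0, 0.0, 1.0]]
        assert z.location.iloc[0] == 2.0 and z.scale.iloc[0] == 1.0

    def test_constant_target_excluded_with_warning(self, caplog):
        rpkm = nz.RpkmMatrix(
            pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                         index=["flat", "ok"], columns=list("abc")),
            np.array([1000.0, 1000.0]))
        with caplog.at_level("WARNING"):
            z = nz.zrpkm(rpkm)
        assert z.excluded_targets == ["flat"]
        assert list(z.values.index) == ["ok"]

    def test_batch_below_three_samples_rejected(self):
        rpkm = nz.RpkmMatrix(pd.DataFrame([[1.0]], columns=["a"]),
                             np.array([1000.0]))
        with pytest.raises(ValueError, match="at least 3"):
            nz.zrpkm(rpkm)


class TestScree:
    def test_rank_one_signal_suggests_one_component(self):
        rng = np.random.default_rng(0)
        m = np.outer(rng.normal(size=30), rng.normal(size=20)) \
            + 1e-3 * rng.normal(size=(30, 20))
        _, k = nz.scree(m)
        assert k == 1

    def test_iid_noise_suggests_few_components(self):
        for seed in range(5):
            m = np.random.default_rng(seed).normal(size=(40, 30))
            _, k = nz.scree(m)
            assert k <= 2

    def test_zero_matrix_suggests_nothing(self):
        s, k = nz.scree(np.zeros((4, 4)))
        assert k == 0 and s[0] == 0


class TestRemoveComponents:
    def test_k_zero_is_identity(self):
        m = np.random.default_rng(1).normal(size=(5, 4))
        out, decomp = nz.remove_components(m, 0)
        assert np.allclose(out, m, atol=1e-10)
        assert decomp.k_removed == 0

    def test_rank_one_input_annihilated_by_k_one(self):
        m = np.outer([1.0, 2.0, 3.0], [4.0, 5.0])
        out, _ = nz.remove_components(m, 1)
        assert np.allclose(out, 0, atol=1e-10)

    def test_matches_independent_partial_reconstruction(self):
        """Residual must equal sum_{i>k} s_i u_i v_i^T from a full SVD
        computed independently (scipy), to 1e-10 in Frobenius norm."""
        import scipy.linalg

        rng = np.random.default_rng(2)
        for trial in range(5):
            m = rng.normal(size=(5, 4))
            k = 2
            u, s, vt = scipy.linalg.svd(m, full_matrices=False)
            oracle = sum(s[i] * np.outer(u[:, i], vt[i]) for i in range(k, 4))
            out, _ = nz.remove_components(m, k)
            assert np.linalg.norm(out - oracle) < 1e-10

    def test_norm_non_increasing_in_k(self):
        m = np.random.default_rng(3).normal(size=(6, 5))
        norms = [np.linalg.norm(nz.remove_components(m, k)[0])
                 for k in range(6)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[0] <= np.linalg.norm(m) + 1e-12

    def test_residual_orthogonal_to_removed_part(self):
        m = np.random.default_rng(4).normal(size=(6, 5))
        out, _ = nz.remove_components(m, 2)
        removed = m - out
        assert abs(np.sum(out * removed)) < 1e-8

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            nz.remove_components(np.zeros((3, 3)), 4)


class TestGeneMeanSignal:
    def _table(self):
        return pd.DataFrame([[1.0, 10.0], [3.0, 30.0], [5.0, 50.0],
                             [7.0, 70.0]],
                            index=list("wxyz"), columns=["s1", "s2"])

    def test_single_target_gene_passes_value_through(self):
        per_gene, _ = nz.gene_mean_signal(self._table(), {"g": ["w"]}, ["g"])
        assert per_gene.loc["g", "s1"] == 1.0

    def test_two_target_gene_averages(self):
        per_gene, _ = nz.gene_mean_signal(self._table(), {"g": ["w", "x"]},
                                          ["g"])
        assert per_gene.loc["g", "s1"] == 2.0

    def test_set_mean_weights_by_targets_not_genes(self):
        # gene a: 1 target {1}, gene b: 3 targets {3,5,7};
        # target-weighted mean 4.0, not mean-of-means 3.0
        gm = {"a": ["w"], "b": ["x", "y", "z"]}
        _, pooled = nz.gene_mean_signal(self._table(), gm, ["a", "b"])
        assert pooled["s1"] == pytest.approx(4.0)

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            nz.gene_mean_signal(self._table(), {"g": ["w"]}, ["nope"])


def test_svd_removal_strips_injected_artifact_but_not_cn(default_cohort,
                                                         default_cohort_results):
    """Injected rank-1 centre artifact: after component removal the
    per-sample gene-set signal must decorrelate from the artifact loading
    (|r| <= 0.1) while staying correlated with true CN (r >= 0.9)."""
    cohort = default_cohort
    results, _ = default_cohort_results
    truth = cohort.truth
    for r in results:
        assert r.error is None
        sig = r.signal
        cn = truth.true_cn[sig.index]
        loading = truth.artifact_loadings.loc[sig.index, "loading_0"]
        assert np.corrcoef(sig, cn)[0, 1] >= 0.9
        assert abs(np.corrcoef(sig, loading)[0, 1]) <= 0.1
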