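"""P-value schemes: permutation nulls, gamma correction, BH FDR, scan."""

import numpy as np
import pytest
import scipy.stats

from geneqx.errors import ValidationError
from geneqx.neutral import estimate_F_arrays
from geneqx.pvalues import (
    PermutationConfig,
    ScanConfig,
    bh_fdr,
    effperm_pvalue,
    freqperm_pvalue,
    gamma_pvalues,
    scan,
    write_results,
)
from geneqx.synth import FrequencyModel, SelectionInjection, generate_dataset, generate_panel, inject_selection

from conftest import make_model, make_panel


@pytest.fixture(scope="module")
def F5():
    panel = generate_panel(FrequencyModel(), 3000, seed=4)
    return estimate_F_arrays(panel.freqs.to_numpy()).matrix


@pytest.fixture(scope="module")
def matched_freqs():
    rng = np.random.default_rng(7)
    return rng.uniform(0.1, 0.9, (3, 50, 5))  # L=3, k=50, M=5


class TestPermutationConfig:
    def test_rejects_inverted_limits(self):
        with pytest.raises(ValidationError):
            PermutationConfig(n_initial=100, n_max=10)

    def test_rejects_bad_escalation(self):
        with pytest.raises(ValidationError):
            PermutationConfig(escalate_below=0.0)


class TestFreqPerm:
    def test_zero_qx_gives_p_one(self, F5, matched_freqs):
        # equal frequencies in every population -> Z' = 0 -> all null >= 0
        w = np.array([0.5, -0.2, 1.0])
        P = np.tile(np.array([[0.3], [0.5], [0.7]]), (1, 5))
        cfg = PermutationConfig(n_initial=500, n_max=500)
        p = freqperm_pvalue(w, P, F5, matched_freqs, cfg, np.random.default_rng(0))
        assert p == 1.0

    def test_deterministic_under_seed(self, F5, matched_freqs, rng):
        w = np.array([0.5, -0.2, 1.0])
        P = rng.uniform(0.2, 0.8, (3, 5))
        cfg = PermutationConfig(n_initial=400, n_max=400)
        p1 = freqperm_pvalue(w, P, F5, matched_freqs, cfg, np.random.default_rng(5))
        p2 = freqperm_pvalue(w, P, F5, matched_freqs, cfg, np.random.default_rng(5))
        assert p1 == p2

    def test_bounds(self, F5, matched_freqs, rng):
        w = rng.normal(0, 1, 3)
        P = rng.uniform(0.2, 0.8, (3, 5))
        cfg = PermutationConfig(n_initial=200, n_max=200)
        p = freqperm_pvalue(w, P, F5, matched_freqs, cfg, rng)
        assert 0 < p <= 1

    def test_escalation_reaches_n_max(self, F5, rng):
        # an extreme observed gene escalates and yields P = 1/(n_max+1)
        w = np.array([2.0, 2.0, 2.0])
        P = rng.uniform(0.45, 0.55, (3, 5))
        P[:, 0] = 0.99  # huge coordinated shift far outside the matched pool
        matched = rng.uniform(0.45, 0.55, (3, 40, 5))
        cfg = PermutationConfig(n_initial=200, n_max=2000, escalate_below=0.01)
        p = freqperm_pvalue(w, P, F5, matched, cfg, rng)
        assert p == pytest.approx(1.0 / 2001)


class TestEffPerm:
    def test_single_variant_scale_invariance_gives_p_one(self, F5, rng):
        w = np.array([0.7])
        P = rng.uniform(0.2, 0.8, (1, 5))
        pool = rng.normal(0, 1, 500)
        cfg = PermutationConfig(n_initial=1000, n_max=1000)
        assert effperm_pvalue(w, P, F5, pool, cfg, rng) == 1.0

    def test_coordinated_gene_with_max_magnitudes_is_extreme(self, F5):
        # all weights at the pool's maximal magnitude, frequency differences
        # aligned with the effect signs -> observed in the upper tail
        rng = np.random.default_rng(11)
        fm = FrequencyModel()
        panel = generate_panel(fm, 6, seed=12)
        model = make_model([3.0, 3.0, 3.0, 3.0, 3.0, 3.0])
        panel.freqs.index = [v.variant_id for v in model.variants]
        shifted = inject_selection(
            panel, model, SelectionInjection(target_pop="POP5", shift_sd_units=1.0)
        )
        pool = np.concatenate([rng.normal(0, 0.3, 400), [3.0]])
        cfg = PermutationConfig(n_initial=2000, n_max=2000)
        p = effperm_pvalue(
            model.weights,
            shifted.freq_matrix(model.variant_ids),
            F5,
            pool,
            cfg,
            rng,
        )
        assert p < 0.05

    def test_empty_pool_errors(self, F5, rng):
        with pytest.raises(ValidationError):
            effperm_pvalue(np.array([1.0]), rng.uniform(0.2, 0.8, (1, 5)), F5, [], None, rng)

    def test_deterministic_under_seed(self, F5, rng):
        w = rng.normal(0, 1, 4)
        P = rng.uniform(0.2, 0.8, (4, 5))
        pool = rng.normal(0, 1, 300)
        cfg = PermutationConfig(n_initial=500, n_max=500)
        p1 = effperm_pvalue(w, P, F5, pool, cfg, np.random.default_rng(3))
        p2 = effperm_pvalue(w, P, F5, pool, cfg, np.random.default_rng(3))
        assert p1 == p2


class TestGamma:
    def test_parameter_recovery_chi2(self):
        scores = scipy.stats.chi2.rvs(4, size=5000, random_state=np.random.default_rng(1))
        fit, _ = gamma_pvalues(scores)
        assert fit.shape == pytest.approx(2.0, rel=0.1)
        assert fit.scale == pytest.approx(2.0, rel=0.1)

    def test_identical_scores_error(self):
        with pytest.raises(ValidationError):
            gamma_pvalues(np.full(100, 3.0))

    def test_median_score_has_p_half(self):
        scores = scipy.stats.chi2.rvs(4, size=2000, random_state=np.random.default_rng(2))
        fit, _ = gamma_pvalues(scores)
        med = scipy.stats.gamma.ppf(0.5, fit.shape, scale=fit.scale)
        _, p = gamma_pvalues(np.concatenate([scores, [med]]))
        assert p[-1] == pytest.approx(0.5, abs=1e-6)

    def test_nonpositive_scores_excluded_and_p_one(self):
        scores = np.concatenate(
            [scipy.stats.chi2.rvs(4, size=200, random_state=3), [0.0, -1.0]]
        )
        fit, p = gamma_pvalues(scores)
        assert fit.n_excluded == 2
        assert p[-1] == 1.0 and p[-2] == 1.0

    def test_ordering_matches_raw_qx(self):
        scores = scipy.stats.chi2.rvs(4, size=300, random_state=4)
        _, p = gamma_pvalues(scores)
        rho = scipy.stats.spearmanr(p, -scores).statistic
        assert rho == pytest.approx(1.0)


class TestBhFdr:
    def test_hand_case(self):
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_gene_q_equals_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_one_stays_one(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_zero(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.0, 0.5])


class TestScan:
    def test_empty_model_list(self, null_dataset):
        res = scan([], null_dataset.panel, null_dataset.neutral_panel)
        assert len(res.table) == 0

    def test_neutral_genes_not_significant(self, null_dataset):
        # 10 synthetic neutral genes, gamma scheme: no q below 0.1
        res = scan(
            null_dataset.models[:10],
            null_dataset.panel,
            null_dataset.neutral_panel,
            ScanConfig(schemes=("gamma",), seed=0),
        )
        assert (res.table["q_gamma"].dropna() > 0.1).all()

    def test_rerun_same_seed_byte_identical(self, null_dataset, tmp_path):
        cfg = ScanConfig(
            schemes=("gamma", "freqperm"),
            perm=PermutationConfig(n_initial=200, n_max=200),
            seed=7,
        )
        paths = []
        for name in ("a.tsv", "b.tsv"):
            res = scan(
                null_dataset.models[:8], null_dataset.panel, null_dataset.neutral_panel, cfg
            )
            path = tmp_path / name
            write_results(res.table, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_degenerate_gene_flagged_not_dropped(self, null_dataset):
        fixed = make_model([1.0], gene_id="FIXED", prefix="fx")
        panel = null_dataset.panel.freqs.copy()
        for v in fixed.variants:
            panel.loc[v.variant_id] = 1.0  # fixed everywhere -> VA = 0
        from geneqx.models import FrequencyPanel

        res = scan(
            null_dataset.models[:12] + [fixed],
            FrequencyPanel(panel),
            null_dataset.neutral_panel,
            ScanConfig(schemes=("gamma",), seed=1),
        )
        row = res.table.set_index("gene_id").loc["FIXED"]
        assert row["status"] == "degenerate_va"
        assert len(res.table) == 13

    def test_scheme_correlation_diagnostic_reported(self, null_dataset):
        cfg = ScanConfig(
            schemes=("gamma", "freqperm"),
            perm=PermutationConfig(n_initial=300, n_max=300),
            seed=3,
        )
        res = scan(
            null_dataset.models[:15], null_dataset.panel, null_dataset.neutral_panel, cfg
        )
        assert "spearman_gamma_freqperm" in res.diagnostics
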