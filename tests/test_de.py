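"""Differential expression: size factors, fold changes, NB LRT calibration,
BH adjustment, and threshold filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from cardiotransit.de import (
    CountMatrix,
    bh_adjust,
    de_table,
    estimate_dispersion,
    filter_degs,
    log2fc_median_norm,
    nb_lrt_test,
    normalized_counts,
    read_counts_tsv,
    size_factors,
    write_counts_tsv,
    write_design_tsv,
)


def _matrix(arr, groups=None):
    arr = np.atleast_2d(np.asarray(arr))
    samples = [f"s{i}" for i in range(arr.shape[1])]
    counts = pd.DataFrame(arr, columns=samples,
                          index=[f"g{i}" for i in range(arr.shape[0])])
    if groups is None:
        groups = {s: "A" for s in samples}
    else:
        groups = dict(zip(samples, groups))
    return CountMatrix(counts, groups)


class TestSizeFactors:
    def test_identical_columns_get_equal_factors(self, rng):
        col = rng.poisson(100, 50)
        cm = _matrix(np.column_stack([col, col, col]))
        sf = size_factors(cm.counts)
        assert np.allclose(sf, sf.iloc[0])

    def test_scaled_column_scales_factor(self, rng):
        col = rng.poisson(100, 200) + 1
        cm = _matrix(np.column_stack([col, col * 3]))
        sf = size_factors(cm.counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(3.0)
        # normalized counts are unchanged by the scaling
        norm = normalized_counts(cm.counts)
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_single_gene_hand_example(self):
        """counts {4, 9}, geometric mean 6: factors {4/6, 9/6}."""
        sf = size_factors(pd.DataFrame([[4, 9]], columns=["a", "b"]))
        assert sf["a"] == pytest.approx(4 / 6)
        assert sf["b"] == pytest.approx(9 / 6)

    def test_no_universally_expressed_gene_is_an_error(self):
        counts = pd.DataFrame([[0, 5], [5, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="size factors"):
            size_factors(counts)


class TestLog2FC:
    def test_identical_groups_give_zero(self, rng):
        col = rng.poisson(200, 100)
        arr = np.column_stack([col, col, col, col])
        cm = _matrix(arr, groups=["A", "A", "B", "B"])
        lfc = log2fc_median_norm(cm.counts, cm.groups, ("B", "A"))
        assert np.allclose(lfc, 0.0, atol=1e-12)

    def test_fourfold_counts_give_lfc_two(self, rng):
        base = rng.poisson(5000, 300)
        arr = np.column_stack([base, base, base * 4, base * 4])
        cm = _matrix(arr, groups=["A", "A", "B", "B"])
        # equal library sizes are enforced so normalization is neutral
        sf = pd.Series(1.0, index=cm.counts.columns)
        lfc = log2fc_median_norm(cm.counts, cm.groups, ("B", "A"), factors=sf)
        assert lfc.mean() == pytest.approx(2.0, abs=0.01)

    def test_empty_group_rejected(self, rng):
        cm = _matrix(np.ones((3, 2)), groups=["A", "A"])
        with pytest.raises(ValueError, match="empty"):
            log2fc_median_norm(cm.counts, cm.groups, ("B", "A"))


class TestNbLrt:
    def test_all_zero_gene_gets_p_one(self):
        arr = np.vstack([np.zeros(6), np.full(6, 50.0)])
        cm = _matrix(arr, groups=["A"] * 3 + ["B"] * 3)
        p = nb_lrt_test(cm.counts, cm.groups, ("B", "A"))
        assert p.iloc[0] == 1.0

    def test_statistic_matches_numeric_likelihood_maximization(self):
        """Single-gene oracle: brute-force ML over the null and per-group
        means at the same fixed dispersion reproduces 2*deltalogL."""
        y = np.array([[0.0, 1.0, 50.0, 60.0]])
        groups = ["A", "A", "B", "B"]
        cm = _matrix(y, groups=groups)
        sf = pd.Series(1.0, index=cm.counts.columns)
        p = nb_lrt_test(cm.counts, cm.groups, ("B", "A"), factors=sf)
        lrt_impl = sps.chi2.isf(p.iloc[0], 1)

        alpha = estimate_dispersion(
            y, np.ones(4), [np.array([0, 1]), np.array([2, 3])]
        )[0]

        def negloglik(mu, counts):
            mu = float(mu)
            if mu <= 0:
                return np.inf
            return -np.sum(sps.nbinom.logpmf(counts, 1 / alpha, 1 / (1 + alpha * mu)))

        ll_null = -optimize.minimize_scalar(
            negloglik, bounds=(1e-6, 1e4), args=(y[0],), method="bounded"
        ).fun
        ll_alt = sum(
            -optimize.minimize_scalar(
                negloglik, bounds=(1e-6, 1e4), args=(y[0, i : i + 2],), method="bounded"
            ).fun
            for i in (0, 2)
        )
        lrt_oracle = 2 * (ll_alt - ll_null)
        assert lrt_impl == pytest.approx(lrt_oracle, rel=1e-3)

    def test_null_p_values_are_uniform(self):
        """Identical groups, NB noise: KS distance to Uniform(0,1) < 0.05
        at 2000 genes."""
        rng = np.random.default_rng(0)
        G, n_c, n_t = 2000, 4, 5
        mu0 = rng.lognormal(np.log(150), 1.0, G)
        sf_true = rng.uniform(0.7, 1.4, n_c + n_t)
        r = 1 / 0.05
        mu = sf_true[None, :] * mu0[:, None]
        y = rng.negative_binomial(r, r / (r + mu))
        cm = _matrix(y, groups=["A"] * n_c + ["B"] * n_t)
        p = nb_lrt_test(cm.counts, cm.groups, ("B", "A"))
        assert sps.kstest(p, "uniform").statistic < 0.05

    def test_needs_two_samples_per_group(self):
        cm = _matrix(np.ones((2, 3)), groups=["A", "B", "B"])
        with pytest.raises(ValueError):
            nb_lrt_test(cm.counts, cm.groups, ("B", "A"))


class TestBH:
    def test_all_ones(self):
        assert np.all(bh_adjust(np.ones(10)) == 1.0)

    def test_hand_example(self):
        """p = {.01,.02,.03,.04}, m = 4: every q = 0.04."""
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.123]))[0] == pytest.approx(0.123)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_statsmodels(self, ps):
        p = np.asarray(ps)
        ours = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=100))
    def test_monotone_in_ranks(self, ps):
        p = np.asarray(ps)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestFilter:
    def test_empty_input(self):
        df = pd.DataFrame(columns=["gene_id", "log2fc", "q_value"])
        assert len(filter_degs(df)) == 0

    def test_toy_enumeration(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [1.2, 0.8, -1.5],
                "q_value": [0.01, 0.01, 0.2],
            }
        )
        out = filter_degs(df, 1.0, 0.05)
        assert out["gene_id"].tolist() == ["a"]
        assert out["direction"].tolist() == ["up"]

    def test_ipsc_cm_threshold_variant(self):
        """The looser (0.5, 0.05) setting used for the knock-out CM screen."""
        df = pd.DataFrame(
            {"gene_id": ["a", "b"], "log2fc": [0.7, -0.6], "q_value": [0.01, 0.02]}
        )
        out = filter_degs(df, 0.5, 0.05)
        assert set(out["gene_id"]) == {"a", "b"}
        assert out.set_index("gene_id")["direction"]["b"] == "down"

    def test_nonpositive_thresholds_rejected(self):
        df = pd.DataFrame({"gene_id": [], "log2fc": [], "q_value": []})
        with pytest.raises(ValueError):
            filter_degs(df, 0.0, 0.05)


class TestEndToEnd:
    def _simulate(self, seed, G=2000, frac_de=0.05, lfc=2.0, mu=200.0, alpha=0.05,
                  n=5):
        rng = np.random.default_rng(seed)
        n_de = int(G * frac_de)
        true_lfc = np.zeros(G)
        true_lfc[:n_de] = lfc * np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
        sf = rng.uniform(0.8, 1.2, 2 * n)
        mu_mat = sf[None, :] * mu * np.ones((G, 1))
        mu_mat[:, n:] *= 2.0 ** true_lfc[:, None]
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu_mat))
        cm = _matrix(y, groups=["A"] * n + ["B"] * n)
        return cm, true_lfc

    def test_fdr_control_with_planted_effects(self):
        """Realized FDR of the (1, 0.05) filter stays <= 0.10 over 20
        replicates with 5% planted log2FC = 2 effects."""
        false = total = 0
        for seed in range(20):
            cm, true_lfc = self._simulate(seed)
            table = de_table(cm, ("B", "A"))
            hits = filter_degs(table, 1.0, 0.05)
            idx = hits.index.to_numpy()
            false += int((true_lfc[idx] == 0).sum())
            total += len(idx)
        assert total > 0
        assert false / total <= 0.10

    def test_power_on_strong_effects(self):
        """>= 90% of planted log2FC = 2 genes at mu = 200 pass the filter."""
        cm, true_lfc = self._simulate(99, G=1000, frac_de=0.10)
        table = de_table(cm, ("B", "A"))
        hits = set(filter_degs(table, 1.0, 0.05)["gene_id"])
        planted = [f"g{i}" for i in np.nonzero(true_lfc)[0]]
        sensitivity = np.mean([g in hits for g in planted])
        assert sensitivity >= 0.90

    def test_tsv_roundtrip(self, tmp_path, rng):
        cm = _matrix(rng.poisson(50, (20, 4)), groups=["A", "A", "B", "B"])
        write_counts_tsv(cm, tmp_path / "counts.tsv")
        write_design_tsv(cm.groups, tmp_path / "design.tsv")
        back = read_counts_tsv(tmp_path / "counts.tsv", tmp_path / "design.tsv")
        assert np.array_equal(back.counts.to_numpy(), cm.counts.to_numpy())
        assert back.groups == cm.groups
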