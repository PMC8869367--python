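import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rgstab import (
    CtMatrix,
    RgstabError,
    bestkeeper,
    delta_ct_stability,
    genorm,
    normfinder,
    pairwise_variation,
    run_all,
)


def make(rows: dict, condition: dict | None = None) -> CtMatrix:
    vals = pd.DataFrame(rows).T
    n = vals.shape[1]
    vals.columns = [f"S{j}" for j in range(n)]
    cond = condition or {c: "CTRL" for c in vals.columns}
    return CtMatrix(values=vals, condition=cond)


class TestPairwiseVariation:
    def test_hand_computed_sd_of_differences(self):
        m = make({"a": [20, 21, 22], "b": [20, 22, 21]})
        assert pairwise_variation(m, "a", "b") == pytest.approx(1.0)

    def test_self_and_constant_offset_are_zero(self):
        m = make({"a": [20, 21, 22], "b": [23, 24, 25]})
        assert pairwise_variation(m, "a", "a") == 0.0
        assert pairwise_variation(m, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, random_matrix_factory):
        m = random_matrix_factory(seed=2)
        a, b = m.gene_ids[0], m.gene_ids[3]
        assert pairwise_variation(m, a, b) == pairwise_variation(m, b, a)


class TestGenorm:
    def test_toy_stepwise_exclusion(self, toy_matrix):
        """V(G1,G2)=0, V(G1,G3)=V(G2,G3)=1: G3 removed at M=1, final pair M=0."""
        t = genorm(toy_matrix)
        assert t.metric.to_dict() == {"G1": 0.0, "G2": 0.0, "G3": 1.0}
        assert t.extras.exclusion_order == ["G3"]
        assert set(t.extras.final_pair) == {"G1", "G2"}
        assert t.rank.to_dict() == {"G1": 1, "G2": 1, "G3": 3}

    def test_duplicated_gene_pair_wins_with_zero_m(self, random_matrix_factory):
        m = random_matrix_factory(seed=4, n_genes=6)
        m.values.loc["dup"] = m.values.loc["g0"] + 1.5
        t = genorm(m)
        assert set(t.extras.final_pair) == {"g0", "dup"}
        assert t.metric["g0"] == pytest.approx(0.0, abs=1e-12)

    def test_final_pair_shares_m_exactly(self, random_matrix_factory):
        for seed in range(10):
            t = genorm(random_matrix_factory(seed=seed))
            a, b = t.extras.final_pair
            assert t.metric[a] == t.metric[b]

    def test_requires_three_genes(self):
        m = make({"a": [20, 21, 22], "b": [20, 22, 21]})
        with pytest.raises(RgstabError):
            genorm(m)


class TestDeltaCt:
    def test_toy_mean_pairwise_sd(self, toy_matrix):
        t = delta_ct_stability(toy_matrix)
        assert t.metric.to_dict() == pytest.approx({"G1": 0.5, "G2": 0.5, "G3": 1.0})

    def test_equals_pre_exclusion_genorm_m(self, random_matrix_factory):
        """Same formula as geNorm's first iteration, checked pair by pair."""
        for seed in range(20):
            m = random_matrix_factory(seed=seed)
            t = delta_ct_stability(m)
            genes = m.gene_ids
            for g in genes:
                expected = np.mean(
                    [pairwise_variation(m, g, k) for k in genes if k != g]
                )
                assert t.metric[g] == pytest.approx(expected, abs=1e-12)


from _helpers import normfinder_sigma2_oracle


class TestNormFinder:
    def test_perfectly_additive_data_has_zero_metrics(self):
        rows = {f"g{i}": [10 + i + j for j in range(5)] for i in range(4)}
        t = normfinder(make(rows))
        assert np.allclose(t.metric, 0.0, atol=1e-9)

    def test_matches_brute_force_estimating_equations(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            arr = rng.uniform(10, 30, size=(5, 8))
            m = CtMatrix(values=pd.DataFrame(
                arr, index=[f"g{i}" for i in range(5)],
                columns=[f"s{j}" for j in range(8)]))
            t = normfinder(m)
            expected = normfinder_sigma2_oracle(arr)
            got = t.extras.intragroup_variance["single"].to_list()
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_metric_tracks_true_noise_levels(self):
        """Noise recovery at n=6: the noisiest gene lands last and the
        metric order correlates positively with the true noise order."""
        last_ok = rho_pos = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            sds = [0.05, 0.1, 0.3, 0.6]
            vals = pd.DataFrame(
                [20 + rng.normal(0, s, 6) for s in sds],
                index=list("ABCD"), columns=[f"S{j}" for j in range(6)])
            t = normfinder(CtMatrix(values=vals))
            last_ok += t.metric.idxmax() == "D"
            rho = stats.spearmanr(range(4), [t.metric[g] for g in "ABCD"]).statistic
            rho_pos += rho > 0
        assert last_ok / reps >= 0.85
        assert rho_pos / reps >= 0.95

    def test_by_condition_mode_two_groups(self, random_matrix_factory):
        m = random_matrix_factory(seed=6)
        t = normfinder(m, mode="by_condition")
        assert t.extras.groups_used == ["CTRL", "SF"]
        assert (t.extras.intragroup_variance >= 0).all().all()
        # per-gene intergroup differences must balance across the two groups
        d = t.extras.intergroup_difference
        np.testing.assert_allclose(d.sum(axis=1), 0.0, atol=1e-9)

    def test_by_condition_detects_treatment_shifted_gene(self):
        rng = np.random.default_rng(5)
        rows = {f"g{i}": list(20 + rng.normal(0, 0.1, 8)) for i in range(5)}
        rows["shifted"] = list(np.r_[20 + rng.normal(0, 0.1, 4), 23 + rng.normal(0, 0.1, 4)])
        cond = {f"S{j}": ("CTRL" if j < 4 else "SF") for j in range(8)}
        m = make(rows, condition=cond)
        t = normfinder(m, mode="by_condition")
        assert t.metric.idxmax() == "shifted"

    def test_requires_three_genes(self):
        m = make({"a": [20, 21, 22], "b": [20, 22, 21]})
        with pytest.raises(RgstabError):
            normfinder(m)


class TestBestKeeper:
    def test_hand_computed_descriptives(self):
        t = bestkeeper(make({"a": [20, 21, 22], "b": [25, 25, 25]}))
        d = t.extras.descriptives.loc["a"]
        assert d["ar_mean"] == pytest.approx(21.0)
        assert d["sd"] == pytest.approx(2 / 3)
        assert d["geo_mean"] == pytest.approx((20 * 21 * 22) ** (1 / 3))
        assert d["min"] == 20 and d["max"] == 22

    def test_constant_gene_has_zero_sd_and_cv(self):
        t = bestkeeper(make({"a": [20, 21, 22], "b": [25, 25, 25]}))
        d = t.extras.descriptives.loc["b"]
        assert d["sd"] == 0.0 and d["cv_pct"] == 0.0

    def test_constant_offset_shifts_mean_not_sd(self):
        a = bestkeeper(make({"a": [20, 21, 22], "b": [21, 22, 20]}))
        b = bestkeeper(make({"a": [25, 26, 27], "b": [21, 22, 20]}))
        assert a.extras.descriptives.loc["a", "sd"] == b.extras.descriptives.loc["a", "sd"]
        assert b.extras.descriptives.loc["a", "ar_mean"] == pytest.approx(26.0)

    def test_geometric_mean_never_exceeds_arithmetic(self, random_matrix_factory):
        t = bestkeeper(random_matrix_factory(seed=8))
        d = t.extras.descriptives
        assert (d["geo_mean"] <= d["ar_mean"] + 1e-12).all()

    def test_index_correlation_bounded(self, random_matrix_factory):
        t = bestkeeper(random_matrix_factory(seed=10))
        assert t.extras.index_correlation.abs().max() <= 1.0 + 1e-12

    def test_sd_option_uses_sample_sd(self):
        m = make({"a": [20.0, 21.0, 22.0], "b": [25, 25.5, 25.2]})
        t = bestkeeper(m, dispersion="sd")
        assert t.extras.descriptives.loc["a", "sd"] == pytest.approx(1.0)


class TestInvariances:
    """Shift / permutation behavior shared by the four algorithms."""

    @staticmethod
    def metrics(m: CtMatrix) -> dict[str, pd.Series]:
        return {t.algorithm: t.metric for t in run_all(m)}

    def test_per_sample_shifts_leave_pairwise_algorithms_unchanged(
        self, random_matrix_factory
    ):
        m = random_matrix_factory(seed=21)
        shifted = m.copy()
        shifts = np.arange(m.values.shape[1]) * 0.7
        shifted.values.iloc[:, :] = m.values.to_numpy() + shifts[None, :]
        a, b = self.metrics(m), self.metrics(shifted)
        for alg in ("genorm", "normfinder", "delta_ct"):
            np.testing.assert_allclose(a[alg], b[alg], atol=1e-9)
        # BestKeeper measures raw dispersion, so nonuniform shifts must show up
        assert not np.allclose(a["bestkeeper"], b["bestkeeper"], atol=1e-9)

    def test_single_gene_shift_leaves_all_metrics_unchanged(self, random_matrix_factory):
        m = random_matrix_factory(seed=22)
        shifted = m.copy()
        shifted.values.loc["g4"] += 3.21
        a, b = self.metrics(m), self.metrics(shifted)
        for alg in a:
            np.testing.assert_allclose(a[alg], b[alg], atol=1e-9)

    def test_sample_permutation_invariance(self, random_matrix_factory):
        m = random_matrix_factory(seed=23)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(m.sample_ids))
        permuted = m.subset(samples=perm)
        a, b = self.metrics(m), self.metrics(permuted)
        for alg in a:
            np.testing.assert_allclose(a[alg], b[alg], atol=1e-9)

    def test_all_metrics_nonnegative(self, random_matrix_factory):
        for seed in range(5):
            for t in run_all(random_matrix_factory(seed=seed)):
                assert (t.metric >= 0).all()

    def test_spike_row_excluded_from_candidates(self, random_matrix_factory):
        m = random_matrix_factory(seed=24)
        with_spike = m.copy()
        with_spike.values.loc["spike"] = np.linspace(13, 16, 6)
        with_spike.spike_gene = "spike"
        a, b = self.metrics(m), self.metrics(with_spike)
        for alg in a:
            np.testing.assert_allclose(a[alg], b[alg], atol=1e-12)
            assert "spike" not in b[alg].index
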