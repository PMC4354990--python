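import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from trioepi import subtypes

from conftest import trio_sheet, truth_subgroup_patients


def two_group_beta(rng, n_probes=300, n_per_group=8, delta=0.4, n_sep=100):
    cols = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    base = rng.uniform(0.2, 0.8, size=n_probes)
    beta = pd.DataFrame(
        np.clip(base[:, None] + rng.normal(0, 0.05, size=(n_probes, 2 * n_per_group)), 0.01, 0.99),
        index=[f"cg{i}" for i in range(n_probes)], columns=cols,
    )
    beta.iloc[:n_sep, n_per_group:] = np.clip(
        beta.iloc[:n_sep, n_per_group:] + delta, 0.01, 0.99
    )
    return beta


class TestConsensusCluster:
    def test_separated_groups_perfectly_recovered(self, rng):
        hits = 0
        for seed in range(5):
            beta = two_group_beta(np.random.default_rng(seed))
            res = subtypes.consensus_cluster(beta, k=2, n_resamples=100, seed=seed)
            truth = [0] * 8 + [1] * 8
            hits += adjusted_rand_score(truth, res.assignments.values) == 1.0
        assert hits >= 4

    def test_consensus_matrix_contract(self, rng):
        beta = two_group_beta(rng)
        res = subtypes.consensus_cluster(beta, k=2, n_resamples=100, seed=0)
        m = res.consensus.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert m.min() >= 0 and m.max() <= 1

    def test_identical_samples_are_degenerate(self):
        beta = pd.DataFrame(0.5, index=[f"cg{i}" for i in range(50)],
                            columns=[f"s{i}" for i in range(6)])
        beta += np.linspace(0, 1e-9, 50)[:, None]  # break exact zero distances
        res = subtypes.consensus_cluster(beta, k=2, n_resamples=50, seed=0)
        off_diag = res.consensus.to_numpy()[np.triu_indices(6, 1)]
        assert off_diag.mean() > 0.45  # samples co-cluster at chance or above

    def test_k_selection_prefers_true_structure(self, rng):
        beta = two_group_beta(rng, delta=0.5)
        res = subtypes.consensus_cluster(beta, k_range=range(2, 6), n_resamples=100, seed=1)
        assert res.k == 2

    def test_relabelling_invariant_under_sample_order(self, rng):
        beta = two_group_beta(rng, delta=0.5)
        a = subtypes.consensus_cluster(beta, k=2, n_resamples=200, seed=3)
        perm = list(rng.permutation(beta.columns))
        b = subtypes.consensus_cluster(beta[perm], k=2, n_resamples=200, seed=3)
        merged = pd.concat([a.assignments.rename("a"), b.assignments.rename("b")], axis=1)
        assert adjusted_rand_score(merged["a"], merged["b"]) == 1.0

    def test_k_above_sample_count_rejected(self, rng):
        beta = two_group_beta(rng, n_per_group=2)
        with pytest.raises(ValueError):
            subtypes.consensus_cluster(beta, k=10, n_resamples=10)


class TestMDS:
    def test_collinear_points_have_one_dimension(self):
        beta = pd.DataFrame(
            {"s1": [0.1, 0.1], "s2": [0.3, 0.3], "s3": [0.7, 0.7]},
            index=["cg1", "cg2"],
        )
        coords = subtypes.mds(beta, n_dims=2)
        assert np.allclose(coords["dim2"], 0.0, atol=1e-8)
        assert coords["dim1"].abs().max() > 0

    def test_exact_embedding_reproduces_distances(self, rng):
        pts = rng.normal(size=(6, 2))
        beta = pd.DataFrame(pts.T, index=["cg1", "cg2"],
                            columns=[f"s{i}" for i in range(6)])
        coords = subtypes.mds(beta, n_dims=2).to_numpy()
        orig = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        emb = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(orig, emb, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        beta = two_group_beta(rng)
        a = subtypes.mds(beta)
        b = subtypes.mds(beta)
        pd.testing.assert_frame_equal(a, b)
        for col in a.columns:
            nz = a[col][a[col].abs() > 1e-12]
            if len(nz):
                assert nz.iloc[0] > 0

    def test_hypervariable_group_disperses_more(self, default_cohort):
        c = default_cohort
        trio = trio_sheet(c)
        g1 = truth_subgroup_patients(c, "group1")
        wt1 = [s for s in trio.index if trio.at[s, "tissue"] == "WT" and trio.at[s, "patient_id"] in g1]
        wt2 = [s for s in trio.index if trio.at[s, "tissue"] == "WT" and trio.at[s, "patient_id"] not in g1]
        from trioepi.preprocess import top_variable
        top = top_variable(c.beta[trio.index], fraction=0.01)
        # enough dimensions to retain probe-level variability, not just the
        # two dominant tissue axes
        coords = subtypes.mds(c.beta.loc[top, trio.index], n_dims=15)

        def dispersion(samples):
            pts = coords.loc[samples].to_numpy()
            return np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean()

        assert dispersion(wt1) > dispersion(wt2)

    def test_too_few_samples_rejected(self):
        beta = pd.DataFrame({"s1": [0.1], "s2": [0.2]}, index=["cg1"])
        with pytest.raises(ValueError):
            subtypes.mds(beta)


def bartlett_oracle(groups):
    """Textbook Bartlett statistic written independently of the module."""
    k = len(groups)
    n_i = np.array([len(g) for g in groups])
    s2 = np.array([np.var(g, ddof=1) for g in groups])
    big_n = n_i.sum()
    sp2 = ((n_i - 1) * s2).sum() / (big_n - k)
    num = (big_n - k) * np.log(sp2) - ((n_i - 1) * np.log(s2)).sum()
    c = 1 + (np.sum(1 / (n_i - 1)) - 1 / (big_n - k)) / (3 * (k - 1))
    return num / c


class TestBartlett:
    def test_identical_variances_give_zero(self):
        beta = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]], index=["cg1"],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]}
        res = subtypes.bartlett_per_probe(beta, groups)
        assert np.isclose(res.table.at["cg1", "K2"], 0.0, atol=1e-12)
        assert np.isclose(res.table.at["cg1", "p"], 1.0)

    def test_matches_closed_form_and_scipy(self, rng):
        beta = pd.DataFrame(rng.uniform(0, 1, size=(50, 12)),
                            index=[f"cg{i}" for i in range(50)],
                            columns=[f"s{i}" for i in range(12)])
        groups = {"a": [f"s{i}" for i in range(5)], "b": [f"s{i}" for i in range(5, 12)]}
        res = subtypes.bartlett_per_probe(beta, groups)
        for probe in beta.index[:20]:
            a = beta.loc[probe, groups["a"]].to_numpy()
            b = beta.loc[probe, groups["b"]].to_numpy()
            assert np.isclose(res.table.at[probe, "K2"], bartlett_oracle([a, b]), atol=1e-10)
            scipy_stat, scipy_p = stats.bartlett(a, b)
            assert np.isclose(res.table.at[probe, "K2"], scipy_stat, atol=1e-10)
            assert np.isclose(res.table.at[probe, "p"], scipy_p, atol=1e-10)

    def test_toy_example_against_oracle(self):
        beta = pd.DataFrame([[0.1, 0.2, 0.3, 0.1, 0.5, 0.9]], index=["cg1"],
                            columns=[f"s{i}" for i in range(6)])
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]}
        res = subtypes.bartlett_per_probe(beta, groups)
        expected = bartlett_oracle([np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.5, 0.9])])
        assert np.isclose(res.table.at["cg1", "K2"], expected, atol=1e-12)

    def test_power_at_variance_ratio_four(self, rng):
        """A four-fold variance ratio with 40 samples per group is detected
        in >= 80% of probes at alpha 0.01 and always attributed to the
        right group.  (At 10 per group the test's power is only ~25%, so
        the power check needs the larger groups.)"""
        n = 1000
        a = pd.DataFrame(rng.normal(0.5, 0.05, size=(n, 40)))
        b = pd.DataFrame(rng.normal(0.5, 0.10, size=(n, 40)))
        beta = pd.concat([a, b], axis=1)
        beta.columns = [f"s{i}" for i in range(80)]
        beta.index = [f"cg{i}" for i in range(n)]
        groups = {"a": [f"s{i}" for i in range(40)], "b": [f"s{i}" for i in range(40, 80)]}
        res = subtypes.bartlett_per_probe(beta, groups, alpha=0.01)
        assert res.n_significant / n >= 0.8
        assert res.counts["b"] > res.counts["a"]

    def test_degenerate_zero_variance_flagged(self):
        beta = pd.DataFrame([[0.5] * 6], index=["cg1"], columns=[f"s{i}" for i in range(6)])
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]}
        res = subtypes.bartlett_per_probe(beta, groups)
        assert res.table.at["cg1", "p"] == 1.0
        assert bool(res.table.at["cg1", "degenerate"])

    def test_small_group_rejected(self):
        beta = pd.DataFrame([[0.1, 0.2, 0.3]], index=["cg1"], columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError):
            subtypes.bartlett_per_probe(beta, {"a": ["s0"], "b": ["s1", "s2"]})


class TestClusterAssociation:
    def test_perfect_diagonal_table(self):
        assign = pd.Series([1] * 10 + [2] * 10, index=[f"s{i}" for i in range(20)])
        labels = pd.Series(["x"] * 10 + ["y"] * 10, index=assign.index)
        chi2, df, p, table = subtypes.cluster_association(assign, labels)
        assert np.isclose(chi2, 20.0) and df == 1
        assert table.to_numpy().tolist() == [[10, 0], [0, 10]]

    def test_matches_hand_formula(self, rng):
        assign = pd.Series(rng.choice([1, 2], size=60), index=[f"s{i}" for i in range(60)])
        labels = pd.Series(rng.choice(["x", "y"], size=60), index=assign.index)
        chi2, df, p, table = subtypes.cluster_association(assign, labels)
        obs = table.to_numpy().astype(float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert np.isclose(chi2, ((obs - expected) ** 2 / expected).sum(), atol=1e-10)

    def test_single_cluster_degenerate(self):
        assign = pd.Series([1] * 10, index=[f"s{i}" for i in range(10)])
        labels = pd.Series(["x"] * 5 + ["y"] * 5, index=assign.index)
        with pytest.raises(ValueError):
            subtypes.cluster_association(assign, labels)

    def test_calibrated_under_independence(self):
        rejections = 0
        reps = 200
        for i in range(reps):
            r = np.random.default_rng(i)
            assign = pd.Series(r.choice([1, 2], size=100), index=range(100))
            labels = pd.Series(r.choice(["x", "y"], size=100), index=range(100))
            try:
                _, _, p, _ = subtypes.cluster_association(assign, labels)
            except ValueError:
                continue
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.12
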