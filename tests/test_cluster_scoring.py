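import numpy as np
import pandas as pd
import pytest

from igvprog.cluster_scoring import (
    PrognosticModel,
    apply_prognostic_score,
    cluster_scores,
    consensus_cluster,
    filter_clusters,
    fit_prognostic_model,
    validate_groups,
)
from igvprog.core_io import ClinicalTable
from igvprog.gene_measures import GeneMeasureMatrix
from igvprog.synthetic_data import gen_score_cohort


def igv_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return GeneMeasureMatrix(
        np.asarray(genes or [f"G{i}" for i in range(g)], dtype=object),
        np.asarray(samples or [f"s{j}" for j in range(n)], dtype=object),
        values, "igv", "Body")


def blocky_igv(seed=0, n_per_block=20, n_samples=50, noise=0.3):
    """Two blocks of internally correlated gene profiles."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=(2, n_samples))
    rows, genes, labels = [], [], []
    for b, f in enumerate((f1, f2)):
        for i in range(n_per_block):
            rows.append(f + noise * rng.normal(size=n_samples))
            genes.append(f"B{b}_{i}")
            labels.append(b)
    vals = np.asarray(rows)
    vals = (vals - vals.min()) / (vals.max() - vals.min()) * 0.2 + 0.01
    return igv_matrix(vals, genes=genes), np.asarray(labels)


def adjusted_rand(a, b):
    from scipy.special import comb

    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ct = pd.crosstab(a, b).to_numpy()
    sum_comb = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    return (sum_comb - expected) / (max_index - expected)


class TestConsensusCluster:
    def test_recovers_two_planted_blocks(self):
        igv, truth = blocky_igv(seed=1)
        cc = consensus_cluster(igv, resamplings=200, seed=2)
        assert cc.chosen_k == 2
        labels = np.array([cc.labels[g] for g in igv.gene_ids])
        assert adjusted_rand(labels, truth) == pytest.approx(1.0)

    def test_duplicate_gene_rows_always_cocluster(self):
        igv, _ = blocky_igv(seed=3, n_per_block=5)
        vals = np.vstack([igv.values, igv.values[0]])
        dup = igv_matrix(vals, genes=list(igv.gene_ids) + ["dup"])
        cc = consensus_cluster(dup, resamplings=100, seed=4)
        i = list(dup.gene_ids).index("B0_0")
        j = list(dup.gene_ids).index("dup")
        assert cc.consensus_matrix[i, j] == pytest.approx(1.0)

    def test_seeded_determinism(self):
        igv, _ = blocky_igv(seed=5, n_per_block=8)
        a = consensus_cluster(igv, resamplings=50, seed=6)
        b = consensus_cluster(igv, resamplings=50, seed=6)
        np.testing.assert_array_equal(a.consensus_matrix, b.consensus_matrix)
        assert a.labels == b.labels

    def test_consensus_entries_are_frequencies(self):
        igv, _ = blocky_igv(seed=7, n_per_block=6)
        cc = consensus_cluster(igv, resamplings=60, seed=8)
        assert np.all(cc.consensus_matrix >= 0) and np.all(cc.consensus_matrix <= 1)
        np.testing.assert_allclose(np.diag(cc.consensus_matrix), 1.0)
        np.testing.assert_allclose(cc.consensus_matrix, cc.consensus_matrix.T)

    def test_consensus_converges_with_resamplings(self):
        igv, _ = blocky_igv(seed=9, n_per_block=8)
        a = consensus_cluster(igv, resamplings=2000, seed=10)
        b = consensus_cluster(igv, resamplings=2000, seed=11)
        assert np.abs(a.consensus_matrix - b.consensus_matrix).max() < 0.05

    def test_too_few_resamplings_or_constant_rows_error(self):
        igv, _ = blocky_igv(seed=12, n_per_block=4)
        with pytest.raises(ValueError):
            consensus_cluster(igv, resamplings=5, seed=0)
        flat = igv_matrix(np.vstack([igv.values, np.full(50, 0.1)]),
                          genes=list(igv.gene_ids) + ["flat"])
        with pytest.raises(ValueError, match="constant"):
            consensus_cluster(flat, resamplings=50, seed=0)


def clinical_for(scores, betas, seed=0, censor=0.3):
    rng = np.random.default_rng(seed)
    lp = scores @ betas
    t = rng.exponential(np.exp(-(lp - lp.mean()))) * 100 + 0.1
    c = np.quantile(t, 1 - censor) * np.ones_like(t)
    times = np.minimum(t, c)
    return ClinicalTable(pd.DataFrame({
        "time": times, "event": t <= c,
        "age": rng.integers(45, 80, len(t)),
        "stage": rng.integers(1, 5, len(t)),
        "grade": rng.integers(1, 4, len(t)),
        "residual": rng.integers(0, 2, len(t)),
    }, index=pd.Index([f"s{j}" for j in range(len(t))], name="sample_id")))


class TestFilterClusters:
    def make_clustering(self, igv, labels):
        from igvprog.cluster_scoring import ConsensusClustering

        return ConsensusClustering(
            gene_ids=igv.gene_ids, consensus_matrix=np.eye(len(igv.gene_ids)),
            k_grid=np.array([2]), chosen_k=2,
            labels={g: int(l) for g, l in zip(igv.gene_ids, labels)})

    def test_small_cluster_dropped_regardless_of_association(self):
        igv, truth = blocky_igv(seed=13, n_per_block=20)
        labels = truth.copy()
        labels[:9] = 2  # carve a 9-gene cluster off block 0
        cc = self.make_clustering(igv, labels)
        mean0 = igv.values[truth == 0].mean(axis=0)
        clin = clinical_for(mean0[:, None], np.array([30.0]), seed=1)
        named = filter_clusters(cc, igv, clin, min_genes=10)
        sizes = sorted(len(g) for g in named.values())
        assert 9 not in sizes

    def test_planted_association_retained_null_dropped(self):
        igv, truth = blocky_igv(seed=14, n_per_block=15)
        cc = self.make_clustering(igv, truth)
        mean0 = igv.values[truth == 0].mean(axis=0)
        clin = clinical_for(mean0[:, None], np.array([60.0]), seed=2)
        named = filter_clusters(cc, igv, clin, min_genes=10, name_prefix="c")
        kept_genes = {g for gs in named.values() for g in gs}
        # block 0 drives hazard strongly; block 1 only via its correlation noise
        assert {g for g, l in zip(igv.gene_ids, truth) if l == 0} <= kept_genes

    def test_null_clusters_mostly_dropped(self):
        drops = 0
        for seed in range(40):
            igv, truth = blocky_igv(seed=200 + seed, n_per_block=12)
            cc = self.make_clustering(igv, truth)
            rng = np.random.default_rng(seed)
            clin = clinical_for(rng.normal(size=(50, 1)), np.array([0.0]),
                                seed=seed)
            try:
                named = filter_clusters(cc, igv, clin, min_genes=10)
                drops += len(named) == 0
            except ValueError:
                drops += 1
        assert drops >= 32  # ~95% expected at p<0.05 per cluster


class TestClusterScores:
    def test_hand_mean(self):
        igv = igv_matrix([[0.1, 0.2], [0.3, 0.4]], genes=["g1", "g2"])
        sc = cluster_scores(igv, {"c1": ["g1", "g2"]})
        np.testing.assert_allclose(sc["c1"], [0.2, 0.3])

    def test_single_gene_cluster_is_identity(self):
        igv = igv_matrix([[0.1, 0.2]], genes=["g1"])
        sc = cluster_scores(igv, {"c1": ["g1"]})
        np.testing.assert_allclose(sc["c1"], [0.1, 0.2])

    def test_duplicate_member_does_not_move_mean(self):
        igv = igv_matrix([[0.1, 0.2], [0.1, 0.2]], genes=["g1", "g1dup"])
        a = cluster_scores(igv, {"c": ["g1"]})
        b = cluster_scores(igv, {"c": ["g1", "g1dup"]})
        np.testing.assert_allclose(a["c"], b["c"])

    def test_missing_gene_is_named(self):
        igv = igv_matrix([[0.1, 0.2]], genes=["g1"])
        with pytest.raises(KeyError, match="ghost"):
            cluster_scores(igv, {"c1": ["g1", "ghost"]})


class TestPrognosticModel:
    def test_training_median_ignores_covariates(self):
        scores, clin = gen_score_cohort(
            {"hyper1": 0.3, "hypo1": -0.3}, n_samples=150, seed=3)
        m1 = fit_prognostic_model(scores, clin)
        df = clin.table.copy()
        df["age"] = 99  # perturb a covariate only
        m2 = fit_prognostic_model(scores, ClinicalTable(df))
        lp1 = scores.to_numpy() @ np.array(
            [m1.cluster_coefficients[c] for c in scores.columns])
        assert m1.training_median == pytest.approx(np.median(lp1))
        # the median is a function of cluster terms alone; with the same
        # cluster coefficients it would be unchanged
        lp2 = scores.to_numpy() @ np.array(
            [m2.cluster_coefficients[c] for c in scores.columns])
        assert m2.training_median == pytest.approx(np.median(lp2))

    def test_null_scores_rarely_significant(self):
        sig = 0
        for seed in range(30):
            scores, clin = gen_score_cohort(
                {"c1": 0.0, "c2": 0.0}, n_samples=120, seed=700 + seed)
            model = fit_prognostic_model(scores, clin)
            sig += any(p < 0.05 for p in
                       model.fit.p_values[:2])
        assert sig <= 8  # ≈ 2 clusters x 5% each under the null

    def test_json_roundtrip(self, tmp_path):
        scores, clin = gen_score_cohort({"c1": 0.4}, n_samples=100, seed=4)
        model = fit_prognostic_model(scores, clin, clusters={"c1": ["g1", "g2"]})
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PrognosticModel.from_json(path)
        assert back.cluster_coefficients == model.cluster_coefficients
        assert back.training_median == model.training_median
        assert back.clusters == model.clusters


class TestApplyScore:
    def make_model(self, coefs, clusters, median=0.0):
        return PrognosticModel(
            clusters=clusters, cluster_coefficients=coefs,
            cluster_coefficients_standardized=coefs,
            covariate_coefficients={}, training_median=median)

    def test_hand_dot_product(self):
        igv = igv_matrix([[0.3], [0.1]], genes=["g1", "g2"])
        model = self.make_model({"c1": 1.0, "c2": -1.0},
                                {"c1": ["g1"], "c2": ["g2"]})
        out = apply_prognostic_score(model, igv)
        assert out["score"].iloc[0] == pytest.approx(0.2)
        assert out["risk_group"].iloc[0] == "worse"

    def test_all_zero_coefficients_scores_zero(self):
        igv = igv_matrix([[0.3, 0.5]], genes=["g1"])
        model = self.make_model({"c1": 0.0}, {"c1": ["g1"]}, median=0.1)
        out = apply_prognostic_score(model, igv)
        assert (out["score"] == 0.0).all()
        assert (out["risk_group"] == "better").all()

    def test_invariant_to_sample_order_and_extra_genes(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.01, 0.3, size=(3, 6))
        igv = igv_matrix(vals, genes=["g1", "g2", "extra"])
        model = self.make_model({"c1": 0.7}, {"c1": ["g1", "g2"]})
        out = apply_prognostic_score(model, igv)
        rev = igv_matrix(vals[:2, ::-1], genes=["g1", "g2"],
                         samples=list(igv.sample_ids[::-1]))
        out_rev = apply_prognostic_score(model, rev)
        np.testing.assert_allclose(out["score"].to_numpy()[::-1],
                                   out_rev["score"].to_numpy())

    def test_missing_gene_tolerance(self):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(6)
        igv = igv_matrix(rng.uniform(0.01, 0.3, size=(9, 4)), genes=genes[:9])
        model = self.make_model({"c1": 1.0}, {"c1": genes})
        with pytest.warns(UserWarning, match="renormalizing"):
            out = apply_prognostic_score(model, igv)  # 10% missing -> warn
        assert len(out) == 4
        big_model = self.make_model({"c1": 1.0}, {"c1": genes + ["g10", "g11"]})
        with pytest.raises(KeyError, match="missing"):
            apply_prognostic_score(big_model, igv)  # 25% missing -> error


class TestValidateGroups:
    def test_planted_model_validates_on_fresh_cohort(self):
        wins = 0
        for seed in range(20):
            scores, clin = gen_score_cohort(
                {"c1": 0.5, "c2": 0.5}, n_samples=300, seed=900 + seed)
            lp = scores.to_numpy() @ np.array([0.5, 0.5])
            groups = pd.Series(np.where(lp > np.median(lp), "worse", "better"),
                               index=scores.index)
            uni, multi, km = validate_groups(groups, clin)
            wins += uni.p_values[0] < 0.05
        assert wins >= 16

    def test_random_labels_cover_unity_hr(self):
        cover = 0
        for seed in range(30):
            scores, clin = gen_score_cohort({"c1": 0.0}, n_samples=200,
                                            seed=1200 + seed)
            rng = np.random.default_rng(seed)
            groups = pd.Series(rng.choice(["better", "worse"], size=200),
                               index=scores.index)
            uni, _, _ = validate_groups(groups, clin)
            cover += uni.ci_lower[0] <= 1.0 <= uni.ci_upper[0]
        assert cover >= 25

    def test_km_curves_start_at_one_and_decrease(self):
        scores, clin = gen_score_cohort({"c1": 0.5}, n_samples=150, seed=7)
        groups = pd.Series(np.where(scores["c1"] > 0, "worse", "better"),
                           index=scores.index)
        _, _, km = validate_groups(groups, clin)
        for _, grp in km.groupby("group"):
            surv = grp.sort_values("time")["survival"].to_numpy()
            assert surv[0] == pytest.approx(1.0)
            assert np.all(np.diff(surv) <= 1e-12)

    def test_single_group_errors(self):
        scores, clin = gen_score_cohort({"c1": 0.5}, n_samples=50, seed=8)
        groups = pd.Series(["worse"] * 50, index=scores.index)
        with pytest.raises(ValueError):
            validate_groups(groups, clin)
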