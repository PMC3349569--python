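import numpy as np
import pytest

from coremod import (
    PathwayActivityModel,
    PathwayActivityTransformer,
    gene_stats,
    infer_cmi,
    infer_corg,
    infer_simple,
    project_activity,
    zscore_normalize,
)
from coremod.pathways import Pathway, PathwayCollection
from conftest import make_dataset
from oracles import exhaustive_cmi, pooled_t


def normalized_cohort(seed=0, n_genes=40, n=30, shifted=10, effect=1.2):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_genes, n))
    labels = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    signs = rng.choice([-1, 1], size=shifted)
    for i in range(shifted):
        vals[i, labels == 1] += signs[i] * effect
    ds = make_dataset(vals, labels)
    zds = zscore_normalize(ds)
    return zds, gene_stats(zds)


def ranked_degs(stats, pathway):
    in_pw = [s for s in stats if s.gene_id in pathway.gene_ids and s.is_deg]
    return sorted(in_pw, key=lambda s: (-abs(s.tscore), s.gene_id))


class TestCmi:
    def test_matches_exhaustive_prefix_search(self):
        zds, stats = normalized_cohort(seed=3)
        rng = np.random.default_rng(7)
        gi = zds.gene_index()
        for trial in range(30):
            genes = rng.choice(zds.gene_ids, size=rng.integers(3, 15),
                               replace=False)
            pw = Pathway(f"p{trial}", "p", frozenset(genes))
            model = infer_cmi(zds, stats, pw)
            members = ranked_degs(stats, pw)
            if not members:
                assert model is None
                continue
            order = [gi[s.gene_id] for s in members]
            signs = [1.0 if s.tscore >= 0 else -1.0 for s in members]
            k, act, tvals = exhaustive_cmi(zds.values, zds.labels, order, signs)
            assert model.k == k
            assert model.inference_tscore == pytest.approx(tvals[k - 1], abs=1e-10)
            assert np.allclose(project_activity(model, zds), act, atol=1e-12)
            # K maximality: no other admissible prefix beats the chosen one
            assert tvals[k - 1] == pytest.approx(tvals.max(), abs=1e-12)

    def test_no_deg_returns_null(self):
        zds, stats = normalized_cohort(seed=4, shifted=0)
        non_degs = [s.gene_id for s in stats if not s.is_deg][:6]
        assert infer_cmi(zds, stats, Pathway("p", "p", frozenset(non_degs))) is None

    def test_single_deg_gives_k1_signed_z(self):
        zds, stats = normalized_cohort(seed=5)
        degs = [s for s in stats if s.is_deg]
        s0 = degs[0]
        non = [s.gene_id for s in stats if not s.is_deg][:4]
        pw = Pathway("p", "p", frozenset([s0.gene_id, *non]))
        model = infer_cmi(zds, stats, pw)
        assert model.k == 1 and model.member_genes == [s0.gene_id]
        sign = 1.0 if s0.tscore >= 0 else -1.0
        expect = zds.values[zds.gene_index()[s0.gene_id]] * sign
        assert np.allclose(project_activity(model, zds), expect)

    def test_member_cap_respected(self):
        zds, stats = normalized_cohort(seed=6, n_genes=60, shifted=60, effect=1.5)
        stats = gene_stats(zds, alpha=1.0)  # everything is a DEG
        pw = Pathway("p", "p", frozenset(zds.gene_ids[:40]))
        model = infer_cmi(zds, stats, pw)
        assert model.k <= 20

    def test_absent_genes_excluded(self):
        zds, stats = normalized_cohort(seed=8)
        degs = [s.gene_id for s in stats if s.is_deg][:2]
        pw = Pathway("p", "p", frozenset([*degs, "NOT_THERE"]))
        model = infer_cmi(zds, stats, pw)
        assert "NOT_THERE" not in model.member_genes


class TestCorg:
    def test_single_signed_members_vs_cmi_mixing(self):
        # strong up- and down-regulated genes in one pathway
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(6, 40)) * 0.5
        labels = np.array([1] * 20 + [-1] * 20)
        vals[0, labels == 1] += 2.0
        vals[1, labels == 1] += 1.8
        vals[2, labels == 1] -= 2.1
        vals[3, labels == 1] -= 1.7
        zds = zscore_normalize(make_dataset(vals, labels))
        stats = gene_stats(zds)
        pw = Pathway("p", "p", frozenset(zds.gene_ids))
        corg = infer_corg(zds, stats, pw)
        cmi = infer_cmi(zds, stats, pw)
        assert len(set(corg.signs)) == 1
        assert len(set(np.sign(cmi.signs))) == 2  # CMI mixes both directions

    def test_matches_exhaustive_prefix_search_on_toy(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(4, 60)) * 0.8
        labels = np.array([1] * 30 + [-1] * 30)
        for i, shift in enumerate([1.2, 1.0, -1.1, 0.05]):
            vals[i, labels == 1] += shift
        zds = zscore_normalize(make_dataset(vals, labels))
        stats = gene_stats(zds)
        pw = Pathway("p", "p", frozenset(zds.gene_ids))
        model = infer_corg(zds, stats, pw)
        # exhaustive: all prefixes of both single-signed subsets
        gi = zds.gene_index()
        best = None
        for sign in (1, -1):
            sub = sorted([s for s in stats if sign * s.tscore > 0],
                         key=lambda s: (-abs(s.tscore), s.gene_id))
            for j in range(1, len(sub) + 1):
                act = sign * sum(zds.values[gi[s.gene_id]] for s in sub[:j]) / np.sqrt(j)
                t = pooled_t(act[labels == 1], act[labels == -1])
                if best is None or abs(t) > abs(best[0]):
                    best = (t, [s.gene_id for s in sub[:j]], sign)
        assert set(model.member_genes) == set(best[1])
        assert model.inference_tscore == pytest.approx(best[0], abs=1e-10)
        assert model.signs[0] == best[2]


class TestSimpleMethods:
    def test_mean_of_single_gene_is_identity(self):
        zds, stats = normalized_cohort(seed=11)
        g = zds.gene_ids[0]
        model = infer_simple(zds, stats, Pathway("p", "p", frozenset([g])), "mean")
        assert np.allclose(project_activity(model, zds), zds.values[0])

    def test_pca_matches_eigendecomposition(self):
        zds, stats = normalized_cohort(seed=12)
        pw = Pathway("p", "p", frozenset(zds.gene_ids[:8]))
        model = infer_simple(zds, stats, pw, "pca")
        act = project_activity(model, zds)
        gi = zds.gene_index()
        z = zds.values[[gi[g] for g in model.member_genes], :]
        cov = np.cov(z)
        vals, vecs = np.linalg.eigh(cov)
        oracle = vecs[:, -1] @ z
        corr = np.corrcoef(act, oracle)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)
        assert model.inference_tscore >= 0  # orientation rule

    def test_llr_symmetric_classes_zero_activity(self):
        vals = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        ds = make_dataset(vals, [1, 1, 1, -1, -1, -1])
        zds = zscore_normalize(ds)
        stats = gene_stats(zds)
        model = infer_simple(zds, stats, Pathway("p", "p", frozenset(["g1"])), "llr")
        assert np.allclose(project_activity(model, zds), 0.0, atol=1e-10)

    def test_gene_models_equal_z_rows(self):
        zds, stats = normalized_cohort(seed=13)
        pw = Pathway("p", "p", frozenset(zds.gene_ids[:5]))
        models = infer_simple(zds, stats, pw, "gene")
        gi = zds.gene_index()
        for m in models:
            assert np.array_equal(project_activity(m, zds),
                                  zds.values[gi[m.member_genes[0]]])


class TestProjection:
    def test_self_projection_reproduces_inference(self):
        zds, stats = normalized_cohort(seed=14)
        for method in ("cmi", "corg", "mean", "median", "pca", "llr"):
            pw = Pathway("p", "p", frozenset(zds.gene_ids[:6]))
            if method == "cmi":
                model = infer_cmi(zds, stats, pw)
            elif method == "corg":
                model = infer_corg(zds, stats, pw)
            else:
                model = infer_simple(zds, stats, pw, method)
            act = project_activity(model, zds)
            t = pooled_t(act[zds.labels == 1], act[zds.labels == -1])
            assert t == pytest.approx(model.inference_tscore, abs=1e-8), method

    def test_hand_evaluated_two_gene_model(self):
        model = PathwayActivityModel(
            pathway_id="p", method="cmi", member_genes=["g1", "g2"],
            signs=np.array([1.0, -1.0]), inference_tscore=1.0,
            params={"denominator": "j"},
        )
        target = make_dataset([[1, -1, 1, -1], [-1, 1, -1, 1]], [1, 1, -1, -1])
        assert np.allclose(project_activity(model, target), [1, -1, 1, -1])

    def test_missing_member_dropped_with_divisor_adjustment(self):
        model = PathwayActivityModel(
            pathway_id="p", method="cmi", member_genes=["g1", "gX"],
            signs=np.array([1.0, -1.0]), inference_tscore=1.0,
            params={"denominator": "j"},
        )
        target = make_dataset([[1, 2, -1, -2], [0, 0, 0, 0]], [1, 1, -1, -1])
        with pytest.warns(UserWarning, match="gX"):
            act = project_activity(model, target)
        assert np.allclose(act, [1, 2, -1, -2])  # divisor reduced to 1

    def test_all_members_missing_raises_named_error(self):
        model = PathwayActivityModel(
            pathway_id="PWX", method="cmi", member_genes=["nope"],
            signs=np.array([1.0]), inference_tscore=1.0,
        )
        target = make_dataset([[1, 2, 3, 4]], [1, 1, -1, -1])
        with pytest.raises(ValueError, match="PWX"):
            project_activity(model, target)

    def test_sample_permutation_permutes_activities(self):
        zds, stats = normalized_cohort(seed=15)
        pw = Pathway("p", "p", frozenset(zds.gene_ids[:6]))
        model = infer_cmi(zds, stats, pw)
        act = project_activity(model, zds)
        perm = np.random.default_rng(1).permutation(zds.n_samples)
        shuffled = make_dataset(zds.values[:, perm], zds.labels[perm],
                                genes=zds.gene_ids)
        assert np.allclose(project_activity(model, shuffled), act[perm])


class TestTransformer:
    def test_ranked_models_and_top_n(self, small_study):
        tf = PathwayActivityTransformer(small_study.pathways, method="cmi",
                                        top_n=5).fit(small_study.cohorts[0])
        ts = [m.inference_tscore for m in tf.models_]
        assert ts == sorted(ts, reverse=True)
        assert len(tf.models_) == 5

    def test_transform_shapes_and_labels(self, small_study):
        tf = PathwayActivityTransformer(small_study.pathways).fit(small_study.cohorts[0])
        am = tf.transform(small_study.cohorts[1])
        assert am.values.shape == (len(tf.models_),
                                   small_study.cohorts[1].n_samples)
        assert np.array_equal(am.labels, small_study.cohorts[1].labels)

    def test_get_params_roundtrip(self, small_study):
        tf = PathwayActivityTransformer(small_study.pathways, method="mean")
        params = tf.get_params()
        assert params["method"] == "mean"
        tf.set_params(alpha=0.01)
        assert tf.alpha == 0.01
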