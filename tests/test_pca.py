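"""Sample/gene PCA, scree, loadings, selections, profiles, multifactor."""

import numpy as np
import pandas as pd
import pytest

import pcascope as p
from pcascope.normalize import SizeFactors, TransformedMatrix

from conftest import unit_size_factors


def make_transformed(arr, genes=None, samples=None) -> TransformedMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=samples)
    return TransformedMatrix(df, "shifted_log", {"pseudocount": 1.0},
                             unit_size_factors(samples))


def eig_oracle(X: np.ndarray):
    """Independent covariance-eigendecomposition PCA (variables = columns)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    k = min(X.shape)
    ve = w[:k] / w.sum()
    scores = Xc @ v[:, :k]
    return ve, scores


class TestPCASamples:
    def test_single_varying_gene_owns_pc1(self):
        t = make_transformed([[1, 2, 3, 4], [5, 5, 5, 5], [7, 7, 7, 7]])
        res = p.pca_samples(t, ntop=3)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        t = make_transformed(rng.normal(size=(20, 6)))
        res = p.pca_samples(t, ntop=20)
        X = t.values.loc[res.variable_ids].T.to_numpy()
        Xc = X - X.mean(axis=0, keepdims=True)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.max(np.abs(recon - Xc)) < 1e-8

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_s, n_g = rng.integers(2, 9), rng.integers(2, 9)
            X = rng.normal(size=(n_s, n_g))
            t = make_transformed(X.T)
            res = p.pca_samples(t, ntop=n_g)
            ve, scores = eig_oracle(X)
            np.testing.assert_allclose(res.variance_explained, ve, atol=1e-8)
            np.testing.assert_allclose(
                np.abs(res.scores.to_numpy()), np.abs(scores), atol=1e-8
            )

    def test_variance_explained_sums_to_one(self, sim):
        res = p.pca_samples(sim["transformed"], 500)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_loadings_orthonormal(self, sim):
        res = p.pca_samples(sim["transformed"], 500)
        L = res.loadings.to_numpy()
        gram = L.T @ L
        assert np.max(np.abs(gram - np.eye(gram.shape[0]))) < 1e-8

    def test_sign_convention_deterministic(self):
        t = make_transformed([[1, 2, 3, 4], [2, 1, 4, 3], [0, 0, 1, 1]])
        res = p.pca_samples(t, ntop=3)
        for col in res.loadings:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_permutation_equivariance(self, sim):
        t = sim["transformed"]
        perm = list(reversed(t.sample_ids))
        tp = TransformedMatrix(t.values[perm], t.method, t.params,
                               SizeFactors(t.size_factors.values.loc[perm]))
        a = p.pca_samples(t, 200)
        b = p.pca_samples(tp, 200)
        np.testing.assert_allclose(a.variance_explained, b.variance_explained,
                                   atol=1e-8)
        np.testing.assert_allclose(
            a.scores.loc[perm].to_numpy(), b.scores.to_numpy(), atol=1e-6
        )

    def test_group_separation_and_loading_recovery(self, sim):
        """Planted two-group structure dominates PC1: scores separate the
        groups with no range overlap and the top loadings are planted."""
        res = p.pca_samples(sim["transformed"], 500)
        groups = sim["bundle"].metadata.factors["condition"]
        s1 = res.scores["PC1"]
        lo, hi = s1[groups == "A"], s1[groups == "B"]
        gap = max(hi.min() - lo.max(), lo.min() - hi.max())
        assert gap > 0
        affected = set(sim["affected"])
        n = len(affected)
        pos, neg = p.hi_loadings(res, 1, n)
        ranked = sorted(zip(pos.loadings + neg.loadings, pos.gene_ids + neg.gene_ids),
                        key=lambda t_: -abs(t_[0]))[:n]
        selected = {g for _, g in ranked}
        assert len(selected & affected) / len(selected) >= 0.8


class TestSelectTopVariable:
    def test_ranking_by_variance(self):
        t = make_transformed([[1, 1, 1], [0, 2, 4], [0, 1, 2]])
        assert p.select_top_variable(t, 2) == ["g2", "g3"]

    def test_ntop_exceeding_gene_count_keeps_order(self):
        t = make_transformed([[1, 2], [3, 4], [5, 6]])
        assert p.select_top_variable(t, 99) == ["g1", "g2", "g3"]

    def test_all_constant_warns_and_keeps_input_order(self, caplog):
        t = make_transformed([[1, 1], [2, 2], [3, 3]])
        with caplog.at_level("WARNING"):
            top = p.select_top_variable(t, 2)
        assert top == ["g1", "g2"]
        assert "zero" in caplog.text


class TestScreeAndHiLoadings:
    def test_cumulative_running_sum(self):
        t = make_transformed(np.random.default_rng(0).normal(size=(10, 4)))
        res = p.pca_samples(t, 10)
        sc = p.scree(res)
        np.testing.assert_allclose(
            sc["cumulative"], np.cumsum(sc["variance_explained"]), atol=1e-12
        )
        assert sc["cumulative"].iloc[-1] == pytest.approx(1.0, abs=1e-8)
        assert (sc["cumulative"].diff().dropna() >= -1e-12).all()

    def test_hi_loadings_sign_split(self):
        t = make_transformed([[1, 2, 3, 4], [4, 3, 2, 1], [1, 1, 1, 1.01]])
        res = p.pca_samples(t, 3)
        pos, neg = p.hi_loadings(res, 1, 1)
        assert len(pos.gene_ids) == 1 and len(neg.gene_ids) == 1
        assert all(l > 0 for l in pos.loadings)
        assert all(l < 0 for l in neg.loadings)

    def test_all_positive_loadings_leave_negative_empty(self):
        # one varying gene => PC1 loading vector is a single +1 coordinate
        t = make_transformed([[1, 2, 3, 4]], genes=["g1"])
        res = p.pca_samples(t, ntop=2)
        pos, neg = p.hi_loadings(res, 1, 2)
        assert pos.gene_ids == ["g1"]
        assert neg.gene_ids == []

    def test_pc_out_of_range(self):
        t = make_transformed([[1, 2], [2, 1]])
        res = p.pca_samples(t, 2)
        with pytest.raises(p.ValidationError):
            p.hi_loadings(res, 99)


class TestRemoveSamples:
    def test_drop_none_is_identity(self, sim):
        a = p.pca_samples(sim["transformed"], 200)
        b = p.pca_remove_samples(sim["transformed"], [], 200)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_outlier_removal_reduces_pc1_share(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(50, 1))
        X = np.repeat(base, 4, axis=1) + rng.normal(scale=0.01, size=(50, 4))
        X[:, 3] += rng.normal(scale=5.0, size=50)  # planted outlier sample
        t = make_transformed(X)
        before = p.pca_samples(t, 50).variance_explained[0]
        after = p.pca_remove_samples(t, ["s4"], 50).variance_explained[0]
        assert after < before

    def test_unknown_sample_named_in_error(self, sim):
        with pytest.raises(p.ValidationError, match="X"):
            p.pca_remove_samples(sim["transformed"], ["X"], 100)

    def test_cannot_drop_below_two_samples(self):
        t = make_transformed([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(p.ValidationError):
            p.pca_remove_samples(t, ["s1", "s2"], 2)


class TestGenesPCA:
    def test_planted_clusters_split_by_pc1_sign(self, sim):
        res = p.pca_genes(sim["transformed"], 500)
        beta = sim["truth"]["genes"]["beta"]
        planted = beta[res.observation_ids]
        planted = planted[planted != 0]
        assert len(planted) > 100
        signs = np.sign(res.scores.loc[planted.index, "PC1"])
        agreement = max(
            (signs == np.sign(planted)).mean(), (signs == -np.sign(planted)).mean()
        )
        assert agreement >= 0.95

    def test_biplot_arrows_point_toward_matching_cluster(self, sim):
        res = p.pca_genes(sim["transformed"], 500)
        beta = sim["truth"]["genes"]["beta"]
        up = [g for g in res.observation_ids if beta[g] > 0]
        centroid = res.scores.loc[up, ["PC1", "PC2"]].mean().to_numpy()
        meta = sim["bundle"].metadata.factors["condition"]
        # group B samples have elevated expression of up-genes
        for s in meta.index[meta == "B"]:
            arrow = res.biplot_arrows.loc[s, ["PC1", "PC2"]].to_numpy()
            assert float(arrow @ centroid) > 0

    def test_identical_samples_have_identical_arrows(self):
        t = make_transformed([[1, 1, 4], [2, 2, 0], [5, 5, 2], [0, 0, 9]])
        res = p.pca_genes(t, 4)
        d = res.biplot_arrows.loc["s1"] - res.biplot_arrows.loc["s2"]
        assert np.max(np.abs(d.to_numpy())) < 1e-8


class TestBoxSelectionAndProfiles:
    @pytest.fixture()
    def gpca(self, sim):
        return p.pca_genes(sim["transformed"], 100)

    def test_whole_plane_selects_all(self, gpca):
        got = p.select_genes_in_box(gpca, 1, 2, (-1e9, 1e9), (-1e9, 1e9))
        assert sorted(got) == sorted(gpca.observation_ids)

    def test_empty_rectangle_is_empty_list(self, gpca):
        assert p.select_genes_in_box(gpca, 1, 2, (1e9, 2e9), (1e9, 2e9)) == []

    def test_closed_boundary_captures_exact_point(self, gpca):
        g = gpca.observation_ids[0]
        x, y = gpca.scores.loc[g, "PC1"], gpca.scores.loc[g, "PC2"]
        assert g in p.select_genes_in_box(gpca, 1, 2, (x, x), (y, y))

    def test_profile_rows_center_to_zero(self, sim):
        genes = sim["transformed"].gene_ids[:5]
        prof = p.profile_data(sim["transformed"], genes, center=True)
        assert np.max(np.abs(prof.sum(axis=1).to_numpy())) < 1e-10
        assert list(prof.columns) == sim["transformed"].sample_ids

    def test_profile_unknown_gene_named(self, sim):
        with pytest.raises(p.ValidationError, match="nope"):
            p.profile_data(sim["transformed"], ["nope"])


@pytest.fixture(scope="module")
def two_factor():
    design = p.SimulationDesign(
        factor_levels=(2, 2), n_replicates=4, frac_affected=0.1,
        frac_interaction=0.1, log2_fc=4.0, seed=0,
    )
    bundle, truth = p.simulate_counts(design)
    sf = p.estimate_size_factors(bundle.counts)
    tr = p.vst(bundle.counts, sf, p.fit_dispersion_trend(bundle.counts, sf))
    return bundle, truth, tr


class TestMultifactor:
    def test_single_level_factor_reduces_to_gene_pca(self, sim):
        meta = sim["bundle"].metadata
        one_level = p.SampleMetadata(pd.DataFrame({
            "dummy": ["only"] * len(meta.sample_ids),
            "condition": meta.factors["condition"],
        }, index=meta.sample_ids))
        mf = p.pca_multifactor(sim["transformed"], one_level, "dummy",
                               "condition", 100)
        # reorder samples by condition to match the stacked column layout
        order = [s for lvl in ("A", "B") for s in meta.sample_ids
                 if meta.factors.at[s, "condition"] == lvl]
        t = sim["transformed"]
        reordered = TransformedMatrix(t.values[order], t.method, t.params,
                                      SizeFactors(t.size_factors.values.loc[order]))
        gp = p.pca_genes(reordered, 100)
        np.testing.assert_allclose(
            np.abs(mf.scores.to_numpy()), np.abs(gp.scores.to_numpy()), atol=1e-8
        )

    def test_factor2_only_genes_keep_linked_rows(self, two_factor):
        """Genes responding only to factor2 produce near-coincident
        gene::level rows, unlike genes with a planted interaction."""
        bundle, truth, tr = two_factor
        mf = p.pca_multifactor(tr, bundle.metadata, "tissue", "condition", 500)
        S = mf.scores[["PC1", "PC2"]]
        in_view = {i.split("::")[0] for i in mf.observation_ids}

        def pair_dist(g):
            return np.linalg.norm(S.loc[f"{g}::A"] - S.loc[f"{g}::B"])

        tg = truth["genes"]
        main = [g for g in tg.index[tg["beta"] != 0] if g in in_view]
        inter = [g for g in tg.index[tg["interaction_beta"] != 0] if g in in_view]
        d_main = np.array([pair_dist(g) for g in main])
        d_inter = np.array([pair_dist(g) for g in inter])
        thr = np.percentile(d_inter, 10)
        assert np.median(d_main) < thr
        assert (d_main < thr).mean() >= 0.9

    def test_unbalanced_design_rejected(self, two_factor):
        bundle, _, tr = two_factor
        keep = bundle.metadata.sample_ids[:-1]  # break one cell
        meta = p.SampleMetadata(bundle.metadata.factors.loc[keep])
        reduced = TransformedMatrix(
            tr.values[keep], tr.method, tr.params,
            SizeFactors(tr.size_factors.values.loc[keep]),
        )
        with pytest.raises(p.ValidationError, match="unbalanced"):
            p.pca_multifactor(reduced, meta, "tissue", "condition", 100)

    def test_unknown_factor_rejected(self, sim):
        with pytest.raises(p.ValidationError, match="nope"):
            p.pca_multifactor(sim["transformed"], sim["bundle"].metadata,
                              "nope", "condition", 100)


def test_scores_preserve_sample_distances(sim):
    """Squared distances between full score vectors equal squared Euclidean
    distances over the centered ntop-gene matrix (orthogonal invariance)."""
    res = p.pca_samples(sim["transformed"], 300)
    genes = p.select_top_variable(sim["transformed"], 300)
    X = sim["transformed"].values.loc[genes].T.to_numpy()
    Xc = X - X.mean(axis=0, keepdims=True)
    from scipy.spatial.distance import pdist
    d_data = pdist(Xc) ** 2
    d_score = pdist(res.scores.to_numpy()) ** 2
    assert np.max(np.abs(d_data - d_score)) < 1e-6
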