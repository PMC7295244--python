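import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eigenmap.assoc import (
    build_network,
    catalog_overlap,
    classify_hits,
    clump_loci,
    fit_null,
    genomic_inflation,
    kinship,
    ols_scan,
    qq_points,
    replicate,
    scan,
)
from conftest import make_genotypes


class TestKinship:
    def test_ibs_identical_and_opposite(self):
        G = np.array([[0, 1, 2, 0], [0, 1, 2, 0], [2, 1, 0, 2]], dtype=float)
        K = kinship(make_genotypes(G), "ibs")
        assert K[0, 1] == pytest.approx(1.0)
        # rows 0 and 2 differ by 2 at three variants, 0 at one: mean (2-|d|)/2
        assert K[0, 2] == pytest.approx(np.mean([(2 - 2) / 2] * 3 + [(2 - 0) / 2]))
        np.testing.assert_allclose(K, K.T)
        assert np.all(np.diag(K) == 1.0)

    def test_fully_opposite_pair_is_zero(self):
        G = np.array([[0, 0, 0], [2, 2, 2]], dtype=float)
        K = kinship(make_genotypes(G), "ibs")
        assert K[0, 1] == 0.0

    def test_grm_matches_matrix_oracle(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, (10, 100)).astype(float)
        K = kinship(make_genotypes(G), "grm")
        p = G.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        Z = (G[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        np.testing.assert_allclose(K, Z @ Z.T / keep.sum(), atol=1e-12)


class TestFitNull:
    def test_identity_kinship_recovers_ols_variance(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        fit = fit_null(y, X, np.eye(n))
        ols_var = np.var(y - y.mean(), ddof=1) * (n - 1) / (n - 1)
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(ols_var, rel=1e-5)

    def test_variance_components_recovered(self):
        """sigma_g2=2, sigma_e2=1 on a fixed kinship, n=500: medians over
        20 seeds within 30%."""
        rng = np.random.default_rng(2)
        n = 500
        A = rng.standard_normal((n, n // 2))
        K = A @ A.T / (n // 2)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        X = np.ones((n, 1))
        sg, se = [], []
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            y = np.sqrt(2.0) * (L @ r.standard_normal(n)) + r.standard_normal(n)
            fit = fit_null(y, X, K)
            sg.append(fit.sigma_g2)
            se.append(fit.sigma_e2)
        assert np.median(sg) == pytest.approx(2.0, rel=0.3)
        assert np.median(se) == pytest.approx(1.0, rel=0.3)

    def test_refined_loglik_dominates_grid(self):
        rng = np.random.default_rng(3)
        n = 80
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        fit = fit_null(y, X, K)
        from eigenmap.assoc import _reml_loglik

        S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
        w, U = np.linalg.eigh(S @ K @ S)
        order = np.argsort(w)[::-1]
        xi = np.clip(w[order][: n - 1], 0, None)
        eta2 = (U[:, order][:, : n - 1].T @ y) ** 2
        grid_best = max(_reml_loglik(g, xi, eta2) for g in np.linspace(-5, 5, 101))
        assert fit.reml_loglik >= grid_best - 1e-9

    def test_asymmetric_kinship_rejected(self):
        with pytest.raises(ValueError):
            fit_null(np.zeros(3), np.ones((3, 1)), np.array([[1.0, 0.5, 0], [0.4, 1, 0], [0, 0, 1]]))


class TestScan:
    def _fixture(self, seed=4, n=50, m=20):
        rng = np.random.default_rng(seed)
        geno = make_genotypes(rng.integers(0, 3, (n, m)).astype(float))
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        K = K / np.diag(K).mean()
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        return y, X, K, geno

    def test_identity_kinship_equals_ols(self):
        y, X, _, geno = self._fixture()
        n = len(y)
        null = fit_null(y, X, np.eye(n))
        res = scan(y, X, np.eye(n), geno, null)
        res0 = ols_scan(y, X, geno)
        np.testing.assert_allclose(res["p"], res0["p"], atol=1e-10)

    def test_matches_explicit_gls_oracle(self):
        y, X, K, geno = self._fixture()
        n, m = geno.n_samples, geno.n_variants
        null = fit_null(y, X, K)
        res = scan(y, X, K, geno, null)
        V = null.sigma_g2 * K + null.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        for j in range(m):
            Xg = np.column_stack([X, geno.dosages[:, j]])
            XtVi = Xg.T @ Vi
            b = np.linalg.solve(XtVi @ Xg, XtVi @ y)
            r = y - Xg @ b
            s2 = (r @ Vi @ r) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(XtVi @ Xg)[1, 1])
            t = b[1] / se
            p_ref = 2 * stats.t.sf(abs(t), n - 2)
            assert res["p"].iloc[j] == pytest.approx(p_ref, rel=1e-8)
            assert res["beta"].iloc[j] == pytest.approx(b[1], rel=1e-8)

    def test_constant_dosage_flagged(self):
        y, X, K, geno = self._fixture()
        geno.dosages[:, 0] = 1.0
        null = fit_null(y, X, K)
        res = scan(y, X, K, geno, null)
        assert res["p"].iloc[0] == 1.0 and res["beta"].iloc[0] == 0.0
        assert bool(res["constant_dosage"].iloc[0])

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(5)
        n = 300
        geno = make_genotypes(rng.binomial(2, 0.3, (n, 30)).astype(float))
        g = geno.dosages[:, 7]
        z = (g - g.mean()) / g.std()
        y = np.sqrt(0.15) * z + np.sqrt(0.85) * rng.standard_normal(n)
        X = np.ones((n, 1))
        res = ols_scan(y, X, geno)
        assert res.nsmallest(1, "p")["id"].iloc[0] == "v8"
        assert res["p"].min() < 1e-5


class TestGenomicInflation:
    def test_all_half_gives_exactly_one(self):
        assert genomic_inflation(np.full(99, 0.5)) == pytest.approx(1.0)

    def test_uniform_null_calibrated(self):
        rng = np.random.default_rng(6)
        lam = genomic_inflation(rng.uniform(0, 1, 100_000) + 1e-12)
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([0.5, 0.0]))
        with pytest.raises(ValueError):
            genomic_inflation(np.array([1.2]))


class TestQQPoints:
    def test_single_point(self):
        e, o = qq_points(np.array([0.5]))
        assert e[0] == pytest.approx(-np.log10(0.5))
        assert o[0] == pytest.approx(-np.log10(0.5))

    def test_monotone_coordinates(self):
        rng = np.random.default_rng(7)
        e, o = qq_points(rng.uniform(0, 1, 500) + 1e-12)
        assert np.all(np.diff(e) >= 0) and np.all(np.diff(o) >= 0)

    def test_uniform_sample_near_diagonal(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 20_000) + 1e-12
        e, o = qq_points(p)
        # KS-style bound away from the extreme tail
        mask = e < 3
        assert np.max(np.abs(e[mask] - o[mask])) < 0.25


class TestHitsAndLoci:
    def _results(self, ps, pos=None, chrom=None):
        m = len(ps)
        return pd.DataFrame(
            {
                "trait_id": "t",
                "id": [f"v{j}" for j in range(m)],
                "chrom": chrom if chrom is not None else ["1"] * m,
                "pos": pos if pos is not None else np.arange(m) * 1000,
                "beta": 0.1,
                "se": 0.01,
                "stat": 1.0,
                "p": ps,
            }
        )

    def test_threshold_classification(self):
        res = self._results([4e-6, 3e-8, 2e-5])
        hits = classify_hits(res)
        got = dict(zip(hits["id"], hits["label"]))
        assert got == {"v0": "suggestive", "v1": "significant"}  # v2 unlabeled

    def test_pooling_keeps_min_p_per_variant(self):
        res = pd.concat(
            [
                self._results([1e-6]).assign(trait_id="a"),
                self._results([1e-9]).assign(trait_id="b"),
            ]
        )
        hits = classify_hits(res, pool_traits=True)
        assert len(hits) == 1 and hits["trait_id"].iloc[0] == "b"

    def test_clump_within_window_single_locus(self):
        hits = classify_hits(self._results([1e-6, 1e-7, 1e-6], pos=[100, 500, 900]))
        out = clump_loci(hits, window_bp=1000)
        assert out["locus_id"].nunique() == 1

    def test_clump_across_chromosomes(self):
        hits = classify_hits(
            self._results([1e-6, 1e-6], pos=[100, 100], chrom=["1", "2"])
        )
        out = clump_loci(hits, window_bp=1000)
        assert out["locus_id"].nunique() == 2

    def test_clump_greedy_hand_case(self):
        """Hits at 1e6, 1.9e6, 3.1e6 with 1 Mb window, strongest at 1.9e6:
        the first two join one locus, the third is its own."""
        hits = classify_hits(
            self._results([1e-6, 1e-8, 1e-6], pos=[1_000_000, 1_900_000, 3_100_000])
        )
        out = clump_loci(hits, window_bp=1_000_000)
        by_pos = out.set_index("pos")["locus_id"]
        assert by_pos[1_000_000] == by_pos[1_900_000]
        assert by_pos[3_100_000] != by_pos[1_900_000]
        assert out["locus_id"].nunique() == 2

    def test_replication_flags(self):
        disc = classify_hits(self._results([1e-6, 1e-6, 1e-6]))
        other = self._results([0.03, 0.2, 0.5]).iloc[:2]  # v2 untested
        out = replicate(disc, {"tcx": other}, alpha=0.05)
        status = dict(zip(out["id"], out["tcx_status"]))
        assert status == {
            "v0": "replicated", "v1": "not_replicated", "v2": "untested"
        }

    def test_catalog_overlap_threshold(self):
        hits = classify_hits(self._results([1e-6, 1e-6]))
        catalog = pd.DataFrame(
            {
                "variant_id": ["v0", "v1", "junk"],
                "trait": ["depression", "neuroticism", "x"],
                "p": [1e-9, 1e-6, "bad"],
            }
        )
        out = catalog_overlap(hits, catalog)
        assert list(out["catalog_trait"]) == ["depression"]
        assert out.attrs["malformed_catalog_rows"] == 1

    def test_empty_catalog(self):
        hits = classify_hits(self._results([1e-6]))
        out = catalog_overlap(
            hits, pd.DataFrame(columns=["variant_id", "trait", "p"])
        )
        assert len(out) == 0


class TestBuildNetwork:
    def _clumped(self, trait, ids, loci):
        return pd.DataFrame(
            {"trait_id": trait, "id": ids, "chrom": "1",
             "pos": range(len(ids)), "p": 1e-6, "locus_id": loci}
        )

    def test_shared_locus(self):
        tables = {
            "submodule": pd.concat(
                [
                    self._clumped("eig:a", ["v1"], ["L1"]),
                    self._clumped("eig:b", ["v1"], ["L1"]),
                ]
            )
        }
        G = build_network(tables)
        assert G.number_of_nodes() == 3 and G.number_of_edges() == 2
        assert G.in_degree("locus:L1") == 2

    def test_disjoint_loci_components(self):
        tables = {
            "subtype": pd.concat(
                [
                    self._clumped("spec:1", ["v1"], ["L1"]),
                    self._clumped("spec:2", ["v2"], ["L2"]),
                ]
            )
        }
        G = build_network(tables)
        assert nx.number_weakly_connected_components(G) == 2
        for _, _, d in G.edges(data=True):
            assert d["association_class"] == "subtype"

    def test_duplicate_edges_collapse(self):
        tables = {
            "module": self._clumped("m", ["v1", "v2"], ["L1", "L1"])
        }
        G = build_network(tables)
        assert G.number_of_edges() == 1
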