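import numpy as np
import pandas as pd
import pytest

from eigenmap.io import RunConfig
from eigenmap.preprocess import standardize
from eigenmap.refine import (
    detect_gene_sets,
    eigengene,
    eigengene_matrix,
    iterative_refine,
    kme,
    soft_adjacency,
    topological_overlap,
)


def _factor_block(rng, n, loadings, factor=None):
    """Genes x samples block generated from one latent factor."""
    f = rng.standard_normal(n) if factor is None else factor
    rows = [
        lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n) for lam in loadings
    ]
    return np.asarray(rows), f


class TestSoftAdjacency:
    def test_power_of_correlation(self):
        # two exact profiles with correlation 0.9 and -0.9
        n = 1000
        rng = np.random.default_rng(0)
        f = rng.standard_normal(n)
        e = rng.standard_normal(n)
        x = f
        y = 0.9 * f + np.sqrt(1 - 0.81) * e
        expr = standardize(
            pd.DataFrame([x, y, -y], index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(n)])
        )
        A = soft_adjacency(expr, beta=6.0)
        r = np.corrcoef(x, y)[0, 1]
        assert A[0, 1] == pytest.approx(abs(r) ** 6, abs=1e-12)
        assert A[0, 2] == pytest.approx(abs(r) ** 6, abs=1e-12)  # unsigned
        assert A[1, 2] == pytest.approx(1.0)  # identical up to sign
        assert A[0, 0] == 1.0

    def test_invalid_power_rejected(self):
        expr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("xyz"))
        with pytest.raises(ValueError):
            soft_adjacency(expr, beta=0.5)


class TestTopologicalOverlap:
    def test_complete_graph_is_all_ones(self):
        A = np.ones((3, 3))
        np.testing.assert_allclose(topological_overlap(A), np.ones((3, 3)))

    def test_empty_graph_off_diagonal_zero(self):
        A = np.eye(4)
        T = topological_overlap(A)
        assert np.all(T[~np.eye(4, dtype=bool)] == 0)
        assert np.all(np.diag(T) == 1)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1, (5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = topological_overlap(A)
        # brute-force evaluation of the defining formula
        n = 5
        ref = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(A[i, u] for u in range(n) if u != i)
                k_j = sum(A[j, u] for u in range(n) if u != j)
                ref[i, j] = (l_ij + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
        np.testing.assert_allclose(T, ref, atol=1e-12)

    def test_asymmetric_input_rejected(self):
        A = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError):
            topological_overlap(A)


class TestDetectGeneSets:
    def _two_block_tom(self, seed=2, n=200, size=40):
        rng = np.random.default_rng(seed)
        lam = np.sqrt(0.8)  # within-block correlation 0.8
        b1, _ = _factor_block(rng, n, [lam] * size)
        b2, _ = _factor_block(rng, n, [lam] * size)
        X = np.vstack([b1, b2])
        ids = [f"g{i}" for i in range(2 * size)]
        expr = standardize(pd.DataFrame(X, index=ids,
                                        columns=[f"s{i}" for i in range(n)]))
        A = soft_adjacency(expr, 6.0)
        return topological_overlap(A), ids, size

    def test_recovers_planted_blocks(self):
        tom, ids, size = self._two_block_tom()
        sets, residual = detect_gene_sets(tom, ids, min_size=20)
        assert len(sets) == 2
        assert {frozenset(ids[:size]), frozenset(ids[size:])} == set(sets)
        assert residual == frozenset()

    def test_min_size_larger_than_input_dissolves_all(self):
        tom, ids, _ = self._two_block_tom()
        sets, residual = detect_gene_sets(tom, ids, min_size=len(ids) + 1)
        assert sets == [] and residual == frozenset(ids)

    def test_permutation_invariance(self):
        tom, ids, _ = self._two_block_tom()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(ids))
        sets1, _ = detect_gene_sets(tom, ids, min_size=20)
        sets2, _ = detect_gene_sets(
            tom[np.ix_(perm, perm)], [ids[i] for i in perm], min_size=20
        )
        assert set(sets1) == set(sets2)


class TestEigengene:
    def test_two_identical_genes(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        expr = standardize(pd.DataFrame([x, x], index=["a", "b"],
                                        columns=[f"s{i}" for i in range(50)]))
        eg = eigengene(expr)
        r = np.corrcoef(eg, expr.loc["a"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert eg.var(ddof=1) == pytest.approx(1.0)

    def test_sign_contract_under_global_flip(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 40))
        expr = standardize(pd.DataFrame(X, index=[f"g{i}" for i in range(6)],
                                        columns=[f"s{i}" for i in range(40)]))
        eg1 = eigengene(expr)
        eg2 = eigengene(-expr)
        # mean profile flips, eigengene flips with it; alignment holds both times
        np.testing.assert_allclose(eg1.to_numpy(), -eg2.to_numpy(), atol=1e-10)
        for e, m in [(eg1, expr), (eg2, -expr)]:
            assert np.corrcoef(e, m.mean(axis=0))[0, 1] >= 0

    def test_variance_explained_matches_full_svd(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 50))
        expr = standardize(pd.DataFrame(X, index=[f"g{i}" for i in range(10)],
                                        columns=[f"s{i}" for i in range(50)]))
        M = expr.to_numpy()
        s = np.linalg.svd(M, compute_uv=False)
        # kME^2 summed over genes against the eigengene reproduces the
        # leading singular value share of a rank-1 factor summary
        eg = eigengene(expr)
        proj = M @ (eg / np.linalg.norm(eg))
        assert (proj**2).sum() == pytest.approx(s[0] ** 2, rel=1e-10)

    def test_single_gene_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["a"], columns=list("xyz"))
        with pytest.raises(ValueError):
            eigengene(expr)


class TestKme:
    def test_identical_pair_gives_one(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(30)
        expr = standardize(pd.DataFrame([x, x], index=["a", "b"],
                                        columns=[f"s{i}" for i in range(30)]))
        k = kme(expr, eigengene(expr))
        np.testing.assert_allclose(k, 1.0, atol=1e-10)

    def test_orthogonal_gene_near_zero(self):
        rng = np.random.default_rng(8)
        n = 3000
        f = rng.standard_normal(n)
        g = rng.standard_normal(n)
        expr = standardize(pd.DataFrame([f, f, g], index=["a", "b", "c"],
                                        columns=[f"s{i}" for i in range(n)]))
        eg = eigengene(expr.loc[["a", "b"]])
        k = kme(expr, eg)
        assert abs(k["c"]) < 0.08

    def test_planted_loading_recovered(self):
        rng = np.random.default_rng(9)
        n = 500
        X, f = _factor_block(rng, n, [0.8] + [0.85] * 20)
        expr = standardize(pd.DataFrame(X, index=[f"g{i}" for i in range(21)],
                                        columns=[f"s{i}" for i in range(n)]))
        eg = eigengene(expr)
        assert kme(expr, eg)["g0"] == pytest.approx(0.8, abs=0.05)

    def test_zero_variance_eigengene_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["x", "y"])
        flat = pd.Series([0.0, 0.0], index=["x", "y"])
        with pytest.raises(ValueError):
            kme(expr, flat)


class TestIterativeRefine:
    def _planted_module(self, seed=10, n=300, per_sub=40, noise=8):
        rng = np.random.default_rng(seed)
        b1, f1 = _factor_block(rng, n, rng.uniform(0.7, 0.9, per_sub))
        b2, f2 = _factor_block(rng, n, rng.uniform(0.7, 0.9, per_sub))
        nz, _ = _factor_block(rng, n, rng.uniform(0.0, 0.2, noise), factor=f1)
        X = np.vstack([b1, b2, nz])
        ids = (
            [f"a{i}" for i in range(per_sub)]
            + [f"b{i}" for i in range(per_sub)]
            + [f"n{i}" for i in range(noise)]
        )
        expr = standardize(pd.DataFrame(X, index=ids,
                                        columns=[f"s{i}" for i in range(n)]))
        return expr, ids, per_sub, noise

    def test_recovers_planted_submodules_and_drops_noise(self):
        expr, ids, per_sub, noise = self._planted_module()
        cfg = RunConfig(min_module_size=20, seed=0)
        subs, dropped = iterative_refine(expr, cfg, parent_label="mod")
        assert len(subs) == 2
        recovered = {frozenset(s.genes) for s in subs}
        planted = {frozenset(ids[:per_sub]), frozenset(ids[per_sub: 2 * per_sub])}
        # allow a few low-kME members to drop, but sets must align
        for rec in recovered:
            assert max(len(rec & p) / len(p) for p in planted) > 0.9
        noise_ids = set(ids[2 * per_sub:])
        assert len(noise_ids & dropped) >= 0.9 * noise

    def test_tight_set_is_fixed_point(self):
        rng = np.random.default_rng(11)
        n = 200
        X, _ = _factor_block(rng, n, [0.95] * 20)
        expr = standardize(pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                                        columns=[f"s{i}" for i in range(n)]))
        cfg = RunConfig(min_module_size=20, seed=0)
        subs, dropped = iterative_refine(expr, cfg, parent_label="tight")
        assert len(subs) == 1
        assert subs[0].genes == frozenset(expr.index)
        assert dropped == frozenset()
        assert subs[0].label == "tight_1"

    def test_low_kme_member_excluded_at_threshold(self):
        """With kme_min=0.6, a 0.3-loading gene is pruned while strong
        members survive."""
        rng = np.random.default_rng(12)
        n = 400
        X, f = _factor_block(rng, n, [0.95] * 15 + [0.9] * 15 + [0.3])
        ids = [f"hi{i}" for i in range(30)] + ["weak"]
        expr = standardize(pd.DataFrame(X, index=ids,
                                        columns=[f"s{i}" for i in range(n)]))
        cfg = RunConfig(min_module_size=20, kme_min=0.6, seed=0)
        subs, dropped = iterative_refine(expr, cfg)
        assert len(subs) == 1
        assert "weak" in dropped
        assert subs[0].kme.abs().min() >= 0.6

    def test_raising_kme_min_never_grows_submodules(self):
        expr, *_ = self._planted_module(seed=13)
        sizes = {}
        for kmin in (0.5, 0.7):
            cfg = RunConfig(min_module_size=20, kme_min=kmin, seed=0)
            subs, _ = iterative_refine(expr, cfg)
            sizes[kmin] = sorted(len(s.genes) for s in subs)
        assert sum(sizes[0.7]) <= sum(sizes[0.5])

    def test_submodules_disjoint(self, small_cohort, desk_config):
        from eigenmap.preprocess import residualize
        from eigenmap.refine import refine_all_modules

        es = standardize(
            residualize(small_cohort["expr"], small_cohort["cov"],
                        ["sex", "age_death", "batch"])
        )
        subs, _ = refine_all_modules(es, small_cohort["modules"], desk_config)
        seen = set()
        for s in subs:
            assert not (s.genes & seen)
            seen |= s.genes

    def test_refinement_sharpens_kme(self):
        """Mean |kME| of surviving members beats the parent module's genes
        against the parent eigengene."""
        expr, ids, per_sub, _ = self._planted_module(seed=14)
        cfg = RunConfig(min_module_size=20, seed=0)
        subs, _ = iterative_refine(expr, cfg)
        parent_eg = eigengene(expr)
        parent_kme = kme(expr, parent_eg).abs().mean()
        child_kme = np.mean([s.kme.abs().mean() for s in subs])
        assert child_kme >= parent_kme


class TestEigengeneMatrix:
    def test_columns_unit_variance_and_ordered(self):
        rng = np.random.default_rng(15)
        n = 100
        b1, _ = _factor_block(rng, n, [0.9] * 10)
        b2, _ = _factor_block(rng, n, [0.9] * 10)
        ids = [f"g{i}" for i in range(20)]
        expr = standardize(pd.DataFrame(np.vstack([b1, b2]), index=ids,
                                        columns=[f"s{i}" for i in range(n)]))
        cfg = RunConfig(min_module_size=5, seed=0)
        subs, _ = iterative_refine(expr, cfg, parent_label="m")
        E1 = eigengene_matrix(expr, subs)
        E2 = eigengene_matrix(expr, subs[::-1])
        assert list(E1.columns) == sorted(E1.columns)
        pd.testing.assert_frame_equal(E1, E2)
        np.testing.assert_allclose(E1.var(ddof=1), 1.0, atol=1e-10)

    def test_missing_gene_rejected(self):
        rng = np.random.default_rng(16)
        expr = standardize(pd.DataFrame(rng.standard_normal((4, 30)),
                                        index=list("abcd"),
                                        columns=[f"s{i}" for i in range(30)]))
        from eigenmap.refine import Submodule

        ghost = Submodule(
            label="x_1", genes=frozenset(["a", "ghost"]),
            eigengene=pd.Series(np.zeros(30), index=expr.columns),
            kme=pd.Series(dtype=float),
        )
        with pytest.raises(KeyError):
            eigengene_matrix(expr, [ghost])
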