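"""LD metrics, pruning, proxy removal, binning, scoring, cascade."""

import numpy as np
import pandas as pd
import pytest

from pgsx.io_formats import GenotypeMatrix
from pgsx.pgs_builder import (
    DEFAULT_BINS,
    assign_deciles,
    compute_score,
    ld_prune,
    ld_r2,
    make_definition,
    partition_by_pvalue,
    remove_proxies,
    residualize_cascade,
    PGSDefinition,
)
from pgsx.synthetic_data import SimulationParams, simulate_genotypes


def _matrix(dosages, positions=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame({
        "id": [f"s{j}" for j in range(m)],
        "chrom": "1",
        "pos": positions if positions is not None else np.arange(1, m + 1) * 100,
        "a1": "A",
        "a2": "G",
    })
    return GenotypeMatrix([f"I{i}" for i in range(n)], snps, dosages)


class TestLdR2:
    def test_self_is_one(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_complement_is_one(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(42)
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        assert ld_r2(a, b) < 0.01

    def test_constant_vector_flagged_nan(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        assert np.isnan(ld_r2(np.ones(100), g))

    def test_missing_pairs_dropped(self, rng):
        g = rng.binomial(2, 0.5, 200).astype(float)
        h = g.copy()
        h[:20] = np.nan
        assert ld_r2(g, h) == pytest.approx(1.0)


class TestLdPrune:
    def test_duplicate_snps_keep_stronger(self, rng):
        g = rng.binomial(2, 0.4, 300).astype(float)
        G = _matrix(np.column_stack([g, g]))
        prio = {"s0": 2.0, "s1": 8.0}  # -log10 p, s1 stronger
        kept = ld_prune(G, ["s0", "s1"], window=10_000, step=5, r2_max=0.5,
                        priority=prio)
        assert kept == ["s1"]

    def test_independent_snps_all_kept(self):
        rng = np.random.default_rng(3)
        G = _matrix(rng.binomial(2, 0.4, size=(2000, 8)).astype(float))
        kept = ld_prune(G, [f"s{j}" for j in range(8)], 10_000, 5, 0.5, {})
        assert kept == [f"s{j}" for j in range(8)]

    def test_correlated_block_reduced_and_constraint_holds(self):
        params = SimulationParams(n_samples=10_000, n_snps=5, n_causal=1,
                                  ld_block_size=5, ld_rho=0.95,
                                  maf_range=(0.3, 0.4), seed=13)
        G = simulate_genotypes(params)
        ids = G.snps["id"].tolist()
        prio = {s: i for i, s in enumerate(ids)}
        kept = ld_prune(G, ids, 10_000, 5, 0.5, prio)
        assert 1 <= len(kept) < 5
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                ja = ids.index(a)
                jb = ids.index(b)
                assert ld_r2(G.dosages[:, ja], G.dosages[:, jb]) <= 0.5

    def test_matches_greedy_oracle_single_window(self):
        params = SimulationParams(n_samples=5000, n_snps=5, n_causal=1,
                                  ld_block_size=5, ld_rho=0.95,
                                  maf_range=(0.3, 0.4), seed=14)
        G = simulate_genotypes(params)
        ids = G.snps["id"].tolist()
        prio = {s: float(i) for i, s in enumerate(ids)}

        # independent greedy oracle on the full window
        alive = list(range(5))
        while True:
            pair = None
            for ai in range(len(alive)):
                for bi in range(ai + 1, len(alive)):
                    i, j = alive[ai], alive[bi]
                    if ld_r2(G.dosages[:, i], G.dosages[:, j]) > 0.5:
                        pair = (i, j)
                        break
                if pair:
                    break
            if pair is None:
                break
            i, j = pair
            victim = i if prio[ids[i]] < prio[ids[j]] else j
            alive.remove(victim)
        oracle = [ids[i] for i in alive]

        kept = ld_prune(G, ids, 10_000, 5, 0.5, prio)
        assert kept == oracle

    def test_unsorted_positions_rejected(self, rng):
        G = _matrix(rng.binomial(2, 0.4, (100, 3)).astype(float),
                    positions=[300, 100, 200])
        with pytest.raises(ValueError, match="sorted"):
            ld_prune(G, ["s0", "s1", "s2"], 10_000, 5, 0.5, {})


class TestRemoveProxies:
    def test_candidate_identical_to_anchor_removed(self, rng):
        g = rng.binomial(2, 0.4, 500).astype(float)
        h = rng.binomial(2, 0.4, 500).astype(float)
        G = _matrix(np.column_stack([g, g, h]))
        kept = remove_proxies(["s1", "s2"], ["s0"], G, r2_threshold=0.2)
        assert kept == ["s2"]

    def test_empty_anchor_set_no_change(self, rng):
        G = _matrix(rng.binomial(2, 0.4, (100, 3)).astype(float))
        assert remove_proxies(["s0", "s1"], [], G) == ["s0", "s1"]

    def test_ld_blockmates_of_anchor_removed(self):
        params = SimulationParams(n_samples=10_000, n_snps=6, n_causal=1,
                                  ld_block_size=3, ld_rho=0.9,
                                  maf_range=(0.3, 0.4), seed=15)
        G = simulate_genotypes(params)
        # s0..s2 one block, s3..s5 another; anchor in the first block
        kept = remove_proxies([f"rs{i}" for i in range(2, 7)], ["rs1"], G)
        assert "rs2" not in kept and "rs3" not in kept
        assert {"rs4", "rs5", "rs6"} <= set(kept)


class TestPartition:
    def _stats(self, pvals):
        return pd.DataFrame({
            "id": [f"r{i}" for i in range(len(pvals))],
            "p": pvals,
        })

    @pytest.mark.parametrize("p,expected_bin", [
        (1e-6, "p1e7_1e5"),
        (1e-5, "p1e7_1e5"),       # right-closed boundary
        (1.00001e-5, "p1e5_1e3"),
        (0.05, "p0.01_0.05"),
        (0.95, "null_p0.95"),     # control bin closed on the left
        (1.0, "null_p0.95"),
    ])
    def test_boundary_assignment(self, p, expected_bin):
        out = partition_by_pvalue(self._stats([p]))
        for label, ids in out.items():
            if label == expected_bin:
                assert ids == ["r0"]
            else:
                assert ids == []

    def test_uniform_p_bin_sizes_match_widths(self):
        rng = np.random.default_rng(8)
        pvals = rng.uniform(0, 1, size=10_000)
        out = partition_by_pvalue(self._stats(pvals))
        for label, lo, hi in DEFAULT_BINS:
            width = hi - lo
            got = len(out[label])
            assert abs(got - 10_000 * width) < 4 * np.sqrt(10_000 * width) + 5


class TestComputeScore:
    def _stats(self, betas, alleles=None):
        m = len(betas)
        return pd.DataFrame({
            "id": [f"s{j}" for j in range(m)],
            "effect_allele": alleles or ["A"] * m,
            "other_allele": "G",
            "beta": betas,
            "se": 0.01,
            "p": 1e-8,
        })

    def test_single_snp_identity(self):
        G = _matrix([[0.0], [1.0], [2.0]])
        d = make_definition("u", self._stats([0.5]), ["s0"])
        out = compute_score(G, d)
        np.testing.assert_allclose(out["score"], [0, 1, 2])

    def test_orientation_invariance_weighted(self, rng):
        G = _matrix(rng.binomial(2, 0.4, (200, 3)).astype(float))
        stats_fwd = self._stats([0.5, -0.2, 0.3])
        stats_flip = stats_fwd.copy()
        stats_flip["effect_allele"], stats_flip["other_allele"] = (
            stats_fwd["other_allele"], stats_fwd["effect_allele"])
        stats_flip["beta"] = -stats_fwd["beta"]
        a = compute_score(G, make_definition("a", stats_fwd, list(stats_fwd["id"]),
                                             weighted=True))
        b = compute_score(G, make_definition("b", stats_flip, list(stats_flip["id"]),
                                             weighted=True))
        np.testing.assert_allclose(a["score"], b["score"], atol=1e-12)

    def test_unweighted_score_bounded(self, rng):
        G = _matrix(rng.binomial(2, 0.4, (300, 7)).astype(float))
        d = make_definition("u", self._stats(rng.standard_normal(7)),
                            [f"s{j}" for j in range(7)])
        out = compute_score(G, d)
        assert (out["score"] >= 0).all()
        assert (out["score"] <= 14).all()

    def test_absent_snp_skipped_with_count(self, rng):
        G = _matrix(rng.binomial(2, 0.4, (100, 2)).astype(float))
        table = pd.DataFrame({
            "id": ["s0", "s1", "missing_snp"],
            "effect_allele": ["A", "A", "A"],
            "weight": [1.0, 1.0, 1.0],
        })
        out = compute_score(G, PGSDefinition("x", table))
        assert out["n_snps_used"].iloc[0] == 2

    def test_allele_mismatch_skipped_zero_usable_raises(self, rng):
        G = _matrix(rng.binomial(2, 0.4, (100, 1)).astype(float))
        table = pd.DataFrame({"id": ["s0"], "effect_allele": ["T"],
                              "weight": [1.0]})
        with pytest.raises(ValueError, match="no usable"):
            compute_score(G, PGSDefinition("x", table))


class TestCascade:
    def test_identical_scores_residual_zero(self, rng):
        s = rng.standard_normal(200)
        out = residualize_cascade(pd.DataFrame({"a": s, "b": s.copy()}))
        assert np.abs(out["b"]).max() < 1e-10

    def test_collinear_previous_levels_error_names_pair(self, rng):
        s = rng.standard_normal(200)
        t = rng.standard_normal(200)
        with pytest.raises(ValueError, match="'a' and 'b'"):
            residualize_cascade(pd.DataFrame({"a": s, "b": s.copy(), "c": t}))

    def test_orthogonal_scores_pass_through_centered(self, rng):
        a = rng.standard_normal(4000)
        a -= a.mean()
        b = rng.standard_normal(4000)
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # centered and exactly uncorrelated
        out = residualize_cascade(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(out["b"], b, atol=1e-8)

    def test_matches_gram_schmidt_oracle(self, rng):
        M = rng.standard_normal((500, 4))
        M[:, 1] += 0.5 * M[:, 0]
        M[:, 2] += 0.3 * M[:, 0] - 0.2 * M[:, 1]
        M[:, 3] += 0.7 * M[:, 2]
        out = residualize_cascade(
            pd.DataFrame(M, columns=list("abcd"))).to_numpy()

        # Gram-Schmidt on [1, M] as the independent oracle; level 1 passes
        # through unchanged
        np.testing.assert_allclose(out[:, 0], M[:, 0], atol=1e-10)
        gs = np.empty_like(M)
        basis = [np.ones(500)]
        for k in range(4):
            v = M[:, k].copy()
            for u in basis:
                v -= u * (u @ v) / (u @ u)
            gs[:, k] = v
            basis.append(v)
        np.testing.assert_allclose(out[:, 1:], gs[:, 1:], atol=1e-8)

        # pairwise correlations below tolerance
        C = np.corrcoef(out, rowvar=False)
        off = np.abs(C[np.triu_indices(4, 1)])
        assert (off < 1e-8).all()

    def test_sequential_equals_joint(self, rng):
        M = rng.standard_normal((300, 3))
        joint = residualize_cascade(pd.DataFrame(M, columns=list("abc")))
        # sequential: orthogonalize b vs a, then c vs (a, b-residual)
        X1 = np.column_stack([np.ones(300), M[:, 0]])
        b_res = M[:, 1] - X1 @ np.linalg.lstsq(X1, M[:, 1], rcond=None)[0]
        X2 = np.column_stack([np.ones(300), M[:, 0], b_res])
        c_res = M[:, 2] - X2 @ np.linalg.lstsq(X2, M[:, 2], rcond=None)[0]
        np.testing.assert_allclose(joint["b"], b_res, atol=1e-8)
        np.testing.assert_allclose(joint["c"], c_res, atol=1e-8)


class TestAssignDeciles:
    def test_equal_sizes_with_ties(self):
        values = np.zeros(103)  # all tied
        bins = assign_deciles(values)
        counts = np.bincount(bins)[1:]
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 103

    def test_monotone_assignment(self, rng):
        v = rng.standard_normal(1000)
        bins = assign_deciles(v)
        assert v[bins == 10].min() >= v[bins == 1].max()
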