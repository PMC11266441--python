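"""Marker QC and relationship matrices: filters, LD pruning vs a brute-force
oracle, hand-computed GRMs, and population-structure PCA."""

import numpy as np
import pandas as pd
import pytest

from metboost import genetics as gen
from metboost.errors import MarkerOrderError, MissingSampleError, MonomorphicMarkerError


def _mm(dosage, chrom=None, pos=None, hybrids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return gen.MarkerMatrix(
        hybrids=hybrids or [f"h{i}" for i in range(n)],
        markers=pd.DataFrame(
            {
                "Marker": [f"m{j}" for j in range(m)],
                "Chrom": chrom if chrom is not None else np.ones(m, dtype=int),
                "Pos": pos if pos is not None else np.arange(1, m + 1),
            }
        ),
        dosage=dosage,
    )


class TestFilters:
    def test_keep_all_is_identity(self):
        m = _mm([[0, 1], [2, 1]])
        out = gen.filter_individuals(m, m.hybrids)
        assert out.hybrids == m.hybrids
        assert np.array_equal(out.dosage, m.dosage)

    def test_subset_respects_requested_order(self):
        m = _mm(np.arange(20).reshape(10, 2) % 3)
        out = gen.filter_individuals(m, ["h7", "h2", "h0"])
        assert out.hybrids == ["h7", "h2", "h0"]
        assert np.array_equal(out.dosage[0], m.dosage[7])

    def test_absent_sample_raises(self):
        with pytest.raises(MissingSampleError, match="hX"):
            gen.filter_individuals(_mm([[0], [1]]), ["hX"])

    def test_synthetic_keep_list_matches_plot_table(self, small_study):
        keep = sorted(small_study.plot_table["Hybrid"].unique())
        m = gen.filter_individuals(gen.from_population(small_study.population), keep)
        assert m.hybrids == keep

    def test_maf_filter_examples(self):
        m = _mm([[0, 0, 0], [0, 1, 1], [0, 1, 1], [0, 2, 2]])
        # marker 0 monomorphic (MAF 0); markers 1-2 have MAF 0.5
        out = gen.filter_maf(m, threshold=0.01)
        assert list(out.markers["Marker"]) == ["m1", "m2"]
        # threshold 0 drops nothing
        assert gen.filter_maf(m, threshold=0.0).n_markers == 3

    def test_maf_survivors_invariant_to_marker_order(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, rng.uniform(0.002, 0.3, 50), size=(40, 50)).astype(float)
        m = _mm(dosage)
        perm = rng.permutation(50)
        m_perm = gen.MarkerMatrix(
            m.hybrids,
            m.markers.iloc[perm].reset_index(drop=True),
            m.dosage[:, perm],
        )
        a = set(gen.filter_maf(m, 0.05).markers["Marker"])
        b = set(gen.filter_maf(m_perm, 0.05).markers["Marker"])
        assert a == b


def _brute_force_prune(m, window, step, r2):
    """Independent O(n^2)-per-window oracle with the same tie-break rule."""
    X = m.dosage.astype(float)
    keep = np.ones(m.n_markers, dtype=bool)
    for chrom in pd.unique(m.markers["Chrom"]):
        idx = np.flatnonzero((m.markers["Chrom"] == chrom).to_numpy())
        start = 0
        while start < len(idx):
            win = list(idx[start : start + window])
            while True:
                alive = [j for j in win if keep[j]]
                worst, pair = 0.0, None
                for ai in range(len(alive)):
                    for bi in range(ai + 1, len(alive)):
                        a, b = alive[ai], alive[bi]
                        if X[:, a].std() == 0 or X[:, b].std() == 0:
                            continue
                        r = np.corrcoef(X[:, a], X[:, b])[0, 1] ** 2
                        if r > worst:
                            worst, pair = r, (ai, bi)
                if pair is None or worst <= r2:
                    break
                means = []
                for k in pair:
                    tot = 0.0
                    for other in range(len(alive)):
                        if other == k:
                            continue
                        a, b = alive[k], alive[other]
                        if X[:, a].std() == 0 or X[:, b].std() == 0:
                            continue
                        tot += np.corrcoef(X[:, a], X[:, b])[0, 1] ** 2
                    means.append(tot / (len(alive) - 1))
                if means[0] > means[1]:
                    drop = pair[0]
                elif means[1] > means[0]:
                    drop = pair[1]
                else:
                    drop = max(pair)
                keep[alive[drop]] = False
            if start + window >= len(idx):
                break
            start += step
    return set(m.markers.loc[keep, "Marker"])


class TestLDPruning:
    def test_duplicated_marker_loses_exactly_one_copy(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.4, 30).astype(float)
        other = rng.binomial(2, 0.4, 30).astype(float)
        m = _mm(np.column_stack([col, col, other]))
        out = gen.ld_prune(m, window=10, step=5, r2=0.9)
        assert out.n_markers == 2
        assert "m2" in set(out.markers["Marker"])

    def test_independent_markers_all_retained(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.5, size=(200, 30)).astype(float)
        m = _mm(dosage)
        out = gen.ld_prune(m, window=10, step=5, r2=0.9)
        assert out.n_markers == 30

    def test_block_structure_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        cols, n = [], 120
        base = None
        for j in range(300):
            if j % 7 == 0 or base is None:
                base = rng.binomial(2, rng.uniform(0.2, 0.5), n).astype(float)
                cols.append(base.copy())
            else:  # correlated variant of the block founder
                noisy = base.copy()
                flip = rng.random(n) < 0.03
                noisy[flip] = rng.binomial(2, 0.5, flip.sum())
                cols.append(noisy)
        chrom = np.repeat([1, 2, 3], 100)
        pos = np.tile(np.arange(1, 101), 3)
        m = _mm(np.column_stack(cols), chrom=chrom, pos=pos)
        ours = set(
            gen.ld_prune(m, window=15, step=4, r2=0.8).markers["Marker"]
        )
        oracle = _brute_force_prune(m, window=15, step=4, r2=0.8)
        assert ours == oracle

    def test_unsorted_markers_rejected(self):
        m = _mm([[0, 1], [1, 2]], pos=[5, 1])
        with pytest.raises(MarkerOrderError):
            gen.ld_prune(m)


class TestRelationshipMatrices:
    def test_additive_hand_computed_two_hybrids_one_marker(self):
        # dosages 0 and 2, p = 0.5: Z = [-1, 1], denom = 0.5 -> A = [[2,-2],[-2,2]]
        A = gen.grm_additive(_mm([[0.0], [2.0]]))
        np.testing.assert_allclose(A.matrix, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_additive_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.5, 800)
        dosage = rng.binomial(2, p, size=(400, 800)).astype(float)
        A = gen.grm_additive(_mm(dosage))
        assert abs(np.diag(A.matrix).mean() - 1.0) < 0.05

    def test_additive_gram_matrix_properties(self, small_study):
        keep = sorted(small_study.plot_table["Hybrid"].unique())[:60]
        m = gen.filter_maf(
            gen.filter_individuals(gen.from_population(small_study.population), keep),
            0.01,
        )
        A = gen.grm_additive(m).matrix.to_numpy()
        assert np.allclose(A, A.T, atol=1e-10)
        # PSD spot-check on 2x2 principal minors
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j = rng.integers(0, len(A), 2)
            minor = A[i, i] * A[j, j] - A[i, j] ** 2
            assert minor >= -1e-8 or i == j

    def test_dominance_hand_computed_toy(self):
        dosage = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 1.0]])
        p = dosage.mean(axis=0) / 2.0
        q = 1 - p
        W = np.zeros_like(dosage)
        for j in range(2):
            W[:, j] = np.where(
                dosage[:, j] == 0,
                -2 * p[j] ** 2,
                np.where(dosage[:, j] == 1, 2 * p[j] * q[j], -2 * q[j] ** 2),
            )
        oracle = W @ W.T / np.sum((2 * p * q) ** 2)
        D = gen.grm_dominance(_mm(dosage))
        np.testing.assert_allclose(D.matrix, oracle, atol=1e-12)

    def test_dominance_finite_without_heterozygotes(self):
        D = gen.grm_dominance(_mm([[0.0, 2.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]]))
        assert np.isfinite(D.matrix.to_numpy()).all()

    def test_monomorphic_marker_guard(self):
        with pytest.raises(MonomorphicMarkerError):
            gen.grm_additive(_mm([[0.0, 1.0], [0.0, 2.0]]))

    def test_same_tester_hybrids_more_related_than_cross_tester(self, small_study):
        pop = small_study.population
        m = gen.filter_maf(gen.from_population(pop), 0.01)
        A = gen.grm_additive(m).matrix.to_numpy()
        tester = pop.pedigree.set_index("Hybrid").loc[m.hybrids, "Tester"].to_numpy()
        same = tester[:, None] == tester[None, :]
        off = ~np.eye(len(A), dtype=bool)
        assert A[same & off].mean() > A[~same & off].mean()

    def test_grms_reproducible(self, small_study):
        m = gen.filter_maf(gen.from_population(small_study.population), 0.01)
        a1 = gen.grm_additive(m).matrix.to_numpy()
        a2 = gen.grm_additive(m).matrix.to_numpy()
        assert np.array_equal(a1, a2)


class TestPCA:
    def test_two_duplicated_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(6)
        a = rng.binomial(2, 0.3, 50).astype(float)
        b = rng.binomial(2, 0.7, 50).astype(float)
        dosage = np.vstack([np.tile(a, (5, 1)), np.tile(b, (5, 1))])
        scores, _ = gen.pca_population(_mm(dosage), n_components=2)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()  # clean separation
        assert np.sign(pc1[:5]).std() == 0 and np.sign(pc1[5:]).std() == 0

    def test_explained_variance_ratios_valid(self, small_study):
        m = gen.from_population(small_study.population)
        _, evr = gen.pca_population(m, n_components=5)
        assert evr.sum() <= 1 + 1e-9
        assert all(x >= y - 1e-12 for x, y in zip(evr, evr[1:]))

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        dosage = rng.binomial(2, 0.4, size=(10, 50)).astype(float)
        scores, _ = gen.pca_population(_mm(dosage), n_components=3)
        Xc = dosage - dosage.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (10 - 1))
        order = np.argsort(evals)[::-1][:3]
        oracle = Xc @ evecs[:, order]
        np.testing.assert_allclose(
            np.abs(scores.to_numpy()), np.abs(oracle), atol=1e-8
        )


def test_vcf_round_trip(tmp_path, small_study):
    from metboost.synthetic import write_vcf

    path = tmp_path / "g.vcf"
    write_vcf(small_study.population, path)
    m = gen.load_vcf(path)
    assert m.hybrids == list(small_study.population.hybrids)
    assert np.array_equal(m.dosage, small_study.population.dosage.astype(float))
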