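"""Pool-specificity and LD filtering pipelines against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from pavcall.containers import DosageMatrix, FailMatrix, MarkerMap, PavcallError
from pavcall.filters import (
    bh_adjust,
    chi2_pool_specificity,
    filter_pool_specific,
    ld_filter,
    ld_profiles,
    pairwise_r2,
)
from pavcall.popstruct import PoolAssignment


def _pools(n_a, n_b):
    ids = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return PoolAssignment(np.asarray(ids, dtype=object),
                          np.asarray(["A"] * n_a + ["B"] * n_b, dtype=object))


def _fail_col(n_fail_a, n_a, n_fail_b, n_b):
    col = [2] * n_fail_a + [0] * (n_a - n_fail_a) + [2] * n_fail_b + [0] * (n_b - n_fail_b)
    return np.asarray(col)


class TestChi2:
    def test_equal_proportions_give_zero(self):
        chi2, p = chi2_pool_specificity(_fail_col(10, 100, 10, 100), _pools(100, 100))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_contingency_oracle_exactly(self):
        col = _fail_col(50, 100, 5, 100)
        chi2, p = chi2_pool_specificity(col, _pools(100, 100))
        table = np.array([[50, 50], [5, 95]])
        chi2_ref, p_ref, _, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(chi2_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)
        assert p < 1e-10

    def test_label_swap_invariance(self):
        col = _fail_col(30, 80, 10, 120)
        pools = _pools(80, 120)
        swapped = PoolAssignment(pools.sample_ids,
                                 np.where(pools.labels == "A", "B", "A").astype(object))
        assert chi2_pool_specificity(col, pools)[0] == pytest.approx(
            chi2_pool_specificity(col, swapped)[0], abs=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(PavcallError):
            chi2_pool_specificity(_fail_col(0, 10, 0, 10), _pools(10, 10))


def _bh_oracle(p):
    """Step-up BH computed literally: adj_(i) = min_{j>=i}(p_(j) m / j), capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBH:
    def test_hand_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.8])
        assert np.allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.8], atol=1e-10)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_equal_p_unchanged_and_single_p(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)
        assert bh_adjust([0.7])[0] == pytest.approx(0.7)

    def test_adjusted_at_least_raw_and_order_equivariant(self, rng):
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(PavcallError):
            bh_adjust([0.5, 1.2])


def _fm(cols, chrom=None):
    cols = np.asarray(cols)
    m = cols.shape[0]
    mm = MarkerMap([f"f{j}" for j in range(m)], chrom or ["chr1"] * m, range(1, m + 1))
    return FailMatrix(cols.T, [f"S{i}" for i in range(cols.shape[1])], mm)


class TestPoolSpecificFilter:
    def test_planted_deletion_detected(self):
        # deletion at frequency 0.4 in pool A, absent in pool B, n = 200/pool
        col = _fail_col(80, 200, 0, 200)
        noise = [_fail_col(20 + j, 200, 20, 200) for j in range(5)]
        fm = _fm([col] + noise)
        fm.sample_ids[:] = _pools(200, 200).sample_ids
        report, sets = filter_pool_specific(fm, _pools(200, 200))
        assert "f0" in sets.failed_ps

    def test_empty_fail_matrix(self):
        fm = _fm(np.empty((0, 10), dtype=int))
        report, sets = filter_pool_specific(fm, _pools(5, 5))
        assert report.table.empty and sets.failed_ps == []

    def test_fdr_under_null(self, rng):
        """Pool-independent failures: expected kept fraction <= alpha."""
        n_pool, m = 100, 60
        kept = []
        pools = _pools(n_pool, n_pool)
        for _ in range(100):
            vals = 2 * (rng.uniform(size=(2 * n_pool, m)) < 0.1).astype(int)
            ok = (vals == 2).any(axis=0) & (vals == 0).any(axis=0)
            mm = MarkerMap([f"f{j}" for j in range(ok.sum())],
                           ["chr1"] * int(ok.sum()), range(1, int(ok.sum()) + 1))
            fm = FailMatrix(vals[:, ok], pools.sample_ids, mm)
            report, _ = filter_pool_specific(fm, pools)
            kept.append(report.table["keep"].mean())
        assert np.mean(kept) <= 0.05


class TestPairwiseR2:
    def test_identical_is_one(self):
        x = np.array([0, 0, 2, 2, 1])
        assert pairwise_r2(x, x) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert pairwise_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_one_third(self):
        assert pairwise_r2([0, 0, 0, 2], [0, 0, 2, 2]) == pytest.approx(1 / 3, abs=1e-10)

    def test_allele_relabel_invariance(self, rng):
        x = rng.integers(0, 3, 20)
        y = rng.integers(0, 3, 20)
        assert pairwise_r2(x, y) == pytest.approx(pairwise_r2(2 - x, y), abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(PavcallError):
            pairwise_r2([1, 1, 1], [0, 1, 2])


class TestLDProfiles:
    def _toy(self, rng):
        n = 40
        vals = rng.integers(0, 3, size=(n, 5))
        mm = MarkerMap([f"m{j}" for j in range(5)], ["chr1"] * 5, range(1, 6))
        dm = DosageMatrix(vals, [f"S{i}" for i in range(n)], mm)
        fail = 2 * (rng.uniform(size=n) < 0.3).astype(int)
        fmm = MarkerMap(["m2"], ["chr1"], [3])
        fm = FailMatrix(fail[:, None], dm.sample_ids, fmm)
        return dm, fm, fail

    def test_profiles_match_brute_force(self, rng):
        dm, fm, fail = self._toy(rng)
        u, v = ld_profiles("m2", fm, dm)
        others = [0, 1, 3, 4]
        u_ref = [pairwise_r2(fail, dm.values[:, j]) for j in others]
        v_ref = [pairwise_r2(dm.values[:, 2], dm.values[:, j]) for j in others]
        assert np.allclose(u, u_ref, atol=1e-10)
        assert np.allclose(v, v_ref, atol=1e-10)
        assert len(u) == len(v)

    def test_duplicated_fail_column_gives_r2_one(self, rng):
        dm, fm, fail = self._toy(rng)
        vals = np.column_stack([dm.values, fail])
        mm = MarkerMap([f"m{j}" for j in range(5)] + ["dup"], ["chr1"] * 6, range(1, 7))
        dm2 = DosageMatrix(vals, dm.sample_ids, mm)
        u, v = ld_profiles("m2", fm, dm2)
        assert u.max() == pytest.approx(1.0)

    def test_too_few_neighbours_flagged(self, rng):
        dm, fm, _ = self._toy(rng)
        dm_single = dm.subset_markers([1, 2])
        with pytest.raises(PavcallError, match="fewer than 2"):
            ld_profiles("m2", fm, dm_single)


class TestLDFilter:
    def test_deletion_haplotype_kept_random_dropped(self):
        """Failures riding a haplotype survive; independent failures do not."""
        from pavcall.preprocess import preprocess
        from pavcall.synth import (
            DeletionEvent,
            PopulationConfig,
            add_technical_failures,
            generate_population,
        )

        # deletion frequency below the haplotype-allele frequency, so the
        # SNP copy keeps segregating after carriers go FF
        dels = [DeletionEvent("chr1", 40, 43, 0.3, 0.25)]
        cfg = PopulationConfig(n_per_pool=150, n_chrom=2, markers_per_chrom=100,
                               fst=0.1, rho=0.95, deletions=dels, seed=21,
                               epsilon=0.0, n_trait_qtl=10,
                               anc_freq_range=(0.5, 0.9))
        cm, truth, _ = generate_population(cfg)
        cm = add_technical_failures(cm, 0.10, seed=22)
        dm, fm, _ = preprocess(cm, seed=23)
        report, sets = ld_filter(fm, dm)
        planted = set(cm.map.marker_id[truth.in_deletion]) & set(fm.map.marker_id)
        assert planted, "planted deletion markers must survive the frequency filter"
        kept = set(sets.failed_ld)
        assert len(planted & kept) / len(planted) >= 0.75
        random_markers = set(fm.map.marker_id) - planted
        dropped = random_markers - kept
        assert len(dropped) / len(random_markers) >= 0.9

    def test_unlinked_snps_keep_markers(self, rng):
        """With mutually unlinked SNPs u ~ v ~ 0: the known failure mode."""
        n, m = 120, 30
        vals = rng.integers(0, 3, size=(n, m))
        mm = MarkerMap([f"m{j}" for j in range(m)], ["chr1"] * m, range(1, m + 1))
        dm = DosageMatrix(vals, [f"S{i}" for i in range(n)], mm)
        fail_cols = 2 * (rng.uniform(size=(n, 5)) < 0.2).astype(int)
        fmm = MarkerMap([f"m{j}" for j in range(5)], ["chr1"] * 5, range(1, 6))
        fm = FailMatrix(fail_cols, dm.sample_ids, fmm)
        report, sets = ld_filter(fm, dm)
        assert report.table["keep"].mean() >= 0.5
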