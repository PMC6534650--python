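import math

import numpy as np
import pandas as pd
import pytest

from aberex import (
    RobustCenter,
    SetTooLargeError,
    SingularScatterError,
    bh_fdr,
    delta_ssmd,
    exhaustive_mcd,
    mahalanobis,
    mcd_location_scatter,
    permutation_test,
    run_screen,
    ssmd,
    subsample_case_screen,
)
from aberex.io_formats import GeneSet, GeneSetCollection
from conftest import make_bundle


def brute_md(x, loc, scatter):
    """Explicit-inverse Mahalanobis distance (independent oracle)."""
    d = np.asarray(x) - loc
    return float(np.sqrt(d @ np.linalg.inv(scatter) @ d))


def identity_center(p):
    return RobustCenter(location=np.zeros(p), scatter=np.eye(p),
                        h_subset=np.arange(p + 1), h=p + 1, n=p + 1)


class TestMcd:
    def test_one_dimensional_outlier_rejected(self):
        # controls (0,1,2,3,100), h = 4: tightest 4-subset is {0,1,2,3}
        c = mcd_location_scatter(np.array([[0.0, 1, 2, 3, 100]]), alpha=0.8)
        assert c.h == 4
        np.testing.assert_allclose(c.location, [1.5])
        np.testing.assert_array_equal(np.sort(c.h_subset), [0, 1, 2, 3])
        np.testing.assert_allclose(c.scatter, [[np.var([0, 1, 2, 3], ddof=1)]])

    def test_clean_gaussian_location_near_mean(self, rng):
        X = rng.normal(0, 1, size=(2, 200))
        c = mcd_location_scatter(X, seed=0)
        se = 1 / math.sqrt(200)
        assert np.all(np.abs(c.location - X.mean(axis=1)) < 3 * se)

    @pytest.mark.parametrize("seed", range(15))
    def test_fast_equals_exhaustive_small_n(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(8, 13))
        p = int(r.integers(1, 4))
        if math.floor(0.8 * n) <= p:
            p = 1
        X = r.normal(size=(p, n))
        fast = mcd_location_scatter(X, seed=seed)
        exact = exhaustive_mcd(X)
        assert abs(np.linalg.slogdet(fast.scatter)[1]
                   - np.linalg.slogdet(exact.scatter)[1]) < 1e-9

    def test_set_too_large_error(self):
        X = np.random.default_rng(0).normal(size=(5, 6))  # h = 4 <= p = 5
        with pytest.raises(SetTooLargeError) as err:
            mcd_location_scatter(X)
        assert err.value.p == 5 and err.value.h == 4

    def test_zero_variance_gene_is_singular(self):
        X = np.vstack([np.ones(20), np.random.default_rng(0).normal(size=20)])
        with pytest.raises(SingularScatterError):
            mcd_location_scatter(X)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(4, 30))
        a = mcd_location_scatter(X, seed=7)
        b = mcd_location_scatter(X, seed=7)
        np.testing.assert_array_equal(a.scatter, b.scatter)
        np.testing.assert_array_equal(a.h_subset, b.h_subset)

    def test_matches_sklearn_raw_support_quality(self, rng):
        # independent cross-check: our h-subset determinant is no worse than
        # the subset sklearn's MinCovDet converges to (raw, un-reweighted)
        from sklearn.covariance import MinCovDet
        X = rng.normal(size=(40, 3))
        X[:4] += 8.0  # planted outliers
        ours = mcd_location_scatter(X.T, alpha=0.8, seed=0)
        sk = MinCovDet(support_fraction=0.8, random_state=0).fit(X)
        sub = X[sk.support_]
        sk_cov = np.cov(sub.T, ddof=1)
        assert np.linalg.slogdet(ours.scatter)[1] <= (
            np.linalg.slogdet(sk_cov)[1] + 1e-9)


class TestMahalanobisSsmd:
    def test_at_center_distance_zero(self):
        c = identity_center(3)
        assert mahalanobis(np.zeros(3), c) == 0.0

    def test_unit_step_identity_scatter(self):
        c = identity_center(3)
        x = np.array([1.0, 0.0, 0.0])
        assert mahalanobis(x, c) == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        c = RobustCenter(location=np.zeros(2),
                         scatter=np.array([[2.0, 1.0], [1.0, 2.0]]),
                         h_subset=np.arange(3), h=3, n=3)
        assert mahalanobis(np.ones(2), c) == pytest.approx(
            math.sqrt(2 / 3), abs=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis(np.array([np.nan, 0, 0]), identity_center(3))

    @pytest.mark.parametrize("seed", range(10))
    def test_against_explicit_inverse_oracle(self, seed):
        r = np.random.default_rng(seed)
        p = int(r.integers(2, 11))
        A = r.normal(size=(p, p))
        scatter = A @ A.T + p * np.eye(p)
        loc = r.normal(size=p)
        c = RobustCenter(location=loc, scatter=scatter,
                         h_subset=np.arange(p + 1), h=p + 1, n=p + 1)
        x = r.normal(size=p)
        assert mahalanobis(x, c) == pytest.approx(
            brute_md(x, loc, scatter), abs=1e-9)

    def test_ssmd_zero_when_cases_at_center(self):
        c = identity_center(2)
        val, md = ssmd(np.zeros((2, 5)), c)
        assert val == 0.0 and np.all(md == 0)

    def test_ssmd_single_case_md2(self):
        c = identity_center(2)
        val, md = ssmd(np.array([[2.0], [0.0]]), c)
        assert val == pytest.approx(4.0) and md[0] == pytest.approx(2.0)

    def test_ssmd_sums_per_case_squares(self, rng):
        p = 4
        A = rng.normal(size=(p, p))
        c = RobustCenter(location=rng.normal(size=p),
                         scatter=A @ A.T + p * np.eye(p),
                         h_subset=np.arange(p + 1), h=p + 1, n=p + 1)
        cases = rng.normal(size=(p, 3))
        val, md = ssmd(cases, c)
        per_case = [mahalanobis(cases[:, i], c) ** 2 for i in range(3)]
        assert val == pytest.approx(sum(per_case), abs=1e-10)
        np.testing.assert_allclose(md ** 2, per_case, atol=1e-10)

    def test_ssmd_invariant_to_case_order_and_gene_relabeling(self, rng):
        X = rng.normal(size=(3, 40))
        cases = rng.normal(size=(3, 8))
        c = mcd_location_scatter(X, seed=1)
        base, _ = ssmd(cases, c)
        perm_cases, _ = ssmd(cases[:, rng.permutation(8)], c)
        assert perm_cases == pytest.approx(base, rel=1e-12)
        gperm = rng.permutation(3)
        c2 = mcd_location_scatter(X[gperm], seed=1)
        relabeled, _ = ssmd(cases[gperm], c2)
        assert relabeled == pytest.approx(base, rel=1e-9)


def null_frames(n_genes=60, n_controls=40, n_cases=8, seed=0):
    r = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    C = pd.DataFrame(r.normal(size=(n_genes, n_controls)), index=genes)
    A = pd.DataFrame(r.normal(size=(n_genes, n_cases)), index=genes)
    return C, A, genes


class TestPermutationTest:
    def test_huge_observed_gives_p_zero(self):
        C, A, genes = null_frames()
        A2 = A.copy()
        A2.iloc[:5] += 50.0  # the observed set is wildly dispersed
        res = permutation_test(genes[:5], genes, C, A2, n_perm=50, seed=0)
        assert res.p_perm == 0.0

    def test_null_centered_cases_give_p_one(self):
        C, A, genes = null_frames()
        C2 = C.copy()
        # huge control scatter on the observed set's genes -> its case
        # distances are ~0, so every random set beats it: M = N, P = 1
        C2.iloc[:5] *= 1e4
        res = permutation_test(genes[:5], genes, C2, A, n_perm=50, seed=0)
        assert res.p_perm == 1.0

    def test_p_on_lattice_and_deterministic(self):
        C, A, genes = null_frames(seed=3)
        res = permutation_test(genes[:4], genes, C, A, n_perm=40, seed=9)
        res2 = permutation_test(genes[:4], genes, C, A, n_perm=40, seed=9)
        assert res.p_perm * 40 == int(round(res.p_perm * 40))
        assert res.p_perm == res2.p_perm
        np.testing.assert_array_equal(res.null_ssmds, res2.null_ssmds)

    def test_add_one_mode(self):
        C, A, genes = null_frames()
        a = permutation_test(genes[:4], genes, C, A, n_perm=20, seed=1)
        b = permutation_test(genes[:4], genes, C, A, n_perm=20, seed=1,
                             mode="add_one")
        M = a.p_perm * 20
        assert b.p_perm == pytest.approx((M + 1) / 21)

    def test_rejects_bad_arguments(self):
        C, A, genes = null_frames()
        with pytest.raises(ValueError):
            permutation_test(genes, genes[:3], C, A, n_perm=10)
        with pytest.raises(ValueError):
            permutation_test(genes[:4], genes, C, A, n_perm=0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_textbook_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_against_hand_step_up(self, rng):
        p = rng.uniform(size=25)
        # independent step-up oracle
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            rank = m - rank_from_top
            prev = min(prev, p[i] * m / rank)
            adj[i] = prev
        np.testing.assert_allclose(bh_fdr(p), adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestDeltaSsmd:
    def test_additive_decomposition_with_identity_center(self, rng):
        # independent standardized genes against a fixed identity scatter:
        # delta_j = sum_i z_ij^2 and the deltas sum to the SSMD exactly
        p, m, n = 5, 7, 30
        genes = [f"g{i}" for i in range(p)]
        C = pd.DataFrame(rng.normal(size=(p, n)), index=genes)
        A = pd.DataFrame(rng.normal(size=(p, m)), index=genes)

        def fixed_center(controls, _rng):
            return identity_center(controls.shape[0])

        out = delta_ssmd(genes, C, A, center_fn=fixed_center)
        total = out.attrs["ssmd"]
        assert out["delta_ssmd"].sum() == pytest.approx(total, abs=1e-8)
        expected = {g: float((A.loc[g] ** 2).sum()) for g in genes}
        for _, row in out.iterrows():
            assert row["delta_ssmd"] == pytest.approx(expected[row["gene"]],
                                                      abs=1e-8)

    def test_duplicate_genes_get_equal_delta(self, rng):
        genes = ["a", "b", "c"]
        C = pd.DataFrame(rng.normal(size=(3, 20)), index=genes)
        A = pd.DataFrame(rng.normal(size=(3, 5)), index=genes)
        C.loc["b"] = C.loc["a"]
        A.loc["b"] = A.loc["a"]

        def fixed_center(controls, _rng):
            return identity_center(controls.shape[0])

        out = delta_ssmd(genes, C, A, center_fn=fixed_center).set_index("gene")
        assert out.loc["a", "delta_ssmd"] == pytest.approx(
            out.loc["b", "delta_ssmd"], abs=1e-10)

    def test_percentages_and_sorting(self, rng):
        genes = [f"g{i}" for i in range(4)]
        C = pd.DataFrame(rng.normal(size=(4, 30)), index=genes)
        A = pd.DataFrame(rng.normal(size=(4, 6)), index=genes)
        out = delta_ssmd(genes, C, A, seed=0)
        assert list(out["delta_ssmd"]) == sorted(out["delta_ssmd"],
                                                 reverse=True)
        total = out.attrs["ssmd"]
        np.testing.assert_allclose(out["pct_of_ssmd"],
                                   100 * out["delta_ssmd"] / total)

    def test_single_gene_set_rejected(self, rng):
        C = pd.DataFrame(rng.normal(size=(1, 10)), index=["g"])
        with pytest.raises(ValueError):
            delta_ssmd(["g"], C, C)


def small_collection(genes, sizes=(4, 5, 6), seed=0):
    r = np.random.default_rng(seed)
    sets = []
    for i, s in enumerate(sizes):
        members = frozenset(r.choice(genes, size=s, replace=False))
        sets.append(GeneSet(f"S{i}", ".", members, total_count=s,
                            included_count=s))
    return GeneSetCollection(sets)


class TestRunScreen:
    def test_scores_every_eligible_set(self):
        b = make_bundle(n_genes=60, n_cases=8, n_controls=40, seed=2)
        coll = small_collection(list(b.expression.index))
        res = run_screen(b, coll, n_perm=30, seed=1, compute_delta="none")
        assert set(res.table["set"]) == {"S0", "S1", "S2"}
        assert res.table["q_bh"].notna().all()

    def test_oversized_set_skipped(self):
        b = make_bundle(n_genes=60, n_cases=5, n_controls=10, seed=2)  # h=8
        genes = list(b.expression.index)
        coll = GeneSetCollection([
            GeneSet("BIG", ".", frozenset(genes[:20]), total_count=20),
            GeneSet("OK", ".", frozenset(genes[:4]), total_count=4),
        ])
        res = run_screen(b, coll, n_perm=20, seed=0, compute_delta="none")
        assert [n for n, _ in res.skipped] == ["BIG"]
        assert list(res.table["set"]) == ["OK"]

    def test_zero_cutoff_needs_p_zero(self):
        b = make_bundle(n_genes=60, n_cases=8, n_controls=40, seed=4)
        coll = small_collection(list(b.expression.index), seed=1)
        res = run_screen(b, coll, n_perm=30, seed=1, p_cutoff=0.0,
                         compute_delta="none")
        assert res.significant == [
            r.set_name for r in res.results if r.p_perm == 0.0]

    def test_delta_attached_to_significant_sets(self):
        b = make_bundle(n_genes=60, n_cases=8, n_controls=40, seed=5)
        # plant a strong dispersion signal in S0's genes
        coll = small_collection(list(b.expression.index), seed=2)
        target = sorted(coll["S0"].members)
        cases = b.samples.index[b.samples["diagnosis"] != "control"]
        b.expression.loc[target, cases] *= 6.0
        res = run_screen(b, coll, n_perm=40, seed=1, p_cutoff=0.05)
        assert "S0" in res.significant
        r0 = next(r for r in res.results if r.set_name == "S0")
        assert r0.delta is not None and len(r0.delta) == len(target)


class TestSubsampleCaseScreen:
    def test_full_size_reps_match_full_screen(self):
        b = make_bundle(n_genes=50, n_cases=6, n_controls=30, seed=6)
        coll = small_collection(list(b.expression.index), seed=3)
        full = run_screen(b, coll, n_perm=25, seed=2, compute_delta="none")
        sub = subsample_case_screen(b, coll, n_cases=6, reps=3, n_perm=25,
                                    seed=2)
        assert sub.counts == [len(full.significant)] * 3

    def test_bad_arguments(self):
        b = make_bundle(n_genes=50, n_cases=6, n_controls=30, seed=6)
        coll = small_collection(list(b.expression.index))
        with pytest.raises(ValueError):
            subsample_case_screen(b, coll, n_cases=6, reps=0, n_perm=10)
        with pytest.raises(ValueError):
            subsample_case_screen(b, coll, n_cases=7, reps=1, n_perm=10)
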