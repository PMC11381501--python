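import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from icfhear.item_bank import items_in_group
from icfhear.responses import Cohort, Respondent, ResponseValue, apply_gating
from icfhear.psychometrics import (
    bartlett_sphericity,
    cronbach_alpha,
    cronbach_alpha_matrix,
    describe_items,
    kmo,
    mann_whitney,
    paf_promax,
    promax,
    response_matrix,
    varimax,
)


# ---------------------------------------------------------------------------
# oracles


def brute_force_mw(a, b):
    """Exact two-sided Mann-Whitney by full enumeration (small n only)."""
    pooled = list(a) + list(b)
    n1, n2 = len(a), len(b)
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        u = sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return min(u_obs, n1 * n2 - u_obs), hits / total


def _cohort_from_column(bank, grades_h1, fill=2):
    """Cohort whose H.1 column is `grades_h1` and every other item `fill`."""
    rs = []
    for i, g in enumerate(grades_h1):
        responses = {
            item.id: (ResponseValue.graded(g if item.id == "H.1" else fill))
            for item in bank
        }
        rs.append(apply_gating(Respondent(id=f"R{i}", responses=responses), bank))
    return Cohort(respondents=tuple(rs))


# ---------------------------------------------------------------------------
# descriptives


class TestDescribeItems:
    def test_floor_requires_strictly_more_than_15_percent(self, bank):
        grades = [0] * 15 + [1] * 85
        cohort = _cohort_from_column(bank, grades)
        d = describe_items(cohort, bank)["H.1"]
        assert d.floor_proportion == pytest.approx(0.15)
        assert not d.floor_present

    def test_floor_present_at_16_percent(self, bank):
        grades = [0] * 16 + [1] * 84
        d = describe_items(_cohort_from_column(bank, grades), bank)["H.1"]
        assert d.floor_present
        assert not d.ceiling_present

    def test_ceiling_effect(self, bank):
        grades = [4] * 20 + [1] * 80
        d = describe_items(_cohort_from_column(bank, grades), bank)["H.1"]
        assert d.ceiling_present

    def test_constant_item(self, bank):
        d = describe_items(_cohort_from_column(bank, [2, 2, 2, 2]), bank)["H.1"]
        assert d.sd == 0.0
        assert d.median == 2.0
        assert d.min == d.max == d.mean == 2.0

    def test_zero_graded_flagged_undefined(self, bank):
        cohort = _cohort_from_column(bank, [1, 1], fill=2)
        # H.87-H.90 gated off for everyone -> no graded responses
        d = describe_items(cohort, bank)["H.88"]
        assert not d.defined
        assert d.n_graded == 0

    def test_statistics_on_graded_only(self, bank):
        d = describe_items(_cohort_from_column(bank, [0, 1, 2, 3, 4]), bank)["H.1"]
        assert d.mean == pytest.approx(2.0)
        assert d.median == 2.0
        assert d.sd == pytest.approx(np.std([0, 1, 2, 3, 4], ddof=1))


# ---------------------------------------------------------------------------
# reliability


class TestCronbachAlpha:
    def test_duplicate_items_alpha_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 5, size=50).astype(float)
        X = np.column_stack([col, col, col])
        assert cronbach_alpha_matrix(X) == pytest.approx(1.0)

    def test_compound_symmetry_closed_form(self):
        # k equicorrelated standard items: alpha = k*r / (1 + (k-1)*r)
        k, r, n = 3, 0.5, 5000
        rng = np.random.default_rng(7)
        cov = np.full((k, k), r)
        np.fill_diagonal(cov, 1.0)
        X = rng.multivariate_normal(np.zeros(k), cov, size=n)
        expected = k * r / (1 + (k - 1) * r)  # 0.75
        assert expected == 0.75
        assert cronbach_alpha_matrix(X) == pytest.approx(expected, abs=0.01)

    @given(
        st.floats(min_value=0.1, max_value=5.0),
        st.lists(st.floats(min_value=-3.0, max_value=3.0), min_size=5, max_size=5),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_common_rescaling_and_shifts(self, slope, intercepts):
        # covariance-based alpha is invariant under a common positive
        # slope and arbitrary per-item intercepts
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5)) + rng.normal(size=(40, 1))
        a0 = cronbach_alpha_matrix(X)
        X2 = slope * X + np.asarray(intercepts)
        assert cronbach_alpha_matrix(X2) == pytest.approx(a0, abs=1e-9)

    def test_adding_duplicate_item_never_decreases_alpha(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 6)) + 0.8 * rng.normal(size=(60, 1))
        a0 = cronbach_alpha_matrix(X)
        X2 = np.column_stack([X, X[:, 0]])
        assert cronbach_alpha_matrix(X2) >= a0 - 1e-12

    def test_listwise_deletion_counts(self, bank, default_cohort):
        cohort, _ = default_cohort
        ids = items_in_group(bank, "all_scored")
        res = cronbach_alpha(cohort, ids, bank)
        mat = response_matrix(cohort, bank, ids)
        assert res.n_complete_respondents == int(mat.dropna().shape[0])
        assert res.n_items == 78
        assert res.alpha <= 1.0

    def test_zero_variance_error(self, bank):
        cohort = _cohort_from_column(bank, [2, 2, 2])
        with pytest.raises(ValueError):
            cronbach_alpha(cohort, ["H.2", "H.3"], bank)


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(2 / 20)

    def test_tied_identical_groups(self):
        res = mann_whitney([1, 2], [1, 2])
        assert res.statistic == 2
        assert res.p_value == pytest.approx(1.0)

    def test_all_identical_values(self):
        res = mann_whitney([3, 3, 3], [3, 3])
        assert res.p_value == 1.0

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    @settings(max_examples=120, deadline=None)
    def test_agrees_with_brute_force(self, a, b):
        res = mann_whitney(a, b)
        u_oracle, p_oracle = brute_force_mw(a, b)
        assert res.method in ("exact", "degenerate")
        assert res.statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_u_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            res = mann_whitney(a, b)
            assert 0 <= res.statistic <= len(a) * len(b)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        res = mann_whitney(a, b)
        assert res.method == "asymptotic"
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# adequacy statistics


class TestKmo:
    def test_two_variables_exactly_half(self):
        R = np.array([[1.0, 0.42], [0.42, 1.0]])
        assert kmo(R) == pytest.approx(0.5)

    def test_single_factor_data_high_kmo(self):
        rng = np.random.default_rng(21)
        n, p, lam = 500, 10, 0.8
        f = rng.normal(size=(n, 1))
        X = lam * f + math.sqrt(1 - lam**2) * rng.normal(size=(n, p))
        R = np.corrcoef(X, rowvar=False)
        assert kmo(R) > 0.8

    def test_near_identity_low_kmo(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(500, 10))
        R = np.corrcoef(X, rowvar=False)
        assert kmo(R) < 0.65

    def test_singular_matrix_error(self):
        R = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular|regulariz"):
            kmo(R)


class TestBartlett:
    def test_df_for_78_items(self):
        chi2, df, p = bartlett_sphericity(np.eye(78), n=215)
        assert df == 3003

    @pytest.mark.parametrize("p_items", [2, 3, 10, 78, 90])
    def test_df_formula(self, p_items):
        _, df, _ = bartlett_sphericity(np.eye(p_items), n=500)
        assert df == p_items * (p_items - 1) // 2

    def test_identity_matrix_null(self):
        chi2, _, p = bartlett_sphericity(np.eye(10), n=100)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computation_p3(self):
        r = 0.5
        R = np.full((3, 3), r)
        np.fill_diagonal(R, 1.0)
        n = 50
        # det = 1 - 3r^2 + 2r^3 = 0.5
        det = 1 - 3 * r**2 + 2 * r**3
        expected = -(n - 1 - (2 * 3 + 5) / 6) * math.log(det)
        chi2, df, p = bartlett_sphericity(R, n=n)
        assert df == 3
        assert chi2 == pytest.approx(expected)
        assert p == pytest.approx(float(stats.chi2.sf(expected, 3)))

    def test_non_positive_determinant_error(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            bartlett_sphericity(R, n=10)


# ---------------------------------------------------------------------------
# factoring


def tucker_congruence(a, b):
    return float(a @ b / math.sqrt((a @ a) * (b @ b)))


def match_factors(loadings, truth):
    """Greedy match of estimated factors to planted ones, sign-resolved."""
    k = truth.shape[1]
    used = set()
    phis = []
    for j in range(k):
        best, best_phi = None, 0.0
        for m in range(loadings.shape[1]):
            if m in used:
                continue
            phi = tucker_congruence(loadings[:, m], truth[:, j])
            if abs(phi) > abs(best_phi):
                best, best_phi = m, phi
        used.add(best)
        phis.append(abs(best_phi))
    return phis


class TestPafPromax:
    def planted_two_factor_data(self, n=2000, loading=0.8, seed=13):
        rng = np.random.default_rng(seed)
        p_half = 10
        L = np.zeros((2 * p_half, 2))
        L[:p_half, 0] = loading
        L[p_half:, 1] = loading
        f = rng.normal(size=(n, 2))
        eps = rng.normal(size=(n, 2 * p_half)) * np.sqrt(1 - loading**2)
        return f @ L.T + eps, L

    def test_two_factor_recovery(self):
        X, L = self.planted_two_factor_data()
        res = paf_promax(X)
        assert res.n_factors == 2  # Kaiser retention
        phis = match_factors(res.loadings, L)
        assert min(phis) > 0.95
        assert res.converged
        assert np.all(res.communalities >= 0) and np.all(res.communalities <= 1)

    def test_single_factor_promax_equals_unrotated(self):
        rng = np.random.default_rng(17)
        f = rng.normal(size=(1000, 1))
        X = 0.7 * f + rng.normal(size=(1000, 8)) * 0.5
        res = paf_promax(X, retention=1)
        # one factor: rotation is a no-op up to sign
        rot, phi = promax(res.loadings)
        assert np.allclose(np.abs(rot), np.abs(res.loadings))
        assert phi.shape == (1, 1)

    def test_single_factor_ssq_equals_reduced_eigenvalue(self):
        rng = np.random.default_rng(19)
        f = rng.normal(size=(2000, 1))
        X = 0.75 * f + rng.normal(size=(2000, 6)) * 0.6
        res = paf_promax(X, retention=1, tol=1e-9, max_iter=1000)
        R = np.corrcoef(X, rowvar=False)
        Rred = R.copy()
        np.fill_diagonal(Rred, res.communalities)
        top_eig = np.linalg.eigvalsh(Rred).max()
        assert (res.loadings**2).sum() == pytest.approx(top_eig, abs=1e-6)

    def test_variance_explained_and_eigen_count(self):
        X, _ = self.planted_two_factor_data()
        res = paf_promax(X)
        assert 0 < res.variance_explained < 1
        assert res.n_factors == int((res.eigenvalues > 1).sum())

    def test_constant_item_rejected(self):
        X = np.random.default_rng(1).normal(size=(100, 4))
        X[:, 2] = 3.0
        with pytest.raises(ValueError, match="constant"):
            paf_promax(X)

    def test_retention_bounds(self):
        X = np.random.default_rng(2).normal(size=(100, 4))
        with pytest.raises(ValueError):
            paf_promax(X, retention=9)

    def test_varimax_preserves_communalities(self):
        rng = np.random.default_rng(23)
        A = rng.normal(size=(12, 3))
        V, T = varimax(A)
        assert np.allclose(T @ T.T, np.eye(3), atol=1e-8)
        assert np.allclose((V**2).sum(axis=1), (A**2).sum(axis=1), atol=1e-8)

    def test_block_structure_recovered_from_synthetic_cohort(self, bank):
        # inflate the default generator ninefold and check hearing vs
        # non-hearing items load on disjoint factor blocks
        from icfhear.synthetic import DEFAULT_SUBGROUP_SIZES, GeneratorConfig, generate_cohort

        sizes = {k: v * 9 for k, v in DEFAULT_SUBGROUP_SIZES.items()}
        cfg = GeneratorConfig(seed=5, subgroup_sizes=sizes)
        cohort, _ = generate_cohort(cfg, bank)
        ids = items_in_group(bank, "all_scored")
        mat = response_matrix(cohort, bank, ids)
        res = paf_promax(mat, retention=7)
        primary = np.argmax(np.abs(res.loadings), axis=1)
        hearing = set(items_in_group(bank, "hearing_related"))
        h_factors = {primary[i] for i, item_id in enumerate(ids) if item_id in hearing}
        nh_factors = {primary[i] for i, item_id in enumerate(ids) if item_id not in hearing}
        assert h_factors.isdisjoint(nh_factors)
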