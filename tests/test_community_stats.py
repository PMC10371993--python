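import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.spatial.distance import pdist, squareform

import oceanconn as oc
from oceanconn.community_stats import DegeneratePairError

from conftest import make_sample_table


def table_from_matrix(X, depths=None):
    rows = []
    for k, ab in enumerate(X):
        d = 25.0 if depths is None else depths[k]
        rows.append((f"s{k}", 7.0 + 0.01 * k, 57.0, d, ab))
    return make_sample_table(rows)


def dmat(D, labels=None):
    n = D.shape[0]
    return oc.DissimilarityMatrix(
        D=D, labels=labels or [str(i) for i in range(n)]
    )


# ---------------------------------------------------------------------------
# Bray-Curtis

class TestBrayCurtis:
    def test_identical_samples_have_zero_distance(self):
        t = table_from_matrix(np.array([[1.0, 2, 3], [1, 2, 3]]))
        assert oc.bray_curtis(t).D[0, 1] == 0.0

    def test_disjoint_species_sets_have_unit_distance(self):
        t = table_from_matrix(np.array([[5.0, 0, 2], [0, 7, 0]]))
        assert oc.bray_curtis(t).D[0, 1] == 1.0

    def test_printed_formula_example(self):
        t = table_from_matrix(np.array([[1.0, 2, 0], [3, 0, 1]]))
        assert oc.bray_curtis(t).D[0, 1] == pytest.approx(5 / 7)

    def test_degenerate_pair_names_samples(self):
        t = table_from_matrix(np.array([[0.0, 0, 0], [0, 0, 0], [1, 1, 1]]))
        with pytest.raises(DegeneratePairError, match="s0.*s1"):
            oc.bray_curtis(t)

    def test_matches_scipy_pairwise(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 500, size=(12, 9)).astype(float)
        D = oc.bray_curtis(table_from_matrix(X)).D
        for i, j in itertools.combinations(range(12), 2):
            assert D[i, j] == pytest.approx(scipy_bc(X[i], X[j]), abs=1e-12)

    def test_scale_sensitive_no_standardisation(self):
        # multiplying one sample by c changes BC exactly per the raw formula
        x = np.array([1.0, 2, 3])
        y = np.array([2.0, 2, 1])
        for c in (2.0, 10.0):
            t = table_from_matrix(np.vstack([x, c * y]))
            expect = np.abs(x - c * y).sum() / (x + c * y).sum()
            assert oc.bray_curtis(t).D[0, 1] == pytest.approx(expect)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        X=arrays(
            float, (5, 4),
            elements=st.floats(0, 1e4, allow_nan=False, allow_infinity=False),
        ).filter(lambda X: (X.sum(axis=1) > 0).all())
    )
    def test_bounds_and_symmetry(self, X):
        D = oc.bray_curtis(table_from_matrix(X)).D
        assert np.all(D >= 0) and np.all(D <= 1 + 1e-12)
        np.testing.assert_allclose(D, D.T)


# ---------------------------------------------------------------------------
# NMDS

class TestNmds2:
    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(42)
        X = rng.random((6, 2))
        D = dmat(squareform(pdist(X)))
        ordn = oc.nmds2(D, n_restarts=20, seed=1)
        assert ordn.stress <= 1e-3
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(X, ordn.coordinates)
        assert disparity <= 1e-3

    def test_four_equidistant_points_hit_the_2d_stress_floor(self):
        """4 equidistant points need 3-D; the 2-D floor comes from direct
        numeric minimisation of raw stress-1 over configurations."""
        from scipy.optimize import minimize

        D = dmat(np.ones((4, 4)) - np.eye(4))
        dvec = D.condensed()

        def stress_of(flat):
            # oracle: metric stress against the constant dissimilarity; for
            # constant input the isotonic fit is the mean of the distances
            dist = pdist(flat.reshape(4, 2))
            dhat = np.full_like(dist, dist.mean())
            return np.sqrt(((dist - dhat) ** 2).sum() / (dist**2).sum())

        rng = np.random.default_rng(0)
        oracle = min(
            minimize(stress_of, rng.standard_normal(8), method="Nelder-Mead").fun
            for _ in range(20)
        )
        ordn = oc.nmds2(D, n_restarts=10, seed=2)
        assert ordn.stress > 0.0
        assert ordn.stress <= oracle + 1e-3

    def test_stress_sequence_non_increasing(self, hand_table):
        D = oc.bray_curtis(hand_table)
        ordn = oc.nmds2(D, n_restarts=5, seed=3)
        assert np.all(np.diff(ordn.stress_sequence) <= 1e-14)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.random((8, 2))
        base = squareform(pdist(X)) ** 0.8
        D1 = dmat(base)
        perm = rng.permutation(8)
        D2 = dmat(base[np.ix_(perm, perm)])
        o1 = oc.nmds2(D1, n_restarts=10, seed=5)
        o2 = oc.nmds2(D2, n_restarts=10, seed=5)
        assert abs(o1.stress - o2.stress) <= 1e-8
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(o1.coordinates[perm], o2.coordinates)
        assert disparity <= 1e-6

    def test_matches_sklearn_nonmetric_mds_stress(self, hand_table):
        """Independent cross-check: within 5% of sklearn's nonmetric MDS."""
        from sklearn.manifold import MDS

        D = oc.bray_curtis(hand_table)
        ours = oc.nmds2(D, n_restarts=20, seed=0)
        ref = MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            n_init=20, random_state=0, normalized_stress=True, max_iter=500,
        )
        ref.fit(D.D)
        assert ours.stress <= ref.stress_ * 1.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            oc.nmds2(dmat(np.zeros((3, 3))))


# ---------------------------------------------------------------------------
# ANOSIM

def brute_force_anosim(D, groups):
    """Naive oracle: rank loops + full enumeration over label assignments."""
    from scipy.stats import rankdata

    n = len(groups)
    pairs = list(itertools.combinations(range(n), 2))
    dvals = np.array([D[i, j] for i, j in pairs])
    ranks = rankdata(dvals)
    M = len(pairs)

    def R_of(g):
        within = [r for r, (i, j) in zip(ranks, pairs) if g[i] == g[j]]
        between = [r for r, (i, j) in zip(ranks, pairs) if g[i] != g[j]]
        return (np.mean(between) - np.mean(within)) / (M / 2)

    R_obs = R_of(groups)
    seen = set()
    count_ge = total = 0
    for perm in itertools.permutations(groups):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if R_of(perm) >= R_obs - 1e-12:
            count_ge += 1
    return R_obs, count_ge / total, total


class TestAnosim:
    def hand_D(self):
        # two groups of 3 with clear but imperfect separation
        D = np.array(
            [
                [0.0, 0.1, 0.2, 0.7, 0.8, 0.6],
                [0.1, 0.0, 0.15, 0.65, 0.75, 0.9],
                [0.2, 0.15, 0.0, 0.5, 0.65, 0.7],
                [0.7, 0.65, 0.5, 0.0, 0.2, 0.25],
                [0.8, 0.75, 0.65, 0.2, 0.0, 0.3],
                [0.6, 0.9, 0.7, 0.25, 0.3, 0.0],
            ]
        )
        return dmat(D), ["a", "a", "a", "b", "b", "b"]

    def test_perfect_separation_gives_R_one(self):
        D, groups = self.hand_D()
        res = oc.anosim(D, groups, method="exact")
        assert res.R == pytest.approx(1.0)

    def test_exact_enumeration_matches_brute_force(self):
        D, groups = self.hand_D()
        # perturb so separation is imperfect and p is informative
        Dm = D.D.copy()
        Dm[0, 3] = Dm[3, 0] = 0.05
        Dm[1, 4] = Dm[4, 1] = 0.12
        D2 = dmat(Dm)
        R_oracle, p_oracle, total = brute_force_anosim(Dm, groups)
        res = oc.anosim(D2, groups, method="exact")
        assert total == math.factorial(6) // math.factorial(3) ** 2  # 20 assignments
        assert res.R == pytest.approx(R_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_permutation_p_matches_exact_closely(self):
        D, groups = self.hand_D()
        Dm = D.D.copy()
        Dm[0, 3] = Dm[3, 0] = 0.05
        D2 = dmat(Dm)
        exact = oc.anosim(D2, groups, method="exact")
        perm = oc.anosim(D2, groups, n_perm=9999, seed=1, method="permutation")
        assert perm.R == exact.R
        assert perm.p == pytest.approx(exact.p, abs=0.02)

    def test_null_R_centred_near_zero(self):
        rng = np.random.default_rng(8)
        n = 12
        D = dmat(squareform(pdist(rng.random((n, 3)))))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        Rs = []
        for _ in range(400):
            g = rng.permutation(groups)
            Rs.append(oc.anosim(D, g, n_perm=0, seed=0).R)
        assert abs(np.mean(Rs)) < 0.02

    def test_R_bounded(self):
        rng = np.random.default_rng(9)
        for k in range(10):
            D = dmat(squareform(pdist(rng.random((8, 2)))))
            g = rng.permutation(["a"] * 4 + ["b"] * 4)
            res = oc.anosim(D, g, n_perm=99, seed=k)
            assert -1.0 <= res.R <= 1.0
            assert res.p >= 1 / (res.n_perm + 1) or res.method == "exact"

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(10)
        X = rng.random((14, 3))
        X[:7] += 0.4
        D = squareform(pdist(X))
        groups = ["a"] * 7 + ["b"] * 7
        ours = oc.anosim(dmat(D), groups, n_perm=999, seed=0, method="permutation")
        ref = skbio_anosim(DistanceMatrix(D), grouping=groups, permutations=999)
        assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)
        assert ours.p == pytest.approx(ref["p-value"], abs=0.03)

    def test_small_group_rejected(self):
        D = dmat(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError, match="2 members"):
            oc.anosim(D, ["a", "a", "a", "b"])


# ---------------------------------------------------------------------------
# Welch t and OLS

class TestWelchT:
    def test_identical_samples(self):
        t, df, p = oc.welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_formula_oracle(self):
        x = np.array([1.0, 2, 3])
        y = np.array([1.0, 2, 3, 4, 5])
        t, df, p = oc.welch_t(x, y)
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 5
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 4)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), df_hand))

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 100)
        ps = [oc.welch_t(x, x + shift)[2] for shift in (0.1, 0.5, 1.0, 2.0)]
        assert ps == sorted(ps, reverse=True)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            oc.welch_t([1.0], [1.0, 2.0])


class TestLinreg:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        res = oc.linreg(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        res = oc.linreg([0.0, 1, 2, 3], [5.0, 5, 5, 5])
        assert res.r_squared == 0.0

    def test_normal_equations_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.1, 2.6, 3.9, 4.2, 5.8])
        res = oc.linreg(x, y)
        # brute-force normal equations
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        ss_res = ((y - A @ beta) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert res.slope == pytest.approx(beta[0])
        assert res.intercept == pytest.approx(beta[1])
        assert res.r_squared == pytest.approx(1 - ss_res / ss_tot)
        # slope t-test oracle
        se = np.sqrt(ss_res / 3 / ((x - x.mean()) ** 2).sum())
        from scipy.stats import t as tdist

        assert res.p == pytest.approx(2 * tdist.sf(abs(beta[0] / se), 3))

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            oc.linreg([1.0, 1, 1], [1.0, 2, 3])
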