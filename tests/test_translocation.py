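import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynamaps import translocation as tr
from dynamaps.profiling import ProfileMatrix


def _profile_matrix(blocks, ids=None, fractions=None):
    """blocks: list of (n x F) per-replicate profile arrays (rows sum to 1)."""
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    n, F = blocks[0].shape
    ids = ids or [f"P{i}" for i in range(n)]
    fractions = fractions or [f"F{j}" for j in range(F)]
    cols = {}
    for r, b in enumerate(blocks):
        for j, f in enumerate(fractions):
            cols[f"P_M{r + 1}_{f}"] = b[:, j]
    df = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    reps = [f"M{r + 1}" for r in range(len(blocks))]
    genes = pd.Series(ids, index=df.index)
    return ProfileMatrix(df, fractions, reps, genes)


def _simplex(rng, n, F=5):
    x = rng.dirichlet(np.full(F, 2.0), size=n)
    return x


class TestDeltaProfiles:
    def test_identical_profiles_zero_delta(self, rng):
        x = _simplex(rng, 4)
        pm = _profile_matrix([x])
        dm = tr.delta_profiles(pm, pm)
        assert np.allclose(dm.deltas[0], 0.0)

    def test_worked_subtraction(self):
        c = np.array([[0.5, 0.5, 0.0, 0.0, 0.0]])
        t = np.array([[0.3, 0.5, 0.2, 0.0, 0.0]])
        dm = tr.delta_profiles(_profile_matrix([c]), _profile_matrix([t]))
        assert np.allclose(dm.deltas[0], [[-0.2, 0.0, 0.2, 0.0, 0.0]])

    def test_deltas_sum_to_zero(self, rng):
        c = [_simplex(rng, 10) for _ in range(3)]
        t = [_simplex(rng, 10) for _ in range(3)]
        dm = tr.delta_profiles(_profile_matrix(c), _profile_matrix(t))
        for D in dm.deltas:
            assert np.allclose(D.sum(axis=1), 0.0, atol=1e-9)

    def test_replicate_mismatch_rejected(self, rng):
        c = _profile_matrix([_simplex(rng, 5)] * 2)
        t = _profile_matrix([_simplex(rng, 5)] * 3)
        with pytest.raises(ValueError, match="pairing"):
            tr.delta_profiles(c, t)


class TestMahalanobis:
    def test_center_point_has_zero_distance(self, rng):
        # symmetric cloud around c plus c itself: sample mean is exactly c
        c = np.array([0.1, -0.2, 0.3, 0.0])
        V = rng.normal(size=(30, 4))
        X = np.vstack([c + V, c - V, c])
        d2, rank = tr.mahalanobis_sq(X, robust=False)
        assert rank == 4
        assert d2[-1] == pytest.approx(0.0, abs=1e-18)

    def test_classical_matches_brute_force(self, rng):
        """Full-rank fixture: distances equal (x-mu)' Sigma^-1 (x-mu) with a
        hand-coded covariance inversion."""
        X = rng.normal(size=(40, 5))
        d2, rank = tr.mahalanobis_sq(X, robust=False)
        assert rank == 5
        mu = X.mean(axis=0)
        cov = (X - mu).T @ (X - mu) / (len(X) - 1)
        inv = np.linalg.inv(cov)
        expected = np.array([(x - mu) @ inv @ (x - mu) for x in X])
        assert np.allclose(d2, expected, atol=1e-8)

    def test_rank_deficiency_handled_by_projection(self, rng):
        X = _simplex(rng, 100) - _simplex(rng, 100)  # sum-zero rows
        d2, rank = tr.mahalanobis_sq(X, robust=False)
        assert rank == 4
        assert np.isfinite(d2).all()

    def test_robust_mode_resists_gross_outlier(self, rng):
        X = rng.normal(size=(100, 4))
        Xo = X.copy()
        Xo[0] = 50.0
        base, _ = tr.mahalanobis_sq(X[1:], robust=True, seed=3)
        rob, _ = tr.mahalanobis_sq(Xo, robust=True, seed=3)
        cla, _ = tr.mahalanobis_sq(Xo, robust=False)
        # the outlier inflates classical scatter, deflating other distances;
        # the robust fit leaves the bulk essentially unchanged
        assert np.median(rob[1:]) > 1.3 * np.median(cla[1:])
        assert abs(np.median(rob[1:]) - np.median(base)) < 0.2 * np.median(base)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="proteins"):
            tr.mahalanobis_sq(rng.normal(size=(5, 5)))


class TestPvalues:
    def test_zero_distance_gives_p_one(self):
        assert tr.pvalue_chi2(0.0, df=5) == 1.0

    def test_chi2_five_df_worked_value(self):
        assert tr.pvalue_chi2(15.086, df=5) == pytest.approx(0.0100, abs=2e-4)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 30, 100)
        p = tr.pvalue_chi2(d, df=5)
        assert (np.diff(p) < 0).all()

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            tr.pvalue_chi2(1.0, df=0)


def brute_force_bh(p):
    """Step-up BH by direct enumeration (independent oracle)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


class TestMScores:
    def test_single_protein_worked_example(self):
        m, q = tr.m_scores(np.array([[0.01, 0.001, 0.005]]))
        assert m[0] == pytest.approx(6.0)
        assert q[0] == pytest.approx(1e-6)

    def test_bh_worked_enumeration(self):
        cubed = np.array([0.001, 0.02, 0.03, 0.04])
        # feed cubed values as single-replicate p with k=1 (identity power)
        m, q = tr.m_scores(cubed[:, None], n_replicates=1)
        assert np.allclose(q, [0.004, 0.04, 0.04, 0.04])
        assert np.allclose(m, -np.log10([0.004, 0.04, 0.04, 0.04]), atol=1e-12)

    def test_all_p_one_gives_zero_m(self):
        m, q = tr.m_scores(np.ones((5, 3)))
        assert np.allclose(m, 0.0)

    def test_bh_matches_brute_force(self, rng):
        p = rng.random(50)
        _, q = tr.m_scores(p[:, None], n_replicates=1)
        assert np.allclose(q, brute_force_bh(p), atol=1e-8)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            tr.m_scores(np.array([[0.5, np.nan, 0.2]]))
        with pytest.raises(ValueError):
            tr.m_scores(np.array([[0.0, 0.5, 0.2]]))


class TestRScores:
    def _dm(self, deltas):
        deltas = [np.asarray(d, dtype=float) for d in deltas]
        ids = pd.Index([f"P{i}" for i in range(deltas[0].shape[0])], name="protein_id")
        return tr.DeltaMatrix(ids, deltas, [f"F{j}" for j in range(deltas[0].shape[1])])

    def test_identical_deltas_give_one(self):
        d = np.array([[0.2, -0.1, -0.1, 0.0, 0.0]])
        r, flag = tr.r_scores(self._dm([d, d, d]))
        assert r[0] == pytest.approx(1.0)
        assert not flag[0]

    def test_anticorrelated_replicate_gives_minus_one(self):
        d = np.array([[0.2, -0.1, -0.1, 0.0, 0.0]])
        r, _ = tr.r_scores(self._dm([d, d, -d]))
        assert r[0] == pytest.approx(-1.0)

    def test_min_pairwise_pearson_worked_example(self):
        d1 = np.array([[1.0, 0.0, -1.0, 0.0, 0.0]])
        d2 = np.array([[0.0, 1.0, -1.0, 0.0, 0.0]])
        r, _ = tr.r_scores(self._dm([d1, d2, d1]))
        assert r[0] == pytest.approx(0.5)

    def test_zero_variance_flagged_as_zero(self):
        d = np.zeros((1, 5))
        live = np.array([[0.1, -0.1, 0.0, 0.0, 0.0]])
        r, flag = tr.r_scores(self._dm([d, live, live]))
        assert r[0] == 0.0 and flag[0]

    def test_fewer_than_three_replicates_rejected(self):
        d = np.array([[0.1, -0.1, 0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            tr.r_scores(self._dm([d, d]))
        r, _ = tr.r_scores(self._dm([d, d]), min_replicates=2)
        assert r[0] == pytest.approx(1.0)


class TestFdrEstimate:
    def _mr(self, m, r):
        return pd.DataFrame(
            {"m_score": m, "r_score": r},
            index=pd.Index([f"P{i}" for i in range(len(m))], name="protein_id"),
        )

    def test_direct_formula(self, rng):
        real = self._mr(
            np.r_[np.full(20, 5.0), np.zeros(1980)], np.r_[np.ones(20), np.zeros(1980)]
        )
        mock = self._mr(
            np.r_[np.full(2, 5.0), np.zeros(998)], np.r_[np.ones(2), np.zeros(998)]
        )
        assert tr.estimate_fdr(2.0, 0.5, real, mock) == pytest.approx(
            (2 / 1000) / (20 / 2000)
        )

    def test_zero_mock_hits(self):
        real = self._mr([5.0], [1.0])
        mock = self._mr([0.0], [0.0])
        assert tr.estimate_fdr(2.0, 0.5, real, mock) == 0.0

    def test_identical_lists_give_one(self):
        real = self._mr([5.0, 0.0], [1.0, 0.0])
        assert tr.estimate_fdr(2.0, 0.5, real, real) == pytest.approx(1.0)

    def test_no_real_hits_undefined(self):
        real = self._mr([0.0], [0.0])
        assert np.isnan(tr.estimate_fdr(2.0, 0.5, real, real))


class TestSelectCutoffs:
    def _mr(self, m, r, p_cubed=None):
        df = pd.DataFrame(
            {"m_score": m, "r_score": r},
            index=pd.Index([f"P{i}" for i in range(len(m))], name="protein_id"),
        )
        if p_cubed is not None:
            df["p_cubed"] = p_cubed
        return df

    def test_extreme_movers_captured_with_zero_fdr(self, rng):
        # mock has no points beyond M = 0.2; real nulls reach 0.5 and the
        # 20 injected movers sit far beyond both
        n_null = 500
        m_null = rng.uniform(0, 0.5, n_null)
        r_null = rng.uniform(-1, 0.3, n_null)
        real = self._mr(
            np.r_[np.full(20, 8.0), m_null], np.r_[np.full(20, 0.95), r_null]
        )
        mock = self._mr(rng.uniform(0, 0.2, n_null), r_null.copy())
        sel = tr.select_cutoffs(0.1, real, mock)
        assert sel is not None
        assert sel.n_hits >= 20
        assert sel.fdr == 0.0
        hits = tr.flag_movers(real, sel.m_cut, sel.r_cut)
        assert hits[:20].all()

    def test_unachievable_target_returns_none(self):
        real = self._mr([1.0, 1.0], [0.5, 0.5])
        sel = tr.select_cutoffs(0.01, real, real.copy())
        assert sel is None

    def test_mock_equivalent_m_identity_on_same_table(self, rng):
        p = np.sort(rng.random(20))
        m = -np.log10(brute_force_bh(p))
        df = self._mr(m, np.zeros(20), p_cubed=p)
        assert np.allclose(tr.mock_equivalent_m(df, df), np.maximum.accumulate(m[::-1])[::-1])


class TestPairMockMaps:
    def test_even_split(self, rng):
        maps = [_profile_matrix([_simplex(rng, 5)]) for _ in range(6)]
        c, t = tr.pair_mock_maps(maps)
        assert len(c) == 3 and len(t) == 3
        assert c[0] is maps[0] and t[0] is maps[1]

    def test_odd_count_rejected(self, rng):
        maps = [_profile_matrix([_simplex(rng, 5)]) for _ in range(3)]
        with pytest.raises(ValueError):
            tr.pair_mock_maps(maps)
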