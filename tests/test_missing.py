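"""Multiple imputation, Rubin's rules and the pooled likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, f as f_dist

from growthmsm.missing import (
    MICEImputer,
    mice_impute,
    pool_lrt_meng_rubin,
    pool_rubin,
)


class TestPoolRubin:
    def test_identical_estimates(self):
        pe = pool_rubin([1.0, 1.0, 1.0], [0.04, 0.04, 0.04])
        assert pe.qbar == 1.0 and pe.B == 0.0 and pe.T == pytest.approx(0.04)

    def test_hand_arithmetic(self):
        pe = pool_rubin([0.9, 1.0, 1.1], [0.04, 0.04, 0.04])
        assert pe.B == pytest.approx(0.01)
        assert pe.T == pytest.approx(0.04 + (4 / 3) * 0.01)
        assert pe.T == pytest.approx(0.0533333333)

    def test_homogeneity_under_scaling(self):
        c = 2.5
        pe1 = pool_rubin([0.9, 1.0, 1.1], [0.04, 0.05, 0.06])
        pe2 = pool_rubin([c * e for e in (0.9, 1.0, 1.1)],
                         [c ** 2 * v for v in (0.04, 0.05, 0.06)])
        assert pe2.W == pytest.approx(c ** 2 * pe1.W)
        assert pe2.B == pytest.approx(c ** 2 * pe1.B)
        assert pe2.T == pytest.approx(c ** 2 * pe1.T)

    def test_total_at_least_within(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            est = rng.normal(size=5)
            var = rng.uniform(0.01, 1, size=5)
            pe = pool_rubin(est, var)
            assert pe.T >= pe.W

    def test_m_equals_one_warns(self):
        with pytest.warns(UserWarning):
            pe = pool_rubin([1.3], [0.2])
        assert pe.T == 0.2 and np.isinf(pe.df)


def _quad_loglik_factory(scale=1.0):
    """Gaussian toy: dataset is (y values); model parameter is the mean."""
    def ll_full(theta, ds):
        return -0.5 * np.sum((ds - theta[0]) ** 2) / scale
    def ll_null(theta, ds):
        return -0.5 * np.sum(ds ** 2) / scale
    return ll_full, ll_null


class TestPooledLRT:
    def test_identical_datasets_degenerate(self):
        ll_full, ll_null = _quad_loglik_factory()
        ds = np.array([0.4, 0.6, 0.8])
        datasets = [ds, ds.copy(), ds.copy()]
        mle = [np.array([ds.mean()])] * 3
        null = [np.array([0.0])] * 3
        res = pool_lrt_meng_rubin(mle, null, ll_full, ll_null, datasets, k=1)
        assert res.dbar_m == pytest.approx(res.dbar_L)
        assert res.r_L == 0.0
        assert res.D3 == pytest.approx(res.dbar_L / 1)

    def test_m1_chi2_limit(self):
        ll_full, ll_null = _quad_loglik_factory()
        # craft a dataset whose LR statistic is 3.84
        n = 16
        mean = np.sqrt(3.84 / n)
        ds = np.full(n, mean)
        with pytest.warns(UserWarning):
            res = pool_lrt_meng_rubin([np.array([mean])], [np.array([0.0])],
                                      ll_full, ll_null, [ds], k=1)
        assert res.D3 == pytest.approx(3.84, abs=1e-9)
        assert res.p_value == pytest.approx(chi2.sf(3.84, 1), abs=1e-6)
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_matches_independent_reference_formulas(self):
        # independent implementation of the pooling arithmetic
        rng = np.random.default_rng(4)
        ll_full, ll_null = _quad_loglik_factory()
        datasets = [rng.normal(0.3, 1, size=30) for _ in range(3)]
        mle = [np.array([d.mean()]) for d in datasets]
        null = [np.array([0.0])] * 3
        res = pool_lrt_meng_rubin(mle, null, ll_full, ll_null, datasets, k=1)

        m, k = 3, 1
        d_own = [2 * (ll_full(mle[i], datasets[i]) - ll_null(null[i], datasets[i]))
                 for i in range(m)]
        dbar_m = np.mean(d_own)
        tbar = np.mean([t[0] for t in mle])
        d_pool = [2 * (ll_full([tbar], ds) - ll_null([0.0], ds)) for ds in datasets]
        dbar_L = np.mean(d_pool)
        r = max(((m + 1) / (k * (m - 1))) * (dbar_m - dbar_L), 0.0)
        D3 = dbar_L / (k * (1 + r))
        t = k * (m - 1)
        df_den = 4 + (t - 4) * (1 + (1 - 2 / t) / r) ** 2 if t > 4 else \
            t * (1 + 1 / k) * (1 + 1 / r) ** 2 / 2
        assert res.D3 == pytest.approx(D3, abs=1e-8)
        assert res.p_value == pytest.approx(float(f_dist.sf(D3, k, df_den)), abs=1e-8)

    def test_invariant_to_imputation_order(self):
        rng = np.random.default_rng(5)
        ll_full, ll_null = _quad_loglik_factory()
        datasets = [rng.normal(0.2, 1, size=25) for _ in range(4)]
        mle = [np.array([d.mean()]) for d in datasets]
        null = [np.array([0.0])] * 4
        res1 = pool_lrt_meng_rubin(mle, null, ll_full, ll_null, datasets, k=1)
        perm = [2, 0, 3, 1]
        res2 = pool_lrt_meng_rubin([mle[i] for i in perm], [null[i] for i in perm],
                                   ll_full, ll_null, [datasets[i] for i in perm], k=1)
        assert res1.D3 == pytest.approx(res2.D3)
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_monotone_in_dbar_L(self):
        # fixed r_L = 0: D3 grows with the pooled statistic
        ll_full, ll_null = _quad_loglik_factory()
        out = []
        for shift in (0.2, 0.4):
            ds = np.full(20, shift)
            datasets = [ds, ds.copy()]
            mle = [np.array([shift])] * 2
            null = [np.array([0.0])] * 2
            out.append(pool_lrt_meng_rubin(mle, null, ll_full, ll_null,
                                           datasets, k=1).D3)
        assert out[1] > out[0]


def test_pooled_lrt_type_i_error_under_mar():
    """End-to-end calibration: MAR missingness on a null covariate, MICE,
    then the pooled LRT rejects at roughly the nominal 5% level
    (acceptance band 2-9% at 400 replications)."""
    rng = np.random.default_rng(0)
    n, n_sim, m = 150, 400, 5
    rej = 0

    def ll_full(theta, ds):
        return -0.5 * np.sum((ds["y"].to_numpy() - theta[0]
                              - theta[1] * ds["x"].to_numpy()) ** 2)

    def ll_null(theta, ds):
        return -0.5 * np.sum((ds["y"].to_numpy() - theta[0]) ** 2)

    for sim in range(n_sim):
        x = rng.normal(size=n)
        y = 0.5 + rng.normal(size=n)            # truth: no x effect
        miss = rng.random(n) < 1 / (1 + np.exp(1.5 - 0.8 * y))  # MAR given y
        df = pd.DataFrame({"child_id": np.arange(n),
                           "x": np.where(miss, np.nan, x), "y": y})
        imps = MICEImputer(m=m, iterations=3, seed=sim, exclude=(),
                           id_cols=("child_id",)).impute(df)
        fulls, nulls = [], []
        for d in imps.datasets:
            X = np.column_stack([np.ones(n), d["x"]])
            fulls.append(np.linalg.lstsq(X, d["y"], rcond=None)[0])
            nulls.append(np.array([d["y"].mean(), 0.0]))
        res = pool_lrt_meng_rubin(fulls, nulls, ll_full, ll_null,
                                  imps.datasets, k=1)
        rej += res.p_value < 0.05
    assert 0.02 <= rej / n_sim <= 0.09, rej / n_sim


@pytest.fixture()
def missing_frame():
    rng = np.random.default_rng(11)
    n = 600
    x = rng.normal(size=n)
    group = rng.choice(["a", "b", "c"], size=n)
    binary = (rng.random(n) < 0.4).astype(float)
    cont = 1.0 + 0.5 * x + rng.normal(scale=0.5, size=n)
    df = pd.DataFrame({"child_id": np.arange(n), "x": x, "group": group,
                       "binary": binary, "cont": cont})
    mcar = rng.random(n) < 0.10
    df.loc[mcar, "binary"] = np.nan
    mcar2 = rng.random(n) < 0.10
    df.loc[mcar2, "cont"] = np.nan
    return df, mcar, mcar2


class TestMICE:
    def test_no_missing_returns_copies(self):
        df = pd.DataFrame({"child_id": [0, 1, 2], "a": [1.0, 2.0, 3.0]})
        imps = mice_impute(df, m=3, iterations=2, seed=0)
        assert len(imps.datasets) == 3
        for d in imps.datasets:
            pd.testing.assert_frame_equal(d, df)

    def test_observed_cells_untouched(self, missing_frame):
        df, mcar, mcar2 = missing_frame
        imps = mice_impute(df, m=2, iterations=3, seed=1)
        for d in imps.datasets:
            obs = ~mcar
            assert np.allclose(d.loc[obs, "binary"], df.loc[obs, "binary"])
            assert d.isna().sum().sum() == 0

    def test_mcar_frequency_consistency(self, missing_frame):
        # pooled imputed frequency close to the observed-cell frequency
        df, mcar, _ = missing_frame
        imps = mice_impute(df, m=5, iterations=5, seed=2)
        obs_freq = df["binary"].mean()  # ignores NaN
        imp_freqs = [d.loc[mcar, "binary"].mean() for d in imps.datasets]
        n_mis = mcar.sum()
        se = np.sqrt(obs_freq * (1 - obs_freq) / n_mis)
        assert abs(np.mean(imp_freqs) - obs_freq) <= 3 * se

    def test_determinism(self, missing_frame):
        df, _, _ = missing_frame
        a = mice_impute(df, m=2, iterations=2, seed=7)
        b = mice_impute(df, m=2, iterations=2, seed=7)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_all_missing_variable_errors(self):
        df = pd.DataFrame({"child_id": [0, 1], "a": [np.nan, np.nan],
                           "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            MICEImputer(m=1, iterations=1).fit(df)

    def test_categorical_imputation_keeps_categories(self, missing_frame):
        df, _, _ = missing_frame
        rng = np.random.default_rng(3)
        df = df.copy()
        df.loc[rng.random(len(df)) < 0.1, "group"] = None
        imps = mice_impute(df, m=2, iterations=3, seed=3)
        for d in imps.datasets:
            assert set(d["group"].unique()) <= {"a", "b", "c"}

    def test_serialization_round_trip(self, missing_frame, tmp_path):
        df, _, _ = missing_frame
        imps = mice_impute(df.head(100), m=2, iterations=2, seed=4)
        imps.save(tmp_path / "imps")
        assert (tmp_path / "imps" / "manifest.json").exists()
        back = pd.read_csv(tmp_path / "imps" / "imputation_00.csv")
        assert len(back) == 100
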