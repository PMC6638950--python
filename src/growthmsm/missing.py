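"""Multiple imputation by chained equations and pooling rules.

Covariates with missing values are imputed by Gibbs-style chained
equations: continuous variables by Bayesian linear regression (posterior
draws of the coefficients and residual variance), binary variables by
logistic regression with approximate posterior draws, and unordered
categoricals by multinomial sampling from per-category predicted
probabilities.  Anthropometric outcome columns are excluded from the
imputation model (they are handled by the selection model, not by MAR
imputation).

Pooling:

* :func:`pool_rubin` — Rubin's rules for a scalar estimate across the m
  completed datasets: qbar, within/between variance, total variance
  T = W + (1 + 1/m) B and small-sample degrees of freedom.
* :func:`pool_lrt_meng_rubin` — the D3 pooled likelihood-ratio statistic:
  per-imputation LR statistics are combined with a re-evaluation of the
  likelihoods at parameter values pooled (averaged) across imputations,
  referred to an F distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

__all__ = ["ImputationSet", "PooledEstimate", "PooledLRT", "MICEImputer",
           "mice_impute", "pool_rubin", "pool_lrt_meng_rubin"]


@dataclass
class ImputationSet:
    """m completed datasets plus the manifest that produced them."""

    datasets: list
    m: int
    iterations: int
    seed: int
    variable_models: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self):
        return self.m

    def save(self, directory):
        import json
        import pathlib
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets):
            df.to_csv(d / f"imputation_{i:02d}.csv", index=False)
        manifest = {"m": self.m, "iterations": self.iterations, "seed": self.seed,
                    "variable_models": self.variable_models}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


@dataclass
class PooledEstimate:
    qbar: float
    W: float
    B: float
    T: float
    df: float
    m: int

    @property
    def se(self):
        return float(np.sqrt(self.T))


@dataclass
class PooledLRT:
    dbar_m: float
    dbar_L: float
    k: int
    r_L: float
    D3: float
    df_num: int
    df_den: float
    p_value: float
    m: int


def pool_rubin(estimates, variances):
    """Rubin's rules for one scalar parameter.

    qbar = mean estimate, W = mean within variance, B = between variance
    (sample variance of the estimates), T = W + (1 + 1/m) B, and the
    standard small-sample degrees of freedom (m-1)(1 + W/((1+1/m)B))^2.
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    if est.ndim != 1 or est.shape != var.shape or len(est) < 1:
        raise ValueError("estimates and variances must be equal-length 1-d")
    if np.any(var < 0):
        raise ValueError("variances must be >= 0")
    m = len(est)
    qbar = float(est.mean())
    W = float(var.mean())
    if m == 1:
        warnings.warn("m = 1: between-imputation variance undefined; T = W",
                      stacklevel=2)
        return PooledEstimate(qbar=qbar, W=W, B=np.nan, T=W, df=np.inf, m=1)
    B = float(est.var(ddof=1))
    T = W + (1 + 1 / m) * B
    if B > 0:
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
    else:
        df = np.inf
    return PooledEstimate(qbar=qbar, W=W, B=B, T=T, df=df, m=m)


def pool_lrt_meng_rubin(full_params, null_params, loglik_full, loglik_null,
                        datasets, k):
    """Pooled likelihood-ratio test across multiply imputed datasets (D3).

    Parameters
    ----------
    full_params, null_params : per-imputation MLE parameter vectors.
    loglik_full, loglik_null : callables ``(theta, dataset) -> float``
        evaluating the respective model log-likelihoods at arbitrary
        parameter values on a completed dataset.
    datasets : the m completed datasets.
    k : number of constraints (difference in free parameters).

    The mean of the per-imputation LR statistics at their own MLEs
    (dbar_m) is combined with the mean re-evaluated at the averaged
    parameters (dbar_L); r_L = ((m+1)/(k(m-1)))(dbar_m - dbar_L) clipped
    at 0; D3 = dbar_L / (k (1 + r_L)) referred to F(k, df_den).
    """
    m = len(datasets)
    if not (len(full_params) == len(null_params) == m):
        raise ValueError("need one parameter vector per completed dataset")
    d_own = []
    for i in range(m):
        ll_f = loglik_full(full_params[i], datasets[i])
        ll_n = loglik_null(null_params[i], datasets[i])
        d_own.append(2.0 * (ll_f - ll_n))
    dbar_m = float(np.mean(d_own))
    theta_full = np.mean(np.asarray(full_params, float), axis=0)
    theta_null = np.mean(np.asarray(null_params, float), axis=0)
    d_pooled = [2.0 * (loglik_full(theta_full, ds) - loglik_null(theta_null, ds))
                for ds in datasets]
    dbar_L = float(np.mean(d_pooled))

    if m == 1:
        warnings.warn("m = 1: D3 reduces to d/k against chi2_k/k", stacklevel=2)
        D3 = dbar_L / k
        p = float(chi2.sf(dbar_L, k))
        return PooledLRT(dbar_m=dbar_m, dbar_L=dbar_L, k=k, r_L=0.0, D3=D3,
                         df_num=k, df_den=np.inf, p_value=p, m=1)

    r_L = ((m + 1) / (k * (m - 1))) * (dbar_m - dbar_L)
    if r_L < 0:
        warnings.warn("negative r_L clipped at 0 (sampling noise)", stacklevel=2)
        r_L = 0.0
    D3 = dbar_L / (k * (1 + r_L))
    t = k * (m - 1)
    if r_L == 0:
        df_den = np.inf
    elif t > 4:
        df_den = 4 + (t - 4) * (1 + (1 - 2 / t) / r_L) ** 2
    else:
        df_den = t * (1 + 1 / k) * (1 + 1 / r_L) ** 2 / 2
    p = float(f_dist.sf(D3, k, df_den)) if np.isfinite(df_den) else float(chi2.sf(k * D3, k))
    return PooledLRT(dbar_m=dbar_m, dbar_L=dbar_L, k=k, r_L=float(r_L), D3=float(D3),
                     df_num=k, df_den=float(df_den), p_value=p, m=m)


# ---------------------------------------------------------------------------
# chained-equations imputation
# ---------------------------------------------------------------------------

_DEFAULT_EXCLUDE = ("waz", "laz", "wlz", "z_true", "z_laz_true",
                    "weight_kg", "length_cm")


def _design(df, predictors):
    """Numeric design matrix with dummy coding for categoricals."""
    if not predictors:
        return np.ones((len(df), 1)), ["const"]
    X = pd.get_dummies(df[predictors], drop_first=True, dtype=float)
    return X.to_numpy(float), list(X.columns)


def _bayes_linear_draw(X, y, Xmis, rng, ridge=1e-6):
    """Posterior draw imputation for a continuous variable."""
    n, p = X.shape
    XtX = X.T @ X + ridge * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ X.T @ y
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / rng.chisquare(dof)
    beta = rng.multivariate_normal(beta_hat, sigma2 * XtX_inv, method="cholesky")
    return Xmis @ beta + rng.normal(0, np.sqrt(sigma2), len(Xmis))


def _pmm_draw(X, y, Xmis, rng, donors=5, ridge=1e-6):
    """Predictive-mean-matching imputation (optional alternative)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X + ridge * np.eye(p))
    beta_hat = XtX_inv @ X.T @ y
    pred_obs = X @ beta_hat
    pred_mis = Xmis @ beta_hat
    out = np.empty(len(Xmis))
    for i, pm in enumerate(pred_mis):
        idx = np.argsort(np.abs(pred_obs - pm))[:donors]
        out[i] = y[idx[rng.integers(len(idx))]]
    return out


def _logistic_draw(X, y, Xmis, rng):
    """Binary imputation: penalised logistic fit, approximate posterior
    coefficient draw, Bernoulli sampling."""
    clf = LogisticRegression(C=1e4, max_iter=500)
    try:
        clf.fit(X, y)
    except Exception:
        clf = LogisticRegression(C=1.0, max_iter=500)
        clf.fit(X, y)
    beta = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    Xa = np.column_stack([np.ones(len(X)), X])
    p_hat = 1 / (1 + np.exp(-(Xa @ beta)))
    Wd = np.clip(p_hat * (1 - p_hat), 1e-6, None)
    info = (Xa * Wd[:, None]).T @ Xa + 1e-6 * np.eye(Xa.shape[1])
    try:
        cov = np.linalg.inv(info)
        beta = rng.multivariate_normal(beta, cov, method="cholesky")
    except np.linalg.LinAlgError:
        warnings.warn("ridge-stabilised logistic imputation (near separation)",
                      stacklevel=3)
    Xma = np.column_stack([np.ones(len(Xmis)), Xmis])
    p_mis = 1 / (1 + np.exp(-(Xma @ beta)))
    return (rng.random(len(Xmis)) < p_mis).astype(float)


def _multinomial_draw(X, y_codes, n_cat, Xmis, rng):
    clf = LogisticRegression(C=1e4, max_iter=500)
    try:
        clf.fit(X, y_codes)
    except Exception:
        clf = LogisticRegression(C=1.0, max_iter=500)
        clf.fit(X, y_codes)
    probs = clf.predict_proba(Xmis)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(Xmis))[:, None]
    picked = (u < cum).argmax(axis=1)
    return clf.classes_[picked]


class MICEImputer(BaseEstimator):
    """Chained-equations multiple imputation.

    Parameters
    ----------
    m : number of completed datasets (independent chains).
    iterations : Gibbs sweeps per chain.
    seed : RNG seed; identical seeds give identical ImputationSets.
    exclude : columns never used as predictors nor imputed (default: the
        anthropometric measurement/z-score columns).
    id_cols : identifier columns excluded from the model.
    pmm : use predictive mean matching for continuous variables instead
        of Bayesian linear draws.
    max_missing_warn : warn when a variable is missing above this rate.
    """

    def __init__(self, m=10, iterations=10, seed=0, exclude=_DEFAULT_EXCLUDE,
                 id_cols=("child_id",), pmm=False, max_missing_warn=0.5):
        self.m = m
        self.iterations = iterations
        self.seed = seed
        self.exclude = exclude
        self.id_cols = id_cols
        self.pmm = pmm
        self.max_missing_warn = max_missing_warn

    def _model_columns(self, df):
        drop = set(self.exclude) | set(self.id_cols)
        return [c for c in df.columns if c not in drop]

    def fit(self, X, y=None):
        cols = self._model_columns(X)
        self.missing_cols_ = [c for c in cols if X[c].isna().any()]
        for c in self.missing_cols_:
            rate = X[c].isna().mean()
            if rate >= 1.0:
                raise ValueError(f"variable {c!r} is entirely missing")
            if rate > self.max_missing_warn:
                warnings.warn(f"{c!r} missing rate {rate:.0%} exceeds "
                              f"{self.max_missing_warn:.0%}", stacklevel=2)
        self.variable_models_ = {}
        for c in self.missing_cols_:
            col = X[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                n_cat = col.dropna().nunique()
                self.variable_models_[c] = "logistic" if n_cat <= 2 else "multinomial"
            else:
                vals = col.dropna().unique()
                if len(vals) <= 2 and set(np.unique(vals)) <= {0.0, 1.0}:
                    self.variable_models_[c] = "logistic"
                else:
                    self.variable_models_[c] = "pmm" if self.pmm else "bayes_linear"
        return self

    def impute(self, X):
        """Run the chains; returns an :class:`ImputationSet`."""
        if not hasattr(self, "missing_cols_"):
            self.fit(X)
        if not self.missing_cols_:
            return ImputationSet(datasets=[X.copy() for _ in range(self.m)],
                                 m=self.m, iterations=self.iterations,
                                 seed=self.seed, variable_models={})
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(self.m)
        datasets = [self._run_chain(X, np.random.default_rng(child))
                    for child in children]
        return ImputationSet(datasets=datasets, m=self.m,
                             iterations=self.iterations, seed=self.seed,
                             variable_models=dict(self.variable_models_))

    fit_transform = impute

    def _run_chain(self, X, rng):
        df = X.copy()
        cols = self._model_columns(df)
        order = sorted(self.missing_cols_, key=lambda c: df[c].isna().sum())
        na_masks = {c: df[c].isna().to_numpy() for c in order}
        # initial fill: random draws from the observed margins
        for c in order:
            obs = df.loc[~na_masks[c], c].to_numpy()
            df.loc[na_masks[c], c] = rng.choice(obs, size=na_masks[c].sum())
        for _ in range(self.iterations):
            for c in order:
                mask = na_masks[c]
                preds = [p for p in cols if p != c]
                Xd, _ = _design(df, preds)
                Xobs, Xmis = Xd[~mask], Xd[mask]
                model = self.variable_models_[c]
                if model in ("bayes_linear", "pmm"):
                    yobs = df.loc[~mask, c].to_numpy(float)
                    draw = (_pmm_draw if model == "pmm" else _bayes_linear_draw)(
                        np.column_stack([np.ones(len(Xobs)), Xobs]), yobs,
                        np.column_stack([np.ones(len(Xmis)), Xmis]), rng)
                    df.loc[mask, c] = draw
                elif model == "logistic":
                    col = df[c]
                    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                        cats = sorted(col.dropna().unique())
                        ybin = (col[~mask] == cats[-1]).to_numpy(float)
                        if len(np.unique(ybin)) < 2:
                            df.loc[mask, c] = cats[-1] if ybin.mean() > 0.5 else cats[0]
                            continue
                        draw = _logistic_draw(Xobs, ybin, Xmis, rng)
                        df.loc[mask, c] = np.where(draw > 0.5, cats[-1], cats[0])
                    else:
                        yobs = col[~mask].to_numpy(float)
                        if len(np.unique(yobs)) < 2:
                            df.loc[mask, c] = yobs[0]
                            continue
                        df.loc[mask, c] = _logistic_draw(Xobs, yobs, Xmis, rng)
                else:
                    col = df[c]
                    codes, cats = pd.factorize(col[~mask])
                    draw = _multinomial_draw(Xobs, codes, len(cats), Xmis, rng)
                    df.loc[mask, c] = cats.take(draw)
        return df


def mice_impute(data, m=10, iterations=10, seed=0, **kw):
    """Functional wrapper over :class:`MICEImputer`."""
    return MICEImputer(m=m, iterations=iterations, seed=seed, **kw).impute(data)
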