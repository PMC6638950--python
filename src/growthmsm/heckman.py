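"""Two-stage Heckman-type correction for informative longitudinal dropout.

Growth z-scores are missing at some scheduled visits, plausibly because
of the (unobserved) growth status itself.  The correction:

1. **Stage 1** — a GEE probit on the per-scheduled-visit indicator "the
   z-score was observed", clustered on child, using baseline and
   time-dependent covariates.
2. **Inverse Mills ratio** — lambda = phi(eta) / Phi(eta) at each
   observed record's stage-1 linear predictor; under a bivariate-normal
   selection model, E[outcome error | selected] is proportional to
   lambda, so adding it to the outcome model absorbs the selection bias.
3. **Stage 2** — a GEE with identity link for the marginal z trajectory
   (age + age^2 and covariates) on the observed records, with and
   without the IMR term.
4. **Cluster bootstrap** — children are resampled with replacement and
   both stages re-run per replicate: because the IMR is a generated
   regressor, analytic stage-2 standard errors are invalid.

GEE estimation is delegated to statsmodels (probit / identity families,
exchangeable or independence working correlation, robust cluster
sandwich covariance) behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = ["GEESpec", "GEEFit", "HeckmanResult", "gee_fit", "inverse_mills",
           "cluster_bootstrap", "heckman_two_stage", "HeckmanGEE"]


@dataclass
class GEESpec:
    """One GEE model: patsy formula, cluster id, link, working correlation."""

    formula: str
    groups: str = "child_id"
    link: str = "identity"             # 'identity' | 'probit'
    corstr: str = "exchangeable"       # 'exchangeable' | 'independence'
    maxiter: int = 100
    tol: float = 1e-7

    def family(self):
        if self.link == "identity":
            return sm.families.Gaussian()
        if self.link == "probit":
            return sm.families.Binomial(link=sm.families.links.Probit())
        raise ValueError(f"unsupported link {self.link!r}")

    def cov_struct(self):
        if self.corstr == "exchangeable":
            return sm.cov_struct.Exchangeable()
        if self.corstr == "independence":
            return sm.cov_struct.Independence()
        raise ValueError(f"unsupported working correlation {self.corstr!r}")


@dataclass
class GEEFit:
    """Fitted GEE: coefficients, naive and sandwich covariance, alpha."""

    params: pd.Series
    cov_robust: pd.DataFrame
    cov_naive: pd.DataFrame
    alpha: float
    converged: bool
    n_clusters: int
    n_obs: int
    spec: GEESpec
    result: object = field(repr=False, default=None)

    @property
    def se(self):
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.params.index)

    def summary_table(self, level=0.95):
        zq = norm.ppf(0.5 + level / 2)
        se = self.se
        return pd.DataFrame({
            "coef": self.params, "se": se,
            "lower": self.params - zq * se, "upper": self.params + zq * se,
            "p": 2 * norm.sf(np.abs(self.params / se)),
        })


def gee_fit(spec, data):
    """Fit one GEE model; returns a :class:`GEEFit`.

    Falls back to an independence working structure (with a warning) if
    the exchangeable update produces a singular working covariance.
    """
    data = data.dropna(subset=_formula_columns(spec.formula, data))
    fam = spec.family()
    try:
        model = smf.gee(spec.formula, groups=spec.groups, data=data,
                        family=fam, cov_struct=spec.cov_struct())
        res = model.fit(maxiter=spec.maxiter, ctol=spec.tol)
    except (np.linalg.LinAlgError, ValueError) as err:
        if spec.corstr == "independence":
            raise
        warnings.warn(f"exchangeable GEE failed ({err}); falling back to "
                      "independence", stacklevel=2)
        model = smf.gee(spec.formula, groups=spec.groups, data=data,
                        family=fam, cov_struct=sm.cov_struct.Independence())
        res = model.fit(maxiter=spec.maxiter, ctol=spec.tol)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise RuntimeError(f"GEE did not converge in {spec.maxiter} iterations "
                           f"for formula {spec.formula!r}")
    alpha = 0.0
    dep = getattr(model.cov_struct, "dep_params", None)
    if dep is not None and np.ndim(dep) == 0:
        alpha = float(dep)
    names = list(res.params.index)
    return GEEFit(
        params=res.params,
        cov_robust=pd.DataFrame(np.asarray(res.cov_robust), index=names, columns=names),
        cov_naive=pd.DataFrame(np.asarray(res.cov_naive), index=names, columns=names),
        alpha=alpha, converged=converged,
        n_clusters=len(np.unique(data[spec.groups])), n_obs=len(data),
        spec=spec, result=res,
    )


def _formula_columns(formula, data):
    """Data columns referenced by a formula (for row-wise NA dropping)."""
    import re
    tokens = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", formula))
    return [c for c in data.columns if c in tokens]


def inverse_mills(eta):
    """lambda(eta) = phi(eta)/Phi(eta), numerically stable for eta << 0.

    Evaluated as exp(logpdf - logcdf); for eta -> -inf, lambda ~ -eta
    without overflow; for eta -> +inf, lambda -> 0.
    """
    eta = np.asarray(eta, dtype=float)
    lam = np.exp(norm.logpdf(eta) - norm.logcdf(eta))
    return lam if lam.ndim else float(lam)


def cluster_bootstrap(procedure, data, reps, seed, cluster_col="child_id",
                      max_failure_rate=0.05):
    """Cluster (child-level) bootstrap of an estimation procedure.

    ``procedure(df) -> Series`` is re-run on ``reps`` resampled datasets
    in which children are drawn with replacement (every record of a
    drawn child moves together; duplicated children get fresh ids so the
    clustering structure is preserved).

    Returns
    -------
    DataFrame of replicate coefficients (one row per successful
    replicate) with attrs ``n_failed``.
    """
    if reps < 50:
        warnings.warn("fewer than 50 bootstrap replicates: percentile "
                      "intervals will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    ids = data[cluster_col].unique()
    by_id = {i: g for i, g in data.groupby(cluster_col, sort=False)}
    rows = []
    n_failed = 0
    for _ in range(reps):
        picks = rng.choice(ids, size=len(ids), replace=True)
        frames = []
        for new_id, old in enumerate(picks):
            g = by_id[old].copy()
            g[cluster_col] = new_id
            frames.append(g)
        boot = pd.concat(frames, ignore_index=True)
        try:
            rows.append(procedure(boot))
        except Exception as err:  # noqa: BLE001 - replicate-level failure
            n_failed += 1
            warnings.warn(f"bootstrap replicate failed: {err}", stacklevel=2)
    if reps and n_failed / reps > max_failure_rate:
        raise RuntimeError(f"{n_failed}/{reps} bootstrap replicates failed")
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.attrs["n_failed"] = n_failed
    return out


def bootstrap_summary(replicates, point, level=0.95):
    """Percentile CIs and symmetry p-values from replicate coefficients."""
    a = (1 - level) / 2
    rows = {}
    for c in replicates.columns:
        r = replicates[c].dropna().to_numpy()
        lo, hi = np.quantile(r, [a, 1 - a]) if len(r) else (np.nan, np.nan)
        p = 2 * min((r <= 0).mean(), (r >= 0).mean()) if len(r) else np.nan
        rows[c] = {"coef": point.get(c, np.nan), "se": r.std(ddof=1) if len(r) > 1 else np.nan,
                   "lower": lo, "upper": hi, "p": min(p, 1.0)}
    return pd.DataFrame(rows).T


@dataclass
class HeckmanResult:
    stage1: GEEFit
    imr: pd.Series
    stage2_naive: GEEFit
    stage2_corrected: GEEFit
    bootstrap: pd.DataFrame | None
    bootstrap_table: pd.DataFrame | None

    def table5_style(self):
        """Side-by-side with/without-IMR coefficient blocks."""
        naive = self.stage2_naive.summary_table().add_prefix("naive_")
        if self.bootstrap_table is not None:
            corr = self.bootstrap_table.add_prefix("corrected_")
        else:
            corr = self.stage2_corrected.summary_table().add_prefix("corrected_")
        return naive.join(corr, how="outer")


def heckman_two_stage(data, stage1_formula, stage2_formula,
                      groups="child_id", corstr="exchangeable",
                      stage1_corstr=None, bootstrap_reps=500, seed=0,
                      check_exclusion=True):
    """Run the full two-stage selection-corrected analysis.

    Parameters
    ----------
    data : scheduled-visit table; the stage-1 response column must be the
        0/1 indicator that the growth outcome was observed at the visit,
        and stage 2 is fit on the observed records only.
    stage1_formula, stage2_formula : patsy formulas, e.g.
        ``"observed ~ group + age_years + site"`` and
        ``"z ~ group + age_years + I(age_years**2)"``.
    bootstrap_reps : cluster-bootstrap replicates for the corrected
        model (0 skips the bootstrap; analytic SEs are then invalid for
        the IMR-adjusted fit and only point estimates should be used).
    check_exclusion : warn when stage 1 has no covariate absent from
        stage 2 (identification then rests on the probit nonlinearity).

    Returns a :class:`HeckmanResult`.
    """
    s1_cols = set(_formula_columns(stage1_formula, data))
    s2_cols = set(_formula_columns(stage2_formula, data))
    if check_exclusion and not (s1_cols - s2_cols - {stage1_formula.split("~")[0].strip()}):
        warnings.warn("no exclusion restriction: every stage-1 covariate also "
                      "appears in stage 2; identification rests on the probit "
                      "nonlinearity", stacklevel=2)

    obs_col = stage1_formula.split("~")[0].strip()

    def run_both(df):
        s1 = gee_fit(GEESpec(stage1_formula, groups=groups, link="probit",
                             corstr=stage1_corstr or corstr), df)
        design = s1.result.model.exog
        eta = pd.Series(design @ s1.params.to_numpy(),
                        index=s1.result.model.data.row_labels)
        lam_all = inverse_mills(eta)
        df = df.copy()
        df["imr"] = pd.Series(lam_all, index=eta.index).reindex(df.index)
        observed = df[df[obs_col] == 1]
        s2n = gee_fit(GEESpec(stage2_formula, groups=groups, link="identity",
                              corstr=corstr), observed)
        s2c = gee_fit(GEESpec(stage2_formula + " + imr", groups=groups,
                              link="identity", corstr=corstr), observed)
        return s1, df["imr"], s2n, s2c

    s1, imr, s2n, s2c = run_both(data)

    boot = boot_table = None
    if bootstrap_reps:
        def proc(df):
            return run_both(df)[3].params
        boot = cluster_bootstrap(proc, data, bootstrap_reps, seed, cluster_col=groups)
        boot_table = bootstrap_summary(boot, s2c.params)

    return HeckmanResult(stage1=s1, imr=imr[data[obs_col] == 1],
                         stage2_naive=s2n, stage2_corrected=s2c,
                         bootstrap=boot, bootstrap_table=boot_table)


class HeckmanGEE(BaseEstimator):
    """Estimator wrapper around :func:`heckman_two_stage`.

    Parameters mirror the function; after ``fit(data)`` the attributes
    ``stage1_``, ``imr_``, ``stage2_naive_``, ``stage2_corrected_`` and
    ``bootstrap_`` hold the fitted pieces.
    """

    def __init__(self, stage1_formula="observed ~ age_years + group + site",
                 stage2_formula="z ~ age_years + I(age_years**2) + group",
                 groups="child_id", corstr="exchangeable", stage1_corstr=None,
                 bootstrap_reps=500, seed=0):
        self.stage1_formula = stage1_formula
        self.stage2_formula = stage2_formula
        self.groups = groups
        self.corstr = corstr
        self.stage1_corstr = stage1_corstr
        self.bootstrap_reps = bootstrap_reps
        self.seed = seed

    def fit(self, data, y=None):
        res = heckman_two_stage(
            data, self.stage1_formula, self.stage2_formula, groups=self.groups,
            corstr=self.corstr, stage1_corstr=self.stage1_corstr,
            bootstrap_reps=self.bootstrap_reps, seed=self.seed)
        self.result_ = res
        self.stage1_ = res.stage1
        self.imr_ = res.imr
        self.stage2_naive_ = res.stage2_naive
        self.stage2_corrected_ = res.stage2_corrected
        self.bootstrap_ = res.bootstrap
        return self
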