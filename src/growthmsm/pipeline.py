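"""End-to-end orchestration: covariate recoding, descriptive tables,
variable selection, and the two analysis arms (multi-state incidence and
Heckman-corrected growth evolution) for each anthropometric index.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, norm

from .anthropometry import classify_states, compute_zscores, synthetic_reference_table
from .heckman import heckman_two_stage
from .missing import MICEImputer, pool_lrt_meng_rubin, pool_rubin
from .multistate import MarkovMultiState
from .synthetic import panel_from_cohort, simulate_cohort

__all__ = ["AnalysisConfig", "ReportBundle", "recode_covariates",
           "describe_cohort", "summarize_children", "select_variables",
           "run_retardation_analysis", "run_growth_evolution", "plot_mean_z"]


@dataclass
class AnalysisConfig:
    """Configuration of one per-index analysis run."""

    index: str = "waz"                       # 'waz' | 'laz' | 'wlz'
    covariates: tuple = ("group_HI", "group_HIL", "group_HUU")
    m: int = 10
    mice_iterations: int = 10
    bootstrap_reps: int = 500
    entry_p: float = 0.25
    retention_p: float = 0.05
    band_edges: tuple = (6.0, 12.0, 60.0)
    seed: int = 0

    def validate(self):
        if not (0 < self.retention_p <= self.entry_p < 1):
            raise ValueError("need 0 < retention_p <= entry_p < 1")
        if self.index not in ("waz", "laz", "wlz"):
            raise ValueError(f"unknown index {self.index!r}")
        return self

    def manifest(self):
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]
        return d


@dataclass
class ReportBundle:
    """Artifacts of one analysis arm; every number is traceable to a fit."""

    hazard_ratios: pd.DataFrame | None = None
    intensities: pd.DataFrame | None = None
    growth_tables: pd.DataFrame | None = None
    descriptives: dict | None = None
    pooled: dict | None = None
    selection_trace: list | None = None
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# covariate recoding
# ---------------------------------------------------------------------------

def _anemia_class(hb, age_months):
    """WHO 2011 age-dependent haemoglobin classification."""
    if pd.isna(hb):
        return None
    if hb < 7.0:
        return "severe"
    if age_months < 24.0:
        return "none" if hb >= 11.0 else "mild_moderate"
    return "none" if hb >= 10.0 else "mild_moderate"


_MARITAL_MAP = {
    "married": "married", "cohabitation": "cohabitation",
    "single": "single_divorced_widow", "divorced": "single_divorced_widow",
    "widow": "single_divorced_widow",
}

_SIGN_COLS = ("fever", "jaundice", "hepatomegaly", "adenopathy", "parotitis")


def recode_covariates(raw):
    """Derive the analysis covariates from raw visit columns.

    Applied rules: marital status collapsed to married / cohabitation /
    single-divorced-widow; household income dichotomised at 100,000 CFA;
    CD4 dichotomised strictly below 25%; haemoglobin classified by the
    age-dependent WHO 2011 anemia cutoffs; "general signs" = any of
    fever, jaundice, hepatomegaly, adenopathy, parotitis; SGAG =
    gestational-age-and-sex-adjusted birth-weight z < -2; small birth
    size = any birth-length z < -2.  Columns absent from ``raw`` are
    skipped; unknown category codes raise with the offending rows.
    """
    df = raw.copy()
    if "marital" in df:
        bad = df["marital"].dropna()[~df["marital"].dropna().isin(_MARITAL_MAP)]
        if len(bad):
            raise ValueError(f"unknown marital codes at rows {list(bad.index[:10])}")
        df["marital"] = df["marital"].map(_MARITAL_MAP)
    if "income_cfa" in df:
        df["income_lt_100k"] = (df["income_cfa"] < 100_000).astype(float).where(df["income_cfa"].notna())
    if "cd4_pct" in df:
        df["cd4_lt25"] = (df["cd4_pct"] < 25.0).astype(float).where(df["cd4_pct"].notna())
    if "hemoglobin" in df:
        df["anemia"] = [
            _anemia_class(h, a) for h, a in zip(df["hemoglobin"], df["age_months"])
        ]
    present_signs = [c for c in _SIGN_COLS if c in df]
    if present_signs:
        df["general_signs"] = df[present_signs].fillna(0).astype(float).max(axis=1)
    if "birth_weight_z_adj" in df:
        df["sgag"] = (df["birth_weight_z_adj"] < -2).astype(float).where(df["birth_weight_z_adj"].notna())
    if "birth_length_z" in df:
        df["small_birth"] = (df["birth_length_z"] < -2).astype(float).where(df["birth_length_z"].notna())
    return df


# ---------------------------------------------------------------------------
# descriptive tables
# ---------------------------------------------------------------------------

def summarize_children(visits, z_cols=("waz", "laz", "wlz"), ltfu_gap=12.0):
    """Child-level summary from a visit table.

    ``ever_*`` flags are NA when the child was never assessed on that
    index; LTFU = no observed visit for more than ``ltfu_gap`` months.
    """
    rows = []
    for cid, g in visits.groupby("child_id"):
        g = g.sort_values("age_months")
        obs = g[g.get("observed", pd.Series(True, index=g.index)).astype(bool)]
        rec = {"child_id": cid}
        for c in ("group", "sex", "site"):
            if c in g:
                rec[c] = g[c].iloc[0]
        rec["deceased"] = bool((g["state"] == 3).any()) if "state" in g else False
        for zc, name in zip(z_cols, ("underweight", "stunted", "wasted")):
            if zc in obs:
                z = obs[zc].dropna()
                rec[f"ever_{name}"] = bool((z < -2).any()) if len(z) else None
        times = obs["age_months"].to_numpy()
        gaps = np.diff(times) if len(times) > 1 else np.array([])
        last_gap = 60.0 - times[-1] if len(times) and not rec["deceased"] else 0.0
        rec["ltfu"] = bool((gaps > ltfu_gap).any() or last_gap > ltfu_gap)
        rows.append(rec)
    return pd.DataFrame(rows)


def _pct(n, d):
    return 100.0 * n / d if d else np.nan


def _group_test(table):
    """Chi-square with Fisher fallback for any expected cell < 5 (2xk only)."""
    table = np.asarray(table, float)
    table = table[:, table.sum(axis=0) > 0]
    if table.size == 0 or table.shape[1] < 2:
        return np.nan
    chi2_stat, p, _, expected = chi2_contingency(table)
    if (expected < 5).any() and table.shape == (2, 2):
        _, p = fisher_exact(table)
    return float(p)


def describe_cohort(children, groups=("HI", "HIL", "HEU", "HUU")):
    """Descriptive tables from a child-level summary table.

    Returns a dict with overall counts/percentages (sex, group, vital
    status, LTFU), the per-index "experienced at least once" table with
    per-group breakdown and a chi-square/Fisher comparison, and the
    same flags among deceased children.  Percentages are both raw and
    rounded to one decimal (reporting convention).
    """
    n = len(children)
    out = {"n": n, "groups": {}, "overall": {}, "malnutrition": {},
           "among_deceased": {}, "group_tests": {}}
    for g in groups:
        ng = int((children["group"] == g).sum()) if "group" in children else 0
        out["groups"][g] = {"n": ng, "pct": _pct(ng, n)}
    if "sex" in children:
        nf = int((children["sex"] == "female").sum())
        out["overall"]["female"] = {"n": nf, "pct": _pct(nf, n)}
    if "deceased" in children:
        nd = int(children["deceased"].sum())
        out["overall"]["deceased"] = {"n": nd, "pct": _pct(nd, n)}
    if "ltfu" in children:
        nl = int(children["ltfu"].astype(bool).sum())
        out["overall"]["ltfu"] = {"n": nl, "pct": _pct(nl, n)}
    for name in ("underweight", "stunted", "wasted"):
        col = f"ever_{name}"
        if col not in children:
            continue
        assessed = children[children[col].notna()]
        ne = int(assessed[col].astype(bool).sum())
        entry = {"n_assessed": len(assessed), "n_ever": ne,
                 "pct": _pct(ne, len(assessed)),
                 "pct_rounded": round(_pct(ne, len(assessed)), 1)}
        by_group = {}
        tab = []
        for g in groups:
            sub = assessed[assessed["group"] == g] if "group" in assessed else assessed.iloc[0:0]
            ng, nge = len(sub), int(sub[col].astype(bool).sum()) if len(sub) else 0
            by_group[g] = {"n": ng, "n_ever": nge, "pct": _pct(nge, ng)}
            tab.append([nge, ng - nge])
        entry["by_group"] = by_group
        out["malnutrition"][name] = entry
        out["group_tests"][name] = _group_test(np.array(tab).T)
        if "deceased" in children:
            dec = children[children["deceased"].astype(bool) & children[col].notna()]
            nde = int(dec[col].astype(bool).sum())
            out["among_deceased"][name] = {
                "n_assessed": len(dec), "n_ever": nde,
                "pct": _pct(nde, len(dec)),
                "pct_rounded": round(_pct(nde, len(dec)), 1)}
    for k, v in list(out["overall"].items()):
        v["pct_rounded"] = round(v["pct"], 1)
    for g, v in out["groups"].items():
        v["pct_rounded"] = round(v["pct"], 1)
    return out


# ---------------------------------------------------------------------------
# variable selection
# ---------------------------------------------------------------------------

def select_variables(candidates, p_fn, entry_p=0.25, retention_p=0.05,
                     interaction_fn=None):
    """Univariable screen then backward elimination.

    ``p_fn(current_vars, var)`` returns the p-value for ``var`` in a
    model containing ``current_vars`` (pooled LRT for multi-state fits,
    Wald for GEE).  Before each removal, ``interaction_fn(var,
    retained)`` may return significant interaction terms to retain.
    Returns ``(final_spec, trace)``; the trace replays deterministically.
    """
    trace = []
    screened = []
    for v in candidates:
        p = p_fn([v], v)
        trace.append({"step": "screen", "variable": v, "p": p,
                      "kept": bool(p < entry_p)})
        if p < entry_p:
            screened.append(v)
    if not screened:
        warnings.warn("no candidate passed the univariable screen; "
                      "returning intercept-only model", stacklevel=2)
        return [], trace
    current = list(screened)
    interactions = []
    while current:
        ps = {v: p_fn([c for c in current if c != v] + interactions, v)
              for v in current}
        worst = max(ps, key=ps.get)
        if ps[worst] <= retention_p:
            break
        if interaction_fn is not None:
            kept_inter = interaction_fn(worst, [c for c in current if c != worst])
            for term in kept_inter or []:
                interactions.append(term)
                trace.append({"step": "interaction", "variable": term,
                              "p": None, "kept": True})
        trace.append({"step": "remove", "variable": worst, "p": ps[worst],
                      "kept": False})
        current.remove(worst)
    final = current + interactions
    trace.append({"step": "final", "variable": final, "p": None, "kept": True})
    return final, trace


# ---------------------------------------------------------------------------
# analysis arms
# ---------------------------------------------------------------------------

def _with_group_dummies(df):
    df = df.copy()
    for g in ("HI", "HIL", "HUU"):            # HEU is the reference
        df[f"group_{g}"] = (df["group"] == g).astype(float)
    return df


def _states_for_index(visits, index, lms_table=None):
    """Attach a per-visit model state for the chosen index."""
    v = visits.copy()
    zcol = {"waz": "waz", "laz": "laz", "wlz": "wlz"}[index]
    if zcol not in v.columns:
        table = lms_table or synthetic_reference_table()
        z = compute_zscores(v, table)
        v = pd.concat([v, z], axis=1)
    alive = v["state"] != 3 if "state" in v else pd.Series(True, index=v.index)
    v["state"] = classify_states(v[zcol], alive)
    return v


def run_retardation_analysis(cohort_or_visits, config=None, lms_table=None):
    """Multi-state arm: states -> panel -> MI -> pooled fits -> tables.

    Accepts a SimulatedCohort or a visits DataFrame.  Returns a
    :class:`ReportBundle` with pooled hazard-ratio and intensity tables
    (Rubin's rules across imputations when covariates are imputed; a
    single fit otherwise).
    """
    config = (config or AnalysisConfig()).validate()
    visits = getattr(cohort_or_visits, "visits", cohort_or_visits)
    visits = _with_group_dummies(visits)
    covs = list(config.covariates)

    if config.index in visits.columns or {"weight_kg", "length_cm"} & set(visits.columns):
        v = _states_for_index(visits, config.index, lms_table)
    elif "state" in visits.columns:
        # states already classified upstream (e.g. state-first simulation)
        v = visits
    else:
        raise ValueError("visits table has neither states, z-scores nor raw "
                         "anthropometry")

    keep = v["observed"].astype(bool) | (v["obs_type"] == "exact_death") if "observed" in v else pd.Series(True, index=v.index)
    panel = v.loc[keep & v["state"].notna(),
                  ["child_id", "age_months", "state", "obs_type", *covs]]
    panel = panel.sort_values(["child_id", "age_months"])
    panel = panel[panel.groupby("child_id")["age_months"].transform("size") >= 2]
    panel = panel.reset_index(drop=True)
    panel["state"] = panel["state"].astype(int)

    need_mi = panel[covs].isna().any().any() if covs else False
    if need_mi:
        imputer = MICEImputer(m=config.m, iterations=config.mice_iterations,
                              seed=config.seed,
                              exclude=("state", "obs_type"))
        imps = imputer.impute(panel)
        datasets = imps.datasets
    else:
        datasets = [panel]

    fits = []
    for ds in datasets:
        est = MarkovMultiState(band_edges=config.band_edges, covariates=covs)
        fits.append(est.fit(ds).fit_)

    pooled = {}
    names = fits[0].param_names
    for j, name in enumerate(names):
        ests = [f.theta[j] for f in fits]
        vars_ = [f.covariance[j, j] if f.covariance is not None else np.nan
                 for f in fits]
        pooled[name] = pool_rubin(ests, vars_) if len(fits) > 1 else None

    ref = fits[0]
    if len(fits) > 1:
        hr_rows = []
        zq = norm.ppf(0.975)
        for j, name in enumerate(names):
            if not name.startswith("beta_"):
                continue
            pe = pooled[name]
            hr_rows.append({"parameter": name, "beta": pe.qbar, "se": pe.se,
                            "aHR": np.exp(pe.qbar),
                            "lower": np.exp(pe.qbar - zq * pe.se),
                            "upper": np.exp(pe.qbar + zq * pe.se),
                            "p": 2 * norm.sf(abs(pe.qbar) / pe.se) if pe.se > 0 else np.nan})
        hr = pd.DataFrame(hr_rows)
        int_rows = []
        for j, name in enumerate(names):
            if not name.startswith("logq_"):
                continue
            pe = pooled[name]
            int_rows.append({"parameter": name,
                             "per1000pm": 1000 * np.exp(pe.qbar),
                             "lower": 1000 * np.exp(pe.qbar - zq * pe.se),
                             "upper": 1000 * np.exp(pe.qbar + zq * pe.se)})
        inten = pd.DataFrame(int_rows)
    else:
        hr = _hr_single(ref)
        inten = _intensity_single(ref)

    manifest = config.manifest()
    manifest.update({"n_children": ref.n_children, "m_effective": len(fits),
                     "loglik": [f.loglik for f in fits]})
    return ReportBundle(hazard_ratios=hr, intensities=inten,
                        pooled=pooled if len(fits) > 1 else None,
                        manifest=manifest)


def _hr_single(fit):
    from .multistate import hazard_ratios
    try:
        return hazard_ratios(fit)
    except ValueError:
        return None


def _intensity_single(fit):
    from .multistate import intensity_summary
    try:
        return intensity_summary(fit)
    except ValueError:
        return None


def plot_mean_z(visits, z_col="z", group_col="group", age_col="age_months",
                ax=None):
    """Simple line plot of the observed mean z-score by age and group."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for g, sub in visits.dropna(subset=[z_col]).groupby(group_col):
        prof = sub.groupby(age_col)[z_col].mean()
        ax.plot(prof.index, prof.to_numpy(), marker="o", ms=3, label=str(g))
    ax.axhline(-2.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("mean z-score")
    ax.legend(title=group_col)
    return ax


def run_growth_evolution(cohort_or_visits, config=None,
                         stage1_extra="site", stage2_covariates=("group",)):
    """Heckman arm: selection-corrected marginal growth model per index.

    Stage 1 models the per-scheduled-visit observation indicator (probit
    GEE); stage 2 models the z trajectory with age + age^2 (age in
    years) and the configured covariates, with and without the IMR.
    """
    config = (config or AnalysisConfig()).validate()
    visits = getattr(cohort_or_visits, "visits", cohort_or_visits)
    v = visits[visits["obs_type"] == "panel"].copy()
    zcol = {"waz": "z", "laz": "z_laz"}.get(config.index, "z")
    if "z_true" in v.columns:
        v["z"] = np.where(v["observed"].astype(bool), v["z_true"], np.nan)
        if "z_laz_true" in v:
            v["z_laz"] = np.where(v["observed"].astype(bool), v["z_laz_true"], np.nan)
    v["age_years"] = v["age_months"] / 12.0
    v["obs_flag"] = v["observed"].astype(int) if "observed" in v else (~v[zcol].isna()).astype(int)
    rhs2 = " + ".join(["age_years", "I(age_years**2)", *stage2_covariates])
    stage2 = f"{zcol} ~ {rhs2}"
    stage1 = f"obs_flag ~ age_years + {' + '.join(stage2_covariates)}"
    if stage1_extra:
        stage1 += f" + {stage1_extra}"
    res = heckman_two_stage(v, stage1, stage2,
                            bootstrap_reps=config.bootstrap_reps,
                            seed=config.seed)
    bundle = ReportBundle(growth_tables=res.table5_style(),
                          manifest=config.manifest())
    bundle.manifest["stage1"] = stage1
    bundle.manifest["stage2"] = stage2
    return bundle, res
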