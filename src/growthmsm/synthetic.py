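"""Synthetic pediatric-cohort generator with known ground truth.

Emulates a four-group HIV-exposure cohort (HI: infected, followed from
birth; HIL: infected, diagnosed late; HEU: exposed uninfected; HUU:
unexposed uninfected) followed to 60 months on fixed visit grids
(3-monthly to 24 months then 6-monthly for infected groups, 6-monthly for
uninfected groups).  Two generator modes:

``state_first``
    Continuous-time Markov paths over healthy/malnourished/dead are drawn
    directly from piecewise-constant band intensities (optionally scaled
    by covariate log-hazard effects); visit states are read off the path
    (interval censoring) and death times are kept exact.  Used for
    multi-state parameter-recovery experiments.

``trajectory_first``
    Continuous z-score trajectories (quadratic in age with group offsets,
    a child random intercept and visit noise) are drawn first; weight and
    length measurements are produced through the inverse LMS transform,
    so states follow from classification.  Used for end-to-end pipeline
    and selection-correction experiments.

Dropout can be MCAR, MAR (on site) or MNAR (probit on the current —
possibly unobserved — z-score with a negative loading, so low z-scores go
missing more often and the observed-data mean is biased upward).
Covariate missingness is MAR given group and site at ~10%.

Per-child random streams are split from the cohort seed and the child id,
so subsetting a cohort leaves the retained children's data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .anthropometry import inverse_lms, synthetic_reference_table

__all__ = ["CohortConfig", "DropoutModel", "GrowthModel", "SimulatedCohort",
           "simulate_ctmc_path", "simulate_cohort", "panel_from_cohort"]

GROUPS = ("HI", "HIL", "HEU", "HUU")
SITES = ("MCH", "LH", "EHC")

_INFECTED_GRID = tuple([float(a) for a in range(0, 25, 3)] + [30.0, 36.0, 42.0, 48.0, 54.0, 60.0])
_UNINFECTED_GRID = tuple(float(a) for a in range(0, 61, 6))


def _default_q0():
    """Baseline intensities per month, bands (0,6], (6,12], (12,60]."""
    return {
        (1, 2): (0.0372, 0.0116, 0.0068),
        (1, 3): (0.0096, 0.0201, 0.0003),
        (2, 1): (0.15, 0.10, 0.05),
        (2, 3): (0.0353, 0.0840, 0.0060),
    }


@dataclass
class DropoutModel:
    """Per-visit missingness model for the growth outcome.

    mode 'MCAR': constant probability ``rate``.
    mode 'MAR': probit on site dummies only.
    mode 'MNAR': probit on the current z plus site dummies:
        P(missing) = Phi(intercept + z_coef * z + site_coef[site]).
    The baseline (age 0) visit is always observed.
    """

    mode: str = "MNAR"
    rate: float = 0.25
    intercept: float = -0.8
    z_coef: float = -0.7
    site_coefs: tuple = (0.0, 0.25, -0.25)


@dataclass
class GrowthModel:
    """Latent z-trajectory: quadratic in age (years) + group offset +
    child random intercept + visit noise."""

    intercept: float = -0.4
    age: float = 0.84
    age2: float = -0.16
    group_offsets: dict = field(default_factory=lambda: {
        "HI": -0.35, "HIL": -0.55, "HEU": 0.0, "HUU": 0.25})
    sd_child: float = 0.9
    sd_resid: float = 0.6

    def mean(self, age_months, group):
        a = np.asarray(age_months, float) / 12.0
        return (self.intercept + self.age * a + self.age2 * a * a
                + self.group_offsets[group])


@dataclass
class CohortConfig:
    """Design of the simulated cohort.

    Defaults reproduce the study conditions: group sizes (69, 141, 205,
    196) for (HI, HIL, HEU, HUU), 3-monthly visits to 24 months then
    6-monthly for infected groups and 6-monthly visits for uninfected
    groups, bands (0,6]/(6,12]/(12,60] months, baseline intensities at
    the published per-1000-person-month scale, ~10% MAR covariate
    missingness and MNAR outcome dropout loading negatively on z.
    """

    group_sizes: tuple = (69, 141, 205, 196)
    visit_grids: dict = field(default_factory=lambda: {
        "HI": _INFECTED_GRID, "HIL": _INFECTED_GRID,
        "HEU": _UNINFECTED_GRID, "HUU": _UNINFECTED_GRID})
    band_edges: tuple = (6.0, 12.0, 60.0)
    true_q0: dict = field(default_factory=_default_q0)
    true_beta: dict = field(default_factory=dict)   # {(r,s): {cov: log-HR}}
    dropout: DropoutModel = field(default_factory=DropoutModel)
    covariate_missing_rate: float = 0.10
    growth: GrowthModel = field(default_factory=GrowthModel)
    t_max: float = 60.0
    seed: int = 0

    def validate(self):
        if len(self.group_sizes) != len(GROUPS):
            raise ValueError("need one size per group")
        for g, grid in self.visit_grids.items():
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"visit grid for {g} not strictly increasing")
        for tr, rates in self.true_q0.items():
            if np.any(np.asarray(rates) < 0):
                raise ValueError(f"negative intensity for {tr}")
        if not 0 <= self.covariate_missing_rate < 1:
            raise ValueError("covariate_missing_rate must be in [0, 1)")
        return self


@dataclass
class SimulatedCohort:
    children: pd.DataFrame
    visits: pd.DataFrame
    paths: dict                 # child_id -> (times, states)
    config: CohortConfig
    mode: str


def _band_index(t, edges):
    return int(np.clip(np.searchsorted(edges, t, side="left"), 0, len(edges) - 1))


def simulate_ctmc_path(q0, band_edges, t0, t_max, rng, multipliers=None,
                       initial_state=1):
    """One continuous-time Markov path under piecewise-constant intensities.

    Band-boundary crossings are handled by re-drawing the sojourn with
    the new band's rates (valid by memorylessness of the exponential).

    Parameters
    ----------
    q0 : {(r, s): per-band rates}; band_edges : upper band edges;
    multipliers : optional {(r, s): hazard multiplier} for this subject.

    Returns
    -------
    (times, states): jump times (starting at ``t0``) and states, ending
    either in the absorbing state 3 or at ``t_max``.
    """
    multipliers = multipliers or {}
    times = [t0]
    states = [initial_state]
    t, state = t0, initial_state
    edges = list(band_edges)
    while t < t_max and state != 3:
        b = _band_index(t + 1e-12, edges)
        band_end = min(edges[b] if b < len(edges) else np.inf, t_max)
        outs = [(s, q0[(state, s)][b] * multipliers.get((state, s), 1.0))
                for (r, s) in q0 if r == state]
        total = sum(q for _, q in outs)
        if total <= 0:
            t = band_end
            continue
        wait = rng.exponential(1.0 / total)
        if t + wait > band_end:
            t = band_end
            continue
        t = t + wait
        probs = np.array([q for _, q in outs]) / total
        state = int(rng.choice([s for s, _ in outs], p=probs))
        times.append(t)
        states.append(state)
    return np.array(times), np.array(states, int)


def _child_rng(seed, child_id):
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(child_id)]))


_EDUC = ("higher", "secondary", "primary")
_OCCUP = ("paid", "student", "housewife")
_MARITAL = ("married", "cohabitation", "single")


def _draw_children(config):
    """Child-level table: group, sex, site and baseline covariates with
    group-dependent marginal frequencies in the range of the study's
    descriptive table."""
    rows = []
    cid = 0
    p_educ = {"HI": (.12, .70, .18), "HIL": (.04, .57, .39), "HEU": (.21, .60, .19), "HUU": (.43, .53, .04)}
    p_sga = {"HI": .19, "HIL": .05, "HEU": .08, "HUU": .02}
    p_small = {"HI": .06, "HIL": .02, "HEU": .06, "HUU": .01}
    p_hosp = {"HI": .20, "HIL": .55, "HEU": .05, "HUU": .02}
    p_water = {"HI": .52, "HIL": .45, "HEU": .52, "HUU": .72}
    p_elec = {"HI": .94, "HIL": .79, "HEU": .96, "HUU": .99}
    for g, n in zip(GROUPS, config.group_sizes):
        for _ in range(n):
            rng = _child_rng(config.seed, cid)
            rows.append({
                "child_id": cid,
                "group": g,
                "sex": "female" if rng.random() < 0.53 else "male",
                "site": SITES[rng.choice(3, p=[.49, .23, .28])],
                "mother_educ": _EDUC[rng.choice(3, p=p_educ[g])],
                "mother_occupation": _OCCUP[rng.choice(3, p=[.45, .15, .40])],
                "marital": _MARITAL[rng.choice(3, p=[.65, .02, .33])],
                "sgag": int(rng.random() < p_sga[g]),
                "small_birth": int(rng.random() < p_small[g]),
                "hospitalization": int(rng.random() < p_hosp[g]),
                "water": int(rng.random() < p_water[g]),
                "electricity": int(rng.random() < p_elec[g]),
            })
            cid += 1
    return pd.DataFrame(rows)


def _time_varying(rng, group, n_visits):
    """Per-visit binary/categorical clinical covariates."""
    infected = group in ("HI", "HIL")
    p_chronic = 0.06 if group == "HIL" else (0.02 if infected else 0.005)
    p_diar = 0.20 if infected else 0.05
    p_cd4 = 0.45 if infected else 0.10
    p_anemia = (0.15, 0.20) if infected else (0.10, 0.05)  # mild, mod/severe
    chronic = (rng.random(n_visits) < p_chronic).astype(int)
    diar = (rng.random(n_visits) < p_diar).astype(int)
    cd4 = (rng.random(n_visits) < p_cd4).astype(int)
    u = rng.random(n_visits)
    anemia = np.where(u < p_anemia[1], "moderate_severe",
                      np.where(u < p_anemia[0] + p_anemia[1], "mild", "none"))
    signs = (rng.random(n_visits) < (0.15 if infected else 0.06)).astype(int)
    return chronic, diar, cd4, anemia, signs


def _covariate_multipliers(config, child):
    """Per-child hazard multipliers exp(beta . x) from ``true_beta``."""
    mult = {}
    for tr, effects in config.true_beta.items():
        m = 1.0
        for cov, b in effects.items():
            if cov.startswith("group_"):
                xv = 1.0 if child["group"] == cov.split("_", 1)[1] else 0.0
            elif cov == "female":
                xv = 1.0 if child["sex"] == "female" else 0.0
            else:
                xv = float(child.get(cov, 0.0))
            m *= np.exp(b * xv)
        mult[tr] = m
    return mult


def _miss_prob(config, z, site):
    d = config.dropout
    if d.mode == "MCAR":
        return np.full_like(np.asarray(z, float), d.rate)
    sc = dict(zip(SITES, d.site_coefs))[site]
    if d.mode == "MAR":
        return norm.cdf(d.intercept + sc) * np.ones_like(np.asarray(z, float))
    return norm.cdf(d.intercept + d.z_coef * np.asarray(z, float) + sc)


def simulate_cohort(config=None, mode="state_first", lms_table=None):
    """Simulate a full cohort; see the module docstring for the two modes.

    Returns a :class:`SimulatedCohort` whose ``visits`` table has one row
    per scheduled pre-death visit (plus an ``exact_death`` row per death)
    with the true state, the observation flag, and — in trajectory mode —
    latent and observed z-scores and raw measurements.
    """
    config = (config or CohortConfig()).validate()
    if mode not in ("state_first", "trajectory_first"):
        raise ValueError(f"unknown mode {mode!r}")
    children = _draw_children(config)
    ref = None
    if mode == "trajectory_first":
        if lms_table is None:
            lms_table = synthetic_reference_table()
        # pre-resolve LMS parameters for every (sex, grid age): the per-child
        # loop then runs on plain numpy
        grid_ages = sorted({a for g in config.visit_grids.values() for a in g})
        ref = {}
        for sex in ("male", "female"):
            for idx in ("waz", "laz"):
                for a in grid_ages:
                    row = lms_table.lookup(idx, sex, a)
                    if row is None:
                        raise ValueError(f"LMS table does not cover {idx}/{sex}/{a}")
                    ref[(sex, idx, a)] = (row["L"], row["M"], row["S"])
    visit_rows = []
    paths = {}
    for child in children.to_dict("records"):
        cid = int(child["child_id"])
        rng = _child_rng(config.seed, cid).spawn(1)[0]
        grid = np.asarray(config.visit_grids[child["group"]], float)
        mult = _covariate_multipliers(config, child)

        if mode == "state_first":
            times, states = simulate_ctmc_path(config.true_q0, config.band_edges,
                                               0.0, config.t_max, rng, mult)
            paths[cid] = (times, states)
            death_time = times[-1] if states[-1] == 3 else np.inf
            pre = grid[grid < death_time]
            vis_states = states[np.searchsorted(times, pre, side="right") - 1]
            z_lat = np.where(vis_states == 2, -2.5, 0.0)  # proxy for dropout models
            n = len(pre)
            chronic, diar, cd4, anemia, signs = _time_varying(rng, child["group"], n)
            if config.dropout.mode == "MCAR":
                miss = rng.random(n) < config.dropout.rate
            else:
                miss = rng.random(n) < _miss_prob(config, z_lat, child["site"])
            miss[0] = False
            for j, a in enumerate(pre):
                visit_rows.append({
                    "child_id": cid, "age_months": a, "state": int(vis_states[j]),
                    "obs_type": "panel", "observed": not miss[j],
                    "chronic": chronic[j], "diarrhea": diar[j], "cd4_lt25": cd4[j],
                    "anemia": anemia[j], "general_signs": signs[j],
                })
            if np.isfinite(death_time):
                visit_rows.append({
                    "child_id": cid, "age_months": float(death_time), "state": 3,
                    "obs_type": "exact_death", "observed": True,
                    "chronic": 0, "diarrhea": 0, "cd4_lt25": 0,
                    "anemia": "none", "general_signs": 0,
                })
        else:
            # death via the healthy->death band rates only (simplified)
            q_death = {(1, 3): config.true_q0[(1, 3)]}
            times, states = simulate_ctmc_path(q_death, config.band_edges,
                                               0.0, config.t_max, rng,
                                               {(1, 3): mult.get((1, 3), 1.0)})
            paths[cid] = (times, states)
            death_time = times[-1] if states[-1] == 3 else np.inf
            pre = grid[grid < death_time]
            n = len(pre)
            b_child = rng.normal(0.0, config.growth.sd_child)
            b_laz = 0.7 * b_child + rng.normal(0.0, 0.6 * config.growth.sd_child)
            z_waz = (config.growth.mean(pre, child["group"]) + b_child
                     + rng.normal(0.0, config.growth.sd_resid, n))
            z_laz = (config.growth.mean(pre, child["group"]) + b_laz
                     + rng.normal(0.0, config.growth.sd_resid, n))
            miss = rng.random(n) < _miss_prob(config, z_waz, child["site"])
            miss[0] = False
            chronic, diar, cd4, anemia, signs = _time_varying(rng, child["group"], n)
            sex = child["sex"]
            wL, wM, wS = (np.array([ref[(sex, "waz", a)][k] for a in pre]) for k in range(3))
            lL, lM, lS = (np.array([ref[(sex, "laz", a)][k] for a in pre]) for k in range(3))
            weight = inverse_lms(z_waz, wL, wM, wS)
            length = inverse_lms(z_laz, lL, lM, lS)
            for j, a in enumerate(pre):
                visit_rows.append({
                    "child_id": cid, "age_months": a,
                    "z_true": z_waz[j], "z_laz_true": z_laz[j],
                    "weight_kg": weight[j], "length_cm": length[j],
                    "state": 2 if z_waz[j] < -2 else 1,
                    "obs_type": "panel", "observed": not miss[j],
                    "chronic": chronic[j], "diarrhea": diar[j], "cd4_lt25": cd4[j],
                    "anemia": anemia[j], "general_signs": signs[j],
                })
            if np.isfinite(death_time):
                visit_rows.append({
                    "child_id": cid, "age_months": float(death_time),
                    "z_true": np.nan, "z_laz_true": np.nan,
                    "weight_kg": np.nan, "length_cm": np.nan,
                    "state": 3, "obs_type": "exact_death", "observed": True,
                    "chronic": 0, "diarrhea": 0, "cd4_lt25": 0,
                    "anemia": "none", "general_signs": 0,
                })
    visits = pd.DataFrame(visit_rows)
    visits = visits.merge(children, on="child_id", how="left")
    _apply_covariate_missingness(visits, config)
    return SimulatedCohort(children=children, visits=visits, paths=paths,
                           config=config, mode=mode)


_MISSABLE = ("mother_educ", "water", "electricity", "anemia", "cd4_lt25", "marital")


def _apply_covariate_missingness(visits, config):
    """MAR-given-(group, site) covariate missingness at ~the configured rate."""
    if config.covariate_missing_rate <= 0:
        return
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 10 ** 9]))
    base = config.covariate_missing_rate
    g_shift = {"HI": 1.2, "HIL": 1.3, "HEU": 0.9, "HUU": 0.8}
    s_shift = {"MCH": 1.0, "LH": 1.15, "EHC": 0.85}
    p = visits["group"].map(g_shift).to_numpy() * visits["site"].map(s_shift).to_numpy() * base
    for col in _MISSABLE:
        if col not in visits:
            continue
        mask = rng.random(len(visits)) < p
        if visits[col].dtype == object:
            visits.loc[mask, col] = None
        else:
            visits[col] = visits[col].astype(float)
            visits.loc[mask, col] = np.nan


def panel_from_cohort(cohort, covariates=()):
    """Long panel table (observed visits + exact deaths) for the MSM fit.

    Children contribute from their first observed visit; unobserved panel
    rows are dropped (their states are interval-censored away), death
    rows are kept with obs_type 'exact_death'.
    """
    v = cohort.visits
    keep = v["observed"] | (v["obs_type"] == "exact_death")
    cols = ["child_id", "age_months", "state", "obs_type", *covariates]
    panel = v.loc[keep, cols].sort_values(["child_id", "age_months"])
    # need >= 2 observations per child to contribute an interval
    counts = panel.groupby("child_id")["age_months"].transform("size")
    return panel[counts >= 2].reset_index(drop=True)
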