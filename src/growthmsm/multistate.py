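"""Three-state illness-death Markov model for interval-censored cohort data.

States: 1 = healthy, 2 = malnourished, 3 = dead (absorbing).  Transitions
1->2, 1->3, 2->1, 2->3 have piecewise-constant baseline intensities on age
bands (0,6], (6,12], (12,60] months (configurable) with proportional
covariate effects:

    q_rs(age, x) = q0_rs(band(age)) * exp(beta_rs . x)

Live states are observed only at visits (panel observation); death times
are exact but the state immediately before death is unknown, so a death
contributes  sum_k P_rk(t1, t2-) q_k3(t2)  to the likelihood (the "exact
death" convention of the msm literature).

The likelihood hot path exploits the absorbing structure: the live-state
block of the generator is 2x2, and its matrix exponential has a closed
eigenvalue form which is evaluated vectorised over all observation
intervals.  The public :func:`transition_probability` uses the generic
scipy matrix exponential; tests cross-check the two routes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm as _scipy_expm
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "TRANSITIONS",
    "MSMParams",
    "MSMFit",
    "MarkovMultiState",
    "build_generator",
    "transition_probability",
    "interval_probability",
    "panel_loglik",
    "fit_msm",
    "hazard_ratios",
    "intensity_summary",
]

#: estimable transitions (from, to) of the illness-death-with-recovery model
TRANSITIONS = ((1, 2), (1, 3), (2, 1), (2, 3))
_TR_INDEX = {t: i for i, t in enumerate(TRANSITIONS)}

DEFAULT_BANDS = (6.0, 12.0, 60.0)


@dataclass
class MSMParams:
    """Parameters of the band-wise proportional-intensity model.

    log_q0 : (4, n_bands) array of log baseline intensities per month, row
        order (1->2, 1->3, 2->1, 2->3); ``-inf`` marks a transition fixed
        at intensity zero.
    beta : mapping transition-index -> (p_t,) array of log hazard ratios.
    covariates : mapping transition-index -> list of covariate names.
    band_edges : upper edges of the age bands (months).
    """

    log_q0: np.ndarray
    beta: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    band_edges: tuple = DEFAULT_BANDS

    @property
    def n_bands(self):
        return self.log_q0.shape[1]

    def q0(self):
        return np.exp(self.log_q0)

    def to_dict(self):
        return {
            "log_q0": self.log_q0.tolist(),
            "beta": {str(k): np.asarray(v).tolist() for k, v in self.beta.items()},
            "covariates": {str(k): list(v) for k, v in self.covariates.items()},
            "band_edges": list(self.band_edges),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            log_q0=np.asarray(d["log_q0"], float),
            beta={int(k): np.asarray(v, float) for k, v in d["beta"].items()},
            covariates={int(k): list(v) for k, v in d["covariates"].items()},
            band_edges=tuple(d["band_edges"]),
        )


def band_of(t, band_edges=DEFAULT_BANDS):
    """Index of the age band containing time ``t`` (bands half-open (lo, hi])."""
    edges = np.asarray(band_edges, float)
    return int(np.clip(np.searchsorted(edges, t, side="left"), 0, len(edges) - 1))


def _intensities(params, x, band):
    """q_rs for every transition at one covariate vector and band."""
    q = np.zeros(4)
    for i in range(4):
        lq = params.log_q0[i, band]
        if np.isneginf(lq):
            continue
        shift = 0.0
        if i in params.beta and len(params.beta[i]):
            shift = float(np.dot(params.beta[i], x[params.covariates[i]] if isinstance(x, pd.Series) else x))
        q[i] = np.exp(lq + shift)
    return q


def build_generator(params, x=None, band=0):
    """3x3 generator matrix Q at covariates ``x`` in age band ``band``.

    Rows sum to zero; the death row is structurally zero.  ``x`` must be
    ordered as the per-transition covariate lists; with no covariates pass
    ``None``.
    """
    if x is None:
        x = np.zeros(0)
    q = _intensities(params, np.asarray(x, float), band)
    Q = np.zeros((3, 3))
    Q[0, 1], Q[0, 2], Q[1, 0], Q[1, 2] = q
    Q[0, 0] = -(Q[0, 1] + Q[0, 2])
    Q[1, 1] = -(Q[1, 0] + Q[1, 2])
    return Q


def transition_probability(Q, dt):
    """P(dt) = expm(dt * Q); rows sum to 1."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return _scipy_expm(float(dt) * np.asarray(Q, float))


def _split_bands(t0, t1, band_edges):
    """Maximal sub-intervals of (t0, t1] with constant band: [(band, dt), ...]."""
    edges = list(band_edges)
    cuts = [t0] + [e for e in edges[:-1] if t0 < e < t1] + [t1]
    return [(band_of(0.5 * (a + b), band_edges), b - a) for a, b in zip(cuts[:-1], cuts[1:])]


def interval_probability(params, x, t_start, t_end):
    """Transition probability over (t_start, t_end] crossing band boundaries.

    Ordered product of band-wise matrix exponentials; covariates are held
    fixed at ``x`` over the interval (last-observation-carried-forward is
    applied upstream when covariates are time-dependent).
    """
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    P = np.eye(3)
    for band, dt in _split_bands(t_start, t_end, params.band_edges):
        P = P @ transition_probability(build_generator(params, x, band), dt)
    return P


# ---------------------------------------------------------------------------
# vectorised likelihood machinery
# ---------------------------------------------------------------------------

def _expm2x2(A, dt):
    """Closed-form expm(dt*A) for stacked 2x2 live-state blocks.

    A : (..., 2, 2) with real eigenvalues (guaranteed for generator blocks
    [[-(a+b), a], [c, -(c+d)]] with a, b, c, d >= 0); dt : (...,).
    """
    a11 = A[..., 0, 0]
    a12 = A[..., 0, 1]
    a21 = A[..., 1, 0]
    a22 = A[..., 1, 1]
    tr = a11 + a22
    disc = (a11 - a22) ** 2 + 4 * a12 * a21
    s = np.sqrt(np.maximum(disc, 0.0))
    lam1 = 0.5 * (tr + s)
    lam2 = 0.5 * (tr - s)
    e1 = np.exp(lam1 * dt)
    e2 = np.exp(lam2 * dt)
    # P = (e1 (A - lam2 I) - e2 (A - lam1 I)) / (lam1 - lam2); series for s ~ 0
    small = s < 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = (e1 - e2) / s
    c1 = np.where(small, dt * np.exp(0.5 * tr * dt), c1)
    c0 = e1 - lam1 * c1
    P = np.empty(np.broadcast(a11, dt).shape + (2, 2))
    P[..., 0, 0] = c0 + c1 * a11
    P[..., 0, 1] = c1 * a12
    P[..., 1, 0] = c1 * a21
    P[..., 1, 1] = c0 + c1 * a22
    return P


@dataclass
class _CompiledPanel:
    """Pre-aggregated observation intervals for fast likelihood evaluation."""

    seg_dt: np.ndarray       # (n, 3) band-segment durations (0-padded)
    seg_band: np.ndarray     # (n, 3) band index per segment
    r: np.ndarray            # (n,) state at interval start (1 or 2)
    s: np.ndarray            # (n,) state at interval end (1, 2 or 3)
    exact_death: np.ndarray  # (n,) bool
    end_band: np.ndarray     # (n,) band at interval end (for death intensity)
    pattern: np.ndarray      # (n,) covariate-pattern id
    counts: np.ndarray       # (n,) multiplicity
    X: np.ndarray            # (n_patterns, p) unique covariate rows
    covariates: list         # column names of X
    n_children: int = 0
    keys: list = None        # (child_id, t1, t2) of one representative per row

    def observed_transitions(self):
        """Set of transitions (r, s) with at least one observed state change."""
        seen = set()
        for r, s, d, c in zip(self.r, self.s, self.exact_death, self.counts):
            if c <= 0:
                continue
            if d or s == 3:
                seen.add((1, 3))
                seen.add((2, 3))
            elif r != s:
                seen.add((int(r), int(s)))
        return seen


def compile_panel(data, covariates=None, band_edges=DEFAULT_BANDS):
    """Turn a long panel table into aggregated interval data.

    ``data`` columns: child_id, age_months, state (1/2/3), obs_type
    ('panel' or 'exact_death') plus covariate columns.  Consecutive
    observation pairs within a child form the likelihood intervals; the
    covariates at the interval start are carried forward.
    """
    covariates = list(covariates or [])
    df = data.sort_values(["child_id", "age_months"], kind="mergesort").reset_index(drop=True)
    if df.groupby("child_id")["age_months"].apply(lambda s: s.is_monotonic_increasing and s.is_unique).eq(False).any():
        raise ValueError("times must be strictly increasing within child")
    g = df.groupby("child_id", sort=False)
    same = g.ngroup().to_numpy()
    t = df["age_months"].to_numpy(float)
    st = df["state"].to_numpy(int)
    obs = df["obs_type"].astype(str).to_numpy() if "obs_type" in df else np.array(["panel"] * len(df))
    X = df[covariates].to_numpy(float) if covariates else np.zeros((len(df), 0))

    keep = (same[1:] == same[:-1])
    i0 = np.flatnonzero(keep)
    t1, t2 = t[i0], t[i0 + 1]
    r, s = st[i0], st[i0 + 1]
    ot = obs[i0 + 1]
    Xv = X[i0]
    live = r != 3
    if np.any((t2 <= t1) & (same[i0] == same[i0 + 1])):
        raise ValueError("non-increasing times within a child")
    if np.any(~live):
        raise ValueError("death (state 3) must be terminal within a child")
    exact = (ot == "exact_death")
    if np.any(exact & (s != 3)):
        raise ValueError("obs_type exact_death requires state 3")

    # aggregate identical intervals (fixed visit grids make this a big win)
    pat, pat_inv = np.unique(Xv, axis=0, return_inverse=True) if Xv.shape[1] else (np.zeros((1, 0)), np.zeros(len(t1), int))
    key = pd.DataFrame({"t1": t1, "t2": t2, "r": r, "s": s, "ex": exact, "p": pat_inv})
    grouped = key.groupby(["t1", "t2", "r", "s", "ex", "p"], sort=False).size().reset_index(name="n")

    n = len(grouped)
    seg_dt = np.zeros((n, 3))
    seg_band = np.zeros((n, 3), int)
    for i, (a, b) in enumerate(zip(grouped["t1"], grouped["t2"])):
        for j, (bd, dt) in enumerate(_split_bands(a, b, band_edges)):
            if j > 2:
                raise ValueError("interval crosses more than 3 bands")
            seg_band[i, j] = bd
            seg_dt[i, j] = dt
    end_band = np.array([band_of(b, band_edges) for b in grouped["t2"]])
    return _CompiledPanel(
        seg_dt=seg_dt, seg_band=seg_band,
        r=grouped["r"].to_numpy(), s=grouped["s"].to_numpy(),
        exact_death=grouped["ex"].to_numpy(bool), end_band=end_band,
        pattern=grouped["p"].to_numpy(), counts=grouped["n"].to_numpy(float),
        X=pat, covariates=covariates, n_children=df["child_id"].nunique(),
        keys=list(zip(grouped["t1"], grouped["t2"])),
    )


def _loglik_compiled(compiled, log_q0, beta_mat, return_diagnostics=False):
    """Vectorised panel log-likelihood.

    log_q0 : (4, n_bands); beta_mat : (4, p) (zero-padded over the shared
    covariate frame of the compiled panel).
    """
    cp = compiled
    n = len(cp.counts)
    # per-pattern, per-band intensities: (4, n_pat, n_bands)
    shift = cp.X @ beta_mat.T if cp.X.shape[1] else np.zeros((cp.X.shape[0], 4))
    with np.errstate(over="ignore"):
        q = np.exp(log_q0[None, :, :] + shift[:, :, None])   # (n_pat, 4, n_bands)
    q = np.where(np.isneginf(log_q0)[None, :, :], 0.0, q)
    # gather per-interval, per-segment: (n, 3, 4)
    qi = q[cp.pattern[:, None], :, cp.seg_band]
    A = np.empty((n, 3, 2, 2))
    A[..., 0, 0] = -(qi[..., 0] + qi[..., 1])
    A[..., 0, 1] = qi[..., 0]
    A[..., 1, 0] = qi[..., 2]
    A[..., 1, 1] = -(qi[..., 2] + qi[..., 3])
    E = _expm2x2(A, cp.seg_dt)
    P = E[:, 0] @ E[:, 1] @ E[:, 2]
    r0 = cp.r - 1
    rows = P[np.arange(n), r0]              # (n, 2) probs of live end states
    q_end = q[cp.pattern, :, cp.end_band]   # (n, 4)
    p_obs = np.empty(n)
    live_s = cp.s < 3
    p_obs[live_s] = rows[live_s, cp.s[live_s] - 1]
    dead = ~live_s
    d_exact = dead & cp.exact_death
    d_panel = dead & ~cp.exact_death
    if d_exact.any():
        p_obs[d_exact] = rows[d_exact, 0] * q_end[d_exact, 1] + rows[d_exact, 1] * q_end[d_exact, 3]
    if d_panel.any():
        p_obs[d_panel] = np.clip(1.0 - rows[d_panel].sum(axis=1), 0.0, 1.0)
    bad = ~(p_obs > 0)
    if bad.any():
        if return_diagnostics:
            return -np.inf, [cp.keys[i] for i in np.flatnonzero(bad)[:10]]
        return -np.inf
    ll = float(np.dot(cp.counts, np.log(p_obs)))
    return (ll, []) if return_diagnostics else ll


def panel_loglik(data, params, covariates=None):
    """Log-likelihood of an MSMParams under a long panel table.

    Mixed observation scheme: 'panel' rows contribute P_rs(t1, t2); an
    'exact_death' row contributes sum_k P_rk(t1, t2) q_k3(t2) over the
    live states k.  Returns ``-inf`` (not an exception) when an observed
    transition has probability zero, with a warning naming an offending
    interval.
    """
    if covariates is None:
        covariates = sorted({c for cols in params.covariates.values() for c in cols})
    compiled = compile_panel(data, covariates, params.band_edges)
    beta_mat = _beta_matrix(params, covariates)
    ll, bad = _loglik_compiled(compiled, params.log_q0, beta_mat, return_diagnostics=True)
    if bad:
        warnings.warn(f"zero-probability observed transition(s), e.g. interval {bad[0]}",
                      stacklevel=2)
    return ll


def _beta_matrix(params, covariates):
    """(4, p) covariate-effect matrix on a shared covariate frame."""
    p = len(covariates)
    B = np.zeros((4, p))
    for ti, names in params.covariates.items():
        for name, b in zip(names, np.atleast_1d(params.beta.get(ti, []))):
            B[ti, covariates.index(name)] = b
    return B


@dataclass
class MSMFit:
    """A fitted multi-state model: estimates, covariance, diagnostics."""

    params: MSMParams
    theta: np.ndarray
    param_names: list
    loglik: float
    covariance: np.ndarray | None
    converged: bool
    n_iter: int
    n_children: int
    message: str = ""

    @property
    def se(self):
        if self.covariance is None:
            return None
        return np.sqrt(np.clip(np.diag(self.covariance), 0, None))

    def to_json(self, path=None):
        d = {
            "params": self.params.to_dict(),
            "theta": self.theta.tolist(),
            "param_names": self.param_names,
            "loglik": self.loglik,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "converged": bool(self.converged),
            "n_children": int(self.n_children),
        }
        if path is None:
            return json.dumps(d, indent=1)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


class MarkovMultiState(BaseEstimator):
    """Maximum-likelihood illness-death model on interval-censored panels.

    Parameters
    ----------
    band_edges : tuple of float
        Upper edges (months) of the piecewise-constant intensity bands.
    covariates : None, list or dict
        Covariate names shared by all four transitions (list) or a mapping
        {transition index or (r, s): [names]} for transition-specific
        designs.  Effects are shared across bands.
    include_transitions : None or sequence
        Transitions to estimate; ``None`` keeps every transition observed
        at least once in the data and fixes the rest at intensity zero.
    max_iter, tol : optimizer controls (quasi-Newton on the log scale).
    init_floor : crude-rate initialisation floor (per month).

    Attributes (after fit)
    ----------------------
    params_ : MSMParams;  loglik_ : float;  covariance_ : array or None;
    fit_ : MSMFit;  converged_ : bool.
    """

    def __init__(self, band_edges=DEFAULT_BANDS, covariates=None,
                 include_transitions=None, max_iter=500, tol=1e-7,
                 init_floor=1e-4):
        self.band_edges = band_edges
        self.covariates = covariates
        self.include_transitions = include_transitions
        self.max_iter = max_iter
        self.tol = tol
        self.init_floor = init_floor

    # -- parameter vector packing ------------------------------------
    def _norm_cov_spec(self):
        cov = self.covariates
        if cov is None:
            return {i: [] for i in range(4)}
        if isinstance(cov, (list, tuple)):
            return {i: list(cov) for i in range(4)}
        out = {i: [] for i in range(4)}
        for k, v in cov.items():
            out[_TR_INDEX[k] if isinstance(k, tuple) else int(k)] = list(v)
        return out

    def _pack(self, log_q0, beta):
        parts = [log_q0[t] for t in self._est_tr]
        parts += [np.atleast_1d(beta[t]) for t in self._est_tr if len(self._cov_spec[t])]
        return np.concatenate(parts) if parts else np.zeros(0)

    def _unpack(self, theta):
        nb = len(self.band_edges)
        log_q0 = np.full((4, nb), -np.inf)
        beta = {}
        k = 0
        for t in self._est_tr:
            log_q0[t] = theta[k:k + nb]
            k += nb
        for t in self._est_tr:
            p = len(self._cov_spec[t])
            if p:
                beta[t] = theta[k:k + p]
                k += p
            else:
                beta[t] = np.zeros(0)
        return log_q0, beta

    def _names(self):
        nb = len(self.band_edges)
        lo = [0.0] + list(self.band_edges[:-1])
        names = []
        for t in self._est_tr:
            r, s = TRANSITIONS[t]
            names += [f"logq_{r}{s}_band({lo[b]:g},{self.band_edges[b]:g}]" for b in range(nb)]
        for t in self._est_tr:
            r, s = TRANSITIONS[t]
            names += [f"beta_{r}{s}_{c}" for c in self._cov_spec[t]]
        return names

    # -- fitting ------------------------------------------------------
    def _crude_init(self, cp):
        """Occurrence/exposure rates per transition (floored)."""
        nb = len(self.band_edges)
        expo = np.zeros((2, nb))
        cnt = np.zeros((4, nb))
        for i in range(len(cp.counts)):
            r = cp.r[i] - 1
            w = cp.counts[i]
            for j in range(3):
                if cp.seg_dt[i, j] > 0:
                    expo[r, cp.seg_band[i, j]] += w * cp.seg_dt[i, j]
            s = cp.s[i]
            eb = cp.end_band[i]
            if s == 3:
                # unknown live state pre-death: credit both death transitions
                cnt[1, eb] += 0.5 * w
                cnt[3, eb] += 0.5 * w
            elif s != cp.r[i]:
                cnt[_TR_INDEX[(int(cp.r[i]), int(s))], eb] += w
        rates = np.zeros((4, nb))
        for t in range(4):
            r = 0 if t < 2 else 1
            tot = cnt[t].sum() / max(expo[r].sum(), 1e-9)
            for b in range(nb):
                rb = cnt[t, b] / expo[r, b] if expo[r, b] > 0 else tot
                rates[t, b] = max(rb, self.init_floor) if rb > 0 else max(tot, self.init_floor)
        return np.log(np.maximum(rates, self.init_floor))

    def fit(self, data, init=None):
        self._cov_spec = self._norm_cov_spec()
        all_cov = sorted({c for cols in self._cov_spec.values() for c in cols})
        cp = compile_panel(data, all_cov, self.band_edges)
        if self.include_transitions is None:
            seen = cp.observed_transitions()
            est = [i for i, tr in enumerate(TRANSITIONS) if tr in seen]
        else:
            est = sorted(_TR_INDEX[t] if isinstance(t, tuple) else int(t)
                         for t in self.include_transitions)
        if not est:
            raise ValueError("no estimable transitions in the data")
        self._est_tr = est
        self._all_cov = all_cov

        tidx = {t: [all_cov.index(c) for c in self._cov_spec[t]] for t in range(4)}

        def beta_mat_of(beta):
            B = np.zeros((4, len(all_cov)))
            for t in est:
                B[t, tidx[t]] = beta[t]
            return B

        def nll(theta):
            log_q0, beta = self._unpack(theta)
            ll = _loglik_compiled(cp, log_q0, beta_mat_of(beta))
            return -ll if np.isfinite(ll) else 1e12

        if init is None:
            crude = self._crude_init(cp)
            beta0 = {t: np.zeros(len(self._cov_spec[t])) for t in range(4)}
            theta0 = self._pack(crude, beta0)
        else:
            theta0 = np.asarray(init, float)
        if not np.isfinite(nll(theta0)) or nll(theta0) >= 1e12:
            theta0 = np.where(np.isfinite(theta0), theta0, np.log(self.init_floor))
            if nll(theta0) >= 1e12:
                raise RuntimeError("log-likelihood not finite at initial values")

        res = minimize(nll, theta0, method="BFGS",
                       options={"maxiter": self.max_iter, "gtol": 1e-6})
        if not res.success:
            # polish with a second pass; BFGS can stall on precision loss
            res2 = minimize(nll, res.x, method="Nelder-Mead",
                            options={"maxiter": 2000, "fatol": self.tol, "xatol": 1e-6})
            if res2.fun <= res.fun:
                res = res2
        theta = res.x
        ll = -res.fun

        cov, msg = self._hessian_covariance(nll, theta)
        log_q0, beta = self._unpack(theta)
        self.params_ = MSMParams(log_q0=log_q0,
                                 beta={t: beta[t] for t in est},
                                 covariates={t: self._cov_spec[t] for t in est},
                                 band_edges=tuple(self.band_edges))
        self.loglik_ = ll
        self.covariance_ = cov
        self.converged_ = bool(res.success or msg == "")
        self.n_iter_ = int(getattr(res, "nit", -1))
        self.fit_ = MSMFit(params=self.params_, theta=theta, param_names=self._names(),
                           loglik=ll, covariance=cov, converged=self.converged_,
                           n_iter=self.n_iter_, n_children=cp.n_children, message=msg)
        self._compiled = cp
        return self

    def _hessian_covariance(self, nll, theta, h=1e-4):
        p = len(theta)
        H = np.empty((p, p))
        f0 = nll(theta)
        steps = h * np.maximum(1.0, np.abs(theta))
        fp = np.empty(p)
        fm = np.empty(p)
        for i in range(p):
            e = np.zeros(p)
            e[i] = steps[i]
            fp[i] = nll(theta + e)
            fm[i] = nll(theta - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
        for i in range(p):
            for j in range(i + 1, p):
                ei = np.zeros(p); ei[i] = steps[i]
                ej = np.zeros(p); ej[j] = steps[j]
                H[i, j] = H[j, i] = (
                    nll(theta + ei + ej) - nll(theta + ei - ej)
                    - nll(theta - ei + ej) + nll(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
        # directions with (numerically) zero curvature carry no information:
        # typically a band with zero observed events, whose log-intensity
        # escapes towards -inf on a flat likelihood.  Report infinite
        # variance there and invert the informative block.
        flat = np.diag(H) <= 1e-8
        keep = ~flat
        cov = np.full((p, p), 0.0)
        try:
            sub = np.linalg.inv(H[np.ix_(keep, keep)])
            sub = 0.5 * (sub + sub.T)
        except np.linalg.LinAlgError:
            return None, "singular observed information"
        if np.any(np.diag(sub) <= 0):
            return None, "observed information not positive definite"
        cov[np.ix_(keep, keep)] = sub
        for i in np.flatnonzero(flat):
            cov[i, i] = np.inf
        msg = f"{int(flat.sum())} parameter(s) without curvature" if flat.any() else ""
        return cov, msg

    # -- post-fit summaries -------------------------------------------
    def loglik(self, theta=None, data=None):
        """Log-likelihood at ``theta`` (default: fitted) on ``data`` (default: training)."""
        if data is None:
            cp = self._compiled
        else:
            cp = compile_panel(data, self._all_cov, self.band_edges)
        if theta is None:
            theta = self.fit_.theta
        log_q0, beta = self._unpack(np.asarray(theta, float))
        tidx = {t: [self._all_cov.index(c) for c in self._cov_spec[t]] for t in range(4)}
        B = np.zeros((4, len(self._all_cov)))
        for t in self._est_tr:
            B[t, tidx[t]] = beta[t]
        return _loglik_compiled(cp, log_q0, B)

    def hazard_ratios(self):
        return hazard_ratios(self.fit_)

    def intensity_summary(self, x=None):
        return intensity_summary(self.fit_, x=x)


def fit_msm(data, covariates=None, band_edges=DEFAULT_BANDS, init=None, **kw):
    """Functional wrapper over :class:`MarkovMultiState`; returns an MSMFit."""
    return MarkovMultiState(band_edges=band_edges, covariates=covariates, **kw).fit(data, init=init).fit_


def _theta_layout(fit):
    """Index of each (kind, transition, band/covariate) in the theta vector."""
    nb = fit.params.n_bands
    est = [i for i in range(4) if np.isfinite(fit.params.log_q0[i]).any()]
    layout_q = {}
    k = 0
    for t in est:
        for b in range(nb):
            layout_q[(t, b)] = k
            k += 1
    layout_b = {}
    for t in est:
        for j, c in enumerate(fit.params.covariates.get(t, [])):
            layout_b[(t, c)] = k
            k += 1
    return layout_q, layout_b


def hazard_ratios(fit, level=0.95):
    """Per-transition adjusted hazard ratios exp(beta) with Wald CIs."""
    if fit.covariance is None:
        raise ValueError("covariance unavailable; cannot form Wald intervals")
    zq = norm.ppf(0.5 + level / 2)
    _, layout_b = _theta_layout(fit)
    se = fit.se
    rows = []
    for (t, c), k in layout_b.items():
        b = fit.theta[k]
        s = se[k]
        r, sto = TRANSITIONS[t]
        rows.append({
            "transition": f"{r}->{sto}", "covariate": c,
            "beta": b, "se": s, "aHR": np.exp(b),
            "lower": np.exp(b - zq * s), "upper": np.exp(b + zq * s),
            "p": 2 * norm.sf(abs(b) / s) if s > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def intensity_summary(fit, x=None, level=0.95, per=1000.0):
    """Transition intensities per 1000 person-months with log-scale CIs.

    ``x``: optional mapping covariate name -> value; defaults to 0
    (reference category) for every covariate.
    """
    if fit.covariance is None:
        raise ValueError("covariance unavailable")
    zq = norm.ppf(0.5 + level / 2)
    layout_q, layout_b = _theta_layout(fit)
    x = x or {}
    lo_edges = [0.0] + list(fit.params.band_edges[:-1])
    rows = []
    p = len(fit.theta)
    for (t, b), k in layout_q.items():
        grad = np.zeros(p)
        grad[k] = 1.0
        logq = fit.theta[k]
        for c in fit.params.covariates.get(t, []):
            xv = float(x.get(c, 0.0))
            kk = layout_b[(t, c)]
            logq += fit.theta[kk] * xv
            grad[kk] = xv
        var = float(grad @ fit.covariance @ grad)
        se = np.sqrt(max(var, 0.0))
        q = np.exp(logq)
        r, sto = TRANSITIONS[t]
        rows.append({
            "transition": f"{r}->{sto}",
            "band": f"({lo_edges[b]:g},{fit.params.band_edges[b]:g}]",
            "per1000pm": per * q,
            "lower": per * q * np.exp(-zq * se),
            "upper": per * q * np.exp(zq * se),
            "se_log": se,
            "degenerate": not np.isfinite(se) or q == 0.0,
        })
    return pd.DataFrame(rows)
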