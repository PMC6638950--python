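"""WHO-style LMS z-scores and malnutrition state classification.

The LMS method summarises an anthropometric reference as three smooth
curves — a Box-Cox power L, a median M and a coefficient of variation S —
per index, sex and key (age in completed months for weight-for-age and
length-for-age; recumbent length in cm for weight-for-length).  A raw
measurement ``y`` maps to a z-score

    z = ((y / M)**L - 1) / (L * S)      (L != 0)
    z = ln(y / M) / S                   (L == 0)

and the WHO convention additionally linearises the weight-based indices
beyond +/-3 SD so that extreme measurements do not explode through the
power transform (``restricted_zscore``).

States for the three-state illness-death model are coded 1 = healthy,
2 = malnourished (index z-score strictly below -2), 3 = dead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "INDICES",
    "STATE_HEALTHY",
    "STATE_MALNOURISHED",
    "STATE_DEAD",
    "LMSTable",
    "lms_zscore",
    "inverse_lms",
    "restricted_zscore",
    "classify_state",
    "classify_states",
    "compute_zscores",
    "synthetic_reference_table",
    "WHOZScorer",
]

INDICES = ("waz", "laz", "wlz")

STATE_HEALTHY = 1
STATE_MALNOURISHED = 2
STATE_DEAD = 3

#: |L| below this uses the logarithmic (L -> 0) branch of the LMS formula.
_L_EPS = 1e-8

#: |z| beyond this is flagged as biologically implausible (WHO cleaning
#: convention); flagged values are retained unless the caller drops them.
IMPLAUSIBLE_Z = 6.0

_TABLE_COLUMNS = [
    "index", "sex", "key", "L", "M", "S",
    "sd3neg", "sd2neg", "sd2pos", "sd3pos",
]


class InvalidMeasurementError(ValueError):
    """Raised for non-positive measurement / median / CV inputs."""


class ReferenceTableError(ValueError):
    """Raised for an inconsistent or degenerate LMS reference table."""


def lms_zscore(y, L, M, S):
    """z-score of measurement ``y`` under LMS parameters (vectorised).

    Continuous in L at 0: for |L| < 1e-8 the log-branch is used.
    """
    y, L, M, S = (np.asarray(a, dtype=float) for a in (y, L, M, S))
    if np.any(y <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise InvalidMeasurementError("y, M and S must all be positive")
    ratio = y / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z_pow = (np.power(ratio, L) - 1.0) / (L * S)
    z_log = np.log(ratio) / S
    z = np.where(np.abs(L) > _L_EPS, z_pow, z_log)
    return z if z.ndim else float(z)


def inverse_lms(z, L, M, S):
    """Measurement with z-score ``z``: inverse of :func:`lms_zscore`."""
    z, L, M, S = (np.asarray(a, dtype=float) for a in (z, L, M, S))
    if np.any(M <= 0) or np.any(S <= 0):
        raise InvalidMeasurementError("M and S must be positive")
    with np.errstate(invalid="ignore"):
        y_pow = M * np.power(1.0 + L * S * z, 1.0 / np.where(np.abs(L) > _L_EPS, L, 1.0))
    y_log = M * np.exp(S * z)
    y = np.where(np.abs(L) > _L_EPS, y_pow, y_log)
    return y if y.ndim else float(y)


def restricted_zscore(z, y, row, index):
    """WHO-restricted z-score for weight-based indices.

    Beyond +/-3 the z-score is replaced by a linear extrapolation on the
    measurement scale anchored at the +/-2 and +/-3 SD reference bounds,
    so z is continuous and piecewise linear in ``y`` outside the centre.
    Height-based laz is returned unchanged.
    """
    index = index.lower()
    if index == "laz":
        return z
    if index not in INDICES:
        raise ValueError(f"unknown index {index!r}")
    if z > 3:
        denom = row["sd3pos"] - row["sd2pos"]
        if denom <= 0:
            raise ReferenceTableError("degenerate upper SD bounds")
        return 3.0 + (y - row["sd3pos"]) / denom
    if z < -3:
        denom = row["sd2neg"] - row["sd3neg"]
        if denom <= 0:
            raise ReferenceTableError("degenerate lower SD bounds")
        return -3.0 + (y - row["sd3neg"]) / denom
    return z


def classify_state(z, alive=True):
    """Map one visit to the model state space.

    Parameters
    ----------
    z : float or nan
        The z-score of the chosen index at the visit.
    alive : bool
        Vital status at the visit; death dominates any z value.

    Returns
    -------
    int or None
        3 if dead; 2 if z < -2 (strict); 1 if z >= -2; ``None`` when the
        child is alive but z is missing (the record belongs to the
        selection model, not the panel likelihood).
    """
    if not alive:
        return STATE_DEAD
    if z is None or (isinstance(z, float) and np.isnan(z)):
        return None
    return STATE_MALNOURISHED if z < -2.0 else STATE_HEALTHY


def classify_states(z, alive):
    """Vectorised :func:`classify_state`; missing live z -> NaN."""
    z = np.asarray(z, dtype=float)
    alive = np.asarray(alive, dtype=bool)
    out = np.where(z < -2.0, float(STATE_MALNOURISHED), float(STATE_HEALTHY))
    out = np.where(np.isnan(z), np.nan, out)
    out = np.where(~alive, float(STATE_DEAD), out)
    return out


@dataclass
class LMSTable:
    """An LMS reference table (index, sex, key -> L, M, S and SD bounds).

    ``data`` uses the CSV schema
    ``index,sex,key,L,M,S,sd3neg,sd2neg,sd2pos,sd3pos``.  Keys are completed
    months for waz/laz and length in cm (0.1 cm grid) for wlz.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ReferenceTableError(f"missing columns: {missing}")
        self.data = self.data[_TABLE_COLUMNS].copy()
        self.data["index"] = self.data["index"].str.lower()
        self.data["sex"] = self.data["sex"].str.lower()
        self._groups = {}
        for (idx, sex), g in self.data.groupby(["index", "sex"]):
            g = g.sort_values("key")
            self._groups[(idx, sex)] = (
                g["key"].to_numpy(float),
                g[["L", "M", "S", "sd3neg", "sd2neg", "sd2pos", "sd3pos"]].to_numpy(float),
            )

    def validate(self, rtol=1e-6):
        """Check ordering of the SD bounds and their consistency with (L,M,S)."""
        d = self.data
        if (d["S"] <= 0).any() or (d["M"] <= 0).any():
            raise ReferenceTableError("M and S must be positive")
        ordered = (
            (d["sd3neg"] < d["sd2neg"]) & (d["sd2neg"] < d["M"])
            & (d["M"] < d["sd2pos"]) & (d["sd2pos"] < d["sd3pos"])
        )
        if not ordered.all():
            raise ReferenceTableError("SD bounds are not strictly ordered around M")
        for col, zval in (("sd3neg", -3), ("sd2neg", -2), ("sd2pos", 2), ("sd3pos", 3)):
            expect = inverse_lms(zval, d["L"], d["M"], d["S"])
            if not np.allclose(d[col], expect, rtol=rtol):
                raise ReferenceTableError(f"{col} inconsistent with (L, M, S)")
        return self

    def lookup(self, index, sex, key):
        """Row of LMS parameters for one index/sex/key, or ``None`` if out of range.

        waz/laz keys use completed months (floor); wlz keys snap to the
        nearest 0.1 cm grid point.
        """
        index = index.lower()
        grp = self._groups.get((index, str(sex).lower()))
        if grp is None:
            return None
        keys, vals = grp
        k = np.floor(key) if index in ("waz", "laz") else np.round(key, 1)
        pos = np.searchsorted(keys, k)
        if pos >= len(keys) or not np.isclose(keys[min(pos, len(keys) - 1)], k):
            return None
        return pd.Series(vals[pos], index=["L", "M", "S", "sd3neg", "sd2neg", "sd2pos", "sd3pos"])

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.data.to_csv(path, index=False)


def _bounds(L, M, S):
    return {f"sd{abs(z)}{'neg' if z < 0 else 'pos'}": inverse_lms(z, L, M, S)
            for z in (-3, -2, 2, 3)}


def synthetic_reference_table(max_age_months=60, length_min=38.0, length_max=120.0):
    """A smooth synthetic stand-in for the WHO 2006 reference tables.

    Curves are chosen to track the broad shape of early-childhood growth
    (median weight ~3.3 kg at birth, ~9.5 kg at 1 y; median length ~50 cm
    at birth, ~75 cm at 1 y) but are *synthetic*: they are for tests and
    simulations only, not for clinical use.  SD bounds are derived exactly
    from (L, M, S), so the table validates by construction.
    """
    rows = []
    ages = np.arange(0, max_age_months + 1)
    for sex, w_scale, l_shift in (("male", 1.0, 0.0), ("female", 0.97, -0.7)):
        for a in ages:
            Mw = w_scale * (3.35 + 6.3 * (1 - np.exp(-a / 10.0)) + 0.145 * a)
            Lw, Sw = 0.25 - 0.001 * a, 0.115 + 0.0002 * a
            rows.append(dict(index="waz", sex=sex, key=float(a), L=Lw, M=Mw, S=Sw,
                             **_bounds(Lw, Mw, Sw)))
            Ml = 49.9 + l_shift + 31.0 * (1 - np.exp(-a / 14.0)) + 0.53 * a
            Ll, Sl = 1.0, 0.035 + 0.00005 * a
            rows.append(dict(index="laz", sex=sex, key=float(a), L=Ll, M=Ml, S=Sl,
                             **_bounds(Ll, Ml, Sl)))
        lengths = np.round(np.arange(length_min, length_max + 1e-9, 0.1), 1)
        for h in lengths:
            u = h - 50.0
            Mwl = w_scale * (3.3 + 0.205 * u + 0.00185 * u * u)
            Lwl, Swl = 0.12, 0.095
            rows.append(dict(index="wlz", sex=sex, key=float(h), L=Lwl, M=Mwl, S=Swl,
                             **_bounds(Lwl, Mwl, Swl)))
    return LMSTable(pd.DataFrame(rows))


def compute_zscores(measures, table, restrict_tails=True, flag_threshold=IMPLAUSIBLE_Z):
    """Per-record z-scores for all three indices.

    Parameters
    ----------
    measures : DataFrame
        Long table with columns ``child_id, age_months, sex, weight_kg,
        length_cm`` (``alive`` optional; defaults to alive).  Absent
        measurements yield absent z-scores.
    table : LMSTable
    restrict_tails : bool
        Apply the WHO tail restriction to waz/wlz (default, matching WHO
        software behaviour).
    flag_threshold : float
        |z| beyond this sets the corresponding ``*_flag`` column; values
        are retained.

    Returns
    -------
    DataFrame with columns waz, laz, wlz and waz_flag, laz_flag, wlz_flag,
    indexed like ``measures``.
    """
    out = {}
    n_oor = 0
    ref = table.data
    sexes = measures["sex"].astype(str).str.lower().to_numpy()
    for idx in INDICES:
        meas_col = "length_cm" if idx == "laz" else "weight_kg"
        key_col = {"waz": "age_months", "laz": "age_months", "wlz": "length_cm"}[idx]
        def _col(name):
            if name in measures:
                return pd.to_numeric(measures[name], errors="coerce").to_numpy(float)
            return np.full(len(measures), np.nan)

        y = _col(meas_col)
        raw_key = _col(key_col)
        key = np.floor(raw_key) if idx in ("waz", "laz") else np.round(raw_key, 1)
        left = pd.DataFrame({"sex": sexes, "key": key, "_y": y})
        sub = ref[ref["index"] == idx]
        merged = left.merge(sub, on=["sex", "key"], how="left")
        have = ~np.isnan(y) & ~np.isnan(key)
        matched = merged["M"].notna().to_numpy()
        n_oor += int((have & ~matched).sum())
        ok = have & matched
        zs = np.full(len(measures), np.nan)
        if ok.any():
            L = merged.loc[ok, "L"].to_numpy()
            M = merged.loc[ok, "M"].to_numpy()
            S = merged.loc[ok, "S"].to_numpy()
            z = lms_zscore(y[ok], L, M, S)
            z = np.atleast_1d(z)
            if restrict_tails and idx != "laz":
                s2p = merged.loc[ok, "sd2pos"].to_numpy()
                s3p = merged.loc[ok, "sd3pos"].to_numpy()
                s2n = merged.loc[ok, "sd2neg"].to_numpy()
                s3n = merged.loc[ok, "sd3neg"].to_numpy()
                z = np.where(z > 3, 3.0 + (y[ok] - s3p) / (s3p - s2p), z)
                z = np.where(z < -3, -3.0 + (y[ok] - s3n) / (s2n - s3n), z)
            zs[ok] = z
        out[idx] = zs
        out[f"{idx}_flag"] = np.abs(zs) > flag_threshold
    if n_oor:
        warnings.warn(f"{n_oor} record/index lookups fell outside the reference table",
                      stacklevel=2)
    return pd.DataFrame(out, index=measures.index)


class WHOZScorer(TransformerMixin, BaseEstimator):
    """Transformer computing waz/laz/wlz z-scores from raw anthropometry.

    Parameters
    ----------
    table : LMSTable or None
        Reference table; ``None`` uses the built-in synthetic table.
    restrict_tails : bool
        WHO-style restriction of weight-based indices beyond +/-3 SD.
    flag_threshold : float
        Implausibility flag threshold on |z|.
    """

    def __init__(self, table=None, restrict_tails=True, flag_threshold=IMPLAUSIBLE_Z):
        self.table = table
        self.restrict_tails = restrict_tails
        self.flag_threshold = flag_threshold

    def fit(self, X=None, y=None):
        table = self.table if self.table is not None else synthetic_reference_table()
        self.table_ = table.validate()
        return self

    def transform(self, X):
        if not hasattr(self, "table_"):
            self.fit()
        z = compute_zscores(X, self.table_, self.restrict_tails, self.flag_threshold)
        return pd.concat([X.reset_index(drop=True), z.reset_index(drop=True)], axis=1)
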