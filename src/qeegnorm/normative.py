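"""Sex- and age-differentiated normative models of log band power.

The core model regresses log band power on age, separately per (band,
channel) and per sex stratum, with a cubic penalized B-spline (P-spline):

    minimize  ||y - B c||^2 + lam * ||D2 c||^2

where ``B`` is a cubic B-spline basis with interior knots at age quantiles
and ``D2`` the second-order divided-difference operator on the
coefficients (over the Greville abscissae, so it is exact for non-uniform
knots).  The penalty's null space is the linear functions, so
straight-line age trends are fitted exactly at any smoothing level;
``lam`` is chosen per component by generalized cross-validation (GCV).

For a new subject of age ``a`` the model supplies a predicted mean
``mu(a)`` and a predicted SD derived from the 95% prediction interval,

    sd_pred(a) = sigma_hat * sqrt(1 + h(a)),

with ``h`` the prediction leverage of the penalized smoother, and
standardizes the subject's log power into a Z-score
``z = (ln power - mu(a)) / sd_pred(a)``.  Both ``mu`` and ``sd_pred`` are
continuous in age — the property that motivates the continuous model over
age-band norms, whose step discontinuities at band boundaries are
reproduced here by :class:`AgeBandNormativeDB` as a comparison baseline.

Model files are versioned JSON holding per-component sufficient statistics
(``B'y``, ``y'y``, shared ``B'B``), so loading re-solves the penalized
normal equations and reproduces predictions exactly; editing the stored
``lam`` of a component yields the consistent refit at that smoothing level.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

from .bands import BAND_NAMES

__all__ = [
    "spline_basis",
    "make_knots",
    "second_difference_penalty",
    "greville_abscissae",
    "fit_penalized_spline",
    "select_lambda_gcv",
    "PenalizedSplineRegressor",
    "NormativeDB",
    "AgeBandNormativeDB",
    "ModelSchemaError",
    "fit_normative_model",
    "fit_age_band_model",
    "save_model",
    "load_model",
]

DEFAULT_LAM_GRID = tuple(np.logspace(-3, 4, 15))
Z_975 = 1.959964  # standard-normal 97.5% quantile: converts 95% PI half-width to SD


class ModelSchemaError(ValueError):
    """A model file is corrupted, truncated, or of an unknown schema."""


def make_knots(x: np.ndarray, n_interior: int = 10, degree: int = 3) -> np.ndarray:
    """Full knot vector: boundary knots at the data range, interior at quantiles."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if not lo < hi:
        raise ValueError("ages must span a nonzero range")
    probs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(x, probs))
    interior = interior[(interior > lo) & (interior < hi)]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def spline_basis(ages, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """B-spline design matrix at *ages*; rows sum to 1 (partition of unity).

    Ages must lie within the knot span [knots[degree], knots[-degree-1]].
    """
    x = np.atleast_1d(np.asarray(ages, dtype=float))
    lo, hi = knots[degree], knots[-degree - 1]
    if x.min() < lo or x.max() > hi:
        raise ValueError(f"ages outside the knot span [{lo}, {hi}]")
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def greville_abscissae(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Greville sites: the knot averages at which B-spline coefficients 'live'."""
    m = len(knots) - degree - 1
    return np.array([knots[j + 1 : j + degree + 1].mean() for j in range(m)])


def second_difference_penalty(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Second-order divided-difference operator on the spline coefficients.

    Built over the Greville abscissae so that coefficients of any *linear*
    function are annihilated even with unequally spaced knots; rescaled by
    the squared mean site spacing, which reduces it to the familiar
    [1, -2, 1] stencil on a uniform knot grid.  Shape (m-2, m).
    """
    g = greville_abscissae(np.asarray(knots, dtype=float), degree)
    m = len(g)
    if m < 3:
        raise ValueError("need at least 3 coefficients for a second-difference penalty")
    h = np.diff(g)
    D = np.zeros((m - 2, m))
    for j in range(m - 2):
        D[j, j] = 1.0 / h[j]
        D[j, j + 1] = -(1.0 / h[j] + 1.0 / h[j + 1])
        D[j, j + 2] = 1.0 / h[j + 1]
    return D * h.mean() ** 2


def _penalized_solve(BtB: np.ndarray, P: np.ndarray, lam: float, Bty: np.ndarray):
    C = BtB + lam * P
    try:
        fac = sla.cho_factor(C)
    except sla.LinAlgError as err:
        raise ValueError(
            f"penalized normal equations singular at lam={lam}; use lam > 0 or fewer knots"
        ) from err
    coef = sla.cho_solve(fac, Bty)
    Cinv = sla.cho_solve(fac, np.eye(len(BtB)))
    return coef, Cinv


def fit_penalized_spline(
    ages, y, lam: float, n_knots: int = 10, degree: int = 3, knots: np.ndarray | None = None
) -> dict:
    """Fit one penalized-spline regression at a fixed smoothing parameter.

    Returns a dict with ``coef``, ``knots``, ``hat_diag`` (training
    leverages), ``sigma`` (residual SD, RSS/(n - edf) based), ``edf`` and
    ``rss``.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if knots is None:
        knots = make_knots(ages, n_interior=n_knots, degree=degree)
    B = spline_basis(ages, knots, degree)
    D = second_difference_penalty(knots, degree)
    P = D.T @ D
    BtB = B.T @ B
    coef, Cinv = _penalized_solve(BtB, P, lam, B.T @ y)
    fitted = B @ coef
    rss = float(np.sum((y - fitted) ** 2))
    edf = float(np.trace(Cinv @ BtB))
    n = len(y)
    if n <= edf:
        raise ValueError(f"n={n} must exceed the effective dof ({edf:.1f})")
    hat_diag = np.einsum("ij,jk,ik->i", B, Cinv, B)
    sigma = float(np.sqrt(rss / (n - edf)))
    return {
        "coef": coef,
        "knots": knots,
        "degree": degree,
        "hat_diag": hat_diag,
        "sigma": sigma,
        "edf": edf,
        "rss": rss,
    }


def select_lambda_gcv(ages, y, lam_grid: Sequence[float] = DEFAULT_LAM_GRID,
                      n_knots: int = 10, degree: int = 3) -> float:
    """Grid minimizer of GCV(lam) = n * RSS / (n - edf)^2."""
    lam_grid = list(lam_grid)
    if len(lam_grid) < 2:
        raise ValueError("lam grid needs at least 2 values")
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    best = None
    for lam in lam_grid:
        fit = fit_penalized_spline(ages, y, lam, n_knots=n_knots, degree=degree)
        gcv = n * fit["rss"] / (n - fit["edf"]) ** 2
        if best is None or gcv < best[1]:
            best = (lam, gcv)
    return best[0]


class PenalizedSplineRegressor(RegressorMixin, BaseEstimator):
    """Penalized cubic B-spline regression of a response on a single covariate.

    Parameters
    ----------
    n_knots : number of interior knots, placed at covariate quantiles.
    degree : spline degree (cubic by default).
    lam : fixed smoothing parameter, or ``"gcv"`` to select by generalized
        cross-validation over ``lam_grid``.
    lam_grid : candidate smoothing parameters for GCV selection.
    """

    def __init__(self, n_knots: int = 10, degree: int = 3, lam="gcv",
                 lam_grid: Sequence[float] = DEFAULT_LAM_GRID):
        self.n_knots = n_knots
        self.degree = degree
        self.lam = lam
        self.lam_grid = lam_grid

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) != len(y):
            raise ValueError("X and y have different lengths")
        if self.lam == "gcv":
            lam = select_lambda_gcv(x, y, self.lam_grid, self.n_knots, self.degree)
        else:
            lam = float(self.lam)
        fit = fit_penalized_spline(x, y, lam, n_knots=self.n_knots, degree=self.degree)
        self.knots_ = fit["knots"]
        self.coef_ = fit["coef"]
        self.lam_ = lam
        self.sigma_ = fit["sigma"]
        self.edf_ = fit["edf"]
        self.x_min_, self.x_max_ = float(x.min()), float(x.max())
        B = spline_basis(x, self.knots_, self.degree)
        self._BtB = B.T @ B
        D = second_difference_penalty(self.knots_, self.degree)
        _, Cinv = _penalized_solve(self._BtB, D.T @ D, lam, B.T @ y)
        self._M = Cinv @ self._BtB @ Cinv
        self.n_ = len(y)
        return self

    def _basis(self, X) -> np.ndarray:
        x = np.clip(np.asarray(X, dtype=float).reshape(-1), self.x_min_, self.x_max_)
        return spline_basis(x, self.knots_, self.degree)

    def predict(self, X) -> np.ndarray:
        return self._basis(X) @ self.coef_

    def leverage(self, X) -> np.ndarray:
        """Prediction leverage h(x) entering sd_pred = sigma * sqrt(1 + h)."""
        B = self._basis(X)
        return np.einsum("ij,jk,ik->i", B, self._M, B)

    def predict_sd(self, X) -> np.ndarray:
        """Predicted SD of a new observation (95% PI half-width / 1.959964)."""
        return self.sigma_ * np.sqrt(1.0 + self.leverage(X))


def _train_hash(subject_ids, ages) -> str:
    payload = ",".join(
        f"{sid}:{age:.6f}" for sid, age in sorted(zip(map(str, subject_ids), ages))
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _join_cohort(band_powers: pd.DataFrame, demographics: pd.DataFrame, sex_mode: str):
    """Pivot the long band-power table to (subjects x components) + aligned ages."""
    if sex_mode not in ("male", "female", "pooled"):
        raise ValueError("sex_mode must be 'male', 'female' or 'pooled'")
    demo = demographics.drop_duplicates("subject_id").set_index("subject_id")
    if sex_mode != "pooled":
        demo = demo[demo["sex"] == sex_mode]
    wide = band_powers.pivot_table(
        index="subject_id", columns=["band", "channel"], values="log_power"
    )
    wide = wide.loc[wide.index.intersection(demo.index)]
    ages = demo.loc[wide.index, "age"].to_numpy(dtype=float)
    return wide, ages


class NormativeDB(BaseEstimator):
    """Continuous-age normative database for one sex stratum (or pooled).

    Fits an independent penalized-spline age regression of log band power
    for every (band, channel) component, sharing the basis (knots at the age
    quantiles of the training cohort) across components while selecting the
    smoothing parameter per component by GCV.

    Parameters
    ----------
    sex_mode : "male", "female", or "pooled" (both sexes, no sex covariate).
    n_knots, degree : spline basis configuration.
    lam_grid : GCV candidate grid.
    min_n : minimum training-cohort size.
    """

    SCHEMA_VERSION = 1

    def __init__(self, sex_mode: str = "pooled", n_knots: int = 10, degree: int = 3,
                 lam_grid: Sequence[float] = DEFAULT_LAM_GRID, min_n: int = 50,
                 condition: str = "EC"):
        self.sex_mode = sex_mode
        self.n_knots = n_knots
        self.degree = degree
        self.lam_grid = lam_grid
        self.min_n = min_n
        self.condition = condition

    # -- fitting ---------------------------------------------------------

    def fit(self, band_powers: pd.DataFrame, demographics: pd.DataFrame):
        """Fit all (band, channel) components from a long band-power table.

        *band_powers* needs columns subject_id/channel/band/log_power;
        *demographics* needs subject_id/age/sex.  Rows should already be
        restricted to screened-eligible subjects.
        """
        wide, ages = _join_cohort(band_powers, demographics, self.sex_mode)
        if len(wide) < self.min_n:
            raise ValueError(
                f"only {len(wide)} subjects for sex_mode={self.sex_mode!r}; "
                f"need at least {self.min_n}"
            )
        self.knots_ = make_knots(ages, n_interior=self.n_knots, degree=self.degree)
        B = spline_basis(ages, self.knots_, self.degree)
        D = second_difference_penalty(self.knots_, self.degree)
        self._P = D.T @ D
        self.BtB_ = B.T @ B
        self.age_range_ = (float(ages.min()), float(ages.max()))
        self.n_subjects_ = len(wide)
        self.train_hash_ = _train_hash(wide.index, ages)
        full = demographics.drop_duplicates("subject_id")
        self.cohort_hash_ = _train_hash(full["subject_id"], full["age"].to_numpy(dtype=float))

        lam_grid = np.asarray(list(self.lam_grid), dtype=float)
        n = len(ages)
        self.components_: dict[tuple[str, str], dict] = {}
        complete = wide.columns[wide.notna().all(axis=0)]
        Y = wide[complete].to_numpy(dtype=float)
        Bty_all = B.T @ Y
        yty_all = np.einsum("ip,ip->p", Y, Y)

        gcv = np.empty((len(lam_grid), Y.shape[1]))
        edfs = np.empty(len(lam_grid))
        for k, lam in enumerate(lam_grid):
            coefs, Cinv = _penalized_solve(self.BtB_, self._P, lam, Bty_all)
            edfs[k] = np.trace(Cinv @ self.BtB_)
            rss = (
                yty_all
                - 2 * np.einsum("ip,ip->p", coefs, Bty_all)
                + np.einsum("ip,ij,jp->p", coefs, self.BtB_, coefs)
            )
            gcv[k] = n * np.maximum(rss, 0.0) / (n - edfs[k]) ** 2
        best_k = np.argmin(gcv, axis=0)

        self._Cinv_cache: dict[float, np.ndarray] = {}
        for j, col in enumerate(complete):
            lam = float(lam_grid[best_k[j]])
            comp = self._solve_component(lam, Bty_all[:, j], float(yty_all[j]), n)
            band, channel = col
            self.components_[(str(band), str(channel))] = comp

        # components with missing cells: per-column fit on available rows
        for col in wide.columns.difference(complete):
            y = wide[col]
            mask = y.notna().to_numpy()
            band, channel = col
            if mask.sum() < self.min_n:
                self.components_[(str(band), str(channel))] = {"usable": False}
                continue
            Bm = B[mask]
            Bty = Bm.T @ y.to_numpy(dtype=float)[mask]
            # GCV on the reduced rows
            best = None
            for lam in lam_grid:
                coefs, Cinv = _penalized_solve(Bm.T @ Bm, self._P, lam, Bty)
                rss = float(
                    y.to_numpy(dtype=float)[mask] @ y.to_numpy(dtype=float)[mask]
                    - 2 * coefs @ Bty + coefs @ (Bm.T @ Bm) @ coefs
                )
                edf = float(np.trace(Cinv @ (Bm.T @ Bm)))
                g = mask.sum() * max(rss, 0.0) / (mask.sum() - edf) ** 2
                if best is None or g < best[0]:
                    best = (g, lam, coefs, rss, edf)
            _, lam, coefs, rss, edf = best
            sigma = float(np.sqrt(max(rss, 0.0) / (mask.sum() - edf)))
            self.components_[(str(band), str(channel))] = {
                "usable": True, "lam": float(lam), "coef": coefs,
                "Bty": Bty, "yty": float(y.dropna() @ y.dropna()),
                "sigma": sigma, "edf": edf, "n": int(mask.sum()),
            }
        return self

    def _solve_component(self, lam: float, Bty: np.ndarray, yty: float, n: int) -> dict:
        coef, Cinv = _penalized_solve(self.BtB_, self._P, lam, Bty)
        self._Cinv_cache.setdefault(lam, Cinv)
        rss = max(float(yty - 2 * coef @ Bty + coef @ self.BtB_ @ coef), 0.0)
        edf = float(np.trace(Cinv @ self.BtB_))
        sigma = float(np.sqrt(rss / (n - edf)))
        return {
            "usable": True, "lam": float(lam), "coef": coef, "Bty": Bty,
            "yty": float(yty), "sigma": sigma, "edf": edf, "n": int(n),
        }

    # -- prediction ------------------------------------------------------

    def _component(self, band: str, channel: str) -> dict:
        try:
            comp = self.components_[(band, channel)]
        except KeyError:
            raise KeyError(f"no component for (band={band!r}, channel={channel!r})")
        if not comp.get("usable", False):
            raise ValueError(f"component ({band}, {channel}) is unusable (too few subjects)")
        return comp

    def _clamped_basis(self, ages):
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.age_range_
        clamped = np.clip(ages, lo, hi)
        return spline_basis(clamped, self.knots_, self.degree), ~np.isclose(ages, clamped)

    def _leverage(self, B: np.ndarray, lam: float) -> np.ndarray:
        if lam not in self._Cinv_cache:
            _, Cinv = _penalized_solve(self.BtB_, self._P, lam, np.zeros(len(self.BtB_)))
            self._Cinv_cache[lam] = Cinv
        Cinv = self._Cinv_cache[lam]
        M = Cinv @ self.BtB_ @ Cinv
        return np.einsum("ij,jk,ik->i", B, M, B)

    def predict_mean(self, age, band: str, channel: str):
        """Predicted mean log power at *age* (clamped to the training range)."""
        comp = self._component(band, channel)
        B, _ = self._clamped_basis(age)
        out = B @ comp["coef"]
        return float(out[0]) if np.isscalar(age) else out

    def predict_sd(self, age, band: str, channel: str):
        """Predicted SD (95% prediction-interval half-width / 1.959964)."""
        comp = self._component(band, channel)
        B, _ = self._clamped_basis(age)
        out = comp["sigma"] * np.sqrt(1.0 + self._leverage(B, comp["lam"]))
        return float(out[0]) if np.isscalar(age) else out

    def zscore(self, band_powers: pd.DataFrame, demographics: pd.DataFrame) -> pd.DataFrame:
        """Standardize subjects' log band powers against the fitted norms.

        Returns a long DataFrame (subject_id, channel, band, z, age_clamped,
        undefined); cells with nonpositive power are flagged undefined (NaN
        z), never silently zeroed.  Subjects whose sex does not match a
        stratified model are rejected.
        """
        demo = demographics.drop_duplicates("subject_id").set_index("subject_id")
        if self.sex_mode != "pooled":
            bad = demo[demo["sex"] != self.sex_mode]
            if len(bad):
                raise ValueError(
                    f"{len(bad)} subjects do not match sex_mode={self.sex_mode!r}: "
                    f"{list(bad.index[:5])}"
                )
        wide = band_powers.pivot_table(
            index="subject_id", columns=["band", "channel"], values="log_power",
            dropna=False,
        )
        cols = [c for c in wide.columns if (str(c[0]), str(c[1])) in self.components_
                and self.components_[(str(c[0]), str(c[1]))].get("usable", False)]
        wide = wide[cols]
        ages = demo.loc[wide.index, "age"].to_numpy(dtype=float)
        B, clamped = self._clamped_basis(ages)
        coefs = np.column_stack([self.components_[(str(b), str(c))]["coef"] for b, c in cols])
        sigmas = np.array([self.components_[(str(b), str(c))]["sigma"] for b, c in cols])
        lams = np.array([self.components_[(str(b), str(c))]["lam"] for b, c in cols])
        mean = B @ coefs
        sd = np.empty_like(mean)
        for lam in np.unique(lams):
            h = self._leverage(B, float(lam))
            sel = lams == lam
            sd[:, sel] = sigmas[sel][None, :] * np.sqrt(1.0 + h)[:, None]
        Y = wide.to_numpy(dtype=float)
        z = (Y - mean) / sd
        out = pd.DataFrame(z, index=wide.index, columns=wide.columns).stack(
            ["band", "channel"], future_stack=True
        ).rename("z").reset_index()
        out["age_clamped"] = out["subject_id"].map(
            dict(zip(wide.index, clamped))
        )
        out["undefined"] = ~np.isfinite(out["z"])
        return out[["subject_id", "channel", "band", "z", "age_clamped", "undefined"]]

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Write the model as versioned JSON (sufficient statistics included)."""
        doc = {
            "schema_version": self.SCHEMA_VERSION,
            "model": "qeegnorm-normdb",
            "sex_mode": self.sex_mode,
            "condition": self.condition,
            "n_knots": self.n_knots,
            "degree": self.degree,
            "lam_grid": list(map(float, self.lam_grid)),
            "min_n": self.min_n,
            "knots": self.knots_.tolist(),
            "BtB": self.BtB_.tolist(),
            "age_range": list(self.age_range_),
            "n_subjects": self.n_subjects_,
            "train_hash": self.train_hash_,
            "cohort_hash": getattr(self, "cohort_hash_", ""),
            "components": [
                {
                    "band": band, "channel": channel,
                    "usable": bool(comp.get("usable", False)),
                    **(
                        {
                            "lam": comp["lam"],
                            "Bty": np.asarray(comp["Bty"]).tolist(),
                            "yty": comp["yty"],
                            "n": comp["n"],
                        }
                        if comp.get("usable", False)
                        else {}
                    ),
                }
                for (band, channel), comp in sorted(self.components_.items())
            ],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "NormativeDB":
        """Reconstruct a model from JSON; predictions are reproduced exactly."""
        try:
            doc = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as err:
            raise ModelSchemaError(f"cannot parse model file {path}: {err}") from err
        if not isinstance(doc, dict) or doc.get("model") != "qeegnorm-normdb":
            raise ModelSchemaError(f"{path} is not a qeegnorm normative-model file")
        if doc.get("schema_version") != cls.SCHEMA_VERSION:
            raise ModelSchemaError(
                f"unsupported schema version {doc.get('schema_version')!r}"
            )
        required = {"knots", "BtB", "age_range", "n_subjects", "components", "sex_mode"}
        missing = required - doc.keys()
        if missing:
            raise ModelSchemaError(f"model file missing fields: {sorted(missing)}")
        model = cls(
            sex_mode=doc["sex_mode"], n_knots=doc["n_knots"], degree=doc["degree"],
            lam_grid=tuple(doc["lam_grid"]), min_n=doc["min_n"],
            condition=doc.get("condition", "EC"),
        )
        model.knots_ = np.asarray(doc["knots"], dtype=float)
        model.BtB_ = np.asarray(doc["BtB"], dtype=float)
        D = second_difference_penalty(model.knots_, model.degree)
        model._P = D.T @ D
        model.age_range_ = tuple(doc["age_range"])
        model.n_subjects_ = int(doc["n_subjects"])
        model.train_hash_ = doc.get("train_hash", "")
        model.cohort_hash_ = doc.get("cohort_hash", "")
        model._Cinv_cache = {}
        model.components_ = {}
        try:
            for entry in doc["components"]:
                key = (entry["band"], entry["channel"])
                if not entry["usable"]:
                    model.components_[key] = {"usable": False}
                    continue
                comp = model._solve_component(
                    float(entry["lam"]),
                    np.asarray(entry["Bty"], dtype=float),
                    float(entry["yty"]),
                    int(entry["n"]),
                )
                model.components_[key] = comp
        except (KeyError, TypeError, ValueError) as err:
            raise ModelSchemaError(f"malformed component entry in {path}: {err}") from err
        return model


class AgeBandNormativeDB(BaseEstimator):
    """Discrete age-band (sliding-window) normative baseline.

    Divides the training ages into contiguous windows of width
    ``2 * half_width`` years, computes per-window mean and SD of log power
    per (band, channel), and standardizes a subject with the statistics of
    the window nearest their age.  Windows thinner than ``min_n`` subjects
    recruit the nearest subjects by age until satisfied.  By construction
    the resulting Z-scores jump at window boundaries — the discontinuity
    the continuous model removes.
    """

    def __init__(self, sex_mode: str = "pooled", half_width: float = 5.0,
                 min_n: int = 30, condition: str = "EC"):
        self.sex_mode = sex_mode
        self.half_width = half_width
        self.min_n = min_n
        self.condition = condition

    def _assign(self, ages: np.ndarray) -> np.ndarray:
        idx = np.floor((ages - self.age_range_[0]) / (2 * self.half_width)).astype(int)
        return np.clip(idx, 0, len(self.window_centers_) - 1)

    def fit(self, band_powers: pd.DataFrame, demographics: pd.DataFrame):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        wide, ages = _join_cohort(band_powers, demographics, self.sex_mode)
        if len(wide) < self.min_n:
            raise ValueError(
                f"cohort of {len(wide)} subjects cannot form any window of >= {self.min_n}"
            )
        lo, hi = float(ages.min()), float(ages.max())
        self.age_range_ = (lo, hi)
        width = 2 * self.half_width
        n_windows = max(1, int(np.ceil((hi - lo) / width)))
        self.window_centers_ = lo + width * (np.arange(n_windows) + 0.5)
        assign = self._assign(ages)
        Y = wide.to_numpy(dtype=float)
        means = np.empty((n_windows, Y.shape[1]))
        sds = np.empty_like(means)
        counts = np.empty(n_windows, dtype=int)
        for w in range(n_windows):
            members = np.flatnonzero(assign == w)
            if len(members) < self.min_n:
                # widen: recruit nearest subjects by age to the window center
                order = np.argsort(np.abs(ages - self.window_centers_[w]))
                members = order[: self.min_n]
            counts[w] = len(members)
            means[w] = Y[members].mean(axis=0)
            sds[w] = Y[members].std(axis=0, ddof=1)
        self.window_means_ = pd.DataFrame(means, columns=wide.columns)
        self.window_sds_ = pd.DataFrame(sds, columns=wide.columns)
        self.window_counts_ = counts
        self.columns_ = wide.columns
        self.n_subjects_ = len(wide)
        self.train_hash_ = _train_hash(wide.index, ages)
        full = demographics.drop_duplicates("subject_id")
        self.cohort_hash_ = _train_hash(full["subject_id"], full["age"].to_numpy(dtype=float))
        return self

    def zscore(self, band_powers: pd.DataFrame, demographics: pd.DataFrame) -> pd.DataFrame:
        demo = demographics.drop_duplicates("subject_id").set_index("subject_id")
        wide = band_powers.pivot_table(
            index="subject_id", columns=["band", "channel"], values="log_power",
            dropna=False,
        )[self.columns_]
        ages = demo.loc[wide.index, "age"].to_numpy(dtype=float)
        assign = self._assign(np.clip(ages, *self.age_range_))
        mean = self.window_means_.to_numpy()[assign]
        sd = self.window_sds_.to_numpy()[assign]
        diff = wide.to_numpy(dtype=float) - mean
        # a window of identical values has sd (and deviations) at rounding level
        tiny = 1e-10 * np.maximum(1.0, np.abs(mean))
        degenerate = (sd <= tiny) & (np.abs(diff) <= tiny)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(degenerate, 0.0, diff / sd)
        out = pd.DataFrame(z, index=wide.index, columns=wide.columns).stack(
            ["band", "channel"], future_stack=True
        ).rename("z").reset_index()
        out["undefined"] = ~np.isfinite(out["z"])
        return out[["subject_id", "channel", "band", "z", "undefined"]]


# -- thin functional wrappers -------------------------------------------


def fit_normative_model(band_powers, demographics, sex_mode: str = "pooled", **kw) -> NormativeDB:
    return NormativeDB(sex_mode=sex_mode, **kw).fit(band_powers, demographics)


def fit_age_band_model(band_powers, demographics, sex_mode: str = "pooled",
                       half_width: float = 5.0, **kw) -> AgeBandNormativeDB:
    return AgeBandNormativeDB(sex_mode=sex_mode, half_width=half_width, **kw).fit(
        band_powers, demographics
    )


def save_model(model: NormativeDB, path) -> None:
    model.save(path)


def load_model(path) -> NormativeDB:
    return NormativeDB.load(path)
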