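"""Multiple imputation of unmeasured fasting plasma glucose (FPG) status.

Undiagnosed diabetes requires A1c >= 6.5 % *or* FPG >= 126 mg/dL, but two of
the three sources never measure FPG, and the national survey measures it on
a random half of respondents only. A logistic model for the probability of
elevated FPG — fitted on the FPG half-sample among persons who are neither
diagnosed nor A1c-positive — supplies that missing evidence: for each person
lacking FPG we draw the elevated-FPG indicator Bernoulli(p-hat), repeated
independently across *m* completions. Downstream estimates average over the
completions and carry the between-imputation variance via Rubin's rules.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

from .config import CutPoints


class FpgImputer(BaseEstimator):
    """Logistic model for elevated FPG among undiagnosed, A1c-negative persons.

    Parameters
    ----------
    predictors : tuple of str
        Columns used as predictors. ``sex`` is dummy-coded (male = 1);
        everything else is treated as numeric.
    min_events : int
        Minimum number of elevated-FPG outcomes required to fit.
    cuts : CutPoints
        Diagnostic thresholds defining the outcome and the A1c screen.

    Fitted attributes
    -----------------
    coef_ : ndarray of model coefficients (excluding intercept)
    intercept_ : float
    predictor_names_ : list of design-matrix column names
    n_obs_, n_events_ : training-population bookkeeping
    """

    def __init__(self, predictors: tuple[str, ...] = ("a1c", "age", "sex"),
                 min_events: int = 30, cuts: CutPoints = CutPoints()):
        self.predictors = predictors
        self.min_events = min_events
        self.cuts = cuts

    # -- design matrix ---------------------------------------------------
    def _design(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for p in self.predictors:
            if p not in X.columns:
                raise ValueError(f"predictor column '{p}' missing")
            if p == "sex":
                cols["sex_male"] = (X[p] == "male").astype(float)
            else:
                cols[p] = pd.to_numeric(X[p], errors="raise").astype(float)
        return pd.DataFrame(cols, index=X.index)

    def fit(self, X: pd.DataFrame, y=None, sample_weight=None) -> "FpgImputer":
        """Fit on records carrying observed FPG.

        ``X`` needs the predictor columns plus ``fpg``, ``a1c`` and a boolean
        ``diagnosed``. The training population is restricted to persons who
        are not diagnosed, have A1c below the diagnostic cut, and have FPG
        observed; the outcome is FPG at or above the diagnostic cut.
        """
        mask = (~X["diagnosed"].astype(bool)
                & (X["a1c"] < self.cuts.a1c_diabetes)
                & X["fpg"].notna())
        sub = X[mask]
        outcome = (sub["fpg"] >= self.cuts.fpg_diabetes).astype(float)
        n_events = int(outcome.sum())
        if n_events < self.min_events:
            raise ValueError(
                f"too few elevated-FPG outcomes to fit: {n_events} < {self.min_events}")
        design = self._design(sub)
        for col in design.columns:
            if design[col].nunique() <= 1:
                raise ValueError(f"predictor column '{col}' is constant")
        design = sm.add_constant(design, has_constant="add")
        w = None
        if sample_weight is not None:
            w = np.asarray(sample_weight)[np.asarray(mask)]
        model = sm.GLM(outcome, design, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(maxiter=200)
        params = res.params.to_numpy()
        if not np.all(np.isfinite(params)) or np.max(np.abs(params[1:])) > 50:
            raise ValueError(
                "logistic fit did not yield finite, stable coefficients "
                "(possible separation); refusing to impute")
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        self.bse_ = res.bse.to_numpy()[1:]
        self.intercept_bse_ = float(res.bse.to_numpy()[0])
        self.predictor_names_ = [c for c in design.columns if c != "const"]
        self.n_obs_ = int(mask.sum())
        self.n_events_ = n_events
        return self

    @classmethod
    def from_coefficients(cls, intercept: float, coefs: dict[str, float],
                          predictors: tuple[str, ...] | None = None,
                          cuts: CutPoints = CutPoints()) -> "FpgImputer":
        """Build an already-'fitted' model from known coefficients — e.g. the
        generating law of a simulation."""
        if predictors is None:
            predictors = tuple("sex" if k == "sex_male" else k for k in coefs)
        obj = cls(predictors=predictors, cuts=cuts)
        obj.intercept_ = float(intercept)
        obj.predictor_names_ = list(coefs)
        obj.coef_ = np.array([coefs[k] for k in obj.predictor_names_], dtype=float)
        obj.n_obs_ = 0
        obj.n_events_ = 0
        return obj

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of elevated FPG for each row; strictly inside (0, 1)."""
        design = self._design(X)[self.predictor_names_]
        eta = self.intercept_ + design.to_numpy() @ self.coef_
        return expit(eta)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "predictors": list(self.predictors),
            "intercept": self.intercept_,
            "coefficients": dict(zip(self.predictor_names_, self.coef_.tolist())),
            "n_obs": self.n_obs_, "n_events": self.n_events_,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FpgImputer":
        payload = json.loads(Path(path).read_text())
        return cls.from_coefficients(payload["intercept"], payload["coefficients"],
                                     predictors=tuple(payload["predictors"]))


def impute_undiagnosed(X: pd.DataFrame, model: FpgImputer, m: int,
                       rng: np.random.Generator | int | None = None,
                       cuts: CutPoints = CutPoints()) -> np.ndarray:
    """Return an (n, m) boolean matrix of undiagnosed-diabetes indicators.

    Deterministic evidence dominates in every completion: diagnosed persons
    are never undiagnosed; an observed A1c or FPG at/above its diagnostic cut
    makes the person undiagnosed in all completions. Only persons with no
    diagnosis, A1c below the cut and *missing* FPG receive stochastic draws,
    independent across completions.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(X)
    diagnosed = X["diagnosed"].astype(bool).to_numpy()
    a1c = pd.to_numeric(X["a1c"], errors="coerce").to_numpy()
    a1c_pos = ~diagnosed & (a1c >= cuts.a1c_diabetes)
    fpg = pd.to_numeric(X.get("fpg", pd.Series(np.nan, index=X.index)),
                        errors="coerce").to_numpy()
    fpg_pos = ~diagnosed & ~a1c_pos & (fpg >= cuts.fpg_diabetes)
    needs_draw = ~diagnosed & ~a1c_pos & np.isnan(fpg) & ~np.isnan(a1c)

    out = np.zeros((n, m), dtype=bool)
    out[a1c_pos | fpg_pos, :] = True
    k = int(needs_draw.sum())
    if k:
        p = model.predict_proba(X[needs_draw])
        out[needs_draw, :] = rng.random((k, m)) < p[:, None]
    return out


def rubin_combine(points: np.ndarray, variances: np.ndarray) -> dict[str, float]:
    """Combine m completed-data estimates: total variance is the mean
    within-imputation variance plus (1 + 1/m) times the between-imputation
    variance. Total variance can never fall below the within component."""
    points = np.asarray(points, dtype=float)
    variances = np.asarray(variances, dtype=float)
    m = len(points)
    qbar = points.mean()
    w = variances.mean()
    b = points.var(ddof=1) if m > 1 else 0.0
    t = w + (1.0 + 1.0 / m) * b
    return {"point": qbar, "variance": t, "within": w, "between": b, "m": m}
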