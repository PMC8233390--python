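"""Binomial mixed-effects models for foraging choices.

Two families are fitted, both with a per-bird random intercept:

* daily learning curves — binomial counts of unpalatable vs palatable visits
  per bird-day explained by species, age, and an orthogonal second-order
  polynomial of experiment day, with AIC selection starting from the
  three-way interaction;
* per-choice models — each visit as a binary response (1 = unpalatable
  chosen) explained by personal-experience counts (N+, N-) and
  network-weighted expected observations (O+, O-), with demonstrator-class
  splits and their difference reparameterisations.

Predictors are z-standardized by default to aid fitting, and every fit
carries the back-transformed (original-scale) coefficients alongside.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glmm
from .exceptions import ComparisonError, SpecificationError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "model_spec",
    "PARAMETERIZATIONS",
    "fit_choice_model",
    "fit_learning_curve",
    "compare_models",
    "orthogonal_poly",
]

#: named per-choice parameterisations: social/asocial terms entering the
#: linear predictor.  In the *_diff forms the coefficient on a split column
#: is the difference between the class effects (a linear recombination of
#: the corresponding *_split form).
PARAMETERIZATIONS = {
    "base": ["N_plus", "N_minus", "O_plus", "O_minus"],
    "asocial_only": ["N_plus", "N_minus"],
    "social_only": ["O_plus", "O_minus"],
    "species_split": ["N_plus", "N_minus",
                      "O_plus_H", "O_minus_H", "O_plus_C", "O_minus_C"],
    "species_diff": ["N_plus", "N_minus",
                     "O_plus", "O_minus", "O_plus_C", "O_minus_C"],
    "final": ["N_plus", "N_minus", "O_minus", "O_plus_H", "O_plus_C"],
    "age_split": ["N_plus", "N_minus",
                  "O_minus_A", "O_minus_J",
                  "O_plus_HA", "O_plus_HJ", "O_plus_CA", "O_plus_CJ"],
    "age_diff": ["N_plus", "N_minus",
                 "O_minus", "O_minus_A",
                 "O_plus_H", "O_plus_HA", "O_plus_C", "O_plus_CA"],
}


@dataclass
class ModelSpec:
    """Which covariates enter a per-choice model and how they are coded."""

    label: str
    terms: list[str]
    standardize: bool = True
    response: str = "per_choice_binary"

    def validate(self, table: pd.DataFrame) -> None:
        missing = [t for t in self.terms if t not in table.columns]
        if missing:
            raise SpecificationError(
                f"choice table lacks columns {missing} required by "
                f"spec {self.label!r}")


def model_spec(label: str, standardize: bool = True) -> ModelSpec:
    if label not in PARAMETERIZATIONS:
        raise SpecificationError(
            f"unknown parameterisation {label!r}; "
            f"choose from {sorted(PARAMETERIZATIONS)}")
    return ModelSpec(label=label, terms=list(PARAMETERIZATIONS[label]),
                     standardize=standardize)


@dataclass
class ModelFit:
    """A fitted choice or learning-curve model with Wald inference.

    ``coef`` columns: estimate, se, z, p (on the fitted, possibly
    standardized scale); ``coef_original`` maps term -> back-transformed
    estimate (standardized beta divided by the predictor SD, intercept
    adjusted for the means).
    """

    spec: ModelSpec
    fit: glmm.GlmmFit
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    response_fingerprint: str = ""
    separation_flag: bool = False
    selection_table: pd.DataFrame | None = None

    @property
    def coef(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.fit.beta, "se": self.fit.se,
             "z": self.fit.z, "p": self.fit.pvalues},
            index=self.fit.names)

    @property
    def coef_original(self) -> dict:
        out = {}
        inter = 0.0
        for name, b in zip(self.fit.names, self.fit.beta):
            if name == "(Intercept)":
                continue
            sd = self.sds.get(name, 1.0)
            mu = self.means.get(name, 0.0)
            out[name] = b / sd
            inter += b * mu / sd
        if "(Intercept)" in self.fit.names:
            a = self.fit.beta[self.fit.names.index("(Intercept)")]
            out["(Intercept)"] = a - inter
        return out

    @property
    def se_original(self) -> dict:
        return {name: s / self.sds.get(name, 1.0)
                for name, s in zip(self.fit.names, self.fit.se)
                if name != "(Intercept)"}

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def sigma_b(self) -> float:
        return self.fit.sigma

    def zvalue(self, term: str) -> float:
        if term not in self.fit.names:
            raise SpecificationError(f"term {term!r} not in fit")
        return float(self.coef.loc[term, "z"])

    def summary_table(self) -> pd.DataFrame:
        """Human-readable coefficient table (standardized and original scale)."""
        tab = self.coef.copy()
        orig = self.coef_original
        tab["estimate_original"] = [orig.get(n, np.nan) for n in tab.index]
        return tab

    def to_json(self) -> str:
        payload = {
            "label": self.spec.label,
            "terms": self.spec.terms,
            "standardize": self.spec.standardize,
            "coefficients": {
                n: {"estimate": float(b), "se": float(s), "z": float(z),
                    "p": float(p)}
                for n, b, s, z, p in zip(
                    self.fit.names, self.fit.beta, self.fit.se,
                    self.fit.z, self.fit.pvalues)},
            "coef_original": {k: float(v)
                              for k, v in self.coef_original.items()},
            "random_intercept_sd": float(self.fit.sigma),
            "boundary_sigma": self.fit.boundary_sigma,
            "loglik": float(self.fit.loglik),
            "aic": float(self.fit.aic),
            "k": self.fit.k,
            "nobs": self.fit.nobs,
            "ngroups": self.fit.ngroups,
            "converged": self.fit.converged,
            "dropped": self.fit.dropped,
            "separation_flag": self.separation_flag,
        }
        return json.dumps(payload, indent=2)


def _fingerprint(y: np.ndarray, groups: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(y, dtype=float).tobytes())
    h.update("|".join(str(g) for g in groups).encode())
    return h.hexdigest()[:16]


def fit_choice_model(
    choice_table: pd.DataFrame,
    spec: ModelSpec,
    method: str = "agh",
    n_quad: int = 25,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> ModelFit:
    """Per-choice binary logistic mixed model (random intercept per bird)."""
    spec.validate(choice_table)
    y = choice_table["chose_unpalatable"].to_numpy(dtype=float)
    groups = choice_table["bird_id"].to_numpy()

    cols, names, means, sds = [], ["(Intercept)"], {}, {}
    for term in spec.terms:
        x = choice_table[term].to_numpy(dtype=float)
        if spec.standardize:
            mu, sd = float(x.mean()), float(x.std(ddof=0))
            if sd > 0:
                x = (x - mu) / sd
                means[term], sds[term] = mu, sd
            # zero-variance columns are left unscaled; the rank-deficiency
            # pass below drops the all-zero ones with a record
        cols.append(x)
        names.append(term)
    X = np.column_stack([np.ones_like(y)] + cols)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = glmm.fit_binomial_glmm(X, y, groups, names=names, method=method,
                                   n_quad=n_quad, start=start,
                                   compute_se=compute_se)
    separation = bool(np.any(np.abs(f.beta) > 15.0))
    return ModelFit(spec=spec, fit=f, means=means, sds=sds,
                    response_fingerprint=_fingerprint(y, groups),
                    separation_flag=separation)


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """AIC table (k, loglik, AIC, dAIC) sorted ascending by AIC."""
    if not fits:
        raise ComparisonError("no fits supplied")
    fps = {f.response_fingerprint for f in fits}
    if len(fps) > 1:
        raise ComparisonError(
            "fits were not computed on identical response rows")
    rows = [{"label": f.spec.label, "k": f.fit.k, "loglik": f.loglik,
             "AIC": f.aic} for f in fits]
    tab = pd.DataFrame(rows).sort_values("AIC", kind="mergesort")
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    return tab.reset_index(drop=True)


def orthogonal_poly(x: np.ndarray, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial coding of a covariate (QR, constant dropped)."""
    x = np.asarray(x, dtype=float)
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    q, _ = np.linalg.qr(V)
    q = q[:, 1:]
    # fix sign so the linear column increases with x
    for j in range(q.shape[1]):
        lead = q[np.argmax(x), j] - q[np.argmin(x), j]
        if lead < 0:
            q[:, j] = -q[:, j]
    return q


#: learning-curve model set, largest first; day1/day2 are the orthogonal
#: polynomial columns, sp/ag the species/age dummies
_CURVE_MODELS = {
    "day2*species*age": [
        "day1", "day2", "sp", "ag", "sp:ag",
        "day1:sp", "day2:sp", "day1:ag", "day2:ag",
        "day1:sp:ag", "day2:sp:ag"],
    "day2*species+day2*age": [
        "day1", "day2", "sp", "ag",
        "day1:sp", "day2:sp", "day1:ag", "day2:ag"],
    "day2*age+species": ["day1", "day2", "sp", "ag", "day1:ag", "day2:ag"],
    "day2*species+age": ["day1", "day2", "sp", "ag", "day1:sp", "day2:sp"],
    "day2+species+age": ["day1", "day2", "sp", "ag"],
    "day2": ["day1", "day2"],
}


def daily_counts(visits: pd.DataFrame) -> pd.DataFrame:
    """Per bird-day unpalatable/palatable visit counts from a visit table."""
    v = visits.copy()
    day = np.floor((v["time"] - v["time"].min()) / 86_400.0).astype(int) + 1
    v["day"] = day
    grp = v.groupby(["bird_id", "species", "age", "day"], sort=True)
    out = grp["palatable"].agg(
        n_unpal=lambda s: int((s == 0).sum()), n_total="count")
    return out.reset_index()


def fit_learning_curve(
    visits: pd.DataFrame,
    pooling: str = "all",
    raw_poly: bool = False,
    method: str = "agh",
    n_quad: int = 25,
) -> ModelFit:
    """Daily binomial learning-curve model with AIC model selection.

    The response is (unpalatable visits, total visits) per bird-day; the day
    enters as a degree-2 polynomial (orthogonal by default), crossed with
    species and age; selection starts from the three-way interaction and
    keeps the lowest-AIC member of the nested set.
    """
    counts = daily_counts(visits)
    if counts["day"].nunique() < 2:
        raise SpecificationError("need at least 2 days of data")
    day = counts["day"].to_numpy(dtype=float)
    if raw_poly:
        poly = np.column_stack([day, day ** 2])
    else:
        poly = orthogonal_poly(day, 2)
    sp_levels = sorted(counts["species"].unique())
    base = {"day1": poly[:, 0], "day2": poly[:, 1],
            "sp": (counts["species"] == sp_levels[-1]).to_numpy(float)
            if len(sp_levels) > 1 else np.zeros(len(counts)),
            "ag": (counts["age"] == "juvenile").to_numpy(float)}
    base["sp:ag"] = base["sp"] * base["ag"]
    for d in ("day1", "day2"):
        base[f"{d}:sp"] = base[d] * base["sp"]
        base[f"{d}:ag"] = base[d] * base["ag"]
        base[f"{d}:sp:ag"] = base[d] * base["sp"] * base["ag"]

    y = counts["n_unpal"].to_numpy(float)
    m = counts["n_total"].to_numpy(float)
    groups = counts["bird_id"].to_numpy()

    best = None
    rows = []
    for label, terms in _CURVE_MODELS.items():
        X = np.column_stack([np.ones(len(counts))] + [base[t] for t in terms])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = glmm.fit_binomial_glmm(
                X, y, groups, trials=m, names=["(Intercept)"] + terms,
                method=method, n_quad=n_quad)
        rows.append({"label": label, "k": f.k, "loglik": f.loglik,
                     "AIC": f.aic})
        if best is None or f.aic < best[1].aic:
            best = (label, f)
    label, f = best
    sel = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    sel["dAIC"] = sel["AIC"] - sel["AIC"].min()
    spec = ModelSpec(label=f"learning_curve[{label}]",
                     terms=_CURVE_MODELS[label], standardize=False,
                     response="daily_binomial")
    separation = bool(np.any(np.abs(f.beta) > 50.0))
    return ModelFit(spec=spec, fit=f, means={}, sds={},
                    response_fingerprint=_fingerprint(y, groups),
                    separation_flag=separation, selection_table=sel)
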