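"""Order-of-acquisition diffusion analysis (OADA) for reversal learning.

The data are the order in which birds first sample the target (previously
avoided) colour.  At each acquisition event the relative rate for naive
bird *i* is

    R_i = exp(beta_A x_i) + sum_m s_m exp(beta_S x_i) sum_j a^(m)_ij z_j(t)

where ``x_i`` is the species individual-level variable (ILV), ``s_m`` the
social-transmission rate per unit connection of transmission network *m*
(observed network masked by demonstrator age and/or species relation, or a
homogenized network), and ``z_j(t)`` the informed status.  The event
contribution is ``log(R_acquirer / sum_naive R_i)``: a baseline rate common
to all individuals cancels, so only the order matters.  Models in a set are
compared by AICc (n = number of acquisition events) and Akaike weights; the
social-transmission parameter s is profiled for confidence intervals, and
the percentage of acquisitions attributable to each network (%ST) is the
mean per-event social fraction of the acquirer's rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .association_network import AssociationMatrix, homogenize
from .exceptions import (FitError, InvalidArgumentError, SpecificationError,
                         TieError)
from .synthetic_data import transmission_mask

__all__ = [
    "AcquisitionData",
    "OadaSpec",
    "OadaModel",
    "build_acquisition_order",
    "transmission_networks",
    "oada_loglik",
    "fit_oada",
    "profile_ci",
    "percent_social",
    "model_set_report",
    "default_model_set",
]


@dataclass
class AcquisitionData:
    """Time-ordered first visits plus the roster context for risk sets.

    ``order`` lists acquirers; ``seeds`` are birds informed at time zero
    (demonstrators); ``censored`` birds never acquired but stay in every
    risk set.
    """

    order: list[str]
    times: list[float]
    roster: pd.DataFrame
    seeds: list[str] = field(default_factory=list)
    censored: list[str] = field(default_factory=list)

    def __post_init__(self):
        if list(self.times) != sorted(self.times):
            raise InvalidArgumentError("acquisition times must be increasing")
        ids = list(self.roster["bird_id"])
        unknown = [b for b in list(self.order) + list(self.seeds)
                   + list(self.censored) if b not in ids]
        if unknown:
            raise InvalidArgumentError(f"birds {unknown} not in roster")

    @property
    def n_events(self) -> int:
        return len(self.order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bird_id": self.order, "time": self.times,
                             "rank": np.arange(1, len(self.order) + 1)})


def build_acquisition_order(
    visits: pd.DataFrame,
    target_colour: str,
    phase: str = "reversal",
    roster: pd.DataFrame | None = None,
    tie_break: bool = False,
) -> AcquisitionData:
    """First visit per bird to the target colour, time-ordered.

    Birds in the roster that never visit are censored non-acquirers.  Exact
    ties between two first-visit times are an error naming the birds unless
    ``tie_break`` orders them deterministically by (time, bird_id).
    """
    sel = visits[(visits["phase"] == phase)
                 & (visits["colour"] == target_colour)]
    if len(sel) == 0:
        raise InvalidArgumentError(
            f"no {phase!r}-phase visits to colour {target_colour!r}")
    first = (sel.sort_values(["time", "bird_id"], kind="mergesort")
             .groupby("bird_id", sort=False).head(1))
    dup = first["time"].duplicated(keep=False)
    if dup.any() and not tie_break:
        tied = sorted(first.loc[dup, "bird_id"])
        raise TieError(
            f"exact first-visit time ties between birds {tied}; "
            "pass tie_break=True to order by (time, bird_id)")
    first = first.sort_values(["time", "bird_id"], kind="mergesort")
    if roster is None:
        roster = (visits[["bird_id", "species", "age"]]
                  .drop_duplicates("bird_id").reset_index(drop=True))
    acquired = set(first["bird_id"])
    censored = [b for b in roster["bird_id"] if b not in acquired]
    return AcquisitionData(order=list(first["bird_id"]),
                           times=list(first["time"].astype(float)),
                           roster=roster, censored=censored)


def transmission_networks(
    network: AssociationMatrix,
    roster: pd.DataFrame,
    by_age: bool = False,
    by_relation: bool = False,
    homogeneous: bool = False,
) -> dict[str, np.ndarray]:
    """Demonstrator-class transmission networks as masks of one base network.

    Masking zeroes the columns (demonstrators) outside the class; combined
    age x relation masks are produced when both splits are requested.  With
    ``homogeneous=True`` the base is the column-homogenized network.
    """
    # align the matrix to roster order so downstream risk-set code can
    # index every structure positionally
    ids = list(roster["bird_id"])
    perm = np.array([network.index(b) for b in ids])
    weights = network.weights[np.ix_(perm, perm)]
    aligned = AssociationMatrix(birds=ids, weights=weights,
                                homogenized=network.homogenized)
    if homogeneous and not aligned.homogenized:
        base_m = homogenize(aligned)
    else:
        base_m = aligned
    age_parts = ["adult", "juvenile"] if by_age else ["all"]
    rel_parts = ["conspecific", "heterospecific"] if by_relation else ["all"]
    out = {}
    for ag, rel in itertools.product(age_parts, rel_parts):
        label = "_".join(p for p in (ag, rel) if p != "all") or "all"
        mask = transmission_mask(base_m.weights, roster, label)
        np.fill_diagonal(mask, 0.0)
        out[label] = mask
    return out


@dataclass
class OadaSpec:
    """One model of the enumerated set.

    ``network_class``: 'asocial' (no transmission), 'homogeneous', or
    'observed'.  ``by_age`` / ``by_relation`` split s by demonstrator class.
    ``ilv``: species enters the asocial rate, the social rate, 'both'
    (separate coefficients), 'equal' (one shared coefficient), or 'none'.
    """

    network_class: str = "observed"
    by_age: bool = False
    by_relation: bool = False
    ilv: str = "none"

    def __post_init__(self):
        if self.network_class not in ("asocial", "homogeneous", "observed"):
            raise SpecificationError(
                f"unknown network class {self.network_class!r}")
        if self.ilv not in ("none", "asocial", "social", "both", "equal"):
            raise SpecificationError(f"unknown ilv placement {self.ilv!r}")
        if self.network_class == "asocial" and self.ilv in ("social", "both",
                                                            "equal"):
            raise SpecificationError(
                "asocial-only models cannot carry a social ILV")

    @property
    def label(self) -> str:
        if self.network_class == "asocial":
            return f"asocial|ilv={self.ilv}"
        parts = [self.network_class,
                 "age=diff" if self.by_age else "age=same",
                 "rel=diff" if self.by_relation else "rel=same",
                 f"ilv={self.ilv}"]
        return "|".join(parts)

    def network_labels(self) -> list[str]:
        if self.network_class == "asocial":
            return []
        age_parts = ["adult", "juvenile"] if self.by_age else ["all"]
        rel_parts = (["conspecific", "heterospecific"]
                     if self.by_relation else ["all"])
        return ["_".join(p for p in (ag, rel) if p != "all") or "all"
                for ag, rel in itertools.product(age_parts, rel_parts)]


class _Prepared:
    """Per-event connection sums and risk-set masks, precomputed once."""

    def __init__(self, data: AcquisitionData, networks: dict[str, np.ndarray]):
        ids = list(data.roster["bird_id"])
        index = {b: i for i, b in enumerate(ids)}
        n = len(ids)
        K = data.n_events
        self.x = (data.roster["species"].to_numpy() == "B").astype(float)
        self.acq = np.array([index[b] for b in data.order], dtype=int)
        self.labels = list(networks)
        M = len(self.labels)
        self.C = np.zeros((K, n, M))
        self.naive = np.zeros((K, n), dtype=bool)
        informed = np.zeros(n, dtype=bool)
        for b in data.seeds:
            informed[index[b]] = True
        z = informed.astype(float)
        mats = [networks[lab] for lab in self.labels]
        for k in range(K):
            self.naive[k] = ~informed
            for m, a in enumerate(mats):
                self.C[k, :, m] = a @ z
            i = self.acq[k]
            if informed[i]:
                raise InvalidArgumentError(
                    f"bird {data.order[k]!r} acquires twice")
            informed[i] = True
            z[i] = 1.0
        if not self.naive.any(axis=1).all():
            raise InvalidArgumentError("empty risk set")


def _rates(prep: _Prepared, s: np.ndarray, beta_a: float, beta_s: float):
    A = np.exp(beta_a * prep.x)[None, :]
    S = np.exp(beta_s * prep.x)[None, :]
    conn = prep.C @ s if s.size else np.zeros(prep.naive.shape)
    return A + S * conn


def oada_loglik(
    data: AcquisitionData,
    networks: dict[str, np.ndarray],
    s: np.ndarray | list | dict,
    beta_asocial: float = 0.0,
    beta_social: float = 0.0,
    _prepared: _Prepared | None = None,
) -> float:
    """Order likelihood: sum_k log(R_acquirer / sum_naive R_i).

    With all ``s`` zero and no ILVs this is the exchangeable-order value
    ``sum_k log(1 / |risk set_k|)``.
    """
    prep = _prepared or _Prepared(data, networks)
    if isinstance(s, dict):
        s = np.array([s[lab] for lab in prep.labels], dtype=float)
    else:
        s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise InvalidArgumentError("transmission rates s must be >= 0")
    R = _rates(prep, s, beta_asocial, beta_social)
    R = np.where(prep.naive, R, 0.0)
    totals = R.sum(axis=1)
    picked = R[np.arange(len(prep.acq)), prep.acq]
    if np.any(picked <= 0) or np.any(totals <= 0):
        return -np.inf
    return float(np.sum(np.log(picked) - np.log(totals)))


@dataclass
class OadaModel:
    """A fitted diffusion model: s per network, ILV effects, AICc."""

    spec: OadaSpec
    s: dict[str, float]
    beta_asocial: float
    beta_social: float
    loglik: float
    n_events: int
    data: AcquisitionData
    networks: dict[str, np.ndarray]
    boundary: dict[str, bool] = field(default_factory=dict)

    @property
    def k(self) -> int:
        k = len(self.s)
        if self.spec.ilv in ("asocial", "social", "equal"):
            k += 1
        elif self.spec.ilv == "both":
            k += 2
        return k

    @property
    def aicc(self) -> float:
        n, k = self.n_events, max(self.k, 1)
        if n - k - 1 <= 0:
            return math.inf
        return -2.0 * self.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)

    def to_dict(self) -> dict:
        return {"label": self.spec.label, "s": dict(self.s),
                "beta_asocial": self.beta_asocial,
                "beta_social": self.beta_social, "loglik": self.loglik,
                "k": self.k, "AICc": self.aicc,
                "boundary": dict(self.boundary)}


def _pack(spec: OadaSpec, n_networks: int):
    """Parameter layout: [s_1..s_M, ilv params]."""
    names = [f"s:{i}" for i in range(n_networks)]
    if spec.ilv in ("asocial", "social", "equal"):
        names.append("beta")
    elif spec.ilv == "both":
        names += ["beta_a", "beta_s"]
    return names


def _unpack(theta, spec: OadaSpec, M: int):
    s = np.asarray(theta[:M], dtype=float)
    rest = theta[M:]
    if spec.ilv == "none":
        return s, 0.0, 0.0
    if spec.ilv == "asocial":
        return s, float(rest[0]), 0.0
    if spec.ilv == "social":
        return s, 0.0, float(rest[0])
    if spec.ilv == "equal":
        return s, float(rest[0]), float(rest[0])
    return s, float(rest[0]), float(rest[1])


def fit_oada(
    data: AcquisitionData,
    spec: OadaSpec,
    network: AssociationMatrix | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> OadaModel:
    """Box-constrained MLE (s >= 0) with seeded multi-start."""
    if spec.network_class == "asocial":
        networks = {}
    else:
        if network is None:
            raise SpecificationError("social models need the base network")
        networks = transmission_networks(
            network, data.roster, by_age=spec.by_age,
            by_relation=spec.by_relation,
            homogeneous=spec.network_class == "homogeneous")
    prep = _Prepared(data, networks) if networks else _Prepared(data, {})
    M = len(networks)
    names = _pack(spec, M)
    n_par = len(names)

    def nll(theta):
        s, ba, bs = _unpack(theta, spec, M)
        ll = oada_loglik(data, networks, s, ba, bs, _prepared=prep)
        return -ll if np.isfinite(ll) else 1e12

    if n_par == 0:
        ll = oada_loglik(data, networks, np.zeros(0), 0.0, 0.0, _prepared=prep)
        return OadaModel(spec=spec, s={}, beta_asocial=0.0, beta_social=0.0,
                        loglik=ll, n_events=data.n_events, data=data,
                        networks=networks)

    bounds = [(0.0, None)] * M + [(-10.0, 10.0)] * (n_par - M)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(n_starts, 1)):
        x0 = np.zeros(n_par)
        if r > 0:
            x0[:M] = rng.exponential(2.0, size=M)
            x0[M:] = rng.normal(0.0, 1.0, size=n_par - M)
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-10})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"OADA fit failed at all {n_starts} starts "
                       f"for model {spec.label!r}")
    s, ba, bs = _unpack(best.x, spec, M)
    labels = prep.labels
    s_dict = {lab: float(v) for lab, v in zip(labels, s)}
    boundary = {lab: bool(v < 1e-6) for lab, v in s_dict.items()}
    return OadaModel(spec=spec, s=s_dict, beta_asocial=ba, beta_social=bs,
                     loglik=-float(best.fun), n_events=data.n_events,
                     data=data, networks=networks, boundary=boundary)


def _profile_nll(model: OadaModel, label: str, value: float) -> float:
    """Max log-likelihood with s_label fixed; other params re-optimised."""
    spec = model.spec
    prep = _Prepared(model.data, model.networks)
    labels = prep.labels
    M = len(labels)
    fixed = labels.index(label)
    free_s = [m for m in range(M) if m != fixed]
    n_ilv = model.k - M

    def nll(theta):
        s = np.zeros(M)
        s[fixed] = value
        for t, m in zip(theta[:len(free_s)], free_s):
            s[m] = t
        rest = theta[len(free_s):]
        full = np.concatenate([s, rest])
        sv, ba, bs = _unpack(full, spec, M)
        ll = oada_loglik(model.data, model.networks, sv, ba, bs,
                         _prepared=prep)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.array([model.s[labels[m]] for m in free_s]
                  + ([model.beta_asocial] if spec.ilv in ("asocial", "equal")
                     else [])
                  + ([model.beta_social] if spec.ilv == "social" else [])
                  + ([model.beta_asocial, model.beta_social]
                     if spec.ilv == "both" else []))
    if x0.size == 0:
        return nll(np.zeros(0)), np.zeros(0)
    bounds = ([(0.0, None)] * len(free_s)
              + [(-10.0, 10.0)] * (x0.size - len(free_s)))
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-10})
    return float(res.fun), res.x


def profile_ci(model: OadaModel, param: str, level: float = 0.95,
               s_max: float = 1e4) -> tuple[float, float]:
    """Profile-likelihood interval for a transmission rate s.

    The interval is {s : 2[l(hat) - l_profile(s)] <= chi2_1(level)},
    bracketed by bisection; the lower bound may sit on the 0 boundary.
    """
    if param not in model.s:
        raise SpecificationError(f"no transmission parameter {param!r}")
    crit = chi2.ppf(level, df=1) / 2.0
    ll_hat = model.loglik
    s_hat = model.s[param]

    def deficit(v):
        nll, _ = _profile_nll(model, param, v)
        return (-nll) - ll_hat + crit  # >0 inside the interval

    # lower bound
    if deficit(0.0) >= 0:
        lo = 0.0
    else:
        lo = _bisect(deficit, 0.0, s_hat, increasing=True)
    # upper bound: expand a bracket beyond s_hat
    hi_bracket = max(s_hat * 2.0, 1.0)
    while deficit(hi_bracket) > 0 and hi_bracket < s_max:
        hi_bracket *= 2.0
    if hi_bracket >= s_max and deficit(hi_bracket) > 0:
        hi = math.inf
    else:
        hi = _bisect(deficit, max(s_hat, 1e-8), hi_bracket, increasing=False)
    return lo, hi


def _bisect(f, a, b, increasing, tol=1e-4, max_iter=80):
    fa, fb = f(a), f(b)
    if fa == 0:
        return a
    if fb == 0:
        return b
    if (fa > 0) == (fb > 0):
        raise FitError("profile deficit does not change sign on the bracket")
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        fm = f(mid)
        if abs(b - a) < tol * max(1.0, abs(mid)):
            return mid
        if (fm > 0) == (fa > 0):
            a, fa = mid, fm
        else:
            b, fb = mid, fm
    return 0.5 * (a + b)


def percent_social(model: OadaModel,
                   ci: bool = False, level: float = 0.95) -> dict:
    """%ST per network: mean per-event social share of the acquirer's rate.

    With ``ci=True`` the share is recomputed at the profile-CI endpoints of
    each s (other parameters re-profiled), giving an interval.
    """
    out = {}
    for lab in model.s:
        est = _percent_for(model, {**model.s}, model.beta_asocial,
                           model.beta_social)[lab]
        if not ci:
            out[lab] = {"percent": est}
            continue
        lo_s, hi_s = profile_ci(model, lab, level=level)
        bounds = []
        for v in (lo_s, hi_s):
            if not np.isfinite(v):
                bounds.append(100.0)
                continue
            _, x = _profile_nll(model, lab, v)
            s_prof = dict(model.s)
            prep_labels = list(model.networks)
            free = [m for m in prep_labels if m != lab]
            for name, m in zip(x[:len(free)], free):
                s_prof[m] = float(name)
            s_prof[lab] = v
            rest = x[len(free):]
            M = len(prep_labels)
            full = np.concatenate(
                [[s_prof[m] for m in prep_labels], rest])
            sv, ba, bs = _unpack(full, model.spec, M)
            bounds.append(_percent_for(model, dict(zip(prep_labels, sv)),
                                       ba, bs)[lab])
        out[lab] = {"percent": est, "ci": (min(bounds), max(bounds)),
                    "s_ci": (lo_s, hi_s)}
    return out


def _percent_for(model: OadaModel, s: dict, ba: float, bs: float) -> dict:
    prep = _Prepared(model.data, model.networks)
    sv = np.array([s[lab] for lab in prep.labels])
    R = _rates(prep, sv, ba, bs)
    K = len(prep.acq)
    idx = np.arange(K)
    denom = R[idx, prep.acq]
    soc_mult = np.exp(bs * prep.x)[prep.acq]
    out = {}
    for m, lab in enumerate(prep.labels):
        contrib = sv[m] * soc_mult * prep.C[idx, prep.acq, m]
        out[lab] = float(100.0 * np.mean(contrib / denom))
    return out


def default_model_set() -> list[OadaSpec]:
    """The standard comparison set: asocial-only, homogeneous- and
    observed-network transmission, crossed with demonstrator-age and
    species-relation rate splits and species ILV placements."""
    specs = [OadaSpec(network_class="asocial", ilv=ilv)
             for ilv in ("none", "asocial")]
    for net in ("homogeneous", "observed"):
        for by_age in (False, True):
            for by_rel in (False, True):
                for ilv in ("none", "asocial", "social", "both", "equal"):
                    specs.append(OadaSpec(network_class=net, by_age=by_age,
                                          by_relation=by_rel, ilv=ilv))
    return specs


def model_set_report(fits: list[OadaModel]) -> pd.DataFrame:
    """AICc comparison: dAICc, Akaike weights, summed weights by class."""
    if len(fits) < 2:
        raise InvalidArgumentError("need at least 2 fitted models")
    rows = []
    for f in fits:
        rows.append({"label": f.spec.label,
                     "network_class": f.spec.network_class,
                     "k": f.k, "loglik": f.loglik, "AICc": f.aicc,
                     "s": "; ".join(f"{lab}={v:.3g}"
                                    for lab, v in f.s.items())})
    tab = pd.DataFrame(rows).sort_values("AICc", kind="mergesort")
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    w = np.exp(-0.5 * tab["dAICc"].to_numpy())
    tab["weight"] = w / w.sum()
    class_w = tab.groupby("network_class")["weight"].sum()
    tab.attrs["class_weights"] = class_w.to_dict()
    return tab.reset_index(drop=True)
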