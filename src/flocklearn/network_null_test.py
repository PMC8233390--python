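"""Simulation null for whether a social effect follows the observed network.

A significant coefficient on a network-weighted observation covariate could
arise even if social learning is homogeneous — every bird equally likely to
observe every feed.  The test keeps the observed visit skeleton (who visited
when) fixed and re-simulates the outcomes: choices are drawn from the fitted
model, but the observation covariates evolve under the *homogenized* network
(each demonstrator's column replaced by its mean, total expected audience
preserved).  Each replicate is refitted with covariates rebuilt from the
*observed* network, and the Wald Z of the target coefficient recorded.  The
simulation p-value is the proportion of replicates at least as far from the
null-distribution mean as the observed Z (distance in either direction):

    p_s = #{ |Z_sim - mean(Z_sim)| >= |Z_obs - mean(Z_sim)| } / n_sims

Small p_s means the observed-network covariate predicts choices better than
homogeneous social learning can explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import glmm
from .association_network import AssociationMatrix, homogenize
from .choice_models import ModelFit, fit_choice_model
from .exposure_covariates import RunningCovariates, build_choice_table
from .exceptions import ReliabilityError, SpecificationError

__all__ = ["NullDistribution", "simulate_null_dataset", "network_effect_test"]

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Null distribution of a coefficient's Z under homogenized learning."""

    coefficient: str
    z_obs: float
    z_sims: np.ndarray
    n_dropped: int = 0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.z_sims))

    @property
    def p_s(self) -> float:
        d = np.abs(self.z_sims - self.null_mean)
        return float(np.mean(d >= abs(self.z_obs - self.null_mean) - 1e-12))

    def to_dict(self) -> dict:
        return {"coefficient": self.coefficient, "z_obs": self.z_obs,
                "null_mean": self.null_mean, "p_s": self.p_s,
                "n_sims": int(len(self.z_sims)),
                "n_dropped": int(self.n_dropped),
                "z_sims": [float(z) for z in self.z_sims]}


def _original_coefs(fit: ModelFit) -> dict:
    coefs = fit.coef_original
    needed = ["(Intercept)"] + fit.spec.terms
    missing = [t for t in needed
               if t not in coefs and t not in fit.fit.dropped]
    if missing:
        raise SpecificationError(f"fit lacks required coefficients {missing}")
    return {t: coefs.get(t, 0.0) for t in needed}


def _tie_batches(times: np.ndarray) -> list[tuple[int, int]]:
    batches = []
    k, n = 0, len(times)
    while k < n:
        k_end = k + 1
        while k_end < n and times[k_end] == times[k]:
            k_end += 1
        batches.append((k, k_end))
        k = k_end
    return batches


def simulate_null_dataset(
    fit: ModelFit,
    visits: pd.DataFrame,
    homogenized_network: AssociationMatrix,
    roster: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Counterfactual choice table under homogenized social learning.

    Walks the observed visit skeleton in time order; covariates are computed
    from *simulated* prior outcomes under the homogenized network, and each
    outcome is drawn from the fitted model with a fresh per-bird random
    intercept drawn from the estimated intercept SD.
    """
    coefs = _original_coefs(fit)
    visits = visits.sort_values("time", kind="mergesort").reset_index(drop=True)
    engine = RunningCovariates(homogenized_network, roster)
    birds = visits["bird_id"].to_numpy()
    times = visits["time"].to_numpy(dtype=float)
    ids = list(homogenized_network.birds)
    B = dict(zip(ids, rng.normal(0.0, fit.sigma_b, size=len(ids))))

    rows = []
    for k, k_end in _tie_batches(times):
        batch = []
        for r in range(k, k_end):
            row = engine.row(birds[r])
            eta = coefs["(Intercept)"] + B[birds[r]]
            for term in fit.spec.terms:
                eta += coefs[term] * row[term]
            choice = int(rng.random() < expit(eta))
            row["bird_id"] = birds[r]
            row["time"] = times[r]
            row["chose_unpalatable"] = choice
            batch.append(row)
            rows.append(row)
        for row in batch:
            engine.update(row["bird_id"], row["chose_unpalatable"])
    table = pd.DataFrame(rows)
    lookup = roster.set_index("bird_id")
    table["species"] = lookup.loc[table["bird_id"], "species"].to_numpy()
    table["age"] = lookup.loc[table["bird_id"], "age"].to_numpy()
    return table


def _fast_applicable(fit: ModelFit) -> bool:
    return set(fit.spec.terms) <= {"N_plus", "N_minus", "O_plus", "O_minus"}


class _FastNull:
    """Scalar-state replicate engine for pooled-O model specifications.

    The homogenized network is column-constant off the diagonal, so the
    expected-observation covariate of bird i is a running scalar sum minus
    the bird's own contribution; one replicate is a single pass of cheap
    scalar updates followed by a warm-started fixed-node quadrature refit.
    """

    def __init__(self, fit, visits, network, homogenized, coefficient):
        self.fit = fit
        self.terms = fit.spec.terms
        self.coefs = _original_coefs(fit)
        self.sigma_b = fit.sigma_b
        self.coefficient = coefficient
        self.net = network
        visits = visits.sort_values("time", kind="mergesort")
        self.bird_ids = visits["bird_id"].to_numpy()
        self.times = visits["time"].to_numpy(dtype=float)
        ids = list(network.birds)
        index = {b: i for i, b in enumerate(ids)}
        self.b_idx = np.array([index[b] for b in self.bird_ids])
        self.n_birds = len(ids)
        self.batches = _tie_batches(self.times)
        # off-diagonal column constant of the homogenized network
        w = homogenized.weights
        n = w.shape[0]
        self.c = np.array([w[(j + 1) % n, j] for j in range(n)])
        self.a_obs = network.weights
        # refit plumbing: groups sorted once, warm start from the outer fit
        self.col_order = ["(Intercept)"] + self.terms
        self.coef_pos = self.col_order.index(coefficient)
        self.warm = np.append(self.fit.fit.beta, self.fit.sigma_b)

    def replicate(self, rng, n_quad=21):
        nb = self.n_birds
        Np = np.zeros(nb)
        Nm = np.zeros(nb)
        Sp = 0.0
        Sm = 0.0
        B = rng.normal(0.0, self.sigma_b, size=nb)
        coefs = self.coefs
        a = coefs["(Intercept)"]
        bNp = coefs.get("N_plus", 0.0)
        bNm = coefs.get("N_minus", 0.0)
        bOp = coefs.get("O_plus", 0.0)
        bOm = coefs.get("O_minus", 0.0)
        use_Op = "O_plus" in self.terms
        use_Om = "O_minus" in self.terms

        nv = len(self.b_idx)
        y = np.zeros(nv)
        Ob_p = np.zeros(nb)   # pooled O under the observed network
        Ob_m = np.zeros(nb)
        Xp = np.zeros(nv)
        Xm = np.zeros(nv)
        XNp = np.zeros(nv)
        XNm = np.zeros(nv)
        u = rng.random(nv)
        c = self.c
        for k, k_end in self.batches:
            for r in range(k, k_end):
                i = self.b_idx[r]
                Op_i = Sp - c[i] * Np[i]
                Om_i = Sm - c[i] * Nm[i]
                eta = a + bNp * Np[i] + bNm * Nm[i] + B[i]
                if use_Op:
                    eta += bOp * Op_i
                if use_Om:
                    eta += bOm * Om_i
                y[r] = 1.0 if u[r] < 1.0 / (1.0 + np.exp(-eta)) else 0.0
                XNp[r] = Np[i]
                XNm[r] = Nm[i]
                Xp[r] = Ob_p[i]
                Xm[r] = Ob_m[i]
            for r in range(k, k_end):
                i = self.b_idx[r]
                if y[r]:
                    Nm[i] += 1.0
                    Sm += c[i]
                    Ob_m += self.a_obs[:, i]
                else:
                    Np[i] += 1.0
                    Sp += c[i]
                    Ob_p += self.a_obs[:, i]

        col_data = {"N_plus": XNp, "N_minus": XNm,
                    "O_plus": Xp, "O_minus": Xm}
        cols = [np.ones(nv)]
        for t in self.terms:
            x = col_data[t]
            if self.fit.spec.standardize:
                sd = x.std()
                if sd > 0:
                    x = (x - x.mean()) / sd
            cols.append(x)
        X = np.column_stack(cols)
        f = glmm.fit_binomial_glmm(
            X, y, self.b_idx, names=self.col_order, method="gh",
            n_quad=n_quad, start=self.warm)
        if not f.converged or self.coefficient not in f.names:
            return None
        j = f.names.index(self.coefficient)
        if not np.isfinite(f.se[j]) or f.se[j] <= 0:
            return None
        return f.beta[j] / f.se[j]


def network_effect_test(
    fit: ModelFit,
    visits: pd.DataFrame,
    network: AssociationMatrix,
    roster: pd.DataFrame,
    coefficient: str,
    n_sims: int = 1000,
    seed: int = 0,
    homogenized: AssociationMatrix | None = None,
    n_quad: int = 21,
    progress: bool = False,
) -> NullDistribution:
    """Distance-from-mean simulation p-value for a social coefficient.

    Each replicate simulates the choice outcomes under homogenized social
    learning (fitted effect sizes, fresh random intercepts), rebuilds the
    covariates with the observed network, refits the same model
    specification, and records the coefficient's Wald Z.  Non-converged
    replicates are dropped and counted; more than 20% dropped is an error.
    """
    if coefficient not in fit.fit.names:
        raise SpecificationError(f"coefficient {coefficient!r} not in fit")
    z_obs = fit.zvalue(coefficient)
    if homogenized is None:
        homogenized = homogenize(network)
    rng = np.random.default_rng(seed)

    z_sims: list[float] = []
    n_dropped = 0
    if _fast_applicable(fit):
        engine = _FastNull(fit, visits, network, homogenized, coefficient)
        for b in range(n_sims):
            z = engine.replicate(rng, n_quad=n_quad)
            if z is None:
                n_dropped += 1
            else:
                z_sims.append(z)
            if progress and (b + 1) % 100 == 0:
                logger.info("null replicate %d/%d (dropped %d)",
                            b + 1, n_sims, n_dropped)
    else:
        for b in range(n_sims):
            sim = simulate_null_dataset(fit, visits, homogenized, roster, rng)
            sim_visits = visits.sort_values(
                "time", kind="mergesort").reset_index(drop=True).copy()
            sim_visits["palatable"] = 1 - sim["chose_unpalatable"].to_numpy()
            table = build_choice_table(sim_visits, network, roster)
            refit = fit_choice_model(
                table, fit.spec, method="gh", n_quad=n_quad,
                start=np.append(fit.fit.beta, fit.sigma_b))
            ok = (refit.fit.converged and coefficient in refit.fit.names
                  and np.isfinite(refit.coef.loc[coefficient, "se"]))
            if ok:
                z_sims.append(refit.zvalue(coefficient))
            else:
                n_dropped += 1
            if progress and (b + 1) % 50 == 0:
                logger.info("null replicate %d/%d (dropped %d)",
                            b + 1, n_sims, n_dropped)

    if n_dropped > 0.2 * n_sims:
        raise ReliabilityError(
            f"{n_dropped}/{n_sims} null replicates failed to converge")
    return NullDistribution(coefficient=coefficient, z_obs=z_obs,
                            z_sims=np.asarray(z_sims), n_dropped=n_dropped)
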