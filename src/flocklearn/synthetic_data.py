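"""Generative models for RFID-style feeder-visit streams with known ground truth.

The generator emulates the statistical structure that the analysis pipeline
assumes: a wild colony of two species (labelled ``A`` and ``B``, e.g. blue
tits and great tits) with adults and juveniles, organised in overlapping
flocks.  Flock co-membership induces heterogeneous pairwise association:
each gathering event at a feeding station is attended by one flock's members,
independently thinned, so the probability that two birds attend the same
event has a closed form and serves as the *true* association network.

Three streams can be produced:

* a pre-training stream of visits to plain (uncoloured) food, used by the
  pipeline to detect gathering events and estimate the association network;
* an avoidance-learning stream in which every visit is a binary colour
  choice generated by a logistic model on the bird's own prior experience
  (N+, N-) and its latent observed feeds of others (R+, R-), the generative
  mirror of the per-choice social/asocial model the pipeline fits;
* a reversal-phase diffusion of first visits to a target colour generated by
  a network-based hazard with known social-transmission rates, the
  generative mirror of the order-of-acquisition diffusion model.

The latent observation process: when bird ``j`` feeds, every other bird
``i``'s counter R increments by the network weight ``a_ij``, included
independently with probability ``p_o``.  Hence ``E(R) = p_o * O`` where
``O`` is the network-weighted expected-observation covariate the pipeline
computes, and at ``p_o = 1`` the two are identical on every choice row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, StalledDiffusionError

__all__ = [
    "SimConfig",
    "simulate_population",
    "simulate_pretraining_stream",
    "simulate_avoidance_stream",
    "simulate_reversal_diffusion",
    "ReversalDiffusion",
]

#: seconds in one observation day
DAY_SECONDS = 86_400.0

#: epoch for converting float seconds to ISO timestamps (start of field season)
EPOCH = pd.Timestamp("2018-06-01 00:00:00")


@dataclass
class SimConfig:
    """Parameters of the synthetic colony and of all three generative streams.

    Logit-scale coefficients (``alpha`` .. ``beta_soc_minus``) parameterise
    the probability of choosing the unpalatable colour; negative social/
    asocial coefficients produce avoidance learning.  ``s_true`` maps
    transmission-network labels (``"adult"``, ``"juvenile"``,
    ``"conspecific"``, ``"heterospecific"``, ``"all"``) to per-unit-connection
    social transmission rates for the reversal diffusion.
    """

    n_birds: int = 60
    prop_juvenile: float = 0.75
    prop_species_a: float = 0.4
    n_flocks: int = 4
    flock_membership_overlap: float = 0.15
    attendance_prob: float = 0.8
    n_stations: int = 3
    n_days: int = 8
    n_days_pretraining: int = 10
    events_per_station_day: float = 6.0
    event_duration: float = 300.0
    visits_per_bird_event: float = 2.0
    activity_sd: float = 0.6
    p_o: float = 1.0
    alpha: float = -0.5
    beta_asoc_plus: float = -0.10
    beta_asoc_minus: float = -0.15
    beta_soc_plus: float = 0.0
    beta_soc_minus: float = -0.05
    random_intercept_sd: float = 0.25
    colour_pair: tuple[str, str] = ("yellow", "orange")  # (unpalatable, palatable)
    s_true: Mapping[str, float] = field(
        default_factory=lambda: {"adult": 10.0, "juvenile": 0.0}
    )
    oada_beta_asocial: float = 0.0
    oada_beta_social: float = 0.0
    asocial_base_rate: float = 1.0
    reversal_days: int = 9
    n_seed_demonstrators: int = 0
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "prop_juvenile": self.prop_juvenile,
            "prop_species_a": self.prop_species_a,
            "flock_membership_overlap": self.flock_membership_overlap,
            "attendance_prob": self.attendance_prob,
            "p_o": self.p_o,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} must lie in [0, 1]")
        if self.n_birds < 2:
            raise InvalidConfigError("n_birds must be at least 2")
        if self.n_flocks < 1:
            raise InvalidConfigError("n_flocks must be at least 1")
        if self.n_flocks > self.n_birds:
            raise InvalidConfigError(
                f"n_flocks={self.n_flocks} exceeds n_birds={self.n_birds}"
            )
        for name in ("events_per_station_day", "event_duration",
                     "visits_per_bird_event", "asocial_base_rate"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if self.event_duration <= 0:
            raise InvalidConfigError("event_duration must be positive")
        if self.random_intercept_sd < 0:
            raise InvalidConfigError("random_intercept_sd must be non-negative")
        if self.activity_sd < 0:
            raise InvalidConfigError("activity_sd must be non-negative")
        if any(s < 0 for s in self.s_true.values()):
            raise InvalidConfigError("all s_true rates must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["colour_pair"] = list(self.colour_pair)
        d["s_true"] = dict(self.s_true)
        return d


def _bird_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"B{idx:0{width}d}" for idx in range(1, n + 1)]


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a roster and the closed-form true association network.

    Every bird gets one primary flock (cycled so that no flock is empty) and
    joins each remaining flock independently with probability
    ``flock_membership_overlap``.  An event is hosted by one uniformly chosen
    flock and each member attends independently with ``attendance_prob``, so
    the probability that birds *i* and *j* attend the same event is
    ``q_ij = (|F_i ∩ F_j| / n_flocks) * attendance_prob**2``.  The network
    weight is the probability that the pair is together *at a sampled
    gathering*, i.e. conditional on at least one of them being seen::

        a_ij = q_ij / (p_i + p_j - q_ij),   p_i = (|F_i| / n_flocks) * attendance_prob

    which is exactly the quantity the simple ratio index estimates, so the
    empirical SRI converges to this matrix under dense sampling.

    Returns
    -------
    roster : DataFrame with columns ``bird_id, species, age, flocks,
        activity`` (``flocks`` is a semicolon-joined list of flock indices).
    true_network : (n, n) symmetric float array with zero diagonal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_birds
    ids = _bird_ids(n)

    species = np.where(rng.random(n) < config.prop_species_a, "A", "B")
    age = np.where(rng.random(n) < config.prop_juvenile, "juvenile", "adult")
    # guarantee both age classes and both species are represented
    if (age == "adult").sum() == 0:
        age[rng.integers(n)] = "adult"
    if (age == "juvenile").sum() == 0:
        age[rng.integers(n)] = "juvenile"
    if (species == "A").sum() == 0:
        species[rng.integers(n)] = "A"
    if (species == "B").sum() == 0:
        species[rng.integers(n)] = "B"

    membership = np.zeros((n, config.n_flocks), dtype=bool)
    primary = rng.permutation(n) % config.n_flocks
    membership[np.arange(n), primary] = True
    extra = rng.random((n, config.n_flocks)) < config.flock_membership_overlap
    membership |= extra

    shared = (membership.astype(float) @ membership.T.astype(float))
    q = shared / config.n_flocks * config.attendance_prob ** 2
    p_seen = membership.sum(axis=1) / config.n_flocks * config.attendance_prob
    denom = p_seen[:, None] + p_seen[None, :] - q
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, q / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(a, 0.0)

    flocks = [";".join(str(f) for f in np.flatnonzero(membership[i]))
              for i in range(n)]
    # per-bird activity multiplier (mean-1 lognormal): real colonies show
    # order-of-magnitude variation in visit counts between individuals
    activity = np.exp(rng.normal(-config.activity_sd ** 2 / 2.0,
                                 config.activity_sd, size=n))
    roster = pd.DataFrame(
        {"bird_id": ids, "species": species, "age": age, "flocks": flocks,
         "activity": np.round(activity, 6)}
    )
    roster.attrs["membership"] = membership
    return roster, a


def _schedule_events(config: SimConfig, rng: np.random.Generator,
                     n_days: int, day_offset: int) -> list[dict]:
    """Poisson number of events per station-day, starts uniform within day."""
    events = []
    for day in range(n_days):
        for station in range(1, config.n_stations + 1):
            k = rng.poisson(config.events_per_station_day)
            starts = rng.uniform(
                0.0, DAY_SECONDS - config.event_duration, size=k)
            for t0 in np.sort(starts):
                events.append({
                    "station": f"S{station}",
                    "day": day + day_offset,
                    "t_start": (day + day_offset) * DAY_SECONDS + t0,
                })
    events.sort(key=lambda e: e["t_start"])
    return events


def _draw_attendees(config: SimConfig, rng: np.random.Generator,
                    membership: np.ndarray) -> np.ndarray:
    flock = rng.integers(membership.shape[1])
    members = np.flatnonzero(membership[:, flock])
    attend = members[rng.random(members.size) < config.attendance_prob]
    return attend


def _visit_times(config: SimConfig, rng: np.random.Generator,
                 t0: float, n_visits: int) -> np.ndarray:
    """Visit times within a gathering event: a Gaussian burst around the
    event midpoint with SD = duration/4 (flocks arrive and depart together,
    with activity peaking mid-event)."""
    mid = t0 + 0.5 * config.event_duration
    return np.sort(rng.normal(mid, config.event_duration / 4.0,
                              size=n_visits))


def _dejitter(visits: pd.DataFrame) -> pd.DataFrame:
    """Sort globally and enforce strictly increasing times within bird."""
    visits = visits.sort_values("time", kind="mergesort").reset_index(drop=True)
    # tiny per-bird jitter so sequential covariates never see ties within bird
    t = visits["time"].to_numpy().copy()
    for _, idx in visits.groupby("bird_id").indices.items():
        tt = t[idx]
        for k in range(1, len(tt)):
            if tt[k] <= tt[k - 1]:
                tt[k] = tt[k - 1] + 1e-3
        t[idx] = tt
    visits["time"] = t
    return visits.sort_values("time", kind="mergesort").reset_index(drop=True)


def _finalise(visits: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    lookup = roster.set_index("bird_id")
    visits = visits.copy()
    visits["species"] = lookup.loc[visits["bird_id"], "species"].to_numpy()
    visits["age"] = lookup.loc[visits["bird_id"], "age"].to_numpy()
    visits["timestamp"] = EPOCH + pd.to_timedelta(visits["time"], unit="s")
    cols = ["bird_id", "species", "age", "station", "feeder_side", "colour",
            "palatable", "timestamp", "phase", "time"]
    return visits[cols]


def simulate_pretraining_stream(
    roster: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Visits to plain food used for event detection and network estimation.

    Returns the visit table and a latent event log (one row per visit with
    its true event id) for oracle checks of the event detector.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    membership = roster.attrs["membership"]
    ids = roster["bird_id"].to_numpy()
    act = roster["activity"].to_numpy() if "activity" in roster else np.ones(len(ids))
    rows = []
    for eid, ev in enumerate(_schedule_events(config, rng,
                                              config.n_days_pretraining, 0)):
        attendees = _draw_attendees(config, rng, membership)
        for b in attendees:
            nv = rng.poisson(config.visits_per_bird_event * act[b])
            for tv in _visit_times(config, rng, ev["t_start"], nv):
                rows.append((ids[b], ev["station"], tv, eid))
    if not rows:
        empty = pd.DataFrame(columns=["bird_id", "station", "time", "event_id"])
        return _finalise(empty.assign(feeder_side="left", colour="plain",
                                      palatable=1, phase="pretraining"),
                         roster), empty
    visits = pd.DataFrame(rows, columns=["bird_id", "station", "time", "event_id"])
    visits["feeder_side"] = "left"
    visits["colour"] = "plain"
    visits["palatable"] = 1
    visits["phase"] = "pretraining"
    visits = _dejitter(visits)
    latent = visits[["bird_id", "station", "time", "event_id"]].copy()
    return _finalise(visits, roster), latent


def simulate_avoidance_stream(
    roster: pd.DataFrame,
    true_network: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Avoidance-phase visit stream with per-visit binary colour choices.

    Choice probability of the unpalatable colour on each visit is
    ``expit(alpha + b_asoc+ N+ + b_asoc- N- + b_soc+ R+ + b_soc- R- + B_i)``
    where N± are the bird's own running counts and R± its latent observed
    feeds of others (network-weighted, thinned with probability ``p_o``).

    Returns
    -------
    visits : DataFrame in the standard visit-table schema.
    latent : dict with keys ``rows`` (per-choice DataFrame of true covariates
        and choice probability), ``intercepts`` (per-bird B_i), ``event_ids``,
        and ``config``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    membership = roster.attrs["membership"]
    ids = roster["bird_id"].to_numpy()
    n = len(ids)
    act = roster["activity"].to_numpy() if "activity" in roster else np.ones(n)
    unpal_colour, pal_colour = config.colour_pair
    day0 = config.n_days_pretraining

    # schedule all (event, attendee, visit-time) triples, then walk in time order
    sched = []
    for eid, ev in enumerate(_schedule_events(config, rng, config.n_days, day0)):
        attendees = _draw_attendees(config, rng, membership)
        for b in attendees:
            nv = rng.poisson(config.visits_per_bird_event * act[b])
            for tv in _visit_times(config, rng, ev["t_start"], nv):
                sched.append((tv, b, ev["station"], eid))
    sched.sort()
    # strictly increasing within bird
    last_t = np.full(n, -np.inf)
    sched2 = []
    for tv, b, st, eid in sched:
        if tv <= last_t[b]:
            tv = last_t[b] + 1e-3
        last_t[b] = tv
        sched2.append((tv, b, st, eid))
    sched2.sort()

    B = rng.normal(0.0, config.random_intercept_sd, size=n)
    N_plus = np.zeros(n)
    N_minus = np.zeros(n)
    R_plus = np.zeros(n)
    R_minus = np.zeros(n)

    from scipy.special import expit

    vrows, lrows = [], []
    for tv, b, st, eid in sched2:
        eta = (config.alpha
               + config.beta_asoc_plus * N_plus[b]
               + config.beta_asoc_minus * N_minus[b]
               + config.beta_soc_plus * R_plus[b]
               + config.beta_soc_minus * R_minus[b]
               + B[b])
        p = float(expit(eta))
        chose_unpal = int(rng.random() < p)
        day = int(tv // DAY_SECONDS)
        side = ("left" if (day + chose_unpal) % 2 == 0 else "right")
        colour = unpal_colour if chose_unpal else pal_colour
        vrows.append((ids[b], st, tv, side, colour, 1 - chose_unpal))
        lrows.append((ids[b], tv, chose_unpal, N_plus[b], N_minus[b],
                      R_plus[b], R_minus[b], p, eid))
        # update own experience, then broadcast the feed to observers
        observed = rng.random(n) < config.p_o
        observed[b] = False
        w = true_network[:, b] * observed
        if chose_unpal:
            N_minus[b] += 1
            R_minus += w
        else:
            N_plus[b] += 1
            R_plus += w

    visits = pd.DataFrame(
        vrows, columns=["bird_id", "station", "time", "feeder_side",
                        "colour", "palatable"])
    visits["phase"] = "avoidance"
    latent_rows = pd.DataFrame(
        lrows, columns=["bird_id", "time", "chose_unpalatable", "N_plus",
                        "N_minus", "R_plus", "R_minus", "p_unpalatable",
                        "event_id"])
    latent = {
        "rows": latent_rows,
        "intercepts": dict(zip(ids, B)),
        "config": config.to_dict(),
    }
    return _finalise(visits, roster), latent


@dataclass
class ReversalDiffusion:
    """Result of a simulated reversal-phase diffusion.

    ``order`` lists acquirers in acquisition order (excluding seeded
    demonstrators); ``times`` are days since the reversal phase started.
    ``censored`` lists birds still naive when the phase ended.
    """

    order: list[str]
    times: list[float]
    seeds: list[str]
    censored: list[str]

    def to_visit_table(self, roster: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
        """First acquisition visits as a reversal-phase visit table."""
        day0 = config.n_days_pretraining + config.n_days
        unpal_colour, _ = config.colour_pair
        rows = []
        for b, t in zip(self.order, self.times):
            tsec = (day0 + t) * DAY_SECONDS
            rows.append((b, "S1", tsec, "left", unpal_colour, 1))
        visits = pd.DataFrame(
            rows, columns=["bird_id", "station", "time", "feeder_side",
                           "colour", "palatable"])
        visits["phase"] = "reversal"
        return _finalise(visits, roster)


def transmission_mask(network: np.ndarray, roster: pd.DataFrame,
                      label: str) -> np.ndarray:
    """Mask the observer x demonstrator network by demonstrator class.

    ``label`` is one of ``all``, ``adult``, ``juvenile`` (demonstrator age),
    ``conspecific``, ``heterospecific`` (species relation to the observer),
    or a combination joined by ``_`` (e.g. ``adult_conspecific``).
    """
    a = network.copy()
    age = roster["age"].to_numpy()
    sp = roster["species"].to_numpy()
    for part in label.split("_"):
        if part == "all":
            continue
        elif part in ("adult", "juvenile"):
            a = a * (age == part)[None, :]
        elif part == "conspecific":
            a = a * (sp[:, None] == sp[None, :])
        elif part == "heterospecific":
            a = a * (sp[:, None] != sp[None, :])
        else:
            raise InvalidConfigError(f"unknown transmission-network label {part!r}")
    return a


def simulate_reversal_diffusion(
    roster: pd.DataFrame,
    true_network: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ReversalDiffusion:
    """Gillespie draw of the order in which birds first sample the target colour.

    Naive bird *i* acquires at rate::

        lambda_0 * [ asocial_base_rate * exp(beta_A x_i)
                     + sum_m s_m exp(beta_S x_i) sum_j a^(m)_ij z_j(t) ]

    where ``x_i`` indicates species ``B`` and ``z_j`` is j's informed status.
    The phase ends after ``reversal_days``; still-naive birds are censored.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    ids = roster["bird_id"].to_numpy()
    n = len(ids)
    x = (roster["species"].to_numpy() == "B").astype(float)
    masks = {lab: transmission_mask(true_network, roster, lab)
             for lab in config.s_true}

    informed = np.zeros(n, dtype=bool)
    seeds: list[str] = []
    if config.n_seed_demonstrators:
        seed_idx = rng.choice(n, size=config.n_seed_demonstrators, replace=False)
        informed[seed_idx] = True
        seeds = [ids[i] for i in seed_idx]

    asoc = config.asocial_base_rate * np.exp(config.oada_beta_asocial * x)
    soc_mult = np.exp(config.oada_beta_social * x)

    order: list[str] = []
    times: list[float] = []
    t = 0.0
    while not informed.all():
        conn = np.zeros(n)
        for lab, s in config.s_true.items():
            if s > 0:
                conn += s * (masks[lab] @ informed.astype(float))
        rates = np.where(informed, 0.0, asoc + soc_mult * conn)
        total = rates.sum()
        if total <= 0:
            raise StalledDiffusionError(
                "all acquisition rates are zero with naive birds remaining")
        t += rng.exponential(1.0 / total)
        if t > config.reversal_days:
            break
        i = rng.choice(n, p=rates / total)
        informed[i] = True
        order.append(ids[i])
        times.append(t)
    censored = [ids[i] for i in range(n) if not informed[i]]
    return ReversalDiffusion(order=order, times=times, seeds=seeds,
                             censored=censored)
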