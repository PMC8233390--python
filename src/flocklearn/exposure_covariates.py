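"""Per-choice covariates: personal experience and network-weighted observations.

For each visit (choice) by bird *i* at time *t* the table carries

* ``N_plus`` / ``N_minus`` — i's own prior visits to the palatable /
  unpalatable feeder within the experiment (strictly before *t*);
* ``O_minus`` / ``O_plus`` — expected numbers of negative / positive feeding
  events observed, ``O_(-,i)(t) = sum_{j != i} N_(-,j)(t) a_ij`` (and the
  analogous positive sum), the network-weighted proxy for witnessed feeds;
* the demonstrator-class cells ``O_{sign}_{C|H}{A|J}`` splitting each O by
  the demonstrator's species relation to the chooser (Conspecific /
  Heterospecific) and age (Adult / Juvenile), plus their marginal pools.

Cells sum exactly to their pools on every row; covariates depend only on
strictly earlier visits (same-timestamp visits do not see each other), so
truncating the stream at time *t* leaves all earlier rows unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association_network import AssociationMatrix
from .exceptions import InvalidConfigError, UnknownBirdError

__all__ = [
    "personal_counts",
    "expected_observations",
    "build_choice_table",
    "RunningCovariates",
    "CELL_COLUMNS",
    "POOL_COLUMNS",
]

_SIGNS = ("plus", "minus")
_AGES = ("adult", "juvenile")

#: the eight demonstrator-class cells, finest split computed
CELL_COLUMNS = [f"O_{s}_{r}{a}" for s in _SIGNS for r in "CH" for a in "AJ"]

#: marginal pools derived from the cells
POOL_COLUMNS = [f"O_{s}{suffix}" for s in _SIGNS
                for suffix in ("", "_C", "_H", "_A", "_J")]


def personal_counts(visits: pd.DataFrame, bird: str, t: float) -> tuple[int, int]:
    """(N_plus, N_minus): the bird's own feeds strictly before ``t``."""
    own = visits[(visits["bird_id"] == bird) & (visits["time"] < t)]
    n_plus = int((own["palatable"] == 1).sum())
    return n_plus, len(own) - n_plus


def expected_observations(
    visits: pd.DataFrame,
    network: AssociationMatrix,
    bird: str,
    t: float,
    sign: str = "minus",
    demonstrator_filter=None,
) -> float:
    """Network-weighted count of others' prior feeds of the given sign.

    ``demonstrator_filter(species_j, age_j)`` optionally restricts which
    demonstrators enter the sum; the chooser itself never does.
    """
    if bird not in network._index:
        raise UnknownBirdError(f"bird {bird!r} absent from network")
    i = network.index(bird)
    want_pal = 1 if sign == "plus" else 0
    prior = visits[(visits["time"] < t) & (visits["bird_id"] != bird)
                   & (visits["palatable"] == want_pal)]
    total = 0.0
    for _, row in prior.iterrows():
        j_id = row["bird_id"]
        if j_id not in network._index:
            raise UnknownBirdError(f"bird {j_id!r} absent from network")
        if demonstrator_filter is not None and not demonstrator_filter(
                row["species"], row["age"]):
            continue
        total += network.weights[i, network.index(j_id)]
    return total


class RunningCovariates:
    """Incremental engine producing one fully split covariate row per feed.

    Maintains, for every (sign, demonstrator age, demonstrator species)
    class, the vector over observers of ``sum_j a_ij N_sign_j``; a feed by
    demonstrator *j* adds column ``a[:, j]`` to one vector.  Works for any
    weight matrix; nonzero diagonals (homogenized networks) are corrected by
    subtracting the observer's own contribution at read time.
    """

    def __init__(self, network: AssociationMatrix, roster: pd.DataFrame):
        self.net = network
        n = len(network.birds)
        lookup = roster.set_index("bird_id")
        missing = [b for b in network.birds if b not in lookup.index]
        if missing:
            raise UnknownBirdError(f"birds {missing} not in roster")
        self.species = lookup.loc[network.birds, "species"].to_numpy()
        self.age = lookup.loc[network.birds, "age"].to_numpy()
        self.n_plus = np.zeros(n)
        self.n_minus = np.zeros(n)
        # vec[(sign, age, species)] over observers
        self._species_values = sorted(set(self.species))
        self.vec = {(s, a, sp): np.zeros(n)
                    for s in _SIGNS for a in _AGES
                    for sp in self._species_values}
        self.diag = np.diag(network.weights).copy()

    def row(self, bird: str) -> dict:
        """Covariate dict for a choice by ``bird`` given the current state."""
        i = self.net.index(bird)
        sp_i, age_i = self.species[i], self.age[i]
        out = {"N_plus": self.n_plus[i], "N_minus": self.n_minus[i]}
        own = {"plus": self.n_plus[i], "minus": self.n_minus[i]}
        for s in _SIGNS:
            for rel in "CH":
                for ag, ag_name in (("A", "adult"), ("J", "juvenile")):
                    cells = [sp for sp in self._species_values
                             if (sp == sp_i) == (rel == "C")]
                    val = sum(self.vec[(s, ag_name, sp)][i] for sp in cells)
                    if rel == "C" and ag_name == age_i:
                        val -= self.diag[i] * own[s]  # self-exclusion
                    out[f"O_{s}_{rel}{ag}"] = val
        for s in _SIGNS:
            out[f"O_{s}_C"] = out[f"O_{s}_CA"] + out[f"O_{s}_CJ"]
            out[f"O_{s}_H"] = out[f"O_{s}_HA"] + out[f"O_{s}_HJ"]
            out[f"O_{s}_A"] = out[f"O_{s}_CA"] + out[f"O_{s}_HA"]
            out[f"O_{s}_J"] = out[f"O_{s}_CJ"] + out[f"O_{s}_HJ"]
            out[f"O_{s}"] = out[f"O_{s}_C"] + out[f"O_{s}_H"]
        return out

    def update(self, bird: str, chose_unpalatable: int) -> None:
        """Record a completed feed so later choices can observe it."""
        j = self.net.index(bird)
        sign = "minus" if chose_unpalatable else "plus"
        if sign == "minus":
            self.n_minus[j] += 1
        else:
            self.n_plus[j] += 1
        self.vec[(sign, self.age[j], self.species[j])] += self.net.weights[:, j]


def build_choice_table(
    visits: pd.DataFrame,
    network: AssociationMatrix,
    roster: pd.DataFrame,
    experiment: str | None = None,
    colour_map: dict | None = None,
) -> pd.DataFrame:
    """One fully populated choice row per visit, in time order.

    ``colour_map`` (colour -> palatable 0/1) overrides the table's
    ``palatable`` column when given; an unmapped colour is a configuration
    error.  Counts start from zero at the head of the supplied stream —
    callers model experiments separately by filtering beforehand (the
    ``experiment`` label is only recorded on the output).
    """
    visits = visits.sort_values("time", kind="mergesort").reset_index(drop=True)
    if colour_map is not None:
        unknown = set(visits["colour"]) - set(colour_map)
        if unknown:
            raise InvalidConfigError(
                f"no palatability mapping for colours {sorted(unknown)}")
        pal = visits["colour"].map(colour_map).to_numpy()
    else:
        pal = visits["palatable"].to_numpy()
    chose_unpal = 1 - np.asarray(pal, dtype=int)

    engine = RunningCovariates(network, roster)
    times = visits["time"].to_numpy(dtype=float)
    birds = visits["bird_id"].to_numpy()
    for b in np.unique(birds):
        if b not in network._index:
            raise UnknownBirdError(f"bird {b!r} absent from network")

    rows = []
    k = 0
    nrows = len(visits)
    while k < nrows:
        # visits sharing a timestamp are computed from the same state:
        # simultaneous choices do not see each other
        k_end = k + 1
        while k_end < nrows and times[k_end] == times[k]:
            k_end += 1
        for r in range(k, k_end):
            row = engine.row(birds[r])
            row["bird_id"] = birds[r]
            row["time"] = times[r]
            row["chose_unpalatable"] = int(chose_unpal[r])
            rows.append(row)
        for r in range(k, k_end):
            engine.update(birds[r], int(chose_unpal[r]))
        k = k_end

    table = pd.DataFrame(rows)
    lookup = roster.set_index("bird_id")
    table["species"] = lookup.loc[table["bird_id"], "species"].to_numpy()
    table["age"] = lookup.loc[table["bird_id"], "age"].to_numpy()
    table["experiment"] = experiment if experiment is not None else ""
    front = ["bird_id", "species", "age", "time", "chose_unpalatable",
             "N_plus", "N_minus"]
    other = [c for c in table.columns if c not in front]
    return table[front + [c for c in other if c != "experiment"] + ["experiment"]]
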