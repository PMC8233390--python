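"""Simple-ratio-index association network and its homogenized null counterpart.

The network edge between birds A and B is the simple ratio index

    SRI = x / (x + y_A + y_B + y_AB)

tallied over *sampling periods*: maximal sets of temporally overlapping
gathering events across stations.  ``x`` counts periods in which A and B
occurred in the same event, ``y_A``/``y_B`` periods where only one of them
was seen, and ``y_AB`` periods where both were seen but in different events
(e.g. simultaneously at different stations).  The SRI estimates the
probability that the two birds are in the same group at a given time, scaled
between 0 (never together) and 1 (always together).

Homogenization replaces each observer-demonstrator weight ``a_ij`` by the
demonstrator's column mean ``sum_i a_ij / n``, keeping every demonstrator's
total expected audience (column sum) exactly equal — the null network for
the test of whether a social effect follows the observed network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, UnknownBirdError
from .gathering_events import GatheringEvent

__all__ = ["AssociationMatrix", "build_sampling_periods", "sri", "homogenize"]

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """Pairwise association weights over a fixed roster order.

    ``weights[i, j]`` is the probability that bird *i* observes a feed by
    bird *j* (via co-membership of gathering events).  Symmetric with zero
    diagonal when estimated; column-constant once homogenized.
    """

    birds: list[str]
    weights: np.ndarray
    homogenized: bool = False
    n_unsampled_pairs: int = 0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.birds), len(self.birds)):
            raise InvalidArgumentError("weights shape does not match roster")
        self._index = {b: k for k, b in enumerate(self.birds)}

    def index(self, bird: str) -> int:
        return self._index[bird]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.birds, columns=self.birds)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.birds)
        n = len(self.birds)
        for i in range(n):
            for j in range(i + 1, n):
                w = self.weights[i, j]
                if w > 0:
                    g.add_edge(self.birds[i], self.birds[j], weight=float(w))
        return g

    def metadata(self) -> dict:
        return {"n_birds": len(self.birds), "homogenized": self.homogenized,
                "n_unsampled_pairs": self.n_unsampled_pairs}


def build_sampling_periods(
    events: list[GatheringEvent],
) -> list[list[GatheringEvent]]:
    """Partition events into maximal temporally overlapping sets.

    Periods are the connected components of the interval-overlap graph over
    event [t_start, t_end] ranges, pooled across stations; every event lands
    in exactly one period.  Non-overlapping events give singleton periods.
    """
    if not events:
        return []
    evs = sorted(events, key=lambda e: (e.t_start, e.t_end))
    periods: list[list[GatheringEvent]] = [[evs[0]]]
    reach = evs[0].t_end
    for ev in evs[1:]:
        if ev.t_start <= reach:  # closed-interval overlap with the component
            periods[-1].append(ev)
            reach = max(reach, ev.t_end)
        else:
            periods.append([ev])
            reach = ev.t_end
    return periods


def sri(events: list[GatheringEvent], roster: pd.DataFrame) -> AssociationMatrix:
    """Simple-ratio-index network over the roster from detected events.

    Pairs never seen in any common sampling period (denominator zero) get
    weight 0; their count is logged and recorded on the result.
    """
    birds = list(roster["bird_id"])
    if not birds:
        raise InvalidArgumentError("roster is empty")
    n = len(birds)
    index = {b: k for k, b in enumerate(birds)}

    together = np.zeros((n, n))
    both_seen = np.zeros((n, n))
    seen = np.zeros(n)
    for period in build_sampling_periods(events):
        inc = np.zeros((len(period), n), dtype=bool)
        for r, ev in enumerate(period):
            for b in ev.members:
                if b not in index:
                    raise UnknownBirdError(f"bird {b!r} not in roster")
                inc[r, index[b]] = True
        present = inc.any(axis=0)
        seen += present
        both_seen += np.outer(present, present)
        tog = (inc.T.astype(int) @ inc.astype(int)) > 0
        together += tog
    # denominator x + y_A + y_B + y_AB = periods where A or B was seen
    denom = seen[:, None] + seen[None, :] - both_seen
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, together / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    iu = np.triu_indices(n, k=1)
    n_unsampled = int((denom[iu] == 0).sum())
    if n_unsampled:
        logger.warning("%d bird pairs never co-sampled; SRI set to 0",
                       n_unsampled)
    return AssociationMatrix(birds=birds, weights=w, homogenized=False,
                             n_unsampled_pairs=n_unsampled)


def homogenize(network: AssociationMatrix,
               exclude_self: bool = False) -> AssociationMatrix:
    """Replace each column by its mean, preserving column sums exactly.

    With ``exclude_self=True`` the mean omits the (zero) diagonal entry and
    divides by n - 1; the default divides by n.
    """
    if network.homogenized:
        raise InvalidArgumentError("network is already homogenized")
    a = network.weights
    n = a.shape[0]
    divisor = (n - 1) if exclude_self else n
    col_mean = a.sum(axis=0) / divisor
    w = np.tile(col_mean, (n, 1))
    if exclude_self:
        np.fill_diagonal(w, 0.0)
    return AssociationMatrix(birds=list(network.birds), weights=w,
                             homogenized=True,
                             n_unsampled_pairs=network.n_unsampled_pairs)
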