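"""Global reference network of gene families.

Nodes are gene families; edges are gene-neighbor links whose evidence
score exceeds a critical threshold (default 275, the score at which
specificity and sensitivity balance for known functionally related
proteins). Edge weights for clustering are unit-based normalized
scores, (score - 275) / (1000 - 275), so they lie in (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .containers import ScoredLinkTable

__all__ = [
    "ReferenceNetwork",
    "build_reference_network",
    "normalize_weights",
    "DEFAULT_SCORE_THRESHOLD",
    "SCORE_MAX",
]

DEFAULT_SCORE_THRESHOLD = 275
SCORE_MAX = 1000


@dataclass
class ReferenceNetwork:
    """Thresholded gene-family network.

    ``graph`` is an undirected :class:`networkx.Graph`; every edge
    carries its original integer ``score`` and, after
    :func:`normalize_weights`, a ``weight`` in (0, 1]. Families with
    no retained link are absent from the node set.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    score_threshold: int = DEFAULT_SCORE_THRESHOLD

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (a, b) if a <= b else (b, a) for a, b in self.graph.edges
        )

    @property
    def weights(self) -> dict[tuple[str, str], float] | None:
        items = {}
        for a, b, data in self.graph.edges(data=True):
            if "weight" not in data:
                return None
            key = (a, b) if a <= b else (b, a)
            items[key] = data["weight"]
        return items

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_reference_network(
    links: ScoredLinkTable,
    threshold: int = DEFAULT_SCORE_THRESHOLD,
) -> ReferenceNetwork:
    """Retain links with score strictly above ``threshold``.

    The strict inequality makes the subsequent weight normalization
    map every retained edge into (0, 1]; a score equal to the
    threshold would normalize to a meaningless zero weight.
    """
    if not 0 <= threshold <= SCORE_MAX:
        raise ValueError(f"threshold {threshold} outside [0, {SCORE_MAX}]")
    g = nx.Graph()
    for a, b, score in links.records:
        if score > threshold:
            g.add_edge(a, b, score=score)
    if g.number_of_edges() == 0:
        warnings.warn(
            f"no links exceed threshold {threshold}; network is empty",
            stacklevel=2,
        )
    return ReferenceNetwork(graph=g, score_threshold=threshold)


def normalize_weights(
    net: ReferenceNetwork,
    score_min: int = DEFAULT_SCORE_THRESHOLD,
    score_max: int = SCORE_MAX,
) -> ReferenceNetwork:
    """Attach unit-based normalized weights (score - min) / (max - min).

    Every retained edge must have score in (score_min, score_max];
    the resulting weights lie in (0, 1] and preserve score order.
    """
    if score_max <= score_min:
        raise ValueError("score_max must exceed score_min")
    rng = score_max - score_min
    out = nx.Graph()
    out.add_nodes_from(net.graph.nodes)
    for a, b, data in net.graph.edges(data=True):
        score = data["score"]
        if not score_min < score <= score_max:
            raise ValueError(
                f"edge ({a}, {b}) score {score} outside "
                f"({score_min}, {score_max}]: thresholding contract violated"
            )
        out.add_edge(a, b, score=score, weight=(score - score_min) / rng)
    return ReferenceNetwork(graph=out, score_threshold=net.score_threshold)
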