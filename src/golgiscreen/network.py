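"""Protein-interaction network handling: confidence filtering and
Golgi-associated neighbor counting (score component 2).

Edges carry per-channel confidences in [0, 1] (STRING-style; the 0-1000
integer convention is auto-detected on load and rescaled). The screen uses
only the experimental-evidence channel, thresholded at >= 0.4, and counts
for each gene its distinct first-shell neighbors that belong to the
Golgi-associated universe. The count is uncapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from golgiscreen.universe import GeneUniverse, normalize_symbol

logger = logging.getLogger(__name__)

DEFAULT_CHANNEL = "experimental"
DEFAULT_MIN_CONF = 0.4


@dataclass(frozen=True)
class InteractorScore:
    gene: str
    n_golgi_interactors: int

    @property
    def score2(self) -> int:
        return self.n_golgi_interactors


class InteractionNetwork:
    """Undirected gene graph with per-channel confidence scores on edges.

    At most one edge per unordered pair; duplicate rows are merged by
    taking the per-channel maximum. Self-loops are dropped.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "InteractionNetwork":
        """Build from a DataFrame with columns ``protein1``, ``protein2`` and
        one column per confidence channel.

        Channel columns whose maximum exceeds 1 are assumed to be on the
        STRING 0-1000 integer scale and are divided by 1000.
        """
        channels = [c for c in edges.columns if c not in ("protein1", "protein2")]
        edges = edges.copy()
        for ch in channels:
            col = pd.to_numeric(edges[ch], errors="raise")
            if col.max() > 1:
                col = col / 1000.0
            if (col < 0).any() or (col > 1).any():
                raise ValueError(f"channel {ch!r} has confidences outside [0, 1]")
            edges[ch] = col

        g = nx.Graph()
        for row in edges.itertuples(index=False):
            a = normalize_symbol(getattr(row, "protein1"))
            b = normalize_symbol(getattr(row, "protein2"))
            if a == b:
                continue  # self-loop
            scores = {ch: float(getattr(row, ch)) for ch in channels}
            if g.has_edge(a, b):
                prev = g.edges[a, b]
                for ch, v in scores.items():
                    prev[ch] = max(prev.get(ch, 0.0), v)
            else:
                g.add_edge(a, b, **scores)
        return cls(g)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_score(self, a: str, b: str, channel: str) -> float | None:
        if not self.graph.has_edge(a, b):
            return None
        return self.graph.edges[a, b].get(channel)


def filter_edges(
    net: InteractionNetwork,
    channel: str = DEFAULT_CHANNEL,
    min_conf: float = DEFAULT_MIN_CONF,
) -> InteractionNetwork:
    """Keep edges whose ``channel`` confidence is >= ``min_conf``.

    Edges lacking the channel are dropped. If no edge in the network carries
    the channel at all, a warning is logged and the result is empty.
    """
    if not 0 <= min_conf <= 1:
        raise ValueError("min_conf must lie in [0, 1]")
    g = net.graph
    if g.number_of_edges() and not any(channel in d for _, _, d in g.edges(data=True)):
        logger.warning("channel %r present on no edge; filtered network is empty", channel)
    kept = nx.Graph()
    for a, b, d in g.edges(data=True):
        if channel in d and d[channel] >= min_conf:
            kept.add_edge(a, b, **d)
    return InteractionNetwork(kept)


def count_golgi_interactors(
    net: InteractionNetwork, gene: str, universe: GeneUniverse
) -> InteractorScore:
    """Count the gene's distinct neighbors that are universe members.

    The network must already be confidence-filtered. Genes absent from the
    network (or isolated) score 0; the gene itself never counts.
    """
    g = net.graph
    if gene not in g:
        return InteractorScore(gene=gene, n_golgi_interactors=0)
    n = sum(1 for nb in g.neighbors(gene) if nb != gene and nb in universe)
    return InteractorScore(gene=gene, n_golgi_interactors=n)
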