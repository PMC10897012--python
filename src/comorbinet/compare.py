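"""Cross-network comparison surfaces: shared pairs, nearest neighbors, MI ranks.

These operations answer the questions asked of per-stratum networks once
built: which comorbid pairs persist across life stages, sex and SES; which
diseases are a given condition's comorbidity nearest neighbors (CNNs, its
direct network neighbors); and where a given pair's association strength
ranks among all edges of its network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .inference import ComorbidityNetwork

__all__ = [
    "SharedPairReport",
    "shared_pairs",
    "nearest_neighbors",
    "pair_mi_rank",
]


@dataclass(frozen=True)
class SharedPairReport:
    """Presence of one disease pair across the analyzed networks."""

    pair: tuple[str, str]
    presence: tuple[tuple[str, bool], ...]  # (stratum label, present) per network

    @property
    def n_present(self) -> int:
        return sum(1 for _, present in self.presence if present)

    def presence_map(self) -> dict[str, bool]:
        return dict(self.presence)


def _network_label(network: ComorbidityNetwork, index: int) -> str:
    return network.stratum if network.stratum is not None else f"network_{index}"


def _edge_set(network: ComorbidityNetwork, top_k_by_mi: int | None):
    edges = [
        (tuple(sorted((a, b))), data["mi"]) for a, b, data in network.graph.edges(data=True)
    ]
    if top_k_by_mi is not None:
        edges = sorted(edges, key=lambda e: (-e[1], e[0]))[:top_k_by_mi]
    return {pair for pair, _ in edges}


def shared_pairs(
    networks: Sequence[ComorbidityNetwork],
    min_networks: int = 2,
    top_k_by_mi: int | None = None,
) -> list[SharedPairReport]:
    """Disease pairs appearing as edges in at least ``min_networks`` networks.

    ``top_k_by_mi`` optionally restricts each network to its k strongest
    edges before counting presence (presence among the *most relevant*
    pairs rather than among all edges). Output is sorted by descending
    ``n_present`` then pair, and is invariant to the order of the input
    networks up to their label order in each report.
    """
    if len(networks) < 2:
        raise ValueError("shared_pairs requires at least 2 networks")
    labels = [_network_label(net, i) for i, net in enumerate(networks)]
    edge_sets = {
        label: _edge_set(net, top_k_by_mi) for label, net in zip(labels, networks)
    }
    all_pairs = sorted(set().union(*edge_sets.values()))
    reports = [
        SharedPairReport(
            pair=pair,
            presence=tuple((label, pair in edge_sets[label]) for label in labels),
        )
        for pair in all_pairs
    ]
    reports = [r for r in reports if r.n_present >= min_networks]
    return sorted(reports, key=lambda r: (-r.n_present, r.pair))


def nearest_neighbors(
    network: ComorbidityNetwork, code: str
) -> list[tuple[str, float]]:
    """Comorbidity nearest neighbors of a disease, sorted by MI descending.

    Ties break lexicographically. Raises ``LookupError`` naming the code
    and stratum when the code is not a node of the network.
    """
    if code not in network.graph:
        raise LookupError(
            f"code {code!r} is not a node of network {network.stratum!r}"
        )
    neigh = [(nbr, network.graph.edges[code, nbr]["mi"]) for nbr in network.graph[code]]
    return sorted(neigh, key=lambda kv: (-kv[1], kv[0]))


def pair_mi_rank(
    network: ComorbidityNetwork, pair: tuple[str, str]
) -> tuple[int, int]:
    """1-based rank of a pair's MI among all edge MIs, plus the edge count.

    Competition ranking: tied MIs share the lowest applicable rank number
    (reporting order among ties is by pair lexicographically). Raises
    ``LookupError`` when the pair is not an edge.
    """
    a, b = sorted(pair)
    if not network.graph.has_edge(a, b):
        raise LookupError(f"pair ({a}, {b}) is not an edge of network {network.stratum!r}")
    mi = network.graph.edges[a, b]["mi"]
    total = network.graph.number_of_edges()
    higher = sum(1 for _, _, d in network.graph.edges(data=True) if d["mi"] > mi)
    return higher + 1, total
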