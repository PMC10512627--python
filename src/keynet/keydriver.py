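"""Key driver analysis on a consensus causal network.

For a module of interest, the enrichment background is the set of nodes
within undirected distance K of any module member. For every node in that
subnetwork and each k in 1..K, the k-step *directed* downstream
neighborhood is tested for enrichment of module members; the per-node
p-value is Bonferroni-corrected over the k values tested and BH-corrected
across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .causalnet import ConsensusNetwork
from .stats_core import bh_adjust, hypergeom_enrichment

__all__ = ["KeyDriverResult", "extract_subnetwork", "find_key_drivers", "validate_key_drivers"]


@dataclass
class KeyDriverResult:
    node: str
    best_k: int
    downstream_size: int
    overlap: int
    fold_enrichment: float
    p: float  # Bonferroni over tested k
    fdr: float = np.nan  # BH over nodes
    is_key_driver: bool = False
    validated: bool = False


def _build_graph(network: ConsensusNetwork | list[tuple[str, str]]) -> nx.DiGraph:
    edges = (
        network.retained_edges() if isinstance(network, ConsensusNetwork) else list(network)
    )
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


def extract_subnetwork(
    network: ConsensusNetwork | list[tuple[str, str]],
    module_members: set[str] | list[str],
    K: int = 7,
) -> set[str]:
    """Nodes within undirected distance <= K of any module member.

    Module members absent from the network are included as isolated nodes;
    this set is the enrichment background.
    """
    members = set(module_members)
    if not members:
        raise ValueError("module member set is empty")
    g = _build_graph(network).to_undirected()
    nodes = set(members)
    frontier = members & set(g.nodes)
    seen = set(frontier)
    for _ in range(K):
        nxt = set()
        for u in frontier:
            nxt.update(g.neighbors(u))
        nxt -= seen
        if not nxt:
            break
        nodes |= nxt
        seen |= nxt
        frontier = nxt
    return nodes


def _downstream_layers(g: nx.DiGraph, node: str, K: int, allowed: set[str]) -> list[set[str]]:
    """Cumulative directed neighborhoods D_1..D_K of ``node`` within ``allowed``."""
    layers: list[set[str]] = []
    reached = {node}
    frontier = {node}
    cumulative: set[str] = set()
    for _ in range(K):
        nxt = set()
        for u in frontier:
            if g.has_node(u):
                nxt.update(v for v in g.successors(u) if v in allowed)
        nxt -= reached
        reached |= nxt
        cumulative = cumulative | nxt
        layers.append(set(cumulative))
        frontier = nxt
        if not frontier:
            # remaining layers identical
            while len(layers) < K:
                layers.append(set(cumulative))
            break
    return layers


def find_key_drivers(
    network: ConsensusNetwork | list[tuple[str, str]],
    module_members: set[str] | list[str],
    K: int = 7,
    min_downstream: int = 5,
    alpha: float = 0.05,
) -> list[KeyDriverResult]:
    """Score every subnetwork node for downstream enrichment of module members.

    A node is a key driver iff its BH FDR <= alpha and fold enrichment > 1
    at its best k. Results are sorted by (fdr, p, -fold).
    """
    members = set(module_members)
    subnet = extract_subnetwork(network, members, K=K)
    g = _build_graph(network)
    universe = len(subnet)  # enrichment background
    results: list[KeyDriverResult] = []
    target = len(members & subnet)
    for node in sorted(subnet):
        if target == 0 or universe <= 1:
            break
        layers = _downstream_layers(g, node, K, allowed=subnet)
        best: tuple[float, int, int, int, float] | None = None
        n_tested = 0
        for k, downstream in enumerate(layers, start=1):
            if len(downstream) < max(min_downstream, 1):
                continue
            if k > 1 and downstream == layers[k - 2]:
                continue  # unchanged neighborhood, not a new test
            n_tested += 1
            overlap = len(downstream & members)
            fold, p = hypergeom_enrichment(overlap, len(downstream), target, universe)
            if best is None or p < best[0]:
                best = (p, k, len(downstream), overlap, fold)
        if best is None:
            continue
        p_adj = min(best[0] * n_tested, 1.0)
        results.append(
            KeyDriverResult(
                node=node,
                best_k=best[1],
                downstream_size=best[2],
                overlap=best[3],
                fold_enrichment=best[4],
                p=p_adj,
            )
        )
    if results:
        fdr = bh_adjust([r.p for r in results])
        for r, q in zip(results, fdr):
            r.fdr = float(q)
            r.is_key_driver = bool(r.fdr <= alpha and r.fold_enrichment > 1)
        results.sort(key=lambda r: (r.fdr, r.p, -r.fold_enrichment, r.node))
    return results


def validate_key_drivers(
    discovery: list[KeyDriverResult], test: list[KeyDriverResult]
) -> list[KeyDriverResult]:
    """Discovery key drivers that are key drivers in the test analysis too."""
    test_drivers = {r.node for r in test if r.is_key_driver}
    out = []
    for r in discovery:
        validated = r.is_key_driver and r.node in test_drivers
        out.append(
            KeyDriverResult(
                node=r.node,
                best_k=r.best_k,
                downstream_size=r.downstream_size,
                overlap=r.overlap,
                fold_enrichment=r.fold_enrichment,
                p=r.p,
                fdr=r.fdr,
                is_key_driver=r.is_key_driver,
                validated=validated,
            )
        )
    return out


def key_driver_table(results: list[KeyDriverResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node": r.node,
                "best_k": r.best_k,
                "downstream_size": r.downstream_size,
                "overlap": r.overlap,
                "fold_enrichment": r.fold_enrichment,
                "p": r.p,
                "fdr": r.fdr,
                "is_key_driver": r.is_key_driver,
                "validated": r.validated,
            }
            for r in results
        ],
        columns=[
            "node",
            "best_k",
            "downstream_size",
            "overlap",
            "fold_enrichment",
            "p",
            "fdr",
            "is_key_driver",
            "validated",
        ],
    )
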