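"""Coupled charge networks.

Two sites are strongly coupled when |W_ij| ≥ 11.5 kJ/mol (a two-pKa-unit
interaction at 300 K); a charge network is a connected component of the
coupling graph after restricting to buried members. Network size is counted
over D/E/K/R/H members only — Cys, Tyr and termini may bridge components if
themselves buried, but never count toward size nor get reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np

from .constants import ASSESSED_GROUPS, COUPLING_THRESHOLD
from .energetics import InteractionMatrix
from .structure import IonizableSite


@dataclass
class ChargeNetwork:
    member_sites: list
    dekrh_size: int

    def dekrh_members(self, sites_by_id: Mapping) -> list:
        return [sid for sid in self.member_sites
                if sites_by_id[sid].group_label in ASSESSED_GROUPS]


def coupling_graph(W: InteractionMatrix,
                   threshold: float = COUPLING_THRESHOLD) -> nx.Graph:
    """Undirected graph with an edge wherever |W_ij| ≥ threshold."""
    if threshold <= 0:
        raise ValueError("coupling threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(W.site_ids)
    n = len(W.site_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(W.W[i, j]) >= threshold:
                g.add_edge(W.site_ids[i], W.site_ids[j], w=float(W.W[i, j]))
    return g


BurialSpec = Union[dict, None]


def charge_networks(graph: nx.Graph, sites: Sequence[IonizableSite],
                    burial: BurialSpec, min_dekrh: int,
                    dh_flags: Optional[Mapping] = None) -> list[ChargeNetwork]:
    """Connected components of the burial-restricted coupling graph.

    ``burial`` is either ``{"sasa_max": x}`` (keep nodes with moiety SASA ≤ x)
    or ``{"mode": "nodh"}`` (keep nodes whose ``dh_flags`` entry is False,
    i.e. no rotamer reaches solvent). Components with fewer than
    ``min_dekrh`` D/E/K/R/H members are dropped.
    """
    by_id = {s.site_id: s for s in sites}

    if burial is None:
        keep = set(graph.nodes)
    elif "sasa_max" in burial:
        cutoff = burial["sasa_max"]
        for sid in graph.nodes:
            if by_id[sid].moiety_sasa is None:
                raise ValueError(f"site {sid}: moiety SASA unavailable")
        keep = {sid for sid in graph.nodes if by_id[sid].moiety_sasa <= cutoff}
    elif burial.get("mode") == "nodh":
        if dh_flags is None:
            raise ValueError("nodh burial requires dh_access flags")
        keep = {sid for sid in graph.nodes if dh_flags.get(sid) is False}
    else:
        raise ValueError(f"unknown burial mode: {burial!r}")

    sub = graph.subgraph(keep)
    out = []
    for comp in nx.connected_components(sub):
        members = sorted(comp, key=str)
        dekrh = sum(1 for sid in members
                    if by_id[sid].group_label in ASSESSED_GROUPS)
        if dekrh >= min_dekrh:
            out.append(ChargeNetwork(member_sites=members, dekrh_size=dekrh))
    return out
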