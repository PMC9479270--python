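"""Core-mRNA intersection and induced key sub-network extraction.

Core mRNAs are the intersection of the reversal mRNA set with the mRNA
nodes of the co-expression network: mRNAs that both respond to treatment in
the reversal sense and co-express tightly with a key lncRNA. The key
sub-network is the parent network restricted to edges whose mRNA endpoint
is a core mRNA; lncRNA nodes are never filtered by the core set, but a
lncRNA left without any edge is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from lncnet.network import CoexpressionEdge, CoexpressionNetwork, NetworkThresholds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubNetwork:
    """A mRNA-side restriction of a co-expression network."""

    lncrna_nodes: frozenset[str]
    mrna_nodes: frozenset[str]
    edges: tuple[CoexpressionEdge, ...]
    thresholds: NetworkThresholds
    core_mrnas: frozenset[str]
    provenance: tuple[str, str] = ("reversal", "coexpression_network")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((e.lncrna_id, e.mrna_id) for e in self.edges)


def core_mrnas(reversal_mrna_ids, network: CoexpressionNetwork) -> set[str]:
    """Plain set intersection of reversal mRNA ids with network mRNA nodes."""
    return set(reversal_mrna_ids) & set(network.mrna_nodes)


def induced_subnetwork(network: CoexpressionNetwork, core) -> SubNetwork:
    """Restrict a network to the edges whose mRNA endpoint is in ``core``.

    Core ids absent from the network's mRNA nodes are ignored with a
    warning. lncRNA nodes that lose all their edges are dropped; the result
    is deterministic and its edges are a subset of the parent's.
    """
    core = set(core)
    stray = core - set(network.mrna_nodes)
    if stray:
        logger.warning("%d core id(s) not among network mRNA nodes; ignoring "
                       "(first: %s)", len(stray), sorted(stray)[0])
    kept = tuple(e for e in network.edges if e.mrna_id in core)
    return SubNetwork(
        lncrna_nodes=frozenset(e.lncrna_id for e in kept),
        mrna_nodes=frozenset(e.mrna_id for e in kept),
        edges=kept,
        thresholds=network.thresholds,
        core_mrnas=frozenset(core & set(network.mrna_nodes)),
    )
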