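"""Chain-interaction network and the combinatorics of assembly paths.

Two chains interact when at least 10% of the shorter chain's CB atoms (CA for
glycine) are within 8 A of the other chain's CBs. Every subcomponent
contributes one edge per interacting chain pair, and duplicate seq-pairs from
different subcomponents are retained as distinct edges: alternative predicted
conformations of the same interface are exactly what trimeric subcomponents
are for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from itertools import combinations

import networkx as nx

from .geometry import CONTACT_CUTOFF, interface_contacts, min_dists
from .structio import ChainStructure, Subcomponent

INTERACTION_FRACTION = 0.10  # inclusive (>=)


class NetworkError(ValueError):
    pass


def detect_interaction(a: ChainStructure, b: ChainStructure) -> bool:
    """True iff >= 10% of the shorter chain's CBs are within 8 A of the other chain."""
    short, other = (a, b) if len(a) <= len(b) else (b, a)
    d = min_dists(short.cb_coords, other.cb_coords)
    return (d <= CONTACT_CUTOFF).sum() >= INTERACTION_FRACTION * len(short)


@dataclass(frozen=True)
class InteractionEdge:
    """A pairwise interface realized by one subcomponent."""

    source_sub: str
    chain_pair: tuple[str, str]
    seq_pair: tuple[str, str]
    n_contacts: int

    def __post_init__(self) -> None:
        if self.chain_pair[0] == self.chain_pair[1]:
            raise NetworkError("edge between a chain and itself")
        if self.n_contacts < 1:
            raise NetworkError("an interaction edge needs >= 1 contact")


@dataclass
class InteractionNetwork:
    """Multigraph over chain copies; edges are subcomponent-realized interfaces."""

    nodes: list[tuple[str, int]]
    edges: list[InteractionEdge]
    stoichiometry: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def seq_ids(self) -> set[str]:
        return set(self.stoichiometry)

    def edges_touching(self, seq_id: str) -> list[int]:
        return [i for i, e in enumerate(self.edges) if seq_id in e.seq_pair]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for i, e in enumerate(self.edges):
            g.add_edge(e.seq_pair[0], e.seq_pair[1], key=i,
                       source_sub=e.source_sub, n_contacts=e.n_contacts)
        return g

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [
            dict(source_sub=e.source_sub, chain_a=e.chain_pair[0], chain_b=e.chain_pair[1],
                 seq_a=e.seq_pair[0], seq_b=e.seq_pair[1], n_contacts=e.n_contacts)
            for e in self.edges
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_network(
    subs: list[Subcomponent],
    stoichiometry: dict[str, int],
    allowed_pairs: set[frozenset[str]] | None = None,
) -> InteractionNetwork:
    """Build the interaction multigraph from subcomponents and a stoichiometry.

    Every unordered chain pair of every subcomponent that passes
    :func:`detect_interaction` becomes an edge, so a trimer contributes up to
    three edges ("all three dimers from a trimer"). ``allowed_pairs``
    optionally restricts edges to a known (guided) set of seq-id pairs.
    """
    nodes = [(sid, i) for sid in sorted(stoichiometry) for i in range(stoichiometry[sid])]
    edges: list[InteractionEdge] = []
    for sub in subs:
        for c in sub.chains:
            if sub.seq_assignment[c.chain_id] not in stoichiometry:
                raise NetworkError(
                    f"subcomponent {sub.name}: chain {c.chain_id} has seq_id "
                    f"{sub.seq_assignment[c.chain_id]!r} absent from the stoichiometry"
                )
        for a, b in combinations(sub.chains, 2):
            pair = frozenset((a.seq_id, b.seq_id))
            if allowed_pairs is not None and pair not in allowed_pairs:
                continue
            if detect_interaction(a, b):
                n = len(interface_contacts(a, b))
                edges.append(InteractionEdge(sub.name, (a.chain_id, b.chain_id),
                                             (a.seq_id, b.seq_id), n))
    return InteractionNetwork(nodes, edges, dict(stoichiometry))


# --- path/edge counting -----------------------------------------------------

def num_dimers(n: int) -> int:
    """Number of possible dimers among n chains: n(n-1)/2."""
    if n < 2:
        raise ValueError(f"need n >= 2 chains, got {n}")
    return n * (n - 1) // 2


def num_trimers(n: int) -> int:
    """Number of possible trimers among n chains: n(n-1)(n-2)/6."""
    if n < 3:
        raise ValueError(f"need n >= 3 chains, got {n}")
    return n * (n - 1) * (n - 2) // 6


def num_edges_all_trimers(n: int) -> int:
    """Total pairwise edges extracted from all trimers: each trimer carries three."""
    return 3 * num_trimers(n)


def num_spanning_paths(n_prime: int) -> int:
    """Number of unique paths containing all of n' nodes: n'^(n'-2).

    This is Cayley's count of labeled spanning trees, evaluated in exact
    integer arithmetic (for 30 effective nodes it is already ~2.3e41).
    """
    if n_prime < 2:
        raise ValueError(f"need n' >= 2 nodes, got {n_prime}")
    return n_prime ** (n_prime - 2)
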