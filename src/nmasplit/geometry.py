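"""Treatment-network geometry: edges, designs, loops and split nodes.

The treatment network is the undirected graph whose vertices are treatments
and whose edges are observed head-to-head comparisons; each edge carries the
studies supporting it and each study belongs to exactly one *design* (the
sorted tuple of its treatments).  A t-arm study supports C(t, 2) edges.

Two structural questions drive eligibility and node selection:

* does the network contain a *valid* closed loop — one not informed
  exclusively by a single multi-arm design spanning the whole loop?  A
  triangle created solely by three-arm studies of one design carries no
  independent indirect evidence and cannot reveal inconsistency;
* which comparisons are *split nodes*, i.e. have direct evidence that can
  be severed from the network while an independent indirect path between
  the two treatments survives?

Split-node selection here severs the two-arm studies of the comparison;
multi-arm studies containing both treatments remain intact on the network
side (their internal contrast cannot be separated from the rest of the
study without losing identification of the indirect estimate).  A
comparison is therefore splittable iff at least one two-arm study compares
the pair head-to-head and the pair stays connected once all such studies
are removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

import networkx as nx

from .data import NMADataset

__all__ = [
    "TreatmentNetwork",
    "SplitNode",
    "build_network",
    "is_connected",
    "has_valid_loop",
    "enumerate_split_nodes",
    "network_summary_json",
]

Comparison = tuple[str, str]  # sorted treatment pair


@dataclass(frozen=True)
class SplitNode:
    """A comparison with direct evidence and an independent indirect path."""

    comparison: Comparison
    n_direct_studies: int
    single_study: bool

    def __post_init__(self) -> None:
        if self.n_direct_studies < 1:
            raise ValueError("a split node needs >= 1 direct study")
        if self.single_study != (self.n_direct_studies == 1):
            raise ValueError("single_study must equal (n_direct_studies == 1)")

    @property
    def label(self) -> str:
        return f"{self.comparison[0]} vs {self.comparison[1]}"


@dataclass(frozen=True)
class TreatmentNetwork:
    """Edges and designs of one treatment network (deterministic ordering)."""

    treatments: tuple[str, ...]
    edges: dict[Comparison, tuple[str, ...]]  # comparison -> supporting studies
    designs: dict[tuple[str, ...], tuple[str, ...]]  # design -> studies

    def graph(self) -> nx.Graph:
        """Simple undirected graph of observed comparisons."""
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        g.add_edges_from(self.edges)
        return g

    def design_of_study(self) -> dict[str, tuple[str, ...]]:
        return {s: d for d, studies in self.designs.items() for s in studies}


def build_network(ds: NMADataset) -> TreatmentNetwork:
    """Build the treatment network of a dataset."""
    designs: dict[tuple[str, ...], list[str]] = {}
    edges: dict[Comparison, list[str]] = {}
    for study, design in sorted(ds.study_treatments().items()):
        designs.setdefault(design, []).append(study)
        for pair in combinations(design, 2):
            edges.setdefault(pair, []).append(study)
    return TreatmentNetwork(
        treatments=tuple(ds.treatments),
        edges={k: tuple(v) for k, v in sorted(edges.items())},
        designs={k: tuple(v) for k, v in sorted(designs.items())},
    )


def is_connected(net: TreatmentNetwork) -> bool:
    """True iff the treatment graph has exactly one component."""
    g = net.graph()
    if g.number_of_nodes() == 0:
        return False
    return nx.is_connected(g)


def _cycles(g: nx.Graph, max_cycles: int = 10000) -> Iterator[list[str]]:
    """Chordless cycles of length >= 3 (treatment networks are small)."""
    for i, cyc in enumerate(nx.chordless_cycles(g)):
        if i >= max_cycles:  # pragma: no cover - safety valve
            break
        if len(cyc) >= 3:
            yield cyc


def has_valid_loop(net: TreatmentNetwork) -> bool:
    """True iff some closed loop is not informed by multi-arm studies only.

    A loop is invalid when every one of its edges is supported exclusively
    by studies of a single multi-arm design that contains the whole loop —
    the loop then restates one study's internal contrasts and carries no
    independent indirect evidence.
    """
    g = net.graph()
    design_of = net.design_of_study()
    for cyc in _cycles(g):
        loop = set(cyc)
        supporting_designs: set[tuple[str, ...]] = set()
        independent = False
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            pair = (a, b) if a <= b else (b, a)
            for study in net.edges[pair]:
                d = design_of[study]
                supporting_designs.add(d)
                if not loop.issubset(d):
                    independent = True
        if independent or len(supporting_designs) > 1:
            return True
    return False


def enumerate_split_nodes(net: TreatmentNetwork) -> list[SplitNode]:
    """Every comparison with severable direct and surviving indirect evidence.

    For each observed comparison (x, y): the direct evidence that can be
    severed is the set of two-arm x-y studies; the comparison is a split
    node iff that set is non-empty and x and y remain connected in the
    graph built from all remaining studies (so an independent indirect
    estimate exists and the network stays connected).  Deterministic order:
    sorted by comparison.
    """
    design_of = net.design_of_study()
    out: list[SplitNode] = []
    for pair, studies in net.edges.items():
        direct = [s for s in studies if len(design_of[s]) == 2]
        if not direct:
            continue
        removed = set(direct)
        g = nx.Graph()
        g.add_nodes_from(net.treatments)
        for other_pair, other_studies in net.edges.items():
            if any(s not in removed for s in other_studies):
                g.add_edge(*other_pair)
        # the x-y edge may survive through multi-arm studies, which stay
        # intact on the network side; the *indirect* path must not use it
        if g.has_edge(*pair):
            g.remove_edge(*pair)
        if nx.has_path(g, pair[0], pair[1]):
            out.append(
                SplitNode(
                    comparison=pair,
                    n_direct_studies=len(direct),
                    single_study=len(direct) == 1,
                )
            )
    return out


def network_summary_json(net: TreatmentNetwork) -> str:
    """JSON export of the network summary for the CLI describe command."""
    nodes = enumerate_split_nodes(net)
    return json.dumps(
        {
            "treatments": list(net.treatments),
            "n_treatments": len(net.treatments),
            "edges": [
                {
                    "comparison": list(pair),
                    "n_studies": len(studies),
                    "studies": list(studies),
                }
                for pair, studies in net.edges.items()
            ],
            "designs": [
                {"design": list(d), "studies": list(s)}
                for d, s in net.designs.items()
            ],
            "connected": is_connected(net),
            "has_valid_loop": has_valid_loop(net),
            "split_nodes": [
                {
                    "comparison": list(n.comparison),
                    "n_direct_studies": n.n_direct_studies,
                    "single_study": n.single_study,
                }
                for n in nodes
            ],
        },
        indent=2,
    )
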