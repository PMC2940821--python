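"""Cause-effect network assembly from per-protein Boolean tables.

Each table column translates into links by three rules: an all-``[0,0]``
column contributes nothing; an all-``[1,0]`` column contributes a direct
stimulus -> protein link; every ``[1,1]`` cell contributes a two-step link
stimulus -> inhibited protein -> measured protein (and suppresses the
direct link for that column).  Per-protein subnetworks are merged on shared
nodes; if the merged graph then connects a stimulus and a protein both
directly and through an inhibited node, the direct link is pruned and the
protein's table records the inhibitor as a mediator for prediction.

Links are ranked by ``k_upper``, the supremum of the significance
multiplier ``k`` at which the link is still supported: the stimulus flip
point for a direct link, the smaller of the stimulus and inhibitor flip
points for a mediated one.  Note the ``k_upper`` of a direct link bounds
the stimulus -> protein *connection*: below an inhibitor's flip point the
route refines into the mediated form rather than disappearing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain
from typing import Iterable, Mapping

import networkx as nx

from .boolean_inference import (
    BooleanTable,
    build_table,
    inhibitor_k_threshold,
    stimulus_k_threshold,
)
from .data_model import ErrorModel, PerturbationDataset

__all__ = [
    "ROLE_STIMULUS",
    "ROLE_INHIBITED",
    "ROLE_MEASURED",
    "SignalingNetwork",
    "RankedLink",
    "table_to_links",
    "merge_and_prune",
    "rank_links",
    "reconstruct",
    "ReconstructionResult",
    "link_support",
    "write_sif",
    "read_sif",
    "write_ranked_links",
]

ROLE_STIMULUS = "stimulus"
ROLE_INHIBITED = "inhibited_protein"
ROLE_MEASURED = "measured_protein"


def _graph_from_paths(paths) -> nx.DiGraph:
    graph = nx.DiGraph()
    for path in paths:
        if len(path) == 2:
            stim, protein = path
            graph.add_node(stim)
            graph.nodes[stim].setdefault("roles", set()).add(ROLE_STIMULUS)
            graph.add_node(protein)
            graph.nodes[protein].setdefault("roles", set()).add(ROLE_MEASURED)
            graph.add_edge(stim, protein)
        else:
            stim, mid, protein = path
            for node, role in ((stim, ROLE_STIMULUS), (mid, ROLE_INHIBITED), (protein, ROLE_MEASURED)):
                graph.add_node(node)
                graph.nodes[node].setdefault("roles", set()).add(role)
            graph.add_edge(stim, mid)
            graph.add_edge(mid, protein)
    return graph


@dataclass
class SignalingNetwork:
    """Directed stimulus / inhibited-protein / measured-protein graph.

    ``paths`` holds the supporting cause-effect links (2- or 3-node tuples);
    ``graph`` is their union as a :class:`networkx.DiGraph` with a ``roles``
    set on each node.  A node may be both inhibited and measured.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    paths: tuple = ()

    @classmethod
    def from_paths(cls, paths: Iterable[tuple]) -> "SignalingNetwork":
        paths = tuple(dict.fromkeys(tuple(p) for p in paths))
        return cls(_graph_from_paths(paths), paths)

    @property
    def edges(self) -> set:
        return set(self.graph.edges())

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def roles(self, node) -> set:
        return self.graph.nodes[node].get("roles", set())


@dataclass(frozen=True)
class RankedLink:
    """A network link with the upper-limit ``k`` that still supports it."""

    path: tuple
    k_upper: float

    def label(self) -> str:
        return "->".join(self.path)


def table_to_links(table: BooleanTable) -> list:
    """Translate one protein's Boolean table into cause-effect links."""
    links = []
    for stimulus in table.stimuli:
        if table.s(stimulus) == 0:
            continue
        mediated = [
            (stimulus, table.target_of(j), table.protein)
            for j in table.inhibitors
            if table.v(stimulus, j) == 1
        ]
        if mediated:
            links.extend(dict.fromkeys(mediated))
        else:
            links.append((stimulus, table.protein))
    return links


def merge_and_prune(
    subnetworks: Iterable[Iterable[tuple]],
    tables: Mapping[str, BooleanTable],
):
    """Merge per-protein link lists and prune redundant direct links.

    A direct stimulus -> protein link is removed whenever the merged graph
    also connects the pair through an inhibited node; the protein's table
    then records the corresponding inhibitor(s) under
    ``mediators_for_prediction`` so prediction uses the mediated route.
    Returns the pruned network and the updated tables.
    """
    all_paths = list(dict.fromkeys(chain.from_iterable(subnetworks)))
    merged = _graph_from_paths(all_paths)
    pruned = set()
    for path in all_paths:
        if len(path) != 2:
            continue
        stim, protein = path
        mediators = [
            q
            for q in merged.successors(stim)
            if ROLE_INHIBITED in merged.nodes[q].get("roles", set())
            and merged.has_edge(q, protein)
        ]
        if not mediators:
            continue
        pruned.add(path)
        table = tables.get(protein)
        if table is not None:
            for q in mediators:
                for j in table.inhibitors:
                    if table.target_of(j) == q:
                        table.mediators_for_prediction.setdefault(stim, set()).add(j)
    kept = [p for p in all_paths if p not in pruned]
    return SignalingNetwork.from_paths(kept), tables


def _path_k_upper(ds, model, path) -> float:
    if len(path) == 2:
        stim, protein = path
        return stimulus_k_threshold(ds, model, protein, stim)
    stim, mid, protein = path
    s_thr = stimulus_k_threshold(ds, model, protein, stim)
    candidates = [j for j in ds.inhibitors if ds.target_of(j) == mid]
    if not candidates:
        raise ValueError(f"no inhibitor targets node {mid!r}")
    i_thr = max(inhibitor_k_threshold(ds, model, protein, stim, j) for j in candidates)
    return min(s_thr, i_thr)


def rank_links(
    ds: PerturbationDataset,
    model: ErrorModel,
    tables: Mapping[str, BooleanTable],
    paths: Iterable[tuple] | None = None,
) -> list:
    """Rank links by ``k_upper``, descending; ties broken by path label."""
    if paths is None:
        paths = dict.fromkeys(chain.from_iterable(table_to_links(t) for t in tables.values()))
    links = [RankedLink(tuple(p), _path_k_upper(ds, model, tuple(p))) for p in paths]
    return sorted(links, key=lambda l: (-l.k_upper, l.label()))


def link_support(tables: Mapping[str, BooleanTable]) -> frozenset:
    """The set of significant effects the tables encode, nested in ``k``.

    ``(stimulus, None, protein)`` is present iff the stimulus significantly
    affects the protein (``s = 1``); ``(stimulus, inhibited_node, protein)``
    iff the inhibitor significantly blocks it (``v = 1``).  Unlike the
    direct/mediated route classification, this set only shrinks as ``k``
    grows.
    """
    support = set()
    for table in tables.values():
        for stimulus in table.stimuli:
            if table.s(stimulus) == 0:
                continue
            support.add((stimulus, None, table.protein))
            for j in table.inhibitors:
                if table.v(stimulus, j) == 1:
                    support.add((stimulus, table.target_of(j), table.protein))
    return frozenset(support)


@dataclass
class ReconstructionResult:
    """Output of :func:`reconstruct`.

    ``raw_paths`` is the pre-pruning union of per-protein links; ``network``
    and ``ranked_links`` reflect the pruned graph used for prediction.
    """

    tables: dict
    network: SignalingNetwork
    ranked_links: list
    raw_paths: tuple


def reconstruct(ds: PerturbationDataset, model: ErrorModel, k: float) -> ReconstructionResult:
    """Full network reconstruction at significance level ``k``."""
    if not k > 0:
        raise ValueError("k must be > 0")
    tables = {p: build_table(ds, model, p, k) for p in ds.proteins}
    subnetworks = [table_to_links(tables[p]) for p in ds.proteins]
    raw_paths = tuple(dict.fromkeys(chain.from_iterable(subnetworks)))
    network, tables = merge_and_prune(subnetworks, tables)
    ranked = rank_links(ds, model, tables, paths=network.paths)
    return ReconstructionResult(tables, network, ranked, raw_paths)


def write_sif(net: SignalingNetwork, path) -> None:
    """Write the network as SIF: one ``source 1 target`` line per edge."""
    with open(path, "w") as fh:
        for source, target in sorted(net.edges):
            fh.write(f"{source} 1 {target}\n")


def read_sif(path) -> set:
    """Read a SIF file back as a set of (source, target) edges."""
    edges = set()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            edges.add((parts[0], parts[2]))
    return edges


def write_ranked_links(links, path, canonical: Iterable[tuple] | None = None) -> None:
    """Write ranked links as CSV (optionally annotated against a canonical set)."""
    canon = {tuple(p) for p in canonical} if canonical is not None else None
    with open(path, "w") as fh:
        header = "path,k_upper" + (",in_canonical" if canon is not None else "")
        fh.write(header + "\n")
        for link in links:
            row = f"{link.label()},{link.k_upper:.6g}"
            if canon is not None:
                row += f",{'yes' if link.path in canon else 'no'}"
            fh.write(row + "\n")
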