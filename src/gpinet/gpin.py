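"""Signed gene–phenotype interaction networks from posterior summaries.

A learned posterior gives every ordered node pair a linkage probability
and a sign probability.  Thresholding these yields the interaction
network reported to the analyst: "up" edges pass a stringent probability
threshold (default 0.995) with a predominantly positive coefficient,
"down" edges pass a separate threshold (default 0.47) with a
predominantly negative one.  The asymmetric defaults mirror the study
protocol; both are configurable because the protocol gives ranges, not a
tuning rule.  This module also diffs treatment networks against a
control and reports topology (root nodes, hubs, components, and the
phenotype-only subnetwork).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .bayesnet import PosteriorSummary
from .datamodel import NodeDescriptor

__all__ = [
    "GPINEdge",
    "GPINetwork",
    "NetworkDiff",
    "TopologyReport",
    "extract_network",
    "diff_networks",
    "topology_report",
    "to_edge_list_tsv",
    "read_edge_list_tsv",
    "to_graphml",
    "to_dot",
    "diff_to_text",
    "diff_to_tsv",
]

SIGNS = ("up", "down")


@dataclass(frozen=True)
class GPINEdge:
    parent: str
    child: str
    sign: str
    probability: float
    beta_mean: float

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValueError(f"edge sign must be one of {SIGNS}, got {self.sign!r}")
        if self.parent == self.child:
            raise ValueError("self-edges are not allowed")


@dataclass
class GPINetwork:
    """Thresholded signed directed network over gene/phenotype/dose nodes."""

    nodes: list[NodeDescriptor]
    edges: list[GPINEdge]
    up_threshold: float
    down_threshold: float
    sign_cut: float = 0.5

    def __post_init__(self) -> None:
        pairs = [(e.parent, e.child) for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("at most one edge per ordered node pair")
        names = {n.name for n in self.nodes}
        for e in self.edges:
            if e.parent not in names or e.child not in names:
                raise ValueError(f"edge {e.parent}->{e.child} references unknown node")

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def edge_map(self) -> dict[tuple[str, str], GPINEdge]:
        return {(e.parent, e.child): e for e in self.edges}

    def degree(self) -> dict[str, int]:
        deg = {n.name: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.parent] += 1
            deg[e.child] += 1
        return deg

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph(edge_direction="parent->child")
        for n in self.nodes:
            g.add_node(n.name, kind=n.kind)
        for e in self.edges:
            g.add_edge(
                e.parent,
                e.child,
                sign=e.sign,
                probability=float(e.probability),
                beta_mean=float(e.beta_mean),
            )
        return g


def extract_network(
    posterior: PosteriorSummary,
    up_threshold: float = 0.995,
    down_threshold: float = 0.47,
    sign_cut: float = 0.5,
) -> GPINetwork:
    """Threshold posterior edge marginals into a signed network.

    Edge i→j enters as "down" when ``edge_prob >= down_threshold`` and
    ``neg_prob >= sign_cut``, as "up" when ``edge_prob >= up_threshold``
    and ``neg_prob < sign_cut``; otherwise it is absent.  Deterministic.
    """
    for name, v in (
        ("up_threshold", up_threshold),
        ("down_threshold", down_threshold),
        ("sign_cut", sign_cut),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    names = posterior.node_names
    P = len(names)
    edges: list[GPINEdge] = []
    for i in range(P):
        for j in range(P):
            if i == j:
                continue
            prob = float(posterior.edge_prob[i, j])
            negp = float(posterior.neg_prob[i, j])
            if negp >= sign_cut:
                if prob >= down_threshold:
                    edges.append(
                        GPINEdge(names[i], names[j], "down", prob,
                                 float(posterior.beta_mean[i, j]))
                    )
            elif prob >= up_threshold:
                edges.append(
                    GPINEdge(names[i], names[j], "up", prob,
                             float(posterior.beta_mean[i, j]))
                )
    return GPINetwork(
        nodes=list(posterior.nodes),
        edges=edges,
        up_threshold=up_threshold,
        down_threshold=down_threshold,
        sign_cut=sign_cut,
    )


@dataclass
class NetworkDiff:
    """Edge-level differences between two networks on identical nodes."""

    edges_gained: list[GPINEdge] = field(default_factory=list)
    edges_lost: list[GPINEdge] = field(default_factory=list)
    sign_flips: list[tuple[GPINEdge, GPINEdge]] = field(default_factory=list)
    nodes_disconnected_in_a: list[str] = field(default_factory=list)
    nodes_disconnected_in_b: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.edges_gained or self.edges_lost or self.sign_flips)


def diff_networks(a: GPINetwork, b: GPINetwork) -> NetworkDiff:
    """Classify every ordered pair as gained / lost / sign-flipped / unchanged.

    ``edges_gained`` are present in ``b`` only, ``edges_lost`` in ``a``
    only; ``sign_flips`` pairs the two conflicting edges.  Also lists
    nodes with zero degree in each network (the "dropped out of the
    network" view used when comparing treatments against control).
    """
    if a.node_names != b.node_names:
        raise ValueError("networks have different node lists")
    ea, eb = a.edge_map(), b.edge_map()
    diff = NetworkDiff()
    for pair in sorted(set(ea) | set(eb)):
        in_a, in_b = pair in ea, pair in eb
        if in_a and in_b:
            if ea[pair].sign != eb[pair].sign:
                diff.sign_flips.append((ea[pair], eb[pair]))
        elif in_b:
            diff.edges_gained.append(eb[pair])
        else:
            diff.edges_lost.append(ea[pair])
    deg_a, deg_b = a.degree(), b.degree()
    diff.nodes_disconnected_in_a = [n for n in a.node_names if deg_a[n] == 0]
    diff.nodes_disconnected_in_b = [n for n in b.node_names if deg_b[n] == 0]
    return diff


@dataclass
class TopologyReport:
    """Roots, hubs and connectivity of a signed network.

    ``roots`` (in-degree 0, out-degree > 0) are the candidate top-of-
    network drivers; the phenotype-only subnetwork is summarized
    separately because the morphology-parameter hierarchy (which
    parameter sits on top and controls the others) is itself a readout.
    """

    roots: list[str]
    hub_scores: dict[str, int]
    components: list[list[str]]
    phenotype_roots: list[str]
    phenotype_edges: list[GPINEdge]

    @property
    def top_hub(self) -> str | None:
        if not self.hub_scores or max(self.hub_scores.values()) == 0:
            return None
        return max(self.hub_scores, key=lambda n: (self.hub_scores[n], n))


def topology_report(net: GPINetwork) -> TopologyReport:
    g = net.to_digraph()
    roots = sorted(
        n for n in g.nodes if g.in_degree(n) == 0 and g.out_degree(n) > 0
    )
    hub_scores = {n: int(g.in_degree(n) + g.out_degree(n)) for n in g.nodes}
    components = [sorted(c) for c in nx.weakly_connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))
    pheno = {n.name for n in net.nodes if n.kind == "phenotype"}
    pheno_edges = [e for e in net.edges if e.parent in pheno and e.child in pheno]
    child_set = {e.child for e in pheno_edges}
    parent_set = {e.parent for e in pheno_edges}
    phenotype_roots = sorted(parent_set - child_set)
    return TopologyReport(
        roots=roots,
        hub_scores=hub_scores,
        components=components,
        phenotype_roots=phenotype_roots,
        phenotype_edges=pheno_edges,
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

_EDGE_HEADER = "parent\tchild\tsign\tprobability\tbeta_mean"


def to_edge_list_tsv(net: GPINetwork, path) -> None:
    """Plain TSV edge list; direction is parent → child."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# edge direction: parent -> child\n")
        fh.write(
            f"# thresholds: up={net.up_threshold!r} down={net.down_threshold!r} "
            f"sign_cut={net.sign_cut!r}\n"
        )
        fh.write(_EDGE_HEADER + "\n")
        for e in sorted(net.edges, key=lambda e: (e.parent, e.child)):
            fh.write(
                f"{e.parent}\t{e.child}\t{e.sign}\t{e.probability!r}\t{e.beta_mean!r}\n"
            )


def read_edge_list_tsv(path, nodes: list[NodeDescriptor],
                       up_threshold: float = 0.0, down_threshold: float = 0.0,
                       sign_cut: float = 0.5) -> GPINetwork:
    edges: list[GPINEdge] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("parent\t"):
                continue
            parent, child, sign, prob, beta = line.split("\t")
            edges.append(GPINEdge(parent, child, sign, float(prob), float(beta)))
    return GPINetwork(list(nodes), edges, up_threshold, down_threshold, sign_cut)


def to_graphml(net: GPINetwork, path) -> None:
    nx.write_graphml(net.to_digraph(), path)


def to_dot(net: GPINetwork, path=None) -> str:
    """Graphviz DOT text; solid arrows for up edges, dashed for down."""
    lines = ["digraph GPIN {", '  // edge direction: parent -> child']
    for n in net.nodes:
        shape = {"gene": "ellipse", "phenotype": "box", "dose": "diamond"}[n.kind]
        lines.append(f'  "{n.name}" [shape={shape}, kind="{n.kind}"];')
    for e in sorted(net.edges, key=lambda e: (e.parent, e.child)):
        style = "solid" if e.sign == "up" else "dashed"
        lines.append(
            f'  "{e.parent}" -> "{e.child}" [style={style}, sign="{e.sign}", '
            f'probability="{e.probability:.6g}", beta_mean="{e.beta_mean:.6g}"];'
        )
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def diff_to_tsv(diff: NetworkDiff, path) -> None:
    """Machine-readable diff: one row per changed edge or dropped node."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("change\tparent\tchild\tsign_a\tsign_b\n")
        for e in diff.edges_gained:
            fh.write(f"gained\t{e.parent}\t{e.child}\t\t{e.sign}\n")
        for e in diff.edges_lost:
            fh.write(f"lost\t{e.parent}\t{e.child}\t{e.sign}\t\n")
        for ea, eb in diff.sign_flips:
            fh.write(f"sign_flip\t{ea.parent}\t{ea.child}\t{ea.sign}\t{eb.sign}\n")
        for n in diff.nodes_disconnected_in_a:
            fh.write(f"disconnected_in_a\t{n}\t\t\t\n")
        for n in diff.nodes_disconnected_in_b:
            fh.write(f"disconnected_in_b\t{n}\t\t\t\n")


def diff_to_text(diff: NetworkDiff, label_a: str = "a", label_b: str = "b") -> str:
    """Human-readable diff summary (b relative to a)."""
    out = [f"network diff: {label_b} vs {label_a}"]
    out.append(f"  edges gained in {label_b}: {len(diff.edges_gained)}")
    for e in diff.edges_gained:
        out.append(f"    + {e.parent} -> {e.child} ({e.sign}, p={e.probability:.3f})")
    out.append(f"  edges lost from {label_a}: {len(diff.edges_lost)}")
    for e in diff.edges_lost:
        out.append(f"    - {e.parent} -> {e.child} ({e.sign}, p={e.probability:.3f})")
    out.append(f"  sign flips: {len(diff.sign_flips)}")
    for ea, eb in diff.sign_flips:
        out.append(f"    ~ {ea.parent} -> {ea.child}: {ea.sign} => {eb.sign}")
    out.append(
        f"  disconnected nodes in {label_a}: "
        + (", ".join(diff.nodes_disconnected_in_a) or "none")
    )
    out.append(
        f"  disconnected nodes in {label_b}: "
        + (", ".join(diff.nodes_disconnected_in_b) or "none")
    )
    return "\n".join(out) + "\n"
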