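"""Network assembly from thresholded MI matrices.

An edge is retained exactly when its MI coefficient strictly exceeds the
calibrated threshold I0; edge weight is the MI value in nats.  Networks
carry node roles (input/output), per-node and per-edge dataset provenance
(so two condition-specific networks can be combined into one system-wide
network with "both"-tagged shared components), and the calibration
metadata (h, I0, p-value) needed to audit every edge.

MI is symmetric, so edges are undirected; the input -> output reading is a
labeling convention, not an inferred direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .kde import Bandwidth, select_bandwidth
from .mi import MIMatrix, compute_mim
from .sample import SampleMatrix
from .threshold import calibrate_threshold


@dataclass
class Node:
    name: str
    role: str  # "input" | "output"
    provenance: str  # dataset label, "both", or "none" (isolated)


@dataclass
class Edge:
    source: str
    target: str
    weight: float  # MI in nats (max across datasets after combination)
    provenance: str  # dataset label or "both"
    weights: dict[str, float] = field(default_factory=dict)  # label -> MI

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.source, self.target)))  # type: ignore[return-value]


@dataclass
class Network:
    nodes: list[Node]
    edges: list[Edge]
    mode: str  # "bipartite" | "full"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = {n.name for n in self.nodes}
        for e in self.edges:
            if e.source not in names or e.target not in names:
                raise InvalidInputError(
                    f"edge ({e.source}, {e.target}) references unknown node"
                )
            if e.source == e.target:
                raise InvalidInputError(f"self-edge on {e.source}")
        keys = [e.key() for e in self.edges]
        if len(set(keys)) != len(keys):
            raise InvalidInputError("duplicate edges")

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def edge_set(self) -> set[tuple[str, str]]:
        return {e.key() for e in self.edges}

    def degree(self, name: str) -> int:
        return sum(1 for e in self.edges if name in (e.source, e.target))


def reconstruct(
    mim: MIMatrix,
    threshold: float,
    dataset_label: str | None = None,
    include_output_output: bool = False,
) -> Network:
    """Keep exactly the MI entries strictly greater than ``threshold``.

    Isolated variables stay in the node list with provenance ``"none"``.
    In full mode, output-output pairs are computed in the MIM but excluded
    from the reconstructed network by default (the reconstruction is
    input-centric); pass ``include_output_output=True`` to keep them.
    """
    if threshold <= 0:
        raise InvalidParameterError(f"threshold must be positive, got {threshold}")
    label = mim.dataset_label if dataset_label is None else dataset_label

    roles = dict(mim.roles)
    if mim.mode == "bipartite":
        roles.update({r: roles.get(r, "input") for r in mim.row_names})
        roles.update({c: roles.get(c, "output") for c in mim.col_names})

    edges: list[Edge] = []
    for r, c, v in mim.entries():
        if v <= threshold:  # strict inequality for retention; ties discarded
            continue
        if (
            mim.mode == "full"
            and not include_output_output
            and roles.get(r) == "output"
            and roles.get(c) == "output"
        ):
            continue
        edges.append(Edge(source=r, target=c, weight=v, provenance=label,
                          weights={label: v}))

    connected = {n for e in edges for n in (e.source, e.target)}
    all_names = list(dict.fromkeys(mim.row_names + mim.col_names))
    nodes = [
        Node(name=n, role=roles.get(n, "input"),
             provenance=label if n in connected else "none")
        for n in all_names
    ]
    return Network(
        nodes=nodes,
        edges=edges,
        mode=mim.mode,
        metadata={
            "h": mim.bandwidth,
            "threshold": float(threshold),
            "dataset_label": label,
            "n_observations": mim.n_observations,
        },
    )


def combine_networks(
    net_a: Network, net_b: Network, labels: tuple[str, str] | None = None
) -> Network:
    """Edge union of two dataset-specific networks with provenance tags.

    A node carrying edges in both inputs becomes ``"both"``; an edge found
    in both keeps both MI weights (its scalar weight is their maximum).
    Commutative up to label swap and idempotent.
    """
    if net_a.mode != net_b.mode:
        raise InvalidInputError(
            f"cannot combine networks of modes {net_a.mode!r} and {net_b.mode!r}"
        )
    if labels is None:
        labels = (
            net_a.metadata.get("dataset_label", "A"),
            net_b.metadata.get("dataset_label", "B"),
        )
    roles: dict[str, str] = {}
    for net in (net_a, net_b):
        for n in net.nodes:
            if n.name in roles and roles[n.name] != n.role:
                raise InvalidInputError(
                    f"conflicting roles for node {n.name!r}: "
                    f"{roles[n.name]!r} vs {n.role!r}"
                )
            roles[n.name] = n.role

    merged: dict[tuple[str, str], Edge] = {}
    for net, label in ((net_a, labels[0]), (net_b, labels[1])):
        for e in net.edges:
            w = dict(e.weights) if e.weights else {label: e.weight}
            if e.key() in merged:
                prev = merged[e.key()]
                weights = {**prev.weights, **w}
                merged[e.key()] = replace(
                    prev,
                    weight=max(weights.values()),
                    provenance="both" if len(weights) > 1 else prev.provenance,
                    weights=weights,
                )
            else:
                merged[e.key()] = replace(e, provenance=label, weights=w)

    conn_a = {n for e in net_a.edges for n in (e.source, e.target)}
    conn_b = {n for e in net_b.edges for n in (e.source, e.target)}
    order = list(dict.fromkeys(net_a.node_names + net_b.node_names))
    nodes = []
    for name in order:
        if name in conn_a and name in conn_b:
            prov = "both"
        elif name in conn_a:
            prov = labels[0]
        elif name in conn_b:
            prov = labels[1]
        else:
            prov = "none"
        nodes.append(Node(name=name, role=roles[name], provenance=prov))

    return Network(
        nodes=nodes,
        edges=list(merged.values()),
        mode=net_a.mode,
        metadata={
            "combined_from": list(labels),
            "per_dataset": {
                labels[0]: dict(net_a.metadata),
                labels[1]: dict(net_b.metadata),
            },
        },
    )


def union_networks(nets: list[Network]) -> Network:
    """Plain edge union of networks sharing one dataset label.

    Used to merge per-output star networks from node-by-node
    reconstruction; edge weights and provenance are kept as-is (an edge
    appearing twice keeps its larger weight).
    """
    if not nets:
        raise InvalidInputError("no networks to union")
    roles: dict[str, str] = {}
    merged: dict[tuple[str, str], Edge] = {}
    order: list[str] = []
    for net in nets:
        for n in net.nodes:
            if n.name not in roles:
                order.append(n.name)
                roles[n.name] = n.role
            elif roles[n.name] != n.role:
                raise InvalidInputError(f"conflicting roles for node {n.name!r}")
        for e in net.edges:
            if e.key() not in merged or e.weight > merged[e.key()].weight:
                merged[e.key()] = e
    connected = {n for e in merged.values() for n in (e.source, e.target)}
    label = nets[0].metadata.get("dataset_label", "")
    nodes = [
        Node(name=n, role=roles[n], provenance=label if n in connected else "none")
        for n in order
    ]
    meta = {"dataset_label": label, "union_of": [n.metadata for n in nets]}
    return Network(nodes=nodes, edges=list(merged.values()), mode=nets[0].mode,
                   metadata=meta)


def node_by_node(
    data: SampleMatrix,
    output_name: str,
    h: float | Bandwidth | None = None,
    p_value: float = 0.005,
    n_permutations: int = 100,
    seed: int = 0,
) -> Network:
    """Reconstruct one output's star network with its own recalibrated threshold.

    The MI matrix and the permutation null are both restricted to the
    single output column; the large-deviation fit and the p-value inversion
    are redone on that restricted null.  The union of these star networks
    over all outputs approximates the jointly calibrated network, differing
    only for edges whose MI sits within calibration noise of I0.
    """
    if output_name not in data.output_names:
        raise InvalidInputError(f"unknown output variable: {output_name!r}")
    sub = data.subset(data.input_names + [output_name])
    if h is None:
        h = select_bandwidth(sub, seed=seed, mode="bipartite")
    mim = compute_mim(sub, mode="bipartite", h=h)
    fit, i0 = calibrate_threshold(
        sub, mode="bipartite", h=h, p_value=p_value,
        n_permutations=n_permutations, seed=seed,
    )
    net = reconstruct(mim, i0)
    net.metadata.update({"p_value": p_value, "output": output_name,
                         "null_fit": fit.to_dict()})
    return net


def node_by_node_union(
    data: SampleMatrix,
    h: float | Bandwidth | None = None,
    p_value: float = 0.005,
    n_permutations: int = 100,
    seed: int = 0,
) -> Network:
    """Union of the per-output star networks over every output variable."""
    nets = [
        node_by_node(data, out, h=h, p_value=p_value,
                     n_permutations=n_permutations, seed=seed)
        for out in data.output_names
    ]
    return union_networks(nets)


def rank_edges(net: Network) -> list[Edge]:
    """Edges by descending MI weight; ties broken by (source, target) names."""
    if not net.edges:
        raise InvalidInputError("cannot rank edges of an edgeless network")
    return sorted(net.edges, key=lambda e: (-e.weight, e.source, e.target))


# -- export / import ------------------------------------------------------


def to_networkx(net: Network):
    """Undirected networkx graph with role/provenance/weight attributes."""
    import networkx as nx

    g = nx.Graph()
    for n in net.nodes:
        g.add_node(n.name, role=n.role, provenance=n.provenance)
    for e in net.edges:
        attrs = {"weight": e.weight, "provenance": e.provenance}
        for label, w in e.weights.items():
            attrs[f"mi_{label}"] = w
        g.add_edge(e.source, e.target, **attrs)
    for k, v in net.metadata.items():
        if isinstance(v, (str, int, float, bool)):
            g.graph[k] = v
    return g


def write_graphml(net: Network, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), path)


def write_edgelist_tsv(net: Network, path) -> None:
    """Three-column TSV (source, target, mi_nats), rank order, deterministic."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tmi_nats\n")
        for e in (rank_edges(net) if net.edges else []):
            fh.write(f"{e.source}\t{e.target}\t{e.weight:.10g}\n")


def read_edgelist_tsv(path, mode: str = "bipartite", dataset_label: str = "") -> Network:
    """Read a 3-column edge list back into a Network (roles inferred bipartite)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    expected = ["source", "target", "mi_nats"]
    if list(df.columns) != expected:
        raise InvalidInputError(f"edge list must have columns {expected}")
    edges = [
        Edge(source=str(r.source), target=str(r.target), weight=float(r.mi_nats),
             provenance=dataset_label, weights={dataset_label: float(r.mi_nats)})
        for r in df.itertuples()
    ]
    sources = list(dict.fromkeys(e.source for e in edges))
    targets = list(dict.fromkeys(e.target for e in edges))
    nodes = [Node(name=s, role="input", provenance=dataset_label) for s in sources]
    nodes += [Node(name=t, role="output", provenance=dataset_label)
              for t in targets if t not in sources]
    return Network(nodes=nodes, edges=edges, mode=mode,
                   metadata={"dataset_label": dataset_label})
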