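"""Network assembly, combination, node-by-node reconstruction, export."""

import numpy as np
import pytest

from minet import (
    Edge,
    InvalidInputError,
    MIMatrix,
    Network,
    Node,
    combine_networks,
    compute_mim,
    node_by_node,
    rank_edges,
    read_edgelist_tsv,
    reconstruct,
    union_networks,
    write_edgelist_tsv,
    write_graphml,
)


def bip_mim(values, rows, cols, roles=None):
    roles = roles or {**{r: "input" for r in rows}, **{c: "output" for c in cols}}
    return MIMatrix(values=np.asarray(values, float), row_names=rows,
                    col_names=cols, mode="bipartite", bandwidth=0.3,
                    n_observations=50, roles=roles, dataset_label="D")


def test_reconstruct_strict_filter():
    mim = bip_mim([[0.3, 0.1]], ["P0"], ["C0", "C1"])
    net = reconstruct(mim, 0.2)
    assert len(net.edges) == 1
    assert net.edges[0].weight == pytest.approx(0.3)
    assert net.edges[0].provenance == "D"
    # isolated node kept with provenance none
    provs = {n.name: n.provenance for n in net.nodes}
    assert provs == {"P0": "D", "C0": "D", "C1": "none"}


def test_reconstruct_boundary_tie_is_discarded():
    mim = bip_mim([[0.2]], ["P0"], ["C0"])
    assert reconstruct(mim, 0.2).edges == []


def test_reconstruct_edgeless_when_threshold_above_max():
    mim = bip_mim([[0.3, 0.1]], ["P0"], ["C0", "C1"])
    net = reconstruct(mim, 0.5)
    assert net.edges == []
    assert all(n.provenance == "none" for n in net.nodes)


def test_reconstruct_edge_count_monotone_in_threshold():
    rng = np.random.default_rng(0)
    mim = bip_mim(rng.uniform(0, 0.5, size=(6, 4)),
                  [f"P{i}" for i in range(6)], [f"C{j}" for j in range(4)])
    counts = [len(reconstruct(mim, t).edges) for t in np.linspace(0.01, 0.5, 20)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_reconstruct_full_mode_drops_output_output_by_default():
    names = ["P0", "P1", "C0", "C1"]
    roles = {"P0": "input", "P1": "input", "C0": "output", "C1": "output"}
    vals = np.full((4, 4), 0.5)
    np.fill_diagonal(vals, np.nan)
    mim = MIMatrix(values=vals, row_names=names, col_names=names, mode="full",
                   bandwidth=0.3, n_observations=50, roles=roles,
                   dataset_label="D")
    net = reconstruct(mim, 0.1)
    kinds = {tuple(sorted((roles[e.source], roles[e.target]))) for e in net.edges}
    assert ("output", "output") not in kinds
    assert len(net.edges) == 5  # 1 input-input + 4 input-output
    net_all = reconstruct(mim, 0.1, include_output_output=True)
    assert len(net_all.edges) == 6


def test_combine_disjoint_union_and_provenance():
    a = reconstruct(bip_mim([[0.3, 0.0], [0.0, 0.0]], ["P0", "P1"],
                            ["C0", "C1"]), 0.2, dataset_label="A")
    b = reconstruct(bip_mim([[0.0, 0.0], [0.0, 0.4]], ["P0", "P1"],
                            ["C0", "C1"]), 0.2, dataset_label="B")
    comb = combine_networks(a, b, labels=("A", "B"))
    assert len(comb.edges) == 2
    provs = {n.name: n.provenance for n in comb.nodes}
    assert provs["P0"] == "A" and provs["P1"] == "B"


def test_combine_identical_networks_is_idempotent():
    net = reconstruct(bip_mim([[0.3, 0.25]], ["P0"], ["C0", "C1"]), 0.2,
                      dataset_label="A")
    comb = combine_networks(net, net, labels=("A", "A"))
    assert comb.edge_set() == net.edge_set()
    assert {e.key(): e.weight for e in comb.edges} == \
           {e.key(): pytest.approx(e.weight) for e in net.edges}


def test_combine_shared_edge_keeps_both_weights():
    a = reconstruct(bip_mim([[0.30]], ["P0"], ["C0"]), 0.2, dataset_label="A")
    b = reconstruct(bip_mim([[0.45]], ["P0"], ["C0"]), 0.2, dataset_label="B")
    comb = combine_networks(a, b)
    assert len(comb.edges) == 1
    e = comb.edges[0]
    assert e.provenance == "both"
    assert e.weights == {"A": pytest.approx(0.30), "B": pytest.approx(0.45)}
    assert e.weight == pytest.approx(0.45)
    assert all(n.provenance == "both" for n in comb.nodes)


def test_combine_commutative_up_to_labels():
    a = reconstruct(bip_mim([[0.3, 0.0]], ["P0"], ["C0", "C1"]), 0.2,
                    dataset_label="A")
    b = reconstruct(bip_mim([[0.0, 0.4]], ["P0"], ["C0", "C1"]), 0.2,
                    dataset_label="B")
    ab = combine_networks(a, b)
    ba = combine_networks(b, a)
    assert ab.edge_set() == ba.edge_set()
    assert {n.name: n.provenance for n in ab.nodes} == \
           {n.name: n.provenance for n in ba.nodes}


def test_combine_conflicting_roles_rejected():
    n1 = Network(nodes=[Node("X", "input", "A")], edges=[], mode="bipartite",
                 metadata={"dataset_label": "A"})
    n2 = Network(nodes=[Node("X", "output", "B")], edges=[], mode="bipartite",
                 metadata={"dataset_label": "B"})
    with pytest.raises(InvalidInputError):
        combine_networks(n1, n2)


def test_rank_edges_orders_and_breaks_ties():
    nodes = [Node(n, "input", "D") for n in "abcd"] + [Node("z", "output", "D")]
    edges = [Edge("b", "z", 0.3, "D", {"D": 0.3}),
             Edge("a", "z", 0.5, "D", {"D": 0.5}),
             Edge("c", "z", 0.4, "D", {"D": 0.4}),
             Edge("d", "z", 0.4, "D", {"D": 0.4})]
    net = Network(nodes=nodes, edges=edges, mode="bipartite", metadata={})
    ranked = rank_edges(net)
    assert [e.weight for e in ranked] == [0.5, 0.4, 0.4, 0.3]
    assert [e.source for e in ranked[1:3]] == ["c", "d"]  # lexicographic tie-break


def test_network_invariants_enforced():
    with pytest.raises(InvalidInputError):
        Network(nodes=[Node("a", "input", "D")],
                edges=[Edge("a", "b", 0.1, "D", {})], mode="bipartite",
                metadata={})
    with pytest.raises(InvalidInputError):
        Network(nodes=[Node("a", "input", "D")],
                edges=[Edge("a", "a", 0.1, "D", {})], mode="bipartite",
                metadata={})


def test_every_edge_exceeds_recorded_threshold(small_pipeline_result):
    res = small_pipeline_result
    i0 = res.network.metadata["threshold"]
    assert all(e.weight > i0 for e in res.network.edges)


def test_node_by_node_single_output_equals_joint(small_planted):
    """With a single output the restricted and joint calibrations coincide."""
    _, data, _ = small_planted
    sub = data.subset(data.input_names + ["C0"])
    from minet import calibrate_threshold

    h = 0.3
    star = node_by_node(sub, "C0", h=h, n_permutations=30, seed=2)
    mim = compute_mim(sub, h=h)
    _, i0 = calibrate_threshold(sub, h=h, n_permutations=30, seed=2)
    joint = reconstruct(mim, i0)
    assert star.edge_set() == joint.edge_set()


def test_node_by_node_unknown_output(small_planted):
    _, data, _ = small_planted
    with pytest.raises(InvalidInputError):
        node_by_node(data, "nope", h=0.3)


def test_node_by_node_union_close_to_joint(small_pipeline_result, small_planted):
    """Per-output recalibration only moves edges near the joint threshold."""
    from minet import node_by_node_union

    _, data, _ = small_planted
    res = small_pipeline_result
    union = node_by_node_union(data, h=res.bandwidth, n_permutations=40, seed=5)
    mim = res.mim
    idx = {(r, c): v for r, c, v in mim.entries()}
    i0 = res.threshold
    for key in union.edge_set() ^ res.network.edge_set():
        a, b = key
        mi = idx.get((a, b), idx.get((b, a)))
        assert abs(mi - i0) < 0.35 * i0  # disagreements hug the threshold


def test_graphml_and_edgelist_roundtrip(tmp_path, small_pipeline_result):
    net = small_pipeline_result.network
    gpath = tmp_path / "net.graphml"
    write_graphml(net, gpath)
    import networkx as nx

    g = nx.read_graphml(gpath)
    assert set(g.nodes) == set(net.node_names)
    assert g.number_of_edges() == len(net.edges)
    roles = nx.get_node_attributes(g, "role")
    assert roles[net.nodes[0].name] == net.nodes[0].role

    epath = tmp_path / "edges.tsv"
    write_edgelist_tsv(net, epath)
    back = read_edgelist_tsv(epath, dataset_label="planted")
    assert back.edge_set() == net.edge_set()
    w_orig = {e.key(): e.weight for e in net.edges}
    for e in back.edges:
        assert e.weight == pytest.approx(w_orig[e.key()], rel=1e-9)


def test_union_networks_merges_stars():
    a = reconstruct(bip_mim([[0.3, 0.0]], ["P0"], ["C0", "C1"]), 0.2)
    b = reconstruct(bip_mim([[0.0, 0.4]], ["P0"], ["C0", "C1"]), 0.2)
    u = union_networks([a, b])
    assert len(u.edges) == 2
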