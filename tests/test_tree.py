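"""MST pocketome: optimality, annotation, homogeneity and export."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ppi_pocketome import (
    DescriptorSampleSpec,
    annotate_tree,
    branch_homogeneity,
    export_tree,
    exposure,
    make_descriptor_sample,
    minimum_spanning_tree,
    pairwise_distances,
    read_graphml,
)
from ppi_pocketome.psi import DistanceMatrix


def _dist_from_matrix(d):
    d = np.asarray(d, float)
    ids = [f"p{i}" for i in range(len(d))]
    tri = d[np.triu_indices(len(d), k=1)]
    sigma = float(tri.std(ddof=0)) if len(tri) > 1 else float(tri[0])
    return DistanceMatrix(pocket_ids=ids, d=d, sigma=max(sigma, 1e-9))


def test_triangle_keeps_two_smallest_edges():
    d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
    tree = minimum_spanning_tree(_dist_from_matrix(d))
    assert tree.total_weight == pytest.approx(3.0)
    assert tree.graph.number_of_edges() == 2
    assert not tree.graph.has_edge("p0", "p2")


def test_two_nodes_single_edge():
    tree = minimum_spanning_tree(_dist_from_matrix([[0.0, 2.5], [2.5, 0.0]]))
    assert tree.graph.number_of_edges() == 1
    assert tree.total_weight == pytest.approx(2.5)


def test_edge_psi_is_consistent_with_sigma():
    d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
    dist = _dist_from_matrix(d)
    tree = minimum_spanning_tree(dist)
    for _, _, attrs in tree.graph.edges(data=True):
        expected = np.exp(-attrs["distance"] ** 2 / (2 * dist.sigma**2))
        assert attrs["psi"] == pytest.approx(expected, abs=1e-12)


def test_rejects_non_finite_distances():
    d = np.array([[0.0, np.inf], [np.inf, 0.0]])
    with pytest.raises(ValueError, match="finite"):
        minimum_spanning_tree(_dist_from_matrix(d))


def _random_spanning_tree_weight(d, rng):
    """Weight of a uniformly random spanning tree via a random Pruefer seq."""
    n = len(d)
    seq = rng.integers(0, n, size=n - 2)
    return sum(d[u, v] for u, v in _edges_from_pruefer(tuple(seq), n))


def _edges_from_pruefer(seq, n):
    """Decode a Pruefer sequence into the edges of its labeled tree."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    for x in seq:
        leaf = leaves.pop(0)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            import bisect
            bisect.insort(leaves, x)
    edges.append((leaves[0], leaves[1]))
    return edges


def test_mst_beats_random_spanning_trees(rng):
    x = rng.normal(size=(12, 4))
    dist = pairwise_distances(x)
    tree = minimum_spanning_tree(dist)
    for _ in range(1000):
        assert tree.total_weight <= \
            _random_spanning_tree_weight(dist.d, rng) + 1e-9


def test_mst_invariant_to_row_permutation(rng):
    x = rng.normal(size=(10, 3))
    ids = [f"pk{i}" for i in range(10)]
    d1 = pairwise_distances(pd.DataFrame(x, index=ids))
    perm = rng.permutation(10)
    d2 = pairwise_distances(pd.DataFrame(x[perm], index=[ids[i] for i in perm]))
    t1 = minimum_spanning_tree(d1)
    t2 = minimum_spanning_tree(d2)
    e1 = {frozenset(e) for e in t1.graph.edges}
    e2 = {frozenset(e) for e in t2.graph.edges}
    assert e1 == e2


def test_exposure_fraction(hd_cavity):
    frac = exposure(hd_cavity)
    b = hd_cavity.buriedness_values()
    assert frac == pytest.approx(np.mean(b <= 60))
    assert 0.0 <= frac <= 1.0


def test_annotation_attachment_and_missing_policy(rng):
    x = rng.normal(size=(5, 3))
    tree = minimum_spanning_tree(pairwise_distances(
        pd.DataFrame(x, index=[f"p{i}" for i in range(5)])))
    ann = pd.DataFrame({"pfam_name": ["Bcl-2"] * 4, "volume": [100.0] * 4},
                       index=[f"p{i}" for i in range(4)])
    with pytest.raises(KeyError):
        annotate_tree(tree, ann)
    annotate_tree(tree, ann, allow_missing=True)
    assert tree.graph.nodes["p0"]["pfam_name"] == "Bcl-2"
    assert tree.graph.nodes["p4"]["pfam_name"] == "NA"
    dup = pd.DataFrame({"pfam_name": ["x", "y"]}, index=["p0", "p0"])
    with pytest.raises(ValueError, match="duplicate"):
        annotate_tree(tree, dup)


def test_branch_homogeneity_extremes(rng):
    x = rng.normal(size=(6, 3))
    tree = minimum_spanning_tree(pairwise_distances(
        pd.DataFrame(x, index=[f"p{i}" for i in range(6)])))
    same = {f"p{i}": {"subset": "HD"} for i in range(6)}
    annotate_tree(tree, same)
    assert branch_homogeneity(tree, "subset") == 1.0
    with pytest.raises(KeyError):
        branch_homogeneity(tree, "nonexistent_field")


def test_branch_homogeneity_alternating_path():
    # path p0-p1-p2-p3 with alternating labels: homogeneity 0
    d = np.array([
        [0.0, 1.0, 2.0, 3.0],
        [1.0, 0.0, 1.0, 2.0],
        [2.0, 1.0, 0.0, 1.0],
        [3.0, 2.0, 1.0, 0.0],
    ])
    tree = minimum_spanning_tree(_dist_from_matrix(d))
    annotate_tree(tree, {f"p{i}": {"subset": "AB"[i % 2]} for i in range(4)})
    assert branch_homogeneity(tree, "subset") == 0.0


def test_homogeneity_manual_recount_on_planted_clusters():
    spec = DescriptorSampleSpec(n_pockets=30, seed=11)
    table, labels = make_descriptor_sample(spec)
    tree = minimum_spanning_tree(pairwise_distances(table))
    by_id = {pid: f"c{lab}" for pid, lab in zip(table.index, labels)}
    annotate_tree(tree, {pid: {"subset": lab} for pid, lab in by_id.items()})
    manual = np.mean([by_id[u] == by_id[v] for u, v in tree.graph.edges])
    assert branch_homogeneity(tree, "subset") == pytest.approx(manual)


def test_homogeneity_monotone_in_separation():
    means = []
    for sep in (0.0, 2.0, 4.0, 6.0):
        homs = []
        for seed in range(3):
            spec = DescriptorSampleSpec(cluster_separation=sep, noise_sd=1.0,
                                        seed=seed)
            table, labels = make_descriptor_sample(spec)
            tree = minimum_spanning_tree(pairwise_distances(table))
            annotate_tree(tree, {pid: {"subset": f"c{lab}"}
                                 for pid, lab in zip(table.index, labels)})
            homs.append(branch_homogeneity(tree, "subset"))
        means.append(np.mean(homs))
    assert all(a <= b + 1e-9 for a, b in itertools.pairwise(means))


def test_graphml_round_trip(tmp_path, rng):
    x = rng.normal(size=(10, 3))
    tree = minimum_spanning_tree(pairwise_distances(
        pd.DataFrame(x, index=[f"p{i}" for i in range(10)])))
    annotate_tree(tree, {f"p{i}": {"subset": "HD", "volume": float(i)}
                         for i in range(10)}, allow_missing=True)
    path = tmp_path / "tree.graphml"
    export_tree(tree, path)
    back = read_graphml(path)
    assert set(back.graph.nodes) == set(tree.graph.nodes)
    assert {frozenset(e) for e in back.graph.edges} \
        == {frozenset(e) for e in tree.graph.edges}
    for node in tree.graph.nodes:
        assert back.graph.nodes[node]["subset"] == "HD"
        assert back.graph.nodes[node]["volume"] \
            == pytest.approx(tree.graph.nodes[node]["volume"])


def test_html_export_is_self_contained(tmp_path, rng):
    x = rng.normal(size=(10, 3))
    tree = minimum_spanning_tree(pairwise_distances(
        pd.DataFrame(x, index=[f"p{i}" for i in range(10)])))
    annotate_tree(tree, {f"p{i}": {"subset": "HD", "volume": float(i)}
                         for i in range(10)})
    path = tmp_path / "tree.html"
    export_tree(tree, path)
    text = path.read_text()
    # no external network resources: the W3C namespace URI is not a fetch
    stripped = text.replace("http://www.w3.org/2000/svg", "")
    assert "http://" not in stripped and "https://" not in stripped
    assert "<script>" in text and "subset" in text


def test_unknown_export_format(tmp_path, rng):
    tree = minimum_spanning_tree(pairwise_distances(rng.normal(size=(3, 2))))
    with pytest.raises(ValueError, match="format"):
        export_tree(tree, tmp_path / "tree.xyz")
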