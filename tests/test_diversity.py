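import numpy as np
import pandas as pd
import pytest

from resurvey_trends import SimConfig, generate_pool, prepare_traits
from resurvey_trends.diversity import (
    CommunityView, community_view, cwm_niche_width, functional_indices,
    group_indices, phylogenetic_indices, taxonomic_indices, trait_space,
)

from conftest import make_obs


def view(taxa, covers):
    return CommunityView(taxa=list(taxa), covers=np.array(covers, float))


def axes_frame(coords):
    return pd.DataFrame({f"axis{j+1}": [c[j] for c in coords.values()]
                         for j in range(len(next(iter(coords.values()))))},
                        index=list(coords))


# ---------------------------------------------------------- taxonomic

def test_equal_cover_community_has_max_entropy():
    out = taxonomic_indices(view(list("abcd"), [10, 10, 10, 10]))
    assert out["shannon"] == pytest.approx(np.log(4))
    assert out["evenness"] == pytest.approx(1.0)


def test_single_species_has_zero_shannon_missing_evenness():
    out = taxonomic_indices(view(["a"], [50]))
    assert out["shannon"] == 0.0
    assert np.isnan(out["evenness"])


def test_shannon_is_scale_invariant():
    h1 = taxonomic_indices(view(["a", "b"], [10, 30]))["shannon"]
    h2 = taxonomic_indices(view(["a", "b"], [1, 3]))["shannon"]
    assert h1 == pytest.approx(h2)
    assert h1 <= np.log(2) + 1e-12


# ---------------------------------------------------------- functional

def _shoelace(points):
    """Independent polygon-area oracle for 2-D hulls."""
    from scipy.spatial import ConvexHull
    hull = ConvexHull(points)
    verts = np.asarray(points)[hull.vertices]
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def test_fric_right_triangle_is_half():
    axes = axes_frame({"a": (0, 0), "b": (1, 0), "c": (0, 1)})
    vals, _ = functional_indices(view(list("abc"), [10, 10, 10]), axes)
    assert vals["fric"] == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(5))
def test_fric_matches_shoelace_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 7))
    pts = rng.normal(size=(n, 2))
    taxa = [f"t{i}" for i in range(n)]
    axes = axes_frame({t: tuple(p) for t, p in zip(taxa, pts)})
    vals, _ = functional_indices(view(taxa, [10.0] * n), axes)
    assert vals["fric"] == pytest.approx(_shoelace(pts), rel=1e-9)


def test_feve_is_one_for_equidistant_equal_abundance_triple():
    h = np.sqrt(3) / 2
    axes = axes_frame({"a": (0.0, 0.0), "b": (1.0, 0.0), "c": (0.5, h)})
    vals, _ = functional_indices(view(list("abc"), [20, 20, 20]), axes)
    assert vals["feve"] == pytest.approx(1.0)


def test_functional_gate_on_trait_coverage():
    axes = axes_frame({"a": (0, 0), "b": (1, 0), "c": (0, 1)})
    # taxon d (cover 60) has no trait data: coverage 70/88.4 < 0.8
    v = view(list("abcd"), [30, 30, 10, 60])
    vals, reasons = functional_indices(v, axes, coverage_threshold=0.80)
    assert all(np.isnan(x) for x in vals.values())
    assert reasons["fric"] == "trait_coverage_below_threshold"


def test_fric_missing_when_too_few_species_for_hull():
    axes = axes_frame({"a": (0, 0), "b": (1, 0)})
    vals, reasons = functional_indices(view(["a", "b"], [10, 10]), axes)
    assert np.isnan(vals["fric"])
    assert reasons["fric"] == "too_few_species_for_hull"


def test_feve_fdiv_bounds_on_random_communities():
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        taxa = [f"t{i}" for i in range(n)]
        axes = axes_frame({t: tuple(rng.normal(size=2)) for t in taxa})
        vals, _ = functional_indices(view(taxa, rng.uniform(1, 50, n)), axes)
        if not np.isnan(vals["feve"]):
            assert -1e-9 <= vals["feve"] <= 1 + 1e-9
        if not np.isnan(vals["fdiv"]):
            assert -1e-9 <= vals["fdiv"] <= 1 + 1e-9


def test_trait_space_is_shared_and_deterministic(default_pool):
    traits = prepare_traits(default_pool.traits)
    a1 = trait_space(traits, m_axes=4)
    a2 = trait_space(traits, m_axes=4)
    pd.testing.assert_frame_equal(a1, a2)
    assert a1.shape[1] == 4


# -------------------------------------------------------- phylogenetic

def _brute_force_distances(phylo):
    """Path-length oracle over the tree seen as a weighted graph."""
    import networkx as nx
    g = nx.Graph()
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node), weight=node.edge.length or 0.0)
    leaves = {lf.taxon.label: id(lf) for lf in phylo.tree.leaf_node_iter()}
    return g, leaves


def _star_phylogeny(lengths):
    import dendropy
    from resurvey_trends.datamodel import Phylogeny
    taxa = [f"t{i}" for i in range(len(lengths))]
    newick = "(" + ",".join(f"{t}:{l}" for t, l in zip(taxa, lengths)) + ");"
    return Phylogeny.from_newick(newick, is_path=False), taxa


def test_two_leaf_star_pd_mpd_mntd():
    phylo, taxa = _star_phylogeny([1.0, 1.0])
    vals, _ = phylogenetic_indices(view(taxa, [10, 10]), phylo)
    assert vals["faith_pd"] == pytest.approx(2.0)
    assert vals["mpd"] == pytest.approx(2.0)
    assert vals["mntd"] == pytest.approx(2.0)


def test_missing_taxon_gates_all_phylo_indices():
    phylo, taxa = _star_phylogeny([1.0, 1.0])
    vals, reasons = phylogenetic_indices(view(taxa + ["zz"], [10, 10, 10]), phylo)
    assert all(np.isnan(x) for x in vals.values())
    assert reasons["mpd"] == "taxon_missing_from_tree"


@pytest.mark.parametrize("seed", range(4))
def test_mpd_mntd_match_path_length_oracle(seed):
    import networkx as nx
    from resurvey_trends.simulate import _pure_birth_tree
    rng = np.random.default_rng(seed)
    taxa = [f"s{i} x" for i in range(8)]
    phylo = _pure_birth_tree(taxa, 1.0, rng)
    comm = list(rng.choice(taxa, size=4, replace=False))
    g, leaves = _brute_force_distances(phylo)
    dists = [nx.shortest_path_length(g, leaves[a], leaves[b], weight="weight")
             for i, a in enumerate(comm) for b in comm[i + 1:]]
    nearest = [min(nx.shortest_path_length(g, leaves[a], leaves[b], weight="weight")
                   for b in comm if b != a) for a in comm]
    vals, _ = phylogenetic_indices(view(comm, [10] * 4), phylo)
    assert vals["mpd"] == pytest.approx(np.mean(dists))
    assert vals["mntd"] == pytest.approx(np.mean(nearest))
    assert vals["mntd"] <= vals["mpd"] + 1e-12


def test_faith_pd_monotone_under_adding_taxa(default_pool):
    phylo = default_pool.phylogeny
    taxa = phylo.leaf_labels
    pd3 = phylo.faith_pd(taxa[:3])
    pd5 = phylo.faith_pd(taxa[:5])
    assert pd5 >= pd3
    assert phylo.faith_pd(taxa[:3], include_root=False) <= pd3


def test_single_species_mpd_missing():
    phylo, taxa = _star_phylogeny([1.0, 2.0])
    vals, reasons = phylogenetic_indices(view([taxa[0]], [10]), phylo)
    assert vals["faith_pd"] > 0
    assert np.isnan(vals["mpd"]) and reasons["mpd"] == "single_species"


def test_weighted_mpd_equals_unweighted_for_equal_abundance():
    phylo, taxa = _star_phylogeny([1.0, 2.0, 3.0])
    vw, _ = phylogenetic_indices(view(taxa, [10, 10, 10]), phylo,
                                 abundance_weighted=True)
    vu, _ = phylogenetic_indices(view(taxa, [5, 5, 5]), phylo)
    assert vw["mpd"] == pytest.approx(vu["mpd"])


# ------------------------------------------------------ groups and CWM

def test_group_indices_cover_uses_overlap_combination():
    v = view(["a b", "c d", "e f"], [30, 30, 50])
    out = group_indices(v, {"nonnative": {"a b", "c d"}, "threatened": set()})
    assert out["n_nonnative"] == 2
    assert out["cover_nonnative"] == pytest.approx(51.0)
    assert out["n_threatened"] == 0 and out["cover_threatened"] == 0.0
    assert out["cover_nonnative"] <= v.total_cover


@pytest.mark.parametrize("widths,covers,expected", [
    ({"a": 0.8}, [50], 0.8),
    ({"a": 0.7, "b": 0.9}, [20, 20], 0.8),
])
def test_cwm_niche_width_values(widths, covers, expected):
    v = view(list(widths), covers)
    val, reason = cwm_niche_width(v, widths)
    assert val == pytest.approx(expected)
    assert reason == ""


def test_cwm_gated_when_scored_cover_below_threshold():
    v = view(["a", "b"], [30, 30])  # scored taxon covers 30 of 51 total
    val, reason = cwm_niche_width(v, {"a": 0.8})
    assert np.isnan(val)
    assert reason == "niche_coverage_below_threshold"
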