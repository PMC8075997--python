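"""Multispecies-coalescent simulation and quartet-frequency concordance."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wgdcoal.msc import (
    GeneTreeSet,
    SpeciesTree,
    concordance,
    expected_topology_freqs,
    simulate_gene_trees,
    topology_freqs,
)
from wgdcoal.trees import BRANCH_I, BRANCH_III, angiosperm_tree


def quartet_tree(t: float, other: float = 1.0) -> SpeciesTree:
    return SpeciesTree.from_newick(f"((A:1,B:1):{t},(C:1,D:1):{other});")


def five_taxon_tree(t: float) -> SpeciesTree:
    """Focal branch {B,C} is interior, so q1 = 1 - (2/3)e^-t up to O(e^-5)."""
    return SpeciesTree.from_newick(f"(((B:1,C:1):{t},A:1):5,(D:1,E:1):5);")


# -- species tree parsing ----------------------------------------------------


def test_newick_branch_lengths_preserved():
    tree = quartet_tree(0.2163)
    assert tree.taxa == ["A", "B", "C", "D"]
    i = tree.find_branch({"A", "B"})
    assert tree.nodes[i].length == pytest.approx(0.2163)
    assert ":0.2163" in tree.to_newick()


def test_missing_terminal_lengths_default_to_one():
    tree = SpeciesTree.from_newick("((A,B):0.5,(C,D):0.5);")
    leaf = next(n for n in tree.nodes if n.label == "A")
    assert leaf.length == 1.0


def test_nonbinary_tree_rejected():
    with pytest.raises(ValueError, match="binary"):
        SpeciesTree.from_newick("((A:1,B:1,C:1):1,D:1);")


# -- simulation --------------------------------------------------------------


def test_two_taxon_trees_have_the_only_topology():
    tree = SpeciesTree.from_newick("(A:1,B:1);")
    gts = simulate_gene_trees(tree, 50, seed=1)
    assert all(m == [(1, 2)] or m == [(2, 1)] for m in gts.merges)


def test_star_branch_gives_uniform_resolutions():
    # both root-child internal branches ~0: all three resolutions equally likely
    tree = quartet_tree(0.0, other=0.0)
    gts = simulate_gene_trees(tree, 20_000, seed=2)
    f = topology_freqs(gts, tree, frozenset({"A", "B"}))
    for q in (f.q1, f.q2, f.q3):
        assert q == pytest.approx(1 / 3, abs=0.01)


def test_long_branch_is_fully_concordant():
    tree = quartet_tree(10.0)
    gts = simulate_gene_trees(tree, 5_000, seed=3)
    f = topology_freqs(gts, tree, frozenset({"A", "B"}))
    assert f.q1 >= 0.999


def test_seeded_determinism():
    tree = angiosperm_tree()
    a = simulate_gene_trees(tree, 200, seed=11)
    b = simulate_gene_trees(tree, 200, seed=11)
    assert a.merges == b.merges
    assert (a.clades == b.clades).all()
    c = simulate_gene_trees(tree, 200, seed=12)
    assert a.merges != c.merges


def test_gene_tree_newick_roundtrip():
    tree = five_taxon_tree(0.5)
    gts = simulate_gene_trees(tree, 20, seed=4)
    lines = [gts.newick(i) for i in range(len(gts))]
    rebuilt = GeneTreeSet.from_newick(lines, tree.taxa)
    # merge order differs (coalescence time vs parse order); topologies match
    assert (np.sort(rebuilt.clades, axis=1) == np.sort(gts.clades, axis=1)).all()


# -- expected frequencies ----------------------------------------------------


@pytest.mark.parametrize(
    "t, expected",
    [
        (0.0, (1 / 3, 1 / 3, 1 / 3)),
        (math.log(2), (2 / 3, 1 / 6, 1 / 6)),
        (50.0, (1.0, 0.0, 0.0)),
    ],
)
def test_closed_form_expectations(t, expected):
    assert expected_topology_freqs(t) == pytest.approx(expected, abs=1e-12)


def test_negative_branch_rejected():
    with pytest.raises(ValueError):
        expected_topology_freqs(-0.1)


def test_simulation_converges_to_closed_form():
    t = 0.5
    tree = five_taxon_tree(t)
    gts = simulate_gene_trees(tree, 20_000, seed=5)
    f = topology_freqs(gts, tree, frozenset({"B", "C"}))
    want = expected_topology_freqs(t)
    assert f.q1 == pytest.approx(want[0], abs=0.01)
    assert f.q2 == pytest.approx(want[1], abs=0.01)
    assert f.q3 == pytest.approx(want[2], abs=0.01)
    # MSC alternates are exchangeable
    assert abs(f.q2 - f.q3) <= 0.015


# -- topology classification -------------------------------------------------


def test_hand_built_quartet_frequencies():
    taxa = ["A", "B", "C", "D"]
    lines = (
        ["((A,B),(C,D));"] * 3 + ["((A,C),(B,D));"] * 2 + ["((A,D),(B,C));"]
    )
    gts = GeneTreeSet.from_newick(lines, taxa)
    tree = quartet_tree(0.5)
    f = topology_freqs(gts, tree, frozenset({"A", "B"}))
    assert (f.q1, f.q2, f.q3) == pytest.approx((0.5, 1 / 3, 1 / 6))
    assert f.q1 + f.q2 + f.q3 == pytest.approx(1.0, abs=1e-12)


def test_species_tree_identical_gene_trees_are_fully_concordant():
    tree = five_taxon_tree(1.0)
    lines = ["(((B,C),A),(D,E));"] * 10
    gts = GeneTreeSet.from_newick(lines, tree.taxa)
    f = topology_freqs(gts, tree, frozenset({"B", "C"}))
    assert (f.q1, f.q2, f.q3) == (1.0, 0.0, 0.0)


def test_focal_branch_alternates_match_study_labels():
    """On the 14-taxon tree, q2 joins Amborella with Euryale and q3 makes
    Euryale the first-diverging lineage."""
    tree = angiosperm_tree()
    # gene tree displaying "Amborella sister to Euryale"
    b, t = 5.0, 1.0
    eud = f"(((Arabidopsis:{t},Prunus:{t}):{b},Vitis:{t}):{b},Aquilegia:{t})"
    mono = f"((Musa:{t},Oryza:{t}):{b},Phalaenopsis:{t})"
    mag = f"((Cinnamomum:{t},Persea:{t}):{b},Liriodendron:{t})"
    mesa = f"({mag}:{b},({mono}:{b},(Ceratophyllum:{t},{eud}:{b}):1):{b})"
    sister = f"(Ginkgo:1,((Amborella:1,Euryale:1):1,{mesa}):1);"
    gts = GeneTreeSet.from_newick([sister], tree.taxa)
    f = topology_freqs(gts, tree, BRANCH_I)
    assert (f.q1, f.q2, f.q3) == (0.0, 1.0, 0.0)
    # gene tree with Euryale alone diverging first
    first = f"(Ginkgo:1,(Euryale:1,(Amborella:1,{mesa}):1):1);"
    f2 = topology_freqs(GeneTreeSet.from_newick([first], tree.taxa), tree, BRANCH_I)
    assert (f2.q1, f2.q2, f2.q3) == (0.0, 0.0, 1.0)


def test_missing_leaf_in_gene_tree_rejected():
    with pytest.raises(ValueError, match="missing"):
        GeneTreeSet.from_newick(["((A,B),C);"], ["A", "B", "C", "D"])


# -- concordance -------------------------------------------------------------


def test_identical_vectors_give_perfect_correlation():
    rho, _ = concordance([0.5, 0.3, 0.2], [0.5, 0.3, 0.2])
    assert rho == pytest.approx(1.0)


def test_reversed_ranks_give_perfect_anticorrelation():
    rho, _ = concordance([1, 2, 3, 4], [4, 3, 2, 1])
    assert rho == pytest.approx(-1.0)


def test_spearman_with_one_swap():
    rho, p = concordance([1, 2, 3, 4], [1, 3, 2, 4])
    assert rho == pytest.approx(0.8)
    assert 0 < p <= 1


def test_mismatched_lengths_rejected():
    with pytest.raises(ValueError):
        concordance([1, 2, 3], [1, 2])
    with pytest.raises(ValueError):
        concordance([1, 2], [1, 2])
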