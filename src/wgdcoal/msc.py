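"""Multispecies-coalescent gene-tree simulation and quartet concordance.

Gene trees are simulated on a rooted binary species tree whose internal branch
lengths are in coalescent units (terminal branches default to 1, one sampled
allele per species).  Within a branch of length t carrying k gene lineages,
lineages coalesce with exponential waiting times at rate k(k-1)/2; lineages
surviving to the root coalesce in an unbounded ancestral branch.

Around a focal internal branch with four neighbouring clades (the two child
clades C1, C2, the sibling clade S and the remainder R), every gene tree
displays one of three arrangements; their frequencies q1 (species-tree
concordant, C1C2|SR), q2 (C1S|C2R) and q3 (C1R|C2S) are measured per-branch
quartet frequencies: each gene tree is scored by the fraction of one-leaf-per-
clade quartets displaying each resolution.  Under the MSC the expectations are
q1 = 1 - (2/3)e^{-t} and q2 = q3 = (1/3)e^{-t} for a branch of length t.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from math import exp

import dendropy
import numpy as np
from scipy import stats


@dataclass
class _Node:
    children: tuple[int, ...]  # indices into the node list; () for leaves
    length: float | None  # edge length above the node (None for root)
    label: str | None
    clade: int  # bitmask over sorted taxa


class SpeciesTree:
    """Rooted binary species tree with coalescent-unit branch lengths."""

    def __init__(self, nodes: list[_Node], taxa: list[str]):
        self.nodes = nodes  # postorder, root last
        self.taxa = taxa  # sorted; bit i of a clade mask = taxa[i]
        self.bit = {t: 1 << i for i, t in enumerate(taxa)}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, default_terminal: float = 1.0) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = sorted(
            leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()
        )
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        bit = {t: 1 << i for i, t in enumerate(labels)}
        nodes: list[_Node] = []

        def build(dnode) -> int:
            kids = dnode.child_nodes()
            if not kids:
                label = dnode.taxon.label.replace(" ", "_")
                length = dnode.edge.length
                nodes.append(
                    _Node((), default_terminal if length is None else float(length),
                          label, bit[label])
                )
                return len(nodes) - 1
            if len(kids) != 2:
                raise ValueError("species tree must be rooted and binary")
            idx = tuple(build(k) for k in kids)
            clade = nodes[idx[0]].clade | nodes[idx[1]].clade
            is_root = dnode.parent_node is None
            length = dnode.edge.length
            if length is None and not is_root:
                raise ValueError("internal branch without a coalescent-unit length")
            if length is not None and length < 0:
                raise ValueError("negative branch length")
            nodes.append(
                _Node(idx, None if is_root else float(length), None, clade)
            )
            return len(nodes) - 1

        build(tree.seed_node)
        return cls(nodes, labels)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            node = self.nodes[i]
            if not node.children:
                body = node.label
            else:
                body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.length is None:
                return body
            return f"{body}:{node.length:.10g}"

        return render(len(self.nodes) - 1) + ";"

    # -- queries -----------------------------------------------------------
    @property
    def root(self) -> int:
        return len(self.nodes) - 1

    def clade_labels(self, mask: int) -> frozenset[str]:
        return frozenset(t for t in self.taxa if self.bit[t] & mask)

    def find_branch(self, clade: frozenset[str] | set[str]) -> int:
        """Index of the internal node whose subtree is exactly ``clade``."""
        mask = 0
        for t in clade:
            mask |= self.bit[t]
        for i, node in enumerate(self.nodes):
            if node.clade == mask and node.children and i != self.root:
                return i
        raise KeyError(f"no internal branch subtends clade {sorted(clade)}")

    def with_branch_length(
        self, clade: frozenset[str] | set[str], length: float
    ) -> "SpeciesTree":
        i = self.find_branch(clade)
        nodes = list(self.nodes)
        nodes[i] = _Node(nodes[i].children, float(length), nodes[i].label,
                         nodes[i].clade)
        return SpeciesTree(nodes, self.taxa)

    def scaled_internals(self, length: float) -> "SpeciesTree":
        """Copy with every internal (non-root) branch set to ``length``."""
        nodes = [
            _Node(n.children, float(length), n.label, n.clade)
            if n.children and i != self.root
            else n
            for i, n in enumerate(self.nodes)
        ]
        return SpeciesTree(nodes, self.taxa)


@dataclass
class GeneTreeSet:
    """Simulated rooted gene-tree topologies, one tip per species.

    ``merges`` holds, per tree, the coalescence events in time order as pairs
    of clade bitmasks; ``clades`` is the (n_trees, n_taxa - 1) matrix of the
    resulting internal-node clade masks used for quartet counting.
    """

    taxa: list[str]
    merges: list[list[tuple[int, int]]]
    clades: np.ndarray

    def __len__(self) -> int:
        return len(self.merges)

    @classmethod
    def from_newick(cls, newicks: list[str], taxa: list[str]) -> "GeneTreeSet":
        """Build a set from rooted newick strings (full leaf set required)."""
        bit = {t: 1 << i for i, t in enumerate(taxa)}
        full = (1 << len(taxa)) - 1
        merges_all = []
        clades = np.zeros((len(newicks), len(taxa) - 1), dtype=np.uint32)
        for t, nwk in enumerate(newicks):
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            merges: list[tuple[int, int]] = []

            def mask(node) -> int:
                kids = node.child_nodes()
                if not kids:
                    label = node.taxon.label.replace(" ", "_")
                    if label not in bit:
                        raise ValueError(f"unknown leaf {label!r} in gene tree {t}")
                    return bit[label]
                if len(kids) != 2:
                    raise ValueError(f"gene tree {t} is not binary")
                a, b = (mask(k) for k in kids)
                merges.append((a, b))
                return a | b

            if mask(tree.seed_node) != full:
                raise ValueError(f"gene tree {t} is missing leaves")
            merges_all.append(merges)
            clades[t] = [a | b for a, b in merges]
        return cls(list(taxa), merges_all, clades)

    def newick(self, i: int) -> str:
        reprs = {1 << k: t for k, t in enumerate(self.taxa)}
        for a, b in self.merges[i]:
            reprs[a | b] = f"({reprs[a]},{reprs[b]})"
        full = (1 << len(self.taxa)) - 1
        return reprs[full] + ";"

    def write_newick(self, handle) -> None:
        for i in range(len(self)):
            handle.write(self.newick(i) + "\n")


def simulate_gene_trees(tree: SpeciesTree, n: int, seed: int) -> GeneTreeSet:
    """Simulate ``n`` gene trees under the multispecies coalescent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    expo, rnd = rng.expovariate, rng.random
    nodes = tree.nodes
    root = tree.root
    n_internal = len(tree.taxa) - 1
    merges_all: list[list[tuple[int, int]]] = []
    clades = np.zeros((n, n_internal), dtype=np.uint32)

    # postorder traversal plan: leaves contribute single lineages
    for t in range(n):
        merges: list[tuple[int, int]] = []
        stacks: dict[int, list[int]] = {}
        for i, node in enumerate(nodes):
            if not node.children:
                stacks[i] = [node.clade]
                lineages = stacks[i]
            else:
                lineages = stacks[node.children[0]] + stacks[node.children[1]]
                stacks[i] = lineages
            limit = float("inf") if i == root else node.length
            clock = 0.0
            k = len(lineages)
            while k > 1:
                clock += expo(k * (k - 1) / 2.0)
                if clock > limit:
                    break
                ia = int(rnd() * k)
                ib = int(rnd() * (k - 1))
                if ib >= ia:
                    ib += 1
                a, b = lineages[ia], lineages[ib]
                merges.append((a, b))
                lineages[min(ia, ib)] = a | b
                lineages[max(ia, ib)] = lineages[k - 1]
                lineages.pop()
                k -= 1
        merges_all.append(merges)
        clades[t] = [a | b for a, b in merges]
    return GeneTreeSet(list(tree.taxa), merges_all, clades)


def expected_topology_freqs(t: float) -> tuple[float, float, float]:
    """MSC expectations (q1, q2, q3) for an internal branch of length t."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e = exp(-t)
    return (1.0 - 2.0 * e / 3.0, e / 3.0, e / 3.0)


def branch_length_from_concordance(q1: float) -> float:
    """Invert q1 = 1 - (2/3)e^-t; defined for q1 in [1/3, 1)."""
    if not 1.0 / 3.0 <= q1 < 1.0:
        raise ValueError("concordant fraction must be in [1/3, 1)")
    return -math.log(1.5 * (1.0 - q1))


@dataclass
class QuartetFrequencies:
    branch: frozenset[str]  # clade subtended by the focal branch
    q1: float
    q2: float
    q3: float
    n: int


def _branch_groups(tree: SpeciesTree, branch_clade) -> tuple[int, int, int, int]:
    """(C1, C2, S, R) clade masks around the focal internal branch."""
    i = tree.find_branch(branch_clade)
    node = tree.nodes[i]
    parent = next(j for j, nd in enumerate(tree.nodes) if i in nd.children)
    c1 = tree.nodes[node.children[0]].clade
    c2 = tree.nodes[node.children[1]].clade
    sib = next(c for c in tree.nodes[parent].children if c != i)
    if parent == tree.root:
        # the root edge is not a fourth neighbour: split the sibling instead
        if not tree.nodes[sib].children:
            raise ValueError("focal branch is root-adjacent-degenerate")
        s = tree.nodes[tree.nodes[sib].children[0]].clade
        r = tree.nodes[tree.nodes[sib].children[1]].clade
    else:
        s = tree.nodes[sib].clade
        full = (1 << len(tree.taxa)) - 1
        r = full & ~(node.clade | s)
    if r == 0:
        raise ValueError("focal branch has no fourth neighbour clade")
    return c1, c2, s, r


def topology_freqs(
    genetrees: GeneTreeSet, tree: SpeciesTree, branch_clade
) -> QuartetFrequencies:
    """Per-branch topology frequencies of a gene-tree set.

    Each gene tree is scored by the fraction of quartets (one leaf from each
    of the branch's four neighbour clades) displaying each of the three
    resolutions; q1 is the species-tree-concordant arrangement, q2 joins C1
    with the sibling clade, q3 joins C1 with the remainder.
    """
    if genetrees.taxa != tree.taxa:
        raise ValueError("gene trees and species tree have different leaf sets")
    c1, c2, s, r = _branch_groups(tree, branch_clade)
    M = genetrees.clades
    n_trees = M.shape[0]
    counts = np.zeros(3, dtype=float)
    bits = lambda m: [1 << i for i in range(len(tree.taxa)) if m & (1 << i)]
    n_quartets = 0
    for ba in bits(c1):
        for bb in bits(c2):
            for bc in bits(s):
                for bd in bits(r):
                    n_quartets += 1
                    for qi, (p, q) in enumerate(
                        (((ba | bb), (bc | bd)), ((ba | bc), (bb | bd)),
                         ((ba | bd), (bb | bc)))
                    ):
                        hit = (
                            (((M & p) == p) & ((M & q) == 0))
                            | (((M & q) == q) & ((M & p) == 0))
                        ).any(axis=1)
                        counts[qi] += int(hit.sum())
    total = n_trees * n_quartets
    q1, q2, q3 = counts / total
    return QuartetFrequencies(frozenset(tree.clade_labels(c1 | c2)), q1, q2, q3,
                              n_trees)


def concordance(empirical, simulated) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p) between frequency vectors."""
    x = np.asarray(empirical, dtype=float)
    y = np.asarray(simulated, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 paired frequencies")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
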