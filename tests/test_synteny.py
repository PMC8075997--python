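"""Anchor chaining against exhaustive search, plus syntenic depth ratios."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from wgdcoal.io import RunConfig
from wgdcoal.simulate import (
    EvolutionScenario,
    Speciation,
    WholeGenomeDuplication,
    emit_anchor_pairs,
    simulate_history,
)
from wgdcoal.synteny import ChainParams, chain_anchors, syntenic_depth


def _toy_tables(pairs, n_ranks=2000):
    """positions for two genomes + anchor table from (ra, rb, score) tuples."""
    positions = {
        name: pd.DataFrame(
            {"chrom": "c1", "rank": range(n_ranks), "strand": "+",
             "gene_id": [f"{name}{i}" for i in range(n_ranks)]}
        )
        for name in ("A", "B")
    }
    anchors = pd.DataFrame(
        {"gene_a": [f"A{ra}" for ra, _, _ in pairs],
         "gene_b": [f"B{rb}" for _, rb, _ in pairs],
         "score": [s for _, _, s in pairs]}
    )
    return anchors, positions


def _block_rank_sets(blocks):
    return {frozenset((ra, rb) for _, _, ra, rb in b.anchors) for b in blocks}


# -- chaining basics ---------------------------------------------------------


def test_perfect_diagonal_forms_single_block():
    anchors, positions = _toy_tables([(i, i, 1.0) for i in range(12)])
    blocks = chain_anchors(anchors, positions, ChainParams())
    assert len(blocks) == 1
    assert len(blocks[0]) == 12
    assert blocks[0].orientation == "+"


def test_nine_anchor_diagonal_is_below_block_threshold():
    anchors, positions = _toy_tables([(i, i, 1.0) for i in range(9)])
    assert chain_anchors(anchors, positions, ChainParams()) == []


def test_distant_diagonals_split_into_two_blocks():
    pairs = [(i, i, 1.0) for i in range(15)]
    pairs += [(i + 515, i + 515, 1.0) for i in range(15)]
    anchors, positions = _toy_tables(pairs)
    blocks = chain_anchors(anchors, positions, ChainParams(max_gap=25))
    assert sorted(len(b) for b in blocks) == [15, 15]


def test_antiparallel_diagonal_reported_with_minus_orientation():
    anchors, positions = _toy_tables([(i, 40 - i, 1.0) for i in range(12)])
    blocks = chain_anchors(anchors, positions, ChainParams())
    assert len(blocks) == 1
    assert blocks[0].orientation == "-"
    rbs = [rb for _, _, _, rb in blocks[0].anchors]
    assert rbs == sorted(rbs, reverse=True)


def test_unknown_gene_id_is_a_hard_error():
    anchors, positions = _toy_tables([(0, 0, 1.0)])
    anchors.loc[0, "gene_a"] = "missing_gene"
    with pytest.raises(KeyError, match="missing_gene"):
        chain_anchors(anchors, positions, ChainParams())


def test_stricter_min_block_yields_subset():
    rng = np.random.default_rng(5)
    pairs = [(int(i), int(i) + int(rng.integers(-2, 3)), float(s))
             for i, s in zip(rng.integers(10, 390, 120), rng.uniform(0.5, 1.5, 120))]
    anchors, positions = _toy_tables(pairs)
    loose = _block_rank_sets(chain_anchors(anchors, positions, ChainParams(min_block=2)))
    strict = _block_rank_sets(chain_anchors(anchors, positions, ChainParams(min_block=6)))
    assert strict <= loose


# -- exhaustive-search oracle ------------------------------------------------


def _oracle_chains_global(pairs, params: ChainParams):
    """As above but scanning every subset size for the true score maximum."""

    def chain_score(subset):
        best = None
        for sign in (1, -1) if params.allow_inversions else (1,):
            pts = sorted(subset, key=lambda t: (t[0], sign * t[1]))
            ok = True
            score = pts[0][2]
            for (ra0, rb0, _), (ra1, rb1, s1) in zip(pts, pts[1:]):
                da, db = ra1 - ra0, sign * (rb1 - rb0)
                if da < 1 or db < 1 or da > params.max_gap or db > params.max_gap:
                    ok = False
                    break
                score += s1 - params.gap_open * (da - 1 + db - 1)
            if ok and (best is None or score > best):
                best = score
        return best

    remaining = list(pairs)
    chains = []
    while True:
        best = None
        for size in range(2, len(remaining) + 1):
            for subset in combinations(remaining, size):
                score = chain_score(subset)
                if score is not None and (
                    best is None or (score, len(subset)) > (best[0], len(best[1]))
                ):
                    best = (score, subset)
        if best is None:
            break
        chains.append(best[1])
        remaining = [p for p in remaining if p not in best[1]]
    return [c for c in chains if len(c) >= params.min_block]


@pytest.mark.parametrize("seed", range(6))
def test_chaining_equals_exhaustive_search_on_small_inputs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 13))
    pairs = [
        (int(ra), int(rb), float(s))
        for ra, rb, s in zip(
            rng.choice(60, size=n, replace=False),
            rng.choice(60, size=n, replace=False),
            rng.uniform(0.5, 1.5, n),
        )
    ]
    params = ChainParams(min_block=2, max_gap=12)
    anchors, positions = _toy_tables(pairs, n_ranks=100)
    got = _block_rank_sets(chain_anchors(anchors, positions, params))
    want = {
        frozenset((ra, rb) for ra, rb, _ in chain)
        for chain in _oracle_chains_global(pairs, params)
    }
    assert got == want


# -- planted-block recall ----------------------------------------------------


def test_planted_block_recall_on_noise_free_fixture():
    scenario = EvolutionScenario(
        species_labels=["A"],
        events=[Speciation(40.0, "anc", {"A": 1.0}),
                WholeGenomeDuplication(30.0, "A", 2, 1.0)],
        genes_per_chromosome=20, chromosomes=20, codons_per_gene=60,
        ks_per_myr=0.004, seed=31, root="anc",
    )
    genomes, truth = simulate_history(scenario)
    anchors = emit_anchor_pairs(truth, 0.0, seed=1)
    blocks = chain_anchors(
        anchors, {"A": genomes[0].positions_frame()}, ChainParams()
    )
    assert len(blocks) >= 20
    covered = {frozenset((a, b)) for blk in blocks for a, b, _, _ in blk.anchors}
    truth_set = {frozenset((p.gene_a, p.gene_b)) for p in truth.pairs}
    recall = len(covered & truth_set) / len(truth_set)
    assert recall >= 0.95


# -- syntenic depth ----------------------------------------------------------


def _two_species_blocks(n_wgd: int, seed: int = 41):
    events = [Speciation(80.0, "anc", {"A": 1.0, "B": 1.0})]
    ages = [60.0, 40.0]
    for i in range(n_wgd):
        events.append(WholeGenomeDuplication(ages[i], "A", 2, 1.0))
    scenario = EvolutionScenario(
        species_labels=["A", "B"], events=events,
        genes_per_chromosome=60, chromosomes=2, codons_per_gene=60,
        ks_per_myr=0.002, seed=seed, root="anc",
    )
    genomes, truth = simulate_history(scenario)
    anchors = emit_anchor_pairs(truth, 0.0, seed=seed)
    cross = anchors[
        anchors.gene_a.str.split("_").str[0] != anchors.gene_b.str.split("_").str[0]
    ]
    positions = {g.species: g.positions_frame() for g in genomes}
    return chain_anchors(cross, positions, ChainParams())


def test_identical_genomes_have_unit_depth_ratio():
    blocks = _two_species_blocks(0)
    assert syntenic_depth(blocks, "A").ratio == (1, 1)


def test_single_wgd_gives_two_to_one():
    blocks = _two_species_blocks(1)
    assert syntenic_depth(blocks, "A").ratio == (2, 1)


def test_double_wgd_gives_four_to_one():
    blocks = _two_species_blocks(2)
    assert syntenic_depth(blocks, "A").ratio == (4, 1)


def test_empty_block_list_rejected():
    with pytest.raises(ValueError, match="empty"):
        syntenic_depth([], "A")
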