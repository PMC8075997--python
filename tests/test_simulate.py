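"""Synthetic genome-evolution generator: mutation calibration, planted
events, ground-truth bookkeeping, and anchor emission."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from wgdcoal.ks import SaturationError, pair_ks
from wgdcoal.simulate import (
    EvolutionScenario,
    Speciation,
    WholeGenomeDuplication,
    emit_anchor_pairs,
    mutate_cds,
    random_cds,
    simulate_history,
)
from wgdcoal.synteny import ChainParams, chain_anchors


# -- mutate_cds --------------------------------------------------------------


def test_zero_target_is_identity():
    seq = random_cds(200, np.random.default_rng(0))
    assert mutate_cds(seq, 0.0, seed=1) == seq


def test_synonymous_only_mutation_preserves_protein():
    seq = random_cds(500, np.random.default_rng(1))
    mutated = mutate_cds(seq, 1.0, seed=2)
    assert mutated != seq
    assert Seq(seq).translate() == Seq(mutated).translate()
    assert "*" not in Seq(mutated).translate()


def test_mean_ng86_ks_matches_target_within_three_percent():
    seq = random_cds(10_000, np.random.default_rng(2))
    estimates = [pair_ks(seq, mutate_cds(seq, 0.3, seed=s)).ks for s in range(50)]
    assert np.mean(estimates) == pytest.approx(0.3, rel=0.03)


def test_expected_ks_increases_with_target():
    seq = random_cds(3_000, np.random.default_rng(3))
    means = []
    for target in (0.1, 0.5, 1.0, 2.0):
        means.append(
            np.mean([pair_ks(seq, mutate_cds(seq, target, seed=s)).ks
                     for s in range(8)])
        )
    assert all(a < b for a, b in zip(means, means[1:]))


def test_target_beyond_saturation_cap_rejected():
    seq = random_cds(100, np.random.default_rng(4))
    with pytest.raises(SaturationError):
        mutate_cds(seq, 3.5, seed=0)


def test_nonsynonymous_fraction_changes_protein_without_stops():
    seq = random_cds(2_000, np.random.default_rng(5))
    mutated = mutate_cds(seq, 1.0, seed=6, nonsyn_fraction=0.2)
    assert Seq(seq).translate() != Seq(mutated).translate()
    assert "*" not in Seq(mutated).translate()


# -- simulate_history --------------------------------------------------------


def _single_wgd_scenario(age: float, retention: float = 1.0, **kw) -> EvolutionScenario:
    defaults = dict(genes_per_chromosome=30, chromosomes=2, codons_per_gene=60,
                    ks_per_myr=0.004, seed=9, root="anc")
    defaults.update(kw)
    return EvolutionScenario(
        species_labels=["A"],
        events=[Speciation(age + 1.0, "anc", {"A": 1.0}),
                WholeGenomeDuplication(age, "A", 2, retention)],
        **defaults,
    )


def test_full_retention_duplicates_every_gene():
    genomes, truth = simulate_history(_single_wgd_scenario(50.0))
    genome = genomes[0]
    n_genes = sum(len(v) for v in genome.loci.values())
    assert n_genes == 2 * 30 * 2
    assert len(truth.pairs) == 30 * 2  # one duplicate pair per ancestral gene
    assert len(genome.cds) == n_genes
    assert len(set(genome.cds)) == n_genes  # unique ids


def test_zero_elapsed_time_gives_identical_duplicates():
    genomes, truth = simulate_history(_single_wgd_scenario(0.0))
    cds = genomes[0].cds
    for pair in truth.pairs:
        assert cds[pair.gene_a] == cds[pair.gene_b]
        assert pair.expected_ks == pytest.approx(0.0)


def test_planted_wgd_ks_recovered_within_tolerance():
    # expected pair Ks = 2 * 0.004 * 62.5 = 0.5 over >= 300 retained pairs
    scenario = _single_wgd_scenario(62.5, genes_per_chromosome=160,
                                    codons_per_gene=300)
    genomes, truth = simulate_history(scenario)
    cds = genomes[0].cds
    assert len(truth.pairs) >= 300
    values = [pair_ks(cds[p.gene_a], cds[p.gene_b]).ks for p in truth.pairs]
    assert truth.pairs[0].expected_ks == pytest.approx(0.5)
    assert np.mean(values) == pytest.approx(0.5, abs=0.05)


def test_retention_follows_binomial_conservation():
    retention = 0.6
    scenario = _single_wgd_scenario(10.0, retention=retention,
                                    genes_per_chromosome=250, chromosomes=2,
                                    codons_per_gene=30)
    genomes, _ = simulate_history(scenario)
    n_before = 500
    n_after = sum(len(v) for v in genomes[0].loci.values())
    expected = (1 + retention) * n_before
    sd = np.sqrt(n_before * retention * (1 - retention))
    assert abs(n_after - expected) <= 3 * sd


def test_seed_determinism_is_byte_identical():
    runs = [simulate_history(_single_wgd_scenario(20.0)) for _ in range(2)]
    (g1, t1), (g2, t2) = runs
    assert g1[0].cds == g2[0].cds
    assert g1[0].loci == g2[0].loci
    assert t1.to_frame().equals(t2.to_frame())


def test_rank_indices_consecutive_per_chromosome():
    genomes, _ = simulate_history(_single_wgd_scenario(30.0, retention=0.5))
    for chrom_entries in genomes[0].loci.values():
        assert [rank for _, rank, _ in chrom_entries] == list(range(len(chrom_entries)))


def test_wgd_on_unknown_lineage_rejected():
    scenario = EvolutionScenario(
        species_labels=["A"],
        events=[Speciation(10.0, "anc", {"A": 1.0}),
                WholeGenomeDuplication(5.0, "ghost", 2, 1.0)],
        seed=0, root="anc",
    )
    with pytest.raises(ValueError, match="unknown or extinct"):
        simulate_history(scenario)


def test_nondecreasing_event_times_rejected():
    scenario = EvolutionScenario(
        species_labels=["A", "B"],
        events=[Speciation(5.0, "anc", {"A": 1.0, "B": 1.0}),
                WholeGenomeDuplication(7.0, "A", 2, 1.0)],
        seed=0, root="anc",
    )
    with pytest.raises(ValueError, match="strictly decrease"):
        simulate_history(scenario)


def test_rate_multipliers_scale_expected_divergence():
    scenario = EvolutionScenario(
        species_labels=["S", "F"],
        events=[Speciation(50.0, "anc", {"S": 1.0, "F": 3.0})],
        genes_per_chromosome=40, chromosomes=1, codons_per_gene=200,
        ks_per_myr=0.004, seed=21, root="anc",
    )
    genomes, truth = simulate_history(scenario)
    # pair Ks = k * (50*1 + 50*3) = 0.8
    assert truth.pairs[0].expected_ks == pytest.approx(0.8)
    cds = {**genomes[0].cds, **genomes[1].cds}
    values = [pair_ks(cds[p.gene_a], cds[p.gene_b]).ks for p in truth.pairs]
    assert np.mean(values) == pytest.approx(0.8, abs=0.05)
    assert truth.rates == {"S": 1.0, "F": 3.0}


# -- emit_anchor_pairs -------------------------------------------------------


def test_zero_noise_anchor_set_equals_truth():
    _, truth = simulate_history(_single_wgd_scenario(20.0))
    anchors = emit_anchor_pairs(truth, 0.0, seed=1)
    got = {frozenset((a, b)) for a, b in zip(anchors.gene_a, anchors.gene_b)}
    want = {frozenset((p.gene_a, p.gene_b)) for p in truth.pairs}
    assert got == want


def test_noise_fraction_row_count():
    _, truth = simulate_history(
        _single_wgd_scenario(20.0, genes_per_chromosome=50, chromosomes=1)
    )
    assert len(truth.pairs) == 50
    anchors = emit_anchor_pairs(truth, 0.2, seed=2)
    assert len(anchors) == 60


def test_scattered_noise_never_chains_into_blocks():
    """Uniform spurious pairs over two 1,000-gene chromosomes stay below the
    10-anchor block threshold (checked over 20 seeds)."""
    import pandas as pd

    positions = {
        name: pd.DataFrame(
            {"chrom": "chr01", "rank": range(1000), "strand": "+",
             "gene_id": [f"{name}_g{i}" for i in range(1000)]}
        )
        for name in ("A", "B")
    }
    params = ChainParams(min_block=10, max_gap=25)
    for seed in range(20):
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, 1000, size=(300, 2))
        anchors = pd.DataFrame(
            {"gene_a": [f"A_g{i}" for i in idx[:, 0]],
             "gene_b": [f"B_g{j}" for j in idx[:, 1]],
             "score": 1.0}
        )
        assert chain_anchors(anchors, positions, params) == []
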