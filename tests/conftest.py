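"""Shared fixtures: synthetic evolutionary scenarios reused across modules."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from wgdcoal.io import RunConfig
from wgdcoal.pipeline import wgd_pipeline
from wgdcoal.simulate import (
    EvolutionScenario,
    Speciation,
    WholeGenomeDuplication,
    emit_anchor_pairs,
    simulate_history,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def three_lineage_scenario(seed: int = 11) -> EvolutionScenario:
    """Basal three-way split with a fast reference lineage carrying two WGDs.

    At and Ef evolve at the baseline rate, Vv twice as fast; the older Vv
    polyploidy (122.5 Ma) plays the calibrated reference event and the younger
    one (60 Ma) is the event whose age the pipeline must recover.
    """
    return EvolutionScenario(
        species_labels=["At", "Ef", "Vv"],
        events=[
            Speciation(150.0, "anc", {"At": 1.0, "Ef": 1.0, "Vv": 2.0}),
            WholeGenomeDuplication(122.5, "Vv", 2, 0.8),
            WholeGenomeDuplication(60.0, "Vv", 2, 0.8),
        ],
        genes_per_chromosome=150,
        chromosomes=6,
        codons_per_gene=300,
        ks_per_myr=0.004,
        seed=seed,
        root="anc",
    )


@pytest.fixture(scope="session")
def three_lineage_run():
    """Full WGD-pipeline run on the three-lineage fixture."""
    scenario = three_lineage_scenario()
    genomes, truth = simulate_history(scenario)
    anchors = emit_anchor_pairs(truth, 0.0, seed=13)
    positions = {g.species: g.positions_frame() for g in genomes}
    cds: dict[str, str] = {}
    for g in genomes:
        cds.update(g.cds)
    blocks, fits = wgd_pipeline(positions, cds, anchors, RunConfig())
    return {
        "scenario": scenario,
        "genomes": genomes,
        "truth": truth,
        "anchors": anchors,
        "positions": positions,
        "cds": cds,
        "blocks": blocks,
        "fits": fits,
    }
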