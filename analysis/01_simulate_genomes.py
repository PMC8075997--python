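#!/usr/bin/env python
"""Generate the synthetic annotated-genome fixtures used by the WGD analysis.

Three lineages diverge simultaneously 150 Ma: two slow anchors (At, Ef;
Amborella- and Euryale-like, baseline clock) and one fast reference lineage
(Vv, grape-like, clock running twice the baseline) that carries two planted
polyploidies — the calibrated reference event at 122.5 Ma (the midpoint of the
115-130 Ma eudicot-hexaploidy window) and a younger event at 60 Ma whose age
the downstream pipeline must recover.  Writes gene-position tables, CDS FASTA,
the anchor-pair table and the ground-truth log under results/fixtures/.
"""

from pathlib import Path

from wgdcoal.io import write_fasta, write_tsv
from wgdcoal.simulate import (
    EvolutionScenario,
    Speciation,
    WholeGenomeDuplication,
    emit_anchor_pairs,
    simulate_history,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"

SCENARIO = EvolutionScenario(
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
    seed=11,
    root="anc",
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genomes, truth = simulate_history(SCENARIO)
    for genome in genomes:
        write_tsv(genome.positions_frame(), OUT / f"{genome.species}.positions.tsv",
                  "positions_tsv")
        write_fasta(genome.cds, OUT / f"{genome.species}.cds.fasta")
        n = sum(len(v) for v in genome.loci.values())
        print(f"{genome.species}: {n} genes on {len(genome.loci)} chromosomes")
    anchors = emit_anchor_pairs(truth, noise_fraction=0.0, seed=13)
    write_tsv(anchors, OUT / "anchors.tsv", "anchors_tsv")
    write_tsv(truth.to_frame(), OUT / "truth.tsv", "truth_tsv")
    print(f"{len(truth.pairs)} true homologous pairs; rates {truth.rates}")
    print(f"fixtures -> {OUT}")


if __name__ == "__main__":
    main()
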