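"""YAML schema for evolution scenarios.

Example::

    species: [At, Ef, Vv]
    root: anc
    chromosomes: 4
    genes_per_chromosome: 200
    codons_per_gene: 200
    ks_per_myr: 0.004
    seed: 1
    events:
      - {type: speciation, time: 150, lineage: anc,
         children: {At: 1.0, EfVv: 1.0}}
      - {type: speciation, time: 148, lineage: EfVv,
         children: {Ef: 1.0, Vv: 2.0}}
      - {type: wgd, time: 122.5, lineage: Vv, ploidy: 2, retention: 0.8}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .io import FormatError
from .simulate import EvolutionScenario, Speciation, WholeGenomeDuplication


def load_scenario(path: str | Path) -> EvolutionScenario:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "species" not in data or "events" not in data:
        raise FormatError(f"{path}: scenario needs 'species' and 'events' keys")
    events = []
    for i, ev in enumerate(data["events"]):
        kind = ev.get("type")
        try:
            if kind == "speciation":
                events.append(Speciation(float(ev["time"]), str(ev["lineage"]),
                                         {str(k): float(v)
                                          for k, v in ev["children"].items()}))
            elif kind == "wgd":
                events.append(WholeGenomeDuplication(
                    float(ev["time"]), str(ev["lineage"]),
                    int(ev.get("ploidy", 2)), float(ev.get("retention", 1.0))))
            else:
                raise FormatError(f"{path}: event {i}: unknown type {kind!r}")
        except KeyError as exc:
            raise FormatError(f"{path}: event {i}: missing field {exc}") from None
    scenario = EvolutionScenario(
        species_labels=[str(s) for s in data["species"]],
        events=events,
        genes_per_chromosome=int(data.get("genes_per_chromosome", 100)),
        chromosomes=int(data.get("chromosomes", 2)),
        codons_per_gene=int(data.get("codons_per_gene", 200)),
        ks_per_myr=float(data.get("ks_per_myr", 0.004)),
        nonsyn_fraction=float(data.get("nonsyn_fraction", 0.0)),
        seed=int(data.get("seed", 0)),
        root=str(data.get("root", "root")),
    )
    scenario.validate()
    return scenario
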