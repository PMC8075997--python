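"""File formats and run configuration.

Plain-text interchange only: gene positions as BED-like TSV (chromosome,
0-based rank, strand, gene id), CDS as FASTA, anchors as 3-column TSV, trees
as newick with coalescent-unit branch lengths, per-pair Ks and per-branch
topology frequencies as TSV, configuration as YAML.  TSV readers validate
line by line and report the offending line number on malformed input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .msc import SpeciesTree


class FormatError(ValueError):
    """Malformed record in an input file; message names file and line."""


_SCHEMAS: dict[str, dict[str, type]] = {
    "positions_tsv": {"chrom": str, "rank": int, "strand": str, "gene_id": str},
    "anchors_tsv": {"gene_a": str, "gene_b": str, "score": float},
    "ks_tsv": {
        "gene_a": str, "gene_b": str, "block_id": str, "S": float, "N": float,
        "Sd": float, "Nd": float, "ks": float, "saturated": int,
    },
    "peaks_tsv": {
        "species_i": str, "species_j": str, "mu": float, "sigma": float,
        "weight": float, "r_squared": float,
    },
    "freqs_tsv": {"branch": str, "q1": float, "q2": float, "q3": float, "n": int},
    "truth_tsv": {
        "gene_a": str, "gene_b": str, "event_id": str, "event_type": str,
        "expected_ks": float,
    },
    "blocks_tsv": {
        "block_id": str, "genome_a": str, "genome_b": str, "chromosome_a": str,
        "chromosome_b": str, "orientation": str, "gene_a": str, "gene_b": str,
        "rank_a": int, "rank_b": int,
    },
}


def read_tsv(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one of the package's TSV schemas."""
    schema = _SCHEMAS[kind]
    columns = list(schema)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != columns:
            raise FormatError(
                f"{path}:1: expected header {columns}, found {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(columns)} fields, "
                    f"found {len(fields)}"
                )
            try:
                rows.append([typ(v) for v, typ in zip(fields, schema.values())])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=columns)


def write_tsv(frame: pd.DataFrame, path: str | Path, kind: str) -> None:
    columns = list(_SCHEMAS[kind])
    frame.loc[:, columns].to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: str | Path, default_terminal: float = 1.0) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text(), default_terminal)


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


@dataclass
class RunConfig:
    """Stage parameters; defaults follow the reproduced study where stated."""

    bandwidth: float = 0.025  # Ks-density kernel bandwidth (Ks units)
    r2_min: float = 0.95  # minimum R^2 for an accepted mixture fit
    max_components: int = 5
    min_block: int = 10  # minimum colinear genes per syntenic block
    max_gap: int = 25
    gap_open: float = 0.05
    depth_window: int = 50
    n_genetrees: int = 20000  # 200,000 also supported
    calibration_low: float = 115.0  # Ma
    calibration_high: float = 130.0  # Ma
    ks_cap: float = 3.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def override(self, **kwargs) -> "RunConfig":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)
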