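"""Synthetic genome-evolution fixtures with planted speciations and WGDs.

The generator produces annotated-genome surrogates (gene order per chromosome
plus coding sequences) for a user-specified evolutionary scenario: an ordered
schedule of speciation events (with per-lineage molecular-clock rate
multipliers) and whole-genome duplication/triplication events (with per-gene
duplicate retention), together with a ground-truth log of every planted
homologous pair and its expected synonymous divergence.

Divergence model
----------------
Synonymous divergence accumulates as a Jukes–Cantor substitution process on
fourfold-degenerate third codon positions.  Ancestral coding sequences are
drawn uniformly over the 24 sense codons of the six fully fourfold-degenerate
codon families (Ala GCN, Gly GGN, Pro CCN, Thr ACN, Val GTN, Ser TCN), so every
codon carries exactly one synonymous site that is exactly fourfold.  A branch
of scaled duration tau (Myr times the lineage rate multiplier) applies a JC
transition of distance ``ks_per_myr * tau`` per synonymous site; JC transitions
compose additively across branches, so a pair separated for total scaled time
T_a + T_b has expected Nei–Gojobori Ks of ``ks_per_myr * (T_a + T_b)`` with no
small-divergence approximation.  Rate multipliers scale branch durations
(a lineage with multiplier r runs its clock r times faster than baseline).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ks as ksmod
from .ks import KS_CAP, SaturationError

# codon index arithmetic: index = 16*i1 + 4*i2 + i3 over the TCAG alphabet
_FOURFOLD3 = np.zeros(64, dtype=bool)
for _i12 in range(16):
    fam = [ksmod.CODONS[4 * _i12 + k] for k in range(4)]
    if all(c in ksmod.AMINO for c in fam) and len({ksmod.AMINO[c] for c in fam}) == 1:
        _FOURFOLD3[4 * _i12 : 4 * _i12 + 4] = True

#: sense codons from fourfold-degenerate families in which *every* member has
#: exactly one NG86 synonymous site (third position only).  Third-position
#: mutation is then closed over the set: the Leu (CTN) and Arg (CGN) families
#: are excluded because some members gain synonymous first-position changes.
FAMILY_CODONS = np.array(
    [
        ksmod.CODON_INDEX[c]
        for c in ksmod.SENSE_CODONS
        if _FOURFOLD3[ksmod.CODON_INDEX[c]]
        and all(
            abs(ksmod.syn_fraction(ksmod.CODONS[4 * (ksmod.CODON_INDEX[c] // 4) + k]) - 1.0)
            < 1e-12
            for k in range(4)
        )
    ]
)

_SENSE_IDX = np.array([ksmod.CODON_INDEX[c] for c in ksmod.SENSE_CODONS])
_SENSE_SET = frozenset(int(i) for i in _SENSE_IDX)


@dataclass(frozen=True)
class Speciation:
    """Split of ``lineage`` into named children, each with a rate multiplier."""

    time: float  # Ma before present
    lineage: str
    children: dict[str, float]  # child lineage name -> rate multiplier (>= 0)


@dataclass(frozen=True)
class WholeGenomeDuplication:
    """In-place genome doubling (ploidy 2) or tripling (ploidy 3)."""

    time: float  # Ma before present
    lineage: str
    ploidy: int = 2
    retention: float = 1.0  # per-duplicate-gene retention probability


Event = Speciation | WholeGenomeDuplication


@dataclass
class EvolutionScenario:
    species_labels: list[str]
    events: list[Event]
    genes_per_chromosome: int = 100
    chromosomes: int = 2
    codons_per_gene: int = 200
    ks_per_myr: float = 0.004  # baseline Ks units per Myr per lineage (r = 1)
    nonsyn_fraction: float = 0.0
    seed: int = 0
    root: str = "root"

    def validate(self) -> None:
        if self.ks_per_myr <= 0:
            raise ValueError("ks_per_myr must be > 0")
        if self.genes_per_chromosome <= 0 or self.chromosomes <= 0:
            raise ValueError("gene/chromosome counts must be positive")
        times = [e.time for e in self.events]
        if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must strictly decrease toward present")
        for ev in self.events:
            if isinstance(ev, WholeGenomeDuplication):
                if not 0.0 <= ev.retention <= 1.0:
                    raise ValueError("retention probability must be in [0, 1]")
                if ev.ploidy not in (2, 3):
                    raise ValueError("ploidy multiplier must be 2 or 3")
            else:
                if any(r < 0 for r in ev.children.values()):
                    raise ValueError("rate multipliers must be >= 0")


@dataclass(frozen=True)
class TruthPair:
    gene_a: str
    gene_b: str
    event_id: str
    event_type: str
    expected_ks: float


@dataclass
class TruthLog:
    """Ground truth: every planted homologous pair, once, with expected Ks."""

    pairs: list[TruthPair]
    rates: dict[str, float]  # extant lineage -> realized rate multiplier
    events: dict[str, tuple[str, float, str]]  # event id -> (type, time, lineage)
    gene_species: dict[str, str]
    ks_per_myr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.gene_a, p.gene_b, p.event_id, p.event_type, p.expected_ks)
                for p in self.pairs
            ],
            columns=["gene_a", "gene_b", "event_id", "event_type", "expected_ks"],
        )


@dataclass
class AnnotatedGenome:
    """Gene order (0-based ranks per chromosome) plus CDS per gene."""

    species: str
    loci: dict[str, list[tuple[str, int, str]]]  # chrom -> [(gene_id, rank, strand)]
    cds: dict[str, str]

    def positions_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, rank, strand, gid)
            for chrom, entries in self.loci.items()
            for gid, rank, strand in entries
        ]
        return pd.DataFrame(rows, columns=["chrom", "rank", "strand", "gene_id"])


# ---------------------------------------------------------------------------
# CDS mutation


def _jc_prob_change(d: float) -> float:
    """Total probability a JC site at distance d differs from its ancestor."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _jc_distance(p: float) -> float:
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def _mutate_codon_array(
    arr: np.ndarray, target_ks: float, rng: np.random.Generator, nonsyn_fraction: float
) -> np.ndarray:
    """Apply synonymous JC divergence (expected NG86 Ks = target) in place."""
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if target_ks > KS_CAP:
        raise SaturationError(f"target_ks {target_ks} exceeds usable cap {KS_CAP}")
    if target_ks == 0 and nonsyn_fraction == 0:
        return arr
    four = _FOURFOLD3[arr]
    n4 = int(four.sum())
    s_ng = float(ksmod._SYN_SITES[arr].sum())
    if target_ks > 0:
        if n4 == 0:
            raise SaturationError("sequence has no fourfold-degenerate sites")
        p_site = _jc_prob_change(target_ks) * s_ng / n4
        if p_site >= 0.75:
            raise SaturationError(
                "target_ks unreachable on this sequence (too few fourfold sites)"
            )
        d_site = _jc_distance(p_site)
        u = rng.random(n4)
        hit = u < _jc_prob_change(d_site)
        if hit.any():
            idx = np.flatnonzero(four)[hit]
            shift = rng.integers(1, 4, size=idx.size)
            arr[idx] = (arr[idx] - arr[idx] % 4) + (arr[idx] % 4 + shift) % 4
    if nonsyn_fraction > 0:
        n_events = rng.poisson(nonsyn_fraction * target_ks * s_ng)
        for _ in range(n_events):
            for _try in range(50):
                pos = int(rng.integers(arr.size))
                which = int(rng.integers(2))  # first or second codon position
                step = int(rng.integers(1, 4))
                old = int(arr[pos])
                i1, i2, i3 = old // 16, (old // 4) % 4, old % 4
                if which == 0:
                    new = 16 * ((i1 + step) % 4) + 4 * i2 + i3
                else:
                    new = 16 * i1 + 4 * ((i2 + step) % 4) + i3
                if new in _SENSE_SET:
                    arr[pos] = new
                    break
    return arr


def codon_str(arr: np.ndarray) -> str:
    return "".join(ksmod.CODONS[i] for i in arr)


def codon_arr(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("CDS length must be divisible by 3")
    out = np.array([ksmod.CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)])
    if any(int(i) not in _SENSE_SET for i in out):
        raise ValueError("CDS contains a stop codon")
    return out


def mutate_cds(
    seq: str, target_ks: float, seed: int, nonsyn_fraction: float = 0.0
) -> str:
    """Return a mutated copy of ``seq`` with expected NG86 Ks of ``target_ks``.

    Synonymous substitutions are applied as exact Jukes–Cantor transitions at
    fourfold-degenerate third positions (scaled so the *NG86-counted* expected
    synonymous difference proportion matches the JC expectation at
    ``target_ks``), plus an optional small nonsynonymous fraction.  Stop codons
    are never introduced; with ``nonsyn_fraction=0`` the protein is unchanged.
    """
    rng = np.random.default_rng(seed)
    arr = codon_arr(seq).copy()
    _mutate_codon_array(arr, target_ks, rng, nonsyn_fraction)
    return codon_str(arr)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random CDS over the fourfold-degenerate codon families (no stops)."""
    return codon_str(rng.choice(FAMILY_CODONS, size=n_codons))


# ---------------------------------------------------------------------------
# History simulation


class _Copy:
    __slots__ = ("node", "family", "strand", "seq")

    def __init__(self, node: int, family: int, strand: str, seq: np.ndarray):
        self.node = node
        self.family = family
        self.strand = strand
        self.seq = seq


class _Lineage:
    __slots__ = ("rate", "depth", "chroms")

    def __init__(self, rate: float, depth: float, chroms: list[list[_Copy]]):
        self.rate = rate
        self.depth = depth
        self.chroms = chroms


def simulate_history(
    scenario: EvolutionScenario,
) -> tuple[list[AnnotatedGenome], TruthLog]:
    """Run the scenario forward in time; return genomes plus ground truth.

    WGD events duplicate whole chromosomes in place (each duplicate chromosome
    inserted next to its template), then each duplicated gene is independently
    retained with the event's retention probability; gene order within retained
    runs is preserved, so colinear blocks exist by construction.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    k = scenario.ks_per_myr

    # genealogy: node -> (parent, event_id, scaled depth at creation)
    parents: dict[int, tuple[int | None, str | None, float]] = {}
    next_node = itertools.count()

    def new_node(parent: int | None, event_id: str | None, depth: float) -> int:
        nid = next(next_node)
        parents[nid] = (parent, event_id, depth)
        return nid

    # ancestral genome
    chroms: list[list[_Copy]] = []
    fam = itertools.count()
    for _c in range(scenario.chromosomes):
        row = []
        for _g in range(scenario.genes_per_chromosome):
            node = new_node(None, None, 0.0)
            strand = "+" if rng.random() < 0.5 else "-"
            seq = rng.choice(FAMILY_CODONS, size=scenario.codons_per_gene)
            row.append(_Copy(node, next(fam), strand, seq))
        chroms.append(row)

    lineages: dict[str, _Lineage] = {scenario.root: _Lineage(1.0, 0.0, chroms)}
    events_meta: dict[str, tuple[str, float, str]] = {}

    def advance(dt: float) -> None:
        if dt <= 0:
            return
        for lin in lineages.values():
            tau = lin.rate * dt
            lin.depth += tau
            target = k * tau
            for chrom in lin.chroms:
                for copy in chrom:
                    _mutate_codon_array(
                        copy.seq, target, rng, scenario.nonsyn_fraction
                    )

    cursor = scenario.events[0].time if scenario.events else 0.0
    for i, ev in enumerate(scenario.events):
        advance(cursor - ev.time)
        cursor = ev.time
        if ev.lineage not in lineages:
            raise ValueError(
                f"event references unknown or extinct lineage {ev.lineage!r}"
            )
        if isinstance(ev, Speciation):
            eid = f"e{i}_speciation_{ev.lineage}"
            events_meta[eid] = ("speciation", ev.time, ev.lineage)
            parent = lineages.pop(ev.lineage)
            for child, rate in ev.children.items():
                if child in lineages:
                    raise ValueError(f"duplicate lineage name {child!r}")
                child_chroms = [
                    [
                        _Copy(
                            new_node(c.node, eid, parent.depth),
                            c.family,
                            c.strand,
                            c.seq.copy(),
                        )
                        for c in chrom
                    ]
                    for chrom in parent.chroms
                ]
                lineages[child] = _Lineage(rate, parent.depth, child_chroms)
        else:
            eid = f"e{i}_wgd_{ev.lineage}"
            events_meta[eid] = ("wgd", ev.time, ev.lineage)
            lin = lineages[ev.lineage]
            new_chroms: list[list[_Copy]] = []
            for chrom in lin.chroms:
                cont = [
                    _Copy(new_node(c.node, eid, lin.depth), c.family, c.strand, c.seq)
                    for c in chrom
                ]
                new_chroms.append(cont)
                for _extra in range(ev.ploidy - 1):
                    dup = [
                        _Copy(
                            new_node(c.node, eid, lin.depth),
                            c.family,
                            c.strand,
                            c.seq.copy(),
                        )
                        for c in chrom
                        if rng.random() < ev.retention
                    ]
                    new_chroms.append(dup)
            lin.chroms = [c for c in new_chroms if c]

    advance(cursor)  # to the present

    if set(lineages) != set(scenario.species_labels):
        raise ValueError(
            f"extant lineages {sorted(lineages)} do not match "
            f"species_labels {sorted(scenario.species_labels)}"
        )

    # emit genomes with final ids
    genomes = []
    leaf_ids: dict[int, str] = {}
    leaf_depth: dict[int, float] = {}
    gene_species: dict[str, str] = {}
    families: dict[int, list[int]] = {}
    for sp in scenario.species_labels:
        lin = lineages[sp]
        loci: dict[str, list[tuple[str, int, str]]] = {}
        cds: dict[str, str] = {}
        for ci, chrom in enumerate(lin.chroms, start=1):
            cname = f"chr{ci:02d}"
            entries = []
            for rank, copy in enumerate(chrom):
                gid = f"{sp}_{cname}_{rank:05d}"
                entries.append((gid, rank, copy.strand))
                cds[gid] = codon_str(copy.seq)
                leaf_ids[copy.node] = gid
                leaf_depth[copy.node] = lin.depth
                gene_species[gid] = sp
                families.setdefault(copy.family, []).append(copy.node)
            loci[cname] = entries
        genomes.append(AnnotatedGenome(sp, loci, cds))

    # truth pairs: every pair of extant copies within a family, once
    def path(node: int) -> list[int]:
        chain = []
        cur: int | None = node
        while cur is not None:
            chain.append(cur)
            cur = parents[cur][0]
        return chain[::-1]

    pairs: list[TruthPair] = []
    for members in families.values():
        if len(members) < 2:
            continue
        paths = {n: path(n) for n in members}
        for na, nb in itertools.combinations(members, 2):
            pa, pb = paths[na], paths[nb]
            depth_idx = 0
            while depth_idx < min(len(pa), len(pb)) and pa[depth_idx] == pb[depth_idx]:
                depth_idx += 1
            # first differing nodes share their creation event
            _, eid, d_split = parents[pa[depth_idx]]
            etype = events_meta[eid][0] if eid else "root"
            exp = k * (leaf_depth[na] + leaf_depth[nb] - 2.0 * d_split)
            pairs.append(
                TruthPair(leaf_ids[na], leaf_ids[nb], eid or "root", etype, exp)
            )

    truth = TruthLog(
        pairs=pairs,
        rates={sp: lineages[sp].rate for sp in scenario.species_labels},
        events=events_meta,
        gene_species=gene_species,
        ks_per_myr=k,
    )
    return genomes, truth


def emit_anchor_pairs(
    truth: TruthLog, noise_fraction: float, seed: int
) -> pd.DataFrame:
    """Anchor table: all true homologous pairs plus random spurious pairs.

    ``noise_fraction`` adds ``round(noise_fraction * n_true)`` uniformly random
    gene pairs that are not true pairs.
    """
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = [(p.gene_a, p.gene_b) for p in truth.pairs]
    true_set = {frozenset(r) for r in rows}
    all_genes = sorted(truth.gene_species)
    n_noise = round(noise_fraction * len(rows))
    while n_noise > 0:
        a, b = (all_genes[int(i)] for i in rng.integers(len(all_genes), size=2))
        if a == b or frozenset((a, b)) in true_set:
            continue
        true_set.add(frozenset((a, b)))
        rows.append((a, b))
        n_noise -= 1
    scores = rng.uniform(50.0, 100.0, size=len(rows))
    return pd.DataFrame(
        {"gene_a": [r[0] for r in rows], "gene_b": [r[1] for r in rows], "score": scores}
    )
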