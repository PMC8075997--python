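"""Synonymous divergence (Ks) estimation by the Nei–Gojobori (1986) method.

Pairs of pre-aligned coding sequences are compared codon by codon. Each codon
position contributes a fractional number of *synonymous sites* (the fraction of
possible single-nucleotide changes that preserve the amino acid, mutations to
stop codons being excluded from the denominator), and each differing codon pair
contributes synonymous/nonsynonymous *differences* averaged over all orderings
of the single-step substitution pathways between the two codons. Pathways that
pass through a stop codon are excluded and the remaining pathways reweighted.
The proportion of synonymous differences per synonymous site is then corrected
for multiple hits with the Jukes–Cantor formula,

    Ks = -(3/4) * ln(1 - (4/3) * Sd/S),

undefined (saturated) once Sd/S >= 3/4.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import log
from statistics import median

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCS = "TCAG"
CODONS = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
AMINO = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

#: Ks values above this are treated as saturated even when finite; near the
#: Jukes–Cantor domain boundary the estimator variance explodes and standard
#: Ks-age analyses truncate there.
KS_CAP = 3.0


class SaturationError(ValueError):
    """Raised when a requested divergence exceeds the usable Ks range."""


@dataclass(frozen=True)
class NGCounts:
    """Nei–Gojobori site and difference counts for one aligned pair."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    codons_used: int

    def __add__(self, other: "NGCounts") -> "NGCounts":
        return NGCounts(
            self.syn_sites + other.syn_sites,
            self.nonsyn_sites + other.nonsyn_sites,
            self.syn_diffs + other.syn_diffs,
            self.nonsyn_diffs + other.nonsyn_diffs,
            self.codons_used + other.codons_used,
        )


@dataclass(frozen=True)
class KsValue:
    """Jukes–Cantor-corrected synonymous divergence with a saturation flag."""

    ks: float
    saturated: bool


def syn_fraction(codon: str) -> float:
    """Number of synonymous sites (0..3) in ``codon``.

    Per position: the fraction of the three alternative nucleotides that give a
    synonymous codon, over the alternatives that are not stop codons.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = AMINO[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if AMINO[alt] == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s


@lru_cache(maxsize=None)
def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two sense codons.

    Averaged over all orderings of the single-nucleotide substitution pathway;
    orderings that pass through a stop codon are dropped and the rest
    reweighted.  If every ordering is blocked (never the case for sense-codon
    pairs under the standard code, but guarded), all orderings are used with
    steps into or out of stop codons counted as nonsynonymous.
    """
    if c1 == c2:
        return (0.0, 0.0)
    positions = [i for i in range(3) if c1[i] != c2[i]]

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        syn = nonsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                if not allow_stops:
                    return None
                nonsyn += 1.0
            elif AMINO[cur] == AMINO[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    paths = [p for p in (walk(o, False) for o in itertools.permutations(positions)) if p]
    if not paths:
        paths = [walk(o, True) for o in itertools.permutations(positions)]
    syn = sum(p[0] for p in paths) / len(paths)
    nonsyn = sum(p[1] for p in paths) / len(paths)
    return (syn, nonsyn)


# Precomputed 64x64 lookup tables so that whole-genome pair scans are array
# operations rather than per-codon Python.
_SYN_SITES = np.array(
    [syn_fraction(c) if c not in STOP_CODONS else np.nan for c in CODONS]
)
_SD = np.full((64, 64), np.nan)
_ND = np.full((64, 64), np.nan)
for _c1 in SENSE_CODONS:
    for _c2 in SENSE_CODONS:
        _sd, _nd = _pair_diffs(_c1, _c2)
        _SD[CODON_INDEX[_c1], CODON_INDEX[_c2]] = _sd
        _ND[CODON_INDEX[_c1], CODON_INDEX[_c2]] = _nd


def _codon_indices(seq: str) -> np.ndarray:
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    seq = seq.upper().replace("U", "T")
    try:
        return np.array([CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)])
    except KeyError:
        # keep ambiguous codons; mark with -1 so they are skipped
        out = []
        for i in range(0, len(seq), 3):
            out.append(CODON_INDEX.get(seq[i : i + 3], -1))
        return np.array(out)


def ng86_counts(seq_a: str, seq_b: str) -> NGCounts:
    """Nei–Gojobori site/difference counts for an aligned codon pair.

    Codons containing gaps, ambiguity codes, or stops (in either sequence) are
    skipped.  Site counts are averaged over the two sequences.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    ia, ib = _codon_indices(seq_a), _codon_indices(seq_b)
    ok = (ia >= 0) & (ib >= 0)
    ok &= ~np.isnan(_SYN_SITES[np.where(ok, ia, 0)])
    ok &= ~np.isnan(_SYN_SITES[np.where(ok, ib, 0)])
    ia, ib = ia[ok], ib[ok]
    n_codons = int(ia.size)
    if n_codons == 0:
        raise ValueError("no usable codons in aligned pair")
    s = float((_SYN_SITES[ia].sum() + _SYN_SITES[ib].sum()) / 2.0)
    sd = float(_SD[ia, ib].sum())
    nd = float(_ND[ia, ib].sum())
    return NGCounts(s, 3.0 * n_codons - s, sd, nd, n_codons)


def ks_jc(counts: NGCounts, cap: float = KS_CAP) -> KsValue:
    """Jukes–Cantor-corrected Ks from NG86 counts.

    Saturated when the synonymous difference proportion reaches 3/4 (the JC
    domain boundary) or the corrected value exceeds ``cap``.
    """
    if counts.syn_sites <= 0:
        raise ValueError("no synonymous sites; Ks undefined")
    p_s = counts.syn_diffs / counts.syn_sites
    if p_s >= 0.75:
        return KsValue(float("inf"), True)
    ks = -0.75 * log(1.0 - (4.0 / 3.0) * p_s)
    return KsValue(ks, ks > cap)


def pair_ks(seq_a: str, seq_b: str, cap: float = KS_CAP) -> KsValue:
    """Convenience: NG86 counts then JC correction."""
    return ks_jc(ng86_counts(seq_a, seq_b), cap=cap)


def block_median_ks(ks_values: list[KsValue]) -> tuple[float, int]:
    """Median Ks over the unsaturated values of a syntenic block.

    Returns ``(median, n_saturated_excluded)``.  Raises if every value is
    saturated — callers drop such blocks and log them.
    """
    usable = [v.ks for v in ks_values if not v.saturated]
    n_sat = len(ks_values) - len(usable)
    if not usable:
        raise ValueError("all Ks values in block saturated")
    return float(median(usable)), n_sat
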