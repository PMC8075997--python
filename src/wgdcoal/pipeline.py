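"""End-to-end stage drivers shared by the CLI, the analysis scripts and tests.

WGD pipeline: anchors -> syntenic blocks -> per-anchor NG86 Ks -> per-block
median Ks -> per-comparison density curve and Gaussian mixture -> rate
correction -> dated events.

ILS pipeline: species tree -> MSC gene trees -> per-branch topology
frequencies -> Spearman concordance with an empirical frequency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ks as ksmod
from .io import RunConfig
from .msc import GeneTreeSet, SpeciesTree, concordance, simulate_gene_trees, topology_freqs
from .peaks import GaussianComponent, KdeCurve, MixtureFit, dominant_component, fit_mixture, kde
from .ratecorr import (
    Calibration,
    CorrectedDistribution,
    PeakTable,
    RateModel,
    correct_distribution,
    date_event,
    estimate_a,
    solve_lambda,
)
from .synteny import ChainParams, SyntenicBlock, chain_anchors

log = logging.getLogger("wgdcoal")


def annotate_block_ks(
    blocks: list[SyntenicBlock], cds: dict[str, str], cap: float = ksmod.KS_CAP
) -> list[SyntenicBlock]:
    """Fill per-anchor Ks and the block median; drop all-saturated blocks."""
    kept = []
    for block in blocks:
        values = []
        for gene_a, gene_b, _, _ in block.anchors:
            values.append(ksmod.pair_ks(cds[gene_a], cds[gene_b], cap=cap))
        block.ks_values = [v.ks for v in values]
        try:
            block.median_ks, n_sat = ksmod.block_median_ks(values)
        except ValueError:
            log.info(
                "dropping block %s-%s %s/%s: all %d Ks values saturated",
                block.genome_a, block.genome_b, block.chromosome_a,
                block.chromosome_b, len(block),
            )
            continue
        if n_sat:
            log.debug("block median over %d values (%d saturated excluded)",
                      len(block) - n_sat, n_sat)
        kept.append(block)
    return kept


def comparison_medians(blocks: list[SyntenicBlock]) -> dict[tuple[str, str], list[float]]:
    """Per-comparison lists of block median Ks (the peak-fitting input)."""
    out: dict[tuple[str, str], list[float]] = {}
    for b in blocks:
        if b.median_ks is None:
            continue
        key = tuple(sorted((b.genome_a, b.genome_b)))
        out.setdefault(key, []).append(b.median_ks)
    return out


@dataclass
class ComparisonFit:
    curve: KdeCurve
    fit: MixtureFit
    n_blocks: int


def fit_all_comparisons(
    medians: dict[tuple[str, str], list[float]], config: RunConfig
) -> dict[tuple[str, str], ComparisonFit]:
    fits = {}
    for key, values in sorted(medians.items()):
        if len(values) < 5:
            log.warning("comparison %s-%s has only %d blocks; skipped", *key, len(values))
            continue
        curve = kde(values, bandwidth=config.bandwidth)
        fit = fit_mixture(curve, config.max_components, config.r2_min)
        fits[key] = ComparisonFit(curve, fit, len(values))
    return fits


def build_peak_table(
    fits: dict[tuple[str, str], ComparisonFit],
    overrides: dict[tuple[str, str], int] | None = None,
) -> PeakTable:
    """Pick each between-genome comparison's divergence peak.

    Default: the largest-weight mixture component; ``overrides`` maps a
    comparison to an explicit component index (sorted by mu) instead.
    """
    table = PeakTable()
    for key, comp_fit in fits.items():
        if key[0] == key[1]:
            continue
        if overrides and key in overrides:
            table[key] = comp_fit.fit.components[overrides[key]]
        else:
            table[key] = dominant_component(comp_fit.fit)
    return table


@dataclass
class DatedEvent:
    label: str
    raw_mu: float
    corrected: CorrectedDistribution
    age_low: float
    age_high: float
    age_low_rounded: int
    age_high_rounded: int


def date_within_genome_events(
    fits: dict[tuple[str, str], ComparisonFit],
    model: RateModel,
    calibration: Calibration,
    reference_species: str,
    reference_component: GaussianComponent,
) -> list[DatedEvent]:
    """Date every within-genome mixture component against the calibration.

    ``reference_component`` is the (raw) paralog peak of the calibrated event
    in ``reference_species``; its corrected value anchors the clock.
    """
    lam_ref = model.lam[reference_species]
    mu_ref = correct_distribution(reference_component, lam_ref, lam_ref).mu_corrected
    cal = Calibration(
        calibration.label, mu_ref, calibration.age_low, calibration.age_high
    )
    events = []
    for (gi, gj), comp_fit in sorted(fits.items()):
        if gi != gj:
            continue
        lam = model.lam.get(gi)
        if lam is None:
            log.warning("no rate coefficient for %s; within-genome peaks undated", gi)
            continue
        for idx, comp in enumerate(comp_fit.fit.components):
            corrected = correct_distribution(comp, lam, lam)
            interval = date_event(corrected, cal)
            events.append(
                DatedEvent(
                    f"{gi} peak {idx + 1}",
                    comp.mu,
                    corrected,
                    interval.low,
                    interval.high,
                    interval.low_rounded,
                    interval.high_rounded,
                )
            )
    return events


def wgd_pipeline(
    genomes: dict[str, pd.DataFrame],
    cds: dict[str, str],
    anchors: pd.DataFrame,
    config: RunConfig = RunConfig(),
) -> tuple[list[SyntenicBlock], dict[tuple[str, str], ComparisonFit]]:
    """Chain anchors, estimate Ks, fit per-comparison peaks."""
    params = ChainParams(
        min_block=config.min_block, max_gap=config.max_gap, gap_open=config.gap_open
    )
    blocks = chain_anchors(anchors, genomes, params)
    log.info("chained %d syntenic blocks", len(blocks))
    blocks = annotate_block_ks(blocks, cds, cap=config.ks_cap)
    fits = fit_all_comparisons(comparison_medians(blocks), config)
    return blocks, fits


@dataclass
class IlsResult:
    frequencies: pd.DataFrame
    genetrees: GeneTreeSet


def ils_pipeline(
    tree: SpeciesTree,
    branches: list[frozenset[str]],
    n: int,
    seed: int,
) -> IlsResult:
    """Simulate gene trees and summarize per-branch topology frequencies."""
    genetrees = simulate_gene_trees(tree, n, seed)
    rows = []
    for clade in branches:
        f = topology_freqs(genetrees, tree, clade)
        rows.append(("|".join(sorted(clade)), f.q1, f.q2, f.q3, f.n))
    table = pd.DataFrame(rows, columns=["branch", "q1", "q2", "q3", "n"])
    return IlsResult(table, genetrees)


def concordance_from_tables(
    empirical: pd.DataFrame, simulated: pd.DataFrame
) -> tuple[float, float]:
    """Spearman concordance of two frequency TSV tables (matched on branch)."""
    merged = empirical.merge(simulated, on="branch", suffixes=("_emp", "_sim"))
    if merged.empty:
        raise ValueError("no shared branch ids between frequency tables")
    emp = merged[["q1_emp", "q2_emp", "q3_emp"]].to_numpy().ravel()
    sim = merged[["q1_sim", "q2_sim", "q3_sim"]].to_numpy().ravel()
    return concordance(emp, sim)
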