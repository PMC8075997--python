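"""Evolutionary-rate correction of Ks peaks and event dating.

Lineages differ in synonymous substitution rate, so raw Ks peaks are not
comparable across genomes.  Writing r_i for the ratio of species i's rate to
the angiosperm average, each species gets a correction coefficient
lambda_i = 1/r_i, and the Ks distribution of an i-j comparison
N(mu_ij, sigma_ij^2) is rescaled to N(lambda_i*lambda_j*mu_ij,
lambda_i^2*lambda_j^2*sigma_ij^2).

The lambdas are estimated from shared basal divergences: because the two
anchor species (Amborella-like "At" and Euryale-like "Ef") diverged from every
other studied genome at essentially the same time, the corrected At-i and Ef-i
peaks must equal the corrected At-Vv and Ef-Vv peaks, giving

    a_i = lambda_i / lambda_Vv = mean{ mu_At-Vv / mu_At-i, mu_Ef-Vv / mu_Ef-i }.

The slowest lineage is taken to evolve at the Amborella rate (lambda_At = 1 and
max{lambda_i} = 1), so lambda_Vv = 1 / max{a_i} and lambda_i = lambda_Vv * a_i.
A reference event of known age (default: the major-eudicot common hexaploidy,
115-130 Ma, seen in the grape paralog peak) converts corrected peaks to ages by
linear scaling of both calibration endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .peaks import GaussianComponent

#: canonical anchor/reference labels used throughout (overridable per call)
ANCHOR_A = "At"  # slow, never re-polyploidized after its basal divergence
ANCHOR_B = "Ef"
REFERENCE = "Vv"  # carries the calibrated reference polyploidy


def _key(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


class PeakTable(dict):
    """Map (species i, species j) -> divergence-peak GaussianComponent.

    Within-genome paralog peaks use i == j.  Keys are order-insensitive.
    """

    def __setitem__(self, key, value):
        super().__setitem__(_key(*key), value)

    def __getitem__(self, key) -> GaussianComponent:
        return super().__getitem__(_key(*key))

    def __contains__(self, key) -> bool:
        return super().__contains__(_key(*key))

    def mu(self, i: str, j: str) -> float:
        if (i, j) not in self:
            raise KeyError(f"missing Ks peak for comparison {i}-{j}")
        return self[i, j].mu


@dataclass
class RateModel:
    a: dict[str, float]  # species -> a_i ratio
    lam: dict[str, float]  # species -> correction coefficient lambda_i
    pin_conflict: float  # |max corrected lambda - 1| (0 when the pins agree)

    @property
    def implied_r(self) -> dict[str, float]:
        return {s: 1.0 / l for s, l in self.lam.items()}


@dataclass(frozen=True)
class CorrectedDistribution:
    mu_corrected: float
    sigma_corrected: float


@dataclass(frozen=True)
class Calibration:
    label: str = "major-eudicot common hexaploidy"
    mu_ref: float = 0.0  # corrected Ks peak of the reference event
    age_low: float = 115.0  # Ma
    age_high: float = 130.0  # Ma

    def __post_init__(self) -> None:
        if not 0.0 < self.age_low < self.age_high:
            raise ValueError("calibration requires 0 < age_low < age_high")


def estimate_a(
    peaks: PeakTable,
    species: str,
    anchor_a: str = ANCHOR_A,
    anchor_b: str = ANCHOR_B,
    reference: str = REFERENCE,
) -> float:
    """a_i = mean of the anchor peak ratios mu_anchor-ref / mu_anchor-i.

    Returns exactly 1 for the reference species itself.  For a species that is
    itself one of the anchors, only the ratio through the other anchor is
    defined and is used alone.
    """
    if species == reference:
        return 1.0
    ratios = []
    for anchor in (anchor_a, anchor_b):
        if species == anchor:
            continue
        ratios.append(peaks.mu(anchor, reference) / peaks.mu(anchor, species))
    if not ratios:
        raise KeyError(f"no anchor comparison available for species {species!r}")
    return sum(ratios) / len(ratios)


def solve_lambda(
    a: dict[str, float], anchor_a: str = ANCHOR_A, reference: str = REFERENCE
) -> RateModel:
    """Solve the lambda coefficients from the a_i ratios.

    lambda_ref = 1 / max{a_i}; lambda_i = lambda_ref * a_i; the anchor species
    is pinned to lambda = 1.  The two pins coincide exactly when the slowest
    corrected species evolves at the anchor rate; any discrepancy is reported
    as ``pin_conflict`` rather than silently rescaled.
    """
    if not a:
        raise ValueError("empty a_i table")
    if any(v <= 0 for v in a.values()):
        raise ValueError("a_i ratios must be positive")
    lam_ref = 1.0 / max(a.values())
    lam = {sp: lam_ref * ai for sp, ai in a.items()}
    conflict = abs(max(lam.values()) - 1.0)
    lam[anchor_a] = 1.0
    lam.setdefault(reference, lam_ref)
    return RateModel(a=dict(a), lam=lam, pin_conflict=conflict)


def correct_distribution(
    peak: GaussianComponent, lam_i: float, lam_j: float
) -> CorrectedDistribution:
    """Rescale a Ks peak by lambda_i*lambda_j (within-genome: i == j, lambda^2)."""
    if lam_i <= 0 or lam_j <= 0:
        raise ValueError("lambda coefficients must be positive")
    f = lam_i * lam_j
    return CorrectedDistribution(f * peak.mu, f * peak.sigma)


@dataclass(frozen=True)
class AgeInterval:
    low: float  # raw Ma
    high: float
    low_rounded: int
    high_rounded: int


def date_event(event_peak: CorrectedDistribution, cal: Calibration) -> AgeInterval:
    """Age interval by linear scaling of the calibration range.

    Both endpoints scale with mu_event/mu_ref, so the high/low ratio of every
    dated interval equals age_high/age_low of the calibration.  Endpoints are
    rounded to integer Ma for reporting; raw values are retained.
    """
    if cal.mu_ref <= 0:
        raise ValueError("calibration reference peak must be positive")
    if event_peak.mu_corrected <= 0:
        raise ValueError("event peak must be positive")
    scale = event_peak.mu_corrected / cal.mu_ref
    low, high = scale * cal.age_low, scale * cal.age_high
    return AgeInterval(low, high, round(low), round(high))


@dataclass
class ConsistencyReport:
    deviations: dict[tuple[str, str], float]
    max_relative_deviation: float


def consistency_check(
    peaks: PeakTable,
    model: RateModel,
    anchor_a: str = ANCHOR_A,
    anchor_b: str = ANCHOR_B,
    reference: str = REFERENCE,
) -> ConsistencyReport:
    """Verify the basal-divergence identity the correction is built on.

    After correction every anchor-i peak should equal the corresponding
    anchor-reference peak; reports the relative deviation per comparison and
    the maximum.
    """
    devs: dict[tuple[str, str], float] = {}
    for anchor in (anchor_a, anchor_b):
        ref_mu = correct_distribution(
            peaks[anchor, reference], model.lam[anchor], model.lam[reference]
        ).mu_corrected
        for sp in model.lam:
            if sp in (anchor, reference) or (anchor, sp) not in peaks:
                continue
            mu = correct_distribution(
                peaks[anchor, sp], model.lam[anchor], model.lam[sp]
            ).mu_corrected
            devs[(anchor, sp)] = abs(mu - ref_mu) / ref_mu
    max_dev = max(devs.values()) if devs else 0.0
    return ConsistencyReport(devs, max_dev)
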