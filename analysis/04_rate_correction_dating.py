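#!/usr/bin/env python
"""Correct the Ks peaks for lineage rate differences and date the events.

Solves the lambda coefficients from the shared basal divergences (anchors At
and Ef against the reference Vv), verifies that the corrected between-genome
peaks coincide, and converts the within-Vv paralog peaks to ages against the
115-130 Ma reference calibration.  The fixture's younger Vv polyploidy was
planted at 60 Ma; its recovered interval is the pipeline's headline number.
"""

import json
from pathlib import Path

import pandas as pd

from wgdcoal.io import RunConfig, read_tsv
from wgdcoal.peaks import GaussianComponent
from wgdcoal.pipeline import ComparisonFit, date_within_genome_events
from wgdcoal.ratecorr import (
    Calibration,
    PeakTable,
    consistency_check,
    estimate_a,
    solve_lambda,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig()
    frame = read_tsv(BASE / "peaks.tsv", "peaks_tsv")
    table = PeakTable()
    within = {}
    for (gi, gj), grp in frame.groupby(["species_i", "species_j"]):
        comps = [GaussianComponent(r.mu, r.sigma, r.weight)
                 for r in grp.itertuples()]
        if gi == gj:
            within[gi] = comps
        else:
            table[gi, gj] = max(comps, key=lambda c: c.weight)

    a = {sp: estimate_a(table, sp) for sp in ("Ef", "Vv")}
    model = solve_lambda(a)
    print("a ratios:", {k: round(v, 4) for k, v in a.items()})
    print("lambda:", {k: round(v, 4) for k, v in model.lam.items()},
          f"(pin conflict {model.pin_conflict:.4f})")
    report = consistency_check(table, model)
    print(f"corrected basal peaks agree to "
          f"{100 * report.max_relative_deviation:.2f}% max deviation")

    # rebuild minimal fit objects for the dating helper
    from wgdcoal.peaks import KdeCurve, MixtureFit
    import numpy as np

    fits = {}
    for sp, comps in within.items():
        fits[(sp, sp)] = ComparisonFit(
            KdeCurve(np.array([0.0, 1.0]), np.array([0.0, 0.0]), config.bandwidth),
            MixtureFit(sorted(comps, key=lambda c: c.mu), 1.0), len(comps))
    reference = max(within["Vv"], key=lambda c: c.mu)
    cal = Calibration(age_low=config.calibration_low,
                      age_high=config.calibration_high)
    events = date_within_genome_events(fits, model, cal, "Vv", reference)
    rows = [(e.label, round(e.raw_mu, 4), round(e.corrected.mu_corrected, 4),
             e.age_low_rounded, e.age_high_rounded) for e in events]
    out = pd.DataFrame(rows, columns=["event", "raw_mu", "corrected_mu",
                                      "age_low", "age_high"])
    out.to_csv(BASE / "dated_events.tsv", sep="\t", index=False)
    (BASE / "rate_model.json").write_text(json.dumps(
        {"a": model.a, "lambda": model.lam,
         "pin_conflict": model.pin_conflict}, indent=2))
    print(out.to_string(index=False))
    print(f"dated events -> {BASE / 'dated_events.tsv'}")


if __name__ == "__main__":
    main()
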