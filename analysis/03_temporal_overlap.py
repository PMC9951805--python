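#!/usr/bin/env python
"""Temporal overlap from the simulated detections: circular KDE and Δ.

Converts filtered capture times to radians, estimates each species' diel
activity density with a von Mises kernel, computes the coefficient of
overlapping with both estimators (Δ̂1 and Δ̂4, the latter being the
appropriate choice since both samples exceed 75 detections), classifies the
overlap, compares against the generating truth, and summarises activity by
diel period (dawn 04:00–06:00, day 06:00–18:30, dusk 18:30–20:30, night
20:30–04:00).

Writes results/temporal_overlap.json and results/activity_overlap.png.
"""

import json
from collections import Counter
from pathlib import Path

from civetniche.core_io import filter_independent, read_detections
from civetniche.plots import activity_overlap_plot
from civetniche.temporal_overlap import (
    activity_profile,
    assign_diel_period,
    overlap_delta1,
    overlap_delta4,
    times_to_radians,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SPECIES = ("asian_palm_civet", "small_indian_civet")


def main() -> None:
    truth = json.loads((OUT / "simulation_truth.json").read_text())
    filtered = filter_independent(read_detections(OUT / "detections.csv"), 30)
    samples = {sp: times_to_radians(filtered.times_for(sp), species=sp) for sp in SPECIES}
    print("sample sizes:", {sp: s.n for sp, s in samples.items()})

    d4 = overlap_delta4(samples[SPECIES[0]], samples[SPECIES[1]])
    d1 = overlap_delta1(samples[SPECIES[0]], samples[SPECIES[1]])
    print(f"Δ̂4 = {d4.value:.4f} ({d4.classification}); Δ̂1 = {d1.value:.4f} "
          f"({d1.classification}); generating-truth Δ = "
          f"{truth['true_temporal_overlap']:.4f}")

    diel = {
        sp: dict(Counter(assign_diel_period(t) for t in filtered.times_for(sp)))
        for sp in SPECIES
    }
    print("detections by diel period:", diel)
    for sp in SPECIES:
        peaks = activity_profile(filtered, sp, bin_hours=1.0)["peaks"]
        print(f"activity peaks ({sp}):", peaks)

    out = {
        "delta4": d4.as_dict(),
        "delta1": d1.as_dict(),
        "true_overlap": truth["true_temporal_overlap"],
        "diel_period_counts": diel,
    }
    (OUT / "temporal_overlap.json").write_text(json.dumps(out, indent=2) + "\n")
    activity_overlap_plot(
        samples[SPECIES[0]], samples[SPECIES[1]], OUT / "activity_overlap.png"
    )


if __name__ == "__main__":
    main()
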