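#!/usr/bin/env python
"""Morphometry utilities on worked numeric examples.

Computes spindle-plane angles for canonical orientations, a Cavalieri volume
from systematically sampled section areas (10 um sections, every tenth
measured), and dye-dilution proliferation indices for reference populations.
Writes results/morphometry.tsv.
"""

import csv
from pathlib import Path

from autozyg.morphometry_stats import (
    GenerationCounts,
    SpindleMeasurement,
    cavalieri_volume,
    proliferation_index,
    spindle_angle,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows: list[tuple[str, str]] = []

    surface = ((0.0, 0.0), (1.0, 0.0))
    for label, b in (("horizontal", (2.0, 0.0)), ("diagonal", (1.0, 1.0)),
                     ("vertical", (0.0, 2.0))):
        angle = spindle_angle(SpindleMeasurement((0.0, 0.0), b, *surface))
        rows.append((f"spindle_angle_{label}_deg", f"{angle:.2f}"))

    areas = [1250.0, 1430.0, 1390.0, 1180.0, 990.0]  # um^2, every tenth 10 um section
    rows.append(("cavalieri_volume_um3", f"{cavalieri_volume(areas, 10.0, 10):.1f}"))

    for label, counts in (
        ("undivided", (400,)),
        ("once_divided", (0, 400)),
        ("mixed", (100, 150, 120, 40)),
    ):
        pi = proliferation_index(GenerationCounts(counts))
        rows.append((f"proliferation_index_{label}", f"{pi:.4f}"))

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "morphometry.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["quantity", "value"])
        writer.writerows(rows)
    for name, value in rows:
        print(f"{name}: {value}")


if __name__ == "__main__":
    main()
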