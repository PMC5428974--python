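#!/usr/bin/env python
"""Run the recessive exclusion cascade — published example and simulated cohort.

First replays the encoded four-variant worked example (ARHGEF2 / EXTL1 /
HMCN1 / IGFN1 with their published annotation evidence), then prioritizes
the shared homozygous variants of the simulated cohort and scans its X
chromosome-free genome for hemizygous candidates.  Reports go to results/.
"""

import subprocess
import sys
from pathlib import Path

from autozyg.case_study import run_worked_example
from autozyg.prioritization import (
    attach_annotations,
    exclusion_rank,
    read_annotations,
    shared_homozygous_candidates,
    write_report,
)
from autozyg.roh_mapping import autozygome
from autozyg.variant_io import read_pedigree, read_variants

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    verdicts = run_worked_example()
    write_report(verdicts, RESULTS / "worked_example_verdicts.tsv")
    print("worked example (published annotation evidence):")
    for v in verdicts:
        reasons = "; ".join(v.reasons) or "-"
        print(f"  {v.variant_id:24s} {v.status:9s} {reasons}")

    sim = RESULTS / "sim"
    if not (sim / "sim.vcf").exists():
        subprocess.run(
            [sys.executable, str(Path(__file__).with_name("01_simulate_cohort.py"))],
            check=True,
        )
    variants = read_variants(sim / "sim.vcf")
    pedigree = read_pedigree(sim / "sim.ped")
    attach_annotations(variants, read_annotations(sim / "sim.annotations.tsv"))
    shared = autozygome(variants, pedigree).shared
    candidates = [
        (v, v.annotations) for v in shared_homozygous_candidates(variants, pedigree)
    ]
    sim_verdicts = exclusion_rank(candidates, pedigree, shared)
    write_report(sim_verdicts, RESULTS / "sim_candidate_verdicts.tsv")
    retained = [v for v in sim_verdicts if v.status == "retained"]
    print(f"\nsimulated cohort: {len(sim_verdicts)} shared homozygous candidates, "
          f"{len(retained)} retained:")
    for v in retained:
        print(f"  retained: {v.variant_id}")


if __name__ == "__main__":
    main()
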