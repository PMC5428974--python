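#!/usr/bin/env python
"""Map the shared autozygome of the two affected children.

Classifies every genotype call (GQ >= 20, depth >= 10, allele fraction >=
0.9), detects runs of >= 4 consecutive high-quality homozygous SNVs per
child, intersects them, and keeps shared pieces > 1 Mb — the candidate
regions for a recessive disease allele.  Writes per-sample and shared BED
tracks plus a summary table under results/.
"""

import csv
import subprocess
import sys
from pathlib import Path

from autozyg.roh_mapping import autozygome
from autozyg.variant_io import read_pedigree, read_variants, write_roh_bed

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = RESULTS / "sim"
    if not (sim / "sim.vcf").exists():
        subprocess.run(
            [sys.executable, str(Path(__file__).with_name("01_simulate_cohort.py"))],
            check=True,
        )
    variants = read_variants(sim / "sim.vcf")
    pedigree = read_pedigree(sim / "sim.ped")
    result = autozygome(variants, pedigree)

    for sample, track in result.per_sample.items():
        path = RESULTS / f"roh.{sample}.bed"
        write_roh_bed(track, path)
        total = sum(iv.length for iv in track) / 1e6
        print(f"{sample}: {len(track)} runs, {total:.2f} Mb -> {path}")
    shared_path = RESULTS / "roh.shared.bed"
    write_roh_bed(result.shared, shared_path)

    table_path = RESULTS / "shared_roh_table.tsv"
    with open(table_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chromosome", "start", "end", "length_mb", "n_supporting_snvs"])
        for iv in result.shared:
            writer.writerow(
                [iv.chromosome, iv.start, iv.end, f"{iv.length / 1e6:.3f}", iv.n_snvs]
            )
    total = sum(iv.length for iv in result.shared) / 1e6
    print(f"shared autozygome: {len(result.shared)} intervals > 1 Mb, "
          f"{total:.2f} Mb total -> {shared_path}, {table_path}")


if __name__ == "__main__":
    main()
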