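#!/usr/bin/env python
"""Predict the consequence of a splice-donor-adjacent single-base deletion.

A two-exon toy transcript models the situation of a 1 bp deletion at the
final exonic base before a splice donor: the donor shifts to recruit the
neighbouring base, the spliced cDNA loses exactly one base, and translation
frameshifts to a premature stop.  The same deletion is re-encoded on the
minus strand to show the genomic delC / cDNA delG coordinate conversion.
"""

from pathlib import Path

from autozyg.consequence import (
    TranscriptModel,
    apply_boundary_deletion,
    spliced_cdna,
    translate_consequence,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RC = str.maketrans("ACGT", "TGCA")


def report(t: TranscriptModel, deletion: tuple[int, int]) -> str:
    original = spliced_cdna(t)
    res = apply_boundary_deletion(t, deletion)
    pc = translate_consequence(original, res.edited_cdna, t.cds_start, t.cds_end)
    lines = [
        f"transcript {t.id} ({t.strand} strand), genomic deletion "
        f"[{deletion[0]}, {deletion[1]})",
        f"  spliced cDNA: {original} -> {res.edited_cdna}",
        f"  cDNA change:  {res.cdna_hgvs}",
        f"  protein:      {pc.hgvs_p} ({pc.kind}, stop offset {pc.stop_offset})",
    ]
    return "\n".join(lines)


def main() -> None:
    genome = "TTT" + "ATGAAG" + "GTAAGT" + "CTGACCTAA" + "TTT"
    plus = TranscriptModel(
        id="toy_plus", strand="+", exons=[(3, 9), (15, 24)],
        cds_start=0, cds_end=15, genomic_sequence=genome,
    )
    out = [report(plus, (8, 9))]  # delete the exon 1 terminal G before the donor

    L = len(genome)
    minus = TranscriptModel(
        id="toy_minus", strand="-",
        exons=[(L - 24, L - 15), (L - 9, L - 3)],
        cds_start=0, cds_end=15,
        genomic_sequence=genome.translate(RC)[::-1],
    )
    # the same deletion in minus-locus coordinates removes a genomic C,
    # reported as delG in cDNA (transcript-strand) coordinates
    out.append(report(minus, (L - 9, L - 8)))

    text = "\n\n".join(out)
    print(text)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "consequence_report.txt").write_text(text + "\n")


if __name__ == "__main__":
    main()
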