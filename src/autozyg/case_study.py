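"""The published worked example: four shared homozygous variants, one survivor.

Whole-exome sequencing of two affected brothers from a first-cousin mating
left four homozygous variants shared by both patients.  This module encodes
those four variants with their published annotation evidence and genotype
configuration (children homozygous-alt, parents heterozygous) so the
exclusion cascade can be replayed end to end:

* ARHGEF2 c.1461delG — absent from population databases, segregates with
  disease, phenotype fits: retained as the causal candidate.
* EXTL1 p.W313X — 16 ESP6500 heterozygotes and, decisively, one healthy
  in-house control homozygote: excluded (control_homozygote).
* HMCN1 p.D2077N — gene associated with macular degeneration, which does not
  fit the patients' neurodevelopmental phenotype: excluded
  (phenotype_mismatch).
* IGFN1 p.G3457S — SIFT "tolerated", PolyPhen2 only "possibly damaging", and
  a GERP conservation score of merely 1.101: excluded
  (benign_prediction_low_conservation).

Genomic coordinates are hg19.  ESP6500 allele frequencies are derived from
the published heterozygote counts over ~6503 exomes (13006 alleles).  The
reference/alternate allele strings are synthetic placeholders where only the
change (e.g. "delC") was published; they play no role in the filters.  The
shared-ROH track is likewise a synthetic stand-in: one >1 Mb interval around
each variant, standing in for the unpublished shared-ROH table.
"""

from __future__ import annotations

from .prioritization import AnnotationBundle, CandidateVerdict, exclusion_rank
from .roh_mapping import ROHInterval
from .variant_io import FEMALE, MALE, GenotypeCall, Individual, Pedigree, VariantRecord

ESP6500_ALLELES = 13006  # ~6503 exomes

FATHER, MOTHER = "I.1", "I.2"
PATIENTS = ("II.1", "II.2")


def index_family() -> Pedigree:
    """The sequenced nuclear quartet: consanguineous healthy parents, two affected boys."""
    return Pedigree(
        members=[
            Individual(FATHER, MALE, False),
            Individual(MOTHER, FEMALE, False),
            Individual("II.1", MALE, True, FATHER, MOTHER),
            Individual("II.2", MALE, True, FATHER, MOTHER),
        ],
        family_id="INDEX",
    )


def _recessive_calls() -> dict[str, GenotypeCall]:
    """Children homozygous-alt, parents heterozygous, with clean evidence."""
    hom = GenotypeCall((1, 1), 60, (0, 30))
    het = GenotypeCall((0, 1), 60, (15, 15))
    return {FATHER: het, MOTHER: het, "II.1": hom, "II.2": hom}


def shared_homozygous_variants() -> list[tuple[VariantRecord, AnnotationBundle]]:
    """The four shared homozygous variants with their published annotations."""
    arhgef2 = VariantRecord(
        chromosome="1",
        position=155_928_109,
        reference_allele="AC",  # placeholder context base + the deleted C
        alternate_alleles=("A",),
        calls=_recessive_calls(),
        variant_id="ARHGEF2:c.1461delG",
        annotations=AnnotationBundle(
            conservation_score=None,  # "highly conserved region"; no score printed
            phenotype_match="yes",
        ),
    )
    extl1 = VariantRecord(
        chromosome="1",
        position=26_356_156,
        reference_allele="G",
        alternate_alleles=("A",),
        calls=_recessive_calls(),
        variant_id="EXTL1:c.939G>A",
        annotations=AnnotationBundle(
            allele_frequency={"ESP6500": 16 / ESP6500_ALLELES},
            control_heterozygote_count={"ESP6500": 16},
            control_homozygote_count={"inhouse": 1},
        ),
    )
    hmcn1 = VariantRecord(
        chromosome="1",
        position=186_010_193,
        reference_allele="G",
        alternate_alleles=("A",),
        calls=_recessive_calls(),
        variant_id="HMCN1:c.6229G>A",
        annotations=AnnotationBundle(
            phenotype_match="no",
            known_disease_link="macular degeneration",
        ),
    )
    igfn1 = VariantRecord(
        chromosome="1",
        position=201_193_885,
        reference_allele="G",
        alternate_alleles=("A",),
        calls=_recessive_calls(),
        variant_id="IGFN1:c.10369G>A",
        annotations=AnnotationBundle(
            allele_frequency={"ESP6500": 7 / ESP6500_ALLELES},
            control_heterozygote_count={"ESP6500": 7},
            prediction_labels={"SIFT": "tolerated", "PolyPhen2": "possibly damaging"},
            conservation_score=1.101,
        ),
    )
    return [(v, v.annotations) for v in (arhgef2, extl1, hmcn1, igfn1)]


def shared_roh_track() -> list[ROHInterval]:
    """Synthetic >1 Mb shared intervals around each variant (stand-in track)."""
    out = []
    for v, _ in shared_homozygous_variants():
        out.append(
            ROHInterval(
                chromosome=v.chromosome,
                start=v.start - 1_000_000,
                end=v.start + 1_000_000,
                n_snvs=50,
                sample_id="shared",
            )
        )
    return sorted(out, key=lambda iv: iv.start)


def run_worked_example() -> list[CandidateVerdict]:
    """Replay the exclusion cascade on the four encoded variants."""
    return exclusion_rank(
        shared_homozygous_variants(), index_family(), shared_roh_track()
    )
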