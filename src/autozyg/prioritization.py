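"""Recessive-variant filter cascade: from shared homozygous variants to a candidate.

The filters encode the standard autosomal-recessive prioritization logic for
a consanguineous sibship:

* segregation — affected members homozygous for the alternate allele,
  unaffected parents obligate heterozygous carriers, no unaffected
  homozygote;
* population frequency — any database frequency above the prevalence cutoff
  (default 0.5%), or any homozygote among healthy controls, excludes;
  heterozygote carrier counts alone do not exclude under a recessive model;
* autozygome containment — the variant must lie inside a shared ROH interval;
* phenotype — a recorded phenotype mismatch (clinical judgment, supplied as
  an annotation flag, never computed) excludes;
* prediction/conservation — a variant with no confidently damaging in-silico
  label *and* a conservation score below the cutoff (default 2.0) is ranked
  unlikely.

Every exclusion carries machine-readable reasons; a retained candidate has
none.  A scan for rare hemizygous X-chromosome variants shared by affected
males (outside the pseudoautosomal regions) completes the recessive screen.
"""

from __future__ import annotations

import csv
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from .roh_mapping import ROHInterval
from .variant_io import MALE, Pedigree, VariantRecord

logger = logging.getLogger(__name__)

# Exclusion reason vocabulary
CONTROL_HOMOZYGOTE = "control_homozygote"
FREQUENCY_EXCEEDS_CUTOFF = "frequency_exceeds_cutoff"
FAILS_SEGREGATION = "fails_segregation"
MISSING_PARENTAL_GENOTYPE = "missing_parental_genotype"
OUTSIDE_SHARED_ROH = "outside_shared_roh"
PHENOTYPE_MISMATCH = "phenotype_mismatch"
BENIGN_PREDICTION_LOW_CONSERVATION = "benign_prediction_low_conservation"

DEFAULT_FREQUENCY_CUTOFF = 0.005
DEFAULT_CONSERVATION_CUTOFF = 2.0
# Labels counting as a confident damaging call from an in-silico tool.  Note
# that PolyPhen's "possibly damaging" is deliberately not in this set: it is
# an equivocal label and does not rescue a variant from the low-conservation
# rule on its own.
DAMAGING_LABELS = frozenset(
    {"damaging", "probably damaging", "probably_damaging", "deleterious", "disease_causing"}
)
BENIGN_LABELS = frozenset({"tolerated", "benign"})

# hg19 X pseudoautosomal regions, 0-based half-open.
PAR_REGIONS_HG19 = ((60000, 2_699_520), (154_931_043, 155_260_560))
X_CHROMOSOME_NAMES = frozenset({"X", "chrX", "x", "chrx", "23"})


@dataclass
class AnnotationBundle:
    """Per-variant population and in-silico annotations consumed as input.

    Maps are keyed by database / tool name.  ``phenotype_match`` records the
    clinical judgment whether the gene's known disease association fits the
    patient phenotype ("yes" / "no" / "unknown"); it is an input, never
    computed here.
    """

    allele_frequency: dict[str, float] = field(default_factory=dict)
    control_heterozygote_count: dict[str, int] = field(default_factory=dict)
    control_homozygote_count: dict[str, int] = field(default_factory=dict)
    prediction_labels: dict[str, str] = field(default_factory=dict)
    conservation_score: float | None = None
    phenotype_match: str = "unknown"
    known_disease_link: str | None = None

    def __post_init__(self) -> None:
        for db, f in self.allele_frequency.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"allele frequency for {db} outside [0,1]: {f}")
        for counts in (self.control_heterozygote_count, self.control_homozygote_count):
            for db, n in counts.items():
                if n < 0:
                    raise ValueError(f"negative control count for {db}: {n}")
        if self.phenotype_match not in ("yes", "no", "unknown"):
            raise ValueError(f"phenotype_match must be yes/no/unknown: {self.phenotype_match!r}")


@dataclass
class CandidateVerdict:
    """Outcome of the exclusion cascade for one candidate variant."""

    variant_id: str
    status: str  # "retained" | "excluded"
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == "retained" and self.reasons:
            raise ValueError("retained verdict must carry no reasons")
        if self.status == "excluded" and not self.reasons:
            raise ValueError("excluded verdict must carry at least one reason")


class SegregationStatus(Enum):
    PASS = "pass"
    FAIL = "fail"
    MISSING_DATA = "missing_data"


def segregation_filter(variant: VariantRecord, pedigree: Pedigree) -> SegregationStatus:
    """Test autosomal-recessive segregation of a variant within the pedigree.

    PASS requires every affected member homozygous for the alternate allele,
    every genotyped unaffected parent of an affected member heterozygous, and
    no unaffected member homozygous for the alternate allele.  A missing
    parental genotype yields MISSING_DATA, which is distinct from an observed
    segregation failure.
    """
    missing_parent = False
    for member in pedigree.affected:
        call = variant.calls.get(member.id)
        if call is None or call.is_missing:
            return SegregationStatus.MISSING_DATA
        if not call.is_hom_alt():
            return SegregationStatus.FAIL
        for parent in pedigree.parents_of(member.id):
            if parent.affected:
                continue
            pcall = variant.calls.get(parent.id)
            if pcall is None or pcall.is_missing:
                missing_parent = True
            elif not pcall.is_heterozygous:
                return SegregationStatus.FAIL
    for member in pedigree.unaffected:
        call = variant.calls.get(member.id)
        if call is not None and not call.is_missing and call.is_hom_alt():
            return SegregationStatus.FAIL
    if missing_parent:
        return SegregationStatus.MISSING_DATA
    return SegregationStatus.PASS


def frequency_filter(
    bundle: AnnotationBundle | None, cutoff: float = DEFAULT_FREQUENCY_CUTOFF
) -> bool:
    """True (pass) iff no database frequency exceeds the prevalence cutoff and
    no healthy-control homozygote is recorded.  An absent/empty bundle passes.
    """
    if bundle is None:
        return True
    if any(f > cutoff for f in bundle.allele_frequency.values()):
        return False
    if any(n > 0 for n in bundle.control_homozygote_count.values()):
        return False
    return True


def roh_containment_filter(
    variant: VariantRecord, shared_roh: Sequence[ROHInterval]
) -> bool:
    """True iff the variant's start position lies inside a shared ROH interval.

    The track must be position-sorted; lookup is by binary search per
    chromosome over half-open intervals.
    """
    starts: list[int] = []
    ivs: list[ROHInterval] = []
    for iv in shared_roh:
        if iv.chromosome == variant.chromosome:
            starts.append(iv.start)
            ivs.append(iv)
    if not ivs:
        return False
    i = bisect_right(starts, variant.start) - 1
    return i >= 0 and variant.start < ivs[i].end


def _benign_prediction_low_conservation(
    bundle: AnnotationBundle, conservation_cutoff: float
) -> bool:
    if bundle.conservation_score is None:
        return False
    if bundle.conservation_score >= conservation_cutoff:
        return False
    labels = {v.strip().lower() for v in bundle.prediction_labels.values()}
    return not (labels & DAMAGING_LABELS)


def exclusion_rank(
    candidates: Sequence[tuple[VariantRecord, AnnotationBundle | None]],
    pedigree: Pedigree,
    shared_roh: Sequence[ROHInterval],
    *,
    frequency_cutoff: float = DEFAULT_FREQUENCY_CUTOFF,
    conservation_cutoff: float = DEFAULT_CONSERVATION_CUTOFF,
) -> list[CandidateVerdict]:
    """Apply the full exclusion cascade and rank candidates.

    Candidates are (variant, annotation) pairs already known to be shared
    homozygous in the affected individuals.  Each filter appends a reason on
    failure; a variant with no reasons is retained.  The returned list is
    deterministic: retained verdicts first, then excluded ordered by number
    of reasons and variant id.
    """
    ids = [v.id_or_key for v, _ in candidates]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate candidate variant ids: {dupes}")

    verdicts: list[CandidateVerdict] = []
    for variant, bundle in candidates:
        reasons: list[str] = []
        seg = segregation_filter(variant, pedigree)
        if seg is SegregationStatus.FAIL:
            reasons.append(FAILS_SEGREGATION)
        elif seg is SegregationStatus.MISSING_DATA:
            reasons.append(MISSING_PARENTAL_GENOTYPE)
        if bundle is not None:
            if any(n > 0 for n in bundle.control_homozygote_count.values()):
                reasons.append(CONTROL_HOMOZYGOTE)
            if any(f > frequency_cutoff for f in bundle.allele_frequency.values()):
                reasons.append(FREQUENCY_EXCEEDS_CUTOFF)
        if not roh_containment_filter(variant, shared_roh):
            reasons.append(OUTSIDE_SHARED_ROH)
        if bundle is not None:
            if bundle.phenotype_match == "no":
                reasons.append(PHENOTYPE_MISMATCH)
            if _benign_prediction_low_conservation(bundle, conservation_cutoff):
                reasons.append(BENIGN_PREDICTION_LOW_CONSERVATION)
        verdicts.append(
            CandidateVerdict(
                variant_id=variant.id_or_key,
                status="retained" if not reasons else "excluded",
                reasons=reasons,
            )
        )
    verdicts.sort(key=lambda v: (v.status != "retained", len(v.reasons), v.variant_id))
    return verdicts


def shared_homozygous_candidates(
    variants: Sequence[VariantRecord], pedigree: Pedigree
) -> list[VariantRecord]:
    """Variants called homozygous for an alternate allele in every affected member."""
    affected = [m.id for m in pedigree.affected]
    out = []
    for v in variants:
        calls = [v.calls.get(s) for s in affected]
        if all(c is not None and c.is_hom_alt() for c in calls):
            out.append(v)
    return out


def attach_annotations(
    variants: Sequence[VariantRecord], bundles: Mapping[str, AnnotationBundle]
) -> None:
    """Attach annotation bundles to variant records in place, keyed by id/key."""
    for v in variants:
        bundle = bundles.get(v.id_or_key)
        if bundle is not None:
            v.annotations = bundle


def _in_par(pos0: int, par_regions: Sequence[tuple[int, int]]) -> bool:
    return any(lo <= pos0 < hi for lo, hi in par_regions)


def x_hemizygous_scan(
    variants: Sequence[VariantRecord],
    pedigree: Pedigree,
    *,
    frequency_cutoff: float = DEFAULT_FREQUENCY_CUTOFF,
    par_regions: Sequence[tuple[int, int]] = PAR_REGIONS_HG19,
) -> list[VariantRecord]:
    """Scan the X chromosome for rare hemizygous variants shared by affected males.

    Returns X-chromosome variants outside the pseudoautosomal regions that
    are carried hemizygously (haploid-alt or called homozygous-alt) by every
    affected individual, are not hemizygous/homozygous-alt in any unaffected
    male, and pass the population-frequency filter.  If any affected member
    is female the X-linked recessive model does not apply and the scan is
    skipped with a logged notice.
    """
    if any(m.sex != MALE for m in pedigree.affected):
        logger.warning(
            "x_hemizygous_scan skipped: affected female present, "
            "hemizygous X model does not apply"
        )
        return []
    affected = [m.id for m in pedigree.affected]
    unaffected_males = [m.id for m in pedigree.unaffected if m.sex == MALE]
    out: list[VariantRecord] = []
    for v in variants:
        if v.chromosome not in X_CHROMOSOME_NAMES:
            continue
        if _in_par(v.start, par_regions):
            continue  # pseudoautosomal: behaves autosomally, out of scope here
        calls = [v.calls.get(s) for s in affected]
        if not all(c is not None and c.is_hom_alt() for c in calls):
            continue
        if any(
            (c := v.calls.get(s)) is not None and not c.is_missing and c.is_hom_alt()
            for s in unaffected_males
        ):
            continue
        if not frequency_filter(v.annotations, frequency_cutoff):
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------
#
# Long format, one row per (variant, database); per-variant columns are
# repeated on every row of that variant (blank where not applicable):
#
#   variant_id  database  allele_frequency  n_het  n_hom
#   sift  polyphen2  conservation  phenotype_match  known_disease_link
#
# A variant with no database evidence uses a single row with database "."
# and blank frequency/count columns.

_ANNOTATION_COLUMNS = [
    "variant_id", "database", "allele_frequency", "n_het", "n_hom",
    "sift", "polyphen2", "conservation", "phenotype_match", "known_disease_link",
]


def read_annotations(path: str | Path) -> dict[str, AnnotationBundle]:
    """Read the long-format annotation TSV into per-variant bundles."""
    bundles: dict[str, AnnotationBundle] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: annotation TSV missing columns: {sorted(missing)}")
        for row in reader:
            vid = row["variant_id"]
            b = bundles.setdefault(vid, AnnotationBundle())
            db = row["database"]
            if db and db != ".":
                if row["allele_frequency"]:
                    b.allele_frequency[db] = float(row["allele_frequency"])
                if row["n_het"]:
                    b.control_heterozygote_count[db] = int(row["n_het"])
                if row["n_hom"]:
                    b.control_homozygote_count[db] = int(row["n_hom"])
            if row["sift"]:
                b.prediction_labels["SIFT"] = row["sift"]
            if row["polyphen2"]:
                b.prediction_labels["PolyPhen2"] = row["polyphen2"]
            if row["conservation"]:
                b.conservation_score = float(row["conservation"])
            if row["phenotype_match"]:
                b.phenotype_match = row["phenotype_match"]
            if row["known_disease_link"]:
                b.known_disease_link = row["known_disease_link"]
    return bundles


def write_annotations(bundles: Mapping[str, AnnotationBundle], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for vid, b in bundles.items():
            databases = sorted(
                set(b.allele_frequency)
                | set(b.control_heterozygote_count)
                | set(b.control_homozygote_count)
            ) or ["."]
            for i, db in enumerate(databases):
                per_variant = (
                    [
                        b.prediction_labels.get("SIFT", ""),
                        b.prediction_labels.get("PolyPhen2", ""),
                        "" if b.conservation_score is None else repr(b.conservation_score),
                        b.phenotype_match if b.phenotype_match != "unknown" else "",
                        b.known_disease_link or "",
                    ]
                    if i == 0
                    else ["", "", "", "", ""]
                )
                writer.writerow(
                    [
                        vid,
                        db,
                        "" if db == "." or db not in b.allele_frequency
                        else repr(b.allele_frequency[db]),
                        "" if db == "." or db not in b.control_heterozygote_count
                        else b.control_heterozygote_count[db],
                        "" if db == "." or db not in b.control_homozygote_count
                        else b.control_homozygote_count[db],
                        *per_variant,
                    ]
                )


def write_report(verdicts: Sequence[CandidateVerdict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["variant_id", "status", "reasons"])
        for v in verdicts:
            writer.writerow([v.variant_id, v.status, ";".join(v.reasons)])
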