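"""Readers/writers for the formats the pipeline touches: VCF, PED, ROH BED.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  The 1-based conventions of VCF
and HGVS appear only at the parse/format boundary: :class:`VariantRecord`
stores the VCF ``POS`` verbatim (1-based) and exposes ``start``/``end`` in
internal coordinates; BED output is natively 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

from cyvcf2 import VCF

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .prioritization import AnnotationBundle
    from .roh_mapping import ROHInterval

MALE = "male"
FEMALE = "female"


class VcfParseError(ValueError):
    """Raised for malformed or contract-violating VCF input."""


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent PED input."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's called genotype with its quality evidence.

    ``allele_indices`` is a tuple of allele indices into
    ``(ref,) + alts`` — length 2 for diploid calls, length 1 for haploid
    (hemizygous) calls — or ``None`` for a missing genotype.
    ``allelic_depths`` has one read count per allele at the site.
    """

    allele_indices: tuple[int, ...] | None
    genotype_quality: int | None
    allelic_depths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.allelic_depths):
            raise ValueError(f"negative allelic depth: {self.allelic_depths}")
        if self.allele_indices is not None and any(a < 0 for a in self.allele_indices):
            raise ValueError(f"negative allele index: {self.allele_indices}")

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    @property
    def is_homozygous(self) -> bool:
        """Homozygous (or hemizygous) for any single allele, incl. reference."""
        if self.allele_indices is None:
            return False
        return len(set(self.allele_indices)) == 1

    @property
    def is_heterozygous(self) -> bool:
        if self.allele_indices is None:
            return False
        return len(set(self.allele_indices)) > 1

    def is_hom_alt(self) -> bool:
        """Homozygous (or hemizygous) for one non-reference allele."""
        return self.is_homozygous and self.allele_indices[0] > 0  # type: ignore[index]

    @property
    def called_allele(self) -> int | None:
        """The single called allele for homozygous calls, else ``None``."""
        if self.is_homozygous:
            return self.allele_indices[0]  # type: ignore[index]
        return None

    @property
    def total_depth(self) -> int:
        return sum(self.allelic_depths)


@dataclass
class VariantRecord:
    """A site across all cohort members plus (optionally) its annotations.

    ``position`` is the 1-based VCF POS; ``start``/``end`` give the 0-based
    half-open reference span.
    """

    chromosome: str
    position: int
    reference_allele: str
    alternate_alleles: tuple[str, ...]
    calls: dict[str, GenotypeCall]
    variant_id: str | None = None
    annotations: "AnnotationBundle | None" = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.position}")
        for allele in (self.reference_allele, *self.alternate_alleles):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"allele must be non-empty uppercase ACGT: {allele!r}")
        n_alleles = 1 + len(self.alternate_alleles)
        for sample, call in self.calls.items():
            if call.allelic_depths and len(call.allelic_depths) != n_alleles:
                raise ValueError(
                    f"{sample} at {self.chromosome}:{self.position}: "
                    f"AD has {len(call.allelic_depths)} entries for {n_alleles} alleles"
                )
            if call.allele_indices is not None and max(call.allele_indices) >= n_alleles:
                raise ValueError(
                    f"{sample} at {self.chromosome}:{self.position}: "
                    f"GT references allele {max(call.allele_indices)} of {n_alleles}"
                )

    @property
    def start(self) -> int:
        """0-based start of the reference span."""
        return self.position - 1

    @property
    def end(self) -> int:
        """0-based half-open end of the reference span."""
        return self.position - 1 + len(self.reference_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.reference_allele) == 1 and all(
            len(a) == 1 for a in self.alternate_alleles
        )

    @property
    def key(self) -> str:
        alts = ",".join(self.alternate_alleles)
        return f"{self.chromosome}:{self.position}:{self.reference_allele}:{alts}"

    @property
    def id_or_key(self) -> str:
        return self.variant_id if self.variant_id not in (None, ".") else self.key


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "male" | "female"
    affected: bool
    father_id: str | None = None
    mother_id: str | None = None


@dataclass
class Pedigree:
    """A validated pedigree: members with sex, affection status, parent links."""

    members: list[Individual]
    family_id: str = "FAM"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise PedigreeError(f"duplicate member ids: {sorted(dupes)}")
        by_id = {m.id: m for m in self.members}
        for m in self.members:
            for parent, expected_sex in ((m.father_id, MALE), (m.mother_id, FEMALE)):
                if parent is None:
                    continue
                if parent not in by_id:
                    raise PedigreeError(f"{m.id}: unknown parent id {parent!r}")
                if by_id[parent].sex != expected_sex:
                    raise PedigreeError(
                        f"{m.id}: parent {parent} has sex {by_id[parent].sex}, "
                        f"expected {expected_sex}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = {m.id: m for m in self.members}
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(mid: str, stack: list[str]) -> None:
            if state.get(mid) == 1:
                return
            if state.get(mid) == 0:
                raise PedigreeError(f"pedigree cycle detected: {' -> '.join(stack + [mid])}")
            state[mid] = 0
            m = by_id[mid]
            for parent in (m.father_id, m.mother_id):
                if parent is not None:
                    visit(parent, stack + [mid])
            state[mid] = 1

        for m in self.members:
            visit(m.id, [])

    def __getitem__(self, member_id: str) -> Individual:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def __contains__(self, member_id: str) -> bool:
        return any(m.id == member_id for m in self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.affected]

    @property
    def unaffected(self) -> list[Individual]:
        return [m for m in self.members if not m.affected]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    def parents_of(self, member_id: str) -> list[Individual]:
        m = self[member_id]
        return [self[p] for p in (m.father_id, m.mother_id) if p is not None]

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b) by the standard recursive definition."""
        order = {m.id: i for i, m in enumerate(self._topological())}
        return self._kinship(a, b, order)

    def _topological(self) -> list[Individual]:
        done: list[Individual] = []
        seen: set[str] = set()

        def visit(m: Individual) -> None:
            if m.id in seen:
                return
            for parent in (m.father_id, m.mother_id):
                if parent is not None:
                    visit(self[parent])
            seen.add(m.id)
            done.append(m)

        for m in self.members:
            visit(m)
        return done

    def _kinship(self, a: str, b: str, order: Mapping[str, int]) -> float:
        if a == b:
            ind = self[a]
            if ind.father_id is None or ind.mother_id is None:
                return 0.5
            return 0.5 * (1.0 + self._kinship(ind.father_id, ind.mother_id, order))
        # recurse on the individual later in topological order (the descendant)
        if order[a] < order[b]:
            a, b = b, a
        ind = self[a]
        if ind.father_id is None or ind.mother_id is None:
            return 0.0
        return 0.5 * (
            self._kinship(ind.father_id, b, order) + self._kinship(ind.mother_id, b, order)
        )

    def inbreeding_coefficient(self, member_id: str) -> float:
        """F of an individual = kinship coefficient of their parents."""
        m = self[member_id]
        if m.father_id is None or m.mother_id is None:
            return 0.0
        return self.kinship(m.father_id, m.mother_id)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_REQUIRED_FORMAT_FIELDS = ("GT", "GQ", "AD")


def _chromosome_sort_key(chrom: str) -> tuple[int, int | str]:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name))
    return (1, name)


def read_variants(path: str | Path, allow_unsorted: bool = False) -> list[VariantRecord]:
    """Read a VCF into a position-sorted list of :class:`VariantRecord`.

    Requires GT, GQ and AD FORMAT declarations.  Out-of-order input raises
    :class:`VcfParseError` unless ``allow_unsorted`` is set, in which case
    records are re-sorted by (chromosome, position).
    """
    path = Path(path)
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"{path}: cannot parse VCF: {exc}") from exc
    header = vcf.raw_header
    missing = [
        f for f in _REQUIRED_FORMAT_FIELDS
        if f'##FORMAT=<ID={f},' not in header
    ]
    if missing:
        raise VcfParseError(f"{path}: missing required FORMAT field(s): {', '.join(missing)}")
    samples = list(vcf.samples)

    records: list[VariantRecord] = []
    prev: tuple[str, int] | None = None
    chrom_done: set[str] = set()
    unsorted = False
    for line_no, v in enumerate(vcf, start=1):
        if v.ALT is None or len(v.ALT) == 0:
            continue  # monomorphic reference block; nothing to analyse
        gqs = v.format("GQ")
        ads = v.format("AD")
        calls: dict[str, GenotypeCall] = {}
        for i, sample in enumerate(samples):
            gt = v.genotypes[i]
            alleles = tuple(a for a in gt[:-1] if a >= 0)
            allele_indices = alleles if alleles else None
            if gqs is not None:
                q = gqs[i]
                q0 = float(q[0]) if getattr(q, "__len__", None) else float(q)
                gq = None if (math.isnan(q0) or q0 < 0) else int(q0)
            else:
                gq = None
            if ads is not None:
                ad = tuple(int(x) for x in ads[i] if int(x) >= 0)
            else:
                ad = ()
            calls[sample] = GenotypeCall(allele_indices, gq, ad)
        try:
            rec = VariantRecord(
                chromosome=v.CHROM,
                position=v.POS,
                reference_allele=v.REF,
                alternate_alleles=tuple(v.ALT),
                calls=calls,
                variant_id=v.ID,
            )
        except ValueError as exc:
            raise VcfParseError(f"{path}: record #{line_no} ({v.CHROM}:{v.POS}): {exc}") from exc
        if prev is not None:
            if rec.chromosome != prev[0] and rec.chromosome in chrom_done:
                unsorted = True
            elif rec.chromosome == prev[0] and rec.position < prev[1]:
                unsorted = True
        if prev is not None and rec.chromosome != prev[0]:
            chrom_done.add(prev[0])
        prev = (rec.chromosome, rec.position)
        records.append(rec)
    if unsorted:
        if not allow_unsorted:
            raise VcfParseError(
                f"{path}: records are not sorted by (chromosome, position); "
                "pass allow_unsorted=True to re-sort"
            )
        records.sort(key=lambda r: (_chromosome_sort_key(r.chromosome), r.position))
    return records


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": MALE, "2": FEMALE}
_AFFECTED_CODES = {"2": True, "1": False, "0": False, "-9": False}


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited 6-column PED file.

    Columns: family, individual, father (0 = founder), mother (0 = founder),
    sex (1 = male, 2 = female), phenotype (2 = affected; 1/0/-9 = unaffected
    or unknown, treated as unaffected).
    """
    path = Path(path)
    members: list[Individual] = []
    family_id: str | None = None
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"{path}:{line_no}: expected 6 columns, got {len(fields)}")
        fam, iid, father, mother, sex, pheno = fields[:6]
        family_id = family_id or fam
        if sex not in _SEX_CODES:
            raise PedigreeError(f"{path}:{line_no}: sex code {sex!r} not in {{1,2}}")
        if pheno not in _AFFECTED_CODES:
            raise PedigreeError(f"{path}:{line_no}: phenotype code {pheno!r} unrecognized")
        members.append(
            Individual(
                id=iid,
                sex=_SEX_CODES[sex],
                affected=_AFFECTED_CODES[pheno],
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
            )
        )
    return Pedigree(members=members, family_id=family_id or "FAM")


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for m in pedigree.members:
        lines.append(
            "\t".join(
                [
                    pedigree.family_id,
                    m.id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    "1" if m.sex == MALE else "2",
                    "2" if m.affected else "1",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ROH BED
# ---------------------------------------------------------------------------


def write_roh_bed(intervals: Sequence["ROHInterval"], path: str | Path) -> None:
    """Write ROH intervals as BED3+2: chrom, start, end, name (sample or
    "shared"), score (number of supporting SNVs).

    Intervals within one track (one ``sample_id``) must be sorted and
    non-overlapping per chromosome.
    """
    by_track: dict[tuple[str, str], list] = {}
    for iv in intervals:
        by_track.setdefault((iv.sample_id, iv.chromosome), []).append(iv)
    for (sample, chrom), ivs in by_track.items():
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping/unsorted intervals in track {sample!r} on {chrom}: "
                    f"[{a.start},{a.end}) then [{b.start},{b.end})"
                )
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tn_snvs\n")
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.sample_id}\t{iv.n_snvs}\n")


def read_roh_bed(path: str | Path) -> list["ROHInterval"]:
    from .roh_mapping import ROHInterval

    out: list[ROHInterval] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("track"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"{path}:{line_no}: expected 5 BED columns, got {len(fields)}")
        chrom, start, end, name, score = fields[:5]
        out.append(
            ROHInterval(
                chromosome=chrom,
                start=int(start),
                end=int(end),
                n_snvs=int(score),
                sample_id=name,
            )
        )
    return out
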