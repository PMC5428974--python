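"""Run-of-homozygosity (ROH) detection and the shared autozygome.

A run of homozygosity is called from at least ``min_run`` (default 4)
consecutive high-quality homozygous SNVs uninterrupted by any heterozygous
SNV.  "High quality" means genotype quality >= 20, total read depth >= 10 and
called-allele read fraction >= 0.9 (all configurable).  Low-quality and
missing sites are transparent: they neither support nor break a run.  The
shared autozygome of the affected individuals is the genomic intersection of
their per-sample ROH tracks, keeping only pieces of at least
``min_shared_length`` (default 1 Mb).

Coordinates are 0-based half-open throughout.  Run boundaries are the
positions of the first and last supporting homozygous SNV — runs are not
extended toward flanking heterozygous sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .variant_io import GenotypeCall, Pedigree, VariantRecord


class CallClass(Enum):
    """Quality classification of one genotype call for ROH support."""

    HQ_HOM = "hq_hom"
    HET = "het"
    LOW_QUALITY = "low_quality"
    MISSING = "missing"


@dataclass(frozen=True)
class ROHParams:
    """Thresholds of the ROH caller.

    min_gq: minimum genotype quality (phred) for a supporting homozygous call.
    min_depth: minimum total read depth (sum of allelic depths).
    min_allele_fraction: minimum called-allele depth / total depth, in (0.5, 1].
    min_run: minimum number of consecutive supporting homozygous SNVs.
    min_shared_length: minimum length (bp) of a *shared* interval; per-sample
        intervals are not length-filtered.
    het_min_gq: if set, heterozygous calls below this GQ are demoted to
        LOW_QUALITY instead of interrupting a run; by default any called
        heterozygote interrupts.
    max_gap: if set, two supporting SNVs further apart than this many bp
        cannot belong to the same run; off by default.
    """

    min_gq: int = 20
    min_depth: int = 10
    min_allele_fraction: float = 0.9
    min_run: int = 4
    min_shared_length: int = 1_000_000
    het_min_gq: int | None = None
    max_gap: int | None = None

    def __post_init__(self) -> None:
        if min(self.min_gq, self.min_depth, self.min_run, self.min_shared_length) <= 0:
            raise ValueError("ROH thresholds must be strictly positive")
        if not (0.5 < self.min_allele_fraction <= 1.0):
            raise ValueError(
                f"min_allele_fraction must be in (0.5, 1], got {self.min_allele_fraction}"
            )


@dataclass(frozen=True)
class ROHInterval:
    """A maximal homozygous run for one sample, or a shared intersection piece.

    ``start``/``end`` are 0-based half-open; ``n_snvs`` counts the supporting
    high-quality homozygous SNVs (for shared pieces: the minimum over the
    intersected source intervals).
    """

    chromosome: str
    start: int
    end: int
    n_snvs: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chromosome: str, pos: int) -> bool:
        return chromosome == self.chromosome and self.start <= pos < self.end


def classify_call(call: GenotypeCall, params: ROHParams = ROHParams()) -> CallClass:
    """Classify one genotype call for ROH support.

    HQ_HOM requires a homozygous genotype with GQ >= min_gq, total depth >=
    min_depth and called-allele fraction >= min_allele_fraction.  Any called
    heterozygote is HET (unless demoted by ``het_min_gq``).  No genotype is
    MISSING; everything else is LOW_QUALITY.
    """
    if call.is_missing:
        return CallClass.MISSING
    if call.is_heterozygous:
        if params.het_min_gq is not None and (
            call.genotype_quality is None or call.genotype_quality < params.het_min_gq
        ):
            return CallClass.LOW_QUALITY
        return CallClass.HET
    # homozygous (or hemizygous)
    if call.genotype_quality is None or call.genotype_quality < params.min_gq:
        return CallClass.LOW_QUALITY
    total = call.total_depth
    if total < params.min_depth:
        return CallClass.LOW_QUALITY
    allele = call.called_allele
    if allele is None or allele >= len(call.allelic_depths):
        return CallClass.LOW_QUALITY
    if call.allelic_depths[allele] / total < params.min_allele_fraction:
        return CallClass.LOW_QUALITY
    return CallClass.HQ_HOM


def detect_roh(
    sites: Sequence[tuple[int, CallClass]],
    params: ROHParams = ROHParams(),
    *,
    chromosome: str = "1",
    sample_id: str = "sample",
) -> list[ROHInterval]:
    """Detect maximal homozygous runs on one chromosome of one sample.

    ``sites`` are (0-based position, CallClass) pairs sorted by position.
    A run is a maximal stretch of HQ_HOM sites with no intervening HET;
    LOW_QUALITY and MISSING sites are skipped.  Runs with fewer than
    ``min_run`` supporting sites are discarded; the reported interval spans
    the first to last supporting SNV (half-open on the last SNV's base).
    """
    for (p0, _), (p1, _) in zip(sites, sites[1:]):
        if p1 < p0:
            raise ValueError(f"sites not sorted by position: {p0} then {p1}")

    out: list[ROHInterval] = []
    run: list[int] = []

    def close() -> None:
        if len(run) >= params.min_run:
            out.append(
                ROHInterval(
                    chromosome=chromosome,
                    start=run[0],
                    end=run[-1] + 1,
                    n_snvs=len(run),
                    sample_id=sample_id,
                )
            )
        run.clear()

    for pos, cls in sites:
        if cls is CallClass.HET:
            close()
        elif cls is CallClass.HQ_HOM:
            if run and params.max_gap is not None and pos - run[-1] > params.max_gap:
                close()
            run.append(pos)
        # LOW_QUALITY / MISSING: transparent
    close()
    return out


def _intersect_two(
    a: Sequence[ROHInterval], b: Sequence[ROHInterval]
) -> list[ROHInterval]:
    """Chromosome-wise two-pointer intersection; n_snvs = min of sources."""
    by_chrom_a: dict[str, list[ROHInterval]] = {}
    by_chrom_b: dict[str, list[ROHInterval]] = {}
    for iv in a:
        by_chrom_a.setdefault(iv.chromosome, []).append(iv)
    for iv in b:
        by_chrom_b.setdefault(iv.chromosome, []).append(iv)
    out: list[ROHInterval] = []
    for chrom in by_chrom_a:
        xs = sorted(by_chrom_a[chrom], key=lambda iv: iv.start)
        ys = sorted(by_chrom_b.get(chrom, []), key=lambda iv: iv.start)
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if hi > lo:
                out.append(
                    ROHInterval(
                        chromosome=chrom,
                        start=lo,
                        end=hi,
                        n_snvs=min(xs[i].n_snvs, ys[j].n_snvs),
                        sample_id="shared",
                    )
                )
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def sort_intervals(intervals: Iterable[ROHInterval]) -> list[ROHInterval]:
    from .variant_io import _chromosome_sort_key

    return sorted(intervals, key=lambda iv: (_chromosome_sort_key(iv.chromosome), iv.start))


def intersect_roh(
    per_sample: Mapping[str, Sequence[ROHInterval]] | Sequence[Sequence[ROHInterval]],
    params: ROHParams = ROHParams(),
) -> list[ROHInterval]:
    """Intersect per-sample ROH tracks into the shared autozygome.

    The genomic intersection across *all* tracks is computed, then pieces
    shorter than ``min_shared_length`` are dropped.  With a single track the
    result is that track, length-filtered and relabelled "shared".
    """
    tracks = list(per_sample.values()) if isinstance(per_sample, Mapping) else list(per_sample)
    if len(tracks) < 1:
        raise ValueError("intersect_roh needs at least one sample track")
    shared = [
        ROHInterval(iv.chromosome, iv.start, iv.end, iv.n_snvs, "shared")
        for iv in tracks[0]
    ]
    for track in tracks[1:]:
        shared = _intersect_two(shared, track)
    shared = [iv for iv in shared if iv.length >= params.min_shared_length]
    return sort_intervals(shared)


@dataclass
class AutozygomeResult:
    per_sample: dict[str, list[ROHInterval]]
    shared: list[ROHInterval]


def autozygome(
    variants: Sequence[VariantRecord],
    pedigree: Pedigree,
    params: ROHParams = ROHParams(),
) -> AutozygomeResult:
    """Per-affected-sample ROH tracks plus their shared intersection.

    Only biallelic/multiallelic *SNV* records support runs (indels are kept in
    the input for prioritization but ignored here).  Every affected pedigree
    member must be present in the VCF sample set.
    """
    affected = [m.id for m in pedigree.affected]
    if not affected:
        raise ValueError("pedigree has no affected members")
    if variants:
        vcf_samples = set(variants[0].calls)
        absent = [s for s in affected if s not in vcf_samples]
        if absent:
            raise ValueError(f"affected sample(s) absent from VCF: {', '.join(absent)}")

    per_sample: dict[str, list[ROHInterval]] = {s: [] for s in affected}
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.is_snv:
            by_chrom.setdefault(v.chromosome, []).append(v)
    for sample in affected:
        for chrom, recs in by_chrom.items():
            sites = [(v.start, classify_call(v.calls[sample], params)) for v in recs]
            per_sample[sample].extend(
                detect_roh(sites, params, chromosome=chrom, sample_id=sample)
            )
        per_sample[sample] = sort_intervals(per_sample[sample])
    shared = intersect_roh(per_sample, params) if variants else []
    return AutozygomeResult(per_sample=per_sample, shared=shared)
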