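"""Gene-dropping simulator of a first-cousin consanguineous sibship.

The simulated family reproduces the study design the pipeline targets: a
shared grandparental couple, two of their children married to unrelated
spouses, and the resulting first cousins marrying and having two affected
boys.  Offspring of first cousins have expected inbreeding coefficient
F = 1/16, so roughly 1/16 of each child's autosomal genome is autozygous
(both haplotypes identical by descent), in long segments whose length is set
by the six meioses separating the two copies.

Meioses draw Poisson crossover counts on a linear genetic map (default
1 cM/Mb, no interference) with uniform crossover positions.  A loss-of-
function variant is planted on one grandparental haplotype and transmitted
by descent; decoy variants with annotation profiles mirroring the classic
exclusion archetypes (healthy control homozygote; phenotype mismatch; benign
predictions with low conservation) are placed inside the realized shared
autozygous segments, exactly where real shared homozygous decoys arise.
Output is an uncompressed VCF (GT:GQ:AD with configurable depth/quality/
genotype-error noise), a 6-column PED, the annotation TSV, and a JSON truth
record (crossovers, founder-origin segments, autozygous segments, genotypes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .prioritization import AnnotationBundle
from .variant_io import FEMALE, MALE, Individual, Pedigree, write_pedigree

# A haplotype is a list of (start, end, founder_label) segments tiling [0, L);
# founder_label = "<founder_id>.<0|1>" names the founder haplotype of origin.
Segment = tuple[int, int, str]
Haplotype = list[Segment]

GRANDFATHER = "G1"
GRANDMOTHER = "G2"
AFFECTED_CHILDREN = ("II.1", "II.2")
SEQUENCED_DEFAULT = ("F", "M", "II.1", "II.2")


@dataclass
class DecoyProfile:
    """Annotation archetype for a decoy shared homozygous variant."""

    name: str
    bundle: AnnotationBundle


def default_decoy_profiles() -> list[DecoyProfile]:
    """The three exclusion archetypes seen in recessive exome studies.

    One decoy carries a homozygote in a healthy in-house control (exclusion
    by control_homozygote despite passing the frequency cutoff); one maps to
    a gene whose known disease association does not fit the patient phenotype
    (clinical exclusion); one has no confidently damaging in-silico label and
    low conservation.  Frequencies are kept below the 0.5% prevalence cutoff
    so each decoy is excluded for exactly its archetypal reason.
    """
    return [
        DecoyProfile(
            "decoy_control_hom",
            AnnotationBundle(
                allele_frequency={"ESP6500": 16 / 13006},
                control_heterozygote_count={"ESP6500": 16},
                control_homozygote_count={"inhouse": 1},
                prediction_labels={"SIFT": "damaging"},
                conservation_score=4.2,
            ),
        ),
        DecoyProfile(
            "decoy_phenotype_mismatch",
            AnnotationBundle(
                prediction_labels={"PolyPhen2": "probably damaging"},
                conservation_score=3.6,
                phenotype_match="no",
                known_disease_link="macular degeneration",
            ),
        ),
        DecoyProfile(
            "decoy_benign_low_conservation",
            AnnotationBundle(
                allele_frequency={"ESP6500": 7 / 13006},
                control_heterozygote_count={"ESP6500": 7},
                prediction_labels={"SIFT": "tolerated", "PolyPhen2": "possibly damaging"},
                conservation_score=1.101,
            ),
        ),
    ]


def planted_bundle() -> AnnotationBundle:
    """Annotation profile of the planted causal loss-of-function variant."""
    return AnnotationBundle(
        prediction_labels={"SIFT": "damaging", "PolyPhen2": "probably damaging"},
        conservation_score=5.1,
        phenotype_match="yes",
    )


@dataclass
class SimConfig:
    """Study-design parameters of the simulated cohort.

    Defaults are desk-sized: a 2 x 50 Mb autosomal genome at 5 markers/Mb is
    large enough to produce >1 Mb shared autozygous segments yet runs in well
    under a second per replicate.
    """

    n_chromosomes: int = 2
    chromosome_length_bp: int = 50_000_000
    marker_density_per_mb: float = 5.0
    recombination_rate_cm_per_mb: float = 1.0
    founder_allele_freq_range: tuple[float, float] = (0.1, 0.5)
    planted_chromosome: str = "1"
    planted_position: int = 25_000_000  # 0-based
    planted_founder_haplotype: str = f"{GRANDFATHER}.0"
    n_decoys: int = 3
    decoy_profiles: list[DecoyProfile] = field(default_factory=default_decoy_profiles)
    genotype_error_rate: float = 0.001
    read_error_rate: float = 0.005
    mean_depth: float = 30.0
    depth_dispersion: float | None = None  # None => Poisson depth
    gq_mean: float = 60.0
    gq_sd: float = 15.0
    include_x: bool = False
    x_length_bp: int = 50_000_000
    x_planted_position: int | None = None
    sequenced_samples: tuple[str, ...] = SEQUENCED_DEFAULT
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length_bp < 1:
            raise ValueError("genome dimensions must be positive")
        for rate in (
            self.marker_density_per_mb,
            self.recombination_rate_cm_per_mb,
            self.genotype_error_rate,
            self.read_error_rate,
        ):
            if rate < 0:
                raise ValueError(f"rates must be >= 0, got {rate}")
        if not (0 <= self.planted_position < self.chromosome_length_bp):
            raise ValueError("planted position outside its chromosome")

    @property
    def autosomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def chromosome_names(self) -> list[str]:
        return self.autosomes + (["X"] if self.include_x else [])

    def chromosome_length(self, chrom: str) -> int:
        return self.x_length_bp if chrom == "X" else self.chromosome_length_bp


@dataclass
class TruthRecord:
    """Ground truth of one replicate: descent, crossovers, autozygosity, genotypes."""

    # member -> chrom -> (paternal haplotype, maternal haplotype); X in males
    # holds a single (maternal) haplotype.
    haplotypes: dict[str, dict[str, tuple[Haplotype, ...]]]
    # (child, parent, chrom) keys flattened to "child|parent|chrom"
    crossovers: dict[str, list[int]]
    # affected child -> chrom -> autozygous (IBD) segments with founder label
    autozygous_segments: dict[str, dict[str, list[Segment]]]
    # chrom -> segments where both affected children are autozygous for the
    # same founder haplotype
    shared_autozygous_segments: dict[str, list[Segment]]
    # variant_id -> member -> alternate-allele count
    variant_genotypes: dict[str, dict[str, int]]
    # variant_id -> (chrom, 0-based position)
    variant_positions: dict[str, tuple[str, int]]
    segregating: bool
    n_resamples: int = 0

    def autozygous_fraction(self, child: str, autosome_lengths: Mapping[str, int]) -> float:
        total = sum(autosome_lengths.values())
        aut = sum(
            e - s
            for chrom, segs in self.autozygous_segments[child].items()
            if chrom in autosome_lengths
            for s, e, _ in segs
        )
        return aut / total


def build_first_cousin_pedigree() -> Pedigree:
    """The 10-member first-cousin-mating pedigree with two affected boys.

    One grandparental couple (G1, G2) has two children (C1, C2) who marry
    unrelated spouses (S1, S2); their children F and M are first cousins
    (kinship 1/16) and have two affected sons II.1 and II.2 (each with
    expected inbreeding coefficient F = 1/16).
    """
    members = [
        Individual(GRANDFATHER, MALE, False),
        Individual(GRANDMOTHER, FEMALE, False),
        Individual("C1", MALE, False, GRANDFATHER, GRANDMOTHER),
        Individual("C2", FEMALE, False, GRANDFATHER, GRANDMOTHER),
        Individual("S1", FEMALE, False),
        Individual("S2", MALE, False),
        Individual("F", MALE, False, "C1", "S1"),
        Individual("M", FEMALE, False, "S2", "C2"),
        Individual("II.1", MALE, True, "F", "M"),
        Individual("II.2", MALE, True, "F", "M"),
    ]
    return Pedigree(members=members, family_id="FAM1")


# ---------------------------------------------------------------------------
# Meiosis and descent
# ---------------------------------------------------------------------------


def _founder_haplotype(founder_id: str, which: int, length: int) -> Haplotype:
    return [(0, length, f"{founder_id}.{which}")]


def _slice_haplotype(hap: Haplotype, lo: int, hi: int) -> Haplotype:
    out: Haplotype = []
    for s, e, label in hap:
        a, b = max(s, lo), min(e, hi)
        if b > a:
            out.append((a, b, label))
    return out


def _merge_adjacent(hap: Haplotype) -> Haplotype:
    out: Haplotype = []
    for seg in hap:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def meiosis(
    hap_a: Haplotype,
    hap_b: Haplotype,
    length: int,
    rate_cm_per_mb: float,
    rng: np.random.Generator,
) -> tuple[Haplotype, list[int]]:
    """One meiosis: Poisson crossovers, uniform positions, no interference.

    Returns the transmitted haplotype and the crossover positions used.
    """
    mean_crossovers = (length / 1e6) * rate_cm_per_mb / 100.0
    n = int(rng.poisson(mean_crossovers))
    positions = sorted(int(p) for p in rng.integers(1, length, size=n)) if n else []
    current = int(rng.integers(2))
    child: Haplotype = []
    bounds = [0] + positions + [length]
    for lo, hi in zip(bounds, bounds[1:]):
        if hi > lo:
            source = hap_a if current == 0 else hap_b
            child.extend(_slice_haplotype(source, lo, hi))
        current ^= 1
    return _merge_adjacent(child), positions


def _label_at(hap: Haplotype, pos: int) -> str:
    for s, e, label in hap:
        if s <= pos < e:
            return label
    raise ValueError(f"position {pos} outside haplotype extent")


def _equal_label_segments(hap_a: Haplotype, hap_b: Haplotype) -> list[Segment]:
    """Maximal segments where the two haplotypes carry the same founder label."""
    bounds = sorted({s for s, _, _ in hap_a + hap_b} | {e for _, e, _ in hap_a + hap_b})
    out: list[Segment] = []
    for lo, hi in zip(bounds, bounds[1:]):
        la = _label_at(hap_a, lo)
        lb = _label_at(hap_b, lo)
        if la == lb:
            out.append((lo, hi, la))
    return _merge_adjacent(out)


def _intersect_labelled(a: list[Segment], b: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for s0, e0, l0 in a:
        for s1, e1, l1 in b:
            if l0 == l1:
                lo, hi = max(s0, s1), min(e0, e1)
                if hi > lo:
                    out.append((lo, hi, l0))
    return sorted(out)


def gene_drop(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
) -> TruthRecord:
    """Drop founder haplotypes through the pedigree, one meiosis at a time.

    Founders receive distinct labelled haplotypes; every non-founder's
    paternal (maternal) haplotype is a recombinant of the father's (mother's)
    pair.  On the X chromosome males carry a single maternal haplotype and
    transmit it to daughters without recombination.
    """
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    haplotypes: dict[str, dict[str, tuple[Haplotype, ...]]] = {}
    crossovers: dict[str, list[int]] = {}

    order = pedigree._topological()
    for member in order:
        haplotypes[member.id] = {}
        for chrom in config.chromosome_names:
            length = config.chromosome_length(chrom)
            is_x = chrom == "X"
            if member.father_id is None:  # founder
                if is_x and member.sex == MALE:
                    haps: tuple[Haplotype, ...] = (
                        _founder_haplotype(member.id, 0, length),
                    )
                else:
                    haps = (
                        _founder_haplotype(member.id, 0, length),
                        _founder_haplotype(member.id, 1, length),
                    )
                haplotypes[member.id][chrom] = haps
                continue
            father_haps = haplotypes[member.father_id][chrom]
            mother_haps = haplotypes[member.mother_id][chrom]
            mat, xo_m = meiosis(
                mother_haps[0],
                mother_haps[-1],
                length,
                config.recombination_rate_cm_per_mb,
                rng,
            )
            crossovers[f"{member.id}|{member.mother_id}|{chrom}"] = xo_m
            if is_x:
                if member.sex == MALE:
                    haplotypes[member.id][chrom] = (mat,)
                else:
                    # daughter: father's single X passes intact
                    haplotypes[member.id][chrom] = (list(father_haps[0]), mat)
                continue
            pat, xo_p = meiosis(
                father_haps[0],
                father_haps[1],
                length,
                config.recombination_rate_cm_per_mb,
                rng,
            )
            crossovers[f"{member.id}|{member.father_id}|{chrom}"] = xo_p
            haplotypes[member.id][chrom] = (pat, mat)

    autozygous: dict[str, dict[str, list[Segment]]] = {}
    for child in AFFECTED_CHILDREN:
        autozygous[child] = {}
        for chrom in config.autosomes:
            pat, mat = haplotypes[child][chrom]
            autozygous[child][chrom] = _equal_label_segments(pat, mat)
    shared: dict[str, list[Segment]] = {}
    for chrom in config.autosomes:
        shared[chrom] = _intersect_labelled(
            autozygous[AFFECTED_CHILDREN[0]][chrom],
            autozygous[AFFECTED_CHILDREN[1]][chrom],
        )

    return TruthRecord(
        haplotypes=haplotypes,
        crossovers=crossovers,
        autozygous_segments=autozygous,
        shared_autozygous_segments=shared,
        variant_genotypes={},
        variant_positions={},
        segregating=False,
    )


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


def _genotype_from_descent(
    truth: TruthRecord, chrom: str, pos: int, carrier_label: str, member_id: str
) -> int:
    haps = truth.haplotypes[member_id].get(chrom)
    if haps is None:
        return 0
    return sum(1 for hap in haps if _label_at(hap, pos) == carrier_label)


def plant_variants(
    truth: TruthRecord, config: SimConfig, rng: np.random.Generator | None = None
) -> TruthRecord:
    """Assign the planted causal variant and decoys onto the realized descent.

    The causal variant sits at its configured position on one grandparental
    haplotype; its genotypes follow descent, and the replicate is flagged
    segregating iff both affected children are homozygous for it.  Decoys are
    placed at random positions inside the realized shared autozygous
    segments, riding whichever founder haplotype is identical by descent
    there, so they are shared homozygous by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.random_seed + 1)
    members = list(truth.haplotypes)
    chrom, pos = config.planted_chromosome, config.planted_position
    truth.variant_positions["planted_lof"] = (chrom, pos)
    truth.variant_genotypes["planted_lof"] = {
        m: _genotype_from_descent(truth, chrom, pos, config.planted_founder_haplotype, m)
        for m in members
    }
    truth.segregating = all(
        truth.variant_genotypes["planted_lof"][c] == 2 for c in AFFECTED_CHILDREN
    )

    # Decoy placement: inside realized shared autozygous segments.
    pool: list[tuple[str, int, int, str]] = [
        (c, s, e, label)
        for c, segs in truth.shared_autozygous_segments.items()
        for s, e, label in segs
    ]
    profiles = list(config.decoy_profiles)
    while len(profiles) < config.n_decoys:
        base = profiles[len(profiles) % max(len(config.decoy_profiles), 1)]
        profiles.append(DecoyProfile(f"{base.name}_{len(profiles)}", base.bundle))
    used: set[tuple[str, int]] = {(chrom, pos)}
    for profile in profiles[: config.n_decoys]:
        if not pool:
            break
        lengths = np.array([e - s for _, s, e, _ in pool], dtype=float)
        idx = int(rng.choice(len(pool), p=lengths / lengths.sum()))
        dchrom, s, e, label = pool[idx]
        dpos = int(rng.integers(s, e))
        while (dchrom, dpos) in used and e - s > 1:
            dpos = int(rng.integers(s, e))
        used.add((dchrom, dpos))
        truth.variant_positions[profile.name] = (dchrom, dpos)
        truth.variant_genotypes[profile.name] = {
            m: _genotype_from_descent(truth, dchrom, dpos, label, m) for m in members
        }
    return truth


def simulate_family(
    config: SimConfig,
    *,
    require_segregating: bool = True,
    max_tries: int = 2000,
) -> tuple[Pedigree, TruthRecord]:
    """Gene-drop the first-cousin pedigree, optionally until the planted
    variant segregates (both children homozygous), and plant all variants.

    With ``require_segregating`` off, the single realized drop is returned
    with its ``segregating`` flag reporting whether the planted variant is
    homozygous in both children (expected in about 1 drop in 256).
    """
    pedigree = build_first_cousin_pedigree()
    rng = np.random.default_rng(config.random_seed)
    tries = 0
    while True:
        truth = gene_drop(pedigree, config, rng)
        truth = plant_variants(truth, config, rng)
        tries += 1
        if truth.segregating or not require_segregating or tries >= max_tries:
            truth.n_resamples = tries - 1
            return pedigree, truth


# ---------------------------------------------------------------------------
# VCF / PED / annotation emission
# ---------------------------------------------------------------------------


def _sample_depth(config: SimConfig, rng: np.random.Generator) -> int:
    if config.depth_dispersion is None:
        return int(rng.poisson(config.mean_depth))
    k = config.depth_dispersion
    p = k / (k + config.mean_depth)
    return int(rng.negative_binomial(k, p))


def _noisy_call(
    true_gt: tuple[int, ...], config: SimConfig, rng: np.random.Generator
) -> tuple[tuple[int, ...], int, tuple[int, int]]:
    """Simulate (called genotype, GQ, AD) for a biallelic site.

    Allele depths are binomial around the true allele dosage with a per-read
    error rate; with probability ``genotype_error_rate`` the *called*
    genotype is replaced by a different one (the evidence fields keep their
    values — miscalls with clean-looking support are the realistic failure
    mode for hard-filtered calls).
    """
    ploidy = len(true_gt)
    dose = sum(true_gt) / ploidy
    p_alt = dose * (1 - config.read_error_rate) + (1 - dose) * config.read_error_rate
    depth = _sample_depth(config, rng)
    n_alt = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
    ad = (depth - n_alt, n_alt)
    gq = int(np.clip(round(rng.normal(config.gq_mean, config.gq_sd)), 0, 99))
    called = tuple(sorted(true_gt))
    if config.genotype_error_rate > 0 and rng.random() < config.genotype_error_rate:
        if ploidy == 1:
            called = (1 - called[0],)
        else:
            options = [g for g in ((0, 0), (0, 1), (1, 1)) if g != called]
            called = options[int(rng.integers(len(options)))]
    return called, gq, ad


def _marker_positions(
    config: SimConfig, chrom: str, forbidden: set[int], rng: np.random.Generator
) -> list[int]:
    length = config.chromosome_length(chrom)
    n = int(round(config.marker_density_per_mb * length / 1e6))
    positions: set[int] = set()
    while len(positions) < n:
        draw = rng.integers(1, length - 1, size=n - len(positions))
        positions.update(int(p) for p in draw if int(p) not in forbidden)
    return sorted(positions)


def emit_vcf(
    truth: TruthRecord,
    config: SimConfig,
    out_dir: str | Path,
    *,
    prefix: str = "sim",
) -> dict[str, Path]:
    """Write sim VCF + PED + annotation TSV + truth JSON into ``out_dir``.

    Markers are biallelic SNVs (REF A, ALT G) at the configured density with
    founder allele frequencies drawn uniformly from the configured range (and
    recorded in the annotation TSV as the population frequency, which is why
    markers never survive the rare-variant filter).  The planted variant is
    emitted as a 1 bp deletion (REF AG, ALT A), decoys as G>A SNVs.  With a
    fixed seed output is byte-identical across runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.random_seed + 2)
    pedigree = build_first_cousin_pedigree()
    samples = [s for s in config.sequenced_samples]

    forbidden: dict[str, set[int]] = {c: set() for c in config.chromosome_names}
    for vid, (chrom, pos) in truth.variant_positions.items():
        forbidden.setdefault(chrom, set()).add(pos)

    annotations: dict[str, AnnotationBundle] = {}
    rows: list[tuple[str, int, str, str, str, dict[str, tuple[int, ...]]]] = []
    # rows: (chrom, pos0, id, ref, alt, true genotype per sample)

    for chrom in config.chromosome_names:
        is_x = chrom == "X"
        marker_pos = _marker_positions(config, chrom, forbidden.get(chrom, set()), rng)
        freqs = rng.uniform(*config.founder_allele_freq_range, size=len(marker_pos))
        founder_labels = sorted(
            {
                label
                for m in pedigree.founders
                for hap in truth.haplotypes[m.id].get(chrom, ())
                for _, _, label in hap
            }
        )
        founder_alleles = {
            label: rng.random(size=len(marker_pos)) < freqs for label in founder_labels
        }
        for j, pos in enumerate(marker_pos):
            gts: dict[str, tuple[int, ...]] = {}
            for s in samples:
                haps = truth.haplotypes[s][chrom]
                gts[s] = tuple(
                    int(founder_alleles[_label_at(h, pos)][j]) for h in haps
                )
            vid = f"{chrom}:{pos + 1}:A:G"
            rows.append((chrom, pos, ".", "A", "G", gts))
            annotations[vid] = AnnotationBundle(
                allele_frequency={"1000Genome": round(float(freqs[j]), 6)}
            )

    for vid, (chrom, pos) in truth.variant_positions.items():
        gts = {}
        for s in samples:
            n_alt = truth.variant_genotypes[vid][s]
            ploidy = len(truth.haplotypes[s].get(chrom, (None, None)))
            gts[s] = tuple([1] * n_alt + [0] * (ploidy - n_alt))
        if vid == "planted_lof":
            ref, alt = "AG", "A"
        else:
            ref, alt = "G", "A"
        rows.append((chrom, pos, vid, ref, alt, gts))
        if vid == "planted_lof":
            annotations[vid] = planted_bundle()
        else:
            profile = next(p for p in config.decoy_profiles if p.name == vid)
            annotations[vid] = profile.bundle

    chrom_order = {c: i for i, c in enumerate(config.chromosome_names)}
    rows.sort(key=lambda r: (chrom_order[r[0]], r[1]))

    vcf_path = out_dir / f"{prefix}.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=autozyg-synthetic-pedigree\n")
        for chrom in config.chromosome_names:
            fh.write(f"##contig=<ID={chrom},length={config.chromosome_length(chrom)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for chrom, pos, vid, ref, alt, gts in rows:
            cols = [chrom, str(pos + 1), vid, ref, alt, ".", "PASS", ".", "GT:GQ:AD"]
            for s in samples:
                called, gq, ad = _noisy_call(gts[s], config, rng)
                gt_str = "/".join(str(a) for a in called)
                cols.append(f"{gt_str}:{gq}:{ad[0]},{ad[1]}")
            fh.write("\t".join(cols) + "\n")

    ped_path = out_dir / f"{prefix}.ped"
    write_pedigree(pedigree, ped_path)

    from .prioritization import write_annotations

    ann_path = out_dir / f"{prefix}.annotations.tsv"
    write_annotations(annotations, ann_path)

    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "segregating": truth.segregating,
                "n_resamples": truth.n_resamples,
                "variant_positions": {
                    vid: [c, p] for vid, (c, p) in truth.variant_positions.items()
                },
                "variant_genotypes": truth.variant_genotypes,
                "autozygous_segments": {
                    child: {c: [[s, e, l] for s, e, l in segs] for c, segs in per.items()}
                    for child, per in truth.autozygous_segments.items()
                },
                "shared_autozygous_segments": {
                    c: [[s, e, l] for s, e, l in segs]
                    for c, segs in truth.shared_autozygous_segments.items()
                },
                "crossovers": truth.crossovers,
            },
            indent=1,
        )
    )
    return {
        "vcf": vcf_path,
        "ped": ped_path,
        "annotations": ann_path,
        "truth": truth_path,
    }
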