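"""Recessive filter cascade: segregation, frequency, containment, ranking, X scan."""

import itertools

import pytest

from autozyg.case_study import run_worked_example, shared_homozygous_variants, index_family, shared_roh_track
from autozyg.prioritization import (
    BENIGN_PREDICTION_LOW_CONSERVATION,
    CONTROL_HOMOZYGOTE,
    PHENOTYPE_MISMATCH,
    AnnotationBundle,
    CandidateVerdict,
    SegregationStatus,
    attach_annotations,
    exclusion_rank,
    frequency_filter,
    read_annotations,
    roh_containment_filter,
    segregation_filter,
    write_annotations,
    x_hemizygous_scan,
)
from autozyg.roh_mapping import ROHInterval
from autozyg.variant_io import FEMALE, MALE, GenotypeCall, Individual, Pedigree, VariantRecord

HOM_ALT = GenotypeCall((1, 1), 60, (0, 30))
HOM_REF = GenotypeCall((0, 0), 60, (30, 0))
HET = GenotypeCall((0, 1), 60, (15, 15))
MISSING = GenotypeCall(None, None, ())


def quartet():
    return index_family()


def variant(calls, chrom="1", pos=155_928_109, vid=None):
    return VariantRecord(chrom, pos, "G", ("A",), calls, variant_id=vid)


class TestSegregationFilter:
    def test_recessive_configuration_passes(self):
        v = variant({"I.1": HET, "I.2": HET, "II.1": HOM_ALT, "II.2": HOM_ALT})
        assert segregation_filter(v, quartet()) is SegregationStatus.PASS

    def test_homozygous_parent_fails(self):
        v = variant({"I.1": HOM_ALT, "I.2": HET, "II.1": HOM_ALT, "II.2": HOM_ALT})
        assert segregation_filter(v, quartet()) is SegregationStatus.FAIL

    def test_heterozygous_affected_child_fails(self):
        v = variant({"I.1": HET, "I.2": HET, "II.1": HET, "II.2": HOM_ALT})
        assert segregation_filter(v, quartet()) is SegregationStatus.FAIL

    def test_missing_parent_is_missing_data_not_failure(self):
        v = variant({"I.1": MISSING, "I.2": HET, "II.1": HOM_ALT, "II.2": HOM_ALT})
        assert segregation_filter(v, quartet()) is SegregationStatus.MISSING_DATA

    def test_homozygous_unaffected_sibling_fails(self):
        ped = Pedigree(
            members=[
                Individual("I.1", MALE, False),
                Individual("I.2", FEMALE, False),
                Individual("II.1", MALE, True, "I.1", "I.2"),
                Individual("II.3", FEMALE, False, "I.1", "I.2"),
            ]
        )
        v = variant({"I.1": HET, "I.2": HET, "II.1": HOM_ALT, "II.3": HOM_ALT})
        assert segregation_filter(v, ped) is SegregationStatus.FAIL


class TestFrequencyFilter:
    def test_below_cutoff_no_homozygotes_passes(self):
        b = AnnotationBundle(allele_frequency={"1000Genome": 0.004})
        assert frequency_filter(b)

    def test_any_database_above_cutoff_fails(self):
        b = AnnotationBundle(allele_frequency={"1000Genome": 0.001, "ESP6500": 0.02})
        assert not frequency_filter(b)

    def test_control_homozygote_fails_despite_zero_frequency(self):
        b = AnnotationBundle(control_homozygote_count={"inhouse": 1})
        assert not frequency_filter(b)

    def test_heterozygote_carriers_alone_do_not_fail(self):
        b = AnnotationBundle(control_heterozygote_count={"ESP6500": 16})
        assert frequency_filter(b)

    def test_empty_bundle_passes(self):
        assert frequency_filter(AnnotationBundle())
        assert frequency_filter(None)

    def test_cutoff_is_strict_inequality(self):
        assert frequency_filter(AnnotationBundle(allele_frequency={"db": 0.005}))
        assert not frequency_filter(AnnotationBundle(allele_frequency={"db": 0.0051}))


class TestRohContainment:
    track = [ROHInterval("1", 1_000_000, 3_000_000, 40, "shared")]

    def test_inside_passes(self):
        assert roh_containment_filter(variant({}, pos=2_000_001), self.track)

    def test_boundary_half_open(self):
        # 0-based start 3_000_000 is one past the interval end
        assert roh_containment_filter(variant({}, pos=3_000_000), self.track)
        assert not roh_containment_filter(variant({}, pos=3_000_001), self.track)

    def test_wrong_chromosome_fails(self):
        assert not roh_containment_filter(variant({}, chrom="2", pos=2_000_001), self.track)


class TestExclusionRank:
    def test_worked_example_reproduces_published_verdicts(self):
        verdicts = {v.variant_id: v for v in run_worked_example()}
        assert verdicts["ARHGEF2:c.1461delG"].status == "retained"
        assert verdicts["EXTL1:c.939G>A"].reasons == [CONTROL_HOMOZYGOTE]
        assert verdicts["HMCN1:c.6229G>A"].reasons == [PHENOTYPE_MISMATCH]
        assert verdicts["IGFN1:c.10369G>A"].reasons == [BENIGN_PREDICTION_LOW_CONSERVATION]
        assert sum(v.status == "excluded" for v in verdicts.values()) == 3

    def test_retained_sorted_first(self):
        order = [v.status for v in run_worked_example()]
        assert order == ["retained", "excluded", "excluded", "excluded"]

    def test_empty_candidate_list(self):
        assert exclusion_rank([], quartet(), []) == []

    def test_duplicate_ids_rejected(self):
        v = variant({"I.1": HET, "I.2": HET, "II.1": HOM_ALT, "II.2": HOM_ALT}, vid="dup")
        with pytest.raises(ValueError, match="duplicate"):
            exclusion_rank([(v, None), (v, None)], quartet(), [])

    def test_filter_order_independence(self):
        """The retained set is a pure conjunction: permuting candidates never
        changes any verdict."""
        candidates = shared_homozygous_variants()
        ped, roh = index_family(), shared_roh_track()
        reference = {v.variant_id: (v.status, tuple(v.reasons)) for v in
                     exclusion_rank(candidates, ped, roh)}
        for perm in itertools.permutations(candidates):
            got = {v.variant_id: (v.status, tuple(v.reasons)) for v in
                   exclusion_rank(list(perm), ped, roh)}
            assert got == reference

    def test_every_exclusion_carries_reasons(self):
        for v in run_worked_example():
            if v.status == "excluded":
                assert len(v.reasons) >= 1
            else:
                assert v.reasons == []

    def test_verdict_invariants_enforced(self):
        with pytest.raises(ValueError):
            CandidateVerdict("x", "retained", ["some_reason"])
        with pytest.raises(ValueError):
            CandidateVerdict("x", "excluded", [])


def x_variant(calls, pos=10_000_001, vid="xvar", annotations=None):
    v = VariantRecord("X", pos, "G", ("A",), calls, variant_id=vid)
    v.annotations = annotations
    return v


def x_family():
    return Pedigree(
        members=[
            Individual("I.1", MALE, False),
            Individual("I.2", FEMALE, False),
            Individual("II.1", MALE, True, "I.1", "I.2"),
            Individual("II.2", MALE, True, "I.1", "I.2"),
        ]
    )


HEMI_ALT = GenotypeCall((1,), 60, (0, 25))
HEMI_REF = GenotypeCall((0,), 60, (25, 0))


class TestXHemizygousScan:
    def test_shared_hemizygous_variant_returned(self):
        v = x_variant({"I.1": HEMI_REF, "I.2": HET, "II.1": HEMI_ALT, "II.2": HOM_ALT})
        assert x_hemizygous_scan([v], x_family()) == [v]

    def test_unaffected_male_carrier_excludes(self):
        v = x_variant({"I.1": HEMI_ALT, "I.2": HET, "II.1": HEMI_ALT, "II.2": HEMI_ALT})
        assert x_hemizygous_scan([v], x_family()) == []

    def test_pseudoautosomal_variant_not_returned(self):
        v = x_variant(
            {"I.1": HEMI_REF, "I.2": HET, "II.1": HOM_ALT, "II.2": HOM_ALT},
            pos=100_000,  # inside PAR1
        )
        assert x_hemizygous_scan([v], x_family()) == []

    def test_common_variant_filtered_by_frequency(self):
        v = x_variant(
            {"I.1": HEMI_REF, "I.2": HET, "II.1": HEMI_ALT, "II.2": HEMI_ALT},
            annotations=AnnotationBundle(allele_frequency={"1000Genome": 0.3}),
        )
        assert x_hemizygous_scan([v], x_family()) == []

    def test_affected_female_skips_scan(self, caplog):
        ped = Pedigree(
            members=[
                Individual("I.1", MALE, False),
                Individual("I.2", FEMALE, False),
                Individual("II.1", FEMALE, True, "I.1", "I.2"),
            ]
        )
        v = x_variant({"I.1": HEMI_REF, "I.2": HET, "II.1": HOM_ALT})
        with caplog.at_level("WARNING"):
            assert x_hemizygous_scan([v], ped) == []
        assert "skipped" in caplog.text

    def test_simulated_x_without_planted_variant_is_clean(self, tmp_path):
        """Simulated X markers are common population SNPs; none survive."""
        from autozyg.synthetic_pedigree import SimConfig, emit_vcf, simulate_family
        from autozyg.variant_io import read_pedigree, read_variants

        config = SimConfig(random_seed=5, include_x=True, n_chromosomes=1)
        _, truth = simulate_family(config)
        paths = emit_vcf(truth, config, tmp_path)
        variants = read_variants(paths["vcf"])
        pedigree = read_pedigree(paths["ped"])
        attach_annotations(variants, read_annotations(paths["annotations"]))
        # the toy X is only 50 Mb, so keep the scan outside a shrunken PAR
        hits = x_hemizygous_scan(
            variants, pedigree, par_regions=((0, 60_000),)
        )
        assert hits == []


class TestAnnotationTsv:
    def test_round_trip(self, tmp_path):
        bundles = {
            "v1": AnnotationBundle(
                allele_frequency={"1000Genome": 0.001, "ESP6500": 0.0025},
                control_heterozygote_count={"ESP6500": 7},
                control_homozygote_count={"inhouse": 1},
                prediction_labels={"SIFT": "tolerated", "PolyPhen2": "possibly damaging"},
                conservation_score=1.101,
                phenotype_match="no",
                known_disease_link="macular degeneration",
            ),
            "v2": AnnotationBundle(),
        }
        path = tmp_path / "ann.tsv"
        write_annotations(bundles, path)
        back = read_annotations(path)
        assert back["v1"] == bundles["v1"]
        assert back["v2"] == bundles["v2"]
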