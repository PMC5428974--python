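"""Splice-boundary deletion -> cDNA -> protein consequence chain."""

import numpy as np
import pytest

from autozyg.consequence import (
    NOT_FOUND,
    ProteinConsequence,
    TranscriptError,
    TranscriptModel,
    apply_boundary_deletion,
    spliced_cdna,
    translate_consequence,
)

# --- independent translation oracle -----------------------------------------
# Standard nuclear code built positionally, not via the implementation's
# translation path (which goes through Bio.Seq).

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(seq: str) -> str:
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


def oracle_consequence(original: str, edited: str, cds_start: int, cds_end: int):
    """Full-translation diff: translate both molecules, locate the divergence,
    and classify by deletion phase; mirrors the contract, not the code path."""
    orig = oracle_translate(original[cds_start:cds_end])
    assert orig.endswith("*") and "*" not in orig[:-1]
    orig = orig[:-1]
    new_all = oracle_translate(edited[cds_start:])
    stop = new_all.find("*")
    new = new_all if stop < 0 else new_all[:stop]
    if orig == new and stop >= 0:
        return ProteinConsequence(kind="synonymous_or_identity")
    i = 0
    while i < min(len(orig), len(new)) and orig[i] == new[i]:
        i += 1
    d = len(original) - len(edited)
    if d % 3 == 0:
        if stop == i:
            return ProteinConsequence("stop_gained", i + 1, orig[i] if i < len(orig) else "*", "*", 1)
        return ProteinConsequence(
            "inframe_deletion", i + 1,
            orig[i] if i < len(orig) else "*",
            new[i] if i < len(new) else None,
        )
    if stop == i:
        return ProteinConsequence("stop_gained", i + 1, orig[i] if i < len(orig) else "*", "*", 1)
    offset = stop - i + 1 if stop >= 0 else NOT_FOUND
    return ProteinConsequence(
        "frameshift", i + 1,
        orig[i] if i < len(orig) else "*",
        new[i] if i < len(new) else None,
        offset,
    )


# --- fixtures ----------------------------------------------------------------

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(RC)[::-1]


def two_exon_plus(genome="TTT" "ATGAAG" "GTAAGT" "CTGACCTAA" "TTT"):
    """Plus-strand toy: exon1 = ATGAAG, intron = GTAAGT, exon2 = CTGACCTAA."""
    return TranscriptModel(
        id="toy+",
        strand="+",
        exons=[(3, 9), (15, 24)],
        cds_start=0,
        cds_end=15,
        genomic_sequence=genome,
    )


def mirror_minus(t: TranscriptModel) -> TranscriptModel:
    """The same transcript encoded on the minus strand of the reverse-complement locus."""
    L = len(t.genomic_sequence)
    return TranscriptModel(
        id=t.id + "rc",
        strand="-",
        exons=[(L - e, L - s) for s, e in reversed(t.exons)],
        cds_start=t.cds_start,
        cds_end=t.cds_end,
        genomic_sequence=revcomp(t.genomic_sequence),
    )


class TestSplicedCdna:
    def test_single_exon_substring_identity(self):
        t = TranscriptModel("t", "+", [(2, 11)], 0, 9, "GGATGAAATAACC")
        assert spliced_cdna(t) == "ATGAAATAA"

    def test_two_exon_plus_strand(self):
        assert spliced_cdna(two_exon_plus()) == "ATGAAGCTGACCTAA"

    def test_minus_strand_is_reverse_complement_of_concatenation(self):
        t = two_exon_plus()
        m = mirror_minus(t)
        assert spliced_cdna(m) == spliced_cdna(t)
        # and by hand: revcomp of the genomic-order exon concatenation
        concat = "".join(m.exon_sequence(i) for i in range(2))
        assert spliced_cdna(m) == revcomp(concat)

    def test_exon_order_violation_is_error(self):
        with pytest.raises(TranscriptError, match="out of order"):
            TranscriptModel("t", "+", [(15, 24), (3, 9)], 0, 15,
                            two_exon_plus().genomic_sequence)

    def test_exon_outside_sequence_is_error(self):
        with pytest.raises(TranscriptError, match="outside"):
            TranscriptModel("t", "+", [(0, 99)], 0, 9, "ATGAAATAA")


class TestBoundaryDeletion:
    def test_last_exonic_base_before_donor(self):
        """Deleting the terminal exonic base shortens the spliced cDNA by 1;
        the donor shifts and the loss lands at the exon-exon junction."""
        t = two_exon_plus()
        res = apply_boundary_deletion(t, (8, 9))  # last base of exon 1 ("G")
        assert len(res.edited_cdna) == len(spliced_cdna(t)) - 1
        assert res.edited_cdna == "ATGAACTGACCTAA"
        assert res.cdna_hgvs == "c.6delG"
        assert res.deleted_exonic_length == 1

    def test_zero_length_deletion_is_identity(self):
        t = two_exon_plus()
        res = apply_boundary_deletion(t, (8, 8))
        assert res.edited_cdna == spliced_cdna(t)
        assert res.deleted_exonic_length == 0

    def test_fully_intronic_deletion_identity_with_notice(self):
        t = two_exon_plus()
        res = apply_boundary_deletion(t, (10, 11))
        assert res.edited_cdna == spliced_cdna(t)
        assert res.cdna_hgvs is None
        assert "intronic" in res.notice

    def test_minus_strand_genomic_delC_reports_delG(self):
        """A genomic delC on a minus-strand transcript is a delG in cDNA
        coordinates (the delC / c.xdelG situation of minus-strand genes)."""
        t = two_exon_plus()
        m = mirror_minus(t)
        # genomic base deleted on the minus locus: complement of exon1's last G = C
        L = len(t.genomic_sequence)
        g_del = (L - 9, L - 8)
        off = m.sequence_start
        assert m.genomic_sequence[g_del[0] - off : g_del[1] - off] == "C"
        res = apply_boundary_deletion(m, g_del)
        assert res.cdna_hgvs == "c.6delG"
        assert res.edited_cdna == "ATGAACTGACCTAA"

    def test_whole_exon_deletion_unsupported(self):
        with pytest.raises(TranscriptError, match="whole exon"):
            apply_boundary_deletion(two_exon_plus(), (3, 9))

    def test_multi_exon_deletion_unsupported(self):
        with pytest.raises(TranscriptError, match="more than one exon"):
            apply_boundary_deletion(two_exon_plus(), (8, 16))


class TestTranslateConsequence:
    def test_frameshift_worked_example(self):
        """CDS ATGAAGCTGACCTAA minus base 4 -> M-S-stop: p.K2Sfs*2."""
        original = "ATGAAGCTGACCTAA"
        edited = original[:3] + original[4:]
        pc = translate_consequence(original, edited, 0, 15)
        assert pc.kind == "frameshift"
        assert (pc.first_affected_residue, pc.original_residue, pc.new_residue) == (2, "K", "S")
        assert pc.stop_offset == 2
        assert pc.hgvs_p == "p.K2Sfs*2"

    def test_whole_codon_deletion_is_inframe(self):
        original = "ATGAAGCTGACCTAA"
        edited = original[:3] + original[6:]  # drop codon 2 (AAG)
        pc = translate_consequence(original, edited, 0, 15)
        assert pc.kind == "inframe_deletion"

    def test_no_edit_is_identity(self):
        s = "ATGAAGCTGACCTAA"
        assert translate_consequence(s, s, 0, 15).kind == "synonymous_or_identity"

    def test_internal_stop_in_original_rejected(self):
        with pytest.raises(TranscriptError, match="internal stop"):
            translate_consequence("ATGTAACTGTAA", "ATGTACTGTAA", 0, 12)

    def test_edit_truncating_start_codon_rejected(self):
        with pytest.raises(TranscriptError, match="start codon"):
            translate_consequence("ATGAAGTAA", "AT", 0, 9)

    def test_frameshift_iff_length_not_multiple_of_three(self):
        """Exhaustive on a stop-free shifted-frame toy: every CDS deletion is a
        frameshift exactly when its length is not a multiple of 3."""
        cds = "ATG" + "GCTTCCGGT" * 3 + "TAA"
        for start in range(3, len(cds) - 3):
            for length in range(1, 7):
                if start + length > len(cds) - 3:
                    continue
                edited = cds[:start] + cds[start + length :]
                pc = translate_consequence(cds, edited, 0, len(cds))
                assert (pc.kind == "frameshift") == (length % 3 != 0), (start, length)

    def test_agrees_with_full_translation_oracle_on_random_deletions(self):
        rng = np.random.default_rng(314)
        non_stop = [c for c in CODON_TABLE if CODON_TABLE[c] != "*"]
        checked = 0
        for _ in range(500):
            n_codons = int(rng.integers(4, 40))
            cds = "ATG" + "".join(
                non_stop[int(k)] for k in rng.integers(0, len(non_stop), n_codons)
            ) + ("TAA", "TAG", "TGA")[int(rng.integers(3))]
            utr5 = "".join("ACGT"[int(k)] for k in rng.integers(0, 4, int(rng.integers(0, 9))))
            utr3 = "".join("ACGT"[int(k)] for k in rng.integers(0, 4, int(rng.integers(0, 30))))
            original = utr5 + cds + utr3
            cds_start, cds_end = len(utr5), len(utr5) + len(cds)
            pos = int(rng.integers(cds_start + 3, cds_end - 3))  # keep start codon
            edited = original[:pos] + original[pos + 1 :]
            got = translate_consequence(original, edited, cds_start, cds_end)
            expected = oracle_consequence(original, edited, cds_start, cds_end)
            assert got == expected, (original, pos)
            checked += 1
        assert checked == 500


class TestStrandInvariance:
    def test_protein_consequence_invariant_under_strand_encoding(self):
        """Random two-exon toys: computing on the plus-strand encoding and on
        its reverse-complement minus-strand encoding yields the same protein
        consequence for the mirrored deletion."""
        rng = np.random.default_rng(2718)
        non_stop = [c for c in CODON_TABLE if CODON_TABLE[c] != "*"]
        for _ in range(100):
            n1 = int(rng.integers(2, 6)) * 3  # exon 1 coding length
            n2 = int(rng.integers(2, 6)) * 3
            cds = "ATG" + "".join(
                non_stop[int(k)] for k in rng.integers(0, len(non_stop), (n1 + n2) // 3 - 1)
            )
            exon1, exon2 = cds[:n1], cds[n1:] + "TAA"
            intron = "GT" + "".join("ACGT"[int(k)] for k in rng.integers(0, 4, 6)) + "AG"
            genome = "TT" + exon1 + intron + exon2 + "TT"
            e1 = (2, 2 + len(exon1))
            e2 = (e1[1] + len(intron), e1[1] + len(intron) + len(exon2))
            t = TranscriptModel("r", "+", [e1, e2], 0, len(cds) + 3, genome)
            m = mirror_minus(t)
            # delete 1-2 terminal bases of exon 1 (donor-adjacent)
            k = int(rng.integers(1, 3))
            deletion = (e1[1] - k, e1[1])
            L = len(genome)
            mirrored = (L - deletion[1], L - deletion[0])
            res_p = apply_boundary_deletion(t, deletion)
            res_m = apply_boundary_deletion(m, mirrored)
            assert res_p.edited_cdna == res_m.edited_cdna
            assert res_p.cdna_hgvs == res_m.cdna_hgvs
            pc_p = translate_consequence(spliced_cdna(t), res_p.edited_cdna, 0, len(cds) + 3)
            pc_m = translate_consequence(spliced_cdna(m), res_m.edited_cdna, 0, len(cds) + 3)
            assert pc_p == pc_m


class TestTranscriptTsv:
    def test_read_transcript_round_trip(self, tmp_path):
        from autozyg.consequence import read_transcript

        t = two_exon_plus()
        fasta = tmp_path / "locus.fa"
        fasta.write_text(">locus\n" + t.genomic_sequence + "\n")
        tsv = tmp_path / "t.tsv"
        tsv.write_text(
            "transcript\ttoy+\t+\n"
            "exon\t3\t9\n"
            "exon\t15\t24\n"
            "cds\t0\t15\n"
        )
        back = read_transcript(tsv, fasta)
        assert spliced_cdna(back) == spliced_cdna(t)
        assert back.exons == t.exons
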