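"""Spliced-cDNA and protein consequences of an exon-boundary deletion.

Models the chain: genomic single-base (or short) deletion at or near a splice
donor → spliced cDNA losing exactly the deleted exonic bases (the donor site
shifts to recruit the neighbouring base, so splicing itself is preserved — an
empirically observed outcome, not a splice-strength prediction) → frameshift
or in-frame protein consequence in HGVS-like ``p.<X><pos><Y>fs*<offset>``
notation with one-letter amino-acid codes.

Transcript exons are genomic 0-based half-open intervals over a supplied
locus sequence; CDS bounds are transcript-space.  Minus-strand transcripts
are reverse-complemented at splicing time, so all cDNA-level reasoning is
strand-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from Bio.Seq import Seq

STOP = "*"
NOT_FOUND = "not found"


class TranscriptError(ValueError):
    """Invalid transcript model or unsupported deletion geometry."""


@dataclass
class TranscriptModel:
    """Strand-aware exon structure over a locus sequence.

    ``exons`` are genomic 0-based half-open intervals, sorted by genomic
    position and non-overlapping, given relative to ``genomic_sequence``
    (optionally offset by ``sequence_start`` from true genomic coordinates).
    ``cds_start``/``cds_end`` are 0-based half-open *transcript-space* bounds.
    """

    id: str
    strand: str  # "+" | "-"
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    genomic_sequence: str
    sequence_start: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise TranscriptError("transcript must have at least one exon")
        for (s, e) in self.exons:
            if e <= s:
                raise TranscriptError(f"empty exon [{s}, {e})")
            if s < self.sequence_start or e > self.sequence_start + len(self.genomic_sequence):
                raise TranscriptError(f"exon [{s}, {e}) outside provided genomic sequence")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise TranscriptError(
                    f"exons out of order or overlapping: [{s0},{e0}) then [{s1},{e1})"
                )
        if not (0 <= self.cds_start < self.cds_end <= self.spliced_length):
            raise TranscriptError(
                f"CDS [{self.cds_start}, {self.cds_end}) outside spliced length "
                f"{self.spliced_length}"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_sequence(self, index: int) -> str:
        s, e = self.exons[index]
        off = self.sequence_start
        return self.genomic_sequence[s - off : e - off]

    def transcript_index(self, genomic_pos: int) -> int:
        """Transcript-space index of an exonic genomic position."""
        plus_index = 0
        for s, e in self.exons:
            if s <= genomic_pos < e:
                plus_index += genomic_pos - s
                break
            plus_index += e - s
        else:
            raise TranscriptError(f"genomic position {genomic_pos} is not exonic")
        if self.strand == "+":
            return plus_index
        return self.spliced_length - 1 - plus_index


def spliced_cdna(t: TranscriptModel) -> str:
    """Concatenate exon sequences in transcript order (reverse complement on minus)."""
    concat = "".join(t.exon_sequence(i) for i in range(len(t.exons)))
    if t.strand == "-":
        return str(Seq(concat).reverse_complement())
    return concat


@dataclass
class BoundaryDeletionResult:
    edited_cdna: str
    cdna_hgvs: str | None  # None for the intronic identity case
    deleted_exonic_length: int
    notice: str | None = None


def apply_boundary_deletion(
    t: TranscriptModel, deletion: tuple[int, int]
) -> BoundaryDeletionResult:
    """Apply a genomic deletion touching at most one exon to the spliced cDNA.

    The deletion (genomic, 0-based half-open) must lie fully within one exon
    or clip one exon's terminal bases at a splice boundary.  Splicing is
    modelled as preserved — the donor/acceptor shifts to recruit the adjacent
    base — so the spliced cDNA loses exactly the deleted *exonic* bases.  The
    returned HGVS string uses CDS ("c.") numbering on the transcript strand.

    A fully intronic deletion returns the unchanged cDNA with a notice; a
    deletion removing a whole exon or touching several exons is unsupported.
    """
    dstart, dend = deletion
    if dend < dstart:
        raise TranscriptError(f"invalid deletion interval [{dstart}, {dend})")
    cdna = spliced_cdna(t)
    if dend == dstart:
        return BoundaryDeletionResult(cdna, None, 0, notice="zero-length deletion")
    hit = [
        (i, max(dstart, s), min(dend, e))
        for i, (s, e) in enumerate(t.exons)
        if min(dend, e) > max(dstart, s)
    ]
    if not hit:
        return BoundaryDeletionResult(
            cdna, None, 0, notice="deletion is fully intronic; spliced cDNA unchanged"
        )
    if len(hit) > 1:
        raise TranscriptError("deletion touches more than one exon; unsupported")
    i, lo, hi = hit[0]
    s, e = t.exons[i]
    if lo == s and hi == e:
        raise TranscriptError("deletion removes a whole exon; unsupported")
    # transcript indices of the deleted exonic bases (contiguous on either strand)
    t_indices = sorted(t.transcript_index(g) for g in range(lo, hi))
    first, last = t_indices[0], t_indices[-1]
    deleted_bases = cdna[first : last + 1]
    edited = cdna[:first] + cdna[last + 1 :]

    def c_pos(ti: int) -> int:
        # CDS-relative 1-based numbering; 5'UTR positions are negative
        # (c.-1 immediately precedes c.1, there is no c.0).
        if ti >= t.cds_start:
            return ti - t.cds_start + 1
        return ti - t.cds_start  # negative

    if len(t_indices) == 1:
        hgvs = f"c.{c_pos(first)}del{deleted_bases}"
    else:
        hgvs = f"c.{c_pos(first)}_{c_pos(last)}del{deleted_bases}"
    return BoundaryDeletionResult(edited, hgvs, len(t_indices))


@dataclass
class ProteinConsequence:
    """Protein-level outcome of a cDNA edit.

    ``stop_offset`` is the 1-based index of the first stop codon in the new
    reading frame, counting the first changed residue as 1 (so a frameshift
    always has offset >= 2; offset 1 is a direct stop gain).
    """

    kind: str  # synonymous_or_identity | inframe_deletion | frameshift | stop_gained
    first_affected_residue: int | None = None
    original_residue: str | None = None
    new_residue: str | None = None
    stop_offset: int | str | None = None

    @property
    def hgvs_p(self) -> str:
        if self.kind == "synonymous_or_identity":
            return "p.(=)"
        pos = self.first_affected_residue
        if self.kind == "stop_gained":
            return f"p.{self.original_residue}{pos}*"
        if self.kind == "frameshift":
            off = self.stop_offset if self.stop_offset != NOT_FOUND else "?"
            return f"p.{self.original_residue}{pos}{self.new_residue}fs*{off}"
        return f"p.{self.original_residue}{pos}del"


def _translate(seq: str) -> str:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def translate_consequence(
    original_cdna: str,
    edited_cdna: str,
    cds_start: int,
    cds_end: int,
) -> ProteinConsequence:
    """Compare translations of the original and edited cDNA.

    ``cds_start``/``cds_end`` bound the CDS in the *original* cDNA (0-based
    half-open).  The edited CDS is read from the same start to the end of the
    edited molecule, so a frameshifted tail is translated through the 3'UTR
    until a stop codon or the end of the transcript.
    """
    orig_cds = original_cdna[cds_start:cds_end]
    if len(orig_cds) < 3:
        raise TranscriptError("CDS shorter than one codon")
    orig_prot_full = _translate(orig_cds)
    orig_prot = orig_prot_full.rstrip(STOP)
    if STOP in orig_prot:
        raise TranscriptError("original CDS contains an internal stop codon")
    if len(edited_cdna) < cds_start + 3:
        raise TranscriptError("edited sequence truncated within the start codon")
    edit_prot_all = _translate(edited_cdna[cds_start:])
    stop_at = edit_prot_all.find(STOP)
    edit_prot = edit_prot_all if stop_at < 0 else edit_prot_all[:stop_at]

    deletion_length = len(original_cdna) - len(edited_cdna)

    # first divergent residue (0-based), comparing up to the edited stop
    i = 0
    while i < len(orig_prot) and i < len(edit_prot) and orig_prot[i] == edit_prot[i]:
        i += 1

    identical = orig_prot == edit_prot and (stop_at >= 0) == orig_prot_full.endswith(STOP)
    if deletion_length == 0 and original_cdna == edited_cdna:
        return ProteinConsequence(kind="synonymous_or_identity")
    if identical:
        return ProteinConsequence(kind="synonymous_or_identity")

    if i >= len(orig_prot) and i >= len(edit_prot):
        # proteins agree over their common extent but stops differ (e.g. the
        # deletion removed the stop codon): report as frameshift-like
        # extension from the residue after the last shared one
        i = min(len(orig_prot), len(edit_prot))

    orig_res = orig_prot[i] if i < len(orig_prot) else STOP
    new_res = edit_prot[i] if i < len(edit_prot) else (STOP if stop_at == i else None)

    if deletion_length % 3 == 0:
        if new_res == STOP or (stop_at >= 0 and stop_at == i):
            return ProteinConsequence(
                kind="stop_gained",
                first_affected_residue=i + 1,
                original_residue=orig_res,
                new_residue=STOP,
                stop_offset=1,
            )
        return ProteinConsequence(
            kind="inframe_deletion",
            first_affected_residue=i + 1,
            original_residue=orig_res,
            new_residue=new_res,
        )

    # frameshift: stop offset counts the first changed residue as 1
    if stop_at >= 0:
        if stop_at == i:
            return ProteinConsequence(
                kind="stop_gained",
                first_affected_residue=i + 1,
                original_residue=orig_res,
                new_residue=STOP,
                stop_offset=1,
            )
        offset: int | str = stop_at - i + 1
    else:
        offset = NOT_FOUND
    return ProteinConsequence(
        kind="frameshift",
        first_affected_residue=i + 1,
        original_residue=orig_res,
        new_residue=new_res,
        stop_offset=offset,
    )


# ---------------------------------------------------------------------------
# Transcript TSV + FASTA input
# ---------------------------------------------------------------------------
#
# GFF-like TSV, tab-separated, one directive per line:
#
#   transcript  <id>  <strand>
#   exon        <genomic_start>  <genomic_end>          (0-based half-open)
#   cds         <transcript_start>  <transcript_end>    (0-based half-open)
#
# The FASTA's first record supplies the locus sequence; its coordinate origin
# may be shifted with an optional "offset  <int>" line.


def read_transcript(tsv_path: str | Path, fasta_path: str | Path) -> TranscriptModel:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    seq = str(record.seq).upper()

    tid = "transcript"
    strand = "+"
    exons: list[tuple[int, int]] = []
    cds: tuple[int, int] | None = None
    offset = 0
    for line_no, line in enumerate(Path(tsv_path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0].lower()
        if kind == "transcript":
            tid, strand = fields[1], fields[2]
        elif kind == "exon":
            exons.append((int(fields[1]), int(fields[2])))
        elif kind == "cds":
            cds = (int(fields[1]), int(fields[2]))
        elif kind == "offset":
            offset = int(fields[1])
        else:
            raise TranscriptError(f"{tsv_path}:{line_no}: unknown directive {kind!r}")
    if cds is None:
        raise TranscriptError(f"{tsv_path}: missing cds line")
    return TranscriptModel(
        id=tid,
        strand=strand,
        exons=exons,
        cds_start=cds[0],
        cds_end=cds[1],
        genomic_sequence=seq,
        sequence_start=offset,
    )
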