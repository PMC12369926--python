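"""Protein-level consequence of a splicing change.

Reference and variant transcripts are conceptually translated from a
supplied CDS start (translation initiation is taken from annotation, never
inferred), and the variant is classified by comparing the two coding
sequences: an exonic-length change that is a multiple of three and
introduces no stop codon gives an in-frame deletion (or insertion), any
other length change shifts the reading frame and truncates, and an
in-frame premature stop inside retained sequence truncates without a
frameshift.  This mirrors how a retained intron whose length is not a
multiple of three removes a C-terminal domain by frameshift while a
skipped cassette exon of length 3k deletes exactly k amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .genome import GenomeSequence, TranscriptModel, spliced_sequence

CONSEQUENCE_CLASSES = (
    "identical",
    "inframe_deletion",
    "inframe_insertion",
    "frameshift_truncation",
    "stop_gain_truncation",
    "start_lost",
)


@dataclass
class ConsequenceCall:
    gene_id: str
    iso_ref: str
    iso_alt: str
    consequence_class: str
    deleted_aa_count: int | None = None      # >0 deletion, <0 insertion
    truncation_position: int | None = None   # 1-based aa index of first change
    ref_protein: str = ""
    alt_protein: str = ""
    utr_only: bool = False
    nonstop_ref: bool = False
    nonstop_alt: bool = False


def conceptual_translate(tx: TranscriptModel, genome: GenomeSequence,
                         cds_start_in_mrna: int) -> tuple[str, bool]:
    """Translate the mRNA from ``cds_start_in_mrna`` to the first stop.

    Returns (protein, nonstop) where ``nonstop`` is True when translation
    ran off the end of the mRNA without meeting a stop codon.
    """
    mrna = spliced_sequence(tx, genome)
    return translate_mrna(mrna, cds_start_in_mrna)


def translate_mrna(mrna: str, cds_start: int) -> tuple[str, bool]:
    if not 0 <= cds_start < len(mrna):
        raise ValueError(f"cds_start {cds_start} outside mRNA of length {len(mrna)}")
    cds = mrna[cds_start:]
    cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate())
    stop = aa.find("*")
    if stop == -1:
        return aa, True
    return aa[:stop], False


def longest_orf_start(mrna: str) -> int | None:
    """Start offset of the longest ATG-initiated open reading frame.

    Helper only; consequence classification never calls this implicitly.
    """
    best: tuple[int, int] | None = None
    for i in range(len(mrna) - 2):
        if mrna[i:i + 3] != "ATG":
            continue
        aa, _ = translate_mrna(mrna, i)
        if best is None or len(aa) > best[1]:
            best = (i, len(aa))
    return None if best is None else best[0]


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str, max_len: int) -> int:
    n = min(len(a), len(b), max_len)
    for i in range(n):
        if a[len(a) - 1 - i] != b[len(b) - 1 - i]:
            return i
    return n


def classify_consequence(ref_tx: TranscriptModel, alt_tx: TranscriptModel,
                         genome: GenomeSequence, cds_start: int) -> ConsequenceCall:
    """Classify the protein-level effect of the difference between two isoforms.

    ``cds_start`` is the translation start offset within the *reference*
    mRNA; the variant is assumed to share the reference 5' end up to the
    splicing difference, so a difference entirely 5' of the CDS shifts the
    variant's start by the length delta and is reported as UTR-only.
    """
    ref_mrna = spliced_sequence(ref_tx, genome)
    alt_mrna = spliced_sequence(alt_tx, genome)
    call = ConsequenceCall(ref_tx.gene_id, ref_tx.transcript_id, alt_tx.transcript_id,
                           "identical")

    delta = len(alt_mrna) - len(ref_mrna)
    p = _common_prefix(ref_mrna, alt_mrna)
    s = _common_suffix(ref_mrna, alt_mrna, min(len(ref_mrna), len(alt_mrna)) - p)
    ref_diff_end = len(ref_mrna) - s  # difference occupies ref_mrna[p:ref_diff_end)

    if ref_diff_end <= cds_start:
        # change entirely within the 5' UTR
        call.utr_only = True
        alt_start = cds_start + delta
        ref_p, call.nonstop_ref = translate_mrna(ref_mrna, cds_start)
        alt_p, call.nonstop_alt = translate_mrna(alt_mrna, alt_start)
        call.ref_protein, call.alt_protein = ref_p, alt_p
        if ref_p != alt_p:  # cannot happen when 3' portions align, kept as guard
            call.consequence_class = "complex"
        return call

    if p <= cds_start:
        # the difference begins at or before the start codon and, by the
        # branch above, extends past it: translation initiation is disrupted
        call.consequence_class = "start_lost"
        ref_p, call.nonstop_ref = translate_mrna(ref_mrna, cds_start)
        call.ref_protein = ref_p
        return call

    ref_p, nonstop_ref = translate_mrna(ref_mrna, cds_start)
    alt_p, nonstop_alt = translate_mrna(alt_mrna, cds_start)
    call.ref_protein, call.alt_protein = ref_p, alt_p
    call.nonstop_ref, call.nonstop_alt = nonstop_ref, nonstop_alt

    if ref_p == alt_p:
        call.consequence_class = "identical"
        return call

    first_div = _common_prefix(ref_p, alt_p) + 1  # 1-based
    call.truncation_position = min(first_div, len(ref_p) + 1)

    if delta % 3 != 0:
        call.consequence_class = "frameshift_truncation"
        return call

    if delta <= 0:
        # in-frame deletion iff alt is ref with one contiguous block removed
        d = -delta // 3
        ap = _common_prefix(ref_p, alt_p)
        asuf = _common_suffix(ref_p, alt_p, min(len(ref_p), len(alt_p)) - ap)
        if len(ref_p) - len(alt_p) == d and ap + asuf >= len(alt_p):
            call.consequence_class = "inframe_deletion"
            call.deleted_aa_count = d
            call.truncation_position = None
            return call
        call.consequence_class = "stop_gain_truncation"
        return call
    # delta > 0, in frame
    d = delta // 3
    ap = _common_prefix(ref_p, alt_p)
    asuf = _common_suffix(ref_p, alt_p, min(len(ref_p), len(alt_p)) - ap)
    if len(alt_p) - len(ref_p) == d and ap + asuf >= len(ref_p):
        call.consequence_class = "inframe_insertion"
        call.deleted_aa_count = -d
        call.truncation_position = None
        return call
    call.consequence_class = "stop_gain_truncation"
    return call
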