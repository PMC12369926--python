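"""Classification of the structural difference between two isoforms.

Two transcripts of the same gene are compared on their internal splice-site
chains.  Differences are resolved only inside the region bounded by the
outermost splice sites the two chains share; anything outside that frame is
an alternative transcription start or termination and is deliberately not
reported.  Within the frame, each maximal stretch of disagreement between
consecutive shared sites (a "bubble") is classified into one of the
elementary alternative-splicing classes:

ES  exon skipping            one isoform splices over a whole exon of the other
IR  intron retention         one isoform's intron lies inside the other's exon
A5  alternative 5' splice site   only a donor position differs
A3  alternative 3' splice site   only an acceptor position differs
ME  mutually exclusive exons     two disjoint exons, each private to one isoform

Bubbles containing more than one elementary difference are labelled
``complex`` rather than decomposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import SpliceJunction, TranscriptModel, ValidationError

EVENT_CLASSES = ("ES", "IR", "A5", "A3", "ME", "complex")


@dataclass
class SpliceEvent:
    gene_id: str
    iso_a: str
    iso_b: str
    event_class: str
    chrom: str
    strand: str
    variable_start: int
    variable_end: int
    # splice junctions private to one isoform (symmetric difference)
    affected_junctions: list[SpliceJunction] = field(default_factory=list)
    junctions_a: list[SpliceJunction] = field(default_factory=list)
    junctions_b: list[SpliceJunction] = field(default_factory=list)

    @property
    def nt_delta(self) -> int:
        """Exonic-length difference of isoform a minus isoform b over the bubble."""
        intron_a = sum(b - a for a, b in (j.interval for j in self.junctions_a))
        intron_b = sum(b - a for a, b in (j.interval for j in self.junctions_b))
        return intron_b - intron_a


class EventList(list):
    """Result of :func:`classify_pair`; ``no_common_frame`` is set when the
    two transcripts share no internal splice site and are therefore not
    comparable."""

    no_common_frame: bool = False


def _bubble_junctions(sites: list[tuple[int, str]], chrom: str, strand: str,
                      lo: tuple[int, str], hi: tuple[int, str]) -> list[SpliceJunction]:
    """Introns of one chain falling within [lo, hi], bubble bounds included."""
    window = [s for s in sites if lo[0] <= s[0] <= hi[0]]
    introns = []
    for (p, tp), (q, tq) in zip(window, window[1:]):
        if tp == "E" and tq == "S":
            if strand == "+":
                introns.append(SpliceJunction(chrom, p, q, "+"))
            else:
                introns.append(SpliceJunction(chrom, q, p, "-"))
    return introns


def _classify_bubble(sub_a: list[tuple[int, str]], sub_b: list[tuple[int, str]],
                     strand: str) -> str:
    """Elementary class of one bubble from its two differing sub-chains."""
    a, b = sorted((sub_a, sub_b), key=len)
    if len(a) == 0 and len(b) == 2:
        (p, tp), (q, tq) = b
        if (tp, tq) == ("E", "S"):
            return "IR"   # b splices the intron [p,q); a retains it in an exon
        if (tp, tq) == ("S", "E"):
            return "ES"   # b includes exon [p,q); a skips it
        return "complex"
    if len(a) == 1 and len(b) == 1:
        (p, tp), (q, tq) = a[0], b[0]
        if tp != tq or p == q:
            return "complex"
        if tp == "E":     # exon-end boundary: donor on +, acceptor on -
            return "A5" if strand == "+" else "A3"
        return "A3" if strand == "+" else "A5"
    if len(a) == 2 and len(b) == 2:
        (pa, ta), (qa, tqa) = a
        (pb, tb), (qb, tqb) = b
        if (ta, tqa) == ("S", "E") and (tb, tqb) == ("S", "E"):
            if qa <= pb or qb <= pa:  # disjoint private exons
                return "ME"
        return "complex"
    return "complex"


def classify_pair(tx_a: TranscriptModel, tx_b: TranscriptModel) -> EventList:
    """Classify all elementary splicing differences between two isoforms.

    Returns an :class:`EventList`; empty for identical chains.  Raises
    :class:`ValidationError` when the transcripts are not comparable
    (different chromosome or strand).
    """
    if tx_a.chrom != tx_b.chrom:
        raise ValidationError("transcripts on different chromosomes")
    if tx_a.strand != tx_b.strand:
        raise ValidationError("transcripts on different strands")
    strand, chrom = tx_a.strand, tx_a.chrom

    chain_a = tx_a.splice_sites()
    chain_b = tx_b.splice_sites()
    # shared transcript termini anchor the comparison frame: a retained
    # first intron between identical transcript starts is a real splicing
    # difference, not an alternative start
    anchors = []
    if tx_a.span[0] == tx_b.span[0]:
        anchors.append((tx_a.span[0], "A"))
    if tx_a.span[1] == tx_b.span[1]:
        anchors.append((tx_a.span[1], "A"))
    shared = sorted((set(chain_a) & set(chain_b)) | set(anchors))
    events = EventList()
    if not shared:
        events.no_common_frame = True
        return events

    for lo, hi in zip(shared, shared[1:]):
        sub_a = [s for s in chain_a if lo[0] < s[0] < hi[0]]
        sub_b = [s for s in chain_b if lo[0] < s[0] < hi[0]]
        if sub_a == sub_b:
            continue
        cls = _classify_bubble(sub_a, sub_b, strand)
        diff = sorted(set(sub_a) ^ set(sub_b))
        var_start, var_end = diff[0][0], diff[-1][0]
        junc_a = _bubble_junctions(chain_a, chrom, strand, lo, hi)
        junc_b = _bubble_junctions(chain_b, chrom, strand, lo, hi)
        affected = [j for j in junc_a if j not in junc_b] + [
            j for j in junc_b if j not in junc_a
        ]
        events.append(
            SpliceEvent(
                gene_id=tx_a.gene_id,
                iso_a=tx_a.transcript_id,
                iso_b=tx_b.transcript_id,
                event_class=cls,
                chrom=chrom,
                strand=strand,
                variable_start=var_start,
                variable_end=var_end,
                affected_junctions=affected,
                junctions_a=junc_a,
                junctions_b=junc_b,
            )
        )
    # order events 5'->3' in transcript sense
    events.sort(key=lambda e: e.variable_start, reverse=(strand == "-"))
    out = EventList(events)
    out.no_common_frame = False
    return out


def affected_junction_regions(event: SpliceEvent) -> list[SpliceJunction]:
    """The introns whose flanks define the event, for flank extraction.

    IR: the retained intron itself.  ES: the two introns flanking the
    skipped exon in the isoform that includes it.  Other classes (and
    complex events) return every junction private to one isoform.
    """
    if event.event_class == "IR":
        return [
            j for j in event.affected_junctions
            if j.interval == (event.variable_start, event.variable_end)
        ]
    if event.event_class == "ES":
        # keep the two short introns; drop the spanning skip junction
        return [
            j for j in event.affected_junctions
            if not (j.interval[0] < event.variable_start
                    and j.interval[1] > event.variable_end)
        ]
    return list(event.affected_junctions)
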