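"""PWM log-odds scanning of splice-junction flank regions.

Around each affected intron four 100-base regions are read in transcript
sense: IR1 (exonic, 5' of the donor), IR2 (first intronic bases after the
donor), IR3 (last intronic bases before the acceptor) and IR4 (exonic, 3'
of the acceptor).  Regions are reported as RNA (T -> U) because the
matrices describe RNA-binding-protein preferences; scanning is
single-stranded, sense only.

Scores are log2 odds against a uniform 0.25 background with a small
pseudocount; a window is a hit when its summed score reaches the threshold
(default 6, inclusive).  Windows containing N score minus infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSequence, SpliceJunction, reverse_complement

RNA_ALPHABET = ("A", "C", "G", "U")
REGION_LABELS = ("IR1", "IR2", "IR3", "IR4")

DEFAULT_THRESHOLD = 6.0
DEFAULT_PSEUDOCOUNT = 1e-3
DEFAULT_FLANK_WIDTH = 100


@dataclass
class PWM:
    """Position probability matrix over A/C/G/U for one RNA-binding protein."""

    rbp_id: str
    probs: np.ndarray  # shape (width, 4), columns in RNA_ALPHABET order

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM {self.rbp_id}: expected (width, 4) matrix")
        if self.width < 3:
            raise ValueError(f"PWM {self.rbp_id}: width {self.width} < 3")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.rbp_id}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        """Maximum-probability word (ties broken by alphabet order)."""
        return "".join(RNA_ALPHABET[i] for i in self.probs.argmax(axis=1))


def read_pwms(path) -> list[PWM]:
    """Read CISBP-RNA-style matrices from a TSV file.

    Format: blocks separated by blank lines; first line of a block is the
    RBP identifier, followed by a header row ``Pos A C G U`` and one row of
    probabilities per motif position.
    """
    pwms = []
    with open(path) as fh:
        block: list[str] = []
        for line in list(fh) + [""]:
            line = line.strip()
            if line:
                block.append(line)
                continue
            if block:
                rbp_id = block[0]
                rows = [b.split("\t") for b in block[2:]]
                probs = np.array([[float(x) for x in r[1:5]] for r in rows])
                pwms.append(PWM(rbp_id, probs))
                block = []
    return pwms


def write_pwms(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(pwm.rbp_id + "\n")
            fh.write("Pos\tA\tC\tG\tU\n")
            for i, row in enumerate(pwm.probs, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{p:.10f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Flank-region extraction
# ---------------------------------------------------------------------------

@dataclass
class Region:
    label: str           # IR1..IR4
    chrom: str
    start: int           # genomic, 0-based half-open
    end: int
    strand: str
    sequence: str        # transcript-sense RNA
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """The four flank regions of one affected intron."""

    junction: SpliceJunction
    regions: dict[str, Region] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.regions.values())


def _to_rna(dna: str) -> str:
    return dna.replace("T", "U")


def extract_regions(junction: SpliceJunction, genome: GenomeSequence,
                    width: int = DEFAULT_FLANK_WIDTH) -> RegionSet:
    """Extract IR1-IR4 around one intron, transcript sense, T->U.

    Exonic flanks shorter than ``width`` (chromosome edge) and intronic
    flanks in introns shorter than ``2*width`` are truncated — intronic
    regions stop at the intron midpoint so IR2 and IR3 never overlap — and
    flagged ``truncated``.
    """
    chrom, strand = junction.chrom, junction.strand
    lo, hi = junction.interval
    clen = genome.length(chrom)
    half = (hi - lo) // 2
    iw = min(width, half) if (hi - lo) < 2 * width else width

    if strand == "+":
        spans = {
            "IR1": (max(0, lo - width), lo),
            "IR2": (lo, lo + iw),
            "IR3": (hi - iw, hi),
            "IR4": (hi, min(clen, hi + width)),
        }
    else:
        spans = {
            "IR1": (hi, min(clen, hi + width)),
            "IR2": (hi - iw, hi),
            "IR3": (lo, lo + iw),
            "IR4": (max(0, lo - width), lo),
        }
    regions = {}
    for label, (s, e) in spans.items():
        seq = genome.fetch(chrom, s, e)
        if strand == "-":
            seq = reverse_complement(seq)
        regions[label] = Region(
            label, chrom, s, e, strand, _to_rna(seq), truncated=(e - s) < width
        )
    return RegionSet(junction, regions)


# ---------------------------------------------------------------------------
# Scoring and scanning
# ---------------------------------------------------------------------------

def logodds_matrix(pwm: PWM, background: float = 0.25,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Per-position log2-odds scores, shape (width, 4)."""
    p = pwm.probs + pseudocount * background
    q = background + pseudocount * background
    with np.errstate(divide="ignore"):  # zero-probability cells at pseudocount 0
        return np.log2(p / q)


@dataclass(frozen=True)
class MotifHit:
    rbp_id: str
    region_label: str
    offset: int
    score: float


_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
_BASE_INDEX["T"] = _BASE_INDEX["U"]


def scan(seq: str, pwm: PWM, threshold: float = DEFAULT_THRESHOLD,
         region_label: str = "", pseudocount: float = DEFAULT_PSEUDOCOUNT,
         background: float = 0.25) -> list[MotifHit]:
    """All windows of ``seq`` scoring >= threshold under the PWM log-odds.

    Windows containing N are scored -inf and never reported.  A sequence
    shorter than the motif yields no hits.
    """
    w = pwm.width
    n = len(seq)
    if n < w:
        return []
    lom = logodds_matrix(pwm, background, pseudocount)
    idx = np.fromiter((_BASE_INDEX.get(c, -1) for c in seq), dtype=np.int64, count=n)
    valid = idx >= 0
    safe = np.where(valid, idx, 0)
    # scores[i] = per-position score of base at i for motif position j, via windows
    windows = np.lib.stride_tricks.sliding_window_view(safe, w)
    win_valid = np.lib.stride_tricks.sliding_window_view(valid, w).all(axis=1)
    scores = lom[np.arange(w), windows].sum(axis=1)
    scores = np.where(win_valid, scores, -math.inf)
    hits = [
        MotifHit(pwm.rbp_id, region_label, int(o), float(s))
        for o, s in zip(np.nonzero(scores >= threshold)[0], scores[scores >= threshold])
    ]
    return hits


def scan_regions(region_sets: list[RegionSet], pwms: list[PWM],
                 threshold: float = DEFAULT_THRESHOLD) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for rs in region_sets:
        for region in rs:
            for pwm in pwms:
                hits.extend(scan(region.sequence, pwm, threshold, region.label))
    return hits


def count_matrix(region_sets: list[RegionSet], pwms: list[PWM],
                 threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """RBP x region hit-count table, pooled over events, singletons removed.

    An RBP whose hits fall in only one region (over all events and region
    labels jointly — a single hit, or several hits all in one region of one
    event) is dropped, mirroring the elimination of singleton sites from
    heatmap summaries.
    """
    per_region: dict[str, dict[tuple[int, str], int]] = {p.rbp_id: {} for p in pwms}
    for ev_index, rs in enumerate(region_sets):
        for region in rs:
            for pwm in pwms:
                n = len(scan(region.sequence, pwm, threshold, region.label))
                if n:
                    key = (ev_index, region.label)
                    per_region[pwm.rbp_id][key] = per_region[pwm.rbp_id].get(key, 0) + n
    rows = {}
    for rbp_id, occ in per_region.items():
        if len(occ) <= 1:   # hits confined to a single region: singleton
            continue
        counts = {label: 0 for label in REGION_LABELS}
        for (_, label), n in occ.items():
            counts[label] += n
        rows[rbp_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(REGION_LABELS))
    df = df.astype(int)
    df.index.name = "rbp_id"
    return df.sort_index()
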