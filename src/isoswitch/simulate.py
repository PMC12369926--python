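"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the structure of a knockdown-vs-control short-read
experiment quantified against a long-read transcript catalogue: a
multi-isoform annotation in which each gene's isoform pair differs by
exactly one planted alternative-splicing event, negative-binomial replicate
counts (3 vs 3 by default) in which a fraction of genes carries an
opposite-direction isoform-usage shift, RNA-binding-protein motif
occurrences planted into splice-junction flanks, and mock phosphosite and
spectral-count tables.  Every planted feature is recorded in a
:class:`GroundTruth` object so downstream detections can be scored.

Randomness: each generator stage draws from its own stream seeded from
(config seed, CRC32 of the stage name), so stages can be re-run
independently and are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Exon, GeneModel, GenomeSequence, TranscriptModel
from .motifs import PWM, Region, RNA_ALPHABET

EVENT_CLASSES_PLANTABLE = ("ES", "IR", "A5", "A3", "ME")

DEFAULT_EVENT_MIX = {"ES": 0.3, "IR": 0.3, "A5": 0.15, "A3": 0.15, "ME": 0.1}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 1
    n_genes: int = 500
    n_exons: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (90, 300)
    intron_length: tuple[int, int] = (250, 500)  # >= 250 so 100-base flanks fit
    event_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    n_replicates: int = 3
    mean_expression: tuple[float, float] = (5.0, 200.0)
    nb_dispersion: float = 0.1
    depth: float = 1e6           # expected total counts per sample
    switch_fraction: float = 0.1
    switch_dif: float = 0.3      # planted |dIF| for switched genes
    cds_offset: int = 30         # translation start within the reference mRNA
    # motif planting
    motif_width: int = 7
    n_motifs: int = 10
    planted_motif_ids: tuple[str, ...] = ("RBP01", "RBP02")
    plant_rate: float = 0.5      # per (region, planted motif) probability

    def __post_init__(self):
        total = sum(self.event_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"event_mix must sum to 1, got {total}")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if not 0 < self.switch_dif <= 0.5:
            raise ConfigurationError("switch_dif must lie in (0, 0.5]")
        if self.intron_length[0] < 2:
            raise ConfigurationError("introns must be at least 2 bases")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    iso_a: str               # reference isoform
    iso_b: str               # variant isoform
    event_class: str
    variable_start: int
    variable_end: int
    cds_start: int
    switched: bool = False
    true_dif: float = 0.0    # planted dIF of iso_a (iso_b moves oppositely)
    control_if_a: float = 0.5


@dataclass
class MotifPlant:
    rbp_id: str
    chrom: str
    genomic_start: int       # forward-strand coordinates of the planted word
    genomic_end: int
    region_label: str
    region_offset: int       # offset within the sense-strand region sequence
    strand: str = "+"        # region sense; the word reads 5'->3' on this strand
    gene_id: str = ""


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    phospho: dict = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)

    def switched_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.switched}

    def to_json(self, path) -> None:
        payload = {
            "genes": {g: dataclasses.asdict(t) for g, t in self.genes.items()},
            "motif_plants": [dataclasses.asdict(m) for m in self.motif_plants],
            "phospho": self.phospho,
            "spectral": self.spectral,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes={g: GeneTruth(**t) for g, t in payload["genes"].items()},
            motif_plants=[MotifPlant(**m) for m in payload["motif_plants"]],
            phospho=payload["phospho"],
            spectral=payload["spectral"],
        )


# ---------------------------------------------------------------------------
# Annotation and genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _apply_event(exons: list[tuple[int, int]], cls: str, strand: str,
                 rng: np.random.Generator,
                 config: SimulationConfig) -> tuple[list[tuple[int, int]],
                                                    list[tuple[int, int]]]:
    """Derive the (iso_a, iso_b) exon chains carrying one planted event.

    Exon chains are lists of genomic (start, end).  iso_a is the reference
    structure; for ME both isoforms are derived from the base chain.
    """
    k = len(exons)
    if cls == "ES":
        j = int(rng.integers(1, k - 1))
        return list(exons), exons[:j] + exons[j + 1:]
    if cls == "IR":
        # retain an internal intron: a shared splice site must remain on both
        # sides, or the difference is trimmed as alternative start/termination
        j = int(rng.integers(1, k - 2))
        merged = exons[:j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2:]
        return list(exons), merged
    if cls == "ME":
        if k < 4:
            raise ConfigurationError("ME needs at least 4 exons")
        j = int(rng.integers(1, k - 2))
        iso_a = exons[:j + 1] + exons[j + 2:]      # keeps exon j, drops j+1
        iso_b = exons[:j] + exons[j + 1:]          # drops exon j, keeps j+1
        return iso_a, iso_b
    if cls in ("A5", "A3"):
        # pick the intron so the moved boundary keeps a shared splice site on
        # both sides (exon-end moves need an upstream exon start; exon-start
        # moves need a downstream exon end)
        move_end_pre = (cls == "A5") == (strand == "+")
        j = int(rng.integers(1, k - 1) if move_end_pre else rng.integers(0, k - 2))
        intron_len = exons[j + 1][0] - exons[j][1]
        exon_left = exons[j][1] - exons[j][0]
        exon_right = exons[j + 1][1] - exons[j + 1][0]
        # move an exon-end boundary for (A5,+)/(A3,-), exon-start otherwise
        move_end = move_end_pre
        max_into_intron = intron_len - 150
        max_into_exon = (exon_left if move_end else exon_right) - 30
        lo, hi = 10, max(11, min(60, max_into_intron, max_into_exon))
        delta = int(rng.integers(lo, hi + 1))
        if bool(rng.integers(0, 2)) and delta <= max_into_exon:
            delta = -delta
        variant = list(exons)
        if move_end:
            s, e = variant[j]
            variant[j] = (s, e + delta)
        else:
            s, e = variant[j + 1]
            variant[j + 1] = (s + delta, e)
        return list(exons), variant
    raise ConfigurationError(f"unknown event class {cls!r}")


def simulate_annotation(config: SimulationConfig
                        ) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """Genome, two-isoform gene models and per-gene event ground truth.

    Each gene sits on its own chromosome of i.i.d. uniform A/C/G/T sequence
    (motifs are planted later by :func:`plant_motifs`); its two isoforms
    differ by exactly the planted event class.
    """
    rng = stage_rng(config.seed, "annotation")
    rng_switch = stage_rng(config.seed, "switch_plan")
    classes = list(config.event_mix)
    probs = np.array([config.event_mix[c] for c in classes])
    margin = 150

    chroms: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth = GroundTruth()
    n_switched_target = int(round(config.switch_fraction * config.n_genes))
    switched_idx = set(
        rng_switch.choice(config.n_genes, size=n_switched_target, replace=False).tolist()
    ) if n_switched_target else set()

    for i in range(config.n_genes):
        gene_id = f"g{i:04d}"
        chrom = f"chr_{gene_id}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        cls = str(rng.choice(classes, p=probs))
        k_lo, k_hi = config.n_exons
        if k_lo < 4:
            raise ConfigurationError("internal event planting needs >= 4 exons")
        k = int(rng.integers(k_lo, k_hi + 1))
        pos = margin
        exons: list[tuple[int, int]] = []
        for _ in range(k):
            elen = int(rng.integers(*config.exon_length))
            exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(*config.intron_length))
        chain_a, chain_b = _apply_event(exons, cls, strand, rng, config)
        chrom_len = exons[-1][1] + margin
        chroms[chrom] = _random_sequence(rng, chrom_len)

        iso_a, iso_b = f"{gene_id}.a", f"{gene_id}.b"
        tx_a = TranscriptModel(iso_a, gene_id, strand,
                               [Exon(chrom, s, e, strand) for s, e in chain_a])
        tx_b = TranscriptModel(iso_b, gene_id, strand,
                               [Exon(chrom, s, e, strand) for s, e in chain_b])
        genes.append(GeneModel(gene_id, [tx_a, tx_b]))

        diff = sorted(set(tx_a.splice_sites()) ^ set(tx_b.splice_sites()))
        truth.genes[gene_id] = GeneTruth(
            gene_id=gene_id, chrom=chrom, strand=strand,
            iso_a=iso_a, iso_b=iso_b, event_class=cls,
            variable_start=diff[0][0], variable_end=diff[-1][0],
            cds_start=config.cds_offset,
            switched=i in switched_idx,
            true_dif=(float(rng_switch.choice([-1.0, 1.0])) * config.switch_dif
                      if i in switched_idx else 0.0),
            control_if_a=0.5,
        )
    return GenomeSequence(chroms), genes, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(genes: list[GeneModel], truth: GroundTruth,
                    config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.Series, "GroupDesign"]:
    """Negative-binomial transcript counts for the two conditions.

    Expected counts are proportional to gene abundance x isoform fraction x
    transcript length, normalised so each sample's expected total is
    ``config.depth``.  Switched genes shift the reference isoform's
    fraction by +-switch_dif between conditions (the pair moves in
    opposite directions since fractions sum to one).
    """
    from .expression import CONTROL, KNOCKDOWN, GroupDesign

    rng = stage_rng(config.seed, "counts")
    tx_ids, lengths = [], []
    weights = {"control": [], "knockdown": []}
    for gene in genes:
        t = truth.genes[gene.gene_id]
        abundance = float(rng.uniform(*config.mean_expression))
        if_a_ctrl = t.control_if_a - t.true_dif / 2.0
        if_a_kd = t.control_if_a + t.true_dif / 2.0
        for tx in gene.transcripts:
            frac_ctrl = if_a_ctrl if tx.transcript_id == t.iso_a else 1.0 - if_a_ctrl
            frac_kd = if_a_kd if tx.transcript_id == t.iso_a else 1.0 - if_a_kd
            tx_ids.append(tx.transcript_id)
            lengths.append(tx.length)
            weights["control"].append(abundance * frac_ctrl * tx.length)
            weights["knockdown"].append(abundance * frac_kd * tx.length)

    lengths = pd.Series(lengths, index=tx_ids, name="length")
    samples, columns = [], []
    for cond, label in ((CONTROL, "control"), (KNOCKDOWN, "kd")):
        w = np.asarray(weights[cond])
        mu = config.depth * w / w.sum()
        for r in range(1, config.n_replicates + 1):
            columns.append(f"{label}_{r}")
            samples.append(_nb_draw(rng, mu, config.nb_dispersion))
    counts = pd.DataFrame(np.column_stack(samples), index=tx_ids, columns=columns)
    counts.index.name = "transcript_id"
    design = GroupDesign({
        c: (CONTROL if c.startswith("control") else KNOCKDOWN) for c in columns
    })
    return counts, lengths, design


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def random_pwms(n: int, width: int, seed: int,
                major_prob: float = 0.85) -> list[PWM]:
    """Informative random PWMs: one dominant base per position."""
    rng = stage_rng(seed, "pwms")
    pwms = []
    for i in range(n):
        consensus = rng.integers(0, 4, size=width)
        probs = np.full((width, 4), (1.0 - major_prob) / 3.0)
        probs[np.arange(width), consensus] = major_prob
        pwms.append(PWM(f"RBP{i + 1:02d}", probs))
    return pwms


def plant_motifs(genome: GenomeSequence, regions: list[Region],
                 pwms: list[PWM], rates: dict[str, float], seed: int,
                 max_retries: int = 20) -> tuple[GenomeSequence, list[MotifPlant]]:
    """Write PWM consensus words into flank regions of the genome.

    For each region and each motif id in ``rates``, with the given
    probability one consensus occurrence is written at a random offset,
    avoiding overlap with earlier plantings in the same region (bounded
    retries, then error).  Returns the mutated genome and the occurrence
    list; with all rates zero the genome is returned unchanged.
    """
    rng = stage_rng(seed, "plant_motifs")
    by_id = {p.rbp_id: p for p in pwms}
    buffers = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    plants: list[MotifPlant] = []
    # collision tracking is genomic and chromosome-wide: flank regions of
    # neighbouring junctions may overlap, and a planting must never
    # overwrite an earlier one
    used: dict[str, list[tuple[int, int]]] = {}
    for region in regions:
        for rbp_id, rate in rates.items():
            pwm = by_id[rbp_id]
            if pwm.width > region.length:
                raise ConfigurationError(
                    f"motif {rbp_id} wider than region {region.label}"
                )
            if rng.random() >= rate:
                continue
            taken = used.setdefault(region.chrom, [])
            for attempt in range(max_retries + 1):
                offset = int(rng.integers(0, region.length - pwm.width + 1))
                if region.strand == "+":
                    gstart = region.start + offset
                else:
                    gstart = region.end - offset - pwm.width
                if all(gstart + pwm.width <= s or gstart >= e
                       for s, e in taken):
                    break
            else:
                raise ConfigurationError(
                    f"could not place motif {rbp_id} in region {region.label} "
                    f"after {max_retries} retries"
                )
            taken.append((gstart, gstart + pwm.width))
            word_dna = pwm.consensus().replace("U", "T")
            planted = word_dna if region.strand == "+" else _revcomp(word_dna)
            buffers[region.chrom][gstart:gstart + pwm.width] = planted.encode("ascii")
            plants.append(MotifPlant(
                rbp_id=rbp_id, chrom=region.chrom,
                genomic_start=gstart, genomic_end=gstart + pwm.width,
                region_label=region.label, region_offset=offset,
                strand=region.strand,
            ))
    mutated = GenomeSequence({n: b.decode("ascii") for n, b in buffers.items()})
    return mutated, plants


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# Coding cohort for consequence classification
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def _stop_free_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence containing no stop-codon triplet in any frame."""
    bases = "ACGT"
    out: list[str] = []
    while len(out) < length:
        c = bases[rng.integers(0, 4)]
        if len(out) >= 2 and ("".join(out[-2:]) + c) in _STOPS:
            continue
        out.append(c)
    return "".join(out)


@dataclass
class CodingTruth:
    gene_id: str
    event_class: str
    nt_delta: int          # alt minus ref exonic length over the event
    stop_planted: bool     # an in-frame stop was written into retained sequence
    cds_start: int


def simulate_cds_cohort(seed: int, n_genes: int = 60
                        ) -> tuple[GenomeSequence, list[GeneModel], list[CodingTruth]]:
    """Transcript pairs with engineered open reading frames.

    Unlike :func:`simulate_annotation`, gene bodies here are stop-free in
    every frame so the protein-level outcome of each planted event is
    controlled: an exon-skip or intron-retention whose length delta is a
    multiple of three stays in frame (unless a stop codon is deliberately
    planted into the retained intron), anything else shifts the frame.
    Each gene ends with a dedicated stop codon so reference translation
    terminates cleanly.
    """
    rng = stage_rng(seed, "cds_cohort")
    margin = 150
    chroms: dict[str, str] = {}
    genes: list[GeneModel] = []
    truths: list[CodingTruth] = []
    classes = ("ES", "IR", "A5", "A3")
    for i in range(n_genes):
        gene_id = f"c{i:04d}"
        chrom = f"chr_{gene_id}"
        cls = classes[i % len(classes)]
        in_frame = (i // len(classes)) % 2 == 0
        plant_stop = cls == "IR" and (i // (2 * len(classes))) % 2 == 1

        k = 4
        exon_lens = [120, 120, 120, 120]
        # tune the variable length so the event delta has the wanted phase
        if cls == "ES":
            exon_lens[1] = 159 if in_frame else 160
        intron_lens = [260, 261 if in_frame and cls == "IR" else 262, 260]
        if cls == "IR" and in_frame:
            intron_lens[1] = 261  # 261 % 3 == 0
        elif cls == "IR":
            intron_lens[1] = 262

        pos = margin
        exons: list[tuple[int, int]] = []
        for j in range(k):
            exons.append((pos, pos + exon_lens[j]))
            pos += exon_lens[j]
            if j < k - 1:
                pos += intron_lens[j]
        chrom_len = exons[-1][1] + margin

        seq = list(_stop_free_sequence(rng, chrom_len))
        # dedicated terminator near the end of the last exon, in the frame of
        # the reference CDS (cds_start 30 within exon 0)
        cds_start_genomic = exons[0][0] + 30
        ref_exonic = sum(e - max(s, cds_start_genomic)
                         for s, e in exons if e > cds_start_genomic)
        stop_offset_in_cds = ((ref_exonic - 30) // 3) * 3  # last full codon
        # walk to the genomic position of that codon within the last exon
        remaining = stop_offset_in_cds
        stop_genomic = None
        for s, e in exons:
            s = max(s, cds_start_genomic)
            if e <= s:
                continue
            if remaining < e - s:
                stop_genomic = s + remaining
                break
            remaining -= e - s
        seq[stop_genomic:stop_genomic + 3] = "TAA"

        delta = 0
        if cls == "ES":
            chain_a = list(exons)
            chain_b = exons[:1] + exons[2:]
            delta = -exon_lens[1]
        elif cls == "IR":
            chain_a = list(exons)
            chain_b = [exons[0], (exons[1][0], exons[2][1]), exons[3]]
            delta = intron_lens[1]
            if plant_stop:
                mid = exons[1][1] + intron_lens[1] // 2
                # phase-align the planted stop with the retained reading frame
                exonic_before = (exons[0][1] - cds_start_genomic) + exon_lens[1]
                into_intron = mid - exons[1][1]
                phase = (exonic_before + into_intron) % 3
                mid -= phase
                seq[mid:mid + 3] = "TAA"
        else:
            d = 33 if in_frame else 34
            if cls == "A5":
                chain_a = list(exons)
                chain_b = [exons[0], (exons[1][0], exons[1][1] + d),
                           exons[2], exons[3]]
                delta = d
            else:
                chain_a = list(exons)
                chain_b = [exons[0], exons[1],
                           (exons[2][0] - d, exons[2][1]), exons[3]]
                delta = d
        chroms[chrom] = "".join(seq)
        tx_a = TranscriptModel(f"{gene_id}.ref", gene_id, "+",
                               [Exon(chrom, s, e, "+") for s, e in chain_a])
        tx_b = TranscriptModel(f"{gene_id}.alt", gene_id, "+",
                               [Exon(chrom, s, e, "+") for s, e in chain_b])
        genes.append(GeneModel(gene_id, [tx_a, tx_b]))
        truths.append(CodingTruth(gene_id, cls, delta, plant_stop, 30))
    return GenomeSequence(chroms), genes, truths


# ---------------------------------------------------------------------------
# Phosphosite and spectral-count tables
# ---------------------------------------------------------------------------

SUBCLASSES = ("hnRNP", "SR protein", "core snRNP", "helicase", "other RBP")


def simulate_phospho_tables(seed: int, n_sites: int = 1000,
                            n_catalogue: int = 60, n_proteins: int = 120,
                            src_overlap: int = 25
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Mock phosphosite, kinase-substrate and splicing-catalogue tables.

    Returns (phospho, kinase, catalogue, truth).  ``truth`` records, from a
    direct row-by-row scan at construction time, how many rows pass the
    evidence filter overall and per residue, and the constructed number of
    Src-substrate tyrosine sites on catalogue proteins.
    """
    rng = stage_rng(seed, "phospho")
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    catalogue = pd.DataFrame({
        "protein": proteins[:n_catalogue],
        "subclass": rng.choice(SUBCLASSES, size=n_catalogue),
        "direct": rng.random(n_catalogue) < 0.8,
    })
    phospho = pd.DataFrame({
        "protein": rng.choice(proteins, size=n_sites),
        "residue": rng.choice(["S", "T", "Y"], size=n_sites, p=[0.60, 0.25, 0.15]),
        "position": rng.integers(1, 2000, size=n_sites),
        "LT_LIT": np.where(rng.random(n_sites) < 0.3, rng.poisson(2, n_sites), 0),
        "MS_LIT": rng.poisson(1.5, n_sites),
        "MS_CST": rng.poisson(1.5, n_sites),
    })
    phospho = phospho.drop_duplicates(["protein", "residue", "position"])
    phospho = phospho.reset_index(drop=True)

    # row-by-row evidence scan for the ground truth
    pass_total = 0
    pass_by_residue = {"S": 0, "T": 0, "Y": 0}
    for _, row in phospho.iterrows():
        if row["LT_LIT"] >= 1 or (row["MS_LIT"] + row["MS_CST"]) >= 3:
            pass_total += 1
            pass_by_residue[row["residue"]] += 1

    cat_set = set(catalogue["protein"])
    y_on_cat = phospho[(phospho["residue"] == "Y")
                       & phospho["protein"].isin(cat_set)]
    y_on_cat_pass = y_on_cat[(y_on_cat["LT_LIT"] >= 1)
                             | ((y_on_cat["MS_LIT"] + y_on_cat["MS_CST"]) >= 3)]
    n_src = min(src_overlap, len(y_on_cat_pass))
    picked = y_on_cat_pass.sample(n=n_src, random_state=int(rng.integers(2**31)))
    kinase = pd.DataFrame({
        "kinase": "SRC",
        "substrate": picked["protein"].to_numpy(),
        "residue": "Y",
        "position": picked["position"].to_numpy(),
    })
    truth = {
        "pass_total": pass_total,
        "pass_by_residue": pass_by_residue,
        "n_src_sites": n_src,
        "src_keys": sorted(picked["protein"] + ":" + picked["position"].astype(str)),
    }
    return phospho, kinase, catalogue, truth


def simulate_spectral_counts(seed: int, n_proteins: int = 300,
                             n_enriched_c: int = 40, n_enriched_n1: int = 15,
                             fold: float = 8.0, lambda_bg: float = 5.0,
                             n_replicates: int = 3
                             ) -> tuple[pd.DataFrame, dict]:
    """Mock pulldown spectral counts over GST, C_SH3 and N1_SH3 baits.

    Background proteins are Poisson(lambda_bg) in every bait; the first
    ``n_enriched_c`` proteins are Poisson(lambda_bg * fold) in C_SH3 and,
    for the first ``n_enriched_n1`` of those, in N1_SH3 as well — the
    neuronal-bait interactor set is a subset of the other by construction.
    """
    if n_enriched_n1 > n_enriched_c:
        raise ConfigurationError("the N1 enriched set must be a subset of C")
    rng = stage_rng(seed, "spectral")
    proteins = [f"Q{i:04d}" for i in range(n_proteins)]
    enriched_c = set(proteins[:n_enriched_c])
    enriched_n1 = set(proteins[:n_enriched_n1])
    rows = []
    for bait in ("GST", "C_SH3", "N1_SH3"):
        for rep in range(1, n_replicates + 1):
            for protein in proteins:
                lam = lambda_bg
                if bait == "C_SH3" and protein in enriched_c:
                    lam = lambda_bg * fold
                elif bait == "N1_SH3" and protein in enriched_n1:
                    lam = lambda_bg * fold
                rows.append((protein, bait, rep, int(rng.poisson(lam))))
    df = pd.DataFrame(rows, columns=["protein", "bait", "replicate", "count"])
    truth = {"enriched_c": sorted(enriched_c), "enriched_n1": sorted(enriched_n1)}
    return df, truth
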