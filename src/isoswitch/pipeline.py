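"""End-to-end orchestration: simulate -> quantify -> de -> switch ->
events -> motifs -> consequence -> phospho -> pulldown.

Every stage is a pure function of its declared input files plus the
configuration: it reads TSVs written by earlier stages (or user-supplied
paths) and writes its own outputs under the run directory, logging each
filter it applies with before/after counts so the funnel from features to
filtered features to significant features to switch calls to events stays
auditable.  ``run_all`` chains the stages and writes a deterministic JSON
summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import consequence as cq
from . import events as ev
from . import expression as ex
from . import motifs as mo
from . import phospho as ph
from . import pulldown as pu
from . import simulate as sim
from . import switches as sw
from .genome import SpliceJunction, read_fasta, read_gtf, write_fasta, write_gtf

log = logging.getLogger("isoswitch")

SUMMARY_SCHEMA_VERSION = 1
STAGES = ("simulate", "quantify", "de", "switch", "events", "motifs",
          "consequence", "phospho", "pulldown")


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "isoswitch_out"
    seed: int = 1
    # input paths; empty string means "use the simulate stage output"
    genome: str = ""
    gtf: str = ""
    counts: str = ""
    design: str = ""
    pwms: str = ""
    phospho: str = ""
    kinase: str = ""
    catalogue: str = ""
    spectral: str = ""
    cds_starts: str = ""   # optional TSV gene_id<TAB>cds_start
    # thresholds
    de_q: float = 0.05
    switch_q: float = 0.1
    dif_min: float = 0.05
    tpm_filter: float = 1.0
    pwm_threshold: float = 6.0
    flank_width: int = 100
    # simulation scale
    n_genes: int = 60
    switch_fraction: float = 0.2
    switch_dif: float = 0.3
    nb_dispersion: float = 0.1
    depth: float = 1e6

    def __post_init__(self):
        if not 0 < self.de_q < 1 or not 0 < self.switch_q < 1:
            raise ValueError("q thresholds must lie in (0, 1)")
        if self.flank_width < 1 or self.pwm_threshold < 0:
            raise ValueError("invalid flank width or PWM threshold")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def path(self, name: str, default: str) -> Path:
        explicit = getattr(self, name)
        return Path(explicit) if explicit else Path(self.outdir) / default


def _sim_config(config: PipelineConfig) -> sim.SimulationConfig:
    return sim.SimulationConfig(
        seed=config.seed,
        n_genes=config.n_genes,
        switch_fraction=config.switch_fraction,
        switch_dif=config.switch_dif,
        nb_dispersion=config.nb_dispersion,
        depth=config.depth,
    )


def _load_models(config: PipelineConfig):
    genes = read_gtf(config.path("gtf", "annotation.gtf"))
    tx2gene = {tx.transcript_id: g.gene_id for g in genes for tx in g.transcripts}
    tx_by_id = {tx.transcript_id: tx for g in genes for tx in g.transcripts}
    return genes, tx2gene, tx_by_id


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    scfg = _sim_config(config)
    genome, genes, truth = sim.simulate_annotation(scfg)
    pwms = sim.random_pwms(scfg.n_motifs, scfg.motif_width, scfg.seed)

    # plant motifs into the flanks of every planted event's affected introns
    regions = []
    for gene in genes:
        for event in ev.classify_pair(*gene.transcripts):
            for junction in ev.affected_junction_regions(event):
                regions.extend(
                    mo.extract_regions(junction, genome, config.flank_width)
                )
    rates = {rbp: scfg.plant_rate for rbp in scfg.planted_motif_ids}
    genome, plants = sim.plant_motifs(genome, regions, pwms, rates, scfg.seed)
    truth.motif_plants = plants

    counts, lengths, design = sim.simulate_counts(genes, truth, scfg)
    phospho, kinase, catalogue, ph_truth = sim.simulate_phospho_tables(scfg.seed)
    spectral, sp_truth = sim.simulate_spectral_counts(scfg.seed)
    truth.phospho = ph_truth
    truth.spectral = sp_truth

    write_fasta(genome, outdir / "genome.fa")
    write_gtf(genes, outdir / "annotation.gtf")
    ex.write_counts_tsv(counts, lengths, outdir / "counts.tsv")
    design.to_tsv(outdir / "design.tsv")
    mo.write_pwms(pwms, outdir / "pwms.tsv")
    phospho.to_csv(outdir / "phospho.tsv", sep="\t", index=False)
    kinase.to_csv(outdir / "kinase.tsv", sep="\t", index=False)
    catalogue.to_csv(outdir / "catalogue.tsv", sep="\t", index=False)
    spectral.to_csv(outdir / "spectral.tsv", sep="\t", index=False)
    with open(outdir / "cds_starts.tsv", "w") as fh:
        for gid, t in truth.genes.items():
            fh.write(f"{gid}\t{t.cds_start}\n")
    truth.to_json(outdir / "truth.json")
    log.info("simulate: %d genes, %d motif plantings", len(genes), len(plants))


def stage_quantify(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    counts, lengths = ex.read_counts_tsv(config.path("counts", "counts.tsv"))
    tpm = ex.counts_to_tpm(counts, lengths)
    tpm.to_csv(outdir / "tpm.tsv", sep="\t")
    log.info("quantify: %d transcripts x %d samples", *tpm.shape)


def stage_de(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    tpm = pd.read_csv(outdir / "tpm.tsv", sep="\t", index_col=0)
    design = ex.GroupDesign.from_tsv(config.path("design", "design.tsv"))
    kept = ex.expression_filter(tpm, design, config.tpm_filter)
    log.info("expression filter (>= %.2f TPM in a group): %d -> %d transcripts",
             config.tpm_filter, len(tpm), len(kept))
    de = ex.de_test(tpm, design, q_threshold=config.de_q, min_tpm=config.tpm_filter)
    de.to_csv(outdir / "de_transcripts.tsv", sep="\t")
    log.info("DE at q <= %.3g: %d up, %d down", config.de_q,
             int((de["status"] == "up").sum()), int((de["status"] == "down").sum()))


def stage_switch(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    tpm = pd.read_csv(outdir / "tpm.tsv", sep="\t", index_col=0)
    design = ex.GroupDesign.from_tsv(config.path("design", "design.tsv"))
    _, tx2gene, _ = _load_models(config)
    if_table = sw.isoform_fractions(tpm, tx2gene, design)
    usage = sw.usage_test(if_table, design)
    usage.to_csv(outdir / "usage_test.tsv", sep="\t")
    calls = sw.detect_switches(usage, q_threshold=config.switch_q,
                               dif_threshold=config.dif_min)
    sw.switches_to_frame(calls).to_csv(outdir / "switches.tsv", sep="\t", index=False)
    log.info("switch detection (Q < %.3g, |dIF| > %.3g): %d calls in %d genes",
             config.switch_q, config.dif_min, len(calls),
             len({c.gene_id for c in calls}))


def _fmt_junctions(junctions) -> str:
    return ";".join(f"{j.donor}-{j.acceptor}" for j in junctions)


def _parse_junctions(text: str, chrom: str, strand: str) -> list[SpliceJunction]:
    out = []
    if not isinstance(text, str) or not text:
        return out
    for token in text.split(";"):
        donor, acceptor = (int(x) for x in token.split("-"))
        out.append(SpliceJunction(chrom, donor, acceptor, strand))
    return out


def stage_events(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    switches = pd.read_csv(outdir / "switches.tsv", sep="\t")
    _, _, tx_by_id = _load_models(config)
    rows = []
    for _, call in switches[switches["best_pair"]].iterrows():
        evts = ev.classify_pair(tx_by_id[call["isoform_up"]],
                                tx_by_id[call["isoform_down"]])
        for event in evts:
            rows.append({
                "gene_id": event.gene_id,
                "iso_a": event.iso_a,
                "iso_b": event.iso_b,
                "event_class": event.event_class,
                "chrom": event.chrom,
                "strand": event.strand,
                "variable_start": event.variable_start,
                "variable_end": event.variable_end,
                "junctions": _fmt_junctions(event.affected_junctions),
                "flank_junctions": _fmt_junctions(ev.affected_junction_regions(event)),
            })
    df = pd.DataFrame(rows, columns=[
        "gene_id", "iso_a", "iso_b", "event_class", "chrom", "strand",
        "variable_start", "variable_end", "junctions", "flank_junctions"])
    df.to_csv(outdir / "events.tsv", sep="\t", index=False)
    log.info("events: %d classified (%s)", len(df),
             ", ".join(f"{k}={v}" for k, v in
                       sorted(df["event_class"].value_counts().items())) or "none")


def stage_motifs(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    genome = read_fasta(config.path("genome", "genome.fa"))
    pwms = mo.read_pwms(config.path("pwms", "pwms.tsv"))
    events_df = pd.read_csv(outdir / "events.tsv", sep="\t")
    region_sets = []
    for _, row in events_df.iterrows():
        for junction in _parse_junctions(row.get("flank_junctions", ""),
                                         row["chrom"], row["strand"]):
            region_sets.append(
                mo.extract_regions(junction, genome, config.flank_width))
    hits = mo.scan_regions(region_sets, pwms, config.pwm_threshold)
    pd.DataFrame(
        [dataclasses.asdict(h) for h in hits],
        columns=["rbp_id", "region_label", "offset", "score"],
    ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    counts_df = mo.count_matrix(region_sets, pwms, config.pwm_threshold)
    counts_df.to_csv(outdir / "motif_counts.tsv", sep="\t")
    log.info("motif scan (threshold %.3g): %d hits, %d RBPs after singleton filter",
             config.pwm_threshold, len(hits), len(counts_df))


def stage_consequence(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    genome = read_fasta(config.path("genome", "genome.fa"))
    _, _, tx_by_id = _load_models(config)
    switches = pd.read_csv(outdir / "switches.tsv", sep="\t")
    cds_path = config.path("cds_starts", "cds_starts.tsv")
    cds_starts: dict[str, int] = {}
    if cds_path.exists():
        tbl = pd.read_csv(cds_path, sep="\t", header=None,
                          names=["gene_id", "cds_start"])
        cds_starts = dict(zip(tbl["gene_id"], tbl["cds_start"]))
    rows = []
    for _, call in switches[switches["best_pair"]].iterrows():
        gene_id = call["gene_id"]
        if gene_id not in cds_starts:
            continue
        result = cq.classify_consequence(
            tx_by_id[call["isoform_down"]], tx_by_id[call["isoform_up"]],
            genome, int(cds_starts[gene_id]))
        rows.append({
            "gene_id": gene_id,
            "iso_ref": result.iso_ref,
            "iso_alt": result.iso_alt,
            "consequence_class": result.consequence_class,
            "deleted_aa_count": result.deleted_aa_count,
            "truncation_position": result.truncation_position,
            "nonstop_flag": result.nonstop_alt,
        })
    pd.DataFrame(rows, columns=[
        "gene_id", "iso_ref", "iso_alt", "consequence_class",
        "deleted_aa_count", "truncation_position", "nonstop_flag",
    ]).to_csv(outdir / "consequences.tsv", sep="\t", index=False)
    log.info("consequence: %d calls", len(rows))


def stage_phospho(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    phospho = pd.read_csv(config.path("phospho", "phospho.tsv"), sep="\t")
    kinase = pd.read_csv(config.path("kinase", "kinase.tsv"), sep="\t")
    catalogue = pd.read_csv(config.path("catalogue", "catalogue.tsv"), sep="\t")
    filtered = ph.evidence_filter(phospho)
    log.info("phospho evidence filter: %d -> %d sites", len(phospho), len(filtered))
    sets, n_rejected = ph.split_by_residue(filtered)
    if n_rejected:
        log.warning("phospho: %d rows with unknown residue codes rejected", n_rejected)
    annotated = ph.crossref_splicing(sets["Y"], catalogue, kinase)
    annotated.to_csv(outdir / "phospho_annotated.tsv", sep="\t", index=False)
    ph.subclass_proportions(annotated, catalogue).to_csv(
        outdir / "phospho_proportions.tsv", sep="\t")
    log.info("phospho: %d catalogue Y sites, %d Src-substrate",
             len(annotated), int(annotated["src_substrate"].sum()))


def stage_pulldown(config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    spectral = pd.read_csv(config.path("spectral", "spectral.tsv"), sep="\t")
    calls_c = pu.enrichment_test(spectral, "C_SH3")
    calls_n1 = pu.enrichment_test(spectral, "N1_SH3")
    for bait, calls in (("C_SH3", calls_c), ("N1_SH3", calls_n1)):
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            outdir / f"pulldown_{bait}.tsv", sep="\t", index=False)
    report = pu.subset_report(calls_c, calls_n1)
    report.ratio_table.to_csv(outdir / "pulldown_ratios.tsv", sep="\t", index=False)
    log.info("pulldown: %d C-bait and %d N1-bait interactors (N1-only: %d)",
             len(report.set_a), len(report.set_b), len(report.only_b))


STAGE_FUNCTIONS = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "de": stage_de,
    "switch": stage_switch,
    "events": stage_events,
    "motifs": stage_motifs,
    "consequence": stage_consequence,
    "phospho": stage_phospho,
    "pulldown": stage_pulldown,
}


def run_stage(config: PipelineConfig, stage: str) -> None:
    if stage not in STAGE_FUNCTIONS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    try:
        STAGE_FUNCTIONS[stage](config)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the summary dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES)
    if config.genome and config.gtf and config.counts:
        stages.remove("simulate")
    for stage in stages:
        run_stage(config, stage)
    summary = _summarise(config)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _summarise(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    tpm = pd.read_csv(outdir / "tpm.tsv", sep="\t", index_col=0)
    de = pd.read_csv(outdir / "de_transcripts.tsv", sep="\t", index_col=0)
    _, tx2gene, _ = _load_models(config)
    switches = pd.read_csv(outdir / "switches.tsv", sep="\t")
    events_df = pd.read_csv(outdir / "events.tsv", sep="\t")
    cons = pd.read_csv(outdir / "consequences.tsv", sep="\t")
    annotated = pd.read_csv(outdir / "phospho_annotated.tsv", sep="\t")
    hits = pd.read_csv(outdir / "motif_hits.tsv", sep="\t")
    motif_counts = pd.read_csv(outdir / "motif_counts.tsv", sep="\t", index_col=0)
    ratios = pd.read_csv(outdir / "pulldown_ratios.tsv", sep="\t")
    calls_c = pd.read_csv(outdir / "pulldown_C_SH3.tsv", sep="\t")
    calls_n1 = pd.read_csv(outdir / "pulldown_N1_SH3.tsv", sep="\t")

    sig_c = set(calls_c[calls_c["significant"]]["protein"])
    sig_n1 = set(calls_n1[calls_n1["significant"]]["protein"])
    return {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "n_transcripts": int(len(tpm)),
        "n_filtered_out": int((de["status"] == "filtered").sum()),
        "n_up": int((de["status"] == "up").sum()),
        "n_down": int((de["status"] == "down").sum()),
        "both_direction_genes": sorted(ex.both_direction_genes(de, tx2gene)),
        "n_switch_calls": int(len(switches)),
        "switch_genes": sorted(set(switches["gene_id"])),
        "events_by_class": {
            str(k): int(v)
            for k, v in sorted(events_df["event_class"].value_counts().items())
        },
        "n_motif_hits": int(len(hits)),
        "retained_rbps": sorted(motif_counts.index),
        "consequence_classes": {
            str(k): int(v)
            for k, v in sorted(cons["consequence_class"].value_counts().items())
        },
        "n_y_sites_on_catalogue": int(len(annotated)),
        "n_src_sites": int(annotated["src_substrate"].sum()),
        "pulldown_c_interactors": len(sig_c),
        "pulldown_n1_interactors": len(sig_n1),
        "pulldown_n1_only": sorted(sig_n1 - sig_c),
        "n_pulldown_shared": int(len(ratios)),
        "thresholds": {
            "de_q": config.de_q, "switch_q": config.switch_q,
            "dif_min": config.dif_min, "tpm_filter": config.tpm_filter,
            "pwm_threshold": config.pwm_threshold, "flank_width": config.flank_width,
        },
    }
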