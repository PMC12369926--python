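"""Ground-truth fidelity and determinism of the synthetic-data generator."""

import numpy as np
import pytest

from isoswitch.events import classify_pair
from isoswitch.expression import counts_to_tpm
from isoswitch.genome import write_fasta, write_gtf
from isoswitch.motifs import extract_regions, scan
from isoswitch.simulate import (ConfigurationError, SimulationConfig,
                                plant_motifs, random_pwms,
                                simulate_annotation, simulate_counts,
                                simulate_spectral_counts)
from isoswitch.switches import isoform_fractions


class TestAnnotation:
    def test_pure_exon_skipping_mix(self):
        cfg = SimulationConfig(seed=3, n_genes=25, event_mix={"ES": 1.0})
        _, genes, truth = simulate_annotation(cfg)
        for gene in genes:
            (event,) = classify_pair(*gene.transcripts)
            assert event.event_class == "ES"

    def test_planted_class_recovered_by_classifier(self):
        cfg = SimulationConfig(seed=4, n_genes=120)
        _, genes, truth = simulate_annotation(cfg)
        for gene in genes:
            t = truth.genes[gene.gene_id]
            (event,) = classify_pair(*gene.transcripts)
            assert event.event_class == t.event_class
            assert (event.variable_start, event.variable_end) == \
                   (t.variable_start, t.variable_end)

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_genes=15)
        for run in ("x", "y"):
            genome, genes, _ = simulate_annotation(cfg)
            write_fasta(genome, tmp_path / f"{run}.fa")
            write_gtf(genes, tmp_path / f"{run}.gtf")
        assert (tmp_path / "x.fa").read_bytes() == (tmp_path / "y.fa").read_bytes()
        assert (tmp_path / "x.gtf").read_bytes() == (tmp_path / "y.gtf").read_bytes()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(event_mix={"ES": 0.7})
        with pytest.raises(ConfigurationError):
            SimulationConfig(switch_dif=0.9)


class TestCounts:
    def test_no_switches_means_no_usage_shift(self):
        # modest overdispersion so replicate noise does not dominate the
        # between-condition comparison the example checks
        cfg = SimulationConfig(seed=1, n_genes=500, switch_fraction=0.0,
                               nb_dispersion=0.01)
        _, genes, truth = simulate_annotation(cfg)
        counts, lengths, design = simulate_counts(genes, truth, cfg)
        tx2gene = {tx.transcript_id: g.gene_id for g in genes
                   for tx in g.transcripts}
        ift = isoform_fractions(counts_to_tpm(counts, lengths), tx2gene, design)
        assert float(ift["dIF"].abs().mean()) < 0.05

    def test_poisson_limit_at_vanishing_dispersion(self):
        cfg = SimulationConfig(seed=2, n_genes=200, nb_dispersion=1e-6,
                               switch_fraction=0.0)
        _, genes, truth = simulate_annotation(cfg)
        counts, _, _ = simulate_counts(genes, truth, cfg)
        mu = counts.mean(axis=1)
        ratio = counts.var(axis=1, ddof=1) / mu.replace(0, np.nan)
        # index of dispersion concentrates near 1 for Poisson counts
        assert abs(float(ratio.mean()) - 1.0) < 0.2

    def test_planted_dif_recovered_in_expectation(self):
        cfg = SimulationConfig(seed=5, n_genes=100, switch_fraction=1.0,
                               switch_dif=0.3)
        _, genes, truth = simulate_annotation(cfg)
        counts, lengths, design = simulate_counts(genes, truth, cfg)
        tx2gene = {tx.transcript_id: g.gene_id for g in genes
                   for tx in g.transcripts}
        ift = isoform_fractions(counts_to_tpm(counts, lengths), tx2gene, design)
        difs = []
        for gid, t in truth.genes.items():
            difs.append(float(ift.loc[t.iso_a, "dIF"]) * np.sign(t.true_dif))
        assert np.mean(difs) == pytest.approx(0.3, abs=0.05)


class TestMotifPlanting:
    def _regions(self, genome, genes, truth, n=30):
        regions = []
        for gene in genes[:n]:
            for event in classify_pair(*gene.transcripts):
                from isoswitch.events import affected_junction_regions

                for junction in affected_junction_regions(event):
                    regions.extend(extract_regions(junction, genome))
        return regions

    def test_zero_rate_leaves_genome_unchanged(self):
        cfg = SimulationConfig(seed=6, n_genes=10)
        genome, genes, truth = simulate_annotation(cfg)
        pwms = random_pwms(3, 7, 6)
        regions = self._regions(genome, genes, truth)
        mutated, plants = plant_motifs(genome, regions,
                                       pwms, {p.rbp_id: 0.0 for p in pwms}, 6)
        assert plants == []
        assert mutated == genome

    def test_planted_word_is_on_genome_at_recorded_offset(self):
        cfg = SimulationConfig(seed=7, n_genes=20)
        genome, genes, truth = simulate_annotation(cfg)
        pwms = random_pwms(3, 7, 7)
        regions = self._regions(genome, genes, truth)
        mutated, plants = plant_motifs(genome, regions,
                                       pwms, {"RBP01": 0.8}, 7)
        assert plants
        by_id = {p.rbp_id: p for p in pwms}
        for plant in plants:
            word = mutated.fetch(plant.chrom, plant.genomic_start,
                                 plant.genomic_end)
            consensus_dna = by_id[plant.rbp_id].consensus().replace("U", "T")
            from isoswitch.genome import reverse_complement

            assert word in (consensus_dna, reverse_complement(consensus_dna))

    def test_scanner_finds_every_planting(self):
        cfg = SimulationConfig(seed=8, n_genes=20)
        genome, genes, truth = simulate_annotation(cfg)
        pwms = random_pwms(3, 7, 8)
        regions = self._regions(genome, genes, truth)
        mutated, plants = plant_motifs(genome, regions, pwms, {"RBP02": 0.8}, 8)
        by_id = {p.rbp_id: p for p in pwms}
        # rebuild the regions on the mutated genome and rescan
        region_by_key = {}
        for gene in genes[:30]:
            for event in classify_pair(*gene.transcripts):
                from isoswitch.events import affected_junction_regions

                for junction in affected_junction_regions(event):
                    for region in extract_regions(junction, mutated):
                        key = (region.chrom, region.start, region.end,
                               region.label)
                        region_by_key[key] = region
        for plant in plants:
            pwm = by_id[plant.rbp_id]
            covering = [
                r for r in region_by_key.values()
                if r.chrom == plant.chrom and r.start <= plant.genomic_start
                and r.end >= plant.genomic_end and r.label == plant.region_label
            ]
            assert covering
            found = False
            for region in covering:
                hits = scan(region.sequence, pwm, threshold=6.0)
                for h in hits:
                    if region.strand == "+":
                        g0 = region.start + h.offset
                    else:
                        g0 = region.end - h.offset - pwm.width
                    if g0 == plant.genomic_start:
                        found = True
            assert found, plant


class TestSpectral:
    def test_zero_background_rate_gives_all_zero_background(self):
        records, truth = simulate_spectral_counts(
            seed=1, n_proteins=50, n_enriched_c=5, n_enriched_n1=2,
            lambda_bg=0.0, fold=10.0)
        background = set(records["protein"]) - set(truth["enriched_c"])
        bg_counts = records[records["protein"].isin(background)]["count"]
        assert (bg_counts == 0).all()

    def test_n1_truth_is_subset_of_c_truth(self):
        _, truth = simulate_spectral_counts(seed=2)
        assert set(truth["enriched_n1"]) <= set(truth["enriched_c"])

    def test_invalid_subset_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_spectral_counts(seed=1, n_enriched_c=5, n_enriched_n1=10)
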