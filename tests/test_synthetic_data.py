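"""Generator contracts: determinism, planted structure, null behaviour."""

import numpy as np
import pandas as pd
import pytest

from methocc.io_formats import GenomeSequence
from methocc.occupancy import bin_coverage, log2_ratio
from methocc.synthetic_data import (
    ConfigError,
    SimConfig,
    _membership,
    combined_density_per_kb,
    condition_labels,
    flat_truth,
    place_genes,
    simulate_chip_experiment,
    simulate_expression,
    simulate_genome,
    simulate_methylome,
    simulate_spike_report,
    simulate_step_domains,
)

SMALL = dict(
    n_chroms=1,
    chrom_length=500_000,
    cgi_count=6,
    domain_length_range=(30_000, 80_000),
)


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        g1, c1, t1 = simulate_genome(SimConfig(seed=5, **SMALL))
        g2, c2, t2 = simulate_genome(SimConfig(seed=5, **SMALL))
        assert g1.sequences == g2.sequences
        assert c1 == c2
        assert [d.name for d in t1.domains] == [d.name for d in t2.domains]

    def test_domains_tile_each_chromosome(self):
        cfg = SimConfig(seed=2, n_chroms=2, chrom_length=400_000,
                        domain_length_range=(30_000, 80_000), cgi_count=4)
        genome, _, truth = simulate_genome(cfg)
        for chrom in genome.chrom_names:
            doms = sorted(truth.domains_on(chrom), key=lambda d: d.start)
            assert doms[0].start == 0 and doms[-1].end == cfg.chrom_length
            for a, b in zip(doms[:-1], doms[1:]):
                assert a.end == b.start

    def test_no_cgis_still_tiles_domains(self):
        cfg = SimConfig(seed=3, cgi_count=0, **{k: v for k, v in SMALL.items() if k != "cgi_count"})
        genome, cgis, truth = simulate_genome(cfg)
        assert cgis == []
        assert sum(len(d) for d in truth.domains) == cfg.chrom_length

    def test_cg_enriched_inside_cgis(self):
        from methocc.meth_context import classify_contexts

        cfg = SimConfig(seed=4, **SMALL)
        genome, cgis, truth = simulate_genome(cfg)
        sites = classify_contexts(genome)
        pos = sites["pos"].to_numpy()
        di = sites["di"].to_numpy()
        inside = _membership(pos, cgis)
        ok = di != "NA"
        frac_in = (di[inside & ok] == "CG").mean()
        frac_out = (di[~inside & ok] == "CG").mean()
        assert frac_in > frac_out

    def test_domain_longer_than_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(chrom_length=10_000, domain_length_range=(20_000, 30_000))


class TestSimulateMethylome:
    def test_level_separation_at_depth(self):
        cfg = SimConfig(seed=6, **SMALL)
        genome, cgis, truth = simulate_genome(cfg)
        sites, _ = simulate_methylome(genome, truth, cfg)
        pos = sites["pos"].to_numpy()
        di = sites["di"].to_numpy()
        inside = _membership(pos, cgis)
        cg = di == "CG"
        assert sites["level"][cg & inside].mean() < 0.1
        assert sites["level"][cg & ~inside].mean() > 0.7

    def test_cac_most_methylated_trinucleotide(self):
        from methocc.meth_context import genome_context_frequencies

        cfg = SimConfig(seed=7, **SMALL)
        genome, _, truth = simulate_genome(cfg)
        sites, _ = simulate_methylome(genome, truth, cfg)
        mean_tri = genome_context_frequencies(sites)["mean_level_tri"]
        non_cg = mean_tri[~mean_tri.index.str.startswith("CG")]
        assert non_cg.idxmax() == "CAC"

    def test_equal_domain_levels_erase_domain_signal(self):
        """With mCAC high == low, per-domain densities are exchangeable.

        Domains are the sampling units: windows are spatially autocorrelated
        through the GC landscape, whereas domain labels are assigned
        independently of it.
        """
        from scipy.stats import mannwhitneyu

        from methocc.io_formats import GenomicInterval
        from methocc.meth_context import region_methylation

        pvals = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, mcac_level_high=0.07, mcac_level_low=0.07,
                            n_chroms=1, chrom_length=2_000_000, cgi_count=10,
                            domain_length_range=(30_000, 80_000))
            genome, _, truth = simulate_genome(cfg)
            sites, _ = simulate_methylome(genome, truth, cfg)
            dens = {
                "high": [], "low": [],
            }
            for d in truth.domains_on("chr1"):
                rm = region_methylation(sites, d, "CAC")
                dens[d.name].append(rm.density_per_kb)
            pvals.append(mannwhitneyu(dens["high"], dens["low"]).pvalue)
        assert (np.array(pvals) < 0.01).sum() <= 1

    def test_tab_channel_reports_low_hmc(self):
        cfg = SimConfig(seed=8, **SMALL)
        genome, _, truth = simulate_genome(cfg)
        sites, tab = simulate_methylome(genome, truth, cfg, with_tab=True)
        cg = tab["di"].to_numpy() == "CG"
        assert 0.0 < tab["level"][cg].mean() < 0.1

    def test_spike_report_reads_nonconversion(self):
        from methocc.meth_context import estimate_conversion_rate

        cfg = SimConfig(seed=9, **SMALL)
        spike = simulate_spike_report(cfg, n_sites=2000)
        cr = estimate_conversion_rate(spike)
        assert cr.ci_low <= cfg.nonconversion_rate <= cr.ci_high


class TestSimulateChip:
    def test_null_coupling_centres_log_ratio(self):
        cfg = SimConfig(seed=10, beta_occupancy=0.0, **SMALL)
        genome, _, truth = simulate_genome(cfg)
        chip, inp = simulate_chip_experiment(genome, None, truth, cfg)
        cw = bin_coverage(chip, genome.lengths, cfg.window, 67)
        iw = bin_coverage(inp, genome.lengths, cfg.window, 67)
        track = log2_ratio(cw, iw, 0.5)
        assert abs(track.log2_ratio.mean()) < 0.02

    def test_poisson_dispersion_without_bias(self):
        """gc_bias 0, beta 0: window counts are Poisson (dispersion ~ 1)."""
        cfg = SimConfig(seed=11, beta_occupancy=0.0, gc_bias_strength=0.0,
                        n_chroms=1, chrom_length=2_000_000, cgi_count=0,
                        domain_length_range=(30_000, 80_000))
        genome, _, truth = simulate_genome(cfg)
        _, inp = simulate_chip_experiment(genome, None, truth, cfg)
        iw = bin_coverage(inp, genome.lengths, cfg.window, 67)
        counts = iw.counts
        assert counts.size >= 1000
        index_of_dispersion = counts.var() / counts.mean()
        assert 0.8 <= index_of_dispersion <= 1.2

    def test_high_domains_more_enriched(self):
        """Per-domain mean log2 ratio is higher in high-mCAC domains.

        Tested on whole domains (independent units) at the default genome
        scale; windows within a domain share the GC landscape and are not
        exchangeable.
        """
        from scipy.stats import mannwhitneyu

        cfg = SimConfig(seed=12)
        genome, _, truth = simulate_genome(cfg)
        sites, _ = simulate_methylome(genome, truth, cfg)
        chip, inp = simulate_chip_experiment(genome, sites, truth, cfg)
        cw = bin_coverage(chip, genome.lengths, cfg.window, 67)
        iw = bin_coverage(inp, genome.lengths, cfg.window, 67)
        track = log2_ratio(cw, iw, 0.5)
        by_label = {"high": [], "low": []}
        for chrom, sub in cw.windows.groupby("chrom", sort=False):
            centers = sub["start"].to_numpy() + cfg.window // 2
            vals = track.log2_ratio[sub.index.to_numpy()]
            for d in truth.domains_on(str(chrom)):
                sel = (centers >= d.start) & (centers < d.end)
                if sel.any():
                    by_label[d.name].append(vals[sel].mean())
        res = mannwhitneyu(by_label["high"], by_label["low"], alternative="greater")
        assert res.pvalue < 0.01

    def test_expected_intensities_recorded_positive(self):
        cfg = SimConfig(seed=13, **SMALL)
        genome, _, truth = simulate_genome(cfg)
        simulate_chip_experiment(genome, None, truth, cfg)
        for chrom in genome.chrom_names:
            assert (truth.expected_input[chrom] > 0).all()
            assert (truth.expected_chip[chrom] > 0).all()


class TestStepDomains:
    def test_counts_match_planted_fold(self):
        cfg = SimConfig(seed=1)
        chip, inp, domains = simulate_step_domains(cfg, 50_000, 2.0, 5)
        inside = np.zeros(chip.counts.size, dtype=bool)
        for d in domains:
            inside[d.start // 100 : d.end // 100] = True
        ratio = chip.counts[inside].mean() / chip.counts[~inside].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestSimulateExpression:
    def _run(self, **over):
        cfg = SimConfig(seed=20, n_chroms=1, chrom_length=5_000_000, n_genes=1000,
                        **over)
        genome = GenomeSequence(["chr1"], {"chr1": "A" * cfg.chrom_length})
        truth = flat_truth(genome, cfg)
        genes = place_genes(genome, cfg)
        return simulate_expression(genes, truth, cfg) + (cfg,)

    def test_null_has_zero_median_fold_change(self):
        counts, truth, cfg = self._run(coupling_alpha=0.0, global_scale_ko=1.0)
        assert truth.genes["true_log2fc_ko"].median() == 0.0
        wt = counts[[c for c in counts if c.startswith("WT")]].mean(axis=1)
        ko = counts[[c for c in counts if c.startswith("KO")]].mean(axis=1)
        est = np.log2((ko + 0.5) / (wt + 0.5))
        assert abs(np.median(est)) < 0.02

    def test_global_scale_shows_up_in_raw_medians(self):
        counts, truth, cfg = self._run(coupling_alpha=0.0, global_scale_ko=0.85)
        wt = counts[[c for c in counts if c.startswith("WT")]].mean(axis=1)
        ko = counts[[c for c in counts if c.startswith("KO")]].mean(axis=1)
        est = np.log2((ko + 0.5) / (wt + 0.5))
        assert np.median(est) == pytest.approx(np.log2(0.85), abs=0.03)
        # truth records pre-scaling fold-changes
        assert truth.genes["true_log2fc_ko"].abs().max() == 0.0

    def test_deterministic_counts(self):
        c1, _, _ = self._run()
        c2, _, _ = self._run()
        pd.testing.assert_frame_equal(c1, c2)

    def test_condition_labels_parsed_from_columns(self):
        counts, _, cfg = self._run()
        labels = condition_labels(counts)
        assert set(labels) == {"WT", "KO", "OE"}
        assert (labels == "WT").sum() == cfg.n_replicates

    def test_too_many_genes_rejected(self):
        with pytest.raises(ConfigError):
            cfg = SimConfig(seed=0, n_chroms=1, chrom_length=100_000, n_genes=200)
            genome = GenomeSequence(["chr1"], {"chr1": "A" * cfg.chrom_length})
            place_genes(genome, cfg)


class TestCombinedDensity:
    def test_density_uses_truth_probabilities(self):
        from conftest import build_sites

        sites = build_sites([
            ("chr1", 100, "+", "CG", "CGA", 0, 10),
            ("chr1", 300, "+", "CA", "CAC", 0, 10),
            ("chr1", 1500, "+", "CA", "CAT", 10, 10),  # not CG/CAC: ignored
        ])
        sites["p_true"] = [0.8, 0.1, 0.9]
        dens = combined_density_per_kb(sites, "chr1", 2000, 1000)
        assert dens.tolist() == pytest.approx([0.9, 0.0])
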