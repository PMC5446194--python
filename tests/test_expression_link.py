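"""Normalisation, NB testing, classification and the occupancy links."""

import numpy as np
import pandas as pd
import pytest

from methocc.io_formats import GenomicInterval
from methocc.msr_domains import Segment
from methocc.occupancy import CoverageWindows, OccupancyTrack, make_partition
from methocc.expression_link import (
    apply_global_scale,
    classify_genes,
    domain_overlap,
    gene_occupancy,
    nb_test,
    occupancy_expression_stats,
    rolling_density,
    size_factors,
    tpm_matrix,
    window_group_curve,
)
from methocc.synthetic_data import _nb_draw


def nb_counts(seed, n=500, reps=3, mu_fn=None, l2fc=None, disp=0.02):
    rng = np.random.default_rng(seed)
    mu = mu_fn(rng) if mu_fn else rng.lognormal(4.6, 1.0, n)
    l2fc = np.zeros(n) if l2fc is None else l2fc
    cols = {}
    for cond, fc in (("WT", np.zeros(n)), ("KO", l2fc)):
        for r in range(reps):
            cols[f"{cond}_{r + 1}"] = _nb_draw(mu * np.exp2(fc), disp, rng)
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
    conds = pd.Series([c.split("_")[0] for c in counts.columns], index=counts.columns)
    return counts, conds, mu


class TestSizeFactors:
    def test_doubled_sample_median_of_ratios(self):
        c = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc"))
        f = size_factors(c)
        assert f["s1"] == pytest.approx(0.70711, abs=1e-5)
        assert f["s2"] == pytest.approx(1.41421, abs=1e-5)

    def test_identical_samples_unit_factors(self):
        c = pd.DataFrame({"s1": [10, 20], "s2": [10, 20], "s3": [10, 20]})
        assert np.allclose(size_factors(c), 1.0)

    def test_all_zero_gene_excluded(self):
        base = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc"))
        with_zero = pd.concat(
            [base, pd.DataFrame({"s1": [0], "s2": [0]}, index=["z"])]
        )
        pd.testing.assert_series_equal(size_factors(base), size_factors(with_zero))

    def test_no_all_positive_gene_rejected(self):
        c = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(c)


class TestApplyGlobalScale:
    def test_targets_only_named_condition(self):
        f = pd.Series({"WT_1": 1.0, "KO_1": 1.0})
        conds = pd.Series({"WT_1": "WT", "KO_1": "KO"})
        out = apply_global_scale(f, conds, "KO", 1.15)
        assert out["WT_1"] == 1.0 and out["KO_1"] == pytest.approx(1.15)

    def test_unit_multiplier_is_identity(self):
        f = pd.Series({"WT_1": 0.9, "KO_1": 1.2})
        conds = pd.Series({"WT_1": "WT", "KO_1": "KO"})
        pd.testing.assert_series_equal(apply_global_scale(f, conds, "KO", 1.0), f)

    def test_nonpositive_multiplier_rejected(self):
        f = pd.Series({"KO_1": 1.0})
        with pytest.raises(ValueError):
            apply_global_scale(f, pd.Series({"KO_1": "KO"}), "KO", 0.0)


class TestNbTest:
    def test_identical_groups_zero_fold_change(self):
        counts, conds, _ = nb_counts(seed=0)
        dup = counts.copy()
        for r in range(3):
            dup[f"KO_{r + 1}"] = dup[f"WT_{r + 1}"]
        res = nb_test(dup, pd.Series(1.0, index=dup.columns), conds)
        pos = dup.sum(axis=1) > 0
        assert (res.loc[pos, "log2fc"] == 0.0).all()
        assert (res.loc[pos, "p_value"] == 1.0).all()

    def test_bh_adjustment_monotone_in_p(self):
        counts, conds, _ = nb_counts(seed=1)
        res = nb_test(counts, pd.Series(1.0, index=counts.columns), conds)
        ok = res.dropna(subset=["p_value"]).sort_values("p_value")
        assert (np.diff(ok["padj"].to_numpy()) >= -1e-12).all()
        assert (ok["padj"] >= ok["p_value"] - 1e-12).all()

    def test_normalisation_invariance(self):
        """Scaling one sample's counts scales its factor, not the log2FCs."""
        counts, conds, _ = nb_counts(seed=2, mu_fn=lambda rng: rng.lognormal(7, 0.5, 500))
        scaled = counts.copy()
        scaled["KO_1"] = scaled["KO_1"] * 3
        f1 = size_factors(counts)
        f2 = size_factors(scaled)
        # the scaled sample's factor rises by c relative to every other
        # sample (the pseudo-reference itself absorbs c^(1/m))
        rel = (f2 / f1)["KO_1"] / (f2 / f1)["WT_1"]
        assert rel == pytest.approx(3.0, rel=1e-3)
        r1 = nb_test(counts, f1, conds)
        r2 = nb_test(scaled, f2, conds)
        assert np.allclose(r1["log2fc"], r2["log2fc"], atol=1e-6)

    def test_missing_condition_rejected(self):
        counts, conds, _ = nb_counts(seed=3)
        with pytest.raises(ValueError):
            nb_test(counts, pd.Series(1.0, index=counts.columns), conds, ("WT", "OE"))

    def test_planted_fold_changes_recovered(self):
        rng = np.random.default_rng(4)
        l2fc = np.where(rng.random(500) < 0.2, 1.0, 0.0)
        counts, conds, mu = nb_counts(seed=4, l2fc=l2fc,
                                      mu_fn=lambda r: r.lognormal(6, 0.5, 500))
        res = nb_test(counts, pd.Series(1.0, index=counts.columns), conds)
        est = res["log2fc"].to_numpy()
        assert np.mean(np.abs(est[l2fc == 1.0] - 1.0) < 0.5) > 0.9


class TestClassifyGenes:
    def _tpm(self, index, value):
        return pd.DataFrame({"s1": value, "s2": value}, index=index)

    def test_threshold_rules(self):
        res = pd.DataFrame(
            {
                "log2fc": [1.2, -0.8, 0.005, 0.3, 2.0],
                "padj": [0.01, 0.01, 0.6, 0.2, 0.01],
            },
            index=list("abcde"),
        )
        tpm = self._tpm(res.index, [50, 50, 50, 50, 3])
        cls = classify_genes(res, tpm)
        assert cls.tolist() == ["up", "down", "unchanged", "other", "filtered"]

    def test_every_gene_gets_exactly_one_class(self):
        rng = np.random.default_rng(5)
        res = pd.DataFrame(
            {"log2fc": rng.normal(0, 1, 300), "padj": rng.random(300)},
            index=[f"g{i}" for i in range(300)],
        )
        tpm = self._tpm(res.index, rng.lognormal(1.5, 1.5, 300))
        cls = classify_genes(res, tpm)
        assert cls.notna().all()
        assert set(cls.cat.categories) == {"up", "down", "unchanged", "other", "filtered"}

    def test_low_tpm_filtered_regardless_of_significance(self):
        res = pd.DataFrame({"log2fc": [3.0], "padj": [1e-10]}, index=["a"])
        cls = classify_genes(res, self._tpm(res.index, [3.0]))
        assert cls.iloc[0] == "filtered"


class TestTpm:
    def test_columns_sum_to_million(self):
        counts = pd.DataFrame({"s1": [10, 0, 30], "s2": [5, 5, 5]}, index=list("abc"))
        lengths = pd.Series([1000, 2000, 500], index=list("abc"))
        tpm = tpm_matrix(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_length_normalisation(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=list("ab"))
        lengths = pd.Series([1000, 2000], index=list("ab"))
        tpm = tpm_matrix(counts, lengths)
        assert tpm.loc["a", "s1"] == pytest.approx(2 * tpm.loc["b", "s1"])


def uniform_track(value, n=200, width=1000):
    part = make_partition({"chr1": n * width}, width)
    return OccupancyTrack(part, np.full(n, float(value)), 0.5)


class TestGeneOccupancy:
    def test_uniform_track_means_equal_value(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [50_000],
             "end": [52_000], "strand": ["+"]}
        )
        out = gene_occupancy(genes, uniform_track(1.75), {"chr1": 200_000},
                             flank=10_000)
        assert out.loc["g1", "body_mean"] == pytest.approx(1.75)
        assert out.loc["g1", "flank_mean"] == pytest.approx(1.75)
        assert not out.loc["g1", "clipped"]

    def test_chromosome_start_clips_flank(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [0], "end": [2000],
             "strand": ["+"]}
        )
        out = gene_occupancy(genes, uniform_track(1.0), {"chr1": 200_000},
                             flank=100_000)
        assert bool(out.loc["g1", "clipped"])

    def test_partial_window_weighting(self):
        # two windows 0/1; gene covers 500 bp of each -> mean 0.5
        part = make_partition({"chr1": 2000}, 1000)
        track = OccupancyTrack(part, np.array([0.0, 1.0]), 0.5)
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [500], "end": [1500],
             "strand": ["+"]}
        )
        out = gene_occupancy(genes, track, {"chr1": 2000}, flank=0)
        assert out.loc["g1", "body_mean"] == pytest.approx(0.5)


class TestCurves:
    def test_rolling_point_count(self):
        occ = np.arange(480.0)
        out = rolling_density(occ, occ, window=400, step=80)
        assert len(out) == 2

    def test_rolling_small_example(self):
        out = rolling_density(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]),
                              window=2, step=1)
        assert out["mean_density"].tolist() == pytest.approx([1.5, 2.5])

    def test_constant_densities_flat_curve(self):
        rng = np.random.default_rng(6)
        out = rolling_density(rng.normal(size=500), np.full(500, 2.0))
        assert (out["mean_density"] == 2.0).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            rolling_density(np.arange(10.0), np.arange(10.0), window=400)

    def test_group_curve_counts_and_identity(self):
        occ = np.arange(2500.0)
        out = window_group_curve(occ, occ, group=1000)
        assert len(out) == 2
        tiny = window_group_curve(np.array([3.0, 1.0, 2.0]), np.array([30.0, 10, 20]),
                                  group=1)
        assert tiny["mean_density"].tolist() == [10.0, 20.0, 30.0]

    def test_ties_broken_by_original_order(self):
        occ = np.zeros(4)
        dens = np.array([1.0, 2.0, 3.0, 4.0])
        out = rolling_density(occ, dens, window=2, step=2)
        assert out["mean_density"].tolist() == [1.5, 3.5]


class TestDomainOverlap:
    def _segments(self):
        return [
            Segment(GenomicInterval("chr1", 10_000, 30_000), 5, 0.8, 1e-9),
            Segment(GenomicInterval("chr1", 50_000, 70_000), 5, -0.8, 1e-9),
        ]

    def test_gene_inside_enriched(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [12_000],
             "end": [14_000], "strand": ["+"]}
        )
        cls = pd.Series(pd.Categorical(["up"]), index=["g1"])
        table = domain_overlap(genes, cls, self._segments())
        assert table.loc["up", "inside_enriched"] == 1.0

    def test_straddling_gene_overlapping(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [29_000],
             "end": [31_000], "strand": ["+"]}
        )
        cls = pd.Series(pd.Categorical(["down"]), index=["g1"])
        table = domain_overlap(genes, cls, self._segments())
        assert table.loc["down", "overlapping_enriched"] == 1.0

    def test_gene_outside_everything_is_neither(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [90_000],
             "end": [92_000], "strand": ["+"]}
        )
        cls = pd.Series(pd.Categorical(["unchanged"]), index=["g1"])
        table = domain_overlap(genes, cls, self._segments())
        assert table.loc["unchanged", "neither"] == 1.0


class TestOccupancyExpressionStats:
    def _de(self, l2fc):
        return pd.DataFrame(
            {"log2fc": l2fc, "padj": np.full(len(l2fc), 0.5)},
            index=[f"g{i}" for i in range(len(l2fc))],
        )

    def test_perfect_monotone_rho_one(self):
        occ = pd.Series(np.arange(20.0), index=[f"g{i}" for i in range(20)])
        stats = occupancy_expression_stats(occ, self._de(np.arange(20.0)))
        assert stats["rho_ko"] == pytest.approx(1.0)

    def test_hand_computed_rank_correlation(self):
        occ = pd.Series([1.0, 2.0, 3.0] * 4, index=[f"g{i}" for i in range(12)])
        fc = [0.3, 0.1, 0.2] * 4
        stats = occupancy_expression_stats(occ, self._de(fc))
        assert stats["rho_ko"] == pytest.approx(-0.5)

    def test_too_few_genes_rejected(self):
        occ = pd.Series([1.0, 2.0], index=["g0", "g1"])
        with pytest.raises(ValueError):
            occupancy_expression_stats(occ, self._de([0.1, 0.2]))

    def test_length_comparison_present_when_classes_given(self):
        rng = np.random.default_rng(7)
        n = 100
        idx = [f"g{i}" for i in range(n)]
        occ = pd.Series(rng.normal(size=n), index=idx)
        de = self._de(rng.normal(size=n))
        cls = pd.Series(
            pd.Categorical(rng.choice(["up", "unchanged"], size=n)), index=idx
        )
        lengths = pd.Series(rng.integers(1000, 100_000, n), index=idx)
        stats = occupancy_expression_stats(occ, de, classes=cls, gene_lengths=lengths)
        assert "length_up_vs_unchanged" in stats
        assert "class_fractions_by_occupancy_bin" in stats
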