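"""Generator correctness: stated expectations, determinism, validation."""

import numpy as np
import pandas as pd
import pytest

from oncoprofile import simulate
from oncoprofile.simulate import CnvEvent


class TestTumorCoverage:
    def test_pure_tumor_four_copies_doubles_ratio(self, spec):
        probes, _, _ = simulate.gen_tumor_coverage(
            spec, tf=1.0, cnv_events=[CnvEvent("EGFR", 4)], seed=1
        )
        egfr = probes.loc[probes["gene"] == "EGFR", "ratio"]
        se = egfr.std() / np.sqrt(len(egfr))
        assert abs(egfr.mean() - 2.0) < 3 * se

    def test_diploid_half_admixture_is_neutral(self, spec):
        probes, snps, _ = simulate.gen_tumor_coverage(spec, tf=0.5, seed=2)
        assert abs(probes["ratio"].mean() - 1.0) < 0.01
        baf = snps["alt_count"] / (snps["ref_count"] + snps["alt_count"])
        assert abs(baf.mean() - 0.5) < 0.01

    def test_homozygous_loss_at_half_tf_gives_half_ratio(self, spec):
        # (0.5*0 + 2*0.5)/2 = 0.5
        probes, _, _ = simulate.gen_tumor_coverage(
            spec, tf=0.5, cnv_events=[CnvEvent("CDKN2A", 0)], seed=3,
            noise_cv=0.0,
        )
        target = probes.loc[probes["gene"] == "CDKN2A", "ratio"]
        assert np.allclose(target, 0.5)

    def test_snp_allele_balance_tracks_copy_state(self, spec):
        # One-copy loss in pure tumor: het SNPs become fully imbalanced.
        _, snps, _ = simulate.gen_tumor_coverage(
            spec, tf=1.0, cnv_events=[CnvEvent("PTEN", 1)], seed=4
        )
        pten = snps[snps["region"] == "PTEN"]
        baf = pten["alt_count"] / (pten["ref_count"] + pten["alt_count"])
        assert ((baf < 0.02) | (baf > 0.98)).all()

    @pytest.mark.parametrize("bad_tf", [0.0, -0.1, 1.2])
    def test_invalid_tumor_fraction_rejected(self, spec, bad_tf):
        with pytest.raises(ValueError):
            simulate.gen_tumor_coverage(spec, tf=bad_tf, seed=0)

    def test_duplicate_events_rejected(self, spec):
        with pytest.raises(ValueError, match="overlapping"):
            simulate.gen_tumor_coverage(
                spec, tf=0.5,
                cnv_events=[CnvEvent("PTEN", 1), CnvEvent("PTEN", 4)], seed=0,
            )

    def test_seed_determinism(self, spec):
        a = simulate.gen_tumor_coverage(spec, tf=0.4, seed=11)
        b = simulate.gen_tumor_coverage(spec, tf=0.4, seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestSwgsBins:
    def test_flat_genome_has_uniform_expectation(self, spec):
        bins, _ = simulate.gen_swgs_bins(spec, [], depth=200, seed=5)
        auto = bins[~bins["chrom"].isin(spec.sex_chromosomes)]
        per_chrom = auto.groupby("chrom")["count"].mean()
        assert (np.abs(per_chrom - 200) < 4 * 200 * 0.16 / np.sqrt(20)).all()

    def test_pure_loss_halves_chromosome_coverage(self, spec):
        bins, _ = simulate.gen_swgs_bins(spec, [("chr10", "loss")], tf=1.0,
                                         depth=100, seed=6)
        auto = bins[~bins["chrom"].isin(spec.sex_chromosomes)]
        med = auto.loc[auto["chrom"] != "chr10", "count"].median()
        chr10 = auto.loc[auto["chrom"] == "chr10", "count"].mean()
        assert chr10 == pytest.approx(0.5 * med, rel=0.10)

    def test_gain_exceeds_genome_median(self, spec):
        bins, _ = simulate.gen_swgs_bins(spec, [("chr8", "gain")], tf=1.0, seed=7)
        auto = bins[~bins["chrom"].isin(spec.sex_chromosomes)]
        med = auto["count"].median()
        assert auto.loc[auto["chrom"] == "chr8", "count"].mean() > med

    def test_arm_event_spares_other_arm(self, spec):
        bins, _ = simulate.gen_swgs_bins(spec, [("chr9p", "loss")], tf=1.0,
                                         depth=200, seed=8)
        chr9 = bins[bins["chrom"] == "chr9"].reset_index(drop=True)
        split = int(round(0.4 * len(chr9)))
        assert chr9.loc[: split - 1, "count"].mean() < 0.7 * chr9.loc[split:, "count"].mean()

    def test_unknown_chromosome_rejected(self, spec):
        with pytest.raises(ValueError, match="unknown chromosome"):
            simulate.gen_swgs_bins(spec, [("chr99", "loss")], seed=0)

    def test_seed_determinism(self, spec):
        a, _ = simulate.gen_swgs_bins(spec, [("chr1", "gain")], seed=9)
        b, _ = simulate.gen_swgs_bins(spec, [("chr1", "gain")], seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestExpressionCohort:
    def test_null_effect_has_no_informative_genes(self):
        _, truth = simulate.gen_expression_cohort(effect_log2fc=0.0, seed=1)
        assert truth.informative_genes == {}

    def test_shapes_and_lengths(self):
        cohort, _ = simulate.gen_expression_cohort(
            n_classes=3, n_per_class=4, n_genes=30, n_informative=6, seed=2
        )
        assert cohort.counts.shape == (30, 12)
        assert (cohort.gene_lengths > 0).all()
        assert cohort.labels.nunique() == 3

    def test_informative_genes_shift_only_their_class(self):
        cohort, truth = simulate.gen_expression_cohort(
            n_classes=2, n_per_class=100, n_genes=20, n_informative=2,
            effect_log2fc=3.0, seed=3,
        )
        gene, cls = next(iter(truth.informative_genes.items()))
        in_cls = cohort.labels == cls
        x = np.log2(cohort.counts.loc[gene] + 1)
        assert x[in_cls].mean() - x[~in_cls].mean() == pytest.approx(3.0, abs=0.5)

    def test_seed_determinism(self):
        a, _ = simulate.gen_expression_cohort(seed=4)
        b, _ = simulate.gen_expression_cohort(seed=4)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_expression_cohort(n_per_class=1)
        with pytest.raises(ValueError):
            simulate.gen_expression_cohort(n_genes=10, n_informative=11)


class TestPlasmaSeries:
    def test_background_only_at_zero_tf(self):
        series, _ = simulate.gen_plasma_series(
            [(float(i), 0.0) for i in range(50)], depth=10_000,
            error_rate=1e-4, seed=5,
        )
        alts = np.concatenate([tp.mutations["alt_reads"].to_numpy() for tp in series])
        depths = np.concatenate([tp.mutations["depth"].to_numpy() for tp in series])
        expected = 1e-4
        se = np.sqrt(expected / depths.sum())
        assert alts.sum() / depths.sum() == pytest.approx(expected, abs=3 * se)

    def test_mean_vaf_recovers_tf(self):
        series, _ = simulate.gen_plasma_series(
            [(0.0, 0.10)], n_tracked_mutations=10, depth=10_000,
            error_rate=1e-4, seed=6,
        )
        muts = series[0].mutations
        vaf = (muts["alt_reads"] / muts["depth"]).mean()
        assert vaf == pytest.approx(0.10, abs=0.005)

    def test_het_convention_halves_vaf(self):
        series, _ = simulate.gen_plasma_series(
            [(0.0, 0.20)], depth=50_000, error_rate=0.0, seed=7,
            vaf_equals_tf=False,
        )
        muts = series[0].mutations
        assert (muts["alt_reads"] / muts["depth"]).mean() == pytest.approx(0.10, abs=0.01)

    def test_seed_determinism(self):
        a, _ = simulate.gen_plasma_series([(0, 0.01), (21, 0.001)], seed=8)
        b, _ = simulate.gen_plasma_series([(0, 0.01), (21, 0.001)], seed=8)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.mutations, y.mutations)
            assert x.cn_signal == y.cn_signal
            assert x.fragment_signal == y.fragment_signal

    @pytest.mark.parametrize("kwargs", [
        {"n_tracked_mutations": 3}, {"n_tracked_mutations": 11},
        {"error_rate": 2e-3}, {"depth": 0},
    ])
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            simulate.gen_plasma_series([(0, 0.01)], seed=0, **kwargs)


class TestDilutionSeries:
    def test_default_design_is_four_levels_in_triplicate(self):
        samples, _ = simulate.gen_dilution_series(seed=1)
        assert len(samples) == 12
        levels = sorted({s.level for s in samples}, reverse=True)
        assert levels == [0.001, 0.0005, 0.00025, 0.0001]

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_dilution_series(replicates=0)

    def test_levels_must_descend_and_stay_below_base(self):
        with pytest.raises(ValueError):
            simulate.gen_dilution_series(levels=[1e-4, 1e-3])
        with pytest.raises(ValueError):
            simulate.gen_dilution_series(base_tf=1e-4, levels=[1e-3])

    def test_detection_frequency_non_increasing_with_dilution(self):
        # Monte-Carlo with the tail-probability mutation detector.
        from oncoprofile.ctdna import annotate_mutations

        rates = []
        for level in (1e-3, 1e-4, 2e-5):
            samples, _ = simulate.gen_dilution_series(
                levels=[level], replicates=120, seed=42,
            )
            hits = 0
            for s in samples:
                muts = annotate_mutations(s.timepoint, error_rate=5e-5)
                hits += muts["positive"].any()
            rates.append(hits / len(samples))
        assert rates == sorted(rates, reverse=True)
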