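"""The cohort generator: panel structure, count model, QC fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mitometab as mm
from mitometab import association
from mitometab.synthetic import panel_metadata


def config(**kw):
    base = dict(n_individuals=100, n_metabolites=10, n_positions=5, seed=2)
    base.update(kw)
    return mm.SimulationConfig(**base)


class TestMetabolitePanel:
    def test_shape_and_zero_missing_at_rate_zero(self):
        panel = mm.simulate_metabolites(config(missing_rate=0.0, outlier_rate=0.0))
        assert panel.values.shape == (100, 10)
        assert panel.n_missing() == 0
        assert (panel.values.to_numpy() > 0).all()

    def test_missing_fraction_within_binomial_bounds(self):
        cfg = config(n_individuals=300, n_metabolites=20, missing_rate=0.1, outlier_rate=0.0)
        panel = mm.simulate_metabolites(cfg)
        cells = 300 * 20
        lo, hi = stats.binom.ppf([0.005, 0.995], cells, 0.1)
        assert lo <= panel.values.isna().to_numpy().sum() <= hi

    def test_block_correlation_realized(self):
        cfg = config(
            n_individuals=500, n_metabolites=10, block_correlation=0.9,
            missing_rate=0.0, outlier_rate=0.0,
        )
        panel = mm.simulate_metabolites(cfg)
        # consecutive glycerophospholipids share a block
        r = np.corrcoef(panel.values["PC aa C28:0"], panel.values["PC aa C28:1"])[0, 1]
        assert r > 0.7

    def test_outliers_exceed_three_sd_of_clean_panel(self):
        cfg = config(n_individuals=400, n_metabolites=10, missing_rate=0.0, outlier_rate=0.01)
        panel = mm.simulate_metabolites(cfg)
        assert panel.outlier_cells
        clean_mean = panel.complete.mean()
        clean_sd = panel.complete.std(ddof=1)
        for ind, met in panel.outlier_cells:
            val = panel.values.loc[ind, met]
            if np.isnan(val):  # may have been masked as missing afterwards
                continue
            assert abs(val - clean_mean[met]) > 3 * clean_sd[met]

    def test_class_mix_matches_panel_composition(self):
        meta = panel_metadata(151)
        counts = meta["class"].value_counts()
        assert counts["hexose"] == 1
        assert counts["acylcarnitine"] == 35
        assert counts["amino acid"] == 14
        assert counts["sphingolipid"] == 14
        assert counts["glycerophospholipid"] == 87
        assert meta.index.is_unique


class TestCounts:
    def test_bit_identical_under_fixed_seed(self):
        a = mm.simulate_cohort(config(seed=42))
        b = mm.simulate_cohort(config(seed=42))
        pd.testing.assert_frame_equal(a.panel.values, b.panel.values)
        assert np.array_equal(a.tensor.counts, b.tensor.counts)
        assert a.truth.reference == b.truth.reference

    def test_mean_coverage_tracks_target(self):
        cfg = config(n_individuals=500, n_positions=50)
        cohort = mm.simulate_cohort(cfg)
        mean_cov = cohort.tensor.total_coverage().mean()
        assert abs(mean_cov - 3500.0) / 3500.0 < 0.01

    def test_counts_nonnegative_two_bases_only(self):
        cohort = mm.simulate_cohort(config())
        counts = cohort.tensor.counts
        assert counts.min() >= 0
        assert ((counts > 0).sum(axis=2) <= 2).all()

    def test_homoplasmic_positions_have_no_minor_reads(self):
        cfg = config(n_positions=30, homoplasmic_fraction=0.5)
        cohort = mm.simulate_cohort(cfg)
        homo = cohort.truth.homoplasmic_positions
        assert len(homo) == 15
        alleles = mm.call_alleles(cohort.tensor, cohort.truth.reference)
        Y, coverage = association.build_heteroplasmy(cohort.tensor, alleles)
        cols = np.isin(cohort.tensor.positions, homo)
        # only the reference base carries reads -> y = log2(2/(A+2)) < 0
        assert ((cohort.tensor.counts[:, cols] > 0).sum(axis=2) <= 1).all()
        assert (Y[:, cols] < 0).all()

    def test_null_positions_uncorrelated_with_ratio(self):
        cfg = config(n_individuals=500, n_positions=1, homoplasmic_fraction=0.0,
                     missing_rate=0.0, outlier_rate=0.0)
        cohort = mm.simulate_cohort(cfg)
        alleles = mm.call_alleles(cohort.tensor, cohort.truth.reference)
        Y, _ = association.build_heteroplasmy(cohort.tensor, alleles)
        mr = (cohort.panel.values["PC aa C28:0"] / cohort.panel.values["PC aa C28:1"]).to_numpy()
        r = np.corrcoef(Y[:, 0], mr)[0, 1]
        assert abs(r) < stats.norm.ppf(0.995) / np.sqrt(500)

    def test_positive_effect_recovers_positive_slope(self):
        cfg = config(
            n_individuals=1000, n_positions=3, homoplasmic_fraction=0.0,
            missing_rate=0.0, outlier_rate=0.0,
            causal_effects=(mm.CausalEffect(2, "PC aa C28:0", "PC aa C28:1", 1.5),),
        )
        cohort = mm.simulate_cohort(cfg)
        alleles = mm.call_alleles(cohort.tensor, cohort.truth.reference)
        Y, _ = association.build_heteroplasmy(cohort.tensor, alleles)
        mr = (cohort.panel.complete["PC aa C28:0"] / cohort.panel.complete["PC aa C28:1"]).to_numpy()
        slope = np.polyfit(mr, Y[:, 1], 1)[0]
        assert slope > 0

    def test_causal_metabolite_must_exist(self):
        cfg = config(causal_effects=(mm.CausalEffect(1, "nope", "PC aa C28:0", 1.0),))
        panel = mm.simulate_metabolites(cfg)
        covariates = mm.simulate_covariates(cfg)
        with pytest.raises(KeyError):
            mm.simulate_counts(cfg, panel, covariates)


class TestQCFixture:
    def test_exact_flag_counts(self):
        spec = mm.QCFixtureSpec(
            n_total=40, n_contaminated=4, n_low_coverage_individuals=3, n_diabetic=6,
            n_lowcov_positions=7, n_homoplasmic_positions=11, genome_length=600,
        )
        fx = mm.make_qc_fixture(spec, seed=1)
        assert fx.covariates["contaminated"].sum() == 4
        assert fx.covariates["diabetes"].sum() == 6
        low = fx.tensor.mean_coverage_per_individual() < 1000
        assert low.sum() == 3
        assert len(fx.expected["lowcov_positions"]) == 7

    def test_all_zero_spec_flags_nothing(self):
        spec = mm.QCFixtureSpec(
            n_total=10, n_contaminated=0, n_low_coverage_individuals=0, n_diabetic=0,
            n_lowcov_positions=0, n_homoplasmic_positions=0, genome_length=200,
        )
        fx = mm.make_qc_fixture(spec, seed=1)
        _, report = mm.exclude_individuals(fx.tensor, fx.covariates)
        assert report.n_excluded == 0

    def test_homoplasmic_positions_below_calling_floor(self):
        spec = mm.QCFixtureSpec(
            n_total=20, n_contaminated=0, n_low_coverage_individuals=0, n_diabetic=0,
            n_lowcov_positions=0, n_homoplasmic_positions=30, genome_length=400,
        )
        fx = mm.make_qc_fixture(spec, seed=3)
        alleles = mm.call_alleles(fx.tensor, fx.reference)
        frac = mm.seq_qc.minor_fraction_matrix(fx.tensor, alleles)
        cols = np.isin(fx.tensor.positions, sorted(fx.expected["homoplasmic_positions"]))
        assert frac[:, cols].max() < 0.007

    def test_overlapping_flag_groups_rejected(self):
        with pytest.raises(ValueError):
            mm.QCFixtureSpec(n_total=10, n_contaminated=6, n_low_coverage_individuals=3,
                             n_diabetic=3, n_lowcov_positions=0,
                             n_homoplasmic_positions=0, genome_length=100)
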