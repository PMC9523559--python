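"""Sequencing-side QC: exclusion rules, allele calling, ledger accounting."""

import numpy as np
import pytest

import mitometab as mm
from mitometab.counts import AlleleCountTensor
from mitometab.seq_qc import SeqQCConfig

from conftest import plain_covariates, tensor_from_planes


def test_long_format_round_trip():
    tensor = tensor_from_planes("G", "A", [[100, 50], [80, 60]], [[3, 0], [5, 1]])
    back = AlleleCountTensor.from_long_frame(tensor.to_long_frame())
    assert np.array_equal(back.counts, tensor.counts)
    assert np.array_equal(back.positions, tensor.positions)


class TestExcludeIndividuals:
    def test_flag_rules_are_disjoint_and_conserved(self):
        a = np.full((10, 4), 1000)
        tensor = tensor_from_planes("G", "A", a, np.zeros_like(a))
        ids = list(tensor.individuals)
        cov = plain_covariates(ids, contaminated=ids[:2], diabetic=ids[2:5])
        filtered, report = mm.exclude_individuals(tensor, cov)
        assert report.counts() == {"contamination": 2, "mean_coverage": 0, "diabetes": 3}
        assert report.is_conserved()
        assert filtered.n_individuals == 5

    def test_mean_coverage_boundary_is_strict(self):
        # 10 positions: totals 9999 -> mean 999.9 excluded; 10000 -> retained
        a = np.array([[999] * 9 + [1008], [1000] * 10])
        tensor = tensor_from_planes("G", "A", a, np.zeros_like(a))
        cov = plain_covariates(list(tensor.individuals))
        filtered, report = mm.exclude_individuals(tensor, cov)
        assert list(filtered.individuals) == [tensor.individuals[1]]
        assert report.excluded["mean_coverage"] == [tensor.individuals[0]]

    def test_no_flags_nothing_excluded(self):
        a = np.full((4, 3), 2000)
        tensor = tensor_from_planes("G", "A", a, np.zeros_like(a))
        _, report = mm.exclude_individuals(tensor, plain_covariates(list(tensor.individuals)))
        assert report.n_excluded == 0

    def test_individual_missing_from_covariates_raises(self):
        a = np.full((3, 2), 2000)
        tensor = tensor_from_planes("G", "A", a, np.zeros_like(a))
        cov = plain_covariates(list(tensor.individuals)[:2])
        with pytest.raises(KeyError):
            mm.exclude_individuals(tensor, cov)


class TestCallAlleles:
    def test_second_most_frequent_base_is_alt(self):
        counts = np.zeros((1, 1, 4), dtype=np.int64)
        counts[0, 0] = [50, 7, 10000, 2]  # A, C, G, T with ref G
        tensor = AlleleCountTensor(np.array(["i1"]), np.array([1]), counts)
        (alleles,) = mm.call_alleles(tensor, "G")
        assert (alleles.ref_base, alleles.alt_base) == ("G", "A")

    def test_tie_breaks_alphabetically(self):
        counts = np.zeros((1, 1, 4), dtype=np.int64)
        counts[0, 0] = [0, 30, 1000, 30]  # C == T tie -> C
        tensor = AlleleCountTensor(np.array(["i1"]), np.array([1]), counts)
        (alleles,) = mm.call_alleles(tensor, "G")
        assert alleles.alt_base == "C"

    def test_all_reference_reads_pick_first_nonref_base(self):
        counts = np.zeros((1, 1, 4), dtype=np.int64)
        counts[0, 0, 2] = 5000
        tensor = AlleleCountTensor(np.array(["i1"]), np.array([1]), counts)
        (alleles,) = mm.call_alleles(tensor, "G")
        assert alleles.alt_base == "A"

    def test_reference_gap_flagged(self):
        counts = np.zeros((1, 1, 4), dtype=np.int64)
        counts[0, 0, 2] = 5000
        tensor = AlleleCountTensor(np.array(["i1"]), np.array([1]), counts)
        (alleles,) = mm.call_alleles(tensor, "N")
        assert alleles.ref_is_gap and alleles.alt_base == "G"


class TestFilterPositions:
    def _cohort(self, fracs, coverage=10000):
        """One position per minor fraction, ten individuals."""
        fracs = np.asarray(fracs)
        a = np.full((10, len(fracs)), coverage)
        b = np.zeros_like(a)
        b[0] = np.round(coverage * fracs).astype(int)  # max over individuals
        a = a - b
        return tensor_from_planes("G", "A", a, b)

    def test_homoplasmy_boundary_at_0007(self):
        tensor = self._cohort([0.0069, 0.0071])
        alleles = mm.call_alleles(tensor, "GG")
        cfg = SeqQCConfig(
            primer_region=(0, 0), gap_positions=frozenset(),
            phantom_positions=frozenset(), blacklist_positions=frozenset(),
        )
        filtered, report = mm.filter_positions(tensor, alleles, cfg)
        assert report.excluded["homoplasmic"] == [1]
        assert list(filtered.positions) == [2]

    def test_low_coverage_positions_removed_strictly(self):
        # total coverage A+B: 999 at position 1 (excluded), 1000 at position 2
        a = np.full((5, 2), 979)
        a[:, 1] = 980
        tensor = tensor_from_planes("G", "A", a, np.full((5, 2), 20))
        alleles = mm.call_alleles(tensor, "GG")
        cfg = SeqQCConfig(
            primer_region=(0, 0), gap_positions=frozenset(),
            phantom_positions=frozenset(), blacklist_positions=frozenset(),
        )
        filtered, report = mm.filter_positions(tensor, alleles, cfg)
        assert report.excluded["low_coverage"] == [1]
        assert list(filtered.positions) == [2]

    def test_fixed_site_rules_and_order(self):
        positions = np.array([301, 3107, 3166, 5000, 16401, 16449])
        a = np.full((4, 6), 9000)
        tensor = tensor_from_planes("G", "A", a, np.full((4, 6), 90), positions)
        ref = ["G"] * 16569
        ref[3106] = "N"
        alleles = mm.call_alleles(tensor, "".join(ref))
        filtered, report = mm.filter_positions(tensor, alleles)
        assert report.counts() == {
            "primer_region": 2, "reference_gap": 1, "phantom": 1,
            "blacklist": 1, "low_coverage": 0, "homoplasmic": 0,
        }
        assert list(filtered.positions) == [5000]
        assert report.is_conserved()

    def test_idempotent(self, small_cohort):
        alleles = mm.call_alleles(small_cohort.tensor, small_cohort.truth.reference)
        once, _ = mm.filter_positions(small_cohort.tensor, alleles)
        kept = set(once.positions)
        again, report = mm.filter_positions(
            once, [a for a in alleles if a.position in kept]
        )
        assert report.n_excluded == 0
        assert np.array_equal(again.positions, once.positions)

    def test_empty_cohort_raises(self):
        tensor = tensor_from_planes("G", "A", np.full((2, 2), 5000), np.full((2, 2), 50))
        empty = tensor.select_individuals(np.zeros(2, dtype=bool))
        alleles = mm.call_alleles(tensor, "GG")
        with pytest.raises(ValueError):
            mm.filter_positions(empty, alleles)


def test_fixture_ledger_conservation_scaled_down():
    """Generated fixture accounting is exact at an arbitrary (small) scale."""
    spec = mm.QCFixtureSpec(
        n_total=60, n_contaminated=3, n_low_coverage_individuals=2, n_diabetic=5,
        n_lowcov_positions=10, n_homoplasmic_positions=20, genome_length=500,
    )
    fx = mm.make_qc_fixture(spec, seed=5)
    tensor, ind_report = mm.exclude_individuals(fx.tensor, fx.covariates)
    alleles = mm.call_alleles(tensor, fx.reference)
    tensor, pos_report = mm.filter_positions(tensor, alleles)
    assert ind_report.counts() == {"contamination": 3, "mean_coverage": 2, "diabetes": 5}
    assert ind_report.n_retained == 50 == fx.expected["n_individuals_retained"]
    assert pos_report.counts()["low_coverage"] == 10
    assert pos_report.counts()["homoplasmic"] == 20
    assert pos_report.n_retained == fx.expected["n_positions_retained"]
    assert ind_report.is_conserved() and pos_report.is_conserved()
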