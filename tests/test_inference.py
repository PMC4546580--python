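"""Goodness of fit, classification, distortion, selfing checks and
two-locus decomposition."""

import math
from fractions import Fraction

import numpy as np
import pytest

from polyseg.errors import (
    AmbiguousPartitionError,
    DecompositionFailedError,
    DegenerateTestError,
    ValidationError,
)
from polyseg.inference import (
    chisq_gof,
    chisq_pvalue,
    classify_locus,
    distortion_scan,
    two_locus_decomposition,
    verify_selfed,
)
from polyseg.io import LocusCounts
from polyseg.models import ParentModel
from polyseg.simulate import SimulationConfig, simulate_s1_population
from polyseg.io import tabulate_locus


class TestChisqPvalue:
    def test_df2_equals_exponential_closed_form(self):
        # at df=2 the upper tail is exactly exp(-x/2)
        for x in [0.0, 0.5, 1.78, 5.0, 20.0, 80.0]:
            assert chisq_pvalue(x, 2) == pytest.approx(math.exp(-x / 2), abs=1e-10)

    def test_df1_equals_erfc_closed_form(self):
        for x in [0.0234, 0.5, 3.84, 10.0]:
            assert chisq_pvalue(x, 1) == pytest.approx(
                math.erfc(math.sqrt(x / 2)), abs=1e-10
            )

    def test_zero_statistic(self):
        assert chisq_pvalue(0.0, 2) == 1.0

    def test_strictly_decreasing_in_statistic(self):
        xs = np.linspace(0, 30, 200)
        ps = [chisq_pvalue(x, 2) for x in xs]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            chisq_pvalue(-1.0, 2)
        with pytest.raises(ValueError):
            chisq_pvalue(1.0, 0)


RATIO_121 = {"AA": Fraction(1, 4), "Aa": Fraction(1, 2), "aa": Fraction(1, 4)}


class TestChisqGof:
    def test_matches_textbook_recomputation(self, hypotheses):
        rng = np.random.default_rng(42)
        probs = [0.25, 0.5, 0.25]
        for _ in range(50):
            o = rng.multinomial(rng.integers(50, 400), probs)
            obs = LocusCounts("x", ("AA", "Aa", "aa"), tuple(int(v) for v in o), 0)
            r = chisq_gof(obs, RATIO_121)
            n = sum(o)
            direct = sum((oi - n * p) ** 2 / (n * p) for oi, p in zip(o, probs))
            assert r.chi2 == pytest.approx(direct, abs=1e-9)
            assert r.df == 2

    def test_two_band_locus_against_1_2_1(self):
        obs = LocusCounts("CDGA8-1765/1766", ("AA", "Aa", "aa"), (48, 117, 61), 2)
        r = chisq_gof(obs, RATIO_121)
        assert r.n_used == 226  # missing excluded
        assert round(r.chi2, 2) == 1.78
        assert round(r.pvalue, 2) == 0.41

    def test_three_to_one_fit(self):
        obs = LocusCounts("CDGA7-1611/1612", ("Aa", "aa"), (172, 56), 0)
        r = chisq_gof(obs, {"Aa": Fraction(3, 4), "aa": Fraction(1, 4)})
        assert round(r.pvalue, 2) == 0.88

    def test_perfect_fit(self):
        obs = LocusCounts("x", ("AA", "Aa", "aa"), (50, 100, 50), 0)
        r = chisq_gof(obs, RATIO_121)
        assert r.chi2 == 0.0 and r.pvalue == 1.0

    def test_pooled_four_band_disomic_drops_zero_classes(self, four_band):
        obs = LocusCounts(
            "CDAAC7", tuple(four_band["phenotype"]), tuple(four_band["observed"]), 0
        )
        r = chisq_gof(obs, list(four_band["expected_disomic"]))
        assert r.dropped_classes == ("ab", "cd")
        assert r.df == 8
        assert round(r.chi2, 1) == 96.3

    def test_pooled_four_band_tetrasomic_explicit_expectations(self, four_band):
        obs = LocusCounts(
            "CDAAC7", tuple(four_band["phenotype"]), tuple(four_band["observed"]), 0
        )
        r = chisq_gof(obs, list(four_band["expected_tetrasomic_1dp"]))
        assert round(r.chi2, 1) == 172.8
        assert r.pvalue < 1e-4

    def test_observed_in_zero_expectation_class_is_impossible(self):
        obs = LocusCounts("x", ("AA", "Aa"), (3, 97), 0)
        r = chisq_gof(obs, {"AA": Fraction(0), "Aa": Fraction(1)})
        assert r.impossible and r.pvalue == 0.0

    def test_degenerate_when_no_informative_classes(self):
        obs = LocusCounts("x", ("AA",), (100,), 0)
        with pytest.raises(DegenerateTestError):
            chisq_gof(obs, {"AA": Fraction(1)})


class TestClassify:
    def test_disomic_verdict(self, hypotheses):
        obs = LocusCounts("m", ("AA", "Aa", "aa"), (48, 117, 61), 2)
        c = classify_locus(obs, [hypotheses["1:2:1"], hypotheses["1:34:1"]])
        assert c.verdict == "disomic"

    def test_three_to_one_is_ambiguous_between_modes(self, hypotheses):
        # 3:1 arises both from tetrasomic Aaaa and from the dual-subgenome
        # disomic aa/Bb with comigrating alleles
        obs = LocusCounts("m", ("AA", "Aa", "aa"), (0, 172, 56), 0)
        c = classify_locus(obs, [hypotheses["3:1-dual"], hypotheses["3:1"]])
        assert c.verdict == "ambiguous"

    def test_distorted_with_nearest_model(self, hypotheses):
        obs = LocusCounts("m", ("AA", "Aa", "aa"), (16, 183, 28), 1)
        c = classify_locus(obs, [hypotheses["1:2:1"], hypotheses["1:34:1"]])
        assert c.verdict == "distorted"
        assert c.nearest_model == "1:2:1"

    def test_model_missing_an_observed_class_is_impossible_not_error(self, hypotheses):
        obs = LocusCounts("m", ("AA", "Aa", "aa"), (24, 52, 24), 0)
        c = classify_locus(obs, [hypotheses["3:1-dual"], hypotheses["1:2:1"]])
        assert c.results["3:1-dual"].impossible
        assert c.verdict == "disomic"

    def test_requires_at_least_one_model(self):
        with pytest.raises(ValidationError):
            classify_locus(LocusCounts("m", ("AA",), (1,), 0), [])


class TestDistortionScan:
    def test_zebra_population_19_of_21(self, zebra, hypotheses):
        counts, _ = zebra
        models = [hypotheses["1:2:1"], hypotheses["1:34:1"]]
        cls = [classify_locus(o, models) for o in counts]
        scan = distortion_scan(cls)
        assert scan.n_loci == 21
        assert scan.distorted[0.05] == 19
        assert scan.fraction_pct[0.05] == 90

    def test_empty_scan(self):
        scan = distortion_scan([])
        assert scan.distorted[0.05] == 0 and scan.modal_verdict is None

    def test_type_one_error_near_nominal(self, hypotheses):
        # 1000 true-1:2:1 loci at n=200: flagged fraction within the 99%
        # binomial interval of 0.05
        rng = np.random.default_rng(2026)
        models = [hypotheses["1:2:1"]]
        cls = []
        for _ in range(1000):
            o = rng.multinomial(200, [0.25, 0.5, 0.25])
            obs = LocusCounts("x", ("AA", "Aa", "aa"), tuple(int(v) for v in o), 0)
            cls.append(classify_locus(obs, models))
        rate = distortion_scan(cls).distorted[0.05] / 1000
        half = 2.576 * math.sqrt(0.05 * 0.95 / 1000)
        assert 0.05 - half <= rate <= 0.05 + half


class TestVerifySelfed:
    PANEL = ["m1", "m2", "m3"]

    def test_subset_of_parent_bands_is_selfed(self):
        ok, off = verify_selfed(
            {"m1": "Aa", "m2": "AA", "m3": "M"},
            {"m1": "Aa", "m2": "Aa", "m3": "Aa"},
            {"m1": "aa", "m2": "aa", "m3": "aa"},
        )
        assert ok is True and off == []

    def test_foreign_band_lists_marker(self):
        ok, off = verify_selfed(
            {"m1": "Ab", "m2": "Aa", "m3": "Aa"},
            {"m1": "Aa", "m2": "Aa", "m3": "Aa"},
            {"m1": "bb", "m2": "Aa", "m3": "Aa"},
        )
        assert ok is False and off == ["m1"]

    def test_all_missing_is_indeterminate(self):
        ok, off = verify_selfed(
            {"m1": "M", "m2": "M", "m3": "M"},
            {"m1": "Aa", "m2": "Aa", "m3": "Aa"},
        )
        assert ok is None and off == []

    def test_panel_mismatch_raises(self):
        with pytest.raises(ValidationError):
            verify_selfed({"m1": "Aa"}, {"m1": "Aa", "m2": "Aa"})


class TestDecomposition:
    def test_observed_four_band_counts_pick_ab_cd(self, four_band):
        joint = dict(zip(four_band["phenotype"], four_band["observed"]))
        dec = two_locus_decomposition(joint)
        assert dec.partition == (("a", "b"), ("c", "d"))
        assert dec.impossible_by_partition[(("a", "b"), ("c", "d"))] == 0
        n = sum(joint.values())
        for lc in dec.locus_counts:
            assert lc.n == n

    def test_recovers_generating_partition_from_simulation(self):
        parent = ParentModel.from_spec("disomic:ac;bd")
        cfg = SimulationConfig(parent=parent, n_progeny=250, seed=11)
        table = simulate_s1_population(cfg)
        joint: dict = {}
        for s in table.progeny_ids:
            pat = table.cell(s, "M1")
            joint[pat] = joint.get(pat, 0) + 1
        dec = two_locus_decomposition(joint)
        assert dec.partition == (("a", "c"), ("b", "d"))

    def test_uninformative_data_is_ambiguous(self):
        with pytest.raises(AmbiguousPartitionError):
            two_locus_decomposition({"abcd": 100})

    def test_no_partition_fits_fails(self):
        # every pair-dropping pattern present in force: all three partitions
        # leave impossible observations
        joint = {"ab": 30, "cd": 30, "ac": 30, "bd": 30, "ad": 30, "bc": 30}
        with pytest.raises((DecompositionFailedError, AmbiguousPartitionError)):
            two_locus_decomposition(joint)

    def test_needs_exactly_four_labels(self):
        with pytest.raises(ValidationError):
            two_locus_decomposition({"abc": 10})
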