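"""Recombinational-history deduction and classification rules."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyndj.experiments import ndj_experiment_config, simulate_recomb_experiment
from flyndj.recomb import (
    InconsistentRecordError,
    analyze_diplo_female,
    classify_missegregation,
    deduce_chromatid_pair,
    recombinant_missegregation_frequency,
)

codes4 = st.text(alphabet="m+", min_size=4, max_size=4)


class TestDeduction:
    def test_fully_mutant_homozygote(self):
        ded = deduce_chromatid_pair("mmmm", ["mmmm"] * 10)
        assert ded.pair == ("mmmm", "mmmm") and ded.confidence == "high"

    def test_parental_heterozygote(self):
        ded = deduce_chromatid_pair("++++", ["++++", "mmmm"] * 5)
        assert ded.pair == ("++++", "mmmm") and ded.confidence == "high"

    def test_three_son_classes_impossible(self):
        with pytest.raises(InconsistentRecordError, match="3 distinct"):
            deduce_chromatid_pair("++++", ["++++", "mmmm", "+m++"] * 3)

    def test_contradiction_names_the_locus(self):
        # mother shows cv but a son is wild type at cv
        with pytest.raises(InconsistentRecordError, match="cv"):
            deduce_chromatid_pair("+m++", ["++++"] * 8)

    def test_both_classes_mutant_but_mother_wild_type(self):
        with pytest.raises(InconsistentRecordError, match="sc"):
            deduce_chromatid_pair("++++", ["mm++", "m+m+"] * 4)

    def test_hidden_second_chromatid_is_low_confidence(self):
        # mother wild type at sc, all sons marked at sc: the unobserved
        # chromatid must be + at sc; record cannot be trusted for counting
        ded = deduce_chromatid_pair("++++", ["mm++"] * 10)
        assert ded.confidence == "low"
        assert ded.pair[0] == "mm++" and ded.pair[1][0] == "+"

    def test_single_class_few_sons_is_low_confidence(self):
        ded = deduce_chromatid_pair("++++", ["++++"] * 4)
        assert ded.pair == ("++++", "++++") and ded.confidence == "low"

    def test_single_class_enough_sons_is_high_confidence(self):
        ded = deduce_chromatid_pair("++++", ["++++"] * 8)
        assert ded.confidence == "high"

    def test_fully_marked_single_class_confident_even_with_few_sons(self):
        # every scored locus visibly homozygous: no hidden class possible
        ded = deduce_chromatid_pair("mmmm", ["mmmm"] * 3)
        assert ded.confidence == "high"

    def test_empty_sons_rejected(self):
        with pytest.raises(ValueError, match="at least one son"):
            deduce_chromatid_pair("++++", [])

    @given(codes4, codes4)
    @settings(max_examples=80, deadline=None)
    def test_recovers_any_true_pair_when_both_classes_seen(self, c1, c2):
        phenotype = "".join(
            "m" if a == "m" and b == "m" else "+" for a, b in zip(c1, c2)
        )
        sons = [c1, c2] * 5
        ded = deduce_chromatid_pair(phenotype, sons)
        assert sorted(ded.pair) == sorted((c1, c2))
        if c1 != c2:
            assert ded.confidence == "high"


class TestClassification:
    @pytest.mark.parametrize(
        "pair,error,flags",
        [
            (("++++", "mmmm"), "MI", (False, False)),
            (("++mm", "mm++"), "MI", (True, True)),  # reciprocal cv-f recombinants
            (("mmmm", "mmmm"), "MII", (False, False)),
            (("+mmm", "mmmm"), "MII", (True, False)),
            (("+++m", "++++"), "MI", (True, False)),
        ],
    )
    def test_car_rule_and_recombinant_flags(self, pair, error, flags):
        cls = classify_missegregation(pair)
        assert cls.error_type == error and cls.recomb_flags == flags

    def test_truth_agreement_without_f_car_crossovers(self, atomic_map):
        """Exhaustive: every <=2-crossover configuration in sc-cv and cv-f.

        With no f-car exchange the car allele equals the centromere origin,
        so the car rule and the recombinant flags must match simulation
        truth for every diplo ovum the bivalent can produce.
        """
        from flyndj.meiosis import enumerate_diplo_ova
        from test_meiosis import all_crossover_configs

        checked = 0
        for bv in all_crossover_configs(atomic_map, intervals=(1, 2), max_co=2):
            for ovum in enumerate_diplo_ova(bv):
                pair = tuple(c.scored_code for c in ovum.chromatids)
                cls = classify_missegregation(pair, atomic_map)
                assert cls.error_type == ovum.error_class
                truth_flags = tuple(c.is_recombinant for c in ovum.chromatids)
                assert cls.recomb_flags == truth_flags
                checked += 1
        assert checked == (1 + 4 + 4 + 16) * 6

    def test_car_misclassification_bounded_by_f_car_recombinants(self):
        # with recombination proximal to car, the car rule can mistake the
        # error type, but never more often than chromatids recombine there
        from flyndj.markers import standard_map

        mm = standard_map(r_f_car=0.2)
        cfg = ndj_experiment_config(p_arm_loss=0.5, marker_map=mm)
        exp = simulate_recomb_experiment(cfg, 4000, np.random.default_rng(31))
        confident = [
            (r, t)
            for r, t in zip(exp.records, exp.truth_error)
            if r.confident
        ]
        mismatch = sum(r.error_type != t for r, t in confident) / len(confident)
        f_car_frac = mm.chromatid_recombination_fraction("f", "car")
        assert mismatch <= f_car_frac + 0.02


class TestFrequency:
    def _records(self, n_recomb, n_plain):
        recs = []
        for i in range(n_recomb):
            recs.append(analyze_diplo_female(f"r{i}", "++++", ["++mm", "mm++"] * 5))
        for i in range(n_plain):
            recs.append(analyze_diplo_female(f"p{i}", "++++", ["++++", "mmmm"] * 5))
        return recs

    def test_per_1000_arithmetic(self):
        comp = recombinant_missegregation_frequency(self._records(12, 8), 4000)
        assert comp.group.r_count == 12
        assert comp.group.freq_per_1000 == pytest.approx(3.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="total_progeny"):
            recombinant_missegregation_frequency([], 0)

    def test_total_below_records_rejected(self):
        with pytest.raises(ValueError, match="below"):
            recombinant_missegregation_frequency(self._records(3, 3), 2)

    def test_no_recombinants_in_either_group_gives_p_one(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = recombinant_missegregation_frequency(
                self._records(0, 5), 1000, self._records(0, 4), 1000
            )
        assert comp.p_vs_control == 1.0

    def test_ambiguous_records_excluded_from_counts(self):
        recs = self._records(2, 2)
        recs.append(analyze_diplo_female("amb", "++++", ["mm++"] * 10))  # low conf
        comp = recombinant_missegregation_frequency(recs, 1000)
        assert comp.group.n_records == 5 and comp.group.n_confident == 4
        assert comp.group.r_count == 2

    def test_mi_mii_breakdown(self):
        recs = [
            analyze_diplo_female("a", "++++", ["++mm", "mm++"] * 5),  # MI recomb
            analyze_diplo_female("b", "+m++", ["+m++", "+mmm"] * 5),  # MI recomb
            analyze_diplo_female("c", "+++m", ["+mmm", "+++m"] * 5),  # MII recomb
            analyze_diplo_female("d", "++++", ["++++", "mmmm"] * 5),  # MI plain
        ]
        comp = recombinant_missegregation_frequency(recs, 2000)
        assert comp.group.mi_recomb == 2
        assert comp.group.mii_recomb == 1
        assert comp.group.r_count == 3
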