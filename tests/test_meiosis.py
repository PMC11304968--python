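"""Meiosis sampler: crossover placement, segregation logic, truth labels."""

import itertools

import numpy as np
import pytest

from flyndj.markers import MarkerMap
from flyndj.meiosis import (
    NON_SISTER_PAIRS,
    Bivalent,
    Chromatid,
    Ovum,
    SimConfig,
    apply_crossovers,
    build_bivalent,
    enumerate_diplo_ova,
    resolve_meiosis,
    simulate_oocytes,
)


def all_crossover_configs(marker_map, intervals, max_co=2):
    """Every crossover configuration with <=max_co exchanges, one per interval."""
    for k in range(0, max_co + 1):
        for combo in itertools.combinations(intervals, k):
            for pairs in itertools.product(NON_SISTER_PAIRS, repeat=k):
                yield apply_crossovers(marker_map, list(zip(combo, pairs)))


class TestBuildBivalent:
    def test_zero_rates_never_cross_over(self, zero_map, rng):
        for _ in range(20):
            bv = build_bivalent(zero_map, rng)
            assert bv.n_crossovers == 0 and not bv.chiasmate

    def test_rate_half_always_crosses_over(self, rng):
        mm = MarkerMap(interval_r=(0.0, 0.5, 0.0, 0.0, 0.0, 0.0))
        assert all(build_bivalent(mm, rng).chiasmate for _ in range(200))

    def test_bivalent_crossover_probability_is_twice_r(self, rng):
        mm = MarkerMap(interval_r=(0.0, 0.137, 0.0, 0.0, 0.0, 0.0))
        hits = sum(build_bivalent(mm, rng).chiasmate for _ in range(20_000))
        assert hits / 20_000 == pytest.approx(2 * 0.137, abs=0.01)

    def test_chromatid_recombinant_fraction_recovers_r(self, rng):
        # a bivalent crossover at rate 2r makes 2 of 4 chromatids recombinant
        mm = MarkerMap(interval_r=(0.0, 0.137, 0.0, 0.0, 0.0, 0.0))
        cfg = SimConfig(marker_map=mm, n_oocytes=50_000, seed=11)
        ova = simulate_oocytes(cfg)
        gametes = ova.origin[ova.n_chromatids == 1, 0, :]
        i_sc, i_cv = mm.locus_index("sc"), mm.locus_index("cv")
        frac = (gametes[:, i_sc] != gametes[:, i_cv]).mean()
        se = np.sqrt(0.137 * (1 - 0.137) / len(gametes))
        assert abs(frac - 0.137) < 4 * se


class TestApplyCrossovers:
    def test_sister_pair_rejected(self, default_map):
        with pytest.raises(ValueError, match="non-sister"):
            apply_crossovers(default_map, [(1, (0, 1))])

    def test_two_crossovers_same_interval_rejected(self, default_map):
        with pytest.raises(ValueError, match="one crossover per interval"):
            apply_crossovers(default_map, [(1, (0, 2)), (1, (1, 3))])

    def test_chromatid_conservation(self, atomic_map):
        # each parental allele at each locus appears exactly twice among products
        for bv in all_crossover_configs(atomic_map, intervals=(1, 2, 3)):
            origin = np.stack([c.origin for c in bv.chromatids])
            assert (origin.sum(axis=0) == 2).all()

    def test_single_crossover_makes_reciprocal_recombinants(self, atomic_map):
        bv = apply_crossovers(atomic_map, [(2, (0, 2))])  # cv-f exchange
        assert bv.chromatids[0].is_recombinant and bv.chromatids[2].is_recombinant
        assert not bv.chromatids[1].is_recombinant
        assert not bv.chromatids[3].is_recombinant
        # centromere origin never moves
        assert [c.homolog_origin for c in bv.chromatids] == [1, 1, 2, 2]
        assert bv.chromatids[0].scored_code == "mm++"
        assert bv.chromatids[2].scored_code == "++mm"


class TestResolveMeiosis:
    def test_no_error_limit(self, atomic_map, rng):
        cfg = SimConfig(marker_map=atomic_map, p_arm_loss=0.0, p_mii_loss=0.0)
        bv = apply_crossovers(atomic_map, [(1, (0, 2))])
        for _ in range(100):
            ovum = resolve_meiosis(bv, cfg, rng)
            assert ovum.error_class == "none" and len(ovum.chromatids) == 1

    def test_lost_chiasma_random_segregation(self, atomic_map, rng):
        cfg = SimConfig(
            marker_map=atomic_map, p_arm_loss=1.0, backup_enabled=False
        )
        bv = apply_crossovers(atomic_map, [(1, (0, 2))])
        outcomes = [resolve_meiosis(bv, cfg, rng) for _ in range(8000)]
        exc = sum(o.error_class != "none" for o in outcomes) / len(outcomes)
        assert exc == pytest.approx(0.5, abs=0.02)
        for o in outcomes:
            if len(o.chromatids) == 2:
                assert o.error_class == "MI"
                assert o.chromatids[0].homolog_origin != o.chromatids[1].homolog_origin

    def test_backup_rescues_all_mi_errors(self, atomic_map, rng):
        cfg = SimConfig(
            marker_map=atomic_map,
            p_arm_loss=1.0,
            backup_enabled=True,
            backup_efficiency=1.0,
            p_mii_loss=0.3,
        )
        ova = simulate_oocytes(
            SimConfig(**{**cfg.__dict__, "n_oocytes": 30_000, "seed": 5})
        )
        # only MII errors remain: exceptional frequency = p_mii_loss / 2
        assert ova.is_exceptional.mean() == pytest.approx(0.15, abs=0.01)
        assert not (ova.error_class == 1).any()


class TestSimulateOocytes:
    def test_reproducible_given_seed(self):
        cfg = SimConfig(n_oocytes=2000, seed=42, p_arm_loss=0.3, backup_enabled=False)
        a, b = simulate_oocytes(cfg), simulate_oocytes(cfg)
        assert np.array_equal(a.origin, b.origin)
        assert np.array_equal(a.error_class, b.error_class)
        assert np.array_equal(a.co, b.co)

    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("n_oocytes", 0, "n_oocytes"),
            ("p_arm_loss", 1.5, "p_arm_loss"),
            ("p_mii_loss", -0.1, "p_mii_loss"),
            ("backup_efficiency", 2.0, "backup_efficiency"),
        ],
    )
    def test_invalid_config_names_offending_field(self, field, value, match):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ValueError, match=match):
            simulate_oocytes(cfg)

    def test_obligate_chiasma_needs_recombination(self, zero_map):
        cfg = SimConfig(marker_map=zero_map, obligate_chiasma=True)
        with pytest.raises(ValueError, match="obligate_chiasma"):
            simulate_oocytes(cfg)

    def test_obligate_chiasma_all_chiasmate_and_all_normal(self):
        cfg = SimConfig(obligate_chiasma=True, n_oocytes=5000, seed=3)
        ova = simulate_oocytes(cfg)
        assert ova.co.any(axis=1).all()
        assert (ova.error_class == 0).all() and (ova.n_chromatids == 1).all()

    def test_mi_mii_homolog_origin_truth(self):
        cfg = SimConfig(
            p_arm_loss=0.5, p_mii_loss=0.1, backup_enabled=False,
            n_oocytes=30_000, seed=7,
        )
        ova = simulate_oocytes(cfg)
        diplo = ova.n_chromatids == 2
        ho = ova.homolog_origin
        mi, mii = ova.error_class == 1, ova.error_class == 2
        assert (mi & diplo).any() and (mii & diplo).any()
        assert (ho[mi & diplo, 0] != ho[mi & diplo, 1]).all()
        assert (ho[mii & diplo, 0] == ho[mii & diplo, 1]).all()

    def test_scalar_and_vector_paths_agree_statistically(self, rng):
        cfg = SimConfig(p_arm_loss=0.4, backup_enabled=False, n_oocytes=20_000, seed=9)
        vec = simulate_oocytes(cfg).is_exceptional.mean()
        scalar = 0
        n = 4000
        for _ in range(n):
            bv = build_bivalent(cfg.marker_map, rng)
            scalar += resolve_meiosis(bv, cfg, rng).error_class != "none"
        p = scalar / n
        se = np.sqrt(vec * (1 - vec) * (1 / n + 1 / cfg.n_oocytes)) or 1e-3
        assert abs(p - vec) < 4 * max(se, 0.005)


class TestOvumInvariants:
    def test_chromatid_count_error_class_consistency(self, atomic_map):
        c = Chromatid(np.zeros(atomic_map.n_loci, dtype=bool), atomic_map)
        with pytest.raises(ValueError):
            Ovum((c,), "MI")
        with pytest.raises(ValueError):
            Ovum((c, c), "none")
        with pytest.raises(ValueError, match="at most 2"):
            Ovum((c, c, c), "MI")

    def test_enumerated_diplo_ova_have_correct_origins(self, atomic_map):
        bv = apply_crossovers(atomic_map, [(2, (0, 2))])
        for ovum in enumerate_diplo_ova(bv):
            a, b = ovum.chromatids
            if ovum.error_class == "MI":
                assert a.homolog_origin != b.homolog_origin
            else:
                assert a.homolog_origin == b.homolog_origin
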