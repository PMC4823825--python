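"""Tests of the synthetic cohort generator: tree shapes, mixtures, expected
allele fractions and read sampling."""

import numpy as np
import pytest
from scipy import stats

from dipgevo.simulate import (SimulationConfig, TrueTumor, NORMAL,
                              simulate_clone_tree, assign_mutations,
                              simulate_region_mixtures, expected_vaf,
                              simulate_read_counts, simulate_baf_sites,
                              arm_clonal_state, simulate_cohort, write_cohort,
                              read_truth_json, InvalidConfigError)
from dipgevo.io import read_counts_tsv


class TestCloneTree:
    def test_single_clone_is_chain(self):
        t = simulate_clone_tree(SimulationConfig(n_clones=1, seed=0))
        assert t.parent == {1: NORMAL}

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_clones=5, seed=7)
        assert simulate_clone_tree(cfg).parent == simulate_clone_tree(cfg).parent

    def test_invalid_clone_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_clone_tree(SimulationConfig(n_clones=0))

    def test_attachment_uniform_over_topologies(self):
        # 4 clones: clone 3 picks among {1,2}, clone 4 among {1,2,3};
        # all 6 labeled topologies should appear with frequency 1/6.
        counts = {}
        n = 1200
        for seed in range(n):
            t = simulate_clone_tree(SimulationConfig(n_clones=4, seed=seed))
            key = (t.parent[2], t.parent[3], t.parent[4])
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 1e-3


class TestMutationAssignment:
    def test_template_drivers_land_on_requested_clones(self):
        cfg = SimulationConfig(n_clones=3, mutations_per_clone=2, seed=1)
        t = simulate_clone_tree(cfg)
        assign_mutations(t, cfg, [("H3F3A", "truncal"), ("TP53", "truncal"),
                                  ("PIK3CA", "subclone")])
        assert t.mutation_clone["H3F3A"] == 1
        assert t.mutation_clone["TP53"] == 1
        assert t.mutation_clone["PIK3CA"] != 1
        assert t.driver_labels["H3F3A"] == "main_driver"
        assert t.driver_labels["PIK3CA"] == "accessory_driver"

    def test_empty_template_all_passengers(self):
        cfg = SimulationConfig(n_clones=2, mutations_per_clone=3, seed=1)
        t = simulate_clone_tree(cfg)
        assign_mutations(t, cfg, [])
        assert set(t.driver_labels.values()) == {"passenger"}
        assert len(t.mutation_clone) == 6

    def test_absent_clone_reference_rejected(self):
        cfg = SimulationConfig(n_clones=2, seed=1)
        t = simulate_clone_tree(cfg)
        with pytest.raises(InvalidConfigError):
            assign_mutations(t, cfg, [("X", 9)])


class TestRegionMixtures:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_mixtures_sum_to_one_nonnegative(self, seed):
        cfg = SimulationConfig(n_clones=4, n_regions=6, seed=seed,
                               dropout_prob=0.3)
        t = simulate_clone_tree(cfg)
        simulate_region_mixtures(t, cfg)
        for mix in t.region_mixtures.values():
            assert abs(sum(mix.values()) - 1.0) < 1e-12
            assert min(mix.values()) >= 0.0

    def test_full_purity_single_clone(self):
        cfg = SimulationConfig(n_clones=1, n_regions=1, purity_range=(1, 1),
                               seed=0)
        t = simulate_clone_tree(cfg)
        simulate_region_mixtures(t, cfg)
        mix = t.region_mixtures["R1"]
        assert mix[1] == pytest.approx(1.0)
        assert mix[NORMAL] == pytest.approx(0.0)

    def test_dropout_creates_regional_absence_but_not_global(self):
        cfg = SimulationConfig(n_clones=4, n_regions=6, seed=3,
                               dropout_prob=0.4)
        t = simulate_clone_tree(cfg)
        simulate_region_mixtures(t, cfg)
        zero_somewhere = any(
            mix[c] == 0.0 for mix in t.region_mixtures.values()
            for c in t.clones if c != 1)
        assert zero_somewhere
        for c in t.clones:  # every clone observable in >= 1 region
            assert any(mix[c] > 0 for mix in t.region_mixtures.values())


def _one_clone_tumor(purity, event=None, arm="1p", **flags):
    t = TrueTumor(parent={1: NORMAL}, **flags)
    t.mutation_clone["m"] = 1
    t.mutation_arm["m"] = arm
    t.region_mixtures["R1"] = {1: purity, NORMAL: 1 - purity}
    if event:
        t.cnv_assignment[(1, arm)] = event
    return t


class TestExpectedVAF:
    def test_clonal_diploid_het_is_half(self):
        assert expected_vaf("m", "R1", _one_clone_tumor(1.0)) == pytest.approx(0.5)

    @pytest.mark.parametrize("p", [0.3, 0.6, 0.9])
    def test_truncal_neutral_scales_with_purity(self, p):
        assert expected_vaf("m", "R1", _one_clone_tumor(p)) == pytest.approx(p / 2)

    def test_duplication_of_wildtype_chromatid(self):
        t = _one_clone_tumor(1.0, "duplication")
        assert expected_vaf("m", "R1", t) == pytest.approx(1 / 3)

    def test_duplication_of_mutant_chromatid(self):
        t = _one_clone_tumor(1.0, "duplication", mutant_on_gained_copy=True)
        assert expected_vaf("m", "R1", t) == pytest.approx(2 / 3)

    def test_cn_loh_retaining_mutant_is_one(self):
        t = _one_clone_tumor(1.0, "cn_loh")
        assert expected_vaf("m", "R1", t) == pytest.approx(1.0)

    def test_monotone_in_carrier_fraction(self):
        vafs = [expected_vaf("m", "R1", _one_clone_tumor(p))
                for p in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(vafs, vafs[1:]))


class TestReadCounts:
    def test_zero_vaf_gives_zero_alt(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, alt = simulate_read_counts(0.0, 70, rng)
            assert alt == 0

    def test_deterministic_given_seed(self):
        a = simulate_read_counts(0.4, 100, np.random.default_rng(9))
        b = simulate_read_counts(0.4, 100, np.random.default_rng(9))
        assert a == b

    def test_mean_alt_fraction_converges(self):
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(1000):
            ref, alt = simulate_read_counts(0.5, 4000, rng)
            fracs.append(alt / (ref + alt))
        se = np.sqrt(0.25 / 4000 / 1000)
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_invalid_depth_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_read_counts(0.5, 0, np.random.default_rng(0))


class TestBafSites:
    def test_neutral_arm_expected_baf_half(self):
        t = _one_clone_tumor(0.8)
        baf, cn = arm_clonal_state("R1", "2q", t)
        assert baf == pytest.approx(0.5)
        assert cn == pytest.approx(2.0)

    def test_clonal_cn_loh_retained_allele_baf_one(self):
        t = _one_clone_tumor(1.0, "cn_loh")
        baf_altered, cn = arm_clonal_state("R1", "1p", t)
        assert baf_altered == pytest.approx(0.0)  # lost haplotype
        assert 1.0 - baf_altered == pytest.approx(1.0)
        assert cn == pytest.approx(2.0)

    def test_duplication_half_clonal_gained_allele(self):
        t = _one_clone_tumor(0.5, "duplication")
        baf, cn = arm_clonal_state("R1", "1p", t)
        assert baf == pytest.approx(1.5 / 2.5)
        assert cn == pytest.approx(2.5)

    def test_coverage_scales_with_copy_number(self):
        t = _one_clone_tumor(1.0, "duplication")
        cfg = SimulationConfig(n_clones=1, het_sites_per_arm=300, seed=2)
        _, cov = simulate_baf_sites("R1", t, cfg, np.random.default_rng(2))
        by_arm = dict((a, (tm, nm)) for a, tm, nm in cov)
        tm, nm = by_arm["1p"]
        assert tm / nm == pytest.approx(1.5, rel=0.06)
        tm2, nm2 = by_arm["2p"]
        assert tm2 / nm2 == pytest.approx(1.0, rel=0.06)


class TestCohortIO:
    def test_row_count_and_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_clones=4, n_regions=6, mutations_per_clone=5,
                               seed=8)
        cohort = simulate_cohort(cfg)
        n_mut = len(cohort.tumor.mutation_clone)
        assert len(cohort.variants) == n_mut * 6
        paths = write_cohort(cohort, tmp_path)
        obs = read_counts_tsv(paths["variants"])
        assert len(obs) == len(cohort.variants)
        back = {(o.mutation_id, o.sample_id): (o.ref_count, o.alt_count)
                for o in obs}
        for r in cohort.variants.itertuples():
            assert back[(r.mutation_id, r.sample_id)] == (r.ref_count, r.alt_count)

    def test_truth_json_round_trip(self, tmp_path):
        cohort = simulate_cohort(SimulationConfig(n_clones=3, seed=4))
        paths = write_cohort(cohort, tmp_path)
        t = read_truth_json(paths["truth"])
        assert t.parent == cohort.tumor.parent
        assert t.mutation_clone == cohort.tumor.mutation_clone
        assert t.cnv_assignment == cohort.tumor.cnv_assignment
        for r, mix in cohort.tumor.region_mixtures.items():
            for c, f in mix.items():
                assert t.region_mixtures[r][c] == pytest.approx(f)

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(n_clones=3, n_regions=2, seed=13)
        p1 = write_cohort(simulate_cohort(cfg), tmp_path / "a")
        p2 = write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
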