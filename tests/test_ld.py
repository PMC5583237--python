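"""Two-locus EM, LD statistics, decay profiles and LODE placement."""

import numpy as np
import pandas as pd
import pytest

from lodemap import (GeneticMapTable, SimulationConfig, em_haplotype_freqs,
                     ld_decay_profile, ld_pair_stats, lode_assign_lg,
                     lode_position, simulate_founders, simulate_true_map)
from lodemap.ld import LODEPlacement, ld_sample

from conftest import M, make_study


def study_from_genotype_pairs(g1, g2):
    codes = np.stack([g1, g2], axis=1).astype(np.int8)
    rows = [(f"s{i}", "", "", "M", "F1", "parent") for i in range(len(g1))]
    return make_study(codes, rows, marker_ids=["A", "B"])


class TestEM:
    def test_unambiguous_counting(self):
        # 40 AABB, 10 AAbb, 10 aaBB, 40 aabb -> direct gamete counting
        g1 = [0] * 50 + [2] * 50
        g2 = [0] * 40 + [2] * 10 + [0] * 10 + [2] * 40
        freqs, n, converged = em_haplotype_freqs(np.array(g1), np.array(g2))
        assert converged and n == 100
        assert np.allclose(freqs, [0.4, 0.1, 0.1, 0.4], atol=1e-9)

    def test_double_het_symmetry(self):
        g = np.ones(30, dtype=np.int8)
        freqs, _, _ = em_haplotype_freqs(g, g)
        assert freqs[0] == pytest.approx(freqs[3])
        assert freqs[1] == pytest.approx(freqs[2])

    def test_matches_phased_counting_without_ambiguity(self):
        """On tables with no double heterozygotes the EM equals counting."""
        rng = np.random.default_rng(12)
        hap_freqs = np.array([0.35, 0.15, 0.2, 0.3])
        n = 500
        while True:
            haps = rng.choice(4, size=(n, 2), p=hap_freqs)
            a = (haps // 2).sum(axis=1)
            b = (haps % 2).sum(axis=1)
            keep = ~((a == 1) & (b == 1))
            if keep.sum() > 100:
                break
        a, b, haps = a[keep], b[keep], haps[keep]
        freqs, _, _ = em_haplotype_freqs(a.astype(np.int8), b.astype(np.int8))
        expected = np.bincount(haps.ravel(), minlength=4) / (2 * keep.sum())
        assert np.allclose(freqs, expected, atol=1e-6)


class TestLDStats:
    def test_worked_example(self):
        d, dp, r2, ok = ld_pair_stats([0.4, 0.1, 0.1, 0.4])
        assert ok
        assert d == pytest.approx(0.15)
        assert dp == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_complete_ld(self):
        d, dp, r2, ok = ld_pair_stats([0.5, 0.0, 0.0, 0.5])
        assert dp == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_equilibrium(self):
        d, dp, r2, ok = ld_pair_stats([0.25, 0.25, 0.25, 0.25])
        assert d == pytest.approx(0.0) and r2 == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_undefined(self):
        *_, ok = ld_pair_stats([0.5, 0.5, 0.0, 0.0])
        assert not ok

    def test_r2_bounded_by_dprime(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            f = rng.dirichlet([1, 1, 1, 1])
            d, dp, r2, ok = ld_pair_stats(f)
            if not ok:
                continue
            assert 0.0 <= r2 <= 1.0 + 1e-12
            assert 0.0 <= dp <= 1.0 + 1e-9
            assert r2 <= dp + 1e-9


class TestFounderLD:
    def test_zero_switch_rate_copies_ancestors(self):
        # with 3 ancestral haplotypes at most 3 of the 4 two-locus gamete
        # classes can occur, so |D'| is forced to 1 for every pair
        config = SimulationConfig(n_lgs=1, markers_per_lg=12, lg_length=30.0,
                                  n_ancestral_haplotypes=3,
                                  mosaic_switch_rate=0.0, n_founders=40, seed=3)
        tmap = simulate_true_map(config)
        panel = simulate_founders(tmap, config)
        # every founder haplotype equals one ancestral haplotype end to end
        uniq = np.unique(panel.haplotypes, axis=0)
        assert len(uniq) <= 3
        # and adjacent-pair |D'| = 1 wherever both loci are polymorphic
        hap = panel.haplotypes
        for j in range(11):
            pA, pB = hap[:, j].mean(), hap[:, j + 1].mean()
            if 0 < pA < 1 and 0 < pB < 1:
                pAB = ((hap[:, j] == 0) & (hap[:, j + 1] == 0)).mean()
                d, dp, r2, ok = ld_pair_stats(
                    [pAB, (hap[:, j] == 0).mean() - pAB,
                     (hap[:, j + 1] == 0).mean() - pAB,
                     1 - (hap[:, j] == 0).mean() - (hap[:, j + 1] == 0).mean() + pAB])
                assert dp == pytest.approx(1.0, abs=1e-9)

    def test_high_switch_rate_reaches_sampling_floor(self):
        """Distant pairs decay to the finite-sample r2 floor ~ 1/n_hap."""
        config = SimulationConfig(n_lgs=1, markers_per_lg=10, lg_length=60.0,
                                  n_ancestral_haplotypes=10,
                                  mosaic_switch_rate=5.0, n_founders=100, seed=5)
        tmap = simulate_true_map(config)
        panel = simulate_founders(tmap, config)
        hap = panel.haplotypes.astype(float)
        pos = tmap.df["pos_cM"].to_numpy()
        r2s = []
        for i in range(10):
            for j in range(i + 1, 10):
                if pos[j] - pos[i] > 20:
                    a, b = hap[:, i], hap[:, j]
                    if a.std() > 0 and b.std() > 0:
                        r2s.append(np.corrcoef(a, b)[0, 1] ** 2)
        floor = 1.0 / hap.shape[0]
        assert np.mean(r2s) < 4 * floor

    def test_founder_maf_tracks_ancestral_frequency(self):
        config = SimulationConfig(n_lgs=1, markers_per_lg=20, lg_length=40.0,
                                  n_ancestral_haplotypes=2,
                                  mosaic_switch_rate=0.05, n_founders=100, seed=9)
        tmap = simulate_true_map(config)
        panel = simulate_founders(tmap, config)
        # with K = 2 polymorphic ancestral haplotypes each marker's ancestral
        # frequency is exactly 1/2; a 99% binomial band on 200 sampled
        # haplotypes is 0.5 +/- 2.58 sqrt(0.25 / 200)
        emp = panel.haplotypes.mean(axis=0)
        band = 2.58 * np.sqrt(0.25 / 200)
        assert np.all(np.abs(emp - 0.5) <= band + 1e-12)


def map_table(rows):
    return GeneticMapTable(pd.DataFrame(
        rows, columns=["marker_id", "lg", "pos_sexavg", "pos_f", "pos_m", "method"]))


class TestLODE:
    def test_position_is_r2_weighted_mean(self):
        p = LODEPlacement("x", "LG3", 3, 0.4,
                          support=[("a", 0.4, 10.0), ("b", 0.2, 12.0),
                                   ("c", 0.2, 14.0)])
        p = lode_position(p)
        assert p.position_cM == pytest.approx(11.5)
        assert p.max_r2_partner_position_cM == pytest.approx(10.0)

    def _synthetic_study(self, seed=21):
        """Orphan duplicated from a mapped marker: perfect LD to one group."""
        rng = np.random.default_rng(seed)
        n = 120
        lg1 = rng.integers(0, 3, size=(n, 4))
        lg2 = rng.integers(0, 3, size=(n, 4))
        orphan = lg1[:, 1].copy()
        codes = np.column_stack([lg1, lg2, orphan]).astype(np.int8)
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)] + ["orp"]
        rows = [(f"s{i}", "", "", "M", "F1", "parent") for i in range(n)]
        study = make_study(codes, rows, marker_ids=ids)
        gmap = map_table(
            [(f"a{i}", "LG1", float(i), np.nan, np.nan, "linkage") for i in range(4)]
            + [(f"b{i}", "LG2", float(i), np.nan, np.nan, "linkage") for i in range(4)])
        return study, gmap

    def test_assignment_rule(self):
        study, gmap = self._synthetic_study()
        # orphan is a copy of a1 and uncorrelated with LG2: a1 plus random
        # same-group partners must dominate
        placement = lode_assign_lg("orp", study, gmap, r2_min=0.1, min_pairs=1)
        assert placement.lg == "LG1"
        assert placement.max_r2 == pytest.approx(1.0)

    def test_min_pairs_gate(self):
        study, gmap = self._synthetic_study()
        placement = lode_assign_lg("orp", study, gmap, r2_min=0.1, min_pairs=4)
        assert not placement.assigned
        assert "min_pairs" in placement.reason

    def test_monomorphic_orphan_unassigned(self):
        study, gmap = self._synthetic_study()
        codes = study.genotypes.codes.copy()
        codes[:, -1] = 1
        codes[:, -1][0] = 1
        study2 = make_study(codes, [(s, "", "", "M", "F1", "parent")
                                    for s in study.sample_ids],
                            marker_ids=study.marker_ids)
        placement = lode_assign_lg("orp", study2, gmap)
        assert not placement.assigned

    def test_tie_between_groups_unassigned(self):
        """Identical LD support on two groups leaves the orphan unplaced."""
        rng = np.random.default_rng(33)
        n = 100
        base = rng.integers(0, 3, size=(n, 1))
        codes = np.column_stack([base, base, base]).astype(np.int8)
        rows = [(f"s{i}", "", "", "M", "F1", "parent") for i in range(n)]
        study = make_study(codes, rows, marker_ids=["a0", "b0", "orp"])
        gmap = map_table([("a0", "LG1", 0.0, np.nan, np.nan, "linkage"),
                          ("b0", "LG2", 0.0, np.nan, np.nan, "linkage")])
        placement = lode_assign_lg("orp", study, gmap, min_pairs=1)
        assert not placement.assigned
        assert "tied" in placement.reason


class TestDecayProfile:
    def test_profile_counts_and_empty_bins(self, small_sim):
        study, truth = small_sim
        gmap = map_table([
            (r.marker_id, r.lg, r.pos_cM, np.nan, np.nan, "linkage")
            for r in truth.true_map.df.itertuples()])
        prof = ld_decay_profile(study, gmap, [0, 5, 10, 20, 100, 200])
        assert (prof["bin"] == "adjacent").sum() == 1
        far = prof[prof["bin"] == "[100,200)"]
        assert int(far["n_pairs"].iloc[0]) == 0
        assert np.isnan(far["mean_r2"].iloc[0])

    def test_ld_declines_with_distance(self, small_sim):
        """Within-group mean r2 decreases across distance bins."""
        study, truth = small_sim
        gmap = map_table([
            (r.marker_id, r.lg, r.pos_cM, np.nan, np.nan, "linkage")
            for r in truth.true_map.df.itertuples()])
        prof = ld_decay_profile(study, gmap, [0, 3, 6, 12, 30])
        means = prof[prof["bin"] != "adjacent"]["mean_r2"].to_numpy()
        assert means[0] > means[-1]

    def test_sample_modes(self, small_sim):
        study, _ = small_sim
        parents = ld_sample(study, "parents")
        everyone = ld_sample(study, "all")
        assert set(parents) < set(everyone)
        gen = study.pedigree.df.set_index("sample_id")["generation"]
        assert all(gen[s] != "progeny" for s in parents)
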