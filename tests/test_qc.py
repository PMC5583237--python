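"""Marker QC statistics, exclusion ledgers and parent reconstruction."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from lodemap import (QCLedger, apply_qc_pipeline, detect_duplicates,
                     hwe_exact_test, insilico_snp_filter, mendelian_agreement,
                     reconstruct_parent_genotype, snp_summary)
from lodemap.qc import InsilicoThresholds, mask_mendelian_errors
from lodemap.simulate import SimulationConfig, simulate_study
from lodemap.errors import IntegrityError

from conftest import M, make_study, trio_rows


# ---------------------------------------------------------------------------
# exact HWE


def hwe_exact_oracle(n_het, n_hom1, n_hom2):
    """Independent enumeration with exact rational arithmetic."""
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            continue
        p = (Fraction(math.factorial(n),
                      math.factorial(h) * math.factorial(rare_hom)
                      * math.factorial(common_hom))
             * Fraction(2) ** h
             * Fraction(math.factorial(n_rare) * math.factorial(2 * n - n_rare),
                        math.factorial(2 * n)))
        probs[h] = p
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def test_hwe_balanced_counts_not_significant():
    # 25 AA / 50 Aa / 25 aa in 100 parents: textbook equilibrium
    p = hwe_exact_test(50, 25, 25)
    assert p > 0.9


def test_hwe_all_heterozygote_extreme():
    assert hwe_exact_test(100, 0, 0) < 1e-6


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_hwe_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(25):
        n = int(rng.integers(2, 51))
        h = int(rng.integers(0, n + 1))
        a = int(rng.integers(0, n - h + 1))
        b = n - h - a
        assert hwe_exact_test(h, a, b) == pytest.approx(
            hwe_exact_oracle(h, a, b), rel=1e-9)


# ---------------------------------------------------------------------------
# per-marker summary and Mendelian agreement


def test_snp_summary_monomorphic_and_maf():
    codes = [[0], [0], [0], [0]]
    rows = [(f"s{i}", "", "", "M", "F1", "parent") for i in range(4)]
    s = snp_summary(make_study(codes, rows))[0]
    assert s.maf == 0.0
    assert "monomorphic" in s.flags and "low_maf" in s.flags


def test_snp_summary_all_missing_marker_flagged():
    codes = [[M], [M]]
    rows = [("s1", "", "", "M", "F1", "parent"), ("s2", "", "", "F", "F1", "parent")]
    s = snp_summary(make_study(codes, rows))[0]
    assert s.call_rate == 0.0 and "no_amplify" in s.flags
    assert math.isnan(s.maf)


def test_mendelian_agreement_arithmetic():
    """agreement = 1 - errors / loci tested, per marker."""
    # family of 10 progeny over 2 markers; marker m2 carries 2 impossible calls
    rows = trio_rows(10)
    codes = np.ones((12, 2), dtype=np.int8)
    codes[0] = [0, 0]   # sire AA
    codes[1] = [0, 0]   # dam AA
    codes[2:] = [0, 0]  # progeny compatible
    codes[2, 1] = 1     # Aa progeny from AA x AA -> error
    codes[3, 1] = 2     # aa progeny -> error
    agr = mendelian_agreement(make_study(codes, rows))
    assert agr["m1"] == 1.0
    assert agr["m2"] == pytest.approx(1 - 2 / 10)


def test_trio_impossibility_single_parent():
    rows = [("p", "", "", "M", "F1", "parent"),
            ("c", "p", "", "U", "F1", "progeny")]
    codes = [[0], [2]]  # parent AA, child aa: impossible through one parent
    agr = mendelian_agreement(make_study(codes, rows))
    assert agr["m1"] == 0.0


def test_mask_mendelian_errors_blanks_only_bad_cells():
    rows = trio_rows(2)
    codes = np.array([[0, 0], [0, 0], [0, 2], [0, 0]], dtype=np.int8)
    masked = mask_mendelian_errors(make_study(codes, rows))
    assert masked.genotypes.genotype("F1_P1", "m2") == M
    assert masked.genotypes.genotype("F1_P1", "m1") == 0
    assert masked.genotypes.genotype("F1_P2", "m2") == 0


# ---------------------------------------------------------------------------
# duplicates


def test_duplicate_detection_rules():
    rng = np.random.default_rng(5)
    col = rng.integers(0, 3, size=60).astype(np.int8)
    noisy = col.copy()
    noisy[:6] = (noisy[:6] + 1) % 3  # 10% discordant
    codes = np.stack([col, col, noisy], axis=1)
    rows = [(f"s{i}", "", "", "M", "F1", "parent") for i in range(60)]
    pairs, flagged = detect_duplicates(make_study(codes, rows))
    assert [(a, b) for a, b, _ in pairs] == [("m1", "m2")]
    assert flagged == ["m2"]  # later-listed member flagged; no self-pairs


# ---------------------------------------------------------------------------
# exclusion ledger


def test_ledger_conservation_and_from_counts():
    ledger = QCLedger.from_counts(100, [("a", 10), ("b", 0), ("c", 25)])
    assert ledger.final_count == 65
    assert ledger.conserved()
    with pytest.raises(IntegrityError):
        ledger.add("overdraw", 99)


def test_qc_pipeline_clean_study_excludes_nothing():
    rng = np.random.default_rng(11)
    # 40 parents, balanced genotypes, no relationships: nothing to exclude
    codes = rng.choice([0, 1, 1, 2], size=(40, 6)).astype(np.int8)
    rows = [(f"s{i}", "", "", "M", "F1", "parent") for i in range(40)]
    filtered, ledger = apply_qc_pipeline(make_study(codes, rows))
    assert ledger.conserved()
    assert ledger.final_count == len(filtered.marker_ids)
    assert ledger.conversion_rate == 100.0
    assert ledger.validation_rate == 100.0
    assert ledger.final_rate == 100.0


def test_qc_pipeline_on_simulated_study(small_sim_noisy):
    study, truth = small_sim_noisy
    filtered, ledger = apply_qc_pipeline(study)
    assert ledger.conserved()
    assert set(filtered.marker_ids) <= set(study.marker_ids)
    labels = [lab for lab, _, _ in ledger.steps]
    assert labels == ["no_amplify", "ambiguous", "monomorphic", "hwe", "mi",
                      "mi_residual", "low_maf", "duplicate", "low_call",
                      "two_cluster"]


# ---------------------------------------------------------------------------
# in-silico candidate filter


def candidate_frame(rows):
    cols = ["contig_id", "position", "alleles", "read_depth",
            "minor_allele_reads", "maf_insilico", "snp_quality",
            "flanking_quality", "probe_type", "repeat_masked", "adt_score",
            "probe_unique"]
    return pd.DataFrame(rows, columns=cols)


def good(contig="c1", pos=1000, alleles="A/C", depth=30, minor=10, maf=0.4,
         squal=40, fqual=40, ptype="infiniumII", rep=False, adt=0.9, uniq=True):
    return (contig, pos, alleles, depth, minor, maf, squal, fqual, ptype, rep,
            adt, uniq)


def test_insilico_depth_threshold():
    df = candidate_frame([good(), good(pos=5000, depth=9)])
    surviving, ledger = insilico_snp_filter(df)
    assert len(surviving) == 1
    assert ledger.remaining_after("quality") == 1


def test_insilico_proximity_drops_both():
    df = candidate_frame([good(pos=1000), good(pos=1040), good(contig="c2")])
    surviving, ledger = insilico_snp_filter(df)
    assert list(surviving["contig_id"]) == ["c2"]
    assert ledger.steps[-1][1] == 2  # both members of the 40 bp pair


def test_insilico_proximity_keep_better_dialect():
    df = candidate_frame([good(pos=1000, depth=50), good(pos=1040, depth=12)])
    surviving, _ = insilico_snp_filter(
        df, InsilicoThresholds(proximity_rule="keep_better"))
    assert list(surviving["position"]) == [1000]


def test_insilico_class_filters():
    df = candidate_frame([
        good(),
        good(pos=2000, alleles="A/C/T"),       # multi-allelic
        good(pos=3000, alleles="A/T"),          # Infinium type I chemistry
        good(pos=4000, rep=True),               # repeat-masked
        good(pos=5000, adt=0.5),                # ADT below 0.7
        good(pos=6000, uniq=False),             # non-unique probe
    ])
    surviving, ledger = insilico_snp_filter(df)
    assert len(surviving) == 1
    assert [ex for _, ex, _ in ledger.steps] == [0, 1, 1, 1, 1, 1, 0]
    assert ledger.conserved()


# ---------------------------------------------------------------------------
# parent reconstruction


def reconstruction_study(dam_genotype, progeny_genotypes):
    n = len(progeny_genotypes)
    rows = trio_rows(n)
    codes = np.array([[M], [dam_genotype]] + [[g] for g in progeny_genotypes],
                     dtype=np.int8)
    return make_study(codes, rows)


def test_reconstruct_sire_all_hom_progeny():
    # dam AA, 10 progeny AA: sire AA has likelihood 1 vs (1/2)^10 for Aa
    study = reconstruction_study(0, [0] * 10)
    rec = reconstruct_parent_genotype(study, "F1_S", "F1_D",
                                      [f"F1_P{i + 1}" for i in range(10)])[0]
    assert rec.ml_genotype == 0
    assert rec.log_likelihoods[0] == pytest.approx(0.0)
    assert rec.log_likelihoods[1] == pytest.approx(10 * np.log(0.5))


def test_reconstruct_sire_het_dam_split_progeny():
    # dam Aa, progeny 5 AA + 5 Aa: sire AA beats Aa
    study = reconstruction_study(1, [0] * 5 + [1] * 5)
    rec = reconstruct_parent_genotype(study, "F1_S", "F1_D",
                                      [f"F1_P{i + 1}" for i in range(10)])[0]
    assert rec.ml_genotype == 0
    # enumeration: (1/2)^10 vs (1/4)^5 (1/2)^5
    assert np.exp(rec.log_likelihoods[0]) == pytest.approx(0.5 ** 10)
    assert np.exp(rec.log_likelihoods[1]) == pytest.approx(0.25 ** 5 * 0.5 ** 5)


def test_reconstruct_incompatible_flagged():
    study = reconstruction_study(0, [2])  # dam AA, progeny aa: impossible
    rec = reconstruct_parent_genotype(study, "F1_S", "F1_D", ["F1_P1"])[0]
    assert rec.incompatible and rec.ml_genotype == -1


def test_reconstruct_all_missing_progeny_undefined():
    study = reconstruction_study(0, [M, M])
    rec = reconstruct_parent_genotype(study, "F1_S", "F1_D",
                                      ["F1_P1", "F1_P2"])[0]
    assert rec.undefined


def test_reconstruction_recovery_on_simulation():
    """With clean genotypes and 20 progeny, >=99% of sire loci recovered."""
    config = SimulationConfig(n_lgs=2, markers_per_lg=15, lg_length=30.0,
                              n_families=6, progeny_per_family=20,
                              genotype_error_rate=0.0, missing_rate=0.0,
                              masked_parent_fraction=1.0, seed=17)
    study, truth = simulate_study(config)
    hits = total = 0
    for fam in ("F001", "F002", "F003", "F004", "F005", "F006"):
        sire = f"{fam}_SIRE"
        true_haps = truth.parent_haplotypes[sire]
        true_geno = true_haps[0] + true_haps[1]
        progeny = [s for s in study.sample_ids if s.startswith(f"{fam}_P")]
        recs = reconstruct_parent_genotype(study, sire, f"{fam}_DAM", progeny)
        for j, rec in enumerate(recs):
            assert not rec.incompatible  # clean data can never be flagged
            if rec.ml_genotype >= 0:
                total += 1
                hits += int(rec.ml_genotype == true_geno[j])
    assert total > 100
    assert hits / total >= 0.99
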