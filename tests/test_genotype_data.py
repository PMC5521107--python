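"""Genotype I/O and quality-control behaviour."""

import numpy as np
import pytest
from scipy import stats

from ldne import (AnimalRecord, GenotypeMatrix, QcConfig, SnpRecord,
                  apply_qc, assign_breed_group, call_rate, hwe_test,
                  ibs_duplicates, infer_sex, ld_snp_filter, maf_spectrum,
                  minor_allele_frequency, read_ped_map,
                  read_genotype_table, write_genotype_table, write_ped_map)
from ldne.genotype_data import hwe_pvalues, ibs_matrix


def _matrix(dosages, chroms=None, sexes=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chroms = chroms or ["1"] * m
    snps = [SnpRecord(f"s{j}", chroms[j], 100 * (j + 1)) for j in range(m)]
    animals = [AnimalRecord(f"a{i}", recorded_sex=(sexes[i] if sexes else "unknown"))
               for i in range(n)]
    return GenotypeMatrix(animals, snps, dosages)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestPedMapIO:
    def test_allele_pair_round_trip(self, tmp_path):
        ped = tmp_path / "x.ped"
        mp = tmp_path / "x.map"
        mp.write_text("1 s1 0 100\n1 s2 0 200\n1 s3 0 300\n")
        ped.write_text("F1 a1 0 0 1 -9 A A A G G G\n"
                       "F1 a2 0 0 2 -9 A G 0 0 G G\n")
        m = read_ped_map(ped, mp)
        assert m.n_animals == 2 and m.n_snps == 3
        # dosage counts the second allele seen per SNP
        assert m.dosages[0, 0] == 0 and m.dosages[1, 0] == 1
        assert np.isnan(m.dosages[1, 1])          # "0 0" is missing
        assert m.animals[1].recorded_sex == "female"
        out_ped, out_map = tmp_path / "y.ped", tmp_path / "y.map"
        write_ped_map(m, out_ped, out_map)
        m2 = read_ped_map(out_ped, out_map)
        np.testing.assert_array_equal(np.isnan(m.dosages), np.isnan(m2.dosages))

    def test_dimension_mismatch_is_an_error(self, tmp_path):
        mp = tmp_path / "x.map"
        mp.write_text("\n".join(f"1 s{j} 0 {100*j+100}" for j in range(4)) + "\n")
        ped = tmp_path / "x.ped"
        ped.write_text("F1 a1 0 0 1 -9 A A A A A A\n")   # 3 genotypes, 4 SNPs
        with pytest.raises(ValueError, match="x.ped:1"):
            read_ped_map(ped, mp)

    def test_genotype_table_round_trip(self, tmp_path):
        m = _matrix([[0, 1, 2], [2, np.nan, 0]])
        path = tmp_path / "g.tsv"
        write_genotype_table(m, path)
        m2 = read_genotype_table(path)
        np.testing.assert_array_equal(np.nan_to_num(m.dosages, nan=-1),
                                      np.nan_to_num(m2.dosages, nan=-1))
        assert [s.chromosome for s in m2.snps] == ["1", "1", "1"]


# ---------------------------------------------------------------------------
# per-SNP / per-animal statistics
# ---------------------------------------------------------------------------

class TestCallRateAndMaf:
    def test_call_rate(self):
        m = _matrix([[0, 1, np.nan, 2]])
        assert call_rate(m, "animal")[0] == pytest.approx(0.75)
        m2 = _matrix([[0, 1], [0, np.nan]])
        np.testing.assert_allclose(call_rate(m2, "snp"), [1.0, 0.5])
        assert call_rate(_matrix([[np.nan], [np.nan]]), "snp")[0] == 0.0

    @pytest.mark.parametrize("counts,expected", [
        ((25, 50, 25), 0.5),
        ((90, 10, 0), 0.05),
        ((100, 0, 0), 0.0),
    ])
    def test_maf_from_genotype_counts(self, counts, expected):
        rows = ([[0]] * counts[0] + [[1]] * counts[1] + [[2]] * counts[2])
        m = _matrix(rows)
        assert minor_allele_frequency(m)[0] == pytest.approx(expected)

    def test_maf_spectrum_hand_binned(self):
        spec = maf_spectrum(np.array([0.005, 0.05, 0.45]))
        np.testing.assert_allclose(
            spec.to_numpy(), [100 / 3, 100 / 3, 0, 0, 0, 0, 100 / 3])
        assert spec.sum() == pytest.approx(100.0)

    def test_maf_boundary_is_retained_by_ld_filter(self):
        rows = [[0]] * 90 + [[1]] * 10          # MAF exactly 0.05
        m = _matrix(rows)
        assert ld_snp_filter(m, 0.05).n_snps == 1


class TestHwe:
    def test_perfect_hwe(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    @pytest.mark.parametrize("counts,chi2", [
        ((0, 100, 0), 100.0),     # all hets: expected (25, 50, 25)
        ((50, 0, 50), 100.0),     # no hets at p = 0.5
    ])
    def test_extreme_departure_vs_chi_square_tail(self, counts, chi2):
        p = hwe_test(counts)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
        assert p < 1e-6

    def test_chisq_matches_independent_oracle_on_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            c = rng.integers(0, 200, 3)
            if c.sum() == 0:
                continue
            n = c.sum()
            p = (c[1] + 2 * c[2]) / (2 * n)
            if p in (0, 1):
                continue
            exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
            chi2 = (((c - exp) ** 2) / exp).sum()
            assert hwe_test(tuple(c)) == pytest.approx(
                stats.chi2.sf(chi2, 1), rel=1e-10)

    def test_exact_test_agrees_qualitatively(self):
        # both tests reject the all-het table and accept balance
        assert hwe_test((0, 100, 0), method="exact") < 1e-6
        assert hwe_test((25, 50, 25), method="exact") > 0.5

    def test_vectorised_pvalues_match_scalar(self):
        m = _matrix([[0], [1], [1], [2]])
        assert hwe_pvalues(m)[0] == pytest.approx(hwe_test((1, 2, 1)))


class TestSexInference:
    def test_no_heterozygotes_is_male(self):
        assert infer_sex(np.zeros(100)) == "male"

    def test_five_percent_heterozygous_is_female(self):
        x = np.zeros(100)
        x[:5] = 1
        assert infer_sex(x) == "female"

    def test_exact_threshold_is_male(self):
        x = np.zeros(100)
        x[:3] = 1                                  # exactly 3%
        assert infer_sex(x) == "male"

    def test_all_missing_is_unknown(self):
        assert infer_sex(np.full(10, np.nan)) == "unknown"


class TestIbs:
    def test_duplicate_rows_flagged_and_one_removed(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(3, 50)).astype(float)
        dos[2] = dos[0]
        m = _matrix(dos)
        pairs, removed = ibs_duplicates(m, 0.95, 2000, 0)
        assert [(p[0], p[1]) for p in pairs] == [("a0", "a2")]
        assert pairs[0][2] == pytest.approx(1.0)
        assert removed == {"a2"}                  # tie broken to later id

    def test_expected_ibs_under_hwe_half(self):
        # brute-force enumeration over genotype pairs at p = 0.5:
        # P(d) = (.25, .5, .25); E|di - dj| = 0.75 -> E(IBS) = 0.625
        probs = np.array([0.25, 0.5, 0.25])
        e_abs = sum(probs[i] * probs[j] * abs(i - j)
                    for i in range(3) for j in range(3))
        expect = (2 - e_abs) / 2
        assert expect == pytest.approx(0.625)
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.5, size=(2, 4000)).astype(float)
        ibs = ibs_matrix(dos)[0, 1]
        assert ibs == pytest.approx(expect, abs=0.02)

    def test_boundary_exactly_at_threshold_is_flagged(self):
        # 40 markers, 4 mismatches of one step: IBS = 1 - 2/40 = 0.95
        dos = np.zeros((2, 40))
        dos[1, :4] = 1.0
        m = _matrix(dos)
        pairs, _ = ibs_duplicates(m, 0.95, 2000, 0)
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(0.95)


# ---------------------------------------------------------------------------
# breed groups
# ---------------------------------------------------------------------------

def _brute_force_group(comp):
    """Independent re-statement of the grouping rules."""
    rom, coop = comp.get("Rom", 0), comp.get("Coop", 0)
    per, tex = comp.get("Peren", 0), comp.get("Tex", 0)
    if rom >= 0.75:
        return "Rom"
    if coop >= 0.75:
        return "Coop"
    if per >= 0.75:
        return "Peren"
    if tex >= 0.75:
        return "Tex"
    rcp = rom + coop + per
    if rcp > 0.5 and tex < 0.25:
        return "CompRCP"
    if rcp > 0.5 and tex >= 0.25:
        return "CompRCPT"
    if 0.3 < rcp <= 0.5:
        return "Comprcp2"
    return "unassigned"


class TestBreedGroups:
    @pytest.mark.parametrize("comp,expected", [
        ({"Rom": 0.8}, "Rom"),
        ({"Rom": 0.3, "Coop": 0.3, "Tex": 0.3}, "CompRCPT"),
        ({"Rom": 0.2, "Coop": 0.2, "Tex": 0.1}, "Comprcp2"),
        ({"Tex": 0.75}, "Tex"),
        ({"Rom": 0.4, "Coop": 0.2, "Tex": 0.1}, "CompRCP"),
        ({}, "unassigned"),
    ])
    def test_examples(self, comp, expected):
        assert assign_breed_group(comp) == expected

    def test_partition_on_composition_grid(self):
        # every grid composition gets exactly one label, matching the
        # independent evaluator
        step = 0.05
        vals = np.arange(0, 1.0001, step)
        for rom in vals:
            for coop in vals:
                for tex in vals:
                    if rom + coop + tex > 1:
                        continue
                    comp = {"Rom": rom, "Coop": coop, "Tex": tex}
                    assert assign_breed_group(comp) == _brute_force_group(comp)

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            assign_breed_group({"Rom": -0.1})


# ---------------------------------------------------------------------------
# the QC cascade
# ---------------------------------------------------------------------------

class TestApplyQc:
    def test_clean_matrix_passes_untouched(self):
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, rng.uniform(0.3, 0.7, 40)[None, :],
                           size=(50, 40)).astype(float)
        m = _matrix(dos)
        out, report = apply_qc(m, QcConfig(check_sex=False))
        assert out.n_snps == 40 and out.n_animals == 50
        assert report.n_snps_removed == 0 and report.n_animals_removed == 0

    def test_planted_defects_and_nothing_else(self, planted_qc):
        matrix, exp = planted_qc
        out, report = apply_qc(matrix, QcConfig())
        assert set(report.snps_removed["call_rate"]) == {exp["missing"]}
        assert set(report.snps_removed["maf"]) == {exp["mono"]}
        assert set(report.snps_removed["hwe"]) == {exp["hwe"]}
        assert set(report.snps_removed["non_autosomal"]) == exp["x_snps"]
        assert set(report.animals_removed["call_rate"]) == {exp["low_call"]}
        assert set(report.animals_removed["sex_mismatch"]) == {exp["missexed"]}
        assert len(report.animals_removed["ibs_duplicate"]) == 1
        assert report.animals_removed["ibs_duplicate"][0] in exp["dup_pair"]

    def test_idempotent(self, planted_qc):
        matrix, _ = planted_qc
        cfg = QcConfig()
        once, _ = apply_qc(matrix, cfg)
        twice, report2 = apply_qc(once, cfg)
        np.testing.assert_array_equal(
            np.nan_to_num(once.dosages, nan=-1),
            np.nan_to_num(twice.dosages, nan=-1))
        assert report2.n_snps_removed == 0
        assert report2.n_animals_removed == 0

    def test_combined_mode_requires_failure_in_every_group(self):
        rng = np.random.default_rng(11)
        n_per = 40
        groups = ["Rom"] * n_per + ["Coop"] * n_per
        # SNP 0: all-het in group 1 only; SNP 1: all-het in both groups
        base = rng.binomial(2, 0.5, size=(2 * n_per, 3)).astype(float)
        base[:n_per, 0] = 1.0
        base[:, 1] = 1.0
        comps = [{"Rom": 1.0}] * n_per + [{"Coop": 1.0}] * n_per
        snps = [SnpRecord(f"s{j}", "1", 100 * (j + 1)) for j in range(3)]
        animals = [AnimalRecord(f"a{i}", breed_composition=comps[i])
                   for i in range(2 * n_per)]
        m = GenotypeMatrix(animals, snps, base)
        _, report = apply_qc(m, QcConfig(mode="combined", check_sex=False),
                             groups=np.array(groups))
        assert report.snps_removed["hwe"] == ["s1"]

    def test_empty_result_is_an_error(self):
        m = _matrix([[0, 0], [0, 0]])              # all monomorphic
        from ldne.genotype_data import EmptyResultError
        with pytest.raises(EmptyResultError):
            apply_qc(m, QcConfig(check_sex=False))
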