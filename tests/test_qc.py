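"""QC cascade, HWE exact test, Mendel errors and sample-level QC."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from rarewin.qc import (
    QCConfig,
    count_mendel_errors,
    filter_variants,
    hwe_exact_test,
    inbreeding_coefficient,
    pihat_matrix,
    sample_qc,
    unrelated_sample_indices,
)

from conftest import make_matrix, make_pedigree, sibship_pedigree


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Independent exact-fraction enumeration of the conditional test."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        a, b = (n_ref - h) // 2, (n_alt - h) // 2
        weights[h] = Fraction(
            factorial(n) * 2**h, factorial(a) * factorial(h) * factorial(b)
        )
    total = sum(weights.values())
    p_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 0, 1), 1 / 3),  # h'∈{0,2}: Pr(0)=1/3 ≤ Pr(0), total 1/3
            ((0, 1, 0), 1.0),  # single compatible configuration
            ((7, 0, 0), 1.0),  # monomorphic
            ((0, 0, 5), 1.0),
        ],
    )
    def test_known_values(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_matches_enumeration_oracle_small(self):
        # exhaustive over all genotype configurations with ≤ 12 alleles
        # (the full ≤ 20 sweep lives in the acceptance suite)
        for n in range(1, 7):
            for het in range(n + 1):
                for hom_alt in range(n - het + 1):
                    hom_ref = n - het - hom_alt
                    got = hwe_exact_test(hom_ref, het, hom_alt)
                    want = hwe_oracle(hom_ref, het, hom_alt)
                    assert got == pytest.approx(want, rel=1e-9), (
                        hom_ref, het, hom_alt)


# ---------------------------------------------------------------------------
# Mendel errors
# ---------------------------------------------------------------------------

class TestMendelErrors:
    def _trio(self, df, dm, dc):
        G = make_matrix(np.array([[df], [dm], [dc]], dtype=float),
                        samples=["P1", "P2", "C"])
        ped = make_pedigree(
            [
                ("F1", "P1", None, None, 1, 0.0),
                ("F1", "P2", None, None, 2, 0.0),
                ("F1", "C", "P1", "P2", 1, 1.0),
            ]
        )
        return count_mendel_errors(G, ped)[0]

    def test_trio_rules(self):
        assert self._trio(0, 0, 1) == 1  # de novo ALT
        assert self._trio(0, 2, 1) == 0  # obligate het
        assert self._trio(0, 2, 0) == 1  # must receive one ALT from hom parent
        assert self._trio(2, 2, 2) == 0
        assert self._trio(np.nan, 0, 2) == 0  # missing parent skips trio rule

    def test_duo_impossibilities(self):
        G = make_matrix(np.array([[0.0, 2.0], [2.0, 0.0]]), samples=["P1", "C"])
        ped = make_pedigree(
            [
                ("F1", "P1", None, None, 1, 0.0),
                ("F1", "C", "P1", None, 1, 1.0),
            ]
        )
        err = count_mendel_errors(G, ped)
        # parent 0 with child 2, and parent 2 with child 0: both impossible
        np.testing.assert_array_equal(err, [1, 1])

    def test_duo_het_child_ok(self):
        G = make_matrix(np.array([[0.0], [1.0]]), samples=["P1", "C"])
        ped = make_pedigree(
            [
                ("F1", "P1", None, None, 1, 0.0),
                ("F1", "C", "P1", None, 1, 1.0),
            ]
        )
        assert count_mendel_errors(G, ped)[0] == 0


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

class TestFilterCascade:
    def test_hand_enumerated_toy(self, qc_toy):
        G, ped, af_table, expected = qc_toy
        out, report = filter_variants(G, ped, af_table)
        assert out.n_variants == 1
        assert out.variants.at[0, "pos"] == 800  # the clean variant
        got = dict(zip(report["filter"], report["removed"]))
        got.pop("input")
        assert got == expected

    def test_counts_are_conserved(self, qc_toy):
        G, ped, af_table, _ = qc_toy
        _, report = filter_variants(G, ped, af_table)
        prev = report.iloc[0]["remaining"]
        for _, row in report.iloc[1:].iterrows():
            assert prev == row["removed"] + row["remaining"]
            prev = row["remaining"]

    def test_empty_matrix(self, qc_toy):
        G, ped, af_table, _ = qc_toy
        empty = G.take_variants([])
        out, report = filter_variants(empty, ped, af_table)
        assert out.n_variants == 0
        assert (report["removed"] == 0).all()

    def test_all_pass_identity_and_idempotence(self, qc_toy):
        G, ped, af_table, _ = qc_toy
        once, rep1 = filter_variants(G, ped, af_table)
        twice, rep2 = filter_variants(once, ped, af_table)
        assert twice.n_variants == once.n_variants
        assert (rep2["removed"] == 0).all()
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_af_rule_disjunctive_vs_conjunctive(self, qc_toy):
        G, ped, _, _ = qc_toy
        # variant at pos 800: rare in NFE only
        af = pd.DataFrame(
            {
                "chrom": ["1"],
                "pos": [800],
                "ref": ["G"],
                "alt": ["A"],
                "AF_all": [0.02],
                "AF_nfe": [0.005],
            }
        )
        out_either, _ = filter_variants(G, ped, af, QCConfig())
        assert 800 in list(out_either.variants["pos"])
        out_both, _ = filter_variants(G, ped, af, QCConfig(af_either=False))
        assert 800 not in list(out_both.variants["pos"])

    def test_variant_absent_from_af_table_removed(self, qc_toy):
        G, ped, _, _ = qc_toy
        af = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "AF_all", "AF_nfe"]
        )
        out, _ = filter_variants(G, ped, af)
        assert out.n_variants == 0

    def test_allow_list_intersection(self, qc_toy):
        G, ped, af_table, _ = qc_toy
        out, rep = filter_variants(G, ped, af_table, allow_list=set())
        assert out.n_variants == 0
        assert rep.loc[rep["filter"] == "allow_list", "removed"].item() == 1

    def test_missing_af_columns_rejected(self, qc_toy):
        G, ped, _, _ = qc_toy
        with pytest.raises(ValueError, match="AF table"):
            filter_variants(G, ped, pd.DataFrame({"chrom": []}))


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

class TestSampleQC:
    def test_duplicate_sample_pihat_near_one(self):
        rng = np.random.default_rng(5)
        n_sites = 1500
        base = rng.binomial(2, rng.uniform(0.1, 0.4, n_sites), size=(6, n_sites))
        dosage = np.vstack([base, base[0]])  # sample 6 duplicates sample 0
        G = make_matrix(dosage.astype(float))
        pihat = pihat_matrix(G)
        assert pihat[0, 6] == pytest.approx(1.0, abs=0.05)
        # unrelated pairs stay near zero
        assert abs(pihat[1, 2]) < 0.1
        ped = make_pedigree(
            [("F%d" % i, f"S{i}", None, None, 1, 0.0) for i in range(7)]
        )
        flags = sample_qc(G, ped)
        dup = flags[flags["reason"] == "duplicate_or_related"]
        assert {"S0", "S6"} <= set(dup["iid"])

    def test_all_missing_sample_flagged_for_call_rate(self):
        dosage = np.array([[0.0, 1.0], [np.nan, np.nan], [1.0, 0.0]])
        G = make_matrix(dosage)
        ped = make_pedigree(
            [("F%d" % i, f"S{i}", None, None, 1, 0.0) for i in range(3)]
        )
        flags = sample_qc(G, ped)
        assert ("S1", "call_rate") in set(map(tuple, flags.to_numpy()))

    def test_inbreeding_near_zero_under_hwe(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.5, 800)
        dosage = rng.binomial(2, p, size=(60, 800)).astype(float)
        F = inbreeding_coefficient(make_matrix(dosage))
        se = F.std(ddof=1) / np.sqrt(len(F))
        assert abs(F.mean()) < 3 * se + 0.01

    def test_declared_sibs_with_low_pihat_flagged(self):
        rng = np.random.default_rng(3)
        # "siblings" simulated as unrelated: PI_HAT ≈ 0 < 0.2
        dosage = rng.binomial(2, rng.uniform(0.2, 0.4, 1000), size=(2, 1000))
        G = make_matrix(dosage.astype(float), samples=["F0_S0", "F0_S1"])
        ped = sibship_pedigree(1, sibs=2)
        flags = sample_qc(G, ped)
        assert set(flags.loc[flags["reason"] == "pedigree_mismatch", "iid"]) == {
            "F0_S0",
            "F0_S1",
        }


class TestUnrelatedSubset:
    def test_one_sibling_per_sibship_plus_founders(self):
        ped = make_pedigree(
            [
                ("F1", "A1", "X1", "X2", 1, 1.0),
                ("F1", "A2", "X1", "X2", 2, 0.0),
                ("F2", "B1", None, None, 1, 0.0),  # founder
                ("F3", "C1", "C_P", "C_M", 1, 1.0),
            ]
        )
        G = make_matrix(np.zeros((4, 1)), samples=["A1", "A2", "B1", "C1"])
        idx = unrelated_sample_indices(G, ped)
        assert [G.samples[i] for i in idx] == ["A1", "B1", "C1"]

    def test_offspring_of_genotyped_parent_excluded(self):
        ped = make_pedigree(
            [
                ("F1", "P1", None, None, 1, 0.0),
                ("F1", "P2", None, None, 2, 0.0),
                ("F1", "K1", "P1", "P2", 1, 1.0),
            ]
        )
        G = make_matrix(np.zeros((3, 1)), samples=["P1", "P2", "K1"])
        idx = unrelated_sample_indices(G, ped)
        assert [G.samples[i] for i in idx] == ["P1", "P2"]
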