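"""Shared fixtures: programmatic genotype/pedigree builders and the
hand-enumerated QC toy used by both the unit and acceptance suites."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rarewin.io import GenotypeMatrix, Pedigree


def make_matrix(
    dosage,
    chrom="1",
    start_pos=1000,
    samples=None,
    half_call=None,
    variants=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a dosage array with generated metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n_s, n_v = dosage.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n_s)]
    if variants is None:
        bases = ["A", "C", "G", "T"]
        variants = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.arange(start_pos, start_pos + 10 * n_v, 10),
                "id": None,
                "ref": [bases[i % 4] for i in range(n_v)],
                "alt": [bases[(i + 1) % 4] for i in range(n_v)],
                "multiallelic": False,
            }
        )
    if half_call is None:
        half_call = np.zeros_like(dosage, dtype=bool)
    return GenotypeMatrix(list(samples), variants, dosage, half_call)


def make_pedigree(rows) -> Pedigree:
    """rows: (fid, iid, father, mother, sex, affection) tuples."""
    return Pedigree(
        pd.DataFrame(
            rows, columns=["fid", "iid", "father", "mother", "sex", "affection"]
        )
    )


def sibship_pedigree(n_families: int, sibs: int = 2, affected: int = 1) -> Pedigree:
    """Families of ``sibs`` siblings with ungenotyped named parents."""
    rows = []
    for f in range(n_families):
        fid = f"F{f}"
        for s in range(sibs):
            rows.append(
                (fid, f"{fid}_S{s}", f"{fid}_P1", f"{fid}_P2", 1 + s % 2,
                 1.0 if s < affected else 0.0)
            )
    return make_pedigree(rows)


@pytest.fixture
def qc_toy():
    """The 8-variant QC cascade toy with its hand-enumerated outcome.

    Two sibships of two.  One variant per targeted filter, one clean
    survivor; expected removals per cascade stage are enumerated by hand.
    """
    samples = ["F1_S1", "F1_S2", "F2_S1", "F2_S2"]
    ped = make_pedigree(
        [
            ("F1", "F1_S1", "F1_P1", "F1_P2", 1, 1.0),
            ("F1", "F1_S2", "F1_P1", "F1_P2", 2, 0.0),
            ("F2", "F2_S1", "F2_P1", "F2_P2", 1, 1.0),
            ("F2", "F2_S2", "F2_P1", "F2_P2", 2, 0.0),
        ]
    )
    nan = np.nan
    # columns: v1 multiallelic, v2 monomorphic, v3 indel, v4 singleton,
    # v5 single-family doubleton, v6 half call, v7 common (AF 2%), v8 clean
    dosage = np.array(
        [
            # v1 v2 v3 v4 v5 v6  v7 v8
            [1, 0, 0, 0, 1, nan, 0, 0],
            [0, 0, 1, 0, 1, 1, 1, 1],
            [1, 0, 1, 1, 0, 0, 1, 1],
            [0, 0, 0, 0, 0, 1, 0, 0],
        ],
        dtype=float,
    )
    half = np.zeros_like(dosage, dtype=bool)
    half[0, 5] = True
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [100, 200, 300, 400, 500, 600, 700, 800],
            "id": None,
            "ref": ["G", "G", "GT", "G", "G", "G", "G", "G"],
            "alt": ["A,T", "A", "G", "A", "A", "A", "A", "A"],
            "multiallelic": [True] + [False] * 7,
        }
    )
    # ref != alt needed for the indel row; fix v3 alleles
    variants.loc[2, ["ref", "alt"]] = ["GT", "G"]
    G = GenotypeMatrix(samples, variants, dosage, half)
    af_table = pd.DataFrame(
        {
            "chrom": ["1", "1"],
            "pos": [700, 800],
            "ref": ["G", "G"],
            "alt": ["A", "A"],
            "AF_all": [0.02, 0.005],
            "AF_nfe": [0.02, 0.005],
        }
    )
    expected_removed = {
        "multiallelic": 1,
        "monomorphic": 1,
        "indel": 1,
        "singleton": 2,
        "half_call": 1,
        "mendel": 0,
        "call_rate": 0,
        "hwe": 0,
        "af_reference": 1,
        "allow_list": 0,
    }
    return G, ped, af_table, expected_removed
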