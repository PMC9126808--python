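"""Standard-format readers/writers and the internal genotype data model.

The pipeline's in-memory currency is :class:`GenotypeMatrix` — a samples ×
variants table of ALT-allele dosages in {0, 1, 2, missing} plus per-entry
half-call flags — together with :class:`Pedigree` for family structure.
All genomic coordinates are 1-based throughout, matching VCF.

VCF parsing is delegated to cyvcf2; writing uses a minimal VCF v4.2 text
emitter (GT only). Phased and unphased genotypes are treated identically:
only the dosage enters any downstream statistic.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_pedigree",
    "write_pedigree",
    "combine_pedigrees",
    "read_phenotypes",
    "write_phenotypes",
    "read_covariates",
    "write_covariates",
    "read_af_table",
    "write_af_table",
    "write_results",
    "read_results",
]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "multiallelic"]

#: required columns of the external allele-frequency reference table
AF_TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "AF_all", "AF_nfe"]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into the diploid GT data model."""


def _check_variant_order(variants: pd.DataFrame) -> None:
    """Require chromosome-grouped records with non-decreasing positions."""
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    seen: set[str] = set()
    prev_chrom = None
    for i, c in enumerate(chroms):
        if c != prev_chrom:
            if c in seen:
                raise ValueError(f"variants not grouped by chromosome (chrom {c!r} reappears)")
            seen.add(c)
            prev_chrom = c
        elif pos[i] < pos[i - 1]:
            raise ValueError(
                f"variants not sorted by position on chrom {c!r} at index {i} "
                f"({pos[i]} < {pos[i - 1]})"
            )


@dataclass
class GenotypeMatrix:
    """Samples × variants ALT-dosage matrix with per-variant metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt, multiallelic``,
        sorted by (chrom, pos) with chromosomes contiguous.
    dosage
        Float array of shape ``(n_samples, n_variants)``; entries are the
        number of ALT alleles (0/1/2) or NaN for missing.
    half_call
        Boolean array, same shape; True where the GT had exactly one
        missing allele (the dosage entry is then NaN as well).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    half_call: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.half_call = np.asarray(self.half_call, dtype=bool)
        n_s, n_v = len(self.samples), len(self.variants)
        if self.dosage.shape != (n_s, n_v) or self.half_call.shape != (n_s, n_v):
            raise ValueError(
                f"shape mismatch: {n_s} samples × {n_v} variants vs dosage "
                f"{self.dosage.shape}, half_call {self.half_call.shape}"
            )
        if n_v:
            if (self.variants["pos"] < 1).any():
                raise ValueError("positions must be ≥ 1 (1-based coordinates)")
            if (self.variants["ref"] == self.variants["alt"]).any():
                raise ValueError("ref allele equals alt allele")
            _check_variant_order(self.variants)
            with np.errstate(invalid="ignore"):
                bad = ~np.isnan(self.dosage) & ~np.isin(self.dosage, (0.0, 1.0, 2.0))
            if bad.any():
                raise ValueError("dosages must be in {0, 1, 2} or missing")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[str]:
        """``chrom:pos:ref:alt`` identifiers, the pipeline's variant keys."""
        v = self.variants
        return [
            f"{c}:{p}:{r}:{a}"
            for c, p, r, a in zip(v["chrom"], v["pos"], v["ref"], v["alt"])
        ]

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[idx],
            dosage=self.dosage[:, idx],
            half_call=self.half_call[:, idx],
        )

    def sample_index(self, iids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in iids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    def take_samples(self, iids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(iids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants,
            dosage=self.dosage[idx],
            half_call=self.half_call[idx],
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT genotypes from a VCF v4.x file (plain or gzipped).

    ``./.`` becomes missing; a half call such as ``./1`` becomes missing
    dosage with the half-call flag set.  Multiallelic records are retained
    with ``multiallelic=True`` (QC removes them); their dosage counts any
    non-reference allele.  Non-diploid GT entries are an error.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows = []
    dosages = []
    halves = []
    for lineno, v in enumerate(vcf, start=1):
        alts = v.ALT
        if not alts:
            alts = ["."]
        gts = v.genotypes
        dos = np.empty(len(samples))
        half = np.zeros(len(samples), dtype=bool)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise VcfParseError(
                    f"non-diploid GT for sample {samples[i]} at record {lineno} "
                    f"({v.CHROM}:{v.POS}); only diploid data are supported"
                )
            n_miss = sum(a < 0 for a in alleles)
            if n_miss == 2:
                dos[i] = np.nan
            elif n_miss == 1:
                dos[i] = np.nan
                half[i] = True
            else:
                dos[i] = sum(a > 0 for a in alleles)
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "id": v.ID if v.ID not in (None, ".") else None,
                "ref": v.REF,
                "alt": ",".join(alts),
                "multiallelic": len(alts) > 1,
            }
        )
        dosages.append(dos)
        halves.append(half)
    vcf.close()
    if rows:
        variants = pd.DataFrame(rows)
        dosage = np.column_stack(dosages)
        half_call = np.column_stack(halves)
    else:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
        dosage = np.empty((len(samples), 0))
        half_call = np.empty((len(samples), 0), dtype=bool)
    return GenotypeMatrix(samples, variants, dosage, half_call)


def _gt_string(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[d]


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes.

    Half calls are written as ``./.`` — the dosage matrix round-trips
    exactly, the half-call flag is an in-session annotation.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rarewin\n")
        for chrom in dict.fromkeys(G.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        v = G.variants
        for j in range(G.n_variants):
            gts = "\t".join(_gt_string(d) for d in G.dosage[:, j])
            vid = v.at[j, "id"]
            fh.write(
                f"{v.at[j, 'chrom']}\t{v.at[j, 'pos']}\t{vid if vid else '.'}\t"
                f"{v.at[j, 'ref']}\t{v.at[j, 'alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Pedigree (PED/FAM dialect)
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Six-column pedigree: fid, iid, father, mother, sex, affection.

    ``affection`` is 1.0 (affected), 0.0 (unaffected) or NaN (missing);
    missing parents are ``None``.  Parents referenced by id need not have
    their own row (ungenotyped parents of a sibship, the common case in
    the sibling-only discovery design).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = ["fid", "iid", "father", "mother", "sex", "affection"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"pedigree lacks columns {missing}")
        if t["iid"].duplicated().any():
            dup = t.loc[t["iid"].duplicated(), "iid"].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        self.table = t
        self._check_no_ancestry_cycles()

    def _check_no_ancestry_cycles(self) -> None:
        parents = {
            r.iid: tuple(p for p in (r.father, r.mother) if p is not None)
            for r in self.table.itertuples()
        }
        for start in parents:
            stack, seen = list(parents[start]), {start}
            while stack:
                cur = stack.pop()
                if cur == start:
                    raise ValueError(f"individual {start!r} is its own ancestor")
                if cur in seen or cur not in parents:
                    continue
                seen.add(cur)
                stack.extend(parents[cur])

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    @property
    def n_families(self) -> int:
        return self.table["fid"].nunique()

    def parent_ids(self) -> set[str]:
        t = self.table
        return set(t["father"].dropna()) | set(t["mother"].dropna())

    def founders(self) -> list[str]:
        t = self.table
        mask = t["father"].isna() & t["mother"].isna()
        return list(t.loc[mask, "iid"])

    def sibships(self) -> list[tuple[str, list[str]]]:
        """Groups of individuals sharing family id and both parent slots.

        Only rows with at least one named parent form sibships; the list
        preserves input order and includes singleton sibships.
        """
        t = self.table
        has_parent = t["father"].notna() | t["mother"].notna()
        groups: dict[tuple, list[str]] = {}
        for r in t[has_parent].itertuples():
            groups.setdefault((r.fid, r.father, r.mother), []).append(r.iid)
        return [(k[0], v) for k, v in groups.items()]

    def affection(self) -> pd.Series:
        return self.table.set_index("iid")["affection"]


_PHENO_DECODE = {"2": 1.0, "1": 0.0, "0": np.nan, "-9": np.nan, "−9": np.nan}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column whitespace-delimited PED/FAM file.

    PLINK conventions: parent id ``0`` → missing; PHENO 2 → affected,
    1 → unaffected, 0/−9 → missing.  Sex codes outside {0, 1, 2} raise a
    warning but are kept.
    """
    t = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        dtype=str,
        names=["fid", "iid", "father", "mother", "sex", "affection"],
        usecols=range(6),
    )
    for col in ("father", "mother"):
        t[col] = t[col].where(t[col] != "0", None)
    bad_sex = ~t["sex"].isin({"0", "1", "2"})
    if bad_sex.any():
        warnings.warn(
            f"unknown sex code(s) {sorted(t.loc[bad_sex, 'sex'].unique())} kept as-is",
            stacklevel=2,
        )
    t["sex"] = pd.to_numeric(t["sex"], errors="coerce")
    unknown = ~t["affection"].isin(_PHENO_DECODE)
    if unknown.any():
        raise ValueError(
            f"unknown PHENO code(s) {sorted(t.loc[unknown, 'affection'].unique())}"
        )
    t["affection"] = t["affection"].map(_PHENO_DECODE).astype(float)
    return Pedigree(t)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write PED with PHENO ∈ {1, 2} (0 for missing)."""
    t = ped.table.copy()
    t["father"] = t["father"].fillna("0")
    t["mother"] = t["mother"].fillna("0")
    pheno = t["affection"].map({1.0: 2, 0.0: 1}).fillna(0).astype(int)
    out = t[["fid", "iid", "father", "mother"]].copy()
    out["sex"] = t["sex"].fillna(0).astype(int)
    out["pheno"] = pheno
    out.to_csv(path, sep="\t", header=False, index=False)


def combine_pedigrees(*peds: Pedigree) -> Pedigree:
    """Concatenate cohort pedigrees (e.g., the two discovery family cohorts).

    Individual ids must be disjoint across cohorts; family ids are assumed
    cohort-specific.
    """
    tables = [p.table for p in peds]
    merged = pd.concat(tables, ignore_index=True)
    return Pedigree(merged)


# ---------------------------------------------------------------------------
# Phenotype / covariate / AF tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.Series:
    """TSV with columns (iid, affection 0/1) → Series indexed by iid."""
    t = pd.read_csv(path, sep="\t", dtype={"iid": str})
    if not {"iid", "affection"} <= set(t.columns):
        raise ValueError("phenotype table needs columns iid, affection")
    return t.set_index("iid")["affection"].astype(float)


def write_phenotypes(phen: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"iid": phen.index, "affection": phen.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_covariates(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"iid": str})
    if "iid" not in t.columns:
        raise ValueError("covariate table needs an iid column")
    return t.set_index("iid")


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index=True, index_label="iid")


def read_af_table(path: str | Path) -> pd.DataFrame:
    """External allele-frequency reference (gnomAD-style stand-in)."""
    t = pd.read_csv(path, sep="\t")
    missing = [c for c in AF_TABLE_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"AF table lacks columns {missing}")
    return t


def write_af_table(t: pd.DataFrame, path: str | Path) -> None:
    t[AF_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result TSV with p-value columns in scientific notation.

    Columns named ``p`` or starting with ``p_`` are rendered as ``%.6E``
    (seven significant digits); everything else uses pandas' default,
    round-trippable formatting.  Column order is preserved.
    """
    out = table.copy()
    for col in out.columns:
        if col == "p" or col.startswith("p_"):
            out[col] = [
                "" if pd.isna(x) else f"{float(x):.6E}" for x in out[col]
            ]
    out.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
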