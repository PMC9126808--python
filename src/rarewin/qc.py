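"""Variant- and sample-level quality control for WGS rare-variant analysis.

The variant filter cascade runs in a fixed order — multiallelic,
monomorphic, indel, singleton (dataset-wide or single-family), half-call,
Mendel errors, call rate, Hardy–Weinberg exact test, external
allele-frequency ceiling, optional allow-list — and reports per-filter
attrition.  The HWE exact test is the conditional test given allele
counts (sum of configuration probabilities not exceeding the observed
one), computed on founders/unrelated samples only since sibships violate
the HWE sampling assumptions.

Sample QC flags low call rate, extreme inbreeding coefficients and
pedigree/IBD mismatches using a PLINK-style method-of-moments estimator
of IBD sharing (PI_HAT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import GenotypeMatrix, Pedigree

__all__ = [
    "QCConfig",
    "hwe_exact_test",
    "count_mendel_errors",
    "filter_variants",
    "sample_qc",
    "unrelated_sample_indices",
    "inbreeding_coefficient",
    "pihat_matrix",
]


@dataclass
class QCConfig:
    """Thresholds of the QC cascade; defaults follow the analysis design."""

    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-8
    af_max: float = 0.01
    mendel_error_max: int = 0
    drop_indels: bool = True
    drop_singletons: bool = True
    drop_half_calls: bool = True
    #: keep a variant if EITHER external AF column is ≤ af_max (disjunctive
    #: reading of the frequency rule); set False for the conjunctive variant
    af_either: bool = True
    sample_call_rate_min: float = 0.95
    inbreeding_F_bounds: tuple[float, float] = (-0.15, 0.15)
    pihat_dup_threshold: float = 0.9
    pihat_sib_min: float = 0.2

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "af_max", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.hwe_p_min < 1:
            raise ValueError("hwe_p_min must be in (0, 1)")
        if self.mendel_error_max < 0:
            raise ValueError("mendel_error_max must be ≥ 0")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

_LOG2 = np.log(2.0)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE test given the allele counts.

    Enumerates every heterozygote count ``h`` compatible with the observed
    allele counts (same parity) and returns the total probability of
    configurations no more likely than the observed one — the standard
    two-sided exact test.  Monomorphic input has a single compatible
    configuration and returns 1.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    if rare == 0:
        return 1.0
    h = np.arange(rare % 2, rare + 1, 2)
    # P(h | n, allele counts) ∝ n! 2^h / (hom_ref! h! hom_alt!)
    logp = (
        h * _LOG2
        - gammaln((n_ref - h) / 2 + 1)
        - gammaln(h + 1)
        - gammaln((n_alt - h) / 2 + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[np.searchsorted(h, n_het)]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, np.exp(logsumexp(logp[logp <= p_obs + 1e-10]))))


# ---------------------------------------------------------------------------
# Mendel errors
# ---------------------------------------------------------------------------

def _allowed_child_table() -> np.ndarray:
    """allowed[df, dm, dc] — is child dosage dc possible given parents."""
    transmissible = {0: {0}, 1: {0, 1}, 2: {1}}
    allowed = np.zeros((3, 3, 3), dtype=bool)
    for df in range(3):
        for dm in range(3):
            for a in transmissible[df]:
                for b in transmissible[dm]:
                    allowed[df, dm, a + b] = True
    return allowed


_ALLOWED = _allowed_child_table()


def count_mendel_errors(G: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Per-variant count of Mendelian inconsistencies across trios/duos.

    Trios (both parents genotyped) use the full biallelic transmission
    table; duos check only the impossible transmissions (parent 0 with
    child 2, parent 2 with child 0).  Any missing genotype skips the check
    for that variant.
    """
    errors = np.zeros(G.n_variants, dtype=int)
    present = {s: i for i, s in enumerate(G.samples)}
    for r in ped.table.itertuples():
        ci = present.get(r.iid)
        if ci is None:
            continue
        fi = present.get(r.father) if r.father is not None else None
        mi = present.get(r.mother) if r.mother is not None else None
        dc = G.dosage[ci]
        if fi is not None and mi is not None:
            df, dm = G.dosage[fi], G.dosage[mi]
            ok = np.isnan(dc) | np.isnan(df) | np.isnan(dm)
            obs = ~ok
            if obs.any():
                bad = ~_ALLOWED[
                    df[obs].astype(int), dm[obs].astype(int), dc[obs].astype(int)
                ]
                errors[np.flatnonzero(obs)[bad]] += 1
        else:
            pi = fi if fi is not None else mi
            if pi is None:
                continue
            dp = G.dosage[pi]
            obs = ~np.isnan(dc) & ~np.isnan(dp)
            bad = obs & (((dp == 0) & (dc == 2)) | ((dp == 2) & (dc == 0)))
            errors += bad.astype(int)
    return errors


# ---------------------------------------------------------------------------
# Unrelated subset (for HWE)
# ---------------------------------------------------------------------------

def unrelated_sample_indices(G: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Indices of a founder/unrelated subset: genotyped founders plus one
    sibling per sibship whose parents are ungenotyped.

    Samples absent from the pedigree count as unrelated singletons.
    Offspring with a genotyped parent are excluded.
    """
    genotyped = set(G.samples)
    rows = {r.iid: r for r in ped.table.itertuples()}
    parent_ids = ped.parent_ids()
    seen_sibships: set[tuple] = set()
    keep = []
    for i, iid in enumerate(G.samples):
        r = rows.get(iid)
        if r is None:
            keep.append(i)
            continue
        if (r.father in genotyped) or (r.mother in genotyped):
            continue  # offspring of a genotyped parent
        if iid in parent_ids or (r.father is None and r.mother is None):
            keep.append(i)  # founder (married-in or parentless)
            continue
        sib_key = (r.fid, r.father, r.mother)
        if sib_key not in seen_sibships:
            seen_sibships.add(sib_key)
            keep.append(i)
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# Variant filter cascade
# ---------------------------------------------------------------------------

def _family_codes(G: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Integer family code per sample; samples not in the pedigree are
    singleton families of their own."""
    fid_of = dict(zip(ped.table["iid"], ped.table["fid"]))
    labels = [fid_of.get(s, f"__solo__{s}") for s in G.samples]
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def _hwe_pvalues(G: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    d = G.dosage[sample_idx]
    p = np.ones(G.n_variants)
    for j in range(G.n_variants):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        p[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return p


def filter_variants(
    G: GenotypeMatrix,
    ped: Pedigree,
    af_table: pd.DataFrame,
    cfg: QCConfig | None = None,
    allow_list: set[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the fixed-order variant QC cascade.

    Parameters
    ----------
    af_table
        External AF reference keyed by (chrom, pos, ref, alt) with columns
        ``AF_all`` and ``AF_nfe``; variants absent from the table are
        removed (conservative stand-in for external calling-quality
        lookups).
    allow_list
        Optional set of ``chrom:pos:ref:alt`` keys to intersect with.

    Returns
    -------
    (filtered matrix, report) where the report has one row per filter with
    the number of variants removed and remaining.
    """
    cfg = cfg or QCConfig()
    required = {"chrom", "pos", "ref", "alt", "AF_all", "AF_nfe"}
    missing = required - set(af_table.columns)
    if missing:
        raise ValueError(f"AF table lacks columns {sorted(missing)}")

    report_rows: list[tuple[str, int, int]] = []
    cur = G
    report_rows.append(("input", 0, cur.n_variants))

    def apply(name: str, remove_mask: np.ndarray) -> None:
        nonlocal cur
        remove_mask = np.asarray(remove_mask, dtype=bool)
        keep = np.flatnonzero(~remove_mask)
        removed = int(remove_mask.sum())
        if removed:
            cur = cur.take_variants(keep)
        report_rows.append((name, removed, cur.n_variants))

    # (1) multiallelic
    apply("multiallelic", cur.variants["multiallelic"].to_numpy(dtype=bool))

    # (2) monomorphic: no dosage variation among non-missing calls
    with np.errstate(all="ignore"):
        mono = np.array(
            [
                np.unique(col[~np.isnan(col)]).size <= 1
                for col in cur.dosage.T
            ]
        ) if cur.n_variants else np.zeros(0, dtype=bool)
    apply("monomorphic", mono)

    # (3) indels
    if cfg.drop_indels and cur.n_variants:
        indel = (
            cur.variants["ref"].str.len().to_numpy() != 1
        ) | (cur.variants["alt"].str.len().to_numpy() != 1)
    else:
        indel = np.zeros(cur.n_variants, dtype=bool)
    apply("indel", indel)

    # (4) singletons: one ALT allele overall, or all ALT alleles in one family
    if cfg.drop_singletons and cur.n_variants:
        ac = np.nansum(cur.dosage, axis=0)
        fam = _family_codes(cur, ped).astype(float)
        carrier = np.nan_to_num(cur.dosage) >= 1
        fmin = np.min(np.where(carrier, fam[:, None], np.inf), axis=0)
        fmax = np.max(np.where(carrier, fam[:, None], -np.inf), axis=0)
        single_family = carrier.any(axis=0) & (fmin == fmax)
        singleton = (ac == 1) | single_family
    else:
        singleton = np.zeros(cur.n_variants, dtype=bool)
    apply("singleton", singleton)

    # (5) any half call
    half = (
        cur.half_call.any(axis=0)
        if cfg.drop_half_calls and cur.n_variants
        else np.zeros(cur.n_variants, dtype=bool)
    )
    apply("half_call", half)

    # (6) Mendel errors
    mendel = count_mendel_errors(cur, ped) > cfg.mendel_error_max
    apply("mendel", mendel)

    # (7) call rate
    if cur.n_variants:
        call_rate = 1.0 - np.isnan(cur.dosage).mean(axis=0)
    else:
        call_rate = np.zeros(0)
    apply("call_rate", call_rate < cfg.call_rate_min)

    # (8) HWE exact test on founders/unrelated samples
    if cur.n_variants:
        hwe_p = _hwe_pvalues(cur, unrelated_sample_indices(cur, ped))
    else:
        hwe_p = np.zeros(0)
    apply("hwe", hwe_p < cfg.hwe_p_min)

    # (9) external AF ceiling
    if cur.n_variants:
        keys = pd.Index(cur.variant_keys())
        af = af_table.copy()
        af_keys = (
            af["chrom"].astype(str)
            + ":"
            + af["pos"].astype(str)
            + ":"
            + af["ref"]
            + ":"
            + af["alt"]
        )
        af = af.set_index(af_keys)
        af = af[~af.index.duplicated()]
        aligned = af.reindex(keys)
        with np.errstate(invalid="ignore"):
            ok_all = aligned["AF_all"].to_numpy() <= cfg.af_max
            ok_nfe = aligned["AF_nfe"].to_numpy() <= cfg.af_max
        keep_af = (ok_all | ok_nfe) if cfg.af_either else (ok_all & ok_nfe)
        keep_af &= ~aligned["AF_all"].isna().to_numpy() | ~aligned["AF_nfe"].isna().to_numpy()
        remove_af = ~np.nan_to_num(keep_af, nan=0.0).astype(bool)
    else:
        remove_af = np.zeros(0, dtype=bool)
    apply("af_reference", remove_af)

    # (10) optional allow-list intersection
    if allow_list is not None and cur.n_variants:
        in_list = np.array([k in allow_list for k in cur.variant_keys()])
        apply("allow_list", ~in_list)
    else:
        report_rows.append(("allow_list", 0, cur.n_variants))

    report = pd.DataFrame(report_rows, columns=["filter", "removed", "remaining"])
    return cur, report


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def _ibs_expectations(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """Per-dataset sums of P(IBS state | IBD state) over sites."""
    q = 1.0 - p
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p * q))
    e2_ibd1 = float(np.sum(p**2 + q**2))
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def pihat_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise PI_HAT (= P(IBD=1)/2 + P(IBD=2)) via method of moments.

    Identity-by-state counts are converted to IBD state probabilities
    using the sample allele frequencies (Purcell-style estimator without
    finite-sample bias corrections); estimates are clamped to [0, 1] and
    renormalised.  Sites monomorphic in the sample are ignored; missing
    genotypes are skipped per pair.
    """
    n = G.n_samples
    with np.errstate(all="ignore"):
        p_all = np.nanmean(G.dosage, axis=0) / 2.0
    poly = np.isfinite(p_all) & (p_all > 0) & (p_all < 1)
    d = G.dosage[:, poly]
    p = p_all[poly]
    pihat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            obs = ~np.isnan(d[i]) & ~np.isnan(d[j])
            if obs.sum() == 0:
                pihat[i, j] = pihat[j, i] = np.nan
                continue
            diff = np.abs(d[i, obs] - d[j, obs])
            n0 = float((diff == 2).sum())
            n1 = float((diff == 1).sum())
            n2 = float((diff == 0).sum())
            e0_0, e1_0, e2_0, e1_1, e2_1 = _ibs_expectations(p[obs])
            z0 = n0 / e0_0 if e0_0 > 0 else 0.0
            z1 = (n1 - z0 * e1_0) / e1_1 if e1_1 > 0 else 0.0
            z2 = (n2 - z0 * e2_0 - z1 * e2_1) / obs.sum()
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            if z.sum() == 0:
                z = np.array([1.0, 0.0, 0.0])
            z = z / z.sum()
            pihat[i, j] = pihat[j, i] = z[1] / 2 + z[2]
    return pihat


def inbreeding_coefficient(G: GenotypeMatrix) -> np.ndarray:
    """Per-sample F = 1 − observed het / expected het, with expected
    heterozygosity from the sample allele frequencies over polymorphic,
    non-missing sites.  NaN when no expected heterozygosity."""
    with np.errstate(all="ignore"):
        p = np.nanmean(G.dosage, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    F = np.full(G.n_samples, np.nan)
    if not poly.any():
        return F
    d = G.dosage[:, poly]
    exp_h = 2 * p[poly] * (1 - p[poly])
    obs_het = np.nansum(d == 1, axis=1).astype(float)
    exp_het = ((~np.isnan(d)) * exp_h).sum(axis=1)
    with np.errstate(all="ignore"):
        F = 1.0 - obs_het / exp_het
    return F


def sample_qc(
    G: GenotypeMatrix, ped: Pedigree, cfg: QCConfig | None = None
) -> pd.DataFrame:
    """Flag samples for call rate, inbreeding and pedigree/IBD mismatches.

    Returns a DataFrame with columns ``iid`` and ``reason``, one row per
    flag (a sample may appear more than once).
    """
    cfg = cfg or QCConfig()
    if G.n_samples < 2:
        raise ValueError("sample QC needs at least 2 samples")
    flags: list[tuple[str, str]] = []

    call_rate = 1.0 - np.isnan(G.dosage).mean(axis=1) if G.n_variants else np.ones(G.n_samples)
    for i in np.flatnonzero(call_rate < cfg.sample_call_rate_min):
        flags.append((G.samples[i], "call_rate"))

    F = inbreeding_coefficient(G)
    lo, hi = cfg.inbreeding_F_bounds
    for i in range(G.n_samples):
        if np.isfinite(F[i]) and not (lo <= F[i] <= hi):
            flags.append((G.samples[i], "inbreeding"))

    # pedigree consistency via PI_HAT
    pihat = pihat_matrix(G)
    idx = {s: i for i, s in enumerate(G.samples)}
    sib_pairs: set[tuple[int, int]] = set()
    same_family: set[tuple[int, int]] = set()
    for fid, group in ped.table.groupby("fid"):
        members = [idx[i] for i in group["iid"] if i in idx]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                same_family.add(tuple(sorted((members[a], members[b]))))
    for _, sibs in ped.sibships():
        members = [idx[s] for s in sibs if s in idx]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                sib_pairs.add(tuple(sorted((members[a], members[b]))))
    for i, j in sib_pairs:
        if np.isfinite(pihat[i, j]) and pihat[i, j] < cfg.pihat_sib_min:
            flags.append((G.samples[i], "pedigree_mismatch"))
            flags.append((G.samples[j], "pedigree_mismatch"))
    for i in range(G.n_samples):
        for j in range(i + 1, G.n_samples):
            if (i, j) in same_family:
                continue
            if np.isfinite(pihat[i, j]) and pihat[i, j] >= cfg.pihat_dup_threshold:
                flags.append((G.samples[i], "duplicate_or_related"))
                flags.append((G.samples[j], "duplicate_or_related"))
    return pd.DataFrame(sorted(set(flags)), columns=["iid", "reason"])
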