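"""Synthetic family and case-control cohorts for the rare-variant pipeline.

The generator emulates the statistical structure the analysis assumes,
not human genome realism: rare variants (AF ≤ 0.01) drawn from a founder
haplotype panel, multiplex sibships ascertained for ≥ 2 affected
siblings, Mendelian transmission without recombination within a
chromosome's simulated span (preserving within-window LD through
transmitted haplotypes), a logistic disease model with population
prevalence ≈ 0.15, an unrelated case/control cohort with covariates, and
optional two-subpopulation structure via subpopulation-private variants.

Every draw flows from a single seeded Generator, so a fixed seed yields
byte-identical output files.  A :class:`TruthRecord` carries the ground
truth (true AFs, causal windows, effect signs, subpopulation labels) for
parameter-recovery and power tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io import (
    GenotypeMatrix,
    Pedigree,
    write_af_table,
    write_covariates,
    write_pedigree,
    write_phenotypes,
    write_vcf,
)

__all__ = [
    "CausalWindow",
    "SimConfig",
    "HaplotypePanel",
    "TruthRecord",
    "simulate_founder_panel",
    "simulate_families",
    "simulate_case_control",
    "af_reference",
    "write_family_cohort",
    "write_case_control_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CausalWindow:
    """A disease-associated window on the simulated variant grid.

    ``effect_model`` is ``"unidirectional"`` (every variant raises risk by
    ``beta`` log-odds per allele) or ``"mixed"`` (signs alternate).
    """

    chrom: str
    window_index: int
    effect_model: str = "unidirectional"
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_model not in ("unidirectional", "mixed"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass
class SimConfig:
    n_families: int = 200
    sibs_per_family: tuple[int, int] = (2, 4)  # inclusive range
    n_cases: int = 500
    n_controls: int = 500
    n_chrom: int = 2
    variants_per_chrom: int = 100
    af_low: float = 1.0 / 20_000
    af_high: float = 0.01
    prevalence: float = 0.15
    causal_windows: tuple[CausalWindow, ...] = ()
    min_affected_sibs: int = 2
    n_subpops: int = 1
    fst_like_divergence: float = 0.5  # fraction of variants private per subpop
    window_k: int = 10  # truth-window size on the simulated variant grid
    mask_parents: bool = True
    n_panel_haplotypes: int = 4000  # founder pool size per subpopulation
    beta_center: float = 0.0  # optional covariate log-odds (case-control)
    beta_sex: float = 0.0
    max_attempts: int = 100_000  # ascertainment rejection cap per family
    seed: int = 0

    def __post_init__(self) -> None:
        if self.af_low <= 0:
            raise ValueError("af_low must be > 0")
        if not self.af_low <= self.af_high <= 0.01:
            raise ValueError("need af_low ≤ af_high ≤ 0.01 (rare variants only)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.variants_per_chrom < 0 or self.n_chrom < 1:
            raise ValueError("variant/chromosome counts must be non-negative")
        if self.sibs_per_family[0] < 1 or self.sibs_per_family[0] > self.sibs_per_family[1]:
            raise ValueError("invalid sibs_per_family range")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be ≥ 1")
        self.causal_windows = tuple(self.causal_windows)


@dataclass
class HaplotypePanel:
    """Founder haplotype pools, one array per chromosome per subpopulation.

    ``haplotypes[s][c]`` has shape (n_panel_haplotypes, n_variants) with
    0/1 entries; ``af[c]`` is the generating (true) allele frequency and
    ``private_to[c]`` the owning subpopulation (−1 = shared).
    """

    chroms: list[str]
    positions: list[np.ndarray]
    refs: list[np.ndarray]
    alts: list[np.ndarray]
    af: list[np.ndarray]
    private_to: list[np.ndarray]
    haplotypes: list[list[np.ndarray]]  # [subpop][chrom]
    n_subpops: int

    @property
    def n_variants(self) -> int:
        return int(sum(len(p) for p in self.positions))

    def variant_table(self) -> pd.DataFrame:
        frames = []
        for c, chrom in enumerate(self.chroms):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": self.positions[c],
                        "id": None,
                        "ref": self.refs[c],
                        "alt": self.alts[c],
                        "multiallelic": False,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["chrom", "pos", "id", "ref", "alt", "multiallelic"]
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class TruthRecord:
    variant_keys: list[str]
    true_af: list[float]
    causal_window_ids: list[str]
    effect_per_variant: dict[str, float]  # signed log-odds per allele
    subpop_of_sample: dict[str, int]
    intercept: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


# ---------------------------------------------------------------------------
# Founder panel
# ---------------------------------------------------------------------------

def simulate_founder_panel(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> HaplotypePanel:
    """Draw per-variant AFs uniformly in [af_low, af_high] and fill the
    founder pools with independent Bernoulli(AF) haplotypes per site.

    With ``n_subpops > 1``, a fraction ``fst_like_divergence`` of variants
    is private to each subpopulation (AF 0 elsewhere) — an idealised
    stand-in for divergence, sufficient for carrier-set structure.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    chroms = [str(c + 1) for c in range(cfg.n_chrom)]
    positions, refs, alts, afs, privs, haps = [], [], [], [], [], []
    for _ in chroms:
        V = cfg.variants_per_chrom
        pos = np.sort(rng.choice(np.arange(10_000, 10_000 + 400 * max(V, 1)), size=V, replace=False))
        ref_idx = rng.integers(0, 4, size=V)
        alt_idx = (ref_idx + rng.integers(1, 4, size=V)) % 4
        af = rng.uniform(cfg.af_low, cfg.af_high, size=V)
        if cfg.n_subpops > 1:
            # with prob fst_like_divergence a variant is private; owner uniform
            private = np.full(V, -1)
            is_priv = rng.random(V) < cfg.fst_like_divergence
            owners = rng.integers(0, cfg.n_subpops, size=V)
            private[is_priv] = owners[is_priv]
        else:
            private = np.full(V, -1)
        positions.append(pos)
        refs.append(_BASES[ref_idx])
        alts.append(_BASES[alt_idx])
        afs.append(af)
        privs.append(private)
    for s in range(cfg.n_subpops):
        per_chrom = []
        for c in range(cfg.n_chrom):
            af_s = np.where((privs[c] == -1) | (privs[c] == s), afs[c], 0.0)
            per_chrom.append(
                (rng.random((cfg.n_panel_haplotypes, cfg.variants_per_chrom)) < af_s)
                .astype(np.int8)
            )
        haps.append(per_chrom)
    return HaplotypePanel(
        chroms=chroms,
        positions=positions,
        refs=refs,
        alts=alts,
        af=afs,
        private_to=privs,
        haplotypes=haps,
        n_subpops=cfg.n_subpops,
    )


# ---------------------------------------------------------------------------
# Disease model
# ---------------------------------------------------------------------------

def _variant_keys(panel: HaplotypePanel) -> list[str]:
    keys = []
    for c, chrom in enumerate(panel.chroms):
        for p, r, a in zip(panel.positions[c], panel.refs[c], panel.alts[c]):
            keys.append(f"{chrom}:{p}:{r}:{a}")
    return keys


def _effect_vectors(cfg: SimConfig, panel: HaplotypePanel) -> list[np.ndarray]:
    """Signed per-allele log-odds per chromosome from the causal windows."""
    effects = [np.zeros(len(p)) for p in panel.positions]
    k = cfg.window_k
    for cw in cfg.causal_windows:
        try:
            c = panel.chroms.index(cw.chrom)
        except ValueError:
            raise ValueError(f"causal window chromosome {cw.chrom!r} not simulated")
        lo = cw.window_index * k
        if lo >= len(panel.positions[c]):
            raise ValueError(
                f"causal window {cw.chrom}:w{cw.window_index} beyond the "
                f"simulated variant grid"
            )
        hi = min(lo + k, len(panel.positions[c]))
        signs = np.ones(hi - lo)
        if cw.effect_model == "mixed":
            signs[1::2] = -1.0
        effects[c][lo:hi] = signs * cw.beta
    return effects


def _calibrate_intercept(
    cfg: SimConfig,
    panel: HaplotypePanel,
    effects: list[np.ndarray],
    rng: np.random.Generator,
) -> float:
    """Solve the logistic intercept so the unascertained population
    prevalence matches cfg.prevalence (1-D root finding on a large
    simulated score sample, tolerance 1e-3 on prevalence)."""
    if all(np.all(e == 0) for e in effects):
        return float(logit(cfg.prevalence))
    n_pop = 20_000
    scores = np.zeros(n_pop)
    for s in range(cfg.n_subpops):
        lo = s * n_pop // cfg.n_subpops
        hi = (s + 1) * n_pop // cfg.n_subpops
        for c in range(len(panel.chroms)):
            causal = np.flatnonzero(effects[c])
            if causal.size == 0:
                continue
            pool = panel.haplotypes[s][c][:, causal]
            idx = rng.integers(0, pool.shape[0], size=(hi - lo, 2))
            dos = pool[idx[:, 0]] + pool[idx[:, 1]]
            scores[lo:hi] += dos @ effects[c][causal]

    def excess(b0: float) -> float:
        return float(np.mean(expit(b0 + scores))) - cfg.prevalence

    return float(brentq(excess, -30.0, 10.0, xtol=1e-6))


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def _assemble_matrix(
    panel: HaplotypePanel, samples: list[str], rows_per_chrom: list[np.ndarray]
) -> GenotypeMatrix:
    dosage = np.concatenate(rows_per_chrom, axis=1).astype(float)
    variants = panel.variant_table()
    half = np.zeros_like(dosage, dtype=bool)
    return GenotypeMatrix(samples, variants, dosage, half)


def simulate_families(
    cfg: SimConfig, panel: HaplotypePanel, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, Pedigree, pd.Series, TruthRecord]:
    """Multiplex sibships under Mendelian transmission and ascertainment.

    Each family draws two founder parents from the panel; every sibling
    receives one haplotype per parent per chromosome (fair transmission,
    no recombination).  Affection is Bernoulli(expit(β₀ + Σ effects));
    families are redrawn until ≥ ``min_affected_sibs`` siblings are
    affected.  Parents are masked (genotypes withheld, ids retained in
    the pedigree) unless ``mask_parents=False``.
    """
    if panel.n_variants == 0:
        raise ValueError("founder panel is empty")
    rng = rng or np.random.default_rng(cfg.seed)
    effects = _effect_vectors(cfg, panel)
    b0 = _calibrate_intercept(cfg, panel, effects, rng)

    samples: list[str] = []
    rows: list[list[np.ndarray]] = [[] for _ in panel.chroms]
    ped_rows = []
    affection: dict[str, float] = {}
    subpop_of: dict[str, int] = {}

    lo_s, hi_s = cfg.sibs_per_family
    for f in range(cfg.n_families):
        fid = f"F{f:04d}"
        sub = int(rng.integers(0, cfg.n_subpops))
        accepted = None
        for _ in range(cfg.max_attempts):
            m = int(rng.integers(lo_s, hi_s + 1))
            par_hap = []  # per chrom: (4, V) father h1,h2, mother h1,h2
            child_dos = []
            score = np.zeros(m)
            for c in range(len(panel.chroms)):
                pool = panel.haplotypes[sub][c]
                ph = pool[rng.integers(0, pool.shape[0], size=4)]
                par_hap.append(ph)
                pick_f = rng.integers(0, 2, size=m)
                pick_m = rng.integers(0, 2, size=m)
                dos = ph[pick_f] + ph[2 + pick_m]
                child_dos.append(dos)
                score += dos @ effects[c]
            aff = rng.random(m) < expit(b0 + score)
            if aff.sum() >= cfg.min_affected_sibs:
                accepted = (m, par_hap, child_dos, aff)
                break
        if accepted is None:
            raise RuntimeError(
                f"ascertainment failed for family {fid}: could not obtain "
                f"{cfg.min_affected_sibs} affected siblings in "
                f"{cfg.max_attempts} attempts (prevalence {cfg.prevalence})"
            )
        m, par_hap, child_dos, aff = accepted
        father, mother = f"{fid}_P1", f"{fid}_P2"
        if not cfg.mask_parents:
            for pi, pid in enumerate((father, mother)):
                samples.append(pid)
                for c in range(len(panel.chroms)):
                    ph = par_hap[c]
                    rows[c].append(ph[2 * pi] + ph[2 * pi + 1])
                p_score = sum(
                    float((par_hap[c][2 * pi] + par_hap[c][2 * pi + 1]) @ effects[c])
                    for c in range(len(panel.chroms))
                )
                p_aff = float(rng.random() < expit(b0 + p_score))
                affection[pid] = p_aff
                subpop_of[pid] = sub
                ped_rows.append((fid, pid, None, None, 1 + pi, p_aff))
        for j in range(m):
            iid = f"{fid}_S{j + 1}"
            samples.append(iid)
            for c in range(len(panel.chroms)):
                rows[c].append(child_dos[c][j])
            affection[iid] = float(aff[j])
            subpop_of[iid] = sub
            ped_rows.append(
                (fid, iid, father, mother, int(rng.integers(1, 3)), float(aff[j]))
            )

    G = _assemble_matrix(
        panel, samples, [np.stack(r) for r in rows]
    )
    ped = Pedigree(
        pd.DataFrame(
            ped_rows,
            columns=["fid", "iid", "father", "mother", "sex", "affection"],
        )
    )
    phen = pd.Series(affection, name="affection")
    truth = _make_truth(cfg, panel, effects, subpop_of, b0)
    return G, ped, phen, truth


def _make_truth(cfg, panel, effects, subpop_of, b0) -> TruthRecord:
    keys = _variant_keys(panel)
    eff_flat = np.concatenate(effects) if effects else np.array([])
    causal_ids = sorted(
        {f"{cw.chrom}:w{cw.window_index}" for cw in cfg.causal_windows}
    )
    return TruthRecord(
        variant_keys=keys,
        true_af=[float(x) for x in np.concatenate(panel.af)] if panel.af else [],
        causal_window_ids=causal_ids,
        effect_per_variant={
            k: float(e) for k, e in zip(keys, eff_flat) if e != 0.0
        },
        subpop_of_sample=subpop_of,
        intercept=float(b0),
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# Case-control cohort
# ---------------------------------------------------------------------------

def simulate_case_control(
    cfg: SimConfig, panel: HaplotypePanel, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.Series, pd.DataFrame, TruthRecord]:
    """Unrelated replication cohort with covariates.

    Individuals are drawn from the panel until the case and control
    quotas fill; disease risk follows the same logistic model plus
    optional center/sex covariate effects.  Controls are 60 or older,
    cases 55 or older (age is a covariate, assigned given status).
    """
    if panel.n_variants == 0:
        raise ValueError("founder panel is empty")
    rng = rng or np.random.default_rng(cfg.seed)
    effects = _effect_vectors(cfg, panel)
    b0 = _calibrate_intercept(cfg, panel, effects, rng)

    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    kept_rows: list[list[np.ndarray]] = [[] for _ in panel.chroms]
    status: list[float] = []
    centers: list[str] = []
    sexes: list[int] = []
    subpops: list[int] = []
    total_cap = max(cfg.max_attempts, 50 * (need_cases + need_controls + 1))
    drawn = 0
    batch = 1024
    while (need_cases > 0 or need_controls > 0) and drawn < total_cap:
        n_b = batch
        drawn += n_b
        sub = rng.integers(0, cfg.n_subpops, size=n_b)
        center = rng.integers(0, 2, size=n_b)  # two sequencing centers
        sex = rng.integers(1, 3, size=n_b)
        score = np.zeros(n_b)
        dos_chrom = []
        for c in range(len(panel.chroms)):
            dos = np.empty((n_b, len(panel.positions[c])), dtype=np.int8)
            for s in range(cfg.n_subpops):
                mask = sub == s
                if not mask.any():
                    continue
                pool = panel.haplotypes[s][c]
                idx = rng.integers(0, pool.shape[0], size=(int(mask.sum()), 2))
                dos[mask] = pool[idx[:, 0]] + pool[idx[:, 1]]
            dos_chrom.append(dos)
            score += dos @ effects[c]
        eta = b0 + score + cfg.beta_center * center + cfg.beta_sex * (sex - 1)
        case = rng.random(n_b) < expit(eta)
        for i in range(n_b):
            if case[i] and need_cases > 0:
                need_cases -= 1
            elif not case[i] and need_controls > 0:
                need_controls -= 1
            else:
                continue
            for c in range(len(panel.chroms)):
                kept_rows[c].append(dos_chrom[c][i])
            status.append(float(case[i]))
            centers.append(f"C{center[i] + 1}")
            sexes.append(int(sex[i]))
            subpops.append(int(sub[i]))
    if need_cases > 0 or need_controls > 0:
        raise RuntimeError(
            f"could not fill case/control quotas ({need_cases} cases, "
            f"{need_controls} controls short) within the draw cap; "
            "prevalence or effect sizes too extreme"
        )
    n = len(status)
    samples = [f"CC{i:05d}" for i in range(n)]
    status_arr = np.array(status)
    age = np.where(
        status_arr == 1,
        rng.integers(55, 91, size=n),
        rng.integers(60, 91, size=n),
    )
    G = _assemble_matrix(panel, samples, [np.stack(r) for r in kept_rows])
    phen = pd.Series(status_arr, index=pd.Index(samples, name="iid"), name="affection")
    cov = pd.DataFrame(
        {"center": centers, "age": age, "sex": sexes},
        index=pd.Index(samples, name="iid"),
    )
    truth = _make_truth(cfg, panel, effects, dict(zip(samples, subpops)), b0)
    return G, phen, cov, truth


# ---------------------------------------------------------------------------
# On-disk cohort writers
# ---------------------------------------------------------------------------

def af_reference(panel: HaplotypePanel) -> pd.DataFrame:
    v = panel.variant_table()
    af = np.concatenate(panel.af) if panel.af else np.array([])
    return pd.DataFrame(
        {
            "chrom": v["chrom"],
            "pos": v["pos"],
            "ref": v["ref"],
            "alt": v["alt"],
            "AF_all": af,
            "AF_nfe": af,
        }
    )


def write_family_cohort(
    outdir: str | Path,
    cfg: SimConfig,
    panel: HaplotypePanel,
    G: GenotypeMatrix,
    ped: Pedigree,
    phen: pd.Series,
    truth: TruthRecord,
) -> dict[str, Path]:
    """Write VCF + PED + phenotype TSV + AF reference + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "families.vcf",
        "ped": outdir / "families.ped",
        "phen": outdir / "families.phen.tsv",
        "af": outdir / "af_reference.tsv",
        "truth": outdir / "families.truth.json",
    }
    write_vcf(G, paths["vcf"])
    write_pedigree(ped, paths["ped"])
    write_phenotypes(phen, paths["phen"])
    write_af_table(af_reference(panel), paths["af"])
    truth.to_json(paths["truth"])
    return paths


def write_case_control_cohort(
    outdir: str | Path,
    cfg: SimConfig,
    panel: HaplotypePanel,
    G: GenotypeMatrix,
    phen: pd.Series,
    cov: pd.DataFrame,
    truth: TruthRecord,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "casecontrol.vcf",
        "phen": outdir / "casecontrol.phen.tsv",
        "cov": outdir / "casecontrol.cov.tsv",
        "af": outdir / "af_reference.tsv",
        "truth": outdir / "casecontrol.truth.json",
    }
    write_vcf(G, paths["vcf"])
    write_phenotypes(phen, paths["phen"])
    write_covariates(cov, paths["cov"])
    write_af_table(af_reference(panel), paths["af"])
    truth.to_json(paths["truth"])
    return paths
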