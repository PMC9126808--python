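"""Fisher combined-probability meta-analysis and report assembly.

Discovery (family) and replication (case-control) p-values for a window
are combined with Fisher's method, X² = −2 Σ ln p_i ~ χ² with 2k degrees
of freedom under the joint null.  Discovery burden p-values pair with
replication burden p-values; discovery variance-component (SKAT)
p-values pair with replication SKAT-O.  Reports mirror the usual
top-regions layout: first/last SNV of the window, per-cohort p-values
and SNV counts, the Fisher statistic and the combined p, flagged against
the Bonferroni genome-wide threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "MetaResult",
    "fisher_combine",
    "chi2_survival",
    "bonferroni_threshold",
    "combine_discovery_replication",
    "assemble_results",
    "manhattan_table",
]


@dataclass
class MetaResult:
    p_values: tuple[float, ...]
    statistic: float  # X² = −2 Σ ln p
    df: int  # 2 × number of studies
    p: float
    window: str = ""


def chi2_survival(x: float, df: int) -> float:
    """Upper tail of the chi-square distribution (p-value of X²)."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be ≥ 0, got {x}")
    if df < 1:
        raise ValueError("df must be ≥ 1")
    return float(chi2.sf(x, df))


def fisher_combine(p_values, window: str = "") -> MetaResult:
    """Fisher's combined probability test over ≥ 2 study p-values."""
    ps = tuple(float(p) for p in p_values)
    if len(ps) < 2:
        raise ValueError("need at least two p-values to combine")
    for p in ps:
        if not 0 < p <= 1:
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    x2 = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * len(ps)
    return MetaResult(ps, x2, df, chi2_survival(x2, df), window)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Cross-stage combination
# ---------------------------------------------------------------------------

#: discovery test → replication p-value column it pairs with
_REPL_COLUMN = {"burden": "p_burden", "skat": "p_skato"}


def combine_discovery_replication(
    discovery: pd.DataFrame,
    replication: dict[str, pd.DataFrame],
    comparable: tuple[str, ...] | list[str],
) -> pd.DataFrame:
    """Fisher-combine each window's discovery p with the replication p of
    the cohorts marked ethnically comparable.

    Returns one row per (window, test) with the Fisher statistic, df and
    combined p (NaN when a replication p is unavailable for the window).
    """
    missing = [c for c in comparable if c not in replication]
    if missing:
        raise KeyError(f"comparable cohort(s) {missing} not among replication tables")
    repl_indexed = {name: t.set_index("window") for name, t in replication.items()}
    rows = []
    for r in discovery.itertuples():
        for test, repl_col in _REPL_COLUMN.items():
            p_disc = getattr(r, f"p_{test}")
            ps = [p_disc]
            ok = np.isfinite(p_disc) if p_disc is not None else False
            for name in comparable:
                t = repl_indexed[name]
                p_rep = (
                    t.at[r.window, repl_col] if r.window in t.index else np.nan
                )
                ps.append(p_rep)
                ok = ok and np.isfinite(p_rep) and p_rep > 0
            if ok:
                m = fisher_combine(ps, window=r.window)
                stat, df, p_meta = m.statistic, m.df, m.p
            else:
                stat, df, p_meta = np.nan, 2 * len(ps), np.nan
            rows.append(
                {
                    "window": r.window,
                    "test": test,
                    "fisher_stat": stat,
                    "df": df,
                    "p_meta": p_meta,
                }
            )
    return pd.DataFrame(rows)


def assemble_results(
    discovery: pd.DataFrame,
    replication: dict[str, pd.DataFrame],
    meta: pd.DataFrame,
    suggestive: float = 5e-6,
    bonferroni: float | None = None,
) -> pd.DataFrame:
    """Top-regions report: windows with discovery p ≤ suggestive under
    either test, one row per (window, test) that passes.

    Raises if the meta table lacks a window present in the discovery
    table's suggestive set.
    """
    repl_indexed = {name: t.set_index("window") for name, t in replication.items()}
    meta_indexed = meta.set_index(["window", "test"])
    rows = []
    for r in discovery.itertuples():
        for test in ("burden", "skat"):
            p_disc = getattr(r, f"p_{test}")
            if not (np.isfinite(p_disc) and p_disc <= suggestive):
                continue
            if (r.window, test) not in meta_indexed.index:
                raise KeyError(
                    f"meta table lacks window {r.window!r} / test {test!r}"
                )
            m = meta_indexed.loc[(r.window, test)]
            row = {
                "test": test,
                "window": r.window,
                "chrom": r.chrom,
                "first_snv": r.first_snv,
                "last_snv": r.last_snv,
                "p_discovery": p_disc,
                "n_sims": getattr(r, "n_sims", np.nan),
            }
            for name, t in repl_indexed.items():
                if r.window in t.index:
                    row[f"p_{name}"] = t.at[r.window, _REPL_COLUMN[test]]
                    row[f"n_snvs_{name}"] = t.at[r.window, "n_variants"]
                else:
                    row[f"p_{name}"] = np.nan
                    row[f"n_snvs_{name}"] = 0
            row["fisher_stat"] = m["fisher_stat"]
            row["p_meta"] = m["p_meta"]
            row["genome_wide"] = bool(
                bonferroni is not None
                and np.isfinite(m["p_meta"])
                and m["p_meta"] < bonferroni
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Manhattan data
# ---------------------------------------------------------------------------

def _pos_from_key(key: str) -> int:
    return int(key.split(":")[1])


def manhattan_table(
    scan: pd.DataFrame,
    p_columns: tuple[str, ...] = ("p_burden", "p_skat"),
    suggestive: float = 5e-6,
) -> pd.DataFrame:
    """Plot-ready table: per-window midpoint, −log10 p per test, and a
    cumulative genome coordinate (strictly increasing down the table)."""
    if len(scan) == 0:
        cols = ["window", "chrom", "midpoint", "cum_pos"] + [
            f"neglog10_{c}" for c in p_columns
        ] + ["suggestive_line"]
        return pd.DataFrame(columns=cols)
    first = scan["first_snv"].map(_pos_from_key)
    last = scan["last_snv"].map(_pos_from_key)
    mid = (first + last) / 2.0
    out = pd.DataFrame(
        {
            "window": scan["window"],
            "chrom": scan["chrom"],
            "midpoint": mid,
        }
    )
    offset = 0.0
    cum = np.empty(len(scan))
    for chrom in dict.fromkeys(scan["chrom"]):
        m = (scan["chrom"] == chrom).to_numpy()
        cum[m] = mid[m] + offset
        offset += float(last[m].max()) + 1.0
    out["cum_pos"] = cum
    with np.errstate(divide="ignore"):
        for c in p_columns:
            out[f"neglog10_{c}"] = -np.log10(scan[c].to_numpy(dtype=float))
    out["suggestive_line"] = -np.log10(suggestive)
    return out
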