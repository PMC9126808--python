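"""Partition post-QC rare variants into non-overlapping testing windows.

The testing unit is a run of up to ``k`` (default 10) consecutive post-QC
variants on one chromosome, in sorted genomic order.  Windows never span a
chromosome boundary; the final window of each chromosome may be shorter
than ``k`` and is tested like any other.  Windows are defined on variant
*order*; the base-pair span (first/last SNV position) is reported metadata
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import _check_variant_order

__all__ = ["Window", "build_windows", "map_windows_by_key", "windows_table"]


@dataclass(frozen=True)
class Window:
    """An ordered run of consecutive variants on one chromosome."""

    wid: str
    chrom: str
    variant_idx: tuple[int, ...]  # column indices into the post-QC matrix
    first_pos: int
    last_pos: int
    first_key: str = ""
    last_key: str = ""
    variant_keys: tuple[str, ...] = ()  # chrom:pos:ref:alt per member

    @property
    def size(self) -> int:
        return len(self.variant_idx)


def build_windows(variants: pd.DataFrame, k: int = 10) -> list[Window]:
    """Chunk sorted variants into consecutive sets of ``k`` per chromosome.

    Parameters
    ----------
    variants
        Variant table sorted by (chrom, pos) with chromosomes contiguous
        (e.g., ``GenotypeMatrix.variants`` after QC).
    k
        Window size in variants; the terminal window of each chromosome
        keeps its partial remainder.

    Returns
    -------
    list of Window covering every variant exactly once; the total count is
    Σ_chrom ⌈n_chrom / k⌉.
    """
    if k < 1:
        raise ValueError("window size k must be ≥ 1")
    if len(variants) == 0:
        return []
    _check_variant_order(variants)  # raises on unsorted input
    keys = [
        f"{c}:{p}:{r}:{a}"
        for c, p, r, a in zip(
            variants["chrom"], variants["pos"], variants["ref"], variants["alt"]
        )
    ]
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    windows: list[Window] = []
    start = 0
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for w, lo in enumerate(range(0, len(idx), k)):
            cols = idx[lo : lo + k]
            windows.append(
                Window(
                    wid=f"{chrom}:w{w}",
                    chrom=str(chrom),
                    variant_idx=tuple(int(c) for c in cols),
                    first_pos=int(pos[cols[0]]),
                    last_pos=int(pos[cols[-1]]),
                    first_key=keys[cols[0]],
                    last_key=keys[cols[-1]],
                    variant_keys=tuple(keys[c] for c in cols),
                )
            )
    return windows


def map_windows_by_key(
    windows: list[Window], target_variants: pd.DataFrame
) -> list[Window]:
    """Re-express windows against another cohort's post-QC variant table.

    Each window keeps its id and span but its variant indices point into
    the target matrix; variants absent there are dropped from the window
    (replication tests use the subset actually present).  Windows with no
    surviving variant are omitted.
    """
    target_keys = {
        f"{c}:{p}:{r}:{a}": i
        for i, (c, p, r, a) in enumerate(
            zip(
                target_variants["chrom"],
                target_variants["pos"],
                target_variants["ref"],
                target_variants["alt"],
            )
        )
    }
    mapped = []
    for w in windows:
        # reconstruct keys from the window's span membership
        cols = [
            target_keys[k]
            for k in w.variant_keys
            if k in target_keys
        ]
        if cols:
            mapped.append(
                Window(
                    wid=w.wid,
                    chrom=w.chrom,
                    variant_idx=tuple(cols),
                    first_pos=w.first_pos,
                    last_pos=w.last_pos,
                    first_key=w.first_key,
                    last_key=w.last_key,
                    variant_keys=tuple(w.variant_keys),
                )
            )
    return mapped


def windows_table(windows: list[Window]) -> pd.DataFrame:
    """Tabular summary (one row per window) for reporting."""
    return pd.DataFrame(
        {
            "window": [w.wid for w in windows],
            "chrom": [w.chrom for w in windows],
            "first_snv": [w.first_key for w in windows],
            "last_snv": [w.last_key for w in windows],
            "n_variants": [w.size for w in windows],
        }
    )
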