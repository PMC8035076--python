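"""Aggregate (meta-region) analysis: domains, loops, enhancer-promoter pairs.

Domain aggregates rescale each domain window (domain plus fractional flanks)
to a fixed pixel grid by area-weighted interpolation and average across
domains. Loop aggregates (APA) average fixed windows around anchor-pair
pixels; loop strength is the center pixel over a 3x3 distal-corner
background. Enhancer-promoter contact tables quantify the O/E at each
pair's pixel and feed both windowed aggregates and cross-condition
Wilcoxon rank-sum comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import BinTable, GenomicInterval
from .stats import rank_sum_test

__all__ = [
    "AggregateMatrix",
    "aggregate_domains",
    "aggregate_loops",
    "ep_contact_table",
    "ep_aggregate",
    "compare_pair_strength",
]


@dataclass
class AggregateMatrix:
    values: np.ndarray  # fixed-size square grid of mean O/E
    n_regions: int
    params: dict = field(default_factory=dict)


def _rescale_weights(n_src: int, n_dst: int) -> np.ndarray:
    """(n_dst x n_src) area-overlap weights; rows sum to 1 (conserves
    constants)."""
    w = np.zeros((n_dst, n_src))
    step = n_src / n_dst
    for t in range(n_dst):
        lo, hi = t * step, (t + 1) * step
        for s in range(int(np.floor(lo)), min(n_src, int(np.ceil(hi)))):
            w[t, s] = min(hi, s + 1) - max(lo, s)
    return w / w.sum(axis=1, keepdims=True)


def _rescale_block(block: np.ndarray, n_pixels: int) -> np.ndarray:
    """Area-weighted rescale, NaN-aware (weights renormalized over finite
    source pixels)."""
    w = _rescale_weights(block.shape[0], n_pixels)
    finite = np.isfinite(block)
    filled = np.where(finite, block, 0.0)
    num = w @ filled @ w.T
    den = w @ finite.astype(float) @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def aggregate_domains(
    oe: dict[str, np.ndarray],
    domains: Sequence[GenomicInterval],
    bins: BinTable,
    n_pixels: int = 40,
    flank_fraction: float = 0.5,
) -> AggregateMatrix:
    """Mean rescaled O/E over domain windows (domain +/- flank x length)."""
    if not domains:
        raise ValueError("empty domain list")
    acc = np.zeros((n_pixels, n_pixels))
    cnt = np.zeros((n_pixels, n_pixels))
    used = 0
    for dom in domains:
        block_oe = oe[dom.chrom]
        n = block_oe.shape[0]
        bs = bins.bin_size
        flank = int(round(flank_fraction * dom.width))
        lo = (dom.start - flank) // bs
        hi = -(-(dom.end + flank) // bs)
        if lo < 0 or hi > n:
            continue
        if hi - lo < 3 or (dom.end - dom.start) // bs < 3:
            continue
        grid = _rescale_block(block_oe[lo:hi, lo:hi], n_pixels)
        finite = np.isfinite(grid)
        acc[finite] += grid[finite]
        cnt[finite] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable domains (too short or out of bounds)")
    with np.errstate(invalid="ignore"):
        values = acc / cnt
    values[cnt == 0] = np.nan
    return AggregateMatrix(
        values, used, {"n_pixels": n_pixels, "flank_fraction": flank_fraction}
    )


def aggregate_loops(
    oe: dict[str, np.ndarray],
    loops: Sequence[tuple[GenomicInterval, GenomicInterval]],
    bins: BinTable,
    window_bins: int = 10,
) -> tuple[AggregateMatrix, float]:
    """APA: mean O/E window around anchor-pair pixels, plus loop strength.

    Loop strength = center pixel / mean of the 3x3 corner block on the
    distal (farther-from-diagonal) side. Pairs closer than window_bins + 1
    bins to the diagonal, or whose window leaves the chromosome, are skipped
    (counted in a warning).
    """
    w = window_bins
    size = 2 * w + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    used = skipped = 0
    for a1, a2 in loops:
        if a1.chrom != a2.chrom:
            skipped += 1
            continue
        block = oe[a1.chrom]
        n = block.shape[0]
        bs = bins.bin_size
        i, j = sorted((a1.mid // bs, a2.mid // bs))
        if j - i < w + 1 or i - w < 0 or j + w >= n:
            skipped += 1
            continue
        win = block[i - w : i + w + 1, j - w : j + w + 1]
        finite = np.isfinite(win)
        acc[finite] += win[finite]
        cnt[finite] += 1
        used += 1
    if used == 0:
        raise ValueError("all loops too close to the diagonal or out of bounds")
    if skipped:
        warnings.warn(f"{skipped} loop(s) skipped (diagonal proximity or bounds)")
    with np.errstate(invalid="ignore"):
        values = acc / cnt
    values[cnt == 0] = np.nan
    center = values[w, w]
    background = np.nanmean(values[:3, -3:])  # distal corner: low row, high col
    strength = float(center / background)
    agg = AggregateMatrix(values, used, {"window_bins": w})
    return agg, strength


def ep_contact_table(
    oe: dict[str, np.ndarray],
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
    bins: BinTable,
    min_separation: int = 10000,
    sample: str = "value",
) -> pd.DataFrame:
    """Per-pair center O/E values.

    Separation is the midpoint distance; pairs below ``min_separation`` are
    dropped. The center value is the mean O/E over the (enhancer-bin x
    promoter-bin) pixels when a feature spans more than one bin.
    """
    rows = []
    for enh, prom in pairs:
        if enh.chrom != prom.chrom:
            continue
        sep = abs(enh.mid - prom.mid)
        if sep < min_separation:
            continue
        block = oe[enh.chrom]
        bi = bins.bin_span(enh) - bins.offset(enh.chrom)
        bj = bins.bin_span(prom) - bins.offset(prom.chrom)
        vals = block[np.ix_(bi, bj)]
        center = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        rows.append(
            {
                "enh_chrom": enh.chrom, "enh_start": enh.start, "enh_end": enh.end,
                "prom_chrom": prom.chrom, "prom_start": prom.start,
                "prom_end": prom.end, "separation": sep, sample: center,
            }
        )
    return pd.DataFrame(rows)


def ep_aggregate(
    oe: dict[str, np.ndarray],
    table: pd.DataFrame,
    bins: BinTable,
    window_bp: int = 60000,
    value_column: str = "value",
) -> AggregateMatrix:
    """Mean O/E window (``window_bp`` wide) centered on each pair's pixel.

    At 2-kb bins a 60-kb window gives a 31 x 31 grid (2 * 15 + 1).
    """
    if table.empty:
        raise ValueError("empty pair table")
    w = window_bp // (2 * bins.bin_size)
    size = 2 * w + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    used = 0
    for row in table.itertuples():
        block = oe[row.enh_chrom]
        n = block.shape[0]
        bs = bins.bin_size
        i = (row.enh_start + row.enh_end) // 2 // bs
        j = (row.prom_start + row.prom_end) // 2 // bs
        i, j = sorted((i, j))
        if i - w < 0 or j + w >= n:
            continue
        win = block[i - w : i + w + 1, j - w : j + w + 1]
        finite = np.isfinite(win)
        acc[finite] += win[finite]
        cnt[finite] += 1
        used += 1
    if used == 0:
        raise ValueError("no pair window fits inside the matrix")
    with np.errstate(invalid="ignore"):
        values = acc / cnt
    values[cnt == 0] = np.nan
    return AggregateMatrix(values, used, {"window_bp": window_bp})


def compare_pair_strength(
    tables: dict[str, pd.DataFrame],
    control: str,
    grouping: Optional[pd.Series] = None,
    value_column: str = "value",
) -> pd.DataFrame:
    """Two-sided rank-sum tests of per-pair contact values, mutant vs control.

    ``tables`` maps condition name to an ep_contact_table output (same pairs
    in each). ``grouping`` optionally labels each pair row with an enhancer
    set; tests are run per set. Groups with fewer than 3 finite values yield
    a missing p-value with a warning.
    """
    conditions = [c for c in tables if c != control]
    ctrl = tables[control]
    if grouping is None:
        grouping = pd.Series(["all"] * len(ctrl), index=ctrl.index)
    rows = []
    for label in grouping.unique():
        sel = grouping == label
        x = ctrl.loc[sel, value_column].dropna().to_numpy()
        for cond in conditions:
            y = tables[cond].loc[sel, value_column].dropna().to_numpy()
            if len(x) < 3 or len(y) < 3:
                warnings.warn(f"{label}/{cond}: fewer than 3 values, p missing")
                p = np.nan
            else:
                p = rank_sum_test(y, x)
            rows.append(
                {"set": label, "condition": cond, "n_control": len(x),
                 "n_condition": len(y), "p_value": p}
            )
    return pd.DataFrame(rows)
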