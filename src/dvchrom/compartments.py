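"""A/B compartments: heterochromatin masking, eigenvector, saddle plots.

Pericentromeric heterochromatin is located from two H3K9me3 enrichment
tracks (e.g. two developmental stages) binned at 10 kb: bins enriched in both
are merged when closer than 25 kb, regions smaller than 20 kb are removed,
survivors within 100 kb are merged, and the largest remaining region per
chromosome is taken as the pericentromeric block.

The compartment signal is the first eigenvector of the Pearson correlation
matrix of the masked observed/expected map, computed per chromosome and
oriented so that it correlates positively with GC content (positive = A /
active). Compartmentalization strength is read off a saddle plot: bins are
ranked by a reference eigenvector, cut into quantiles, and the mean O/E
between quantile pairs is tabulated, with all zero-eigenvector bins collapsed
into a single extra row/column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome import BinTable, GenomicInterval, merge_intervals
from .matrix import ContactMatrix, observed_expected

__all__ = [
    "CompartmentTrack",
    "SaddleMatrix",
    "heterochromatin_mask",
    "compartment_eigenvector",
    "saddle",
]


@dataclass
class CompartmentTrack:
    """Signed per-bin eigenvector; 0 at masked or degenerate bins.
    Positive values correlate with higher GC (A compartment)."""

    bins: BinTable
    values: np.ndarray


@dataclass
class SaddleMatrix:
    """Quantile x quantile mean O/E, ordered most-negative to most-positive
    eigenvector, plus one collapsed row/column (last index) for
    zero-eigenvector bins."""

    values: np.ndarray  # (n_quantiles + 1) x (n_quantiles + 1)
    quantile_edges: np.ndarray
    strength: float


def heterochromatin_mask(
    track_a: np.ndarray,
    track_b: np.ndarray,
    bins: BinTable,
    merge_gap: int = 25000,
    min_region: int = 20000,
    final_merge_gap: int = 100000,
    threshold: float = 0.0,
) -> list[GenomicInterval]:
    """One pericentromeric region per chromosome from two enrichment tracks.

    A bin counts as enriched when its value exceeds ``threshold`` (log-ratio
    convention) in both tracks. Rule order: merge enriched bins with gaps
    < ``merge_gap``; drop regions < ``min_region``; merge survivors within
    ``final_merge_gap``; keep the largest region per chromosome.
    """
    if track_a.shape != (bins.n_bins,) or track_b.shape != (bins.n_bins,):
        raise ValueError("tracks must be per-bin on the given bin table")
    enriched = (track_a > threshold) & (track_b > threshold)
    out: list[GenomicInterval] = []
    for chrom in bins.chrom_sizes:
        s = bins.chrom_slice(chrom)
        idx = np.flatnonzero(enriched[s])
        if idx.size == 0:
            warnings.warn(f"no enriched bins on {chrom}; no region emitted")
            continue
        ivs = [
            GenomicInterval(
                chrom,
                bins.bin_interval(s.start + i).start,
                bins.bin_interval(s.start + i).end,
            )
            for i in idx
        ]
        regions = merge_intervals(ivs, gap=merge_gap - 1)
        regions = [r for r in regions if r.width >= min_region]
        if not regions:
            warnings.warn(f"no region >= {min_region} bp on {chrom}")
            continue
        regions = merge_intervals(regions, gap=final_merge_gap)
        out.append(max(regions, key=lambda r: r.width))
    return out


def compartment_eigenvector(
    matrix: ContactMatrix,
    mask: Sequence[GenomicInterval] = (),
    gc_track: Optional[np.ndarray] = None,
    oe: Optional[dict[str, np.ndarray]] = None,
    min_bins: int = 10,
) -> CompartmentTrack:
    """GC-oriented first eigenvector of the per-chromosome O/E correlation.

    Bins overlapping ``mask`` are excluded; chromosomes with fewer than
    ``min_bins`` usable bins are skipped with a warning. Masked and
    degenerate bins carry the value 0.
    """
    bins = matrix.bins
    if oe is None:
        oe = observed_expected(matrix)
    values = np.zeros(bins.n_bins)
    masked = np.zeros(bins.n_bins, dtype=bool)
    for region in mask:
        masked[bins.bin_span(region)] = True
    for chrom in bins.chrom_sizes:
        s = bins.chrom_slice(chrom)
        block = oe[chrom]
        usable = matrix.valid[s] & ~masked[s]
        usable &= np.isfinite(block).sum(axis=1) >= 2
        idx = np.flatnonzero(usable)
        if idx.size < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} usable bins, skipped")
            continue
        sub = block[np.ix_(idx, idx)]
        sub = np.where(np.isfinite(sub), sub, np.nanmean(sub))
        sd = sub.std(axis=0)
        keep = sd > 0
        idx = idx[keep]
        if idx.size < min_bins:
            warnings.warn(f"{chrom}: degenerate O/E, skipped")
            continue
        sub = sub[np.ix_(keep, keep)]
        corr = np.corrcoef(sub, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        lead = evecs[:, np.argmax(np.abs(evals))]
        ev = np.zeros(s.stop - s.start)
        ev[idx] = lead
        if gc_track is not None:
            gc = np.asarray(gc_track)[s][idx]
            if np.std(gc) > 0 and np.std(lead) > 0:
                r = np.corrcoef(lead, gc)[0, 1]
                if r < 0:
                    ev = -ev
        values[s] = ev
    return CompartmentTrack(bins, values)


def saddle(
    oe: dict[str, np.ndarray],
    reference: CompartmentTrack,
    n_quantiles: int = 50,
    corner_size: int = 1,
) -> SaddleMatrix:
    """Aggregate compartment plot against a reference eigenvector.

    Nonzero-eigenvector bins are ranked and cut into ``n_quantiles``
    equal-count groups (most negative first); zero-value bins form one
    collapsed extra row/column (last index). Entry (p, q) is the mean cis O/E
    over all pixel pairs with one bin in group p and one in group q.
    Strength = (mean BB corner + mean AA corner) / (2 x mean of the two
    anti-diagonal corners), using ``corner_size`` x ``corner_size`` blocks.
    """
    bins = reference.bins
    ev = reference.values
    nonzero = ev != 0
    if not nonzero.any():
        raise ValueError("all eigenvector values are zero")
    ranks = np.full(bins.n_bins, -1, dtype=np.int64)
    order = np.argsort(ev[nonzero], kind="stable")
    q = np.minimum(
        (np.arange(order.size) * n_quantiles) // order.size, n_quantiles - 1
    )
    tmp = np.empty(order.size, dtype=np.int64)
    tmp[order] = q
    ranks[nonzero] = tmp
    group = np.where(nonzero, ranks, n_quantiles)  # collapsed group = last

    nq = n_quantiles + 1
    sums = np.zeros((nq, nq))
    counts = np.zeros((nq, nq))
    for chrom in bins.chrom_sizes:
        s = bins.chrom_slice(chrom)
        block = oe[chrom]
        g = group[s]
        finite = np.isfinite(block)
        gi = g[:, None] * np.ones_like(g)[None, :]
        gj = np.ones_like(g)[:, None] * g[None, :]
        flat_g = (gi * nq + gj)[finite]
        np.add.at(sums, (flat_g // nq, flat_g % nq), block[finite])
        np.add.at(counts, (flat_g // nq, flat_g % nq), 1)
    with np.errstate(invalid="ignore"):
        values = sums / counts
    c = corner_size
    bb = np.nanmean(values[:c, :c])
    aa = np.nanmean(values[n_quantiles - c : n_quantiles, n_quantiles - c : n_quantiles])
    ab = np.nanmean(values[:c, n_quantiles - c : n_quantiles])
    ba = np.nanmean(values[n_quantiles - c : n_quantiles, :c])
    strength = float((bb + aa) / (ab + ba))
    edges = np.quantile(ev[nonzero], np.linspace(0, 1, n_quantiles + 1))
    return SaddleMatrix(values, edges, strength)
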