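"""Genomic coordinate system: intervals, chromosome sizes, bin tables, gene models.

All coordinates are 0-based half-open internally. Conversion to/from 1-based
inclusive happens only at the GFF3 format boundary (see :mod:`dvchrom.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "BinTable",
    "GeneModel",
    "interval_distance",
    "closest_feature",
    "bin_track",
    "merge_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : chromosome name
    start, end : base-pair coordinates, ``0 <= start < end``
    strand : '+', '-' or '.' (unstranded)
    name : optional label
    score : optional numeric score
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


class ChromSizes:
    """Ordered map of chromosome name -> length in bp."""

    def __init__(self, sizes: dict[str, int] | Sequence[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, L in items:
            if L <= 0:
                raise ValueError(f"chromosome {n} has non-positive length {L}")
        self._sizes: dict[str, int] = dict(items)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and list(self.items()) == list(
            other.items()
        )

    def check(self, interval: GenomicInterval) -> None:
        """Raise if the interval's chromosome is unknown or out of bounds."""
        if interval.chrom not in self._sizes:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self._sizes[interval.chrom]:
            raise ValueError(
                f"interval {interval} exceeds chromosome length "
                f"{self._sizes[interval.chrom]}"
            )


class BinTable:
    """Fixed-width binning of a genome.

    Bins tile each chromosome left to right; the last bin of a chromosome may
    be short. The global bin index is dense and contiguous, ordered by the
    chromosome order of ``chrom_sizes``.
    """

    def __init__(self, chrom_sizes: ChromSizes, bin_size: int):
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.chrom_sizes = chrom_sizes
        self.bin_size = int(bin_size)
        self._n_per_chrom: dict[str, int] = {}
        self._offsets: dict[str, int] = {}
        off = 0
        for chrom, L in chrom_sizes.items():
            n = -(-L // bin_size)  # ceil division
            self._n_per_chrom[chrom] = n
            self._offsets[chrom] = off
            off += n
        self.n_bins = off

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinTable)
            and self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
        )

    def n_bins_chrom(self, chrom: str) -> int:
        return self._n_per_chrom[chrom]

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self._n_per_chrom[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos``."""
        if chrom not in self._n_per_chrom:
            raise KeyError(f"unknown chromosome {chrom!r}")
        i = pos // self.bin_size
        if not 0 <= i < self._n_per_chrom[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return self._offsets[chrom] + i

    def bin_span(self, interval: GenomicInterval) -> np.ndarray:
        """Global indices of all bins overlapping the interval."""
        self.chrom_sizes.check(interval)
        first = interval.start // self.bin_size
        last = (interval.end - 1) // self.bin_size
        off = self._offsets[interval.chrom]
        return np.arange(off + first, off + last + 1)

    def bin_interval(self, index: int) -> GenomicInterval:
        for chrom, off in self._offsets.items():
            n = self._n_per_chrom[chrom]
            if off <= index < off + n:
                local = index - off
                start = local * self.bin_size
                end = min(start + self.bin_size, self.chrom_sizes[chrom])
                return GenomicInterval(chrom, start, end)
        raise IndexError(index)

    def to_frame(self) -> pd.DataFrame:
        """Bin table as a (chrom, start, end) DataFrame indexed by global id."""
        rows = []
        for chrom, L in self.chrom_sizes.items():
            starts = np.arange(0, L, self.bin_size)
            ends = np.minimum(starts + self.bin_size, L)
            rows.append(
                pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class GeneModel:
    """Genes, transcripts and derived promoter (TSS) positions.

    ``genes`` columns: gene_id, symbol, chrom, housekeeping (bool).
    ``transcripts`` columns: transcript_id, gene_id, chrom, start, end, strand.
    Every transcript has exactly one parent gene. The promoter is the 1-bp
    transcription start: transcript start on '+', transcript end - 1 on '-'.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.transcripts["gene_id"]) - set(self.genes["gene_id"])
        if missing:
            raise ValueError(f"transcripts with unknown parent genes: {missing}")
        if "housekeeping" not in self.genes.columns:
            self.genes = self.genes.assign(housekeeping=False)

    def promoters(self, gene_ids: Optional[Iterable[str]] = None) -> pd.DataFrame:
        """Unique TSS positions: columns chrom, pos, gene_id, transcript_id."""
        tx = self.transcripts
        if gene_ids is not None:
            keep = set(gene_ids)
            tx = tx[tx["gene_id"].isin(keep)]
        pos = np.where(tx["strand"] == "-", tx["end"] - 1, tx["start"])
        out = pd.DataFrame(
            {
                "chrom": tx["chrom"].to_numpy(),
                "pos": pos,
                "gene_id": tx["gene_id"].to_numpy(),
                "transcript_id": tx["transcript_id"].to_numpy(),
            }
        )
        return out.drop_duplicates(subset=["chrom", "pos", "gene_id"]).reset_index(
            drop=True
        )

    def promoter_windows(self, flank: int = 500) -> list[GenomicInterval]:
        """Symmetric windows of +/-``flank`` bp around every TSS."""
        out = []
        for row in self.promoters().itertuples():
            start = max(0, row.pos - flank)
            out.append(GenomicInterval(row.chrom, start, row.pos + flank + 1))
        return out


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap in bp between two intervals; 0 if they overlap; None if trans."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def _gap(a: GenomicInterval, b: GenomicInterval) -> tuple[int, int]:
    """Open interval strictly between two non-overlapping cis intervals."""
    if b.start >= a.end:
        return a.end, b.start
    return b.end, a.start


def closest_feature(
    query: GenomicInterval,
    subjects: Sequence[GenomicInterval],
    blockers: Sequence[GenomicInterval] = (),
) -> Optional[GenomicInterval]:
    """Nearest same-chromosome subject not separated from the query by a blocker.

    Distance is the end-to-start gap (0 on overlap). A blocker separates query
    and subject when it intersects the open interval strictly between them;
    an overlapping subject can never be blocked. Ties go to the subject with
    the smaller start coordinate.
    """
    best: Optional[GenomicInterval] = None
    best_key: Optional[tuple[int, int]] = None
    cis_blockers = [b for b in blockers if b.chrom == query.chrom]
    for s in subjects:
        d = interval_distance(query, s)
        if d is None:
            continue
        if d > 0:
            lo, hi = _gap(query, s)
            if any(b.start < hi and b.end > lo for b in cis_blockers):
                continue
        key = (d, s.start)
        if best_key is None or key < best_key:
            best, best_key = s, key
    return best


def bin_track(
    intervals: Sequence[GenomicInterval],
    bins: BinTable,
    reducer: str = "mean",
) -> np.ndarray:
    """Reduce scored intervals onto a bin grid, weighting by overlap length.

    ``mean`` averages over covered bases only (bases with no interval do not
    dilute the value); ``sum`` accumulates score x overlap-length. Bins with
    no overlapping interval are NaN.
    """
    if reducer not in ("mean", "sum"):
        raise ValueError(f"unknown reducer {reducer!r}")
    num = np.zeros(bins.n_bins)
    cov = np.zeros(bins.n_bins)
    for iv in intervals:
        if iv.score is None:
            raise ValueError(f"interval {iv} has no score")
        if iv.chrom not in bins.chrom_sizes:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        for j in bins.bin_span(iv):
            b = bins.bin_interval(j)
            ovl = min(iv.end, b.end) - max(iv.start, b.start)
            num[j] += iv.score * ovl
            cov[j] += ovl
    out = np.full(bins.n_bins, np.nan)
    hit = cov > 0
    if reducer == "mean":
        out[hit] = num[hit] / cov[hit]
    else:
        out[hit] = num[hit]
    return out


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge same-chromosome intervals whose gap is <= ``gap`` bp."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out
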