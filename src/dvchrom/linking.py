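"""Tissue-specific enhancer calling and enhancer-to-gene assignment.

Per-window differential H3K27ac statistics (150-bp windows with log-fold-
change and FDR per pairwise genotype contrast; the upstream window selection
and dispersion modeling are consumed, not reproduced) are merged into signed
enriched regions (gap tolerance 100 bp, maximum region width 5 kb,
region-level Simes FDR < 0.05, direction-consistent). A genotype's candidate
enhancers are the intersections of its regions enriched against both other
genotypes, excluding anything overlapping a promoter window. Candidate
target genes exclude housekeeping genes and genes below 1 TPM on average;
each enhancer is then assigned to a single gene by the first applicable
rule: (1) overlap with transcripts of exactly one candidate gene; (2)
closest promoter not separated by a domain boundary; (3) closest promoter
within the enhancer's domain; (4) closest promoter unconditionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneModel,
    GenomicInterval,
    closest_feature,
    interval_distance,
)
from .insulation import Boundary
from .stats import rank_sum_test, simes

__all__ = [
    "SignedRegion",
    "EnhancerAssignment",
    "merge_windows",
    "tissue_specific_regions",
    "filter_expressed_genes",
    "assign_enhancers",
    "validate_assignment_expression",
    "domain_size_comparison",
]

RULES = (
    "overlap_single_transcript",
    "closest_no_boundary",
    "closest_in_domain",
    "closest_any",
)


@dataclass(frozen=True)
class SignedRegion:
    chrom: str
    start: int
    end: int
    sign: int  # +1 or -1
    fdr: float

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class EnhancerAssignment:
    enhancer: GenomicInterval
    gene_id: str
    rule: str
    distance: int


def merge_windows(
    table: pd.DataFrame,
    contrast: str,
    tol_bp: int = 100,
    max_width_bp: int = 5000,
    fdr_max: float = 0.05,
    window_fdr_max: Optional[float] = None,
) -> list[SignedRegion]:
    """Merge significant differential windows of one contrast into signed
    regions.

    Windows with FDR < ``window_fdr_max`` (defaults to ``fdr_max``) are
    merged when gaps are <= ``tol_bp``; runs wider than ``max_width_bp`` are
    packed left-to-right into regions no wider than that cap. Region FDR is
    the Simes combination of member FDRs; regions are kept when that FDR is
    below ``fdr_max`` and every member log-fold-change shares one sign.
    """
    if window_fdr_max is None:
        window_fdr_max = fdr_max
    sub = table[(table["contrast"] == contrast) & (table["FDR"] < window_fdr_max)]
    if sub.empty:
        return []
    sub = sub.sort_values(["chrom", "start"])
    out: list[SignedRegion] = []
    for chrom, group in sub.groupby("chrom", sort=False):
        members: list[tuple[int, int, float, float]] = []
        runs: list[list] = []
        for row in group.itertuples():
            if members and row.start - members[-1][1] <= tol_bp:
                members.append((row.start, row.end, row.logFC, row.FDR))
            else:
                if members:
                    runs.append(members)
                members = [(row.start, row.end, row.logFC, row.FDR)]
        if members:
            runs.append(members)
        for run in runs:
            # greedy left-to-right packing under the width cap
            chunk: list[tuple[int, int, float, float]] = []
            chunks: list[list] = []
            for w in run:
                if chunk and w[1] - chunk[0][0] > max_width_bp:
                    chunks.append(chunk)
                    chunk = []
                chunk.append(w)
            if chunk:
                chunks.append(chunk)
            for ch in chunks:
                lfc = np.array([w[2] for w in ch])
                fdr = simes([w[3] for w in ch])
                if fdr >= fdr_max:
                    continue
                if not ((lfc > 0).all() or (lfc < 0).all()):
                    continue
                out.append(
                    SignedRegion(
                        chrom, ch[0][0], ch[-1][1],
                        1 if lfc[0] > 0 else -1, fdr,
                    )
                )
    return out


def _intersect(
    a: Sequence[SignedRegion], b: Sequence[SignedRegion]
) -> list[GenomicInterval]:
    out = []
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            lo = max(ra.start, rb.start)
            hi = min(ra.end, rb.end)
            if lo < hi:
                out.append(GenomicInterval(ra.chrom, lo, hi))
    return out


def tissue_specific_regions(
    regions_by_contrast: dict[str, Sequence[SignedRegion]],
    genotypes: Sequence[str],
    promoter_windows: Sequence[GenomicInterval] = (),
) -> dict[str, list[GenomicInterval]]:
    """Genotype-specific enhancer candidates from six signed contrasts.

    Genotype A's set is the span intersection of its positive regions in
    A-vs-B and A-vs-C, minus any region overlapping a promoter window.
    Contrast keys are '<a>_vs_<b>'.
    """
    out: dict[str, list[GenomicInterval]] = {}
    for g in genotypes:
        others = [o for o in genotypes if o != g]
        lists = []
        for o in others:
            key = f"{g}_vs_{o}"
            if key not in regions_by_contrast:
                raise KeyError(f"missing contrast {key!r}")
            lists.append(
                [r for r in regions_by_contrast[key] if r.sign > 0]
            )
        inter = _intersect(lists[0], lists[1])
        kept = [
            iv
            for iv in inter
            if not any(iv.overlaps(p) for p in promoter_windows)
        ]
        out[g] = [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=f"{g}_e{k}")
            for k, iv in enumerate(sorted(kept, key=lambda x: (x.chrom, x.start)))
        ]
    return out


def filter_expressed_genes(
    model: GeneModel,
    expression: pd.DataFrame,
    min_mean_tpm: float = 1.0,
) -> list[str]:
    """Candidate target genes: not housekeeping and mean TPM >= 1 across
    genotypes. Genes missing from the table count as TPM 0 with a warning."""
    genes = model.genes
    missing = set(genes["gene_id"]) - set(expression.index)
    if missing:
        warnings.warn(f"{len(missing)} gene(s) missing from expression table")
    means = expression.reindex(genes["gene_id"]).fillna(0.0).mean(axis=1)
    keep = (~genes["housekeeping"].to_numpy()) & (
        means.to_numpy() >= min_mean_tpm
    )
    return genes.loc[keep, "gene_id"].tolist()


def _promoter_intervals(model: GeneModel, gene_ids) -> list[GenomicInterval]:
    out = []
    for row in model.promoters(gene_ids).itertuples():
        out.append(GenomicInterval(row.chrom, row.pos, row.pos + 1, name=row.gene_id))
    return out


def assign_enhancers(
    enhancers: Sequence[GenomicInterval],
    candidate_genes: Sequence[str],
    model: GeneModel,
    boundaries: Sequence[Boundary] = (),
    domains: Sequence[GenomicInterval] = (),
) -> list[EnhancerAssignment]:
    """Assign each enhancer to one target gene by the first applicable rule.

    1. The enhancer overlaps transcripts of exactly one candidate gene.
    2. Closest promoter not separated from the enhancer by a boundary
       (the boundary bin strictly inside the open interval between them).
    3. Closest promoter inside the enhancer's domain.
    4. Closest promoter, unconstrained.

    Distances are enhancer edge to TSS (0 on overlap); ties go to the
    smaller coordinate. Enhancers with no candidate promoter on their
    chromosome are skipped with a warning.
    """
    candidates = set(candidate_genes)
    proms = _promoter_intervals(model, candidates)
    blockers = [b.interval() for b in boundaries]
    tx = model.transcripts[model.transcripts["gene_id"].isin(candidates)]
    out: list[EnhancerAssignment] = []
    for enh in enhancers:
        hit_genes = set(
            tx.loc[
                (tx["chrom"] == enh.chrom)
                & (tx["start"] < enh.end)
                & (enh.start < tx["end"]),
                "gene_id",
            ]
        )
        if len(hit_genes) == 1:
            out.append(
                EnhancerAssignment(enh, next(iter(hit_genes)),
                                   "overlap_single_transcript", 0)
            )
            continue
        cis = [p for p in proms if p.chrom == enh.chrom]
        if not cis:
            warnings.warn(f"no candidate promoter on {enh.chrom}; {enh} unassigned")
            continue
        best = closest_feature(enh, cis, blockers)
        if best is not None:
            out.append(
                EnhancerAssignment(
                    enh, best.name, "closest_no_boundary",
                    interval_distance(enh, best),
                )
            )
            continue
        dom = next(
            (d for d in domains if d.chrom == enh.chrom and d.start <= enh.mid < d.end),
            None,
        )
        if dom is not None:
            inside = [p for p in cis if dom.start <= p.start < dom.end]
            best = closest_feature(enh, inside)
            if best is not None:
                out.append(
                    EnhancerAssignment(
                        enh, best.name, "closest_in_domain",
                        interval_distance(enh, best),
                    )
                )
                continue
        best = closest_feature(enh, cis)
        out.append(
            EnhancerAssignment(
                enh, best.name, "closest_any", interval_distance(enh, best)
            )
        )
    return out


def validate_assignment_expression(
    assignments: dict[str, Sequence[EnhancerAssignment]],
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Rank-sum comparison of target-gene TPM: matching genotype vs others.

    For each genotype's enhancer set, the TPM of assigned target genes in
    that genotype is compared with the same genes' TPM in each other
    genotype (unpaired two-sided test). Sets with fewer than 3 genes yield
    missing p-values with a warning.
    """
    rows = []
    genotypes = list(expression.columns)
    for g, asgn in assignments.items():
        gene_ids = [a.gene_id for a in asgn]
        if len(gene_ids) < 3:
            warnings.warn(f"{g}: fewer than 3 assignments, p missing")
        sub = expression.reindex(gene_ids)
        for other in genotypes:
            if other == g:
                continue
            if len(gene_ids) < 3:
                p = np.nan
            else:
                p = rank_sum_test(sub[g].to_numpy(), sub[other].to_numpy())
            rows.append(
                {
                    "set": g,
                    "versus": other,
                    "n": len(gene_ids),
                    "median_matching": float(sub[g].median()) if gene_ids else np.nan,
                    "median_other": float(sub[other].median()) if gene_ids else np.nan,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def domain_size_comparison(
    domains: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
) -> dict:
    """Compare sizes of domains that do or do not overlap any feature.

    Returns group mean sizes and a two-sided rank-sum p (NaN when a group is
    empty or has fewer than 3 members)."""
    with_f, without_f = [], []
    for d in domains:
        if any(d.overlaps(f) for f in features):
            with_f.append(d.width)
        else:
            without_f.append(d.width)
    p = (
        rank_sum_test(with_f, without_f)
        if len(with_f) >= 3 and len(without_f) >= 3
        else float("nan")
    )
    return {
        "n_with": len(with_f),
        "n_without": len(without_f),
        "mean_with": float(np.mean(with_f)) if with_f else float("nan"),
        "mean_without": float(np.mean(without_f)) if without_f else float("nan"),
        "p_value": p,
    }
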