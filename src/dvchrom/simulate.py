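"""Synthetic contact maps and regulatory annotations with planted structure.

The generator produces binned contact counts with the statistical features the
analysis assumes: power-law distance decay, self-interacting domains, A/B
compartments, focal loops, multiplicative per-bin biases and Poisson counting
noise. Heterozygous rearrangements (inversions, translocations) are emulated
by mixing the intensity of the rearranged genome, expressed in reference
coordinates, into the wild-type intensity before sampling — matching a pooled
sample in which only a fraction of individuals carry the rearrangement.

Expected intensity of a cis pixel (i, j):

    e(i, j) = (d_ij + s0)^(-alpha)
              * (1 + tau * [i, j in the same domain])
              * prod_loops (1 + lambda * exp(-delta^2 / (2 sigma^2)))
              * exp(kappa * v_i * v_j)

with d_ij the separation in bp, v the compartment profile, and delta the
pixel distance (in bins) from a loop-anchor pixel. Counts are drawn
Poisson(scale * b_i * b_j * e(i, j)) with log-normal biases b of mean 1 and
scale set so the expected genome-wide total equals the requested depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .genome import BinTable, ChromSizes, GeneModel, GenomicInterval
from .matrix import ContactMatrix

__all__ = [
    "Rearrangement",
    "SimulationSpec",
    "SyntheticTruth",
    "expected_intensity",
    "generate_contact_map",
    "apply_rearrangement",
    "generate_regulatory_annotation",
    "block_compartment_profile",
    "adjacent_domains",
    "truth_to_json",
]


@dataclass(frozen=True)
class Rearrangement:
    """An inversion of [start, end) on ``chrom``, or a reciprocal
    translocation joining ``chrom``:``start`` to ``chrom2``:``end``.
    Breakpoints must fall on bin edges."""

    kind: str  # {"inversion", "translocation"}
    chrom: str
    start: int
    end: int
    chrom2: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "translocation"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if self.kind == "translocation" and self.chrom2 is None:
            raise ValueError("translocation needs chrom2")

    def breakpoints(self) -> list[tuple[str, int]]:
        if self.kind == "inversion":
            return [(self.chrom, self.start), (self.chrom, self.end)]
        return [(self.chrom, self.start), (self.chrom2, self.end)]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic genome."""

    chrom_sizes: ChromSizes
    bin_size: int
    decay_exponent: float = 1.0  # alpha > 0
    decay_offset: Optional[int] = None  # s0 in bp; default: one bin
    domains: list[GenomicInterval] = field(default_factory=list)
    domain_boost: float = 1.0  # tau
    compartment_profile: dict[str, np.ndarray] = field(default_factory=dict)
    compartment_strength: float = 0.0  # kappa
    loops: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)
    loop_boost: float = 1.0  # lambda
    loop_sigma_bins: float = 1.0
    bias_sigma: float = 0.2  # log-normal sigma of per-bin biases
    depth: float = 1e6  # expected genome-wide pair count
    carrier_fraction: float = 1.0  # f, for rearrangements in the spec
    rearrangements: list[Rearrangement] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.decay_offset is None:
            self.decay_offset = self.bin_size
        if self.domain_boost < 0 or self.loop_boost < 0:
            raise ValueError("boosts must be >= 0")
        if not 0 <= self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in [0, 1]")
        for d in self.domains:
            self.chrom_sizes.check(d)
        inv = [r for r in self.rearrangements if r.kind == "inversion"]
        for a in range(len(inv)):
            for b in range(a + 1, len(inv)):
                x, y = inv[a], inv[b]
                if x.chrom == y.chrom and x.start < y.end and y.start < x.end:
                    raise ValueError("overlapping contradictory rearrangements")

    @property
    def bins(self) -> BinTable:
        return BinTable(self.chrom_sizes, self.bin_size)


@dataclass
class SyntheticTruth:
    """Planted features of one synthetic genome, the oracle for recovery tests."""

    boundaries: list[tuple[str, int]] = field(default_factory=list)
    domains: list[GenomicInterval] = field(default_factory=list)
    compartment_labels: dict[str, np.ndarray] = field(default_factory=dict)
    loop_anchors: list[tuple[GenomicInterval, GenomicInterval]] = field(
        default_factory=list
    )
    breakpoints: list[tuple[str, int]] = field(default_factory=list)
    enhancers: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    targets: dict[str, list[str]] = field(default_factory=dict)
    expression: Optional[pd.DataFrame] = None


def block_compartment_profile(
    bins: BinTable, block_bins: int
) -> dict[str, np.ndarray]:
    """Alternating +1/-1 blocks of ``block_bins`` bins per chromosome."""
    out = {}
    for chrom in bins.chrom_sizes:
        n = bins.n_bins_chrom(chrom)
        out[chrom] = np.where((np.arange(n) // block_bins) % 2 == 0, 1.0, -1.0)
    return out


def adjacent_domains(
    chrom: str,
    start: int,
    end: int,
    n: int,
    rng: np.random.Generator,
    min_size: int = 30000,
    max_size: int = 80000,
    bin_size: int = 1000,
) -> list[GenomicInterval]:
    """``n`` adjacent domains with sizes drawn uniformly, snapped to bin edges."""
    sizes = rng.uniform(min_size, max_size, size=n)
    sizes = sizes / sizes.sum() * min(end - start, sizes.sum())
    out, pos = [], start
    for s in sizes:
        width = max(bin_size, int(round(s / bin_size)) * bin_size)
        if pos + width > end:
            width = end - pos
        if width >= bin_size:
            out.append(GenomicInterval(chrom, pos, pos + width))
        pos += width
    return out


def _feature_multiplier(spec: SimulationSpec, chrom: str, n: int) -> np.ndarray:
    """Domain, loop and compartment multipliers for a cis block (distance-free)."""
    bins = spec.bins
    bs = spec.bin_size
    mult = np.ones((n, n))
    for dom in spec.domains:
        if dom.chrom != chrom:
            continue
        lo = dom.start // bs
        hi = -(-dom.end // bs)
        mult[lo:hi, lo:hi] *= 1.0 + spec.domain_boost
    if spec.loop_boost > 0 and spec.loops:
        ii, jj = np.indices((n, n))
        for a1, a2 in spec.loops:
            if a1.chrom != chrom or a2.chrom != chrom:
                continue
            c1, c2 = a1.mid // bs, a2.mid // bs
            for x, y in ((c1, c2), (c2, c1)):
                d2 = (ii - x) ** 2 + (jj - y) ** 2
                mult *= 1.0 + spec.loop_boost * np.exp(
                    -d2 / (2.0 * spec.loop_sigma_bins**2)
                )
    if spec.compartment_strength != 0 and chrom in spec.compartment_profile:
        v = np.asarray(spec.compartment_profile[chrom], dtype=float)
        if v.shape[0] != n:
            raise ValueError(f"compartment profile length mismatch on {chrom}")
        mult *= np.exp(spec.compartment_strength * np.outer(v, v))
    return mult


def _rearranged_positions(
    spec: SimulationSpec, rearrangements: Sequence[Rearrangement]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (molecule id, position index) in the rearranged genome.

    Bins on the same molecule interact with power-law decay of their position
    separation; bins on different molecules do not interact.
    """
    bins = spec.bins
    bs = spec.bin_size
    molecule = np.empty(bins.n_bins, dtype=np.int64)
    position = np.empty(bins.n_bins, dtype=np.int64)
    for k, chrom in enumerate(bins.chrom_sizes):
        s = bins.chrom_slice(chrom)
        molecule[s] = k
        position[s] = np.arange(s.stop - s.start)
    for r in rearrangements:
        if r.start % bs or r.end % bs:
            raise ValueError("breakpoints must fall on bin edges")
        if r.kind == "inversion":
            s = spec.bins.chrom_slice(r.chrom)
            lo, hi = r.start // bs, r.end // bs
            seg = slice(s.start + lo, s.start + hi)
            position[seg] = position[seg][::-1]
        else:
            sa = bins.chrom_slice(r.chrom)
            sb = bins.chrom_slice(r.chrom2)
            a = r.start // bs
            b = r.end // bs
            new_mol = molecule.max() + 1
            # der1 = A[:a] + B[b:], der2 = B[:b] + A[a:]
            headA = slice(sa.start, sa.start + a)
            tailA = slice(sa.start + a, sa.stop)
            headB = slice(sb.start, sb.start + b)
            tailB = slice(sb.start + b, sb.stop)
            molecule[headA] = new_mol
            position[headA] = np.arange(a)
            molecule[tailB] = new_mol
            position[tailB] = a + np.arange(tailB.stop - tailB.start)
            molecule[headB] = new_mol + 1
            position[headB] = np.arange(b)
            molecule[tailA] = new_mol + 1
            position[tailA] = b + np.arange(tailA.stop - tailA.start)
    return molecule, position


def expected_intensity(
    spec: SimulationSpec, rearranged: bool = False
) -> dict[tuple[str, str], np.ndarray]:
    """Expected intensity blocks keyed by (chrom, chrom); cis blocks always,
    trans blocks only when a translocation makes them nonzero."""
    bins = spec.bins
    bs = spec.bin_size
    alpha, s0 = spec.decay_exponent, spec.decay_offset
    rearr = spec.rearrangements if rearranged else []
    molecule, position = _rearranged_positions(spec, rearr)
    chroms = list(bins.chrom_sizes)
    out: dict[tuple[str, str], np.ndarray] = {}
    for ci, c1 in enumerate(chroms):
        s1 = bins.chrom_slice(c1)
        for c2 in chroms[ci:]:
            s2 = bins.chrom_slice(c2)
            same = molecule[s1][:, None] == molecule[s2][None, :]
            if not same.any():
                continue
            dist = np.abs(position[s1][:, None] - position[s2][None, :]) * bs
            e = np.where(same, (dist + s0) ** (-alpha), 0.0)
            if c1 == c2:
                e *= _feature_multiplier(spec, c1, s1.stop - s1.start)
            out[(c1, c2)] = e
    return out


def _mixture_intensity(
    spec: SimulationSpec,
) -> dict[tuple[str, str], np.ndarray]:
    base = expected_intensity(spec, rearranged=False)
    if not spec.rearrangements or spec.carrier_fraction == 0:
        return base
    mut = expected_intensity(spec, rearranged=True)
    f = spec.carrier_fraction
    keys = set(base) | set(mut)
    return {
        k: f * mut.get(k, 0.0) + (1.0 - f) * base.get(k, 0.0) for k in keys
    }


def _sample_counts(
    spec: SimulationSpec,
    intensity: dict[tuple[str, str], np.ndarray],
    rng: np.random.Generator,
) -> ContactMatrix:
    bins = spec.bins
    biases = rng.lognormal(
        mean=-spec.bias_sigma**2 / 2.0, sigma=spec.bias_sigma, size=bins.n_bins
    )
    total_e = 0.0
    for (c1, c2), e in intensity.items():
        if c1 == c2:
            total_e += np.triu(e).sum()
        else:
            total_e += e.sum()
    scale = spec.depth / total_e
    rows, cols, data = [], [], []
    for (c1, c2), e in intensity.items():
        s1, s2 = bins.chrom_slice(c1), bins.chrom_slice(c2)
        b = np.outer(biases[s1], biases[s2])
        lam = scale * b * e
        if c1 == c2:
            lam = np.triu(lam)
        counts = rng.poisson(lam)
        i, j = np.nonzero(counts)
        rows.append(i + s1.start)
        cols.append(j + s2.start)
        data.append(counts[i, j])
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    counts = sparse.coo_matrix(
        (np.concatenate(data).astype(float), (lo, hi)),
        shape=(bins.n_bins, bins.n_bins),
    ).tocsr()
    counts.sum_duplicates()
    return ContactMatrix(bins, counts, np.ones(bins.n_bins, dtype=bool))


def _truth_from_spec(spec: SimulationSpec) -> SyntheticTruth:
    boundaries: list[tuple[str, int]] = []
    for dom in spec.domains:
        boundaries.extend([(dom.chrom, dom.start), (dom.chrom, dom.end)])
    boundaries = sorted(set(boundaries))
    labels = {
        c: np.sign(np.asarray(v, dtype=float))
        for c, v in spec.compartment_profile.items()
    }
    breakpoints = [bp for r in spec.rearrangements for bp in r.breakpoints()]
    return SyntheticTruth(
        boundaries=boundaries,
        domains=list(spec.domains),
        compartment_labels=labels,
        loop_anchors=list(spec.loops),
        breakpoints=breakpoints,
    )


def generate_contact_map(
    spec: SimulationSpec, seed: Optional[int] = None
) -> tuple[ContactMatrix, SyntheticTruth]:
    """Sample a contact matrix from the spec; reproducible under a fixed seed.

    ``seed`` overrides ``spec.seed`` (use different seeds for replicate
    samplings of the same truth)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    matrix = _sample_counts(spec, _mixture_intensity(spec), rng)
    return matrix, _truth_from_spec(spec)


def apply_rearrangement(
    spec: SimulationSpec,
    rearrangement: Rearrangement,
    carrier_fraction: float,
    seed: Optional[int] = None,
) -> tuple[ContactMatrix, SyntheticTruth]:
    """Contact map of a pooled sample in which a fraction of individuals carry
    the rearrangement: intensities are mixed before Poisson sampling."""
    if not 0 <= carrier_fraction <= 1:
        raise ValueError("carrier fraction must be in [0, 1]")
    mutant_spec = SimulationSpec(
        **{
            **{k: getattr(spec, k) for k in spec.__dataclass_fields__},
            "rearrangements": spec.rearrangements + [rearrangement],
            "carrier_fraction": carrier_fraction,
        }
    )
    return generate_contact_map(mutant_spec, seed=seed)


# ---------------------------------------------------------------------------
# Regulatory annotation: genes, differential windows, expression
# ---------------------------------------------------------------------------


def generate_regulatory_annotation(
    chrom_sizes: ChromSizes,
    n_enhancers: int = 20,
    seed: int = 0,
    genotypes: Sequence[str] = ("gd7", "Tollrm9rm10", "Toll10B"),
    n_genes_per_mb: float = 30.0,
    housekeeping_fraction: float = 0.2,
    low_expressed_fraction: float = 0.15,
    window_size: int = 150,
    enhancer_windows: int = 6,
    enhancer_logfc: float = 3.0,
    target_effect: float = 4.0,
    baseline_tpm: float = 10.0,
    promoter_flank: int = 500,
    avoid_boundaries: Sequence[tuple[str, int]] = (),
    n_null_windows: int = 200,
) -> tuple[GeneModel, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Gene models, a differential H3K27ac window table, and a TPM table with
    planted tissue-specific enhancers and matching expression effects.

    Each genotype receives ``n_enhancers`` enhancers planted near the TSS of a
    chosen target gene (closer to it than to any other eligible promoter, with
    no avoided boundary in between), tiled by ``enhancer_windows`` significant
    150-bp windows in both pairwise contrasts against the other genotypes.
    Target genes get a log-normal TPM boost (median fold ``target_effect``) in
    the matching genotype. Housekeeping genes are expressed in every genotype;
    a ``low_expressed_fraction`` of genes sit below the mean-TPM-of-1 floor.
    """
    rng = np.random.default_rng(seed)
    genotypes = list(genotypes)
    if len(genotypes) != 3:
        raise ValueError("exactly three genotypes expected")

    # --- genes: one transcript each, spaced along each chromosome ---
    genes, transcripts = [], []
    gid = 0
    for chrom, length in chrom_sizes.items():
        n_genes = max(4, int(n_genes_per_mb * length / 1e6))
        spacing = length // (n_genes + 1)
        for k in range(n_genes):
            center = (k + 1) * spacing + int(rng.integers(-spacing // 8, spacing // 8))
            width = int(rng.integers(2000, 8000))
            start = max(0, center - width // 2)
            end = min(length, start + width)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gid:04d}"
            genes.append(
                {"gene_id": gene_id, "symbol": gene_id, "chrom": chrom,
                 "housekeeping": False}
            )
            transcripts.append(
                {"transcript_id": f"{gene_id}.t1", "gene_id": gene_id,
                 "chrom": chrom, "start": start, "end": end, "strand": strand}
            )
            gid += 1
    genes_df = pd.DataFrame(genes)
    tx_df = pd.DataFrame(transcripts)
    n_total = len(genes_df)
    hk = rng.choice(n_total, size=int(housekeeping_fraction * n_total), replace=False)
    genes_df.loc[hk, "housekeeping"] = True
    remaining = np.setdiff1d(np.arange(n_total), hk)
    low = rng.choice(
        remaining, size=int(low_expressed_fraction * n_total), replace=False
    )
    model = GeneModel(genes_df, tx_df)

    tss = model.promoters().set_index("gene_id")
    eligible = genes_df.loc[
        ~genes_df["housekeeping"] & ~genes_df.index.isin(low), "gene_id"
    ].tolist()

    # --- enhancers: planted next to target TSSs, unambiguously closest ---
    enhancer_width = window_size * enhancer_windows
    used: list[GenomicInterval] = []
    enhancers: dict[str, list[GenomicInterval]] = {g: [] for g in genotypes}
    targets: dict[str, list[str]] = {g: [] for g in genotypes}
    all_tss = model.promoters()
    avoid = list(avoid_boundaries)

    def _placement_ok(iv: GenomicInterval, target_gene: str) -> bool:
        for t in tx_df.itertuples():  # keep clear of every transcript body
            if t.chrom == iv.chrom and iv.start < t.end and t.start < iv.end:
                return False
        for p in all_tss.itertuples():  # and of every promoter window
            if p.chrom == iv.chrom and iv.start < p.pos + promoter_flank + 1 and \
                    p.pos - promoter_flank < iv.end:
                return False
        for u in used:
            if u.overlaps(iv):
                return False
        trow = tss.loc[target_gene]
        tpos = int(trow["pos"])
        d_target = min(abs(iv.start - tpos), abs(iv.end - 1 - tpos))
        cis = all_tss[(all_tss["chrom"] == iv.chrom) &
                      (all_tss["gene_id"] != target_gene)]
        others = np.minimum(
            np.abs(cis["pos"].to_numpy() - iv.start),
            np.abs(cis["pos"].to_numpy() - (iv.end - 1)),
        )
        if others.size and others.min() <= d_target:
            return False
        lo, hi = sorted((iv.mid, tpos))
        for bc, bp in avoid:  # no planted boundary between enhancer and target
            if bc == iv.chrom and lo < bp < hi:
                return False
        return True

    pool = list(eligible)
    rng.shuffle(pool)
    for g in genotypes:
        placed = 0
        while placed < n_enhancers and pool:
            gene = pool.pop()
            trow = tss.loc[gene]
            tpos, chrom = int(trow["pos"]), str(trow["chrom"])
            ok = None
            for _ in range(40):
                offset = int(rng.integers(2000, 15000))
                side = -1 if rng.random() < 0.5 else 1
                start = tpos + side * offset - enhancer_width // 2
                if start < 0 or start + enhancer_width > chrom_sizes[chrom]:
                    continue
                iv = GenomicInterval(chrom, start, start + enhancer_width,
                                     name=f"{g}_e{placed}")
                if _placement_ok(iv, gene):
                    ok = iv
                    break
            if ok is None:
                continue
            used.append(ok)
            enhancers[g].append(ok)
            targets[g].append(gene)
            placed += 1
        if placed < n_enhancers:
            raise ValueError(
                f"could not place {n_enhancers} enhancers for {g}; "
                "increase gene spacing or chromosome size"
            )

    # --- differential 150-bp window table, six ordered contrasts ---
    rows = []
    for g in genotypes:
        others = [o for o in genotypes if o != g]
        for iv in enhancers[g]:
            starts = np.arange(iv.start, iv.end, window_size)
            for s in starts:
                e = min(s + window_size, iv.end)
                lfc = float(rng.normal(enhancer_logfc, 0.25))
                for o in others:
                    rows.append((iv.chrom, s, e, f"{g}_vs_{o}", lfc,
                                 float(10 ** rng.uniform(-6, -3))))
                    rows.append((iv.chrom, s, e, f"{o}_vs_{g}", -lfc,
                                 float(10 ** rng.uniform(-6, -3))))
    contrasts = [f"{a}_vs_{b}" for a in genotypes for b in genotypes if a != b]
    chroms = list(chrom_sizes)
    for _ in range(n_null_windows):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, chrom_sizes[chrom] - window_size))
        s -= s % window_size
        rows.append(
            (chrom, s, s + window_size, contrasts[int(rng.integers(len(contrasts)))],
             float(rng.normal(0, 0.3)), float(rng.uniform(0.1, 1.0)))
        )
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "contrast", "logFC", "FDR"]
    ).sort_values(["chrom", "start", "contrast"]).reset_index(drop=True)

    # --- expression table (TPM) ---
    tpm = pd.DataFrame(
        rng.lognormal(np.log(baseline_tpm), 1.0, size=(n_total, 3)),
        index=genes_df["gene_id"], columns=genotypes,
    )
    tpm.loc[genes_df.loc[hk, "gene_id"]] = rng.lognormal(
        np.log(5 * baseline_tpm), 0.5, size=(len(hk), 3)
    )
    tpm.loc[genes_df.loc[low, "gene_id"]] = rng.lognormal(
        np.log(0.05), 0.8, size=(len(low), 3)
    )
    for g in genotypes:
        boost = rng.lognormal(np.log(target_effect), 0.3, size=len(targets[g]))
        tpm.loc[targets[g], g] = tpm.loc[targets[g], g] * boost
    tpm.index.name = "gene_id"

    truth = SyntheticTruth(
        enhancers=enhancers, targets=targets, expression=tpm
    )
    return model, windows, tpm, truth


def truth_to_json(truth: SyntheticTruth, path) -> None:
    """Serialize planted truth to a structured JSON file."""

    def iv(x: GenomicInterval):
        return {"chrom": x.chrom, "start": x.start, "end": x.end, "name": x.name}

    payload = {
        "boundaries": [list(b) for b in truth.boundaries],
        "domains": [iv(d) for d in truth.domains],
        "compartment_labels": {
            c: np.asarray(v).tolist() for c, v in truth.compartment_labels.items()
        },
        "loop_anchors": [[iv(a), iv(b)] for a, b in truth.loop_anchors],
        "breakpoints": [list(b) for b in truth.breakpoints],
        "enhancers": {
            g: [iv(e) for e in lst] for g, lst in truth.enhancers.items()
        },
        "targets": truth.targets,
        "expression": (
            None if truth.expression is None
            else truth.expression.reset_index().to_dict(orient="list")
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
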