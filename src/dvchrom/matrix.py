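"""Contact-matrix data model and primitives.

A :class:`ContactMatrix` stores binned, symmetric contact counts
upper-triangularly in sparse form, together with a per-bin validity mask and
(after balancing) per-bin biases. Normalized values are ``b_i * b_j *
count(i, j)`` and are never materialized sparsely; dense per-chromosome views
carry NaN at masked bins.

Balancing targets row sums of 1 on the valid submatrix, so observed/expected
and aggregate values are directly comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import sparse

from .genome import BinTable, GenomicInterval

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "DecayCurve",
    "BalancingError",
    "filter_low_coverage",
    "kr_balance",
    "ice_balance",
    "expected_profile",
    "observed_expected",
    "contact_decay",
    "virtual_4c",
    "coarsen",
]


class BalancingError(RuntimeError):
    pass


@dataclass
class ContactMatrix:
    """Binned symmetric contact counts with mask and balancing biases."""

    bins: BinTable
    counts: sparse.csr_matrix  # upper triangle, i <= j
    valid: np.ndarray  # bool, per bin
    biases: Optional[np.ndarray] = None  # positive on valid bins when set

    @classmethod
    def from_dense(cls, dense: np.ndarray, bins: BinTable) -> "ContactMatrix":
        """Build from a dense symmetric count matrix (upper triangle kept)."""
        if dense.shape != (bins.n_bins, bins.n_bins):
            raise ValueError("matrix shape does not match bin table")
        upper = sparse.csr_matrix(np.triu(dense))
        return cls(bins, upper, np.ones(bins.n_bins, dtype=bool))

    @property
    def is_balanced(self) -> bool:
        return self.biases is not None

    def symmetric(self) -> sparse.csr_matrix:
        """Full symmetric sparse counts."""
        u = self.counts
        d = sparse.diags(u.diagonal())
        return (u + u.T - d).tocsr()

    def marginals(self) -> np.ndarray:
        """Per-bin total contact count (row sums of the symmetric matrix)."""
        return np.asarray(self.symmetric().sum(axis=1)).ravel()

    def dense_counts(self, chrom: Optional[str] = None) -> np.ndarray:
        s = self.bins.chrom_slice(chrom) if chrom else slice(None)
        return self.symmetric()[s, s].toarray().astype(float)

    def normalized_dense(self, chrom: Optional[str] = None) -> np.ndarray:
        """Dense normalized values; NaN rows/columns at masked bins."""
        if self.biases is None:
            raise ValueError("matrix is not balanced; run kr_balance/ice_balance")
        s = self.bins.chrom_slice(chrom) if chrom else slice(None)
        d = self.dense_counts(chrom)
        b = self.biases[s]
        out = d * np.outer(b, b)
        bad = ~self.valid[s]
        out[bad, :] = np.nan
        out[:, bad] = np.nan
        return out

    def bin_is_valid(self, interval: GenomicInterval) -> np.ndarray:
        idx = self.bins.bin_span(interval)
        return self.valid[idx]


def filter_low_coverage(
    matrix: ContactMatrix, fraction: float = 0.10
) -> ContactMatrix:
    """Mask bins whose marginal is below ``fraction`` x median coverage.

    The median is taken over bins with nonzero coverage, so the filter is
    idempotent. Raises if nothing survives.
    """
    marg = matrix.marginals()
    nonzero = marg > 0
    if not nonzero.any():
        raise BalancingError("matrix empty after filtering")
    threshold = fraction * np.median(marg[nonzero])
    valid = matrix.valid & (marg >= threshold) & nonzero
    if not valid.any():
        raise BalancingError("matrix empty after filtering")
    return replace(matrix, valid=valid, biases=None)


def _valid_dense(matrix: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    idx = np.flatnonzero(matrix.valid)
    a = matrix.symmetric()[np.ix_(idx, idx)].toarray().astype(float)
    if a.shape[0] == 0:
        raise BalancingError("no valid bins")
    if (a.sum(axis=1) == 0).any():
        raise BalancingError(
            "valid bin with zero contacts: matrix is structurally unbalanceable; "
            "run filter_low_coverage first"
        )
    return a, idx


def _kr_vector(
    a: np.ndarray, tol: float, max_iter: int, delta: float = 0.1, Delta: float = 3.0
) -> np.ndarray:
    """Knight-Ruiz scaling of a symmetric nonnegative matrix.

    Returns x with diag(x) a diag(x) doubly stochastic (row sums 1). Inner-outer
    Newton iteration with conjugate-gradient inner solves.
    """
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (a @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    mvp = 0
    while rout > rt:
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (a @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = ((Delta - y[big]) / ap[big]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k >= max_iter:
                break
        x = x * y
        v = x * (a @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        mvp += k + 1
        if mvp > max_iter:
            raise BalancingError(
                f"KR balancing did not converge in {max_iter} matrix-vector "
                f"products (residual {np.sqrt(rout):.3e})"
            )
        rat = rout / rold
        rold = rout
        eta = g * rat
        if g * eta**2 > 0.1:  # pragma: no cover - safeguard from the algorithm
            eta = max(eta, g * eta**2)
        eta = min(max(eta, stop_tol / max(np.sqrt(rout), 1e-300)), etamax)
    return x


def kr_balance(
    matrix: ContactMatrix, tol: float = 1e-10, max_iter: int = 10000
) -> ContactMatrix:
    """Knight-Ruiz balancing; valid rows of the normalized matrix sum to 1."""
    a, idx = _valid_dense(matrix)
    x = _kr_vector(a, tol, max_iter)
    biases = np.full(matrix.bins.n_bins, np.nan)
    biases[idx] = x
    return replace(matrix, biases=biases)


def ice_balance(
    matrix: ContactMatrix, tol: float = 1e-9, max_iter: int = 5000
) -> ContactMatrix:
    """Iterative correction: alternate division by marginals until row sums
    of the normalized valid submatrix are 1 within ``tol``."""
    a, idx = _valid_dense(matrix)
    b = np.ones(a.shape[0])
    for _ in range(max_iter):
        s = b * (a @ b)
        dev = np.abs(s - 1.0).max()
        if dev < tol:
            break
        b = b / np.sqrt(s)
    else:
        raise BalancingError(
            f"iterative correction did not converge in {max_iter} iterations "
            f"(max marginal deviation {dev:.3e})"
        )
    biases = np.full(matrix.bins.n_bins, np.nan)
    biases[idx] = b
    return replace(matrix, biases=biases)


@dataclass
class ExpectedProfile:
    """Mean normalized contact value per genomic-distance separation.

    ``cis[chrom][d]`` is the mean over valid pixels at separation ``d`` bins
    (NaN where no valid pixel exists); ``trans[(c1, c2)]`` is the mean over
    all valid trans pixels for that chromosome pair.
    """

    bins: BinTable
    cis: dict[str, np.ndarray]
    trans: dict[tuple[str, str], float] = field(default_factory=dict)


def _diag_means(dense: np.ndarray) -> np.ndarray:
    n = dense.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        vals = np.diagonal(dense, offset=d)
        finite = np.isfinite(vals)
        if finite.any():
            out[d] = vals[finite].sum() / finite.sum()
    return out


def expected_profile(matrix: ContactMatrix) -> ExpectedProfile:
    """Average normalized contacts at each distance separation, per chromosome."""
    cis = {}
    for chrom in matrix.bins.chrom_sizes:
        cis[chrom] = _diag_means(matrix.normalized_dense(chrom))
    trans = {}
    chroms = list(matrix.bins.chrom_sizes)
    if len(chroms) > 1:
        full = matrix.normalized_dense()
        for i, c1 in enumerate(chroms):
            for c2 in chroms[i + 1 :]:
                block = full[matrix.bins.chrom_slice(c1), matrix.bins.chrom_slice(c2)]
                finite = np.isfinite(block)
                if finite.any():
                    trans[(c1, c2)] = float(block[finite].mean())
    return ExpectedProfile(matrix.bins, cis, trans)


def observed_expected(
    matrix: ContactMatrix, expected: Optional[ExpectedProfile] = None
) -> dict[str, np.ndarray]:
    """Per-chromosome dense observed/expected matrices.

    Entries at masked bins, or at separations whose expected value is zero or
    undefined, are NaN.
    """
    if expected is None:
        expected = expected_profile(matrix)
    out = {}
    for chrom in matrix.bins.chrom_sizes:
        dense = matrix.normalized_dense(chrom)
        n = dense.shape[0]
        exp = expected.cis[chrom]
        i, j = np.indices((n, n))
        e = exp[np.abs(i - j)]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = dense / e
        oe[~np.isfinite(oe)] = np.nan
        out[chrom] = oe
    return out


@dataclass
class DecayCurve:
    """Contact probability P(s) in log-spaced distance bins with its
    log-log derivative."""

    distances: np.ndarray  # bp, geometric bin centers
    ps: np.ndarray
    derivative: np.ndarray


def contact_decay(
    matrix: ContactMatrix,
    log_bin_factor: float = 1.15,
    total_sum_normalize: bool = True,
) -> DecayCurve:
    """P(s) pooled over chromosomes in log-spaced distance bins.

    With ``total_sum_normalize`` the curve is scaled so that
    sum(P(s) * bin width) = 1, making curves comparable across samples with
    different depths.
    """
    if log_bin_factor <= 1:
        raise ValueError("log_bin_factor must be > 1")
    bs = matrix.bins.bin_size
    max_bins = max(
        matrix.bins.n_bins_chrom(c) for c in matrix.bins.chrom_sizes
    )
    sums = np.zeros(max_bins)
    counts = np.zeros(max_bins)
    for chrom in matrix.bins.chrom_sizes:
        dense = matrix.normalized_dense(chrom)
        for d in range(1, dense.shape[0]):
            vals = np.diagonal(dense, offset=d)
            finite = np.isfinite(vals)
            sums[d] += vals[finite].sum()
            counts[d] += finite.sum()
    edges = [bs]
    while edges[-1] < max_bins * bs:
        edges.append(max(edges[-1] * log_bin_factor, edges[-1] + bs))
    edges = np.array(edges)
    centers, ps, widths = [], [], []
    dist_bp = np.arange(max_bins) * bs
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist_bp >= lo) & (dist_bp < hi) & (counts > 0)
        if not sel.any():
            continue
        centers.append(np.sqrt(lo * hi))
        ps.append(sums[sel].sum() / counts[sel].sum())
        widths.append(hi - lo)
    centers = np.array(centers)
    ps = np.array(ps)
    widths = np.array(widths)
    if total_sum_normalize and ps.sum() > 0:
        ps = ps / (ps * widths).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        logp, logs = np.log(ps), np.log(centers)
        deriv = np.gradient(logp, logs)
    return DecayCurve(centers, ps, deriv)


def virtual_4c(matrix: ContactMatrix, anchor: GenomicInterval) -> np.ndarray:
    """Mean normalized interaction of the anchor bins with every genomic bin.

    The returned track covers the whole genome (global bin order), NaN at
    masked bins.
    """
    anchor_bins = matrix.bins.bin_span(anchor)
    anchor_bins = anchor_bins[matrix.valid[anchor_bins]]
    if anchor_bins.size == 0:
        raise ValueError("anchor is fully masked")
    full = matrix.normalized_dense()
    return np.nanmean(full[anchor_bins, :], axis=0) if anchor_bins.size > 1 else full[
        anchor_bins[0], :
    ]


def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum raw counts into bins ``factor`` times larger.

    Returns a raw (unfiltered, unbalanced) matrix; rerun filtering/balancing.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    bins = matrix.bins
    new_bins = BinTable(bins.chrom_sizes, bins.bin_size * factor)
    mapping = np.empty(bins.n_bins, dtype=np.int64)
    for chrom in bins.chrom_sizes:
        s = bins.chrom_slice(chrom)
        local = np.arange(s.stop - s.start)
        mapping[s] = new_bins.offset(chrom) + local // factor
    coo = matrix.counts.tocoo()
    i = mapping[coo.row]
    j = mapping[coo.col]
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    new = sparse.coo_matrix(
        (coo.data, (lo, hi)), shape=(new_bins.n_bins, new_bins.n_bins)
    ).tocsr()
    new.sum_duplicates()
    return ContactMatrix(new_bins, new, np.ones(new_bins.n_bins, dtype=bool))
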