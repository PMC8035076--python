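"""On-disk formats for contact matrices.

Primary format is COO text (``bin1_id<TAB>bin2_id<TAB>count``) with sidecar
``bins.bed`` and ``chrom.sizes`` files. A single-resolution HDF5 layout
mirroring the cooler schema (chroms/bins/pixels groups, balancing weights in
``bins/weight``) is provided for interoperability.
"""

from __future__ import annotations

import os
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .genome import BinTable, ChromSizes
from .io import read_chrom_sizes, write_chrom_sizes
from .matrix import ContactMatrix

__all__ = ["save_coo", "load_coo", "save_hdf5", "load_hdf5"]

_COO = "matrix.coo.txt"
_BINS = "bins.bed"
_SIZES = "chrom.sizes"
_BIASES = "biases.tsv"


def save_coo(matrix: ContactMatrix, directory) -> None:
    """Write matrix.coo.txt, bins.bed, chrom.sizes (and biases.tsv if balanced)."""
    os.makedirs(directory, exist_ok=True)
    coo = matrix.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    pd.DataFrame(
        {"bin1_id": coo.row[order], "bin2_id": coo.col[order], "count": coo.data[order]}
    ).to_csv(os.path.join(directory, _COO), sep="\t", header=False, index=False)
    bins_df = matrix.bins.to_frame()
    bins_df["valid"] = matrix.valid.astype(int)
    bins_df.to_csv(os.path.join(directory, _BINS), sep="\t", header=False, index=False)
    write_chrom_sizes(matrix.bins.chrom_sizes, os.path.join(directory, _SIZES))
    if matrix.biases is not None:
        pd.DataFrame({"bias": matrix.biases}).to_csv(
            os.path.join(directory, _BIASES), sep="\t", header=False, index=False
        )


def load_coo(directory) -> ContactMatrix:
    chrom_sizes = read_chrom_sizes(os.path.join(directory, _SIZES))
    bins_df = pd.read_csv(
        os.path.join(directory, _BINS),
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "valid"],
    )
    bin_size = int((bins_df["end"] - bins_df["start"]).max())
    bins = BinTable(chrom_sizes, bin_size)
    if len(bins_df) != bins.n_bins:
        raise ValueError("bins.bed does not tile chrom.sizes at a fixed bin size")
    pix = pd.read_csv(
        os.path.join(directory, _COO),
        sep="\t",
        header=None,
        names=["bin1_id", "bin2_id", "count"],
    )
    lo = np.minimum(pix["bin1_id"], pix["bin2_id"])
    hi = np.maximum(pix["bin1_id"], pix["bin2_id"])
    counts = sparse.coo_matrix(
        (pix["count"].to_numpy(float), (lo, hi)), shape=(bins.n_bins, bins.n_bins)
    ).tocsr()
    counts.sum_duplicates()
    valid = bins_df["valid"].to_numpy(bool)
    biases: Optional[np.ndarray] = None
    bias_path = os.path.join(directory, _BIASES)
    if os.path.exists(bias_path):
        biases = pd.read_csv(bias_path, sep="\t", header=None)[0].to_numpy(float)
    return ContactMatrix(bins, counts, valid, biases)


def save_hdf5(matrix: ContactMatrix, path) -> None:
    """Single-resolution cooler-dialect HDF5 writer."""
    bins_df = matrix.bins.to_frame()
    chroms = list(matrix.bins.chrom_sizes)
    codes = {c: k for k, c in enumerate(chroms)}
    coo = matrix.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with h5py.File(path, "w") as f:
        f.attrs["bin-size"] = matrix.bins.bin_size
        f.attrs["format"] = "HDF5::Cooler"
        g = f.create_group("chroms")
        g.create_dataset(
            "name", data=np.array(chroms, dtype=h5py.string_dtype())
        )
        g.create_dataset(
            "length",
            data=np.array([matrix.bins.chrom_sizes[c] for c in chroms], dtype="i8"),
        )
        g = f.create_group("bins")
        g.create_dataset(
            "chrom", data=bins_df["chrom"].map(codes).to_numpy("i4")
        )
        g.create_dataset("start", data=bins_df["start"].to_numpy("i8"))
        g.create_dataset("end", data=bins_df["end"].to_numpy("i8"))
        if matrix.biases is not None:
            g.create_dataset("weight", data=matrix.biases)
        g.create_dataset("valid", data=matrix.valid.astype("i1"))
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=coo.row[order].astype("i8"))
        g.create_dataset("bin2_id", data=coo.col[order].astype("i8"))
        g.create_dataset("count", data=coo.data[order])


def load_hdf5(path) -> ContactMatrix:
    with h5py.File(path, "r") as f:
        names = [n.decode() for n in f["chroms/name"][:]]
        lengths = f["chroms/length"][:]
        chrom_sizes = ChromSizes(list(zip(names, (int(x) for x in lengths))))
        bins = BinTable(chrom_sizes, int(f.attrs["bin-size"]))
        i = f["pixels/bin1_id"][:]
        j = f["pixels/bin2_id"][:]
        data = f["pixels/count"][:].astype(float)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        counts = sparse.coo_matrix(
            (data, (lo, hi)), shape=(bins.n_bins, bins.n_bins)
        ).tocsr()
        counts.sum_duplicates()
        valid = (
            f["bins/valid"][:].astype(bool)
            if "valid" in f["bins"]
            else np.ones(bins.n_bins, dtype=bool)
        )
        biases = f["bins/weight"][:] if "weight" in f["bins"] else None
    return ContactMatrix(bins, counts, valid, biases)
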