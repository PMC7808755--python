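"""Reading and writing 10x-style sparse count triplets and TSV tables.

The on-disk layout mirrors the CellRanger convention: a MatrixMarket
coordinate file ``matrix.mtx`` (genes x cells, 1-based indices), a
``features.tsv`` with one gene identifier per row, and a ``barcodes.tsv``
with one cell identifier per row.  Metadata tables travel as plain TSV
with a header line.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_mtx_dir(path: str, counts: sp.spmatrix, genes, barcodes) -> None:
    """Write a gene x cell count matrix as a 10x-style triplet directory."""
    counts = sp.csr_matrix(counts)
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"counts shape {counts.shape} does not match "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), counts, field="integer")
    pd.Series(list(genes)).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(list(barcodes)).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
    )


def read_mtx_dir(path: str):
    """Read a triplet directory; returns (csr counts, gene list, barcode list)."""
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(path, "matrix.mtx")))
    genes = pd.read_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=None
    )[0].tolist()
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].tolist()
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError("matrix dimensions disagree with features/barcodes")
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("negative entries in count matrix")
    return counts, genes, barcodes


def write_table(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_set(path: str, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_set(path: str) -> list:
    """One gene per line; GMT lines (tab-separated with description) also accepted."""
    out: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) > 2:  # GMT: name, description, genes...
                out.extend(fields[2:])
            else:
                out.append(fields[0])
    return out


def checksum(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
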