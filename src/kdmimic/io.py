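"""File-format adapters: GCT/GCTX signature matrices, GMT gene sets, TSV/CSV tables.

The text GCT dialect written here is `#1.3` with no extra row/column
metadata (version line, dimension line, header, then one row per gene).
GCTX reading follows the CMap HDF5 layout (``/0/DATA/0/matrix`` with row and
column ids under ``/0/META``), so real compendium slices drop in where the
synthetic generator is used in tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .repositioning import META_COLUMNS, SignatureMatrix

__all__ = [
    "read_gct",
    "write_gct",
    "read_gctx",
    "read_gmt",
    "write_gmt",
    "read_signature_meta",
    "write_signature_meta",
    "read_de_table",
    "read_essentiality",
    "read_dpi",
    "read_ppi",
    "read_plate",
]


def write_gct(matrix: SignatureMatrix, path) -> Path:
    """Write a signature matrix as text GCT `#1.3` (no extra metadata rows)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_signatures}\t0\t0\n")
        fh.write("id\t" + "\t".join(matrix.sig_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


def read_gct(path) -> SignatureMatrix:
    """Read a text GCT (`#1.2` or `#1.3`) into a SignatureMatrix."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise ValueError(f"not a GCT file (version line {version!r})")
        dims = fh.readline().split("\t")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_rmeta = int(dims[2]) if version == "#1.3" and len(dims) > 2 else 0
        n_cmeta = int(dims[3]) if version == "#1.3" and len(dims) > 3 else 0
        header = fh.readline().rstrip("\n").split("\t")
        sig_ids = header[1 + n_rmeta:]
        for _ in range(n_cmeta):
            fh.readline()
        genes, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            genes.append(parts[0])
            rows.append([float(v) for v in parts[1 + n_rmeta:]])
    if len(genes) != n_rows or len(sig_ids) != n_cols:
        raise ValueError("GCT dimension line does not match the data block")
    return SignatureMatrix(genes, sig_ids, np.asarray(rows, dtype=float))


def read_gctx(path, sig_ids: list[str] | None = None) -> SignatureMatrix:
    """Read a (subset of a) GCTX/HDF5 matrix in the CMap layout."""
    import h5py

    with h5py.File(path, "r") as f:
        rid = [r.decode() if isinstance(r, bytes) else str(r)
               for r in f["/0/META/ROW/id"][:]]
        cid = [c.decode() if isinstance(c, bytes) else str(c)
               for c in f["/0/META/COL/id"][:]]
        data = f["/0/DATA/0/matrix"]
        if sig_ids is None:
            values = data[:]
        else:
            idx = [cid.index(s) for s in sig_ids]
            order = np.argsort(idx)
            # h5py fancy indexing needs increasing indices on the stored axis
            if data.shape == (len(cid), len(rid)):  # cols stored as rows
                values = data[np.asarray(idx)[order], :][np.argsort(order)].T
            else:
                values = data[:, np.asarray(idx)[order]][:, np.argsort(order)]
            cid = list(sig_ids)
        if sig_ids is None and data.shape == (len(cid), len(rid)):
            values = values.T
    return SignatureMatrix(rid, cid, np.asarray(values, dtype=float))


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([label, collection.name, *sorted(genes)])
        for label, genes in sorted(collection.sets.items())
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    path = Path(path)
    sets = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return GeneSetCollection(name=name or path.stem, sets=sets)


def write_signature_meta(meta: pd.DataFrame, path) -> Path:
    path = Path(path)
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_signature_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"signature metadata lacks columns {sorted(missing)}")
    return meta


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression TSV with columns gene, region, logFC, FDR."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "region", "logFC", "FDR"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table lacks columns {sorted(missing)}")
    return df


def read_essentiality(path, lineages: dict[str, str] | None = None) -> pd.DataFrame:
    """Essentiality CSV, long (gene,cell_line,score) or wide (gene x lines).

    The layout is auto-detected: a table with ``gene``/``cell_line``/``score``
    columns is taken as long form, anything else as a wide gene-by-cell-line
    matrix with genes in the first column.  ``lineages`` optionally maps cell
    lines to lineage labels (default "unknown").
    """
    df = pd.read_csv(path)
    if {"gene", "cell_line", "score"} <= set(df.columns):
        long = df.copy()
        if "lineage" not in long.columns:
            long["lineage"] = [
                (lineages or {}).get(c, "unknown") for c in long["cell_line"]
            ]
        return long[["gene", "cell_line", "lineage", "score"]]
    gene_col = df.columns[0]
    long = df.melt(id_vars=gene_col, var_name="cell_line", value_name="score")
    long = long.rename(columns={gene_col: "gene"}).dropna(subset=["score"])
    long["lineage"] = [(lineages or {}).get(c, "unknown") for c in long["cell_line"]]
    return long[["gene", "cell_line", "lineage", "score"]]


def read_dpi(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"compound_id", "protein_symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"DPI table lacks columns {sorted(missing)}")
    return df


def read_ppi(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_a", "protein_b"} - set(df.columns)
    if missing:
        raise ValueError(f"PPI table lacks columns {sorted(missing)}")
    return df


def read_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"well", "role", "absorbance", "wavelength_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"plate table lacks columns {sorted(missing)}")
    if (df["absorbance"] < 0).any():
        raise ValueError("negative absorbance in plate table")
    return df
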