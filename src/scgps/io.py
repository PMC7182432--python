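"""Readers and writers for the standard text formats the pipeline touches.

Supported formats:

* Matrix Market coordinate triplets (``matrix.mtx``) with companion
  one-record-per-line ``genes`` and ``barcodes`` files — the CellRanger-style
  triplet layout for UMI count matrices. Matrix Market is 1-based; the
  1-based/0-based boundary lives entirely in this module.
* GMT gene-set files: ``name <TAB> description <TAB> gene1 <TAB> gene2 ...``.
* Delimited cell-metadata tables with a header (TSV/CSV).
* Score tables as TSV, written at full precision so a write/read round trip
  is bit-exact.

Duplicate gene identifiers in a triplet ingest are collapsed by summation
(one identifier must map to one row for identifier-driven scoring); a warning
enumerates the collapsed identifiers.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from ._errors import DataError, FormatError
from .types import RAW_COUNTS, CellTable, ExpressionMatrix, GeneSetCollection, ScoreTable

logger = logging.getLogger("scgps")


def _read_lines(path) -> list:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def _first_field(line: str) -> str:
    # genes/barcodes files may carry extra columns (e.g. id \t symbol)
    return line.split("\t")[0].split(",")[0].strip()


def read_mtx_triplet(matrix_path, genes_path, barcodes_path) -> ExpressionMatrix:
    """Read a 10x-style triplet (matrix.mtx + genes + barcodes) as raw counts.

    Rows with duplicate gene identifiers are collapsed by summation, with a
    warning listing the identifiers involved. Raises :class:`FormatError` on
    dimension mismatches, negative entries, or non-integer entries.
    """
    try:
        mat = spio.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    genes = [_first_field(l) for l in _read_lines(genes_path)]
    barcodes = [_first_field(l) for l in _read_lines(barcodes_path)]
    n_g, n_c = mat.shape
    if len(genes) != n_g:
        raise FormatError(
            f"genes file {genes_path} has {len(genes)} records but matrix header "
            f"declares {n_g} rows"
        )
    if len(barcodes) != n_c:
        raise FormatError(
            f"barcodes file {barcodes_path} has {len(barcodes)} records but matrix "
            f"header declares {n_c} columns"
        )
    if mat.nnz:
        if mat.data.min() < 0:
            raise FormatError(f"{matrix_path}: negative entries in count matrix")
        if not np.array_equal(mat.data, np.floor(mat.data)):
            raise FormatError(f"{matrix_path}: non-integer entries in count matrix")

    genes_arr = np.asarray(genes, dtype=object)
    uniq, first_idx, inverse = np.unique(genes_arr, return_index=True, return_inverse=True)
    if len(uniq) != len(genes_arr):
        counts = np.bincount(inverse)
        dup_names = [str(u) for u, c in zip(uniq, counts) if c > 1]
        logger.warning(
            "collapsing %d duplicate gene identifier(s) by summation: %s",
            len(dup_names), ", ".join(dup_names[:20]),
        )
        # keep first-occurrence order of the unique identifiers
        order = np.argsort(first_idx, kind="stable")
        rank_of_uniq = np.empty(len(uniq), dtype=int)
        rank_of_uniq[order] = np.arange(len(uniq))
        rows = rank_of_uniq[inverse]  # original row -> collapsed row
        collapse = sparse.csr_matrix(
            (np.ones(len(genes_arr)), (rows, np.arange(len(genes_arr)))),
            shape=(len(uniq), len(genes_arr)),
        )
        mat = sparse.csr_matrix(collapse @ mat)
        genes_arr = genes_arr[np.sort(first_idx)]

    return ExpressionMatrix(
        values=mat, gene_ids=genes_arr,
        cell_ids=np.asarray(barcodes, dtype=object), layer=RAW_COUNTS,
    )


def write_mtx_triplet(em: ExpressionMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write an ExpressionMatrix as a Matrix Market triplet with id files."""
    mat = em.values.tocoo()
    if em.layer == RAW_COUNTS:
        mat = mat.astype(np.int64)
    _atomic(matrix_path, lambda tmp: spio.mmwrite(tmp, mat, precision=17))
    _atomic_text(genes_path, "\n".join(map(str, em.gene_ids)) + ("\n" if len(em.gene_ids) else ""))
    _atomic_text(barcodes_path, "\n".join(map(str, em.cell_ids)) + ("\n" if len(em.cell_ids) else ""))


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file.

    Each non-empty line is ``name <TAB> description <TAB> gene...``; duplicate
    genes within a line are dropped keeping the first occurrence. A line with
    fewer than three fields raises :class:`FormatError` naming the line.
    """
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one gene ({len(fields)} field(s) found)"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g != ""]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            seen: dict = {}
            for g in genes:
                seen.setdefault(g, None)
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = list(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    _atomic_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_cell_table(path, sep=None) -> CellTable:
    """Read a delimited per-cell metadata table (must contain `barcode`).

    Delimiter is sniffed from the extension unless given (`.csv` → comma,
    otherwise tab). Missing optional columns (cluster/genotype/stage) become
    a single "unassigned" level. Duplicated barcodes raise :class:`DataError`.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse cell table {path}: {exc}") from exc
    if "barcode" not in df.columns:
        raise FormatError(f"{path}: cell table has no 'barcode' column")
    return CellTable(table=df)


def write_cell_table(cells: CellTable, path) -> None:
    _atomic(path, lambda tmp: cells.table.to_csv(tmp, sep="\t", index=False))


def write_scores(score_table: ScoreTable, path) -> None:
    """Write a score table as TSV, one row per cell, one column per set.

    Floats are written at full (repr) precision so that
    :func:`read_scores` reproduces the values bit-exactly.
    """
    df = score_table.to_frame()
    _atomic(path, lambda tmp: df.to_csv(tmp, sep="\t"))


def read_scores(path) -> ScoreTable:
    """Read a TSV written by :func:`write_scores`.

    ``genes_used`` is not stored in the TSV; it is restored as 1 per set (the
    minimum valid value) — the run log is the authoritative record of m.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ScoreTable(
        scores=df.to_numpy(dtype=float) if df.size else np.empty((len(df), len(df.columns))),
        cell_ids=df.index.astype(str).to_numpy(dtype=object),
        set_names=list(df.columns),
        genes_used={c: 1 for c in df.columns},
    )


# -- atomic write helpers ----------------------------------------------------

def _atomic(path, write_fn) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_text(path, text: str) -> None:
    def _w(tmp):
        with open(tmp, "w") as fh:
            fh.write(text)
    _atomic(path, _w)
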