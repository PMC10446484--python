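"""Readers and writers for the external formats the pipeline touches.

The on-disk interface mirrors the 10x Genomics conventions: a gene x cell UMI
count matrix as Matrix Market coordinate triplets (``matrix.mtx``) with
``features.tsv`` / ``barcodes.tsv`` sidecars, and V(D)J contig annotations in
the Cell Ranger ``filtered_contig_annotations.csv`` dialect.  Results are
emitted as TSV (tables), Matrix Market (matrices) and a JSON run manifest.

All text I/O is UTF-8.  TSV is used for outputs instead of CSV to avoid
quoting ambiguity in gene symbols and CDR3 strings.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, LabelingError, ParseError, SchemaError

CHAIN_VOCABULARY = frozenset({"TRA", "TRB"})

CONTIG_REQUIRED_COLUMNS = (
    "barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "productive",
    "umis",
)


@dataclass
class GeneCellCounts:
    """Sparse gene x cell UMI count matrix with labelled axes.

    Attributes
    ----------
    matrix
        genes x cells sparse matrix of nonnegative integer counts.
    gene_ids
        Ordered, unique gene symbols (rows).
    barcodes
        Ordered, unique cell barcodes (columns).
    cell_meta
        DataFrame indexed by barcode with at least ``sample`` and
        ``condition`` columns.
    """

    matrix: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.matrix.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise FormatError("negative counts")
        data = self.matrix.data
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("non-integer counts")
        missing = set(self.barcodes) - set(self.cell_meta.index)
        if missing:
            raise LabelingError(
                f"{len(missing)} barcodes missing from cell_meta "
                f"(e.g. {sorted(missing)[:3]})")
        for col in ("sample", "condition"):
            if col not in self.cell_meta.columns:
                raise LabelingError(f"cell_meta lacks required column {col!r}")
        self.cell_meta = self.cell_meta.loc[list(self.barcodes)]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def conditions(self) -> pd.Series:
        return self.cell_meta["condition"]

    def subset(self, gene_mask=None, cell_mask=None) -> "GeneCellCounts":
        """Return a new GeneCellCounts restricted to the given boolean masks."""
        m = self.matrix
        genes = self.gene_ids
        cells = self.barcodes
        if gene_mask is not None:
            m = m[np.asarray(gene_mask)]
            genes = genes[np.asarray(gene_mask)]
        if cell_mask is not None:
            m = m[:, np.asarray(cell_mask)]
            cells = cells[np.asarray(cell_mask)]
        return GeneCellCounts(m.tocsr(), genes, cells,
                              self.cell_meta.loc[list(cells)].copy())


@dataclass(frozen=True)
class ContigRecord:
    """One V(D)J contig annotation row."""

    barcode: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    umis: int

    def __post_init__(self) -> None:
        if self.chain not in CHAIN_VOCABULARY:
            raise SchemaError(
                f"chain {self.chain!r} not in {sorted(CHAIN_VOCABULARY)}")
        if not self.cdr3_nt:
            raise SchemaError("empty cdr3_nt")
        if self.umis < 0:
            raise SchemaError("negative UMI count")


def dedupe_gene_ids(symbols: Iterable[str]) -> list[str]:
    """Disambiguate duplicate gene symbols with a deterministic ``.k`` suffix.

    The k-th repeat of a symbol becomes ``symbol.k`` (first occurrence keeps
    the bare name), so no data is dropped and the mapping is reproducible.
    """
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        k = seen.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        seen[s] = k + 1
    return out


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _find_sidecar(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {dir_path}")


def read_10x_triplet(dir_path, sample_sheet: pd.DataFrame) -> GeneCellCounts:
    """Read a 10x-style Matrix Market triplet directory.

    Parameters
    ----------
    dir_path
        Directory containing ``matrix.mtx``, ``features.tsv`` and
        ``barcodes.tsv`` (each optionally gzip-compressed; ``genes.tsv`` is
        accepted as an alias for the features file).
    sample_sheet
        DataFrame assigning each cell a ``sample`` and ``condition``.  Either
        a ``barcode`` column mapping barcodes directly, or a ``suffix`` column
        matched against the end of each barcode (the common ``-1`` style
        sample suffix).

    Notes
    -----
    The features file may have 1, 2 or 3 tab-separated columns
    (id / id+symbol / id+symbol+type); the symbol column is preferred when
    present.  Duplicate symbols get a deterministic ``.k`` suffix.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_sidecar(dir_path, "matrix.mtx")
    try:
        feat_path = _find_sidecar(dir_path, "features.tsv")
    except FormatError:
        feat_path = _find_sidecar(dir_path, "genes.tsv")
    bc_path = _find_sidecar(dir_path, "barcodes.tsv")

    try:
        with _open_maybe_gz(mtx_path) as fh:
            matrix = scipy.io.mmread(fh)
    except ValueError as exc:
        raise ParseError(f"{mtx_path}: {exc}") from exc
    matrix = sp.csr_matrix(matrix)

    with _open_maybe_gz(feat_path) as fh:
        feats = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if len(feats) != matrix.shape[0]:
        raise ParseError(
            f"{feat_path}: {len(feats)} features but MTX header declares "
            f"{matrix.shape[0]} rows")
    if len(barcodes) != matrix.shape[1]:
        raise ParseError(
            f"{bc_path}: {len(barcodes)} barcodes but MTX header declares "
            f"{matrix.shape[1]} columns")

    ncol = len(feats[0]) if feats else 1
    symbols = [row[1] if ncol >= 2 else row[0] for row in feats]
    gene_ids = dedupe_gene_ids(symbols)

    cell_meta = _labels_from_sheet(barcodes, sample_sheet)
    return GeneCellCounts(matrix, np.array(gene_ids, dtype=object),
                          np.array(barcodes, dtype=object), cell_meta)


def _labels_from_sheet(barcodes: list[str],
                       sample_sheet: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample", "condition"):
        if col not in sample_sheet.columns:
            raise SchemaError(f"sample sheet lacks required column {col!r}")
    if "barcode" in sample_sheet.columns:
        sheet = sample_sheet.set_index("barcode")
        missing = [b for b in barcodes if b not in sheet.index]
        if missing:
            raise LabelingError(
                f"{len(missing)} barcodes absent from sample sheet "
                f"(e.g. {missing[:3]})")
        return sheet.loc[barcodes, ["sample", "condition"]].copy()
    if "suffix" in sample_sheet.columns:
        rows = []
        # longest suffix wins so "-2" does not shadow "-12"
        entries = sorted(sample_sheet.itertuples(index=False),
                         key=lambda r: -len(str(r.suffix)))
        for b in barcodes:
            for entry in entries:
                if b.endswith(str(entry.suffix)):
                    rows.append((b, entry.sample, entry.condition))
                    break
            else:
                raise LabelingError(f"barcode {b!r} matches no suffix rule")
        return pd.DataFrame(rows, columns=["barcode", "sample", "condition"]
                            ).set_index("barcode")
    raise SchemaError("sample sheet needs a 'barcode' or 'suffix' column")


_TRUE_STRINGS = {"true"}


def read_contigs(csv_path) -> list[ContigRecord]:
    """Read a Cell Ranger ``filtered_contig_annotations.csv`` table.

    Rows whose ``productive`` field is not parseable as true (the dialects
    True/TRUE/true) are retained with ``productive=False``; this covers the
    "None" value Cell Ranger emits for chains it could not call.
    """
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FormatError(f"missing contig file {csv_path}")
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    for col in CONTIG_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"contig table lacks required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        productive = str(row.productive).strip().lower() in _TRUE_STRINGS
        records.append(ContigRecord(
            barcode=row.barcode,
            chain=row.chain,
            v_gene=row.v_gene,
            j_gene=row.j_gene,
            cdr3_nt=row.cdr3_nt,
            cdr3_aa=row.cdr3,
            productive=productive,
            umis=int(row.umis),
        ))
    return records


def contigs_to_frame(records: list[ContigRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "barcode": r.barcode, "chain": r.chain, "v_gene": r.v_gene,
        "j_gene": r.j_gene, "cdr3": r.cdr3_aa, "cdr3_nt": r.cdr3_nt,
        "productive": "True" if r.productive else "False", "umis": r.umis,
    } for r in records])


def config_hash(config) -> str:
    """Stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: Mapping[str, pd.DataFrame], out_dir, *,
                  matrices: Mapping[str, sp.spmatrix] | None = None,
                  config=None, seed: int | None = None,
                  manifest_name: str = "manifest.json") -> dict:
    """Write named tables (TSV) and matrices (Matrix Market) plus a manifest.

    Returns the manifest dict, which is also written as JSON in ``out_dir``.
    The manifest records every file, its row count, and the run's config hash
    and seed so any output can be traced back to the exact invocation.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output dir {out_dir}: {exc}") from exc
    files = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, encoding="utf-8")
        files.append({"name": name, "path": path.name,
                      "kind": "table", "rows": int(len(table))})
    for name, mat in (matrices or {}).items():
        path = out_dir / f"{name}.mtx"
        mat = sp.coo_matrix(mat)
        field_kind = "integer" if np.issubdtype(mat.dtype, np.integer) else "real"
        scipy.io.mmwrite(str(path), mat, field=field_kind)
        files.append({"name": name, "path": path.name,
                      "kind": "matrix", "rows": int(mat.shape[0])})
    manifest = {
        "files": files,
        "n_files": len(files),
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
    }
    with open(out_dir / manifest_name, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_10x_triplet(counts: GeneCellCounts, dir_path) -> None:
    """Write a GeneCellCounts as a 10x-style triplet directory plus samples.tsv."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"),
                     sp.coo_matrix(counts.matrix.astype(np.int64)),
                     field="integer")
    with open(dir_path / "features.tsv", "w", encoding="utf-8") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w", encoding="utf-8") as fh:
        for b in counts.barcodes:
            fh.write(f"{b}\n")
    sheet = counts.cell_meta.reset_index(names="barcode")
    sheet.to_csv(dir_path / "samples.tsv", sep="\t", index=False)


def read_matrix_market(path) -> sp.csr_matrix:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing matrix file {path}")
    return sp.csr_matrix(scipy.io.mmread(str(path)))
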