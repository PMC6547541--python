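"""Core containers and readers/writers for expression data and annotation tables.

The central object is :class:`ExpressionMatrix`, a gene x cell count matrix with
identifiers. Genes are rows, cells are columns, and all coordinates are 0-based
internally (Matrix Market files are 1-based on disk, as the format dictates).
Supporting containers hold gene-set collections (GMT), "regulator of gene
expression" annotations, and gene essentiality tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared format."""


def _check_unique(values, what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dupes = s[s.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Gene x cell expression counts.

    Parameters
    ----------
    genes
        Ordered gene identifiers (rows).
    cells
        Ordered cell identifiers (columns).
    counts
        Non-negative gene x cell matrix (dense ndarray or scipy sparse).
    normalized
        Whether library-size normalisation has been applied.
    pseudocount
        Scalar added inside log transforms downstream.
    """

    genes: np.ndarray
    cells: np.ndarray
    counts: object
    normalized: bool = False
    pseudocount: float = 1.0

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts, dtype=np.float64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        if self.dense().size and self.dense().min() < 0:
            raise ValueError("counts must be non-negative")

    # -- basic views -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return self.counts.toarray()
        return self.counts

    def sparsity(self) -> float:
        """Fraction of zero entries: 1 - nnz / (rows * cols)."""
        total = self.n_genes * self.n_cells
        if total == 0:
            return 0.0
        if sp.issparse(self.counts):
            nnz = self.counts.count_nonzero()
        else:
            nnz = int(np.count_nonzero(self.counts))
        return 1.0 - nnz / total

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.dense().sum(axis=0)).ravel()

    def expressed_mask(self, min_cells: int = 5) -> np.ndarray:
        """Boolean mask of genes detected (count > 0) in at least `min_cells` cells.

        All-zero genes are retained in the container but excluded from
        differential expression and correlation through this mask.
        """
        detected = (self.dense() > 0).sum(axis=1)
        return detected >= min_cells

    def log_values(self) -> np.ndarray:
        """log2(counts + pseudocount), dense."""
        return np.log2(self.dense() + self.pseudocount)

    def subset_cells(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.genes, self.cells[idx], self.dense()[:, idx],
            normalized=self.normalized, pseudocount=self.pseudocount,
        )

    def subset_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.genes[idx], self.cells, self.dense()[idx, :],
            normalized=self.normalized, pseudocount=self.pseudocount,
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dense(), index=self.genes, columns=self.cells)
        df.to_csv(path, sep="\t", index_label="gene")

    def to_mtx_dir(self, path) -> None:
        """Write a 10x-style triplet directory: matrix.mtx, genes.tsv, barcodes.tsv."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(self.dense()))
        pd.Series(self.genes).to_csv(path / "genes.tsv", sep="\t",
                                     index=False, header=False)
        pd.Series(self.cells).to_csv(path / "barcodes.tsv", sep="\t",
                                     index=False, header=False)


def read_counts(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a count matrix from a dense TSV/CSV file or a Matrix Market directory.

    ``fmt`` is one of ``"tsv"``, ``"csv"``, ``"mtx"``; inferred from the path
    when omitted (a directory implies the 10x triplet layout).
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix.lower() == ".csv":
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "mtx":
        return _read_mtx_dir(path)
    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise ParseError(f"{path}: no data columns found")
    return ExpressionMatrix(df.index.to_numpy(), df.columns.to_numpy(),
                            df.to_numpy(dtype=float))


def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    mtx_path = None
    for name in ("matrix.mtx", "matrix.mtx.gz"):
        if (path / name).exists():
            mtx_path = path / name
            break
    if mtx_path is None:
        raise ParseError(f"{path}: no matrix.mtx found")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:
        raise ParseError(f"{mtx_path}: malformed Matrix Market file: {exc}") from exc

    def _read_ids(*names):
        for name in names:
            p = path / name
            if p.exists():
                return pd.read_csv(p, sep="\t", header=None)[0].to_numpy()
        raise ParseError(f"{path}: missing identifier file (tried {names})")

    genes = _read_ids("genes.tsv", "features.tsv")
    cells = _read_ids("barcodes.tsv")
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise ParseError(
            f"{path}: matrix dimensions {mat.shape} do not match "
            f"{len(genes)} genes / {len(cells)} barcodes"
        )
    return ExpressionMatrix(genes, cells, mat)


def normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalisation: scale every cell to the mean library size.

    Cells with zero total counts are removed with a warning. The result has
    ``normalized=True``; column sums are all equal to the mean library size of
    the retained cells.
    """
    libs = expr.library_sizes()
    keep = libs > 0
    if not keep.all():
        warnings.warn(f"removed {int((~keep).sum())} zero-library cells")
    counts = expr.dense()[:, keep]
    libs = libs[keep]
    if libs.size == 0:
        raise ValueError("no cells with non-zero library size")
    target = libs.mean()
    scaled = counts * (target / libs)[None, :]
    return ExpressionMatrix(expr.genes, expr.cells[keep], scaled,
                            normalized=True, pseudocount=expr.pseudocount)


# ---------------------------------------------------------------------------
# gene sets, regulators, essentiality


@dataclass
class GeneSetCollection:
    """Named gene sets (MSigDB-style); `universe` is the union of all members."""

    sets: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            self.sets[name] = set(members)

    @property
    def universe(self) -> set:
        out = set()
        for members in self.sets.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, fields name, description, members."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            sets[name] = members
    if not sets:
        warnings.warn(f"{path}: empty GMT file, returning empty collection")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


@dataclass
class RegulatorAnnotation:
    """Genes annotated as regulators of gene expression (GO:0010468 subtree)."""

    regulators: set = field(default_factory=set)

    def __contains__(self, gene) -> bool:
        return gene in self.regulators

    def __len__(self) -> int:
        return len(self.regulators)


def regulators_from_obo_gaf(obo_path, gaf_path,
                            root_term: str = "GO:0010468"
                            ) -> RegulatorAnnotation:
    """Extract regulator genes from an ontology + annotation file pair.

    Collects the ontology closure (the root term and all of its descendants,
    e.g. everything under "regulation of gene expression") and returns the
    genes annotated to any term in that closure. Pinning results to a
    versioned OBO/GAF pair matters because ontology releases drift; the flat
    two-column regulator file produced from this helper is the reproducible
    input for network construction.
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(obo_path)
    if root_term not in graph:
        raise ParseError(f"{obo_path}: term {root_term} not found")
    # obonet edges point child -> parent, so descendants of the root are its
    # networkx "ancestors"
    closure = {root_term} | nx.ancestors(graph, root_term)
    regs = set()
    with open(gaf_path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError(f"{gaf_path}: annotation line with "
                                 f"{len(fields)} fields")
            if fields[4] in closure:
                regs.add(fields[2])
    return RegulatorAnnotation(regs)


def read_regulators(path) -> RegulatorAnnotation:
    """Read a flat one- or two-column TSV of regulator gene identifiers.

    Only the first column is used; extra columns (e.g. the GO term of origin)
    are ignored.
    """
    regs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            regs.add(line.split("\t")[0])
    return RegulatorAnnotation(regs)


@dataclass
class EssentialityTable:
    """Per-gene essentiality status (e.g. from the OGEE database)."""

    table: pd.DataFrame  # columns: gene, essential (bool)

    def __post_init__(self):
        if list(self.table.columns[:2]) != ["gene", "essential"]:
            self.table = self.table.rename(
                columns=dict(zip(self.table.columns[:2], ["gene", "essential"]))
            )
        _check_unique(self.table["gene"], "gene")
        self.table = self.table.reset_index(drop=True)

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene"].to_numpy()

    @property
    def essential(self) -> np.ndarray:
        return self.table["essential"].to_numpy(dtype=bool)

    def counts(self) -> tuple[int, int]:
        e = int(self.essential.sum())
        return e, len(self.table) - e


_TRUTHY = {"1", "true", "yes", "y", "e", "essential"}
_FALSY = {"0", "false", "no", "n", "ne", "nonessential", "non-essential"}


def read_essentiality(path) -> EssentialityTable:
    """Read a two-column TSV: gene, essential status (boolean-ish labels)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "essential"], dtype=str)
    # tolerate a header row
    if str(df.iloc[0, 0]).lower() in {"gene", "symbol"}:
        df = df.iloc[1:]

    def to_bool(v):
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise ParseError(f"{path}: unrecognised essentiality label {v!r}")

    df = pd.DataFrame({
        "gene": df["gene"].astype(str),
        "essential": df["essential"].map(to_bool),
    })
    return EssentialityTable(df)


def case_insensitive_map(query, reference) -> dict:
    """Map identifiers in `query` to identifiers in `reference` ignoring case.

    Mouse symbols are capitalised (Actb) where human ones are upper-case
    (ACTB); this matcher is used only at the boundary with gene sets and
    essentiality tables. Ambiguous folds resolve to the first occurrence in
    `reference`.
    """
    folded = {}
    for r in reference:
        folded.setdefault(str(r).lower(), r)
    return {q: folded[str(q).lower()] for q in query if str(q).lower() in folded}
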