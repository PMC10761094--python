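"""Reading, writing and validating drug-disease association data.

The data layout follows the drug-repositioning benchmark convention:
a binary association matrix ``Y`` with drugs as rows and diseases as
columns, a square drug-drug similarity matrix (chemical-substructure
based) and a square disease-disease similarity matrix (phenotype
semantic based), both with scores in [0, 1].

Dense matrices travel as TSV/CSV (optionally with a header row and an
index column); sparse association matrices additionally as MatrixMarket
(``.mtx``).  A dataset directory holds ``assoc.{tsv|csv|mtx}``,
``drug_sim.tsv``, ``disease_sim.tsv`` and an optional ``meta.yaml``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "SimilarityMatrix",
    "AssociationMatrix",
    "DatasetSummary",
    "DrugDiseaseDataset",
    "MatrixFormatError",
    "MatrixValidationError",
    "load_association_matrix",
    "load_similarity_matrix",
    "write_association_matrix",
    "write_similarity_matrix",
    "dataset_summary",
    "load_dataset_dir",
    "write_dataset_dir",
]

SYMMETRY_TOL = 1e-8


class MatrixFormatError(ValueError):
    """A file could not be parsed as the expected matrix layout."""


class MatrixValidationError(ValueError):
    """A parsed matrix violates a domain invariant."""


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity scores in [0, 1] for one entity kind.

    Asymmetry within ``SYMMETRY_TOL`` is repaired by averaging with the
    transpose; larger asymmetry is rejected.  A diagonal different from
    1 triggers a warning, not an error (some published similarity files
    store self-similarity slightly below the maximum).
    """

    values: np.ndarray
    entity_ids: list[str] = field(default_factory=list)
    entity_kind: str = "drug"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise MatrixValidationError(
                f"similarity matrix must be square, got shape {self.values.shape}")
        asym = np.abs(self.values - self.values.T).max() if self.values.size else 0.0
        if asym > SYMMETRY_TOL:
            raise MatrixValidationError(
                f"similarity matrix asymmetric beyond tolerance ({asym:.3g} > {SYMMETRY_TOL:g})")
        if asym > 0:
            self.values = (self.values + self.values.T) / 2.0
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            bad = np.unravel_index(
                np.argmax(np.abs(self.values - np.clip(self.values, 0, 1))), self.values.shape)
            raise MatrixValidationError(
                f"similarity entry out of [0,1] at row {bad[0]}, column {bad[1]}: "
                f"{self.values[bad]!r}")
        if not self.entity_ids:
            prefix = "d" if self.entity_kind == "drug" else "s"
            self.entity_ids = [f"{prefix}{i}" for i in range(self.values.shape[0])]
        if len(self.entity_ids) != self.values.shape[0]:
            raise MatrixValidationError("entity_ids length does not match matrix size")
        if self.values.size and not np.allclose(np.diag(self.values), 1.0):
            warnings.warn(
                f"{self.entity_kind} similarity diagonal is not all 1", stacklevel=2)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AssociationMatrix:
    """Binary drug x disease association labels (drugs = rows)."""

    values: np.ndarray
    drug_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise MatrixValidationError(
                f"association matrix must be 2-D and non-empty, got shape {vals.shape}")
        bad = (vals != 0.0) & (vals != 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-binary association entry at row {i}, column {j}: {vals[i, j]!r}")
        self.values = vals.astype(np.int8)
        if not self.drug_ids:
            self.drug_ids = [f"d{i}" for i in range(vals.shape[0])]
        if not self.disease_ids:
            self.disease_ids = [f"s{j}" for j in range(vals.shape[1])]
        if len(self.drug_ids) != vals.shape[0] or len(self.disease_ids) != vals.shape[1]:
            raise MatrixValidationError("label lengths do not match matrix shape")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class DatasetSummary:
    """Benchmark-table style counts: drugs, diseases, positives, sparsity."""

    n_drugs: int
    n_diseases: int
    n_associations: int
    sparsity: float

    def __str__(self) -> str:  # display convention: sparsity to 4 decimals
        return (f"{self.n_drugs} drugs x {self.n_diseases} diseases, "
                f"{self.n_associations} associations, sparsity {self.sparsity:.4f}")


@dataclass
class DrugDiseaseDataset:
    """The input triple the model consumes."""

    drug_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    assoc: AssociationMatrix

    def __post_init__(self) -> None:
        if self.drug_sim.n != self.assoc.n_drugs:
            raise MatrixValidationError(
                f"drug similarity is {self.drug_sim.n}x{self.drug_sim.n} but the "
                f"association matrix has {self.assoc.n_drugs} drug rows")
        if self.disease_sim.n != self.assoc.n_diseases:
            raise MatrixValidationError(
                f"disease similarity is {self.disease_sim.n}x{self.disease_sim.n} but the "
                f"association matrix has {self.assoc.n_diseases} disease columns")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.assoc.n_drugs, self.assoc.n_diseases)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    return {"tsv": "tsv", "csv": "csv", "mtx": "mtx", "txt": "tsv"}.get(suffix, "tsv")


def _is_number(token) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def _read_dense(path: Path, sep: str) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    """Read a dense table, auto-detecting an optional header row / index column."""
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                          comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if raw.empty:
        raise MatrixFormatError(f"{path} contains no data")
    first_row_numeric = all(_is_number(v) for v in raw.iloc[0])
    has_header = not first_row_numeric
    body = raw.iloc[1:] if has_header else raw
    first_col_numeric = all(_is_number(v) for v in body.iloc[:, 0])
    has_index = not first_col_numeric
    col_ids = None
    row_ids = None
    if has_header:
        cols = list(raw.iloc[0])
        col_ids = [str(c) for c in (cols[1:] if has_index else cols)]
    if has_index:
        row_ids = [str(v) for v in body.iloc[:, 0]]
        body = body.iloc[:, 1:]
    try:
        values = body.to_numpy(dtype=float)
    except ValueError as exc:
        for i in range(body.shape[0]):
            for j in range(body.shape[1]):
                if not _is_number(body.iloc[i, j]):
                    raise MatrixFormatError(
                        f"{path}: non-numeric value {body.iloc[i, j]!r} at data "
                        f"row {i}, column {j}") from exc
        raise MatrixFormatError(f"{path}: {exc}") from exc
    return values, row_ids, col_ids


def _read_matrix(path: Path, fmt: str) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:
            raise MatrixFormatError(f"cannot parse {path} as MatrixMarket: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        return np.asarray(mat, dtype=float), None, None
    if fmt in ("tsv", "csv"):
        return _read_dense(path, "\t" if fmt == "tsv" else ",")
    raise MatrixFormatError(f"unknown format {fmt!r} (expected tsv, csv or mtx)")


# ---------------------------------------------------------------------------
# public loaders / writers
# ---------------------------------------------------------------------------

def load_association_matrix(path, format: str | None = None, *,
                            transpose: bool = False,
                            expected_associations: int | None = None) -> AssociationMatrix:
    """Load a binary association matrix (drugs = rows unless ``transpose``).

    ``expected_associations`` cross-checks the number of ones against
    declared metadata and raises on mismatch.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    values, row_ids, col_ids = _read_matrix(path, _infer_format(path, format))
    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    assoc = AssociationMatrix(values, drug_ids=row_ids or [], disease_ids=col_ids or [])
    if expected_associations is not None and assoc.n_associations != expected_associations:
        raise MatrixValidationError(
            f"file holds {assoc.n_associations} associations but metadata declares "
            f"{expected_associations}")
    return assoc


def load_similarity_matrix(path, format: str | None = None, *,
                           entity_kind: str = "drug") -> SimilarityMatrix:
    """Load a square symmetric similarity matrix with entries in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    values, row_ids, col_ids = _read_matrix(path, _infer_format(path, format))
    ids = row_ids or col_ids or []
    return SimilarityMatrix(values, entity_ids=ids, entity_kind=entity_kind)


def write_association_matrix(assoc: AssociationMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(assoc.values))
        return
    sep = "\t" if fmt == "tsv" else ","
    frame = pd.DataFrame(assoc.values, index=assoc.drug_ids, columns=assoc.disease_ids)
    frame.to_csv(path, sep=sep)


def write_similarity_matrix(sim: SimilarityMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    sep = "\t" if fmt == "tsv" else ","
    frame = pd.DataFrame(sim.values, index=sim.entity_ids, columns=sim.entity_ids)
    frame.to_csv(path, sep=sep, float_format="%.17g")


def dataset_summary(assoc: AssociationMatrix) -> DatasetSummary:
    """Counts and sparsity (= positives / all pairs) of an association matrix."""
    n, m = assoc.values.shape
    ones = assoc.n_associations
    return DatasetSummary(n_drugs=n, n_diseases=m, n_associations=ones,
                          sparsity=ones / (n * m))


# ---------------------------------------------------------------------------
# dataset directory convention
# ---------------------------------------------------------------------------

def load_dataset_dir(path) -> DrugDiseaseDataset:
    """Load ``assoc.{tsv|csv|mtx}``, ``drug_sim.tsv``, ``disease_sim.tsv``.

    An optional ``meta.yaml`` may declare ``n_associations`` (verified)
    and ``transpose: true`` when the association file stores diseases
    as rows.
    """
    path = Path(path)
    meta: dict = {}
    meta_path = path / "meta.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
    assoc_path = None
    for candidate in ("assoc.tsv", "assoc.csv", "assoc.mtx"):
        if (path / candidate).exists():
            assoc_path = path / candidate
            break
    if assoc_path is None:
        raise FileNotFoundError(f"no assoc.{{tsv|csv|mtx}} in {path}")
    assoc = load_association_matrix(
        assoc_path,
        transpose=bool(meta.get("transpose", False)),
        expected_associations=meta.get("n_associations"))
    drug_sim = load_similarity_matrix(path / "drug_sim.tsv", entity_kind="drug")
    disease_sim = load_similarity_matrix(path / "disease_sim.tsv", entity_kind="disease")
    return DrugDiseaseDataset(drug_sim=drug_sim, disease_sim=disease_sim, assoc=assoc)


def write_dataset_dir(data: DrugDiseaseDataset, path, *, assoc_format: str = "tsv") -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_association_matrix(data.assoc, path / f"assoc.{assoc_format}")
    write_similarity_matrix(data.drug_sim, path / "drug_sim.tsv")
    write_similarity_matrix(data.disease_sim, path / "disease_sim.tsv")
    summary = dataset_summary(data.assoc)
    (path / "meta.yaml").write_text(yaml.safe_dump({
        "n_drugs": summary.n_drugs,
        "n_diseases": summary.n_diseases,
        "n_associations": summary.n_associations,
        "sparsity": float(summary.sparsity),
    }))
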