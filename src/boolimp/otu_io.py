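"""Reading, writing and normalizing OTU tables and sample metadata.

Classic QIIME OTU tables are tab-delimited with a ``#OTU ID`` leading header
cell, rows = OTUs, columns = samples, and an optional trailing ``taxonomy``
column.  On disk the orientation is OTUs x samples; everything downstream of
this module works samples x OTUs, so the single transpose lives here.

BIOM support covers feature-table semantics only: BIOM 1.0 (JSON, dense or
sparse) and BIOM 2.x (HDF5, CSR layout) are read into the same
:class:`CountMatrix`; writing emits BIOM 1.0 JSON.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "AbundanceMatrix",
    "SampleMetadata",
    "Scaling",
    "OtuIOError",
    "FormatError",
    "DuplicateIdError",
    "AlignmentError",
    "MISSING",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "transform_log2",
    "align_samples",
]

#: Marker stored for empty metadata cells, distinct from a real empty string.
MISSING = None


class OtuIOError(ValueError):
    """Base class for OTU table / metadata I/O failures."""


class FormatError(OtuIOError):
    """Malformed file: bad header, non-numeric count, unknown format."""


class DuplicateIdError(OtuIOError):
    """Duplicate OTU or sample identifier in one table."""


class AlignmentError(OtuIOError):
    """Sample sets of matrix and metadata do not intersect."""


class Scaling(str, Enum):
    """Per-sample depth normalization applied before the log2 transform."""

    NONE = "none"
    TOTAL_SUM = "total_sum"


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountMatrix:
    """Raw counts, samples x OTUs.

    Parameters
    ----------
    values
        Non-negative array of shape ``(n_samples, n_otus)``.
    sample_ids, otu_ids
        Unique identifiers for rows and columns.
    taxonomy
        Optional per-OTU taxonomy strings carried through from the classic
        table's trailing column; never used by the statistics.
    """

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise OtuIOError("count matrix must be 2-D (samples x otus)")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.otu_ids = _check_ids(self.otu_ids, "OTU")
        ns, no = self.values.shape
        if ns != len(self.sample_ids) or no != len(self.otu_ids):
            raise OtuIOError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.all(np.isfinite(self.values)):
            raise OtuIOError("counts must be finite")
        if np.any(self.values < 0):
            raise OtuIOError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class AbundanceMatrix:
    """Log2-scale abundances, samples x OTUs, with provenance of the transform."""

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    pseudocount: float = 1.0
    scaling: Scaling = Scaling.NONE
    target_depth: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scaling = Scaling(self.scaling)
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.otu_ids = _check_ids(self.otu_ids, "OTU")
        ns, no = self.values.shape
        if ns != len(self.sample_ids) or no != len(self.otu_ids):
            raise OtuIOError("abundance shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise OtuIOError("log2 abundances must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def column(self, otu_id: str) -> np.ndarray:
        try:
            j = self.otu_ids.index(otu_id)
        except ValueError:
            raise KeyError(f"unknown OTU id {otu_id!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class SampleMetadata:
    """Per-sample categorical factors from a QIIME mapping file.

    Values are kept verbatim as strings; empty cells become :data:`MISSING`
    (``None``) so a genuinely empty string in the file is distinguishable.
    """

    sample_ids: list[str]
    factors: dict[str, list[str | None]]

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for name, col in self.factors.items():
            if len(col) != n:
                raise OtuIOError(f"factor {name!r} has {len(col)} values for {n} samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def factor(self, name: str) -> dict[str, str | None]:
        if name not in self.factors:
            raise KeyError(f"unknown metadata factor {name!r}")
        return dict(zip(self.sample_ids, self.factors[name]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.factors, index=self.sample_ids)


# ---------------------------------------------------------------------------
# classic QIIME TSV


def _read_classic_tsv(path: Path) -> CountMatrix:
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    # tolerate a leading "# Constructed from biom file" comment line
    while lines and lines[0].startswith("#") and not lines[0].startswith("#OTU ID"):
        lines.pop(0)
    if not lines or not lines[0].split("\t")[0] == "#OTU ID":
        raise FormatError(f"{path}: classic OTU table must start with a '#OTU ID' header")
    header = lines[0].split("\t")
    has_tax = header and header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_tax else None]
    otu_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    rows: list[list[float]] = []
    ncol = len(header)
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != ncol:
            raise FormatError(f"{path}: row {parts[0]!r} has {len(parts)} fields, expected {ncol}")
        otu = parts[0]
        if has_tax:
            taxonomy[otu] = parts[-1]
            vals = parts[1:-1]
        else:
            vals = parts[1:]
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric count in row {otu!r}: {exc}") from None
        otu_ids.append(otu)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    # disk layout is OTUs x samples; internal convention is samples x OTUs
    return CountMatrix(values.T, sample_ids, otu_ids, taxonomy)


def write_otu_table(m: CountMatrix, path: str | Path) -> None:
    """Write a classic QIIME TSV (OTUs x samples, '#OTU ID' header)."""
    path = Path(path)
    has_tax = bool(m.taxonomy)
    with open(path, "wt", encoding="utf-8") as fh:
        header = ["#OTU ID", *m.sample_ids] + (["taxonomy"] if has_tax else [])
        fh.write("\t".join(header) + "\n")
        for j, otu in enumerate(m.otu_ids):
            col = m.values[:, j]
            cells = [otu] + [_fmt_count(v) for v in col]
            if has_tax:
                cells.append(m.taxonomy.get(otu, ""))
            fh.write("\t".join(cells) + "\n")


def _fmt_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# BIOM


def _read_biom_json(path: Path) -> CountMatrix:
    with open(path, "rt", encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mtype = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM 1.0 table ({exc})") from None
    values = np.zeros(shape, dtype=float)
    if mtype == "dense":
        values[:] = np.asarray(data, dtype=float)
    else:
        for r, c, v in data:
            values[int(r), int(c)] = float(v)
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        if isinstance(md, dict) and "taxonomy" in md:
            tax = md["taxonomy"]
            taxonomy[r["id"]] = "; ".join(tax) if isinstance(tax, list) else str(tax)
    return CountMatrix(values.T, sample_ids, otu_ids, taxonomy)


def _read_biom_hdf5(path: Path) -> CountMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        otu_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
    from scipy.sparse import csr_matrix

    mat = csr_matrix((data, indices, indptr), shape=(len(otu_ids), len(sample_ids)))
    return CountMatrix(np.asarray(mat.todense(), dtype=float).T, sample_ids, otu_ids)


def write_biom_json(m: CountMatrix, path: str | Path, table_id: str = "boolimp") -> None:
    """Write a minimal dense BIOM 1.0 JSON feature table."""
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "boolimp",
        "date": datetime.datetime.now().isoformat(),
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [m.n_otus, m.n_samples],
        "rows": [
            {"id": o, "metadata": ({"taxonomy": m.taxonomy[o]} if o in m.taxonomy else None)}
            for o in m.otu_ids
        ],
        "columns": [{"id": s, "metadata": None} for s in m.sample_ids],
        "data": m.values.T.tolist(),
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_otu_table(path: str | Path, format_hint: str = "auto") -> CountMatrix:
    """Read an OTU table into samples x OTUs orientation.

    ``format_hint`` is one of ``classic_tsv``, ``biom`` or ``auto``.  BIOM
    dispatches on the file's leading bytes (HDF5 magic vs JSON).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint == "classic_tsv":
        return _read_classic_tsv(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
    is_hdf5 = magic.startswith(b"\x89HDF\r\n\x1a\n")
    if format_hint == "biom":
        return _read_biom_hdf5(path) if is_hdf5 else _read_biom_json(path)
    if format_hint != "auto":
        raise ValueError(f"unknown format_hint {format_hint!r}")
    if is_hdf5:
        return _read_biom_hdf5(path)
    if magic.lstrip()[:1] == b"{":
        return _read_biom_json(path)
    return _read_classic_tsv(path)


# ---------------------------------------------------------------------------
# metadata mapping files


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a QIIME mapping file ('#SampleID' header, tab-delimited)."""
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0].split("\t")[0] != "#SampleID":
        raise FormatError(f"{path}: mapping file must start with a '#SampleID' header")
    header = lines[0].split("\t")
    factor_names = header[1:]
    sample_ids: list[str] = []
    columns: list[list[str | None]] = [[] for _ in factor_names]
    for ln in lines[1:]:
        parts = ln.split("\t")
        parts += [""] * (len(header) - len(parts))
        sample_ids.append(parts[0])
        for k in range(len(factor_names)):
            cell = parts[1 + k]
            columns[k].append(MISSING if cell == "" else cell)
    return SampleMetadata(sample_ids, dict(zip(factor_names, columns)))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        names = list(meta.factors)
        fh.write("\t".join(["#SampleID", *names]) + "\n")
        for i, sid in enumerate(meta.sample_ids):
            cells = [sid] + [
                "" if meta.factors[n][i] is MISSING else str(meta.factors[n][i]) for n in names
            ]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# transforms


def transform_log2(
    m: CountMatrix,
    pseudocount: float = 1.0,
    scaling: Scaling | str = Scaling.NONE,
    target_depth: float = 10_000.0,
) -> AbundanceMatrix:
    """Log2-transform counts: ``log2(scaled_count + pseudocount)``.

    With ``scaling=total_sum`` each sample is first rescaled to
    ``target_depth`` total counts; with ``none`` counts are taken as-is
    (appropriate for tables that arrive pre-normalized).
    """
    scaling = Scaling(scaling)
    vals = m.values
    if scaling is Scaling.TOTAL_SUM:
        depths = vals.sum(axis=1)
        if np.any(depths <= 0):
            bad = [m.sample_ids[i] for i in np.nonzero(depths <= 0)[0]]
            raise OtuIOError(f"zero-total samples under total_sum scaling: {bad}")
        vals = vals * (target_depth / depths)[:, None]
    if pseudocount <= 0 and np.any(vals == 0):
        raise ValueError("pseudocount must be > 0 when zero counts are present")
    return AbundanceMatrix(
        np.log2(vals + pseudocount),
        list(m.sample_ids),
        list(m.otu_ids),
        pseudocount=pseudocount,
        scaling=scaling,
        target_depth=target_depth if scaling is Scaling.TOTAL_SUM else None,
    )


def align_samples(
    m: AbundanceMatrix, meta: SampleMetadata
) -> tuple[AbundanceMatrix, SampleMetadata, list[str]]:
    """Restrict matrix and metadata to their shared samples, same order.

    Returns ``(matrix, metadata, dropped_ids)`` where ``dropped_ids`` lists
    samples present on one side only (matrix order first, then metadata).
    """
    meta_set = set(meta.sample_ids)
    shared = [s for s in m.sample_ids if s in meta_set]
    if not shared:
        raise AlignmentError("matrix and metadata share no sample ids")
    shared_set = set(shared)
    dropped = [s for s in m.sample_ids if s not in shared_set]
    dropped += [s for s in meta.sample_ids if s not in shared_set]
    idx = [m.sample_ids.index(s) for s in shared]
    am = AbundanceMatrix(
        m.values[idx, :],
        shared,
        list(m.otu_ids),
        pseudocount=m.pseudocount,
        scaling=m.scaling,
        target_depth=m.target_depth,
    )
    meta_pos = {s: i for i, s in enumerate(meta.sample_ids)}
    factors = {
        name: [col[meta_pos[s]] for s in shared] for name, col in meta.factors.items()
    }
    return am, SampleMetadata(shared, factors), dropped
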