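"""Reading and validating expression matrices and dataset registries.

A *dataset* is one already-normalized gene x sample expression matrix from a
purified-microglia study (microarray intensities, RNA-seq quantifications, or
a Mars-seq-like single-cell aggregate with limited gene detection).  This
module loads such matrices from delimited text or MatrixMarket triplets,
harmonizes gene symbols across species by case-folding (mouse *Oprm1* and
human *OPRM1* share the key ``OPRM1``), and reads the dataset registry that
assigns each matrix its platform, species, tissue and analysis group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

log = logging.getLogger(__name__)

PLATFORMS = frozenset({"microarray", "rnaseq", "sc_like"})
SPECIES = frozenset({"mouse", "rat", "human"})
SEXES = frozenset({"female", "male", "mixed", "unknown"})


class ValidationError(ValueError):
    """Input violates a structural invariant (shape, sign, uniqueness)."""


class ParseError(ValueError):
    """Input file is malformed."""


class AmbiguousSymbolError(ValidationError):
    """Two distinct gene rows collide on the same harmonized key."""


def canonical_symbol(symbol: str) -> str:
    """Case-folded matching key for a gene symbol (``Oprm1`` -> ``OPRM1``)."""
    return symbol.strip().upper()


@dataclass
class ExpressionDataset:
    """One dataset's gene x sample expression matrix plus metadata.

    ``values`` is genes x samples on the linear (pre-log) scale unless
    ``is_log2`` is set, in which case it holds log2(1+x)-transformed values.
    """

    dataset_id: str
    gene_symbols: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform: str = "rnaseq"
    species: str = "mouse"
    tissue: str = "unknown"
    group: str = "default"
    sex: str = "unknown"
    is_log2: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"{self.dataset_id}: values must be 2-D")
        if self.values.shape != (len(self.gene_symbols), len(self.sample_ids)):
            raise ValidationError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.gene_symbols)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 1:
            raise ValidationError(f"{self.dataset_id}: at least one sample required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(f"{self.dataset_id}: duplicate sample ids")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValidationError(f"{self.dataset_id}: duplicate gene symbols")
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"{self.dataset_id}: unknown platform {self.platform!r}; "
                f"allowed: {sorted(PLATFORMS)}"
            )
        if self.species not in SPECIES:
            raise ValidationError(
                f"{self.dataset_id}: unknown species {self.species!r}; "
                f"allowed: {sorted(SPECIES)}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"{self.dataset_id}: unknown sex {self.sex!r}; allowed: {sorted(SEXES)}"
            )
        if not self.is_log2 and np.any(self.values < 0):
            raise ValidationError(
                f"{self.dataset_id}: negative expression values present "
                "(pass clip_negative=True to the reader to clip at zero)"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def symbol_keys(self) -> list[str]:
        return [canonical_symbol(s) for s in self.gene_symbols]

    def to_log2(self) -> "ExpressionDataset":
        """Return a copy with values log2(1+x)-transformed (idempotent)."""
        if self.is_log2:
            return self
        return replace(self, values=np.log2(1.0 + self.values), is_log2=True)


@dataclass
class DatasetRecord:
    """One registry row: where a dataset lives and how it is analyzed."""

    dataset_id: str
    path: str
    platform: str
    species: str
    tissue: str
    group: str
    display_label: str = ""
    include_in_correlation: bool = True
    sex: str = "unknown"

    def __post_init__(self) -> None:
        for attr, vocab in (("platform", PLATFORMS), ("species", SPECIES), ("sex", SEXES)):
            val = getattr(self, attr)
            if val not in vocab:
                raise ValidationError(
                    f"dataset {self.dataset_id!r}: unknown {attr} {val!r}; "
                    f"allowed values: {sorted(vocab)}"
                )
        if not self.display_label:
            self.display_label = self.dataset_id


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path: Path) -> pd.DataFrame:
    sep = {".tsv": "\t", ".txt": "\t", ".csv": ","}.get(path.suffix.lower())
    try:
        if sep is None:
            frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
        else:
            # pandas silently mangles duplicate header names; check them raw
            with open(path) as fh:
                header = fh.readline().rstrip("\r\n").split(sep)[1:]
            if len(set(header)) != len(header):
                dupes = sorted({h for h in header if header.count(h) > 1})
                raise ValidationError(f"{path}: duplicate sample ids {dupes}")
            frame = pd.read_csv(path, sep=sep, index_col=0,
                                float_precision="round_trip")
    except (ValidationError, FileNotFoundError):
        raise
    except Exception as exc:  # pandas raises many flavours; unify
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (missing header?)")
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ]
    if len(non_numeric):
        raise ParseError(
            f"{path}: non-numeric values in columns {list(non_numeric)[:3]}"
        )
    return frame


def _read_mtx_triplet(path: Path) -> pd.DataFrame:
    genes_file = path.with_suffix("").with_suffix(path.suffix + ".genes.txt")
    # sidecars live next to the matrix: <name>.mtx + <name>.genes.txt / .samples.txt
    stem = path.with_suffix("")
    genes_file = Path(str(stem) + ".genes.txt")
    samples_file = Path(str(stem) + ".samples.txt")
    for sidecar in (genes_file, samples_file):
        if not sidecar.exists():
            raise ParseError(f"missing sidecar list {sidecar} for {path}")
    genes = genes_file.read_text().split()
    samples = samples_file.read_text().split()
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(genes), len(samples)):
        raise ParseError(
            f"{path}: matrix is {mat.shape} but sidecars list "
            f"{len(genes)} genes x {len(samples)} samples"
        )
    return pd.DataFrame(mat, index=genes, columns=samples)


def read_expression_matrix(
    path: str | Path,
    layout: str = "genes_by_samples",
    fmt: str | None = None,
    dataset_id: str | None = None,
    clip_negative: bool = False,
    collapse: str = "mean",
) -> ExpressionDataset:
    """Read an expression matrix into a partially-filled :class:`ExpressionDataset`.

    Metadata (platform, species, tissue, group) defaults until attached from a
    registry record with :func:`attach_metadata`.  Duplicate gene rows — e.g.
    multiple microarray probes reported under one symbol, or case variants of
    the same symbol — are collapsed by arithmetic mean on the linear scale.

    Parameters
    ----------
    layout
        ``genes_by_samples`` (rows are genes) or ``samples_by_genes``.
    fmt
        ``delimited`` or ``mtx_triplet``; inferred from the extension if None.
    clip_negative
        Clip negative upstream-normalized values at zero instead of failing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown layout {layout!r}")
    if fmt is None:
        fmt = "mtx_triplet" if path.suffix.lower() == ".mtx" else "delimited"
    if fmt == "delimited":
        frame = _read_delimited(path)
    elif fmt == "mtx_triplet":
        frame = _read_mtx_triplet(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if layout == "samples_by_genes":
        frame = frame.T

    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].unique()
        raise ValidationError(f"{path}: duplicate sample ids {list(dupes)[:3]}")

    values = frame.to_numpy(dtype=float)
    if np.any(values < 0):
        if clip_negative:
            n_neg = int(np.sum(values < 0))
            log.warning("%s: clipped %d negative values at zero", path, n_neg)
            values = np.clip(values, 0.0, None)
            frame = pd.DataFrame(values, index=frame.index, columns=frame.columns)
        else:
            raise ValidationError(
                f"{path}: negative expression values present; pass "
                "clip_negative=True to clip at zero"
            )

    symbols = [str(s) for s in frame.index]
    keys = [canonical_symbol(s) for s in symbols]
    if len(set(keys)) != len(keys):
        if collapse != "mean":
            raise ValueError(f"unknown collapse policy {collapse!r}")
        n_before = len(keys)
        grouped = frame.groupby(pd.Index(keys, name="key"), sort=False)
        first_spelling = {}
        for sym, key in zip(symbols, keys):
            first_spelling.setdefault(key, sym)
        frame = grouped.mean()
        frame.index = [first_spelling[k] for k in frame.index]
        log.info(
            "%s: collapsed %d duplicate gene rows by linear-scale mean "
            "(%d -> %d rows)", path, n_before - len(frame), n_before, len(frame),
        )

    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        gene_symbols=[str(s) for s in frame.index],
        sample_ids=[str(c) for c in frame.columns],
        values=frame.to_numpy(dtype=float),
    )


def write_expression_matrix(ds: ExpressionDataset, path: str | Path) -> Path:
    """Write a dataset as a genes x samples TSV (round-trips exactly)."""
    path = Path(path)
    frame = pd.DataFrame(ds.values, index=ds.gene_symbols, columns=ds.sample_ids)
    frame.index.name = "gene"
    # shortest-repr floats + round_trip parsing on read keep values bit-exact
    frame.to_csv(path, sep="\t")
    return path


def attach_metadata(ds: ExpressionDataset, record: DatasetRecord) -> ExpressionDataset:
    """Fill a dataset's metadata fields from its registry record."""
    return replace(
        ds,
        dataset_id=record.dataset_id,
        platform=record.platform,
        species=record.species,
        tissue=record.tissue,
        group=record.group,
        sex=record.sex,
    )


# ---------------------------------------------------------------------------
# symbol harmonization and target resolution
# ---------------------------------------------------------------------------

def harmonize_gene_symbols(ds: ExpressionDataset) -> tuple[ExpressionDataset, dict[str, str]]:
    """Map symbols to canonical case-folded keys, preserving original spelling.

    Returns the dataset unchanged (harmonization is lossless; matching happens
    through ``symbol_keys``) together with the original->key mapping table.
    """
    mapping = {s: canonical_symbol(s) for s in ds.gene_symbols}
    return ds, mapping


def resolve_target(ds: ExpressionDataset, symbol: str) -> np.ndarray | None:
    """Per-sample value vector for *symbol*, or None when the gene is absent.

    Absence (the Mars-seq "not expressed in the dataset" situation) is an
    expected outcome, reported as None rather than an error.  Two rows
    colliding on the harmonized key make the lookup ambiguous and raise.
    """
    key = canonical_symbol(symbol)
    hits = [i for i, k in enumerate(ds.symbol_keys) if k == key]
    if not hits:
        return None
    if len(hits) > 1:
        spellings = [ds.gene_symbols[i] for i in hits]
        raise AmbiguousSymbolError(
            f"{ds.dataset_id}: symbol {symbol!r} matches {len(hits)} rows "
            f"after harmonization: {spellings}"
        )
    return ds.values[hits[0], :]


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = [
    "dataset_id", "path", "platform", "species", "tissue", "group",
    "display_label", "include_in_correlation",
]

_TRUTHY = {"true", "1", "yes", "y"}
_FALSY = {"false", "0", "no", "n"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, np.integer)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUTHY:
        return True
    if token in _FALSY:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean flag")


def load_registry(path: str | Path) -> list[DatasetRecord]:
    """Load a dataset registry from YAML or TSV.

    Records flagged ``include_in_correlation=false`` (the declared outlier
    exclusions) are carried through so the exclusion is applied — and logged —
    at the correlation stage, not silently at load time.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        payload = yaml.safe_load(path.read_text())
        if isinstance(payload, dict):
            payload = payload.get("datasets", payload)
        if not isinstance(payload, list):
            raise ParseError(f"{path}: expected a list of dataset records")
        rows = payload
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _REGISTRY_COLUMNS[:6] if c not in frame.columns]
        if missing:
            raise ParseError(f"{path}: missing registry columns {missing}")
        rows = frame.to_dict(orient="records")

    records: list[DatasetRecord] = []
    seen: set[str] = set()
    for row in rows:
        row = {k: v for k, v in dict(row).items() if v is not None and v == v}
        incl = _parse_bool(row.get("include_in_correlation", True))
        rec = DatasetRecord(
            dataset_id=str(row["dataset_id"]),
            path=str(row.get("path", "")),
            platform=str(row["platform"]),
            species=str(row["species"]),
            tissue=str(row["tissue"]),
            group=str(row["group"]),
            display_label=str(row.get("display_label", "") or ""),
            include_in_correlation=incl,
            sex=str(row.get("sex", "unknown")),
        )
        if rec.dataset_id in seen:
            raise ValidationError(f"{path}: duplicate dataset_id {rec.dataset_id!r}")
        seen.add(rec.dataset_id)
        records.append(rec)
    return records


def write_registry(records: Sequence[DatasetRecord], path: str | Path) -> Path:
    """Write registry records as YAML."""
    path = Path(path)
    payload = [
        {
            "dataset_id": r.dataset_id, "path": r.path, "platform": r.platform,
            "species": r.species, "tissue": r.tissue, "group": r.group,
            "display_label": r.display_label,
            "include_in_correlation": r.include_in_correlation, "sex": r.sex,
        }
        for r in records
    ]
    path.write_text(yaml.safe_dump({"datasets": payload}, sort_keys=False))
    return path


def load_datasets(
    records: Sequence[DatasetRecord], base_dir: str | Path = "."
) -> list[ExpressionDataset]:
    """Read every registry record's matrix and attach its metadata."""
    base = Path(base_dir)
    out = []
    for rec in records:
        p = Path(rec.path)
        if not p.is_absolute():
            p = base / p
        ds = read_expression_matrix(p, dataset_id=rec.dataset_id)
        out.append(attach_metadata(ds, rec))
    return out
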