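"""Abundance-table data model, I/O and taxa-level transformations.

The central currency is :class:`AbundanceTable`, a samples x taxa matrix of
raw counts or relative abundances with optional taxonomy annotations and
per-sample metadata.  Tables can be read from BIOM v1 (JSON), BIOM v2 (HDF5)
or a plain TSV OTU table (taxa as rows, samples as columns, optional trailing
``taxonomy`` column with semicolon-delimited ranks).
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AbundanceTable",
    "FormatError",
    "ValidationError",
    "EmptySelectionError",
    "RANKS",
    "read_biom",
    "read_metadata",
    "normalize_tss",
    "filter_dominance",
    "aggregate_taxa",
    "write_assignments",
    "write_tsv",
    "write_biom_json",
    "write_biom_hdf5",
]

#: Canonical rank order used by :func:`aggregate_taxa`.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_NORM_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in any supported dialect."""


class ValidationError(ValueError):
    """Raised when table contents violate an :class:`AbundanceTable` invariant."""


class EmptySelectionError(ValidationError):
    """Raised when a filtering operation would leave zero taxa."""


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with taxonomy and sample metadata.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (matrix rows).
    taxon_ids : list of str
        Ordered, unique taxon identifiers (matrix columns).
    values : ndarray of shape (n_samples, n_taxa)
        Non-negative, finite abundances; raw counts or relative abundances.
    taxonomy : dict, optional
        Map ``taxon_id -> tuple of rank names`` (kingdom..species order).
    metadata : dict
        Map ``sample_id -> {subject_id, time_index, ...}``; missing samples
        get empty metadata.
    normalized : bool
        True iff every row sums to 1 (total-sum scaling applied).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    taxonomy: dict[str, tuple[str, ...]] | None = None
    metadata: dict[str, dict] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.values = np.asarray(self.values, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, t = self.values.shape
        if n != len(self.sample_ids) or t != len(self.taxon_ids):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != t:
            raise ValidationError("duplicate taxon ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite abundance values")
        if np.any(self.values < 0):
            raise ValidationError("negative abundance values")
        if self.normalized and n > 0:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9, rtol=0):
                raise ValidationError("normalized flag set but row sums differ from 1")
        unknown = set(self.metadata) - set(self.sample_ids)
        if unknown:
            raise ValidationError(f"metadata refers to unknown samples: {sorted(unknown)}")

    # -- convenience ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_metadata(self, sample_id: str) -> dict:
        return self.metadata.get(sample_id, {})

    def with_values(self, values: np.ndarray, taxon_ids=None, taxonomy="keep",
                    normalized: bool | None = None) -> "AbundanceTable":
        """Return a copy with a new matrix (and optionally new taxa)."""
        taxon_ids = list(self.taxon_ids) if taxon_ids is None else list(taxon_ids)
        if taxonomy == "keep":
            taxonomy = (
                None
                if self.taxonomy is None
                else {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
            )
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=taxon_ids,
            values=np.asarray(values, dtype=float),
            taxonomy=taxonomy,
            metadata={s: dict(v) for s, v in self.metadata.items()},
            normalized=self.normalized if normalized is None else normalized,
        )


# ---------------------------------------------------------------------------
# Readers


def _rows_normalized(values: np.ndarray) -> bool:
    if values.size == 0:
        return False
    return bool(np.allclose(values.sum(axis=1), 1.0, atol=_NORM_TOL, rtol=0))


def parse_lineage(text: str | list | tuple | None) -> tuple[str, ...] | None:
    """Parse a taxonomy annotation into a tuple of rank names.

    Accepts semicolon-delimited strings (``k__Bacteria;p__Firmicutes;...``)
    or sequences.  Rank prefixes (``g__``) are preserved as written; empty
    trailing ranks are trimmed.
    """
    if text is None:
        return None
    if isinstance(text, (list, tuple)):
        parts = [str(p).strip() for p in text]
    else:
        parts = [p.strip() for p in str(text).split(";")]
    while parts and not parts[-1]:
        parts.pop()
    if not parts:
        return None
    return tuple(parts)


def read_metadata(path: str) -> dict[str, dict]:
    """Read a sample-metadata TSV with a mandatory ``sample_id`` column."""
    meta: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise FormatError(f"metadata file {path!r} lacks a 'sample_id' column")
        for row in reader:
            sid = row.pop("sample_id")
            rec = {k: v for k, v in row.items() if v not in (None, "")}
            if "time_index" in rec:
                try:
                    rec["time_index"] = int(rec["time_index"])
                except ValueError as exc:
                    raise FormatError(
                        f"non-integer time_index for sample {sid!r}"
                    ) from exc
                if rec["time_index"] < 0:
                    raise FormatError(f"negative time_index for sample {sid!r}")
            meta[sid] = rec
    return meta


def _read_biom_json(path: str) -> AbundanceTable:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path!r}: not valid JSON") from exc
    try:
        rows = doc["rows"]
        cols = doc["columns"]
        shape = doc["shape"]
        data = doc["data"]
        mtype = doc.get("matrix_type", "dense")
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path!r}: not a BIOM v1 (JSON) table") from exc
    taxon_ids = [r["id"] for r in rows]
    sample_ids = [c["id"] for c in cols]
    mat = np.zeros((int(shape[0]), int(shape[1])), dtype=float)
    if mtype == "dense":
        mat[:, :] = np.asarray(data, dtype=float)
    elif mtype == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = float(v)
    else:
        raise FormatError(f"{path!r}: unknown BIOM matrix_type {mtype!r}")
    taxonomy: dict[str, tuple[str, ...]] = {}
    for r in rows:
        md = r.get("metadata") or {}
        lin = parse_lineage(md.get("taxonomy"))
        if lin is not None:
            taxonomy[r["id"]] = lin
    return _build_table(sample_ids, taxon_ids, mat.T, taxonomy or None)


def _read_biom_hdf5(path: str) -> AbundanceTable:
    import h5py

    with h5py.File(path, "r") as f:
        try:
            taxon_ids = [x.decode() if isinstance(x, bytes) else str(x)
                         for x in f["observation/ids"][:]]
            sample_ids = [x.decode() if isinstance(x, bytes) else str(x)
                          for x in f["sample/ids"][:]]
            grp = f["observation/matrix"]
            data = grp["data"][:]
            indices = grp["indices"][:]
            indptr = grp["indptr"][:]
        except KeyError as exc:
            raise FormatError(f"{path!r}: not a BIOM v2 (HDF5) table") from exc
        mat = np.zeros((len(taxon_ids), len(sample_ids)), dtype=float)
        for i in range(len(taxon_ids)):
            cols = indices[indptr[i]:indptr[i + 1]]
            mat[i, cols] = data[indptr[i]:indptr[i + 1]]
        taxonomy: dict[str, tuple[str, ...]] = {}
        if "observation/metadata/taxonomy" in f:
            tax = f["observation/metadata/taxonomy"][:]
            for tid, row in zip(taxon_ids, tax):
                lin = parse_lineage(
                    [x.decode() if isinstance(x, bytes) else str(x) for x in np.atleast_1d(row)]
                )
                if lin is not None:
                    taxonomy[tid] = lin
    return _build_table(sample_ids, taxon_ids, mat.T, taxonomy or None)


def _read_tsv(path: str) -> AbundanceTable:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise FormatError(f"{path!r}: cannot parse as TSV OTU table") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path!r}: TSV has no sample columns")
    taxonomy = None
    if str(df.columns[-1]).lower() == "taxonomy":
        tax_col = df.iloc[:, -1]
        df = df.iloc[:, :-1]
        taxonomy = {}
        for tid, text in tax_col.items():
            lin = parse_lineage(text if isinstance(text, str) else None)
            if lin is not None:
                taxonomy[str(tid)] = lin
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path!r}: non-numeric abundance values") from exc
    taxon_ids = [str(t) for t in df.index]
    sample_ids = [str(s) for s in df.columns]
    return _build_table(sample_ids, taxon_ids, values.T, taxonomy)


def _build_table(sample_ids, taxon_ids, values, taxonomy) -> AbundanceTable:
    return AbundanceTable(
        sample_ids=sample_ids,
        taxon_ids=taxon_ids,
        values=values,
        taxonomy=taxonomy,
        normalized=_rows_normalized(np.asarray(values, dtype=float)),
    )


def read_biom(path: str, metadata_path: str | None = None,
              fmt: str | None = None) -> AbundanceTable:
    """Read an abundance table from BIOM (HDF5 or JSON) or TSV.

    The dialect is auto-detected unless ``fmt`` is one of ``"biom"``/``"tsv"``.
    Sample metadata from ``metadata_path`` (TSV with a ``sample_id`` column)
    is merged by sample id; samples absent from the metadata file get empty
    metadata.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    import h5py

    if fmt == "tsv":
        table = _read_tsv(path)
    elif h5py.is_hdf5(path):
        table = _read_biom_hdf5(path)
    else:
        try:
            table = _read_biom_json(path)
        except FormatError:
            if fmt == "biom":
                raise
            table = _read_tsv(path)
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        table.metadata = {s: meta[s] for s in table.sample_ids if s in meta}
    return table


# ---------------------------------------------------------------------------
# Writers


def write_tsv(table: AbundanceTable, path: str) -> None:
    """Write a TSV OTU table (taxa rows x sample columns, taxonomy last)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        header = ["#OTU_ID", *table.sample_ids]
        has_tax = table.taxonomy is not None
        if has_tax:
            header.append("taxonomy")
        w.writerow(header)
        for j, tid in enumerate(table.taxon_ids):
            row = [tid, *(repr(float(v)) for v in table.values[:, j])]
            if has_tax:
                row.append(";".join(table.taxonomy.get(tid, ())))
            w.writerow(row)


def write_metadata_tsv(table: AbundanceTable, path: str,
                       extra: dict[str, dict] | None = None) -> None:
    """Write sample metadata as TSV, optionally merging extra per-sample keys."""
    keys: list[str] = []
    merged: dict[str, dict] = {}
    for sid in table.sample_ids:
        rec = dict(table.sample_metadata(sid))
        if extra and sid in extra:
            rec.update(extra[sid])
        merged[sid] = rec
        for k in rec:
            if k not in keys:
                keys.append(k)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id", *keys])
        for sid in table.sample_ids:
            rec = merged[sid]
            w.writerow([sid, *(rec.get(k, "") for k in keys)])


def write_biom_json(table: AbundanceTable, path: str) -> None:
    """Write a BIOM v1 (JSON, dense) table."""
    rows = []
    for tid in table.taxon_ids:
        md = None
        if table.taxonomy and tid in table.taxonomy:
            md = {"taxonomy": list(table.taxonomy[tid])}
        rows.append({"id": tid, "metadata": md})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "mbstates",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [table.n_taxa, table.n_samples],
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.values.T.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_biom_hdf5(table: AbundanceTable, path: str) -> None:
    """Write a BIOM v2 (HDF5, observation-major CSR) table."""
    import h5py

    mat = table.values.T  # taxa x samples
    data, indices, indptr = [], [], [0]
    for i in range(mat.shape[0]):
        nz = np.nonzero(mat[i])[0]
        indices.extend(nz.tolist())
        data.extend(mat[i, nz].tolist())
        indptr.append(len(indices))
    with h5py.File(path, "w") as f:
        f.attrs["format-version"] = [2, 1]
        f.create_dataset("observation/ids",
                         data=np.array(table.taxon_ids, dtype="S"))
        f.create_dataset("sample/ids",
                         data=np.array(table.sample_ids, dtype="S"))
        g = f.create_group("observation/matrix")
        g.create_dataset("data", data=np.array(data, dtype=float))
        g.create_dataset("indices", data=np.array(indices, dtype=np.int64))
        g.create_dataset("indptr", data=np.array(indptr, dtype=np.int64))
        if table.taxonomy:
            depth = max(len(v) for v in table.taxonomy.values())
            tax = np.full((table.n_taxa, depth), b"", dtype="S128")
            for i, tid in enumerate(table.taxon_ids):
                lin = table.taxonomy.get(tid, ())
                for j, name in enumerate(lin):
                    tax[i, j] = name.encode()
            f.create_dataset("observation/metadata/taxonomy", data=tax)


def write_assignments(states, path: str) -> None:
    """Write ``sampleID,clusterID`` CSV for a selected :class:`RobustStates`.

    Cluster ids are consecutive integers starting at 1, in order of first
    appearance; rows follow the input sample order.
    """
    if getattr(states, "outcome", None) == "none":
        raise ValidationError(
            "no robust states were selected; nothing to write "
            "(inspect the decision trail instead)"
        )
    labels = getattr(states, "labels", None)
    sample_ids = getattr(states, "sample_ids", None)
    if labels is None or sample_ids is None or len(labels) == 0:
        raise ValidationError("states carries no labeling")
    labels = _canonical_labels(np.asarray(labels, dtype=int))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sampleID", "clusterID"])
        for sid, lab in zip(sample_ids, labels):
            w.writerow([sid, int(lab)])


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by order of first appearance in sample order."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# Transformations


def normalize_tss(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scale each sample to relative abundances summing to 1."""
    sums = table.values.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValidationError(
            f"cannot normalize all-zero sample(s): "
            f"{[table.sample_ids[i] for i in zero]}"
        )
    return table.with_values(table.values / sums[:, None], normalized=True)


def filter_dominance(table: AbundanceTable, threshold: float = 0.01,
                     mode: str = "dominant", statistic: str = "mean",
                     renormalize: bool = True) -> AbundanceTable:
    """Subset taxa by dominance of their relative abundance across samples.

    ``mode="dominant"`` keeps taxa whose ``statistic`` ("mean" or "max")
    relative abundance is >= ``threshold``; ``mode="nondominant"`` keeps the
    complement.  The two modes partition the taxon set.  Rows are
    re-normalized to sum to 1 unless ``renormalize=False``.
    """
    if not table.normalized:
        raise ValidationError("filter_dominance requires a normalized table")
    if mode not in ("dominant", "nondominant"):
        raise ValueError(f"unknown mode {mode!r}")
    if statistic == "mean":
        stat = table.values.mean(axis=0)
    elif statistic == "max":
        stat = table.values.max(axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    keep = stat >= threshold
    if mode == "nondominant":
        keep = ~keep
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        raise EmptySelectionError(
            f"no taxa selected (mode={mode}, threshold={threshold})"
        )
    values = table.values[:, idx]
    out = table.with_values(values, taxon_ids=[table.taxon_ids[j] for j in idx],
                            normalized=False)
    if renormalize:
        out = normalize_tss(out)
    return out


def aggregate_taxa(table: AbundanceTable, level: str,
                   unclassified: str = "drop",
                   renormalize: bool = True) -> AbundanceTable:
    """Sum taxa sharing a lineage prefix down to ``level`` into one taxon.

    Taxa lacking an annotation at ``level`` are dropped by default, or pooled
    into a single ``"unclassified"`` taxon with ``unclassified="pool"``.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}; expected one of {RANKS}")
    if unclassified not in ("drop", "pool"):
        raise ValueError("unclassified must be 'drop' or 'pool'")
    depth = RANKS.index(level) + 1
    taxonomy = table.taxonomy or {}

    groups: dict[str, list[int]] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    n_annotated = 0
    for j, tid in enumerate(table.taxon_ids):
        lin = taxonomy.get(tid)
        name = None
        if lin is not None and len(lin) >= depth:
            label = lin[depth - 1]
            # a bare rank prefix like "g__" carries no annotation
            bare = label.split("__", 1)[-1] if "__" in label else label
            if bare.strip():
                name = ";".join(lin[:depth])
        if name is None:
            if unclassified == "pool":
                groups.setdefault("unclassified", []).append(j)
            continue
        n_annotated += 1
        groups.setdefault(name, []).append(j)
        lineages.setdefault(name, tuple(lin[:depth]))
    if n_annotated == 0:
        raise ValidationError(f"not enough taxonomic data at rank {level!r}")

    agg_ids = list(groups)
    values = np.column_stack(
        [table.values[:, groups[g]].sum(axis=1) for g in agg_ids]
    )
    new_tax = {g: lineages[g] for g in agg_ids if g in lineages}
    out = table.with_values(values, taxon_ids=agg_ids, taxonomy=new_tax,
                            normalized=False)
    if renormalize and table.normalized:
        out = normalize_tss(out)
    return out
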