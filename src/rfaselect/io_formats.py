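"""Expression-matrix I/O: delimited text and Broad RES/CLS formats.

The in-memory container is :class:`ExpressionDataset`, a genes × samples
matrix with exactly two sample classes.  All downstream selection code indexes
genes by integer row into this container.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class DataFormatError(ValueError):
    """A file does not conform to the expected layout."""


class DataValidationError(ValueError):
    """Parsed content violates a dataset invariant (classes, duplicates, NaNs)."""


@dataclass
class ExpressionDataset:
    """A labelled two-class expression matrix, genes in rows.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per matrix row.
    sample_ids : list of str
        Unique sample identifiers, one per matrix column.
    values : ndarray, shape (n_genes, n_samples)
        Expression values as provided (raw or normalised).
    labels : ndarray of int, shape (n_samples,)
        0/1 class codes; code 0 is the first class name encountered.
    class_names : tuple of (str, str)
        Display names for codes 0 and 1.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    labels: np.ndarray
    class_names: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise DataValidationError(
                f"matrix has {self.values.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.values.shape[1] != len(self.sample_ids):
            raise DataValidationError(
                f"matrix has {self.values.shape[1]} columns but {len(self.sample_ids)} sample ids"
            )
        if len(self.labels) != len(self.sample_ids):
            raise DataValidationError("one label per sample required")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        codes = set(int(c) for c in np.unique(self.labels))
        if not codes <= {0, 1} or len(codes) != 2:
            raise DataValidationError(
                f"exactly two classes (codes 0 and 1) required, got codes {sorted(codes)}"
            )
        if len(self.class_names) != 2:
            raise DataValidationError("class_names must name exactly two classes")
        if np.isnan(self.values).any():
            raise DataValidationError("matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_by_genes(self) -> np.ndarray:
        """The matrix transposed to the samples × features orientation."""
        return self.values.T

    def subset_genes(self, rows) -> "ExpressionDataset":
        rows = np.asarray(rows, dtype=int)
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in rows],
            values=self.values[rows],
        )

    def subset_samples(self, cols) -> "ExpressionDataset":
        cols = np.asarray(cols, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in cols],
            values=self.values[:, cols],
            labels=self.labels[cols],
        )


def _check_unique(ids, kind):
    seen = set()
    for x in ids:
        if x in seen:
            raise DataValidationError(f"duplicated {kind}: {x!r}")
        seen.add(x)


def _encode_labels(raw_labels):
    """Map arbitrary label values to 0/1 codes, first-seen label = 0."""
    names = []
    codes = []
    for lab in raw_labels:
        lab = str(lab)
        if lab not in names:
            names.append(lab)
        codes.append(names.index(lab))
    if len(names) != 2:
        raise DataValidationError(
            f"exactly two classes required, found {len(names)}: {names}"
        )
    return np.array(codes, dtype=int), (names[0], names[1])


def _to_float_matrix(frame: pd.DataFrame, impute_missing: bool) -> np.ndarray:
    """Convert a string DataFrame to floats, naming the first bad cell."""
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    stripped = frame.astype(str).apply(lambda col: col.str.strip())
    bad = numeric.isna() & frame.notna() & (stripped != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"non-numeric value {frame.iat[r, c]!r} at gene {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r}"
        )
    # numpy's parser is correctly rounded; pd.to_numeric is only used above
    # to locate bad cells
    raw = frame.to_numpy()
    mat = np.where(pd.isna(raw) | (np.char.strip(raw.astype(str)) == ""), "nan",
                   raw.astype(str)).astype(float)
    if np.isnan(mat).any():
        if impute_missing:
            row_means = np.nanmean(mat, axis=1)
            idx = np.where(np.isnan(mat))
            mat[idx] = np.take(row_means, idx[0])
        else:
            r, c = np.argwhere(np.isnan(mat))[0]
            raise DataValidationError(
                f"missing value at gene {frame.index[r]!r}, sample "
                f"{frame.columns[c]!r} (pass impute_missing=True to mean-impute)"
            )
    return mat


def read_delimited(
    path,
    delimiter: str = "\t",
    orientation: str = "genes_by_samples",
    label_row: str = "class",
    labels_path=None,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression matrix with a header row of sample ids.

    Labels come either from an in-file row whose first field equals
    ``label_row`` (default ``"class"``) or from a two-column sidecar file
    ``labels_path`` mapping sample id → class label.

    ``orientation="samples_by_genes"`` transposes the file on load, so a matrix
    stored samples-in-rows yields the identical dataset.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep=delimiter, header=0, index_col=0, dtype=str)
    if frame.shape[1] == 0:
        raise DataFormatError(f"{path}: no data columns found (bad header?)")
    if orientation == "samples_by_genes":
        frame = frame.T

    raw_labels = None
    if label_row is not None and label_row in frame.index:
        raw_labels = [str(v) for v in frame.loc[label_row]]
        frame = frame.drop(index=label_row)
    if labels_path is not None:
        side = pd.read_csv(labels_path, sep=delimiter, header=None, index_col=0, dtype=str)
        try:
            raw_labels = [str(side.loc[s].iloc[0]) for s in frame.columns]
        except KeyError as exc:
            raise DataValidationError(f"label file missing sample {exc}") from exc
    if raw_labels is None:
        raise DataFormatError(
            f"{path}: no label row {label_row!r} found and no labels_path given"
        )

    labels, class_names = _encode_labels(raw_labels)
    values = _to_float_matrix(frame, impute_missing)
    return ExpressionDataset(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=values,
        labels=labels,
        class_names=class_names,
    )


def write_delimited(ds: ExpressionDataset, path, delimiter: str = "\t",
                    label_row: str = "class") -> None:
    """Write a dataset in the delimited layout `read_delimited` accepts."""
    with open(path, "w") as fh:
        fh.write("gene_id" + delimiter + delimiter.join(ds.sample_ids) + "\n")
        fh.write(label_row + delimiter
                 + delimiter.join(ds.class_names[c] for c in ds.labels) + "\n")
        for gid, row in zip(ds.gene_ids, ds.values):
            fh.write(gid + delimiter + delimiter.join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Broad RES / CLS
# ---------------------------------------------------------------------------

def read_res_cls(res_path, cls_path) -> ExpressionDataset:
    """Read a Broad RES expression file paired with a CLS class-label file.

    The RES header carries Description/Accession columns followed by sample
    names; data rows interleave an Absent/Present/Marginal call column after
    each value column (plain value columns are also accepted).  Call columns
    are discarded.  The CLS file is the standard three-line format: a counts
    line, a ``#``-prefixed class-name line, and a label line; integer labels
    index the class names in order.
    """
    gene_ids, sample_ids, values = _parse_res(res_path)
    raw_labels = _parse_cls(cls_path)
    if len(raw_labels) != len(sample_ids):
        raise DataValidationError(
            f"CLS file declares {len(raw_labels)} samples but RES file has "
            f"{len(sample_ids)}"
        )
    labels, class_names = _encode_labels(raw_labels)
    return ExpressionDataset(gene_ids, sample_ids, values, labels, class_names)


def _parse_res(path):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 3:
        raise DataFormatError(f"{path}: RES file needs header, scale and count lines")
    header = lines[0].split("\t")
    if len(header) < 3:
        raise DataFormatError(f"{path}: RES header too short")
    sample_ids = [f for f in header[2:] if f.strip() != ""]
    # line 2 (sample descriptions / scale factors) is ignored; line 3 = gene count
    try:
        n_genes_declared = int(lines[2].split("\t")[0])
    except ValueError as exc:
        raise DataFormatError(f"{path}: third RES line must be the gene count") from exc
    data_lines = lines[3:]
    if len(data_lines) != n_genes_declared:
        raise DataFormatError(
            f"{path}: RES declares {n_genes_declared} genes but has {len(data_lines)} rows"
        )
    n = len(sample_ids)
    gene_ids, rows = [], []
    for ln in data_lines:
        fields = ln.split("\t")
        if len(fields) == 2 + 2 * n:          # value + call pairs
            vals = fields[2::2]
        elif len(fields) == 2 + n:            # plain values
            vals = fields[2:]
        else:
            raise DataFormatError(
                f"{path}: row {fields[0]!r} has {len(fields) - 2} data fields, "
                f"expected {n} or {2 * n}"
            )
        gid = fields[1].strip() or fields[0].strip()
        gene_ids.append(gid)
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise DataFormatError(f"{path}: non-numeric value in row {gid!r}") from exc
    return gene_ids, sample_ids, np.asarray(rows, dtype=float)


def _parse_cls(path):
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise DataFormatError(f"{path}: CLS file needs a counts line and a label line")
    counts = lines[0].split()
    try:
        n_samples, n_classes = int(counts[0]), int(counts[1])
    except (IndexError, ValueError) as exc:
        raise DataFormatError(f"{path}: malformed CLS counts line") from exc
    names = None
    if lines[1].startswith("#"):
        names = lines[1].lstrip("#").split()
        label_line = lines[2] if len(lines) > 2 else ""
    else:
        label_line = lines[1]
    tokens = label_line.split()
    if len(tokens) != n_samples:
        raise DataFormatError(
            f"{path}: CLS counts line declares {n_samples} samples but label "
            f"line has {len(tokens)}"
        )
    if names is not None and len(names) != n_classes:
        raise DataFormatError(
            f"{path}: CLS declares {n_classes} classes but names {len(names)}"
        )
    if names is not None and all(t.lstrip("-").isdigit() for t in tokens):
        try:
            return [names[int(t)] for t in tokens]
        except IndexError as exc:
            raise DataFormatError(f"{path}: CLS label index out of range") from exc
    return tokens


# ---------------------------------------------------------------------------
# Selection trajectories
# ---------------------------------------------------------------------------

def write_selection(trajectory, path, delimiter: str = "\t") -> None:
    """Write a selection trajectory as a delimited table.

    Columns: dimension, gene index, gene id, cumulative gene-id list
    (comma-joined), correct count, total count, training accuracy.  Metadata
    (criterion, classifier, accuracy mode) goes into ``#`` header lines so the
    table round-trips through :func:`read_selection`.
    """
    if len(trajectory.chosen) == 0:
        raise ValueError("cannot write an empty trajectory")
    with open(path, "w") as fh:
        fh.write(f"# criterion={trajectory.criterion}\n")
        fh.write(f"# classifier={trajectory.classifier.name}\n")
        fh.write(f"# mode={trajectory.mode}\n")
        fh.write(delimiter.join(
            ["dim", "gene_index", "gene_id", "cumulative_genes",
             "correct", "total", "train_acc"]) + "\n")
        for j, (gi, acc) in enumerate(zip(trajectory.chosen, trajectory.train_acc), start=1):
            cum = ",".join(trajectory.chosen_ids[:j])
            fh.write(delimiter.join([
                str(j), str(gi), trajectory.chosen_ids[j - 1], cum,
                str(acc.correct), str(acc.total), repr(acc.accuracy)]) + "\n")


def read_selection(path, delimiter: str = "\t"):
    """Read a trajectory written by :func:`write_selection`."""
    from .classifiers import AccuracyCount, ClassifierSpec
    from .rfa_core import SelectionTrajectory

    meta = {}
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("#"):
                key, _, val = ln.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            elif ln.startswith("dim") or ln.strip() == "":
                continue
            else:
                rows.append(ln.split(delimiter))
    if not rows:
        raise DataFormatError(f"{path}: no trajectory rows found")
    chosen = [int(r[1]) for r in rows]
    chosen_ids = [r[2] for r in rows]
    accs = [AccuracyCount(int(r[4]), int(r[5])) for r in rows]
    name = meta.get("classifier", "nbc")
    seed = 0 if name == "rf" else None
    return SelectionTrajectory(
        chosen=chosen,
        chosen_ids=chosen_ids,
        train_acc=accs,
        criterion=meta.get("criterion", "msc"),
        classifier=ClassifierSpec(name=name, seed=seed),
        mode=meta.get("mode", "loo"),
    )
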