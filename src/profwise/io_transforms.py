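"""Expression-matrix containers, delimited-text I/O and normalization.

Two preprocessing regimes are supported, matching the two kinds of proteomic
input the pipeline is designed for:

* positive RFU-like aptamer intensities that need a log2 transform
  (serum SomaScan-style panels), and
* already-normalized tissue proteomics that need per-feature z-scoring
  (CPTAC-style matrices).

Matrices are wide delimited text: first column sample ID, remaining columns
feature (marker) IDs, with an optional target column split out on load.
Missing or non-numeric cells are hard errors — silent imputation would change
downstream feature selection invisibly.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("profwise")

UNKNOWN_TOKENS = {"unknown", "", "na", "nan"}


class MatrixFormatError(ValueError):
    """Raised for structurally invalid expression-matrix input."""


def _find_duplicates(items) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """A samples x features real-valued expression matrix.

    Parameters
    ----------
    sample_ids : unique sample identifiers, one per row of ``values``.
    feature_ids : unique marker identifiers (SeqId-like), one per column.
    values : float array of shape (n_samples, n_features); all finite.
    gene_symbols : optional map feature_id -> gene symbol. Coverage may be
        partial and the map need not be injective (several aptamers can
        target the same protein).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    gene_symbols: dict[str, str] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise MatrixFormatError(f"duplicate sample IDs: {dups}")
        dups = _find_duplicates(self.feature_ids)
        if dups:
            raise MatrixFormatError(f"duplicate feature IDs: {dups}")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise MatrixFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixFormatError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if self.gene_symbols is not None:
            extra = set(self.gene_symbols) - set(self.feature_ids)
            if extra:
                raise MatrixFormatError(
                    f"gene_symbols maps unknown feature IDs: {sorted(extra)[:5]}"
                )
        self._index = {f: j for j, f in enumerate(self.feature_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._index[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def columns(self, feature_ids) -> np.ndarray:
        """Value block restricted to the given features, in matrix column order."""
        idx = sorted(self.feature_index(f) for f in feature_ids)
        return self.values[:, idx]

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        idx = sorted(self.feature_index(f) for f in feature_ids)
        keep = [self.feature_ids[j] for j in idx]
        symbols = None
        if self.gene_symbols is not None:
            symbols = {f: self.gene_symbols[f] for f in keep if f in self.gene_symbols}
        return ExpressionMatrix(self.sample_ids, keep, self.values[:, idx], symbols)

    def subset_samples(self, row_indices) -> "ExpressionMatrix":
        row_indices = np.asarray(row_indices)
        return ExpressionMatrix(
            [self.sample_ids[i] for i in row_indices],
            list(self.feature_ids),
            self.values[row_indices],
            dict(self.gene_symbols) if self.gene_symbols is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )


@dataclass
class TargetVector:
    """Per-sample prediction target, binary or continuous.

    For binary targets ``values`` holds string labels; the class named by
    ``positive_label`` is the positive class (default ``"methylated"``,
    matching the promoter-methylation convention). ``unknown_mask`` marks
    samples whose status is unknown; they are excluded from classification
    but may participate in regression.
    """

    kind: str  # "binary" | "continuous"
    values: np.ndarray
    positive_label: str = "methylated"
    unknown_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.unknown_mask is None:
            self.unknown_mask = np.zeros(len(self.values), dtype=bool)
        self.unknown_mask = np.asarray(self.unknown_mask, dtype=bool)
        if len(self.unknown_mask) != len(self.values):
            raise ValueError("unknown_mask length mismatch")
        if self.kind == "binary":
            levels = sorted(set(map(str, self.values[~self.unknown_mask])))
            if len(levels) != 2:
                raise ValueError(
                    f"binary target must have exactly two known levels, got {levels}"
                )
            self.levels = levels
        else:
            vals = self.values[~self.unknown_mask].astype(float)
            if not np.isfinite(vals).all():
                raise ValueError("continuous target has non-finite known values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def known_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.unknown_mask)

    def binary_codes(self) -> np.ndarray:
        """0/1 codes over all samples (unknowns get -1); 1 = positive class."""
        if self.kind != "binary":
            raise ValueError("binary_codes requires a binary target")
        codes = np.full(len(self.values), -1, dtype=int)
        labels = np.array([str(v).lower() for v in self.values])
        pos = self.positive_label.lower()
        codes[~self.unknown_mask] = (labels[~self.unknown_mask] == pos).astype(int)
        return codes

    def numeric(self) -> np.ndarray:
        """Numeric view: float values (continuous) or 0/1 codes (binary)."""
        if self.kind == "continuous":
            return self.values.astype(float)
        return self.binary_codes()

    def subset(self, row_indices) -> "TargetVector":
        row_indices = np.asarray(row_indices)
        return TargetVector(
            self.kind,
            self.values[row_indices],
            self.positive_label,
            self.unknown_mask[row_indices],
        )


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------


def _sep_for(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def _read_header(path: str, sep: str) -> list[str]:
    with open(path, newline="") as fh:
        row = next(csv.reader(fh, delimiter=sep))
    return row


def _type_target(raw: pd.Series, positive_label: str) -> TargetVector:
    """Split a raw target column into a typed TargetVector.

    Rule: if the non-unknown entries form at most two distinct string levels
    that do not all parse as numbers, the target is binary; otherwise it is
    continuous. Unknown/empty tokens populate the unknown mask either way.
    """
    strings = raw.astype(str).str.strip()
    unknown = strings.str.lower().isin(UNKNOWN_TOKENS) | raw.isna()
    known = strings[~unknown]
    numeric = pd.to_numeric(known, errors="coerce")
    if numeric.notna().all():
        values = np.zeros(len(raw), dtype=float)
        values[np.flatnonzero(~unknown.to_numpy())] = numeric.to_numpy()
        return TargetVector("continuous", values, positive_label, unknown.to_numpy())
    levels = sorted(set(known.str.lower()))
    if len(levels) != 2:
        raise MatrixFormatError(
            f"target column has {len(levels)} non-unknown levels {levels}; "
            "expected 2 (binary) or all-numeric (continuous)"
        )
    return TargetVector(
        "binary", strings.str.lower().to_numpy(), positive_label, unknown.to_numpy()
    )


def load_matrix(
    path: str,
    layout: str = "samples_in_rows",
    target_column: str | None = None,
    positive_label: str = "methylated",
    gene_symbol_path: str | None = None,
) -> tuple[ExpressionMatrix, TargetVector | None]:
    """Load a wide CSV/TSV expression matrix, optionally splitting a target.

    The delimiter is chosen from the file extension (``.tsv``/``.tab``/
    ``.txt`` -> tab, otherwise comma). ``layout="samples_in_cols"``
    transposes after reading. Duplicate IDs, missing cells and non-numeric
    cells in the value block are hard errors.
    """
    if layout not in ("samples_in_rows", "samples_in_cols"):
        raise ValueError(f"unknown layout {layout!r}")
    sep = _sep_for(path)
    header = _read_header(path, sep)
    dups = _find_duplicates(header[1:])
    if dups:
        raise MatrixFormatError(f"duplicate column names in {path}: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.columns = header[1:]  # undo pandas' dup mangling; dups already rejected
    if layout == "samples_in_cols":
        df = df.T

    target: TargetVector | None = None
    if target_column is not None:
        if target_column not in df.columns:
            raise MatrixFormatError(f"target column {target_column!r} not found")
        target = _type_target(df[target_column], positive_label)
        df = df.drop(columns=[target_column])

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        cell = df.iat[i, j]
        what = "missing value" if pd.isna(cell) or str(cell).strip() == "" else (
            f"non-numeric cell {cell!r}"
        )
        raise MatrixFormatError(
            f"{what} at row {df.index[i]!r}, column {df.columns[j]!r}"
        )

    symbols = None
    if gene_symbol_path is not None:
        symbols = load_gene_symbols(gene_symbol_path, set(df.columns))

    matrix = ExpressionMatrix(
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        # numpy's parser is correctly rounding (pd.to_numeric is not), so the
        # written %.17g text round-trips bit-identically
        df.to_numpy(dtype=float),
        symbols,
    )
    return matrix, target


def load_gene_symbols(path: str, restrict_to: set[str] | None = None) -> dict[str, str]:
    """Read a two-column feature_id -> gene symbol TSV (no header required)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.lower().startswith("feature"):
                continue
            fid, sym = line.split("\t")[:2]
            if restrict_to is None or fid in restrict_to:
                mapping[fid] = sym
    return mapping


def write_matrix(
    matrix: ExpressionMatrix,
    path: str,
    target: TargetVector | None = None,
    target_column: str = "target",
) -> None:
    """Write a wide matrix (samples in rows); values use repr-exact %.17g."""
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        header = ["sample_id", *matrix.feature_ids]
        if target is not None:
            header.append(target_column)
        w.writerow(header)
        for i, sid in enumerate(matrix.sample_ids):
            row = [sid] + ["%.17g" % v for v in matrix.values[i]]
            if target is not None:
                if target.unknown_mask[i]:
                    row.append("unknown")
                elif target.kind == "continuous":
                    row.append("%.17g" % float(target.values[i]))
                else:
                    row.append(str(target.values[i]))
            w.writerow(row)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 each cell; all values must be strictly positive."""
    if (matrix.values <= 0).any():
        i, j = np.argwhere(matrix.values <= 0)[0]
        raise ValueError(
            f"log2_transform requires positive values; found "
            f"{matrix.values[i, j]!r} at sample {matrix.sample_ids[i]!r}, "
            f"feature {matrix.feature_ids[j]!r}"
        )
    return replace(matrix, values=np.log2(matrix.values))


def zscore_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature z-score (mean 0, sd 1, ddof=1). Constant features are
    dropped with a warning rather than producing 0/0."""
    sd = matrix.values.std(axis=0, ddof=1) if matrix.n_samples > 1 else np.zeros(
        matrix.n_features
    )
    constant = sd == 0
    keep = matrix
    if constant.any():
        dropped = [f for f, c in zip(matrix.feature_ids, constant) if c]
        msg = f"dropping {len(dropped)} constant feature(s): {dropped[:5]}"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
        keep = matrix.subset_features(
            [f for f, c in zip(matrix.feature_ids, constant) if not c]
        )
    mean = keep.values.mean(axis=0)
    sd = keep.values.std(axis=0, ddof=1)
    return replace(keep, values=(keep.values - mean) / sd)


def exclude_target_feature(matrix: ExpressionMatrix, feature_id: str) -> ExpressionMatrix:
    """Drop the marker being predicted from the predictor set (regression:
    a 7289-marker panel becomes 7288 predictors)."""
    matrix.feature_index(feature_id)  # raises KeyError if absent
    return matrix.subset_features([f for f in matrix.feature_ids if f != feature_id])


PREPROCESSING_PRESETS = ("log2_rfu", "zscore", "none")


def apply_preset(matrix: ExpressionMatrix, preset: str) -> ExpressionMatrix:
    """Named preprocessing regimes: ``log2_rfu`` (positive RFU intensities),
    ``zscore`` (already-normalized values), or ``none``."""
    if preset == "log2_rfu":
        return log2_transform(matrix)
    if preset == "zscore":
        return zscore_normalize(matrix)
    if preset == "none":
        return matrix
    raise ValueError(f"unknown preprocessing preset {preset!r}; "
                     f"expected one of {PREPROCESSING_PRESETS}")
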