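"""Reading, validating and summarizing drug x kinase inhibition matrices.

A kinome profiling screen is stored as a wide matrix: one row per compound
(or compound + dose combination), one column per kinase, each cell the
percent inhibition of that kinase by that compound.  Internally every matrix
uses a single value convention — percent inhibition in [0, 100], higher
meaning stronger inhibition — regardless of whether the source file reported
percent inhibition or percent of control (residual activity).  Missing cells
(kinase not profiled for that compound) are NaN and stay NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import MatrixIOError, ValidationError

logger = logging.getLogger(__name__)

#: Conventions a source file may use for its cell values.
PERCENT_INHIBITION = "percent-inhibition"
PERCENT_OF_CONTROL = "percent-of-control"
CONVENTIONS = (PERCENT_INHIBITION, PERCENT_OF_CONTROL)

#: Cell tokens parsed as "not measured" unless the caller overrides them.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "ND"})


@dataclass(frozen=True)
class DatasetStats:
    """Summary statistics for one screen, as published per-dataset.

    ``n_compounds`` counts distinct base compounds, ``n_entries`` counts
    matrix rows (the same chemical at two doses is two entries), and
    ``pairwise_coverage`` is the percent of compound x kinase cells that
    carry a measured value.
    """

    n_compounds: int
    n_entries: int
    n_kinases: int
    pairwise_coverage: float


class AliasTable:
    """Mapping from raw kinase labels to standardized kinase names.

    Lookup is case- and whitespace-insensitive.  The table is idempotent by
    construction: every standard name maps to itself, so applying it twice
    changes nothing.
    """

    def __init__(self, entries: Iterable[tuple[str, str]] = ()):
        self._map: dict[str, str] = {}
        for raw, standard in entries:
            self.add(raw, standard)

    @staticmethod
    def _key(label: str) -> str:
        return "".join(str(label).split()).casefold()

    def add(self, raw: str, standard: str) -> None:
        key = self._key(raw)
        standard = str(standard).strip()
        existing = self._map.get(key)
        if existing is not None and existing != standard:
            raise ValidationError(
                f"alias table maps {raw!r} to both {existing!r} and {standard!r}"
            )
        self._map[key] = standard
        # idempotence: the standard name resolves to itself
        self._map.setdefault(self._key(standard), standard)

    def resolve(self, label: str) -> str:
        """Return the standard name for ``label``; unknown labels pass through."""
        return self._map.get(self._key(label), str(label).strip())

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, label: str) -> bool:
        return self._key(label) in self._map

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None) -> "AliasTable":
        """Load a two-column (raw_label, standard_name) delimited file.

        A header row is required; the delimiter is sniffed unless given.
        """
        path = Path(path)
        try:
            df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
        except OSError as exc:
            raise MatrixIOError(f"cannot read alias file {path}: {exc}") from exc
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise MatrixIOError(f"cannot parse alias file {path}: {exc}") from exc
        if df.shape[1] < 2:
            raise ValidationError(
                f"alias file {path} must have two columns (raw_label, standard_name)"
            )
        return cls(
            (str(r), str(s))
            for r, s in zip(df.iloc[:, 0], df.iloc[:, 1])
            if pd.notna(r) and pd.notna(s)
        )


@dataclass
class InhibitionMatrix:
    """Compounds x kinases percent-inhibition matrix.

    ``data`` is a float DataFrame indexed by compound entry label with kinase
    names as columns; NaN marks an unprofiled cell.  Construction validates
    the structural invariants (unique labels, at least one compound and two
    kinases, values in [0, 100]).
    """

    data: pd.DataFrame
    dataset_name: str = "unnamed"
    source_convention: str = PERCENT_INHIBITION
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.map(str)
        self.data.columns = self.data.columns.map(str)
        self.validate()

    def validate(self) -> None:
        dup_rows = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_rows:
            raise ValidationError(f"duplicate compound labels: {dup_rows}")
        dup_cols = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_cols:
            raise ValidationError(f"duplicate kinase labels: {dup_cols}")
        if self.data.shape[0] < 1:
            raise ValidationError("matrix needs at least one compound row")
        if self.data.shape[1] < 2:
            raise ValidationError(
                "matrix needs at least two kinases (a score needs a potential off-target)"
            )
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValidationError(
                "percent-inhibition values must lie in [0, 100]; "
                f"found range [{finite.min():g}, {finite.max():g}]"
            )
        if np.isinf(vals).any():
            raise ValidationError("matrix contains non-finite (infinite) values")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def kinase_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_compounds(self) -> int:
        return self.data.shape[0]

    @property
    def n_kinases(self) -> int:
        return self.data.shape[1]

    def row(self, compound_id: str) -> pd.Series:
        if compound_id not in self.data.index:
            raise ValidationError(f"unknown compound {compound_id!r}")
        return self.data.loc[compound_id]


def to_percent_inhibition(value: float, convention: str) -> float:
    """Convert one cell value to percent inhibition, clamped to [0, 100].

    Percent-of-control v (residual activity) becomes 100 - v; percent
    inhibition passes through.  Values below 0 after conversion — i.e.
    kinase activation above control — clamp to 0 so downstream geometric
    means stay defined; values above 100 clamp to 100.
    """
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown value convention {convention!r}")
    value = float(value)
    if not np.isfinite(value):
        raise ValidationError(f"non-finite cell value {value!r}")
    if convention == PERCENT_OF_CONTROL:
        value = 100.0 - value
    return float(min(100.0, max(0.0, value)))


def _convert_frame(df: pd.DataFrame, convention: str) -> pd.DataFrame:
    if convention == PERCENT_OF_CONTROL:
        df = 100.0 - df
    return df.clip(lower=0.0, upper=100.0)


def read_matrix(
    path: str | Path,
    *,
    orientation: str = "rows-are-compounds",
    convention: str = PERCENT_INHIBITION,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    sep: str | None = None,
    dataset_name: str | None = None,
) -> InhibitionMatrix:
    """Read a delimited wide matrix into canonical compounds x kinases form.

    The first column holds row labels; the header row holds column labels.
    ``orientation`` says whether file rows are compounds (the canonical
    layout) or kinases (the transpose).  The delimiter is sniffed from the
    header line unless ``sep`` is given.  Cells matching ``missing_tokens``
    (after stripping whitespace, case-sensitive) parse as missing; any other
    non-numeric cell is a validation error reporting the cell address.
    """
    path = Path(path)
    if orientation not in ("rows-are-compounds", "rows-are-kinases"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown value convention {convention!r}")
    tokens = {str(t).strip() for t in missing_tokens}

    try:
        with path.open("r", encoding="utf-8") as handle:
            header = handle.readline().rstrip("\r\n")
    except OSError as exc:
        raise MatrixIOError(f"cannot read {path}: {exc}") from exc
    if sep is None:
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    # duplicate header labels must be caught before pandas mangles them
    header_labels = [c.strip() for c in header.split(sep)[1:]]
    header_dups = sorted({c for c in header_labels if header_labels.count(c) > 1})
    if header_dups:
        kind = "kinase" if orientation == "rows-are-compounds" else "compound"
        raise ValidationError(f"duplicate {kind} labels in {path}: {header_dups}")
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise MatrixIOError(f"cannot read {path}: {exc}") from exc
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MatrixIOError(f"cannot parse {path}: {exc}") from exc

    if orientation == "rows-are-kinases":
        raw = raw.T

    raw.index = raw.index.map(lambda s: str(s).strip())
    raw.index.name = None
    raw.columns = raw.columns.map(lambda s: str(s).strip())
    raw.columns.name = None
    for axis_name, labels in (("compound", raw.index), ("kinase", raw.columns)):
        dups = labels[labels.duplicated()].unique().tolist()
        if dups:
            raise ValidationError(f"duplicate {axis_name} labels in {path}: {dups}")

    values = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        cells = raw[col].astype(str).str.strip()
        is_missing = cells.isin(tokens)
        numeric = pd.to_numeric(cells.where(~is_missing), errors="coerce")
        bad = (~is_missing) & numeric.isna()
        if bad.any():
            row_label = raw.index[bad.to_numpy().nonzero()[0][0]]
            cell = cells[bad].iloc[0]
            raise ValidationError(
                f"non-numeric cell {cell!r} at row {row_label!r}, column {col!r} in {path}"
            )
        values[:, j] = numeric.to_numpy(dtype=float)

    df = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    df = _convert_frame(df, convention)
    return InhibitionMatrix(
        data=df,
        dataset_name=dataset_name or path.stem,
        source_convention=convention,
    )


def write_matrix(matrix: InhibitionMatrix, path: str | Path, *, sep: str = ",") -> None:
    """Write a matrix in the canonical layout read back by :func:`read_matrix`.

    Missing cells are written as ``NA``; a write/read round trip preserves
    labels, values and the missing pattern.
    """
    path = Path(path)
    try:
        matrix.data.to_csv(path, sep=sep, na_rep="NA", index_label="compound")
    except OSError as exc:
        raise MatrixIOError(f"cannot write {path}: {exc}") from exc


def standardize_kinase_names(
    matrix: InhibitionMatrix,
    aliases: AliasTable,
    *,
    on_collision: str = "error",
) -> InhibitionMatrix:
    """Replace kinase column labels with their standardized names.

    Unknown labels pass through unchanged with a logged warning.  When two
    source columns map to the same standard name, ``on_collision`` decides:
    ``"error"`` rejects the matrix, ``"merge-mean"`` averages the non-missing
    cells of the colliding columns per compound.
    """
    if on_collision not in ("error", "merge-mean"):
        raise ValidationError(f"unknown on_collision policy {on_collision!r}")
    mapped = [aliases.resolve(k) for k in matrix.kinase_ids]
    unknown = [k for k in matrix.kinase_ids if k not in aliases]
    if unknown and len(aliases):
        logger.warning(
            "%d kinase label(s) not in alias table passed through unchanged: %s",
            len(unknown), ", ".join(unknown[:10]),
        )

    seen: dict[str, list[str]] = {}
    for original, standard in zip(matrix.kinase_ids, mapped):
        seen.setdefault(standard, []).append(original)
    collisions = {std: cols for std, cols in seen.items() if len(cols) > 1}
    if collisions and on_collision == "error":
        names = ", ".join(sorted(collisions))
        raise ValidationError(f"kinase name collision(s) after standardization: {names}")

    df = matrix.data.copy()
    df.columns = mapped
    if collisions:
        # merge-mean: average non-missing cells per compound across colliding columns
        df = df.T.groupby(level=0, sort=False).mean().T
        df = df[[std for std in dict.fromkeys(mapped)]]
    return InhibitionMatrix(
        data=df,
        dataset_name=matrix.dataset_name,
        source_convention=matrix.source_convention,
        notes=dict(matrix.notes),
    )


def pairwise_coverage(matrix: InhibitionMatrix) -> float:
    """Percent of compound x kinase cells that carry a measured value."""
    n_cells = matrix.data.size
    n_measured = int(matrix.data.notna().sum().sum())
    return 100.0 * n_measured / n_cells


def dataset_stats(
    matrix: InhibitionMatrix,
    base_compound_of: Mapping[str, str] | None = None,
) -> DatasetStats:
    """Per-dataset summary: compound, entry and kinase counts plus coverage.

    ``base_compound_of`` optionally maps entry labels (compound + dose) to
    base compound names so the same chemical at several doses counts once in
    ``n_compounds``.  Entries absent from the mapping are an error; without a
    mapping every entry is its own compound.
    """
    n_entries = matrix.n_compounds
    if base_compound_of is None:
        n_compounds = n_entries
    else:
        unknown = set(base_compound_of) - set(matrix.compound_ids)
        if unknown:
            raise ValidationError(
                f"dose mapping references unknown entries: {sorted(unknown)}"
            )
        n_compounds = len(
            {base_compound_of.get(entry, entry) for entry in matrix.compound_ids}
        )
    return DatasetStats(
        n_compounds=n_compounds,
        n_entries=n_entries,
        n_kinases=matrix.n_kinases,
        pairwise_coverage=pairwise_coverage(matrix),
    )
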