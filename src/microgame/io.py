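"""Reading and writing expression matrices, group labels and result tables.

The on-disk formats are plain delimited text (TSV or CSV):

* expression matrix — first row sample identifiers, first column gene
  identifiers, remaining cells real-valued normalized expression;
* group labels — two columns ``sample_id<sep>label`` (or inline
  ``sample_id=label`` tokens), labels drawn from a two-value vocabulary
  with case-insensitive aliases (``control``/``c`` and
  ``experimental``/``case``/``e``);
* results table — one row per gene with the per-condition Shapley values,
  ADSV, CASh p-value and selection flag.

Missing values are rejected at load time: the Boolean encoding has no
missing-data rule, and silently imputing a cell would silently change the
coalitions it enters.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "CONTROL",
    "EXPERIMENTAL",
    "ExpressionMatrix",
    "GroupLabels",
    "read_expression_matrix",
    "read_group_labels",
    "write_results_table",
]

CONTROL = "control"
EXPERIMENTAL = "experimental"

#: case-insensitive label vocabulary
_LABEL_ALIASES = {
    "control": CONTROL,
    "ctrl": CONTROL,
    "c": CONTROL,
    "experimental": EXPERIMENTAL,
    "case": EXPERIMENTAL,
    "e": EXPERIMENTAL,
}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise DataError(f"duplicate {what} identifier: {name!r}")
        seen.add(name)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of real-valued normalized expression.

    Parameters
    ----------
    gene_ids : tuple of str
        Row labels, unique, in file/input order.
    sample_ids : tuple of str
        Column labels, unique, in file/input order.
    values : ndarray of float, shape (n_genes, n_samples)
        Finite expression values X[i, j] for gene i in sample j.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise DataError("expression values must form a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if values.size == 0:
            raise DataError("empty expression matrix")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite expression value at "
                f"(gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r})"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame with genes as index and samples as columns."""
        return cls(
            gene_ids=tuple(map(str, df.index)),
            sample_ids=tuple(map(str, df.columns)),
            values=df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)


def _normalize_label(token: str) -> str:
    try:
        return _LABEL_ALIASES[token.strip().lower()]
    except KeyError:
        raise DataError(
            f"unknown group label {token!r}; expected one of "
            f"{sorted(set(_LABEL_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class GroupLabels:
    """Assignment of every sample to the control or experimental group."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        norm = {str(k): _normalize_label(v) for k, v in dict(self.assignment).items()}
        object.__setattr__(self, "assignment", norm)

    def label_of(self, sample_id: str) -> str:
        return self.assignment[sample_id]

    def group_ids(self, sample_ids: Sequence[str], label: str) -> tuple[str, ...]:
        """Sample ids carrying ``label``, in the order of ``sample_ids``."""
        return tuple(s for s in sample_ids if self.assignment.get(s) == label)

    def control_ids(self, sample_ids: Sequence[str]) -> tuple[str, ...]:
        return self.group_ids(sample_ids, CONTROL)

    def experimental_ids(self, sample_ids: Sequence[str]) -> tuple[str, ...]:
        return self.group_ids(sample_ids, EXPERIMENTAL)

    @property
    def n_control(self) -> int:
        return sum(1 for v in self.assignment.values() if v == CONTROL)

    @property
    def n_experimental(self) -> int:
        return sum(1 for v in self.assignment.values() if v == EXPERIMENTAL)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check completeness and group-size preconditions for ``matrix``.

        Every sample needs exactly one label, the control group needs at
        least two samples (its standard deviation is a sample SD) and the
        experimental group at least one.
        """
        missing = [s for s in matrix.sample_ids if s not in self.assignment]
        if missing:
            raise DataError(f"samples without a group label: {missing}")
        n_ctrl = len(self.control_ids(matrix.sample_ids))
        n_exp = len(self.experimental_ids(matrix.sample_ids))
        if n_ctrl < 2:
            raise DataError(
                f"need at least 2 control samples (got {n_ctrl}): "
                "the control standard deviation is undefined otherwise"
            )
        if n_exp < 1:
            raise DataError("need at least 1 experimental sample")


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_expression_matrix(
    path: str | os.PathLike, delimiter: str | None = None
) -> ExpressionMatrix:
    """Load a genes x samples expression matrix from delimited text.

    The delimiter is sniffed from the first line (tab, then comma) unless
    given explicitly.  Duplicate identifiers, empty matrices, missing and
    non-numeric cells are all rejected with positional error messages.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first_line = fh.readline()
    if not first_line.strip():
        raise DataError(f"empty expression file: {path}")
    sep = delimiter or _sniff_delimiter(first_line)

    header = [tok.strip() for tok in first_line.rstrip("\r\n").split(sep)]
    sample_ids = [tok for tok in header[1:] if tok != ""]
    _check_unique(sample_ids, "sample")

    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, skipinitialspace=True)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise DataError(f"empty expression matrix in {path}")
    gene_ids = [str(g) for g in raw.index]
    _check_unique(gene_ids, "gene")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        positions = []
        for i, j in np.argwhere(bad)[:10]:
            cell = raw.iat[i, j]
            kind = "missing" if (cell is None or pd.isna(cell)) else f"non-numeric ({cell!r})"
            positions.append(f"(gene {gene_ids[i]!r}, sample {raw.columns[j]!r}): {kind}")
        raise DataError(
            f"{int(bad.sum())} unparseable cell(s) in {path}; first few: "
            + "; ".join(positions)
        )
    return ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(map(str, raw.columns)),
        values=numeric.to_numpy(dtype=float),
    )


def read_group_labels(
    source: str | os.PathLike | Iterable[str], delimiter: str | None = None
) -> GroupLabels:
    """Read group labels from a two-column file or ``sample=label`` tokens.

    A file may carry an optional header line (detected by its second field
    not being a recognized label).  Repeated consistent assignments are
    tolerated; conflicting ones are an error.
    """
    pairs: list[tuple[str, str]] = []
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
        if not lines:
            raise DataError(f"empty labels file: {source}")
        sep = delimiter or _sniff_delimiter(lines[0])
        for k, line in enumerate(lines):
            fields = [f.strip() for f in line.split(sep) if f.strip() != ""]
            if len(fields) != 2:
                raise DataError(
                    f"labels file line {k + 1} has {len(fields)} fields, expected 2: {line!r}"
                )
            if k == 0 and fields[1].lower() not in _LABEL_ALIASES:
                continue  # header line
            pairs.append((fields[0], fields[1]))
    else:
        for tok in source:
            if "=" not in tok:
                raise DataError(f"label token {tok!r} is not of the form sample=label")
            sid, lab = tok.split("=", 1)
            pairs.append((sid.strip(), lab.strip()))
    if not pairs:
        raise DataError("no group labels provided")

    assignment: dict[str, str] = {}
    for sid, lab in pairs:
        norm = _normalize_label(lab)
        if sid in assignment and assignment[sid] != norm:
            raise DataError(
                f"sample {sid!r} labeled both {assignment[sid]!r} and {norm!r}"
            )
        assignment[sid] = norm
    return GroupLabels(assignment)


def write_results_table(comparison, path: str | os.PathLike, delimiter: str = "\t") -> None:
    """Write one direction's per-gene results as a delimited table.

    Columns: ``gene_id``, ``meanShC``, ``meanShE``, ``ADSV``, ``CASh_p``,
    ``adjusted_p`` (only when computed) and ``selected``.  Values are written
    at full precision so the table round-trips.
    """
    df = comparison.to_frame()
    df.to_csv(path, sep=delimiter, index=False)
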