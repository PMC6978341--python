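"""Tabular input/output and packaged gene-family definitions.

The on-disk dialect is fixed: expression matrices are tab-separated text
with samples as rows (first column ``sample_id``) and genes as columns
(header row of symbols, uppercased on read). Values are linear-scale,
RSEM-like, non-negative expression estimates. A ``transpose`` flag on the
reader accommodates genes-as-rows exports.

Gene-family files carry a ``#family=<name>`` header line followed by one
symbol per line; two families ship with the package: the 19-member human
aldehyde dehydrogenase (ALDH) superfamily and a 37-member cytokeratin
(KRT) control family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "GeneFamily",
    "ClinicalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical",
    "read_family_file",
    "load_builtin_family",
    "builtin_family_names",
]


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass(frozen=True)
class GeneFamily:
    """A named, ordered list of gene symbols (uppercase)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(m.upper() for m in self.members)
        object.__setattr__(self, "members", members)
        if len(members) < 2:
            raise ValidationError(f"family {self.name!r} needs >= 2 members")
        if len(set(members)) != len(members):
            raise ValidationError(f"family {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExpressionMatrix:
    """Samples x genes non-negative expression values (linear scale).

    ``data`` is a DataFrame indexed by sample_id with uppercase gene-symbol
    columns. Validation (non-negativity, uniqueness, non-emptiness) runs on
    construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("expression matrix needs >= 1 sample and >= 1 gene")
        df.columns = [str(c).upper() for c in df.columns]
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate gene symbols: {dups}")
        neg = df.lt(0)
        if neg.any().any():
            row = df.index[neg.any(axis=1)][0]
            col = neg.columns[neg.loc[row]][0]
            raise ValidationError(
                f"negative expression value at sample {row!r}, gene {col!r}: "
                f"{df.loc[row, col]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    Columns: ``class_label`` (categorical), ``mrnasi`` (stemness index in
    [0, 1], NaN when missing), ``time`` (months, >= 0), ``event`` (1 =
    death, 0 = censored), optional ``endpoint`` tag ("OS" or "DSS").
    Indexed by sample_id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"class_label", "time", "event"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        if "mrnasi" not in df.columns:
            df["mrnasi"] = np.nan
        bad_event = ~df["event"].isin((0, 1))
        if bad_event.any():
            sid = df.index[bad_event][0]
            raise ValidationError(
                f"event must be 0 or 1; sample {sid!r} has {df.loc[sid, 'event']!r}"
            )
        if (df["time"] < 0).any():
            sid = df.index[df["time"] < 0][0]
            raise ValidationError(f"negative survival time for sample {sid!r}")
        mr = df["mrnasi"].dropna()
        if ((mr < 0) | (mr > 1)).any():
            raise ValidationError("mrnasi values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def read_expression_matrix(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (samples x genes; first column sample_id).

    ``transpose=True`` reads a genes-as-rows export. Raises
    :class:`ValidationError` naming the offending cell on negative or
    non-numeric values.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: no samples (empty body)")
    if transpose:
        raw = raw.T
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        try:
            # numpy's parser round-trips %.17g text bit-exactly
            numeric[col] = raw[col].to_numpy(dtype="U32").astype(float)
        except ValueError:
            for row, cell in raw[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{path}: non-numeric cell at sample {row!r}, gene {col!r}: "
                        f"{cell!r}"
                    ) from None
            raise
    if numeric.isna().any().any():
        row = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValidationError(f"{path}: missing value in row {row!r}")
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV at full precision (read/write round-trips bit-exactly)."""
    df = matrix.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV (sample_id, class_label, time, event[, mrnasi, endpoint]).

    Blank mrnasi cells are retained as missing (NaN), never imputed to zero.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_family_file(path: str | Path) -> GeneFamily:
    """Parse a gene-family file: a ``#family=<name>`` line, one symbol per line."""
    name = None
    members: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#family="):
            name = line.split("=", 1)[1].strip()
        elif line.startswith("#"):
            continue
        else:
            members.append(line.upper())
    if name is None:
        raise ValidationError(f"{path}: missing '#family=<name>' header line")
    return GeneFamily(name=name, members=tuple(members))


_BUILTIN_FILES = {"ALDH": "aldh.txt", "KRT": "krt.txt"}


def builtin_family_names() -> list[str]:
    return sorted(_BUILTIN_FILES)


def load_builtin_family(name: str) -> GeneFamily:
    """Load a packaged family: "ALDH" (19 isoforms) or "KRT" (37 cytokeratins)."""
    key = name.upper()
    if key not in _BUILTIN_FILES:
        raise KeyError(
            f"unknown family {name!r}; available: {builtin_family_names()}"
        )
    ref = resources.files("famvar.data") / _BUILTIN_FILES[key]
    with resources.as_file(ref) as path:
        return read_family_file(path)
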