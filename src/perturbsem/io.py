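"""Readers and writers for the plain-text formats the tool exchanges.

All tabular files are tab-separated UTF-8 text by default (``sep`` lets a
caller switch to commas).  Readers validate strictly and raise
:class:`FormatError` with the offending row/column named; there is no silent
coercion of malformed input.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSignature",
    "OrthologMap",
    "GeneSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_signature",
    "write_signature",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gene_set",
    "write_gene_set",
    "write_tscores",
    "read_tscores",
]


class FormatError(ValueError):
    """A file violated the schema its reader expects."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A numeric expression matrix, rows = probes or genes, columns = samples.

    ``level`` declares whether row ids are probe ids (duplicates allowed)
    or gene symbols (must be unique).  Values are stored as a float
    DataFrame; all cells must be finite.
    """

    data: pd.DataFrame
    level: str = "gene"  # {"probe", "gene"}

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.level == "gene" and self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene id at level=gene: {dup!r}")
        if not np.isfinite(self.data.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.data.to_numpy()))[0]
            raise FormatError(
                "non-finite expression value at row "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneSignature:
    """Directional gene signature: disjoint up- and down-regulated symbol sets."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    species: str = "unknown"

    def __post_init__(self) -> None:
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise FormatError(
                f"genes listed both up and down: {sorted(overlap)[:5]}"
            )
        if not (self.up_genes or self.down_genes):
            raise FormatError("signature is empty")

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass
class OrthologMap:
    """Many-to-many mapping between gene symbols of two species."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = frozenset(self.pairs)
        if not self.pairs:
            raise FormatError("ortholog map is empty")

    @classmethod
    def identity(cls, symbols: Iterable[str]) -> "OrthologMap":
        """Self-mapping, for same-species signature/matrix pairs."""
        return cls(frozenset((s, s) for s in symbols))

    def image(self, symbols: Iterable[str]) -> frozenset[str]:
        symbols = set(symbols)
        return frozenset(t for s, t in self.pairs if s in symbols)

    def as_dict(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, set()).add(t)
        return {k: frozenset(v) for k, v in out.items()}


@dataclass
class GeneSet:
    """A named, nonempty set of gene symbols."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: PathLike, level: str = "gene", sep: str = "\t"
) -> ExpressionMatrix:
    """Read a genes-or-probes × samples matrix.

    First row = sample ids, first column = row ids, numeric body.
    Missing or non-numeric cells are a hard error (the downstream t-test
    assumes complete columns).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    samples = [h.strip() for h in header[1:]]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    missing = df.isna()
    for mask, what in ((bad, "non-numeric"), (missing, "missing")):
        if mask.to_numpy().any():
            r, c = np.argwhere(mask.to_numpy())[0]
            raise FormatError(
                f"{path}: {what} cell at row {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
    try:
        return ExpressionMatrix(numeric.astype(float), level=level)
    except FormatError as exc:  # re-anchor to the file
        raise FormatError(f"{path}: {exc}") from None


def write_expression_matrix(
    matrix: ExpressionMatrix, path: PathLike, sep: str = "\t"
) -> None:
    matrix.data.to_csv(path, sep=sep, index_label="id", float_format="%.17g")


# ---------------------------------------------------------------------------
# signature
# ---------------------------------------------------------------------------

_DIRECTIONS = {"up": "up", "down": "down"}


def read_signature(path: PathLike, species: str = "unknown", sep: str = "\t") -> GeneSignature:
    """Read a two-column (symbol, up|down) signature file.

    Direction tokens are case-insensitive; duplicate rows within one
    direction collapse; a symbol in both directions is an error.
    """
    path = Path(path)
    up: set[str] = set()
    down: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2 or not parts[0]:
                raise FormatError(f"{path}:{lineno}: expected 'symbol{sep}up|down'")
            symbol, direction = parts
            direction = direction.lower()
            if direction not in _DIRECTIONS:
                raise FormatError(
                    f"{path}:{lineno}: unknown direction {parts[1]!r} "
                    "(expected 'up' or 'down')"
                )
            (up if direction == "up" else down).add(symbol)
    both = up & down
    if both:
        raise FormatError(f"{path}: genes listed both up and down: {sorted(both)[:5]}")
    if not (up or down):
        raise FormatError(f"{path}: signature file has no entries")
    return GeneSignature(frozenset(up), frozenset(down), species=species)


def write_signature(sig: GeneSignature, path: PathLike, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(sig.up_genes):
            fh.write(f"{g}{sep}up\n")
        for g in sorted(sig.down_genes):
            fh.write(f"{g}{sep}down\n")


# ---------------------------------------------------------------------------
# ortholog map
# ---------------------------------------------------------------------------


def read_ortholog_map(path: PathLike, sep: str = "\t") -> OrthologMap:
    """Read a two-column (source symbol, target symbol) mapping; may be many-to-many."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2 or not all(parts):
                raise FormatError(f"{path}:{lineno}: expected 'source{sep}target'")
            pairs.add((parts[0], parts[1]))
    if not pairs:
        raise FormatError(f"{path}: ortholog map file has no entries")
    return OrthologMap(frozenset(pairs))


def write_ortholog_map(mapping: OrthologMap, path: PathLike, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in sorted(mapping.pairs):
            fh.write(f"{s}{sep}{t}\n")


# ---------------------------------------------------------------------------
# gene set
# ---------------------------------------------------------------------------


def read_gene_set(path: PathLike, name: str | None = None) -> GeneSet:
    """One symbol per line; an optional leading ``#name`` line names the set."""
    path = Path(path)
    genes: set[str] = set()
    set_name = name or path.stem
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if lineno == 1 and line[1:].strip() and name is None:
                    set_name = line[1:].strip()
                continue
            genes.add(line)
    if not genes:
        raise FormatError(f"{path}: gene set file has no symbols")
    return GeneSet(set_name, frozenset(genes))


def write_gene_set(gs: GeneSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#{gs.name}\n")
        for g in sorted(gs.genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# T-score table
# ---------------------------------------------------------------------------

TSCORE_COLUMNS = ["sample_id", "tscore", "pvalue", "n_up", "n_down", "df"]


def write_tscores(table: pd.DataFrame, path: PathLike, sep: str = "\t") -> None:
    """Write a per-sample T-score table (columns per :data:`TSCORE_COLUMNS`)."""
    if len(table) == 0:
        raise FormatError("refusing to write an empty T-score table")
    out = table.reset_index() if table.index.name == "sample_id" else table.copy()
    missing = [c for c in TSCORE_COLUMNS if c not in out.columns]
    if missing:
        raise FormatError(f"T-score table missing columns: {missing}")
    out[TSCORE_COLUMNS].to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_tscores(path: PathLike, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TSCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: T-score table missing columns: {missing}")
    return df.set_index("sample_id")
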