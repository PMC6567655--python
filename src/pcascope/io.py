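"""Typed ingestion and export of count matrices, metadata and annotations.

Count matrices and sample metadata arrive as delimiter-separated text
(tab, comma or semicolon) with row names in the first column and a header
line of IDs.  Gene-to-GO assignments are accepted either as a two-column
``(gene_id, go_id)`` TSV or as a GAF 2.x file (columns 2 and 5).  All
exports are tab-separated UTF-8 with missing values spelled ``NA``.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DELIMITERS = ("\t", ",", ";")
_GO_ID_RE = re.compile(r"^GO:\d{7}$")


class ValidationError(ValueError):
    """Input violates a structural contract (duplicates, negatives, ...)."""


class ParseError(ValueError):
    """Input text could not be interpreted as the expected table."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw read counts, genes (rows) by samples (columns).

    ``values`` is an integer DataFrame whose index holds the gene IDs and
    whose columns hold the sample IDs; both must be unique, entries
    non-negative.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleMetadata:
    """Experimental factors per sample (condition, tissue, batch, ...)."""

    factors: pd.DataFrame  # index = sample IDs, one column per factor

    def __post_init__(self) -> None:
        if self.factors.index.has_duplicates:
            dups = self.factors.index[self.factors.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dups[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factors.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.columns)


@dataclass
class GeneAnnotation:
    """Map from primary gene IDs to alternative IDs (symbol, accession...).

    Lookup is exact-match and case-sensitive; IDs are never normalized.
    """

    table: pd.DataFrame  # index = primary IDs, one column per alt-ID type

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate primary gene IDs in annotation")

    def resolve(self, query: str) -> list[str]:
        """Return primary IDs matching *query* (as primary ID or any alt ID)."""
        if query in self.table.index:
            return [query]
        hits: list[str] = []
        for col in self.table.columns:
            matched = self.table.index[self.table[col] == query]
            hits.extend(m for m in matched if m not in hits)
        return hits


@dataclass
class GOAnnotation:
    """Gene Ontology term assignments: term -> gene set, plus labels."""

    term_to_genes: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    namespace: str = "BP"

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            if not _GO_ID_RE.match(term):
                raise ValidationError(f"malformed GO ID {term!r}")
            if not genes:
                raise ValidationError(f"term {term} has an empty gene set")

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return frozenset(out)

    def name_of(self, term: str) -> str:
        return self.term_names.get(term, term)


@dataclass
class ExperimentBundle:
    """Counts + metadata (+ optional annotation), sample-aligned.

    After :func:`bind_experiment` the counts columns and the metadata rows
    hold exactly the same samples in the same order.
    """

    counts: CountMatrix
    metadata: SampleMetadata
    annotation: Optional[GeneAnnotation] = None

    def __post_init__(self) -> None:
        if self.counts.sample_ids != self.metadata.sample_ids:
            raise ValidationError(
                "counts and metadata sample IDs differ or are ordered differently; "
                "use bind_experiment() to align them"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _detect_dialect(lines: Sequence[str]) -> str:
    """Pick tab, comma or semicolon, in that order of preference.

    A delimiter qualifies if it splits the header into >= 2 fields and
    yields a consistent field count across the first 50 data lines.
    """
    header, body = lines[0], [ln for ln in lines[1:51] if ln.strip()]
    for d in _DELIMITERS:
        ncol = len(header.split(d))
        if ncol < 2:
            continue
        widths = {len(ln.split(d)) for ln in body}
        if widths <= {ncol, ncol + 1}:  # header may omit the row-name stub
            return d
    raise ParseError(
        "could not detect delimiter (tried tab, comma, semicolon); "
        "pass dialect= explicitly"
    )


def _read_delimited(path: str | Path, dialect: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    if dialect is None:
        dialect = _detect_dialect(lines)
    df = pd.read_csv(
        _stdio.StringIO(text), sep=dialect, index_col=0, dtype=str,
        keep_default_na=False, na_values=["NA", ""],
    )
    df.index = df.index.astype(str)
    return df


def read_counts(
    path: str | Path, dialect: Optional[str] = None, strict: bool = True
) -> CountMatrix:
    """Read a genes x samples count table from delimited text.

    With ``strict=True`` (default) every cell must be a non-negative
    integer literal; ``strict=False`` additionally accepts floats that are
    integral to within 1e-6 (rounded), for upstream quantifiers that emit
    fractional estimates.
    """
    raw = _read_delimited(path, dialect)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            values[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()]
            raise ParseError(
                f"{path}: non-numeric count {bad.iloc[0]!r} at gene "
                f"{bad.index[0]!r}, sample {col!r}"
            ) from None
    arr = values.to_numpy()
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ParseError(
            f"{path}: missing count at gene {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    frac = np.abs(arr - np.round(arr))
    tol = 1e-6 if not strict else 0.0
    if (frac > tol).any():
        i, j = np.argwhere(frac > tol)[0]
        raise ParseError(
            f"{path}: non-integral count {arr[i, j]!r} at gene "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )
    return CountMatrix(pd.DataFrame(
        np.round(arr).astype(np.int64), index=values.index, columns=values.columns
    ))


def read_metadata(path: str | Path, dialect: Optional[str] = None) -> SampleMetadata:
    """Read a samples x factors metadata table; all-blank columns are dropped."""
    df = _read_delimited(path, dialect)
    empty = [c for c in df.columns if df[c].isna().all()]
    if empty:
        logger.warning("dropping all-blank metadata columns: %s", empty)
        df = df.drop(columns=empty)
    return SampleMetadata(df)


def read_gene_annotation(path: str | Path, dialect: Optional[str] = None) -> GeneAnnotation:
    """Read a primary-ID-indexed table of alternative gene IDs."""
    return GeneAnnotation(_read_delimited(path, dialect))


def read_go_annotation(
    path: str | Path, format: str = "two-column-tsv",
    term_names: Optional[Mapping[str, str]] = None, namespace: str = "BP",
) -> GOAnnotation:
    """Read gene-to-GO assignments.

    ``two-column-tsv``: (gene_id, go_id) pairs, optional ``#`` comments.
    ``gaf``: GAF 2.x; column 2 is the object ID, column 5 the GO ID, lines
    starting with ``!`` are headers.
    """
    path = Path(path)
    term_to_genes: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "gaf":
                if line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise ParseError(f"{path}:{lineno}: GAF line has <5 columns")
                gene, term = fields[1], fields[4]
            elif format == "two-column-tsv":
                if line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 columns")
                gene, term = fields[0], fields[1]
            else:
                raise ValueError(f"unknown GO annotation format {format!r}")
            if not _GO_ID_RE.match(term):
                raise ValidationError(f"{path}:{lineno}: malformed GO ID {term!r}")
            term_to_genes.setdefault(term, set()).add(gene)
    return GOAnnotation(
        {t: frozenset(g) for t, g in term_to_genes.items()},
        dict(term_names or {}), namespace,
    )


def bind_experiment(
    counts: CountMatrix,
    metadata: SampleMetadata,
    annotation: Optional[GeneAnnotation] = None,
) -> ExperimentBundle:
    """Align counts and metadata on their shared samples.

    Samples present in both inputs are kept, in counts-matrix order (counts
    are the primary object); samples unique to one side are reported at
    warning level.  Zero overlap is a hard error.
    """
    shared = [s for s in counts.sample_ids if s in set(metadata.sample_ids)]
    if not shared:
        raise ValidationError("counts and metadata share no sample IDs")
    only_counts = [s for s in counts.sample_ids if s not in set(shared)]
    only_meta = [s for s in metadata.sample_ids if s not in set(shared)]
    if only_counts:
        logger.warning("samples only in counts, dropped: %s", only_counts)
    if only_meta:
        logger.warning("samples only in metadata, dropped: %s", only_meta)
    return ExperimentBundle(
        CountMatrix(counts.values[shared]),
        SampleMetadata(metadata.factors.loc[shared]),
        annotation,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def table_to_tsv(table: pd.DataFrame, index_label: Optional[str] = None) -> str:
    """Serialize a table as TSV text: header row, NA for missing, floats at
    repr (round-trip) precision."""
    buf = _stdio.StringIO()
    table.to_csv(buf, sep="\t", na_rep="NA", index_label=index_label)
    return buf.getvalue()


def write_table(table: pd.DataFrame, path: str | Path, index_label: Optional[str] = None) -> None:
    """Write any tabular result as TSV (UTF-8, NA for missing)."""
    Path(path).write_text(table_to_tsv(table, index_label), encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table produced by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                       keep_default_na=False, float_precision="round_trip")
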