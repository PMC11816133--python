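"""Expression tables, gene annotations and replicate-set definitions.

The central container is :class:`ExpressionMatrix`, a validated gene x sample
table of FPKM values (fragments per kilobase of transcript per million mapped
reads, the length-normalised abundance unit produced by StringTie-style
quantifiers).  Every downstream computation — gene selection, variability
profiling, dose-pattern calls — reads from it.

All tabular formats are plain text.  TSV is the canonical dialect (header
row, '.' decimal); CSV is accepted via ``sep=","``.  Sample identifiers are
matched case-sensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

Source = Union[str, TextIO]

#: biotype assigned to genes missing from an annotation
UNKNOWN_BIOTYPE = "unknown"


@dataclass(frozen=True)
class SampleSet:
    """A named, ordered group of replicate samples for one condition.

    Parameters
    ----------
    label
        Condition name, e.g. ``"B11_0"``.
    sample_ids
        Ordered replicate sample identifiers; at least two, typically three.
    """

    label: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(self.sample_ids) < 2:
            raise ValidationError(
                f"sample set {self.label!r} has {len(self.sample_ids)} sample(s); "
                "at least 2 replicates are required"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(f"sample set {self.label!r} lists a sample twice")

    def __len__(self) -> int:
        return len(self.sample_ids)


class ExpressionMatrix:
    """Gene x sample FPKM matrix with validated invariants.

    Invariants: all values are finite and non-negative, no missing cells,
    gene and sample identifiers are unique.  Backed by a pandas DataFrame
    (genes in rows).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id(s): {dupes[:5]}")
        if frame.columns.has_duplicates:
            dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dupes[:5]}")
        values = _coerce_numeric(frame)
        bad = ~np.isfinite(values)
        if bad.any():
            g, s = _first_offender(frame, bad)
            raise ValidationError(f"missing or non-finite FPKM for gene {g!r}, sample {s!r}")
        neg = values < 0
        if neg.any():
            g, s = _first_offender(frame, neg)
            raise ValidationError(
                f"negative FPKM {frame.loc[g, s]} for gene {g!r}, sample {s!r}; "
                "FPKM values must be >= 0"
            )
        self._frame = pd.DataFrame(values, index=frame.index, columns=frame.columns)
        self._frame.index.name = None
        self._frame.columns.name = None

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (genes in rows). Do not mutate."""
        return self._frame

    @property
    def gene_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self._frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self._frame.shape[1]

    def values_for(self, gene_id: str, sample_ids: Sequence[str]) -> np.ndarray:
        """FPKM values for one gene over the given samples, in order."""
        return self._frame.loc[gene_id, list(sample_ids)].to_numpy(dtype=float)

    def submatrix(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self._frame.columns]
        if missing:
            raise ValidationError(f"sample id(s) not in matrix: {missing}")
        return self._frame[list(sample_ids)]

    def require_samples(self, sample_set: SampleSet) -> None:
        missing = [s for s in sample_set.sample_ids if s not in self._frame.columns]
        if missing:
            raise ValidationError(
                f"sample set {sample_set.label!r} references sample(s) absent "
                f"from the matrix: {missing}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, dest: Source, sep: str = "\t") -> None:
        """Write as a table with genes in rows, column 1 = gene id."""
        self._frame.to_csv(dest, sep=sep, index_label="gene_id", lineterminator="\n")


def _coerce_numeric(frame: pd.DataFrame) -> np.ndarray:
    try:
        return frame.to_numpy(dtype=float)
    except (TypeError, ValueError):
        pass
    # locate the offending cell for a useful message
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            gene = frame.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"cell for gene {gene!r}, sample {col!r} is not numeric: "
                f"{frame.loc[gene, col]!r}"
            )
    raise ParseError("table contains non-numeric cells")  # pragma: no cover


def _first_offender(frame: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return str(frame.index[i]), str(frame.columns[j])


def read_expression_table(
    source: Source,
    layout: str = "genes-in-rows",
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read an FPKM table into a validated :class:`ExpressionMatrix`.

    Parameters
    ----------
    source
        Path or open text stream.
    layout
        ``"genes-in-rows"`` (canonical: column 1 = gene id, remaining
        columns = samples) or ``"genes-in-columns"`` (transposed).
    sep
        Field separator; tab by default, pass ``","`` for CSV.
    """
    if layout not in ("genes-in-rows", "genes-in-columns"):
        raise ValidationError(f"unknown layout {layout!r}")
    frame = pd.read_csv(source, sep=sep, index_col=0, dtype=str)
    frame = frame.apply(lambda col: col.str.strip() if col.dtype == object else col)
    if layout == "genes-in-columns":
        frame = frame.T
    return ExpressionMatrix(frame)


class GeneAnnotation:
    """Total mapping gene id -> (symbol, biotype).

    Genes absent from the annotation resolve to biotype ``"unknown"`` and
    their own id as symbol, so the protein-coding screen excludes them;
    the count of such lookups is logged, not raised.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]] | None = None):
        self._entries: dict[str, tuple[str, str]] = dict(entries or {})
        self._unknown_seen: set[str] = set()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._entries

    def symbol(self, gene_id: str) -> str:
        entry = self._entries.get(gene_id)
        return entry[0] if entry else gene_id

    def biotype(self, gene_id: str) -> str:
        entry = self._entries.get(gene_id)
        if entry is None:
            self._unknown_seen.add(gene_id)
            return UNKNOWN_BIOTYPE
        return entry[1]

    def is_protein_coding(self, gene_id: str) -> bool:
        return self.biotype(gene_id) == "protein_coding"

    @property
    def unannotated_seen(self) -> int:
        """Number of distinct gene ids that resolved to biotype 'unknown'."""
        return len(self._unknown_seen)

    def items(self) -> Iterable[tuple[str, tuple[str, str]]]:
        return self._entries.items()

    def to_tsv(self, dest: Source, sep: str = "\t") -> None:
        frame = pd.DataFrame(
            [(g, s, b) for g, (s, b) in self._entries.items()],
            columns=["gene_id", "symbol", "biotype"],
        )
        frame.to_csv(dest, sep=sep, index=False, lineterminator="\n")


def read_gene_annotation(source: Source, sep: str = "\t") -> GeneAnnotation:
    """Read a gene annotation table with columns gene_id, symbol, biotype."""
    frame = pd.read_csv(source, sep=sep, dtype=str)
    required = {"gene_id", "symbol", "biotype"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"annotation is missing column(s): {sorted(missing)}")
    entries: dict[str, tuple[str, str]] = {}
    for gene_id, symbol, biotype in frame[["gene_id", "symbol", "biotype"]].itertuples(index=False):
        if gene_id in entries:
            raise ValidationError(f"duplicate gene id in annotation: {gene_id!r}")
        entries[str(gene_id)] = (str(symbol), str(biotype))
    return GeneAnnotation(entries)


def load_sample_sets(source: Source) -> list[SampleSet]:
    """Load replicate-set definitions from a YAML mapping label -> sample ids.

    Order of sets and of samples within a set is preserved.  Disjointness of
    two sets is enforced at comparison time, not here (a sample may belong
    to sets that are never compared against each other).
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict) or not doc:
        raise SchemaError("sample-set config must be a non-empty mapping of label -> sample ids")
    sets = []
    for label, ids in doc.items():
        if not isinstance(ids, list):
            raise SchemaError(f"sample set {label!r} must map to a list of sample ids")
        sets.append(SampleSet(str(label), tuple(str(s) for s in ids)))
    return sets


def write_sample_sets(sets: Sequence[SampleSet], dest: Source) -> None:
    doc = {s.label: list(s.sample_ids) for s in sets}
    text = yaml.safe_dump(doc, sort_keys=False)
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        dest.write(text)


def sets_by_label(sets: Sequence[SampleSet]) -> dict[str, SampleSet]:
    out = {}
    for s in sets:
        if s.label in out:
            raise ValidationError(f"duplicate sample-set label {s.label!r}")
        out[s.label] = s
    return out
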