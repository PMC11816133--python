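"""Pathway over-representation scoring and rank-based score adjustment.

The top-ranked selected genes (default 400) are tested against a gene-set
collection for over-representation: per pathway, the upper-tail binomial
probability of observing at least the matched number of members among the
submitted genes, Benjamini–Hochberg corrected across pathways, reported as
``raw_score = -log2(q)``.  This scorer is a transparent stand-in for
commercial over-representation services; an exported score table from such
a service can be loaded instead and fed through the same adjustment.

The adjustment is the distinctive step: each pathway's score is multiplied
by the mean rank weight of its matched genes, so a pathway hit by the
top-ranked genes outranks an equally enriched pathway hit only by genes at
the bottom of the submitted list.  The default weight is linear,
``w(g) = (N + 1 - rank(g)) / N``; reciprocal-rank and exponential half-life
schemes are available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ComparisonResult
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 400
#: above this submission size, over-representation scorers are known to be
#: biased toward large pathways; a warning is emitted, not an error
LARGE_SUBMISSION_WARNING = 300
#: cap on -log2(q) so that q underflowing to 0 stays finite
DEFAULT_SCORE_CAP = 100.0


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a symbol universe of ``background_size`` genes."""

    sets: Mapping[str, frozenset[str]]
    background_size: int

    def __post_init__(self) -> None:
        norm = {}
        for name, members in self.sets.items():
            members = frozenset(str(m).upper() for m in members)
            if not members:
                raise ValidationError(f"pathway {name!r} is empty")
            norm[str(name)] = members
        object.__setattr__(self, "sets", norm)
        if self.background_size < max((len(m) for m in norm.values()), default=0):
            raise ValidationError("background_size smaller than the largest pathway")
        if self.background_size <= 0:
            raise ValidationError("background_size must be positive")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(source: Union[str, TextIO], background_size: int | None = None) -> GeneSetCollection:
    """Read a GMT file (one set per line: name, description, member symbols).

    When ``background_size`` is not given, the number of distinct symbols
    across all sets is used.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    else:
        lines = source.read().splitlines()
    sets: dict[str, frozenset[str]] = {}
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"GMT line {ln}: expected name, description and >= 1 symbol")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"GMT line {ln}: duplicate pathway name {name!r}")
        sets[name] = frozenset(s for s in parts[2:] if s)
    if background_size is None:
        background_size = len(set().union(*sets.values())) if sets else 1
    return GeneSetCollection(sets=sets, background_size=background_size)


def write_gmt(collection: GeneSetCollection, dest: Union[str, TextIO]) -> None:
    lines = [
        "\t".join([name, "na", *sorted(members)])
        for name, members in collection.sets.items()
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        dest.write(text)


@dataclass
class PathwayRecord:
    """One pathway with its raw and rank-adjusted over-representation score."""

    name: str
    matched_genes: tuple[str, ...]
    raw_score: float
    p_value: float | None = None
    q_value: float | None = None
    matched_ranks: tuple[int, ...] = ()
    adjusted_score: float | None = None
    adjusted_rank: int | None = None


def select_top_n(result: ComparisonResult, n: int = DEFAULT_TOP_N) -> list[str]:
    """The first min(n, N) gene symbols by final rank, order preserved."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if n > LARGE_SUBMISSION_WARNING:
        warnings.warn(
            f"submitting more than {LARGE_SUBMISSION_WARNING} genes can bias "
            "over-representation scores toward large pathways",
            stacklevel=2,
        )
    ordered = sorted(result.records, key=lambda r: r.final_rank)[:n]
    return [r.symbol or r.gene_id for r in ordered]


def overrepresentation_score(
    genes: Sequence[str],
    collection: GeneSetCollection,
    score_cap: float = DEFAULT_SCORE_CAP,
) -> list[PathwayRecord]:
    """Score every pathway with at least one matched submitted gene.

    p is the upper-tail binomial probability of >= k matches in |genes|
    draws with success probability pathway_size / background_size; q is the
    Benjamini–Hochberg adjustment across the tested pathways;
    raw_score = -log2(q), capped at ``score_cap``.  Matching is by symbol,
    case-insensitive.
    """
    submitted = [str(g) for g in genes]
    if not submitted:
        return []
    upper = [g.upper() for g in submitted]
    n = len(submitted)
    records: list[PathwayRecord] = []
    pvals: list[float] = []
    for name in collection.sets:
        members = collection.sets[name]
        matched = tuple(g for g, u in zip(submitted, upper) if u in members)
        if not matched:
            continue
        k = len(matched)
        p0 = len(members) / collection.background_size
        p = float(stats.binom.sf(k - 1, n, p0))
        records.append(PathwayRecord(name=name, matched_genes=matched,
                                     raw_score=0.0, p_value=p))
        pvals.append(p)
    if not records:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    floor_q = 2.0 ** (-score_cap)
    for rec, q in zip(records, qvals):
        rec.q_value = float(q)
        rec.raw_score = float(-np.log2(max(q, floor_q)))
    return records


WeightFn = Callable[[int, int], float]


def _linear_weight(rank: int, n: int) -> float:
    return (n + 1 - rank) / n


def _reciprocal_weight(rank: int, n: int) -> float:
    return 1.0 / rank


def _exponential_weight(rank: int, n: int, half_life: float = 50.0) -> float:
    return 2.0 ** (-(rank - 1) / half_life)


WEIGHT_SCHEMES: dict[str, WeightFn] = {
    "linear": _linear_weight,
    "reciprocal": _reciprocal_weight,
    "exponential": _exponential_weight,
}


def adjust_by_rank(
    records: Sequence[PathwayRecord],
    submitted: Sequence[str],
    scheme: str = "linear",
) -> list[PathwayRecord]:
    """Re-score pathways by the ranking of their matched genes.

    Each matched gene g at 1-based position rank(g) in the submitted list
    contributes weight w(rank); adjusted_score = raw_score * mean(w).  All
    schemes give weight 1 to rank 1 and weights <= 1 elsewhere, so
    adjusted_score <= raw_score always.  Pathways are re-sorted by
    adjusted_score descending (ties by raw_score, then name) and assigned a
    dense adjusted_rank.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValidationError(f"unknown weight scheme {scheme!r}; options: {sorted(WEIGHT_SCHEMES)}")
    weight = WEIGHT_SCHEMES[scheme]
    position: dict[str, int] = {}
    for i, g in enumerate(submitted, start=1):
        position.setdefault(str(g).upper(), i)  # first occurrence wins
    n = len(submitted)
    adjusted = [replace(r) for r in records]
    for rec in adjusted:
        ranks = []
        for g in rec.matched_genes:
            u = str(g).upper()
            if u not in position:
                raise ValidationError(
                    f"pathway {rec.name!r} matches gene {g!r} absent from the submitted list"
                )
            ranks.append(position[u])
        rec.matched_ranks = tuple(ranks)
        rec.adjusted_score = rec.raw_score * float(
            np.mean([weight(r, n) for r in ranks])
        )
    adjusted.sort(key=lambda r: (-r.adjusted_score, -r.raw_score, r.name))
    for i, rec in enumerate(adjusted, start=1):
        rec.adjusted_rank = i
    return adjusted


def load_external_pathway_scores(source: Union[str, TextIO], sep: str = "\t") -> list[PathwayRecord]:
    """Load a pathway score table: columns pathway, score, genes
    (';'-delimited symbols).

    Accepts both the external-export schema (``score``/``genes``) and this
    package's own output schema (``raw_score``/``matched_genes``), so
    adjusted tables written by :func:`write_pathways` round-trip.
    """
    frame = pd.read_csv(source, sep=sep, dtype=str)
    frame = frame.rename(columns={"raw_score": "score", "matched_genes": "genes"})
    required = {"pathway", "score", "genes"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"pathway score table is missing column(s): {sorted(missing)}")
    records = []
    for row in frame[["pathway", "score", "genes"]].itertuples(index=False):
        try:
            score = float(row.score)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"pathway {row.pathway!r}: score {row.score!r} is not numeric") from exc
        if not isinstance(row.genes, str) or not row.genes.strip():
            raise SchemaError(f"pathway {row.pathway!r}: gene list cell is empty or unparseable")
        genes = tuple(g.strip() for g in row.genes.split(";") if g.strip())
        records.append(PathwayRecord(name=str(row.pathway), matched_genes=genes, raw_score=score))
    return records


def pathways_to_frame(records: Sequence[PathwayRecord]) -> pd.DataFrame:
    rows = []
    ordered = sorted(
        records,
        key=lambda r: (r.adjusted_rank if r.adjusted_rank is not None else 0, r.name),
    )
    for r in ordered:
        rows.append({
            "pathway": r.name,
            "raw_score": r.raw_score,
            "adjusted_score": r.adjusted_score,
            "adjusted_rank": r.adjusted_rank,
            "matched_genes": ";".join(r.matched_genes),
        })
    return pd.DataFrame(rows, columns=["pathway", "raw_score", "adjusted_score",
                                       "adjusted_rank", "matched_genes"])


def write_pathways(records: Sequence[PathwayRecord], dest: Union[str, TextIO]) -> None:
    pathways_to_frame(records).to_csv(dest, sep="\t", index=False, lineterminator="\n")
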