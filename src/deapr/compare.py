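"""Set algebra between comparisons and dose-pattern classification.

When two comparisons share a reference condition (e.g. an unmutated control
compared against two different mutants), the genes selected in both carry the
shared biology; subtracting the concordant common genes leaves a
condition-specific list.  Genes selected in both comparisons but moving in
*opposite* directions are the most condition-discriminating of all, so they
are retained in both specific lists.

For a three-dose series the per-set means of each selected gene are
classified into four shapes — monotone upward, monotone downward, a peak at
the middle dose (A-shift) or a trough at the middle dose (V-shift) — with a
configurable tolerance ratio deciding what counts as a step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_FLOOR,
    ComparisonResult,
    floored,
    rank_genes,
)
from .errors import ValidationError
from .matrix import ExpressionMatrix, SampleSet

PATTERN_UPWARD = "upward"
PATTERN_DOWNWARD = "downward"
PATTERN_A_SHIFT = "A_shift"
PATTERN_V_SHIFT = "V_shift"
PATTERN_UNCLASSIFIED = "unclassified"

DEFAULT_PATTERN_TOLERANCE = 1.25


@dataclass(frozen=True)
class CommonGeneReport:
    """A gene selected in two comparisons, with direction concordance."""

    gene_id: str
    symbol: str
    fc_in_a: float
    fc_in_b: float

    @property
    def concordant(self) -> bool:
        return (self.fc_in_a > 0) == (self.fc_in_b > 0)


def intersect_comparisons(a: ComparisonResult, b: ComparisonResult) -> list[CommonGeneReport]:
    """Genes selected in both comparisons, ordered by their rank in ``a``."""
    in_b = {r.gene_id: r for r in b.records}
    reports = []
    for rec in sorted(a.records, key=lambda r: r.final_rank):
        other = in_b.get(rec.gene_id)
        if other is not None:
            reports.append(CommonGeneReport(
                gene_id=rec.gene_id, symbol=rec.symbol,
                fc_in_a=rec.signed_fc, fc_in_b=other.signed_fc,
            ))
    return reports


def specific_genes(a: ComparisonResult, common: Sequence[CommonGeneReport]) -> ComparisonResult:
    """Condition-specific list: ``a`` minus concordant common genes.

    Common genes moving in opposite directions are retained — they change
    with the condition even though both comparisons select them.  The
    surviving records are re-ranked from scratch so downstream top-N
    selection sees a dense 1..N ranking.
    """
    drop = {c.gene_id for c in common if c.concordant}
    survivors = [replace(r) for r in a.records if r.gene_id not in drop]
    return ComparisonResult(
        reference_set=a.reference_set,
        test_set=a.test_set,
        records=rank_genes(survivors),
        screened_gene_count=a.screened_gene_count,
        floor=a.floor,
        min_fpkm=a.min_fpkm,
        reference_samples=a.reference_samples,
        test_samples=a.test_samples,
    )


def direction_summary(result: ComparisonResult) -> dict[str, int]:
    """Counts of up- and down-regulated records by the sign of signed_fc."""
    up = sum(1 for r in result.records if r.signed_fc > 0)
    return {"up_count": up, "down_count": len(result.records) - up}


def classify_dose_pattern(
    mean_low: float,
    mean_mid: float,
    mean_high: float,
    tolerance: float = DEFAULT_PATTERN_TOLERANCE,
    floor: float = DEFAULT_FLOOR,
) -> str:
    """Classify three dose-ordered set means into a trend shape.

    With floored means and tolerance ratio t (how many-fold a step must be
    to count): upward if mid >= t*low and high >= t*mid; downward if the
    reverse chain holds; A_shift if the middle dose exceeds both neighbours
    by t; V_shift if it falls below both by t; otherwise unclassified.
    Checked in that order, first match wins; for t > 1 the four shaped
    labels are mutually exclusive anyway.
    """
    if tolerance < 1:
        raise ValidationError(f"tolerance must be >= 1, got {tolerance}")
    low = floored(float(mean_low), floor)
    mid = floored(float(mean_mid), floor)
    high = floored(float(mean_high), floor)
    t = float(tolerance)
    if mid >= t * low and high >= t * mid:
        return PATTERN_UPWARD
    if low >= t * mid and mid >= t * high:
        return PATTERN_DOWNWARD
    if mid >= t * low and mid >= t * high:
        return PATTERN_A_SHIFT
    if mid <= low / t and mid <= high / t:
        return PATTERN_V_SHIFT
    return PATTERN_UNCLASSIFIED


@dataclass(frozen=True)
class DosePattern:
    """Trend call for one gene over three ascending dose levels."""

    gene_id: str
    symbol: str
    pattern: str
    mean_low: float
    mean_mid: float
    mean_high: float


def classify_dose_patterns(
    matrix: ExpressionMatrix,
    selected: ComparisonResult,
    low: SampleSet,
    mid: SampleSet,
    high: SampleSet,
    tolerance: float = DEFAULT_PATTERN_TOLERANCE,
    floor: float = DEFAULT_FLOOR,
) -> list[DosePattern]:
    """Dose-pattern calls for the genes of an already-run comparison.

    ``selected`` is normally the mid-vs-high comparison of the dose series;
    the low-dose set contributes shape only.  Means are arithmetic over the
    replicates of each set.
    """
    for s in (low, mid, high):
        matrix.require_samples(s)
    patterns = []
    for rec in sorted(selected.records, key=lambda r: r.final_rank):
        m_low = float(np.mean(matrix.values_for(rec.gene_id, low.sample_ids)))
        m_mid = float(np.mean(matrix.values_for(rec.gene_id, mid.sample_ids)))
        m_high = float(np.mean(matrix.values_for(rec.gene_id, high.sample_ids)))
        patterns.append(DosePattern(
            gene_id=rec.gene_id, symbol=rec.symbol,
            pattern=classify_dose_pattern(m_low, m_mid, m_high, tolerance, floor),
            mean_low=m_low, mean_mid=m_mid, mean_high=m_high,
        ))
    return patterns


# -- tabular forms ---------------------------------------------------------

def common_to_frame(common: Sequence[CommonGeneReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.symbol, c.fc_in_a, c.fc_in_b, c.concordant) for c in common],
        columns=["gene_id", "symbol", "fc_in_a", "fc_in_b", "concordant"],
    )


def patterns_to_frame(patterns: Sequence[DosePattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_id, p.symbol, p.pattern, p.mean_low, p.mean_mid, p.mean_high)
         for p in patterns],
        columns=["gene_id", "symbol", "pattern", "mean_low", "mean_mid", "mean_high"],
    )


def write_common(common: Sequence[CommonGeneReport], dest: Union[str, TextIO]) -> None:
    common_to_frame(common).to_csv(dest, sep="\t", index=False, lineterminator="\n")


def write_patterns(patterns: Sequence[DosePattern], dest: Union[str, TextIO]) -> None:
    patterns_to_frame(patterns).to_csv(dest, sep="\t", index=False, lineterminator="\n")
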