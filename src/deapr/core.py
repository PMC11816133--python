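"""DE-gene selection for small replicate sets: DELV, SRMM and combined ranking.

The method is deliberately non-statistical.  With n = 3 replicates per
condition, dispersion-based tests are underpowered and outlier-sensitive, so
genes are selected by two absolute criteria instead:

* **DELV** (differential expression of low-variability genes): a gene whose
  replicate range stays under 2-fold within *both* compared sets is
  reproducible; it is selected when the ratio of the two set means reaches
  2-fold.
* **SRMM** (separation of ranges by minimum and maximum): a gene whose
  replicate ranges do not overlap between the sets, with at least a 2-fold
  gap between the nearer extremes (min of the higher set vs max of the lower
  set).  This rescues genes that carry a single within-set outlier — exactly
  the genes dispersion-based tests discard for high FDR.

Fold changes are signed: magnitude always >= 1, positive when the test set
is higher than the reference set.  A floor (minimum detectable FPKM, default
0.01) enters every ratio so that zeros are well-defined; reported FPKM
differences are never floored.

Selected genes are ranked twice — by absolute fold change and by absolute
FPKM difference, both descending — and combined as
``0.9 * fc_rank + 0.1 * diff_rank``; the FPKM-difference term lets a highly
expressed gene outrank an equally fold-changed but barely expressed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .matrix import ExpressionMatrix, GeneAnnotation, SampleSet

#: minimum detectable FPKM used inside fold-change calculations
DEFAULT_FLOOR = 0.01
#: a gene must reach this FPKM in at least one compared sample to be screened in
DEFAULT_MIN_FPKM = 1.0
#: selection threshold on |signed fold change|
FC_THRESHOLD = 2.0
#: within-set max/min ratio must stay strictly below this for DELV eligibility
DELV_RANGE_LIMIT = 2.0

METHOD_DELV = "DELV"
METHOD_SRMM = "SRMM"


def floored(value: float, floor: float = DEFAULT_FLOOR) -> float:
    """Clamp an FPKM from below by the minimum detectable level.

    Applied only inside ratio computations, never to reported FPKMs or
    differences.
    """
    if floor <= 0:
        raise ValidationError(f"floor must be positive, got {floor}")
    return value if value > floor else floor


def signed_ratio(ref_value: float, test_value: float, floor: float = DEFAULT_FLOOR) -> float:
    """Signed fold change of test over reference.

    Returns r = floored(test)/floored(ref) when r >= 1, else -1/r, so the
    magnitude is always >= 1 and the sign gives the direction in the test
    set (negative = down-regulated relative to the reference).
    """
    r = floored(test_value, floor) / floored(ref_value, floor)
    return r if r >= 1.0 else -1.0 / r


@dataclass(frozen=True)
class DelvOutcome:
    """Result of the DELV test for one gene.

    ``eligible`` is the within-set reproducibility gate (both replicate
    ranges under 2-fold, on floored values); ``selected`` additionally
    requires |signed_fc| >= 2.  ``signed_fc``/``fpkm_diff`` are None when
    the gene is not eligible.
    """

    eligible: bool
    selected: bool
    signed_fc: float | None = None
    fpkm_diff: float | None = None


@dataclass(frozen=True)
class SrmmOutcome:
    """Result of the SRMM test for one gene.

    ``separated`` is True when the replicate ranges do not overlap; then the
    fold change and FPKM difference are measured between the nearer extremes
    of the two sets (the minimum view of the true change).
    """

    separated: bool
    selected: bool
    signed_fc: float | None = None
    fpkm_diff: float | None = None


def _check_replicates(values: Sequence[float], which: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError(f"{which} needs at least 2 replicate values, got {arr.size}")
    return arr


def delv_test(
    ref_values: Sequence[float],
    test_values: Sequence[float],
    floor: float = DEFAULT_FLOOR,
) -> DelvOutcome:
    """Differential expression of low-variability genes.

    Eligibility: floored(max)/floored(min) strictly below 2 within the
    reference set AND within the test set (an all-zero set floors to a
    ratio of exactly 1 and passes).  For eligible genes the fold change is
    the signed ratio of the arithmetic set means and the FPKM difference is
    mean(test) - mean(ref) on unfloored values.
    """
    ref = _check_replicates(ref_values, "reference set")
    test = _check_replicates(test_values, "test set")
    for arr in (ref, test):
        ratio = floored(float(arr.max()), floor) / floored(float(arr.min()), floor)
        if not ratio < DELV_RANGE_LIMIT:
            return DelvOutcome(eligible=False, selected=False)
    ref_mean = float(ref.mean())
    test_mean = float(test.mean())
    fc = signed_ratio(ref_mean, test_mean, floor)
    diff = test_mean - ref_mean
    return DelvOutcome(
        eligible=True,
        selected=abs(fc) >= FC_THRESHOLD,
        signed_fc=fc,
        fpkm_diff=diff,
    )


def srmm_test(
    ref_values: Sequence[float],
    test_values: Sequence[float],
    floor: float = DEFAULT_FLOOR,
) -> SrmmOutcome:
    """Separation of ranges by minimum and maximum values.

    When min(test) > max(ref) the gene moved up: the fold change is
    +floored(min(test))/floored(max(ref)) and the FPKM difference is
    min(test) - max(ref) — both taken between the nearer extremes, i.e. the
    smallest change consistent with every replicate.  The mirrored rule
    applies when max(test) < min(ref).  Overlapping ranges are never
    selected.
    """
    ref = _check_replicates(ref_values, "reference set")
    test = _check_replicates(test_values, "test set")
    ref_min, ref_max = float(ref.min()), float(ref.max())
    test_min, test_max = float(test.min()), float(test.max())
    if test_min > ref_max:
        fc = floored(test_min, floor) / floored(ref_max, floor)
        diff = test_min - ref_max
    elif test_max < ref_min:
        fc = -(floored(ref_min, floor) / floored(test_max, floor))
        diff = test_max - ref_min
    else:
        return SrmmOutcome(separated=False, selected=False)
    return SrmmOutcome(
        separated=True,
        selected=abs(fc) >= FC_THRESHOLD,
        signed_fc=fc,
        fpkm_diff=diff,
    )


@dataclass
class DEGeneRecord:
    """One selected differentially expressed gene.

    ``signed_fc`` always satisfies |signed_fc| >= 2 and shares its sign with
    ``fpkm_diff``.  Rank fields are filled by :func:`rank_genes`;
    ``final_rank`` = 1 is the most important gene.
    """

    gene_id: str
    symbol: str
    method: str  # METHOD_DELV or METHOD_SRMM
    signed_fc: float
    fpkm_diff: float
    fc_rank: int = 0
    diff_rank: int = 0
    combined_rank: float = 0.0
    final_rank: int = 0


@dataclass
class ComparisonResult:
    """Full output of one reference-set vs test-set comparison."""

    reference_set: str
    test_set: str
    records: list[DEGeneRecord] = field(default_factory=list)
    screened_gene_count: int = 0
    floor: float = DEFAULT_FLOOR
    min_fpkm: float = DEFAULT_MIN_FPKM
    reference_samples: tuple[str, ...] = ()
    test_samples: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.records)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def record_for(self, gene_id: str) -> DEGeneRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    # -- tabular form ------------------------------------------------------

    _COLUMNS = (
        "gene_id", "symbol", "method", "signed_fc", "fpkm_diff",
        "fc_rank", "diff_rank", "combined_rank", "final_rank",
    )

    def to_frame(self, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
        """Tabulate records sorted by final rank; with a matrix, append the
        per-sample FPKMs of the compared samples."""
        rows = [
            {c: getattr(r, c) for c in self._COLUMNS}
            for r in sorted(self.records, key=lambda r: r.final_rank)
        ]
        frame = pd.DataFrame(rows, columns=list(self._COLUMNS))
        if matrix is not None and len(frame):
            samples = list(self.reference_samples) + list(self.test_samples)
            fpkms = matrix.frame.loc[frame["gene_id"], samples].reset_index(drop=True)
            frame = pd.concat([frame, fpkms], axis=1)
        return frame

    def to_tsv(self, dest: Union[str, TextIO], matrix: ExpressionMatrix | None = None) -> None:
        self.to_frame(matrix).to_csv(dest, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        reference_set: str = "",
        test_set: str = "",
        floor: float = DEFAULT_FLOOR,
    ) -> "ComparisonResult":
        missing = set(cls._COLUMNS) - set(frame.columns)
        if missing:
            raise SchemaError(f"comparison table is missing column(s): {sorted(missing)}")
        records = [
            DEGeneRecord(
                gene_id=str(row.gene_id),
                symbol=str(row.symbol),
                method=str(row.method),
                signed_fc=float(row.signed_fc),
                fpkm_diff=float(row.fpkm_diff),
                fc_rank=int(row.fc_rank),
                diff_rank=int(row.diff_rank),
                combined_rank=float(row.combined_rank),
                final_rank=int(row.final_rank),
            )
            for row in frame.itertuples(index=False)
        ]
        records.sort(key=lambda r: r.final_rank)
        return cls(reference_set=reference_set, test_set=test_set,
                   records=records, floor=floor)

    @classmethod
    def from_tsv(cls, source: Union[str, TextIO], **kwargs) -> "ComparisonResult":
        return cls.from_frame(pd.read_csv(source, sep="\t"), **kwargs)


def prefilter(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    ref: SampleSet,
    test: SampleSet,
    min_fpkm: float = DEFAULT_MIN_FPKM,
) -> list[str]:
    """Screen genes before selection.

    Keeps genes that are protein-coding and reach ``min_fpkm`` in at least
    one sample of the two compared sets (genes below that level vary as much
    between technical replicates as between conditions).  The expression
    screen is scoped to the compared samples because comparisons run
    pairwise and independently.
    """
    _check_disjoint(ref, test)
    matrix.require_samples(ref)
    matrix.require_samples(test)
    samples = list(ref.sample_ids) + list(test.sample_ids)
    sub = matrix.submatrix(samples)
    detectable = sub.max(axis=1) >= min_fpkm
    coding = np.fromiter(
        (annotation.is_protein_coding(g) for g in matrix.gene_ids),
        dtype=bool, count=matrix.n_genes,
    )
    keep = detectable.to_numpy() & coding
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def _check_disjoint(ref: SampleSet, test: SampleSet) -> None:
    overlap = set(ref.sample_ids) & set(test.sample_ids)
    if overlap:
        raise ValidationError(
            f"sample sets {ref.label!r} and {test.label!r} overlap: {sorted(overlap)}"
        )


def _tie_key(record: DEGeneRecord) -> tuple:
    return (-abs(record.signed_fc), -abs(record.fpkm_diff), record.gene_id)


def rank_genes(records: Sequence[DEGeneRecord]) -> list[DEGeneRecord]:
    """Assign component, combined and final ranks.

    fc_rank orders |signed_fc| descending, diff_rank orders |fpkm_diff|
    descending; combined_rank = 0.9 * fc_rank + 0.1 * diff_rank; final_rank
    orders combined_rank ascending.  Ties at every stage are broken by
    (|signed_fc| desc, |fpkm_diff| desc, gene_id), so the ranking is a
    deterministic permutation independent of input order.
    """
    ranked = [replace(r) for r in records]
    by_fc = sorted(ranked, key=_tie_key)
    for i, r in enumerate(by_fc, start=1):
        r.fc_rank = i
    by_diff = sorted(ranked, key=lambda r: (-abs(r.fpkm_diff), -abs(r.signed_fc), r.gene_id))
    for i, r in enumerate(by_diff, start=1):
        r.diff_rank = i
    for r in ranked:
        r.combined_rank = 0.9 * r.fc_rank + 0.1 * r.diff_rank
    by_combined = sorted(ranked, key=lambda r: (r.combined_rank,) + _tie_key(r))
    for i, r in enumerate(by_combined, start=1):
        r.final_rank = i
    return by_combined


def select_de_genes(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    ref: SampleSet,
    test: SampleSet,
    floor: float = DEFAULT_FLOOR,
    min_fpkm: float = DEFAULT_MIN_FPKM,
) -> ComparisonResult:
    """Run one full comparison: prefilter, DELV, SRMM, rank.

    Each screened gene is put through the DELV test first.  Eligible genes
    are decided by DELV alone (an eligible-but-unselected gene has both
    ranges under 2-fold and set means under 2-fold apart, so SRMM could not
    add it except at flooring boundaries — by construction DELV owns that
    decision).  Ineligible genes fall through to SRMM.
    """
    eligible_genes = prefilter(matrix, annotation, ref, test, min_fpkm=min_fpkm)
    ref_block = matrix.submatrix(ref.sample_ids).to_numpy(dtype=float)
    test_block = matrix.submatrix(test.sample_ids).to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    records: list[DEGeneRecord] = []
    for gene in eligible_genes:
        i = index[gene]
        ref_vals = ref_block[i]
        test_vals = test_block[i]
        delv = delv_test(ref_vals, test_vals, floor)
        if delv.eligible:
            if delv.selected:
                records.append(DEGeneRecord(
                    gene_id=gene, symbol=annotation.symbol(gene),
                    method=METHOD_DELV,
                    signed_fc=delv.signed_fc, fpkm_diff=delv.fpkm_diff,
                ))
            continue
        srmm = srmm_test(ref_vals, test_vals, floor)
        if srmm.selected:
            records.append(DEGeneRecord(
                gene_id=gene, symbol=annotation.symbol(gene),
                method=METHOD_SRMM,
                signed_fc=srmm.signed_fc, fpkm_diff=srmm.fpkm_diff,
            ))
    return ComparisonResult(
        reference_set=ref.label,
        test_set=test.label,
        records=rank_genes(records),
        screened_gene_count=len(eligible_genes),
        floor=floor,
        min_fpkm=min_fpkm,
        reference_samples=ref.sample_ids,
        test_samples=test.sample_ids,
    )
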