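"""Deterministic synthetic FPKM fixtures with known ground truth.

The generator emulates the data regime the selection method assumes: six
replicate sets (two cell lines x three dose levels, samples S1-S18, three
replicates each) whose within-set variability is tight — replicate values
are the set-level mean times a multiplicative noise factor drawn
uniform-in-log within a stated bound, so within-set max/min ratios are
*provably* below the bound rather than probably.  That makes recovery of
planted genes exact, not statistical.

Planted categories (counts configurable via :class:`FixtureSpec`):

===================  =========================================================
flat                 same mean everywhere; must never be selected
delv_up / delv_down  clean fold change between the mutant comparison's sets
srmm_outlier         fold change plus one inflated replicate in the test set,
                     breaking the within-set gate so only range separation
                     can recover the gene
subthreshold         strong fold change entirely below 1 FPKM; screened out
noncoding            strong fold change, biotype lincRNA; screened out
opposite_direction   up in one comparison's test set, down in the other's
dose_*               the four three-dose shapes (upward, downward, peak at
                     the middle dose, trough at the middle dose)
===================  =========================================================

Default dose-category counts (15/36/78/11) and the 12 opposite-direction
genes reproduce the census structure of the three-dose experiment this kind
of analysis is built for; the default noise bound of 1.3 puts flat coding
genes deep inside the "under 2-fold within-set variability" regime seen in
real replicate sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneAnnotation, SampleSet, write_sample_sets
from .pathways import GeneSetCollection, write_gmt
from .errors import ValidationError

SET_LABELS = ("THP1_0", "THP1_1", "THP1_10", "B11_0", "B11_1", "B11_10")
REPLICATES = 3
SAMPLE_IDS = tuple(f"S{i}" for i in range(1, len(SET_LABELS) * REPLICATES + 1))

#: the canonical comparison graph over the six sets: name -> (reference, test)
CANONICAL_COMPARISONS: dict[str, tuple[str, str]] = {
    "Comp1": ("B11_0", "THP1_0"),    # mutant A vs no-mutant control
    "Comp2": ("B11_0", "B11_1"),     # mutant B vs no-mutant control
    "Comp3": ("THP1_0", "THP1_1"),   # dose-only control, cell line A
    "Comp7": ("B11_1", "B11_10"),    # dose escalation, cell line B
    "Comp8": ("THP1_0", "THP1_10"),  # dose-only control, cell line A
}

_CATEGORIES = (
    "flat", "delv_up", "delv_down", "srmm_outlier", "subthreshold",
    "noncoding", "opposite_direction",
    "dose_upward", "dose_downward", "dose_a_shift", "dose_v_shift",
)

# per-category set-mean multipliers as powers of the planted fold change f,
# ordered like SET_LABELS: (THP1_0, THP1_1, THP1_10, B11_0, B11_1, B11_10)
_FC_EXPONENTS: dict[str, tuple[float, ...]] = {
    "flat":               (0, 0, 0, 0, 0, 0),
    "delv_up":            (1, 1, 1, 0, 0, 0),
    "delv_down":          (0, 0, 0, 1, 1, 1),
    "srmm_outlier":       (1, 1, 1, 0, 0, 0),
    "subthreshold":       (1, 1, 1, 0, 0, 0),
    "noncoding":          (1, 1, 1, 0, 0, 0),
    "opposite_direction": (1, 1, 1, 0, -1, -1),
    "dose_upward":        (0, 0, 0, 0, 1, 2),
    "dose_downward":      (2, 2, 2, 2, 1, 0),
    "dose_a_shift":       (0, 0, 0, 0, 1, 0),
    "dose_v_shift":       (1, 1, 1, 1, 0, 1),
}

_SYMBOL_PREFIX = {
    "flat": "FLAT", "delv_up": "DLVU", "delv_down": "DLVD",
    "srmm_outlier": "SRMO", "subthreshold": "SUBT", "noncoding": "NCOD",
    "opposite_direction": "OPPD", "dose_upward": "DOSU",
    "dose_downward": "DOSD", "dose_a_shift": "DOSA", "dose_v_shift": "DOSV",
}

_PATTERN_TRUTH = {
    "dose_upward": "upward", "dose_downward": "downward",
    "dose_a_shift": "A_shift", "dose_v_shift": "V_shift",
}

_METHOD_TRUTH = {
    "delv_up": "DELV", "delv_down": "DELV", "srmm_outlier": "SRMM",
    "opposite_direction": "DELV",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters: category counts, noise model, fold change, seed.

    ``within_set_noise`` bounds the max/min replicate ratio per gene per set
    (multiplicative, uniform in log).  ``planted_fc`` is the true fold
    change of every differential category; with noise bound b the observed
    mean fold change lies in [planted_fc / b, planted_fc * b].
    ``base_log_mean``/``base_log_sigma`` parameterise the log-normal draw of
    per-gene baseline FPKM (default median ~20 FPKM, roughly a StringTie
    moderately expressed gene).
    """

    n_flat: int = 800
    n_delv_up: int = 50
    n_delv_down: int = 50
    n_srmm_outlier: int = 20
    n_subthreshold: int = 25
    n_noncoding: int = 25
    n_opposite_direction: int = 12
    n_dose_upward: int = 15
    n_dose_downward: int = 36
    n_dose_a_shift: int = 78
    n_dose_v_shift: int = 11
    planted_fc: float = 4.0
    within_set_noise: float = 1.3
    outlier_factor: float = 2.5
    base_log_mean: float = math.log(20.0)
    base_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("n_") and getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be >= 0")
        if self.planted_fc < 1:
            raise ValidationError("planted_fc must be >= 1")
        if self.within_set_noise < 1:
            raise ValidationError("within_set_noise bound must be >= 1")
        if self.outlier_factor < 2:
            raise ValidationError("outlier_factor must be >= 2 to defeat the within-set gate")

    def count(self, category: str) -> int:
        return getattr(self, f"n_{category}")

    @property
    def n_total(self) -> int:
        return sum(self.count(c) for c in _CATEGORIES)


@dataclass
class FixtureBundle:
    """Everything one run of :func:`generate` produces."""

    matrix: ExpressionMatrix
    annotation: GeneAnnotation
    sample_sets: list[SampleSet]
    gene_sets: GeneSetCollection
    truth: pd.DataFrame  # indexed by gene_id


def default_sample_sets() -> list[SampleSet]:
    sets = []
    for i, label in enumerate(SET_LABELS):
        ids = SAMPLE_IDS[i * REPLICATES:(i + 1) * REPLICATES]
        sets.append(SampleSet(label, ids))
    return sets


def _signed(power: float, f: float) -> float:
    """Exponent difference -> signed fold change convention (+r or -r, or 1)."""
    r = f ** power
    if r >= 1:
        return r
    return -1.0 / r if r > 0 else 1.0


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate a matrix over the six canonical sets, with ground truth.

    Deterministic for a fixed seed; the noise draws do not depend on the
    noise bound, so regenerating with a different ``within_set_noise`` and
    the same seed reuses the same underlying uniforms (within-set ratios
    scale monotonically with the bound).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    n_samples = len(SAMPLE_IDS)

    # fixed draw order, independent of parameter values
    base = rng.lognormal(spec.base_log_mean, spec.base_log_sigma, size=n)
    u = rng.uniform(-0.5, 0.5, size=(n, n_samples))
    sub_base = rng.uniform(0.05, 0.15, size=spec.count("subthreshold"))
    outlier_pos = rng.integers(0, REPLICATES, size=spec.count("srmm_outlier"))

    categories = np.concatenate([
        np.full(spec.count(c), c, dtype=object) for c in _CATEGORIES
    ]) if n else np.empty(0, dtype=object)

    # planted differential genes must clear the 1-FPKM screen on their low side
    differential = ~np.isin(categories, ("flat", "subthreshold"))
    base = np.where(differential, np.maximum(base, 2.0), base)
    sub_idx = np.flatnonzero(categories == "subthreshold")
    base[sub_idx] = sub_base

    noise = spec.within_set_noise ** u  # per-replicate multiplicative factor
    f = spec.planted_fc
    values = np.empty((n, n_samples), dtype=float)
    set_of_sample = np.repeat(np.arange(len(SET_LABELS)), REPLICATES)
    for i in range(n):
        expo = _FC_EXPONENTS[categories[i]]
        mult = np.array([f ** expo[s] for s in set_of_sample])
        values[i] = base[i] * mult * noise[i]

    # inflate one test-set replicate of each srmm_outlier gene past the
    # within-set gate: 2.5x the largest drawn value guarantees a >= 2.5
    # max/min ratio while leaving the set's minimum (hence separation) intact
    test_cols = np.arange(REPLICATES)  # THP1_0 = S1..S3
    for j, i in enumerate(np.flatnonzero(categories == "srmm_outlier")):
        col = test_cols[outlier_pos[j]]
        values[i, col] = spec.outlier_factor * values[i, test_cols].max()

    gene_ids = [f"G{i + 1:06d}" for i in range(n)]
    counters: dict[str, int] = {}
    symbols = []
    for cat in categories:
        counters[cat] = counters.get(cat, 0) + 1
        symbols.append(f"{_SYMBOL_PREFIX[cat]}{counters[cat]:04d}")
    biotypes = ["lincRNA" if c == "noncoding" else "protein_coding" for c in categories]

    frame = pd.DataFrame(values, index=gene_ids, columns=list(SAMPLE_IDS))
    matrix = ExpressionMatrix(frame)
    annotation = GeneAnnotation({
        g: (s, b) for g, s, b in zip(gene_ids, symbols, biotypes)
    })

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": symbols,
        "category": list(categories),
        "biotype": biotypes,
        "true_fc_comp1": [_signed(_FC_EXPONENTS[c][0] - _FC_EXPONENTS[c][3], f)
                          for c in categories],
        "true_fc_comp2": [_signed(_FC_EXPONENTS[c][4] - _FC_EXPONENTS[c][3], f)
                          for c in categories],
        "true_fc_comp7": [_signed(_FC_EXPONENTS[c][5] - _FC_EXPONENTS[c][4], f)
                          for c in categories],
        "true_pattern": [_PATTERN_TRUTH.get(c, "none") for c in categories],
        "planted_method": [_METHOD_TRUTH.get(c, "none") for c in categories],
    }).set_index("gene_id", drop=False)

    gene_sets = _build_gene_sets(truth, rng)
    return FixtureBundle(
        matrix=matrix, annotation=annotation,
        sample_sets=default_sample_sets(),
        gene_sets=gene_sets, truth=truth,
    )


def _build_gene_sets(truth: pd.DataFrame, rng: np.random.Generator) -> GeneSetCollection:
    """Small pathway collection over the coding symbol universe.

    Planted pathways collect the differential categories (diluted with flat
    genes); decoy pathways draw flat genes only.
    """
    coding = truth[truth["biotype"] == "protein_coding"]
    flat = coding.loc[coding["category"] == "flat", "symbol"].tolist()
    background = len(coding)

    def sample_flat(k: int) -> list[str]:
        k = min(k, len(flat))
        return list(rng.choice(flat, size=k, replace=False)) if k else []

    sets: dict[str, frozenset[str]] = {}

    def add(name: str, members: list[str]) -> None:
        if members:
            sets[name] = frozenset(members)

    by_cat = lambda c: coding.loc[coding["category"] == c, "symbol"].tolist()
    add("UP_RESPONSE", by_cat("delv_up") + sample_flat(10))
    add("DOWN_RESPONSE", by_cat("delv_down") + sample_flat(10))
    add("OUTLIER_RESPONSE", by_cat("srmm_outlier") + sample_flat(5))
    add("INNATE_LIKE", by_cat("opposite_direction") + sample_flat(5))
    add("DOSE_RESPONSE",
        by_cat("dose_upward") + by_cat("dose_downward")
        + by_cat("dose_a_shift") + by_cat("dose_v_shift") + sample_flat(10))
    for i in range(5):
        add(f"DECOY_{i + 1}", sample_flat(30))
    return GeneSetCollection(sets=sets, background_size=max(background, 1))


def write_fixture(bundle: FixtureBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files readable by the I/O modules.

    Emits matrix.tsv, annotation.tsv, sets.yaml, pathways.gmt, truth.tsv;
    returns their paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.tsv",
        "annotation": directory / "annotation.tsv",
        "sets": directory / "sets.yaml",
        "gene_sets": directory / "pathways.gmt",
        "truth": directory / "truth.tsv",
    }
    try:
        bundle.matrix.to_tsv(str(paths["matrix"]))
        bundle.annotation.to_tsv(str(paths["annotation"]))
        write_sample_sets(bundle.sample_sets, str(paths["sets"]))
        write_gmt(bundle.gene_sets, str(paths["gene_sets"]))
        bundle.truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths
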