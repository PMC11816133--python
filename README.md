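# deapr

Differential expression and pathway ranking for small-replicate RNA-seq
FPKM data.

With n ≈ 3 replicates per condition, dispersion-based differential-expression
tests are underpowered and outlier-sensitive: genes with a single aberrant
replicate get discarded for high FDR, and genes expressed near zero in one
group produce distorted fold changes. This package selects and ranks
differentially expressed (DE) genes by two absolute, reproducibility-driven
criteria instead, then carries the ranking through to pathway scoring. It is
aimed at laboratory researchers comparing carefully controlled experimental
groups — gene knockouts, inducible mutants, drug doses — quantified as FPKM
(fragments per kilobase of transcript per million mapped reads, e.g. from a
HISAT2 + StringTie pipeline).

## Method

After screening to protein-coding genes reaching ≥ 1 FPKM in at least one
compared sample, each gene is tested two ways:

* **DELV** (differential expression of low-variability genes). The gene is
  *eligible* when its within-set max/min FPKM ratio is strictly below 2 in
  **both** compared replicate sets — i.e. its expression is reproducible.
  It is *selected* when the signed ratio of the two set means reaches
  2-fold.
* **SRMM** (separation of ranges by minimum and maximum). Genes failing the
  DELV gate (typically because of one outlier replicate) are selected when
  the replicate ranges do not overlap and the gap between the nearer
  extremes — min of the higher set vs max of the lower set — is at least
  2-fold. The reported fold change is this minimum view of the change.

Fold changes are signed (magnitude ≥ 1; positive = up in the test set) and
a floor of 0.01 FPKM — the minimum detectable level — enters every ratio so
zeros are well defined; reported FPKM differences are never floored.
Selected genes are ranked by |fold change| and |FPKM difference| (both
descending) and combined as

```
combined_rank = 0.9 · fc_rank + 0.1 · diff_rank
```

so a highly expressed gene outranks an equally fold-changed but barely
expressed one. Downstream, comparisons sharing a reference are intersected
(concordant common genes subtracted, opposite-direction genes kept in both
specific lists), three-dose series are classified into
upward/downward/A-shift/V-shift trends, and the top-N ranked genes (default
400) are scored against pathway gene sets by a binomial/Benjamini–Hochberg
over-representation score which is then *rank-adjusted*: each pathway's
score is multiplied by the mean linear weight `(N + 1 − rank)/N` of its
matched genes.

## Worked example

```
python examples/01_select_de_genes.py
```

```
132 DE genes selected from 1072 screened

rank  symbol     method fold change  FPKM diff
   1  DLVU0022   DELV          4.65      281.5
   2  DLVU0044   DELV          4.53       61.8
   3  DLVD0020   DELV         -4.42      -63.1
   4  DLVD0036   DELV         -4.38      -88.9
   5  DLVU0027   DELV          4.37       69.1
```

The generator planted 4-fold changes under a 1.3× replicate-noise bound;
all planted genes come back (observed fold changes scatter around ±4), the
sign gives the direction in the test set, and the 90/10 ranking puts
equally fold-changed genes with larger absolute FPKM differences first.
The other examples walk through set algebra between comparisons
(`02_set_algebra.py`), dose-trend classification (`03_dose_patterns.py`),
replicate-variability profiling (`04_variability.py`) and rank-adjusted
pathway scoring (`05_pathway_ranking.py`).

The same capabilities are available from a shell via the `deapr` command
(`simulate`, `select`, `compare`, `patterns`, `variability`, `pathway`, and
`run` for a full configured pipeline with a reproducibility manifest):

```
deapr simulate --seed 42 --out fixture/
deapr select --matrix fixture/matrix.tsv --annotation fixture/annotation.tsv \
             --sets fixture/sets.yaml --ref B11_0 --test THP1_0 --out comp1.tsv
```

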