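# Methods

## The selection model and its assumptions

The package targets the small-replicate regime (n = 2–4 per condition,
typically 3) where dispersion estimation is unreliable. Its premise is
empirical: with modern library preparation and mapping, protein-coding genes
expressed above ~1 FPKM show under 2-fold variation across replicates for
roughly nine genes in ten, so *absolute* criteria on replicate ranges and
set means are meaningful without a noise model. Two consequences of that
premise are built in:

1. Genes that never reach 1 FPKM in the compared samples are screened out —
   below that level, variation between technical replicates rivals
   variation between conditions. The screen is scoped to the two compared
   sets (comparisons run pairwise and independently), not the whole matrix.
2. Non-protein-coding genes are screened out; they are systematically
   noisier under standard mapping stacks, and the variability profiler
   exists to verify both halves of this premise on any given dataset.

Selection is two-pronged. The low-variability route (DELV) demands
reproducibility first — within-set floored max/min ratio strictly below 2
in both sets — and then a 2-fold change of arithmetic set means. The
range-separation route (SRMM) exists for genes with a single outlier
replicate: if the replicate ranges do not overlap, the change is real no
matter the outlier, and the fold change is taken between the *nearer*
extremes of the two sets, the smallest change consistent with every
replicate. DELV-eligible genes are decided by DELV alone: an eligible gene
whose set means differ by under 2-fold has both ranges within 2-fold bands,
so a ≥ 2-fold range separation is arithmetically excluded except at
flooring boundaries, and the eligibility gate owns the decision there too.

Degenerate inputs are defined, not special-cased away: an all-zero
replicate set floors to a range ratio of exactly 1 (eligible) and a set
mean at the floor, so complete on/off genes — the strongest signal there
is — get finite fold changes (e.g. mean 5 vs all-zero ⇒ |fc| = 500 at the
default floor).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `floor` | 0.01 | FPKM | minimum detectable level; enters every ratio, never reported values |
| `min_fpkm` | 1.0 | FPKM | detectability screen over the compared samples |
| fold-change threshold | 2.0 | ratio | selection cut for both routes (fixed; it defines the method) |
| within-set gate | < 2.0 | ratio | DELV eligibility, strict inequality |
| rank weights | 0.9 / 0.1 | — | combined rank of fc_rank and diff_rank |
| `top_n` | 400 | genes | submission size for pathway scoring; > 300 triggers a large-pathway-bias warning |
| `tolerance` | 1.25 | ratio | dose-trend step size (see below) |
| weight scheme | linear | — | pathway rank weight `(N+1−r)/N`; reciprocal and exponential available |

Ranking ties are broken deterministically by (|fold change| desc,
|FPKM difference| desc, gene id), at every stage, so the final ranking is a
permutation independent of input order.

## Set algebra and dose patterns

For two comparisons against a shared reference, common genes are those
selected in both; a common gene is concordant when its fold changes share a
sign. Specific lists subtract concordant common genes only — opposite-
direction genes are retained in both lists, and the identity
|specific(A)| = |A| − |common| + |discordant| holds by construction.
Specific lists are re-ranked from scratch so top-N pathway submission sees
a dense 1..N ranking.

Dose-trend classification is applied to the genes already selected as DE
between the middle and highest dose (the lowest dose contributes shape
only), using floored per-set means and a tolerance ratio t (default 1.25,
chosen just above the within-replicate noise a tight experiment shows, so a
"step" must exceed replicate scatter): upward if mid ≥ t·low and
high ≥ t·mid; downward if the reverse chain holds; A-shift if the middle
dose exceeds both neighbours by t; V-shift if it falls below both by t;
otherwise unclassified. Checked in that order, though for t > 1 the four
shaped labels are mutually exclusive anyway. Labels are invariant under
uniform scaling of the three means (away from the floor). Using set means
rather than per-sample values makes the call independent of replicate
ordering.

## Pathway scoring

The over-representation scorer is a transparent stand-in for commercial
services: per pathway with ≥ 1 matched submitted gene, p is the upper-tail
binomial probability of the matched count among N submitted genes with
success probability (pathway size / background size); q is
Benjamini–Hochberg across tested pathways; raw_score = −log2 q, capped
(default 100) against q-underflow. Matching is by symbol,
case-insensitive; exported score tables from an external service can be
loaded instead and fed through the same adjustment.

The rank adjustment multiplies raw_score by the mean weight of the matched
genes' positions in the submitted list. The linear default
w(r) = (N+1−r)/N was chosen for transparency and provable monotonicity:
all schemes give w(1) = 1 and w ≤ 1, hence adjusted ≤ raw always, and
improving any matched gene's rank can only raise the score. The exact
arithmetic of proprietary score adjustment is not recoverable, so the
weight scheme is pluggable behind one flag.

## The synthetic generator

The generator emulates the regime the method assumes: six replicate sets
(two cell lines × three dose levels, samples S1–S18), per-gene baseline
FPKM log-normal (median 20 FPKM, σ = 1 in log units), and multiplicative
replicate noise drawn uniform-in-log within a bound (default 1.3×). The
noise is bounded rather than Gaussian deliberately: within-set ratios
provably never exceed the bound, so planted-gene recovery and
zero-false-positive statements are exact consequences of the construction,
not probabilistic ones. Planted categories cover both selection routes, a
sub-threshold and a non-coding decoy, opposite-direction genes (up with one
condition, down with the other) and the four dose shapes; default dose
counts (15 upward / 36 downward / 78 A-shift / 11 V-shift) and 12
opposite-direction genes mirror the census structure of a three-dose
inducible-mutant experiment, which also fixes the ~80% down-regulated share
at the top dose. Differential genes have their baseline clipped to ≥ 2 FPKM
so the planted signal cannot be silently removed by the detectability
screen. Noise draws do not depend on the bound's value, so regenerating at
a larger bound with the same seed reuses the same uniforms and the
below-2-fold fraction is exactly non-increasing in the bound.

What the generator does **not** emulate: count-level sampling noise,
gene-length effects, correlated genes, batch structure, heavy-tailed
non-coding noise, or unbounded outliers. Passing recovery tests therefore
demonstrates that the implementation applies the stated rules correctly
under the stated assumptions — not that the assumptions hold for any
particular real dataset; the variability profiler is the tool for checking
that on real data.

## Numerical choices and limitations

* Flooring uses `max(value, floor)`; comparisons against thresholds are
  exact float comparisons, and the strict "< 2" eligibility gate means a
  range ratio of exactly 2.0 fails it, while fold changes of exactly 2.0
  are selected ("≥ 2").
* Set means are plain arithmetic means of replicate FPKMs.
* The whole pipeline is deterministic: identical inputs and parameters
  produce byte-identical tables (the run manifest additionally records
  input digests and parameters; its timestamp is the one non-reproducible
  field).
* Problem sizes throughout the tests and the acceptance script (≈ 1100-gene
  matrices, ≈ 1000-gene oracle sweeps, 10-pathway collections) are chosen
  so every property that is provable at any size is exercised in seconds;
  the method itself is linear in genes × samples and runs comfortably on
  genome-scale tables.
* The method reports no p-values by design; it orders genes by effect
  magnitude and reproducibility. It will miss genuine changes smaller than
  2-fold, and a gene with overlapping ranges that fails the reproducibility
  gate is never selected regardless of its mean change.
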