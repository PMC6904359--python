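# Methods

## Consensus classification model

Each gene in the catalog (the *universe*) is scored against four
dosage-evidence sets: copy-number conservation across mammals
(`conserved_cnv`), ohnolog status (`ohnolog`), and two haploinsufficiency
sets (`hi_exac`, `hi_hipred`).  The consensus rule is deliberately
non-probabilistic:

* **MRDS** — member of all four sets (`n_evidence_sets = 4`);
* **MRDIS** — member of none, *and* pLI ≤ t *and* hipred ≤ t with
  t = 0.5 by default;
* **UNCLASSIFIED** — everything else.

Two reading choices matter.  First, the score filter is a
*strictly-greater exclusion*: a gene with pLI exactly 0.5 is retained as a
candidate insensitive gene.  Second, a gene missing either score cannot be
cleared of haploinsufficiency and is left unclassified rather than called
insensitive; this keeps the MRDIS class conservative at the cost of a
smaller denominator.  Raising t can only grow the MRDIS set
(monotonicity), and classification is order-independent.

Evidence sets are reconciled against the universe at construction:
identifiers absent from the catalog are dropped with a logged count
(strict mode fails instead).  Published per-analysis universes are not
always mutually consistent, so the universe here is always explicit — it
is the catalog itself.

## Enrichment statistics

For family `F` against target class `S` in universe of size `N`, the 2×2
table has `a = |F ∩ S|` with expected value `E = |F|·|S|/N`.  The test is
Pearson's χ² (df = 1, no continuity correction by default; a Yates flag
exists) when `E > 5` and the table is non-degenerate, otherwise the
two-sided Fisher exact test (sum of hypergeometric point probabilities not
exceeding the observed table's).  `E` — not the minimum expected cell — is
the selection criterion because it is the quantity the enrichment tables
report.  BH adjustment spans all family tests against one target class;
families of size zero are skipped with a warning.  Pooled small-family
categories (all families with ≤ 5, ≤ 7, ≤ 9 and ≤ 11 members) and the
all-TF group are tested alongside the named families.  Direction is
`over`/`under` by comparison of observed with expected, `none` on ties.

Mann–Whitney U comparisons use the exact null distribution when the data
are tie-free and `n_a·n_b ≤ 400`, otherwise the normal approximation with
tie and continuity corrections; a pooled sample with zero variance yields
p = 1.  dN/dS is undefined for dS = 0 and such genes are excluded from
that comparison (the conservative reading of "valid" ratios); every
comparison reports its effective per-group n after missing-data filtering.
Motif base composition is the mean of the position-probability columns —
well-defined for any position frequency matrix, including degenerate
positions — and proteins with several DNA-binding domains contribute their
mean domain size.  ORA uses the upper-tail hypergeometric probability with
BH adjustment; the default background is the annotated universe (genes in
≥ 1 term), term sizes outside 10–500 are not tested.

## Synthetic-data generator

The generator emulates the joint structure the analysis assumes, at the
study's scale: 22,810 genes, 1,639 TFs in 65 families whose size
distribution is strongly skewed (C2H2-ZF 747, homeodomain 196, …, a
46-family long tail arranged so the pooled small-family categories hold
exactly 87/126/186/238 TFs), and 399 KRAB zinc-finger proteins (KZFPs)
inside the C2H2-ZF family.

A latent Bernoulli(0.35) indicator marks each gene dosage-sensitive.
Given the latent class the four evidence sets are drawn conditionally
independently — Bernoulli(0.57) per set for sensitive genes,
Bernoulli(0.15) for insensitive ones.  These three rates were calibrated
once, from the binomial expectations, so that each evidence set holds
≈ 6,800 genes, the four-way intersection ≈ 850 genes (bracketing the
published 853), ≈ 8,000 genes sit in no set, and after the score filter
≈ 4,700 genes are called insensitive (echoing the published 5,579 of
9,459).  Scores are two-component Betas: pLI/hipred ~ Beta(5, 1.5) for
sensitive vs Beta(1, 2.2) for insensitive genes (≈ 61 % of all-absent
genes pass the double ≤ 0.5 filter), and pNull ~ Beta(0.3, 3) vs
Beta(0.8, 1) so that ≈ 5.3 % of genes exceed the 0.9 cutoff that defines
the pNull-based HLOF-tolerant set (echoing 1,226 of 22,810).  A second
HLOF-tolerant set is drawn at rates 0.01/0.083 per class (≈ 1,300 genes).

Feature shifts use the published class contrasts as defaults: CDS length
log-normal with mean ± SD 2640 ± 1783 vs 1310 ± 1956 bp (rounded to codon
multiples); dN/dS gamma with mean 0.062 vs 0.257 (dS gamma with mean 0.6,
2 % of genes with dS = 0 to exercise the exclusion policy); PPI degree
negative binomial with mean 851 vs 263; TF fraction of interactors Beta
with mean 0.25 vs 0.17; mRNA level normal 6.36 ± 0.679 vs 6.26 ± 1.767 (an
arbitrary continuous score; its units are not modelled); protein
expression levels multinomial over a 31-sample panel with class-specific
probabilities matching mean counts ≈ (4.5, 9.2, 5.9, 11.4) vs
(3.1, 7.6, 4.8, 15.5); motif length normal 12.0 ± 3.84 vs 12.7 ± 4.60 with
Dirichlet position columns whose A-concentration is higher in the
insensitive class (mean A fraction 28.2 % vs 30.1 %); DBD sizes log-normal
118 vs 52 residues with two-domain rates 5.7 % vs 0.5 %; activation-domain
rates 17 % vs 0.8 %; KZFPs always carry a repressor (KRAB) domain.

**Planted effects.**  A planted `(family, rr)` multiplies the family's
latent-sensitivity probability by `rr` (capped at 1) and each per-set
sensitivity by `rr^(1/4)` (capped at 1), so the probability of joint
four-set membership scales roughly linearly with `rr`.  The defaults plant
the nuclear-receptor family at rr = 8 (strongly sensitive) and C2H2-ZF at
rr = 0.3 (insensitive), reproducing the qualitative family contrast the
consensus analysis is designed to detect.  Annotation terms are planted
among latent-sensitive genes at a 10-fold membership rate (0.04 vs 0.004).
The fold is deliberately high because the sensitive class is 35 % of the
background: the *marginal* enrichment of a sensitive-pure study set
against a mixed background is capped near 1/prevalence ≈ 2.9×, so a
10-fold class effect yields only ≈ 2.4× marginal enrichment — enough for
reliable detection, while a 6-fold effect is not.

Generation is fully vectorised over one `numpy` PCG64 generator: one
config and one seed give one byte stream, and the emitted files (catalog
TSV, gene-set lists, JASPAR-style PFMs, GMT, ground truth, JSON manifest)
are byte-identical across runs.  `generate(..., with_features=False)`
skips feature columns, motifs and terms for many-replicate recovery
studies of classification and enrichment alone.

## What the generator does and does not emulate

It reproduces marginal set sizes, class mixtures, family skew and
first/second moments of the feature shifts.  It does **not** model:
correlation between the evidence sets beyond the shared latent class
(real haploinsufficiency sets share their underlying data); correlation
between scores and set membership (the real `hi_exac` set *is* a pLI
threshold); sequence-level motif structure or real PPI graph topology
(degrees only); GO DAG structure or real term identities.  Passing
recovery tests therefore demonstrates that the pipeline's statistics
behave correctly under the assumed generative structure — not that the
published biological conclusions follow from real data.

## Numerical and design choices

* Catalog reals are written with 4 significant digits and counts as
  integers; the canonical column order makes write∘read idempotent
  byte-for-byte.
* The Yates continuity correction is off by default (exposed as a flag):
  the method description never invokes it, and the expected ≤ 5 rule
  already routes small tables to the exact test.
* Sub-family analyses (e.g. KZFPs inside C2H2-ZF) are 2×2 tests like any
  other group; raw and adjusted p are both reported.
* BH families: one target set = one adjustment family; the four target
  sets (MRDS, MRDIS, two HLOF sets) are adjusted separately.
* Ties in enrichment direction give `none`; a zero-variance Mann–Whitney
  comparison gives p = 1 rather than an error.
* Problem sizes in the test suite: recovery tests use 100 replicates of
  the lean generator at full scale (22,810 genes) for classification and
  enrichment, 12 full-feature replicates for feature-shift recovery, and
  200 replicates for the null calibrations; these sizes give the
  assertions comfortable statistical margins at interactive runtimes.

## Known limitations

* The mRNA-level shift (0.1 between class means against within-class SDs
  of 0.679 and 1.767) is detectable in sign but not recoverable to 10 %
  relative accuracy at the class sizes the classifier yields; the recovery
  suite asserts magnitude only for CDS length, dN/dS and PPI degree.
* The consensus rule is unweighted; no per-set reliability weighting or
  probabilistic consensus is attempted (by design).
* Identifiers are opaque strings; no accession resolution, ortholog
  calling or dN/dS estimation from alignments is performed.
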