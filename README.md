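# tfdosage

Consensus dosage-sensitivity analysis of human transcription-factor (TF)
genes: classify genes as reliably dosage-sensitive or dosage-insensitive
from four independent lines of evidence, test TF families for enrichment in
either class, and characterize the two classes across binding-site, domain,
expression and evolutionary features — with a calibrated synthetic-data
generator so every stage is testable against known ground truth.

## The scientific problem

Changing a gene's copy number (or silencing one allele) is harmless for
some genes and pathogenic for others.  Several genome-scale proxies for
this *dosage sensitivity* exist — copy-number conservation across mammals,
ohnolog status (retention from whole-genome duplication), and two
haploinsufficiency predictions (pLI from exome-scale variation, and a
machine-learning score here called `hipred`) — but they disagree
substantially.  `tfdosage` implements the consensus approach:

* **MRDS** (most reliable dosage-sensitive): genes present in *all four*
  evidence sets;
* **MRDIS** (most reliable dosage-insensitive): genes present in *none* of
  the four sets **and** with both haploinsufficiency scores ≤ 0.5 (a gene
  missing either score cannot be cleared, and stays unclassified);
* everything else: UNCLASSIFIED.

Each TF family `F` is then crossed with a target class `S` in a 2×2 table
over the `N`-gene universe.  The expected in-family-in-class count under
independence is

```
E = |F| · |S| / N
```

and the test is Pearson's χ² (df = 1) when `E > 5`, Fisher's exact test
when `E ≤ 5`, with Benjamini–Hochberg FDR adjustment across all family
tests against one target class.  Two-group feature contrasts (CDS length,
dN/dS, PPI degree, motif length and base composition, DNA-binding-domain
sizes, expression-level profiles) use two-sided Mann–Whitney U tests;
activator/repressor proportions use the same χ²/Fisher switch; annotation
terms are tested by hypergeometric over-representation analysis (ORA).

## Worked example

```python
from tfdosage import (
    default_config, generate, classify, label_sets,
    build_family_groups, run_enrichment,
)

data = generate(default_config(seed=1))          # 22,810 genes, 1,639 TFs
labels = classify(data.frame, data.evidence)     # MRDS / MRDIS / UNCLASSIFIED
mrds, mrdis = label_sets(labels)
print(len(mrds), len(mrdis))                     # 847 4675

families = build_family_groups(data.frame)
results = run_enrichment(mrds, families, set(data.frame["gene_id"]))
top = min(results, key=lambda r: r.p_adj)
print(top.group_name, top.observed, round(top.expected, 2), f"{top.p_adj:.1e}")
# Nuclear receptor 41 1.71 7.1e-52
```

The default generator plants a strongly dosage-sensitive nuclear-receptor
family and a dosage-insensitive C2H2 zinc-finger family: 41 of the 46
nuclear receptors land in the 847-gene consensus-sensitive class against an
expectation of 1.71, and the enrichment is recovered at adjusted
p ≈ 7×10⁻⁵².

The same pipeline runs from the shell over files (TSV catalog, one-id-per-
line gene sets, JASPAR-style motifs, GMT terms):

```
tfdosage simulate --outdir sim/
tfdosage all --config run.yaml --outdir out/
tfdosage report --outdir out/
```

`out/` then holds `labels.tsv`, `venn.tsv`, four `enrichment_*.tsv` tables,
`comparisons.tsv`, `terms.tsv`, a `manifest.json` with input/output digests,
and a rendered `report.md`.

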