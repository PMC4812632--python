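# chromarch

Chromosome-architecture analysis for compact fungal genomes.

Filamentous fungi such as *Trichoderma reesei* keep many of their
niche-adaptation genes — carbohydrate-active enzymes (CAZymes), small
secreted cysteine-rich proteins (SSCPs), secreted proteases — in loose
clusters along their chromosomes, and concentrate some of those clusters in
the subtelomeric regions, where heterochromatin (H3K9me3) keeps basal
expression low until an inducing condition lifts it. `chromarch` provides
the full analysis chain for questions of this kind, for anyone with a
genome FASTA, a gene annotation with functional labels, and (optionally)
gene-level expression and histone-mark tables:

* **Cluster detection.** For a family of *n* genes in a genome of *N* genes
  the *average distribution number* D = N/n is the expected ordinal spacing
  under uniform placement. A cluster is a run of ≥ 3 family genes whose
  spacing beats that expectation fivefold: either every adjacent pair is
  separated by ≤ ⌊D/5⌋ other genes (`max_gap`) or the run's mean separation
  stays below D/5 (`mean_gap`). A stricter adjacency rule for secreted
  proteins (≥ 3 adjacent secreted genes, or ≥ 4 with a single non-secreted
  interruption) is also implemented, and a label-shuffle permutation test
  calibrates the clustered fraction against the uniform null.
* **Chromosome ends.** Telomere tracts as the longest exact tandem array of
  (TTAGGG)\_N at the 3′ terminus (CCCTAA at the 5′); AT-rich subtelomeric
  segments as maximal-scoring subsequences (score +(1−θ) per A/T, −θ per
  G/C, so a segment is positive iff its AT fraction exceeds θ); a
  window-less cumulative AT/GC disparity curve; and a random-region GC
  control. Features and genes are classed by distance to the nearest
  terminus: **CEC** (≤ 50 kb), **NCEC** (65–150 kb), **MCC** (interior).
* **Expression & chromatin.** Class-wise means and standard deviations,
  induction ratios relative to a reference carbon source, induced-gene
  (> 2-fold) enrichment tables, histone-mark counts per class, and Welch's
  unequal-variance t test with Benjamini–Hochberg correction for multi-way
  reports.
* **Synthetic genomes.** A generator plants all of the above — clusters,
  telomeres, AT tracts, a 100-fold CEC basal-expression deficit, >2-fold
  induction, H3K9me3 enrichment at the ends — and writes a ground-truth
  manifest, so the whole pipeline is testable end to end without any
  downloads.

## Worked example

```python
import chromarch as ca

ds = ca.generate(ca.SyntheticGenomeConfig(seed=1))   # 7 chromosomes, ~3.4 Mb
ann = ds.annotation

spec = ca.FamilySpec.from_annotation(ann, "CAZYME")
print(round(spec.D, 1), spec.gap_threshold)          # 40.3 8
clusters = ca.detect_clusters(ann, spec)
print([(c.chrom_id, c.n_members) for c in clusters])
# [('chr1', 4), ('chr2', 4), ('chr6', 3)]

tel = [t for c in ann.chromosomes for t in ca.find_telomere_tracts(c)]
print([(t.chrom_id, t.terminus, t.n_copies) for t in tel][:2])
# [('chr1', 'five_prime', 16), ('chr1', 'three_prime', 14)]

cls = ca.classify_genes(ann)
basal = ca.group_mean_expression(ds.expression, cls, "glucose")
print(round(basal["MCC"].mean / basal["CEC"].mean, 1))   # 105.1
folds = ca.induction_ratio(ds.expression, cls, "cellulose", "glucose")
print({k: round(v, 1) for k, v in folds.items()})
# {'CEC': 99.7, 'MCC': 2.0, 'NCEC': 5.5}
```

With 23 CAZymes among 927 genes the expected spacing is one CAZyme per
~40 genes, so runs with ≤ 8 intervening genes are fivefold denser than
chance; the two planted clusters are recovered (plus one arising from the
randomly placed members). The telomere detector reports the planted copy
numbers exactly. Chromosome-end genes sit two orders of magnitude below
interior genes on glucose, which is why their induction fold on cellulose
(~100×) dwarfs that of interior genes even though induced levels are
comparable.

The same pipeline runs from a shell:

```sh
chromarch simulate --out sim/ --seed 1
chromarch report --annotation sim/genes.tsv --fasta sim/genome.fa \
    --expr sim/expression.tsv --marks sim/marks.tsv --out run/
```

`run/summary.json` then holds per-family clustered percentages, cluster
positional classes, enrichment and mark tables; per-stage TSV/BED files sit
alongside it.

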