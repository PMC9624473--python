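# clonolink

Paired single-cell TCR-repertoire and transcriptome analytics for studying
why genetically identical tumor-bearing mice diverge into responders (R) and
non-responders (NR) under anti-PD-L1 checkpoint blockade.

Given per-sample 10x-style `filtered_contig_annotations.csv` tables, a
cell-by-gene count matrix with activation-cluster labels, tumor-volume
courses, and (optionally) a survival cohort, the pipeline quantifies:

* **clonal expansion** — cells grouped into *clones* (identical CDR3α/β
  nucleotide sequences) and *clonotypes* (identical amino-acid sequences),
  with percent abundance `100 · n_clonotype / n_sample`;
* **mutual exclusivity** — whether the top clonotypes of R mice
  (abundance > 1% in at least one sample; 0.65% for R in expression
  analyses) are detected in NR mice and vice versa, tested with a
  two-sided Fisher's exact test on (clonotype, sample) detection events;
* **repertoire structure** — pairwise overlap coefficients
  `|A∩B| / min(|A|,|B|)`, binned relative clonal abundance, Vα–Jα / Vβ–Jβ
  usage, and K-means clustering of samples on TRBV usage;
* **specificity networks** — CDR3β similarity groups with per-node
  `node_size = 100·(mean %R + mean %NR)` and
  `relative ratio = mean %NR / (mean %R + mean %NR)`, so 0 means
  responder-exclusive and 1 non-responder-exclusive;
* **clonotype–transcriptome linkage** — per-clonotype occupancy of
  activation clusters (N1–N5, A1–A7, D1–D2), R-vs-NR occupancy comparison
  by Mann–Whitney U, and the A6/A5 occupancy ratio;
* **cross-cohort differential expression** — per-cohort Wilcoxon rank-sum
  on log-normalized counts (`ln(1 + 10⁴·c/total)`), consolidated across
  cohorts by the most conservative (maximum) p-value and mean ln fold
  change, reported as signed fold change `e^lnFC` (or `−1/e^lnFC` for
  negative lnFC);
* **response classification** — `RCTV = (TV_n − TV_0)/TV_0` with
  R: RCTV < 0, SP: 0 ≤ RCTV ≤ 1.5, NR: RCTV > 1.5;
* **signature survival** — subjects scored by the mean z-scored expression
  of a gene signature, median-split (strictly above the median is "high"),
  and compared with the two-group log-rank test.

A first-class synthetic-data generator (`clonolink.synth`) emulates the
study's structure — private clonal expansion over a Dirichlet tail,
near-uniform splenic repertoires, disjoint or shared top-clonotype pools,
group-conditional cluster occupancy, negative-binomial counts with planted
differentially expressed genes and QC violators — with full ground truth,
so every downstream stage is testable without any data download.

## Worked example

Simulate a reduced study (2×4 mice, 800 TIL / 400 splenic cells each) and
run every stage:

```sh
clonolink simulate -o demo/data --seed 1 --n-cells-til 800 --n-cells-spleen 400
clonolink run -c demo/data/dataset.yaml -o demo/results --seed 1
```

or equivalently from Python:

```python
from clonolink import pipeline
pipeline.demo("demo", seed=1)
```

`demo/results/report.md` then reads (seed 1):

```
Top clonotypes (vdj preset): {'NR': 42, 'R': 40}
Top clonotypes present in >1 mouse: 0.0% of 82
Mutual exclusivity (Fisher's exact, unit=events): table=[[40, 0], [0, 42]],
  OR=6.88e+03, p=2.41e-24
Occupancy R-vs-NR clusters with p<0.05: A1, A2, A3, A4, A5, A6, A7
Mean cluster ratio by group: NR=10.64, R=1.65
Signature survival split: log-rank chi2=6.32, p=0.0119 (high n=150, low n=150)
Response classification: {'NR': 4, 'R': 4}
```

Reading the numbers: all 40 responder top clonotypes were detected only in
responder TILs and all 42 non-responder tops only in non-responder TILs
(perfect mutual exclusivity, Fisher p ≈ 2×10⁻²⁴); non-responder top
clonotypes sit ~10× more in cluster A6 than A5, responder tops ~1.6×,
recovering the planted occupancy skew (A6 probability 0.6 vs 0.3); and the
simulated 21-gene-signature cohort splits into survival strata that differ
at p ≈ 0.012.

Stage outputs (`cells.tsv`, `abundance.tsv`, `overlap_matrix.tsv`,
`exclusivity.json`, `network_nodes.tsv`, `occupancy_*.tsv`, `deg_I..IV.tsv`,
`signature_logrank.json`, `response_calls.tsv`, `manifest.json`) are plain
TSV/JSON; re-running with the same seed reproduces them byte for byte.

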