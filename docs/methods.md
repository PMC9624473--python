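# Methods

This note records the models, formulas, numerical conventions and design
choices behind clonolink, and what the synthetic-data generator does and
does not emulate.

## Receptor model

A cell's receptor is one TCRβ chain plus one or two TCRα chains (the TCRα
locus lacks allelic exclusion). Ingest keeps only full-length, productive,
high-confidence TRA/TRB contigs with complete V/J calls and CDR3
nucleotide and amino-acid sequences, collapses duplicate
(barcode, chain, CDR3-nt) rows to the highest-UMI copy, and accepts a
barcode as a cell iff it carries exactly 1 TRB and 1–2 TRA contigs.
Dropped barcodes are tallied by reason with priority
no-TRB → ≥2 TRB → no-TRA → ≥3 TRA, so kept + reasons = distinct barcodes.

Identity keys are flat strings `TRB|TRA1[,TRA2]` with the α chains sorted
lexicographically. A clone uses nucleotide CDR3s, a clonotype amino-acid
CDR3s; the clone partition therefore refines the clonotype partition, and
a dual-α clonotype never merges with a single-α one even when one α
matches (the sorted α tuple is part of the identity — the conservative
reading of a grouping rule that does not resolve dual-α cells).

## Abundance, top clonotypes, sharing

Percent abundance is `100 · n / N` per sample. "Top" selection is strict
(`>`), with two presets: `vdj` (1% both groups) and `expression`
(0.65% R / 1% NR, which equalizes the clonotype count contributed by each
group). A clonotype is top for a group if it exceeds the threshold in at
least one sample of that group. Sharing uses presence at ≥1 cell
("identified in"), not a percent floor.

## Mutual-exclusivity test

The 2×2 table has rows (R-top, NR-top) and columns (detections in R TIL
samples, detections in NR TIL samples), where one detection is one
(clonotype, sample) presence event; a flag switches to clonotype-level
counting (at most one detection per group). Fisher's exact test is
implemented with exact integer arithmetic: the weights
`C(r1,x)·C(r2,c1−x)` are integers proportional to the conditional
hypergeometric pmf, so the standard two-sided rule — sum the
probabilities of all margin-fixed tables no more probable than the
observed one — is applied with exact tie resolution, and the only
floating-point operation is the final division. The odds ratio uses the
Haldane 0.5 correction when any cell is zero. Counting detection events
rather than clonotypes uses the frequency information in repeated
detections; both units are exposed because the choice is not dictated by
the analysis design itself.

## Repertoire summaries

Overlap coefficient `|A∩B| / min(|A|,|B|)` over clonotype-key sets
(≥1 cell); undefined (NaN, with a warning) when both sets are empty.
Relative clonal abundance bins clonotype proportions over a partition of
(0, 1], default (0,1e−4], (1e−4,1e−3], (1e−3,1e−2], (1e−2,1e−1],
(1e−1,1]. V–J usage is cell-weighted; a dual-α cell contributes 0.5 per α
chain so every cell has weight 1. K-means on marginal TRBV usage vectors
uses Lloyd's algorithm with Euclidean distance and the best of `n_init`
(default 25) random initializations (scikit-learn), seeded; k defaults
to 2 (the spleen-vs-TIL contrast), since the number of clusters is a
user choice, not an inference.

## Specificity network

Nodes are β-chain CDR3 amino-acid sequences; a node's percent in a sample
sums the percents of all clonotypes sharing that β (abundance is
clonotype-level, nodes are β-level; summation is the natural projection).
Metrics follow the literal formulas with percents on the 0–100 scale:
`node_size = 100·(mean %R + mean %NR)` and
`relative_ratio = mean %NR / (mean %R + mean %NR)` (NaN when absent
everywhere). The grouping itself is a deliberately simplified stand-in,
not a reimplementation of published specificity-clustering algorithms:
"global" edges join equal-length sequences at Hamming distance ≤ 1, and
"local" edges join sequences sharing an interior k-mer (CDR3 trimmed by 3
residues per end, k ∈ {2,3,4}, default 3) whose sample frequency is at
least `fold_threshold` (default 10) times its frequency in a reference
multiset and whose count reaches `min_count` (default 3). Externally
computed group assignments can be imported from TSV and drive the same
node metrics; groups are connected components (singletons excluded),
ranked by summed node size.

## Expression: QC, normalization, occupancy, DEG

QC removes cells with fewer than 500 detected features or a mitochondrial
count share strictly above 10% (prefix `mt-`, configurable; both rules
strict as stated). Normalization is `ln(1 + 10⁴·c/total)` per cell.
Occupancy tables are percents over cluster labels summing to 100 per
clonotype (or per sample); the display layer is log10 with zeros masked.
Occupancy comparison uses the two-sided Mann–Whitney U test — exact null
when both sides have ≤ 8 observations and no pooled ties, tie-corrected
normal approximation otherwise; an all-tied comparison returns p = 1.
Per-clonotype occupancy requires ≥ 40 cells; shared-clonotype profiles
require ≥ 20 cells in each group.

Differential expression runs per cohort (cohort i pairs mouse R_i with
NR_i): two-sided Wilcoxon rank-sum on the normalized layer, with
`lnFC = ln[(mean(eˣ−1)_A + 1) / (mean(eˣ−1)_B + 1)]` — the de-logged-mean
ratio with pseudocount 1. Cohorts are consolidated by the maximum
("most conservative") p-value and the arithmetic-mean lnFC; genes with
sign disagreement across cohorts are flagged. The signed fold change is
`e^lnFC` for positive lnFC, `−1/e^lnFC` for negative, and 1.0 at exactly
zero, so |FC| ≥ 1 always and FC(−x) = −FC(x). The four standing
comparisons are R-top vs "Other", NR-top vs "Other", R-top vs NR-top, and
its reverse; "Other" cells carry clonotypes below 1% in **every** splenic
sample (a flag switches to the cell's own mouse's spleen — the stricter
every-spleen reading is the default because it guarantees the reference
population is unexpanded in all animals). A display filter keeps genes
whose R and NR fold changes differ by ≥ 0.4.

## Response classification and survival

`RCTV = (TVn − TV0)/TV0`; R: RCTV < 0, SP: 0 ≤ RCTV ≤ 1.5,
NR: RCTV > 1.5. RCTV exactly 0 is assigned to SP: a tumor that did not
shrink is not a response. Signature scoring z-scores each gene across
subjects (n−1 denominator), averages over the signature genes present
(missing genes dropped with a warning), and splits at the sample median
with "high" strictly above. The log-rank test is the standard two-group
statistic `(ΣO−E)²/ΣV` with the hypergeometric tie variance (lifelines);
censored subjects remain in risk sets until their censoring time. The
signature is always user-supplied; no gene list is hard-coded.

## Synthetic-data generator

Defaults encode the emulated study conditions: 4 mice per group, one TIL
(2000 cells) and one splenic (1000 cells) sample each, 10 top clonotypes
per mouse at 1–15% (rescaled if their sum exceeds 85% of the sample), a
private 400-clonotype Dirichlet(1) tail, spleens Dirichlet(5) over the
same mouse's clonotypes (near-uniform, so TIL–spleen overlap is high
within a mouse and ~0 across mice). CDR3s are `C` + 8–16 random residues
+ `F`, back-translated codon-wise; 20% of clonotypes carry two synonymous
nucleotide variants so the clone/clonotype distinction is always
exercised. V/J genes come from fixed catalogs of 20 TRBV / 12 TRBJ /
40 TRAV / 30 TRAJ names; 30% of cells are dual-α. Top pools are private
per mouse; `shared_clonotype_count` injects clonotypes into one R and one
NR mouse's pools for shared-clonotype analyses.

`top_pool_shared` is the group-exchangeable null: one common pool of
2·n_mice·n_top clonotypes, each expanding in exactly one mouse chosen
uniformly regardless of group, with the truth R-top/NR-top labels a
random half partition. One carrier per clonotype is deliberate: it makes
the detection table follow the classic two-binomial-proportion design for
which Fisher's conditional test is calibrated (designs where every mouse
samples several pool clonotypes make the cells sums of independent
binomials, for which the conditional test is severely conservative), and
it mirrors the real observation that top clonotypes are private to one
animal. Calibration checks accordingly condition on the exchangeable
truth labels, because selecting top sets from the observed R samples
biases detections toward the selecting group even under the null — a
caveat of the selection-then-test procedure itself.

Expression is negative-binomial (dispersion θ = 2, Gamma–Poisson
sampling) over 800 genes with lognormal base means (median ≈ 2.5 counts),
10 mitochondrial genes scaled to a 3% expected share, 3 marker genes per
cluster boosted e¹, and 20 planted genes boosted e^0.7 in R-top TIL
cells. Planted genes are drawn from the better-expressed half so the
effect survives normalization (`10⁴·c/total ≫ 1`); the measured
consolidated lnFC is ≈ 0.62 for a planted 0.7 — the expected mild
attenuation from the pseudocount and library-size coupling. A 5% QC
violator fraction (half scaled ×0.08 for low features, half with
mitochondrial means ×8) exercises the filter. Cluster labels are drawn
per cell from group-conditional occupancy maps over N1–N5 / A1–A7 /
D1–D2, with the planted skew NR A6 = 0.6 vs R A6 = 0.3. Tumor courses
interpolate geometrically from a 250–350 mm³ baseline to an endpoint
implied by a class-typical RCTV with 5% lognormal jitter on interior
points; survival cohorts have exponential event times with hazard
`base·HR^score` (score = mean signature z) and independent exponential
censoring calibrated to the requested marginal rate.

Not emulated: read-level data, doublets, batch effects, UMAP/clustering
(cluster labels are an input contract), convergent recombination, and
real repertoire gene-usage biases. Passing tests therefore demonstrate
that the pipeline recovers planted effects under a faithful structural
model, not that it is robust to artifacts the generator does not produce.

## Problem sizes and determinism

Simulation studies in the test suite use the study-scale conditions where
a check specifies them (e.g. 2000 TIL cells per mouse, 500 cells per DEG
arm, n = 300 survival cohorts) and reduced nuisance dimensions (spleen
size, tail length) where they are immaterial to the quantity under test;
the demo pipeline uses 800 TIL / 400 splenic cells so a complete run
takes well under a minute. All randomness flows through
`numpy.random.default_rng` seeded by the caller; identical config + seed
reproduces every output byte for byte. Degenerate inputs follow explicit
conventions: empty abundance tables and empty strata are errors, an
all-tied rank-sum comparison and an empty-margin Fisher table return
p = 1, a zero denominator in ratios returns missing rather than infinity.
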