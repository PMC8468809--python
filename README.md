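# xtalk — thyroid-hormone × glucocorticoid cross-talk genomics

`xtalk` re-implements, as a tested and reusable pipeline, the bespoke
computations used to characterize cross-talk between thyroid hormone (T3) and
glucocorticoid (CORT) signaling in amphibian metamorphosis: ternary response
clustering of expression changes, permutation-calibrated differential
methylation calling from capture sequencing, DMR genomic annotation, nuclear
receptor binding-site scanning with an explicit-topology HMM, and
pathway-network hub analysis. It is aimed at endocrinologists and
computational biologists who work with multi-hormone treatment designs
(CTRL / T3 / CORT / T3+CORT) and want the full analysis to run, end to end,
on synthetic data with planted ground truth — no external downloads required.

## The core methods

**Ternary response clustering.** Each gene's expression profile across the
four conditions is standardized to mean 0 and (population) variance 1. For
each treatment *i* ∈ {T3, CORT, T3+CORT} the standardized difference to
control, Δᵢ = zᵢ − z_CTRL, is called **u** (up) if Δᵢ ≥ t, **d** (down) if
Δᵢ ≤ −t, else **n**, yielding a triad code such as `u_n_u` (letters in T3,
CORT, T3+CORT order). The threshold t* is selected on a grid as the most
stringent value at which the `n_n_n` cluster is empty — every gene is
differentially regulated at least once. Codes map onto four categories:
**T3** (`u_n_u`, `d_n_d`), **CORT** (`n_u_u`, `n_d_d`), **ADDITIVE**
(`u_u_u`, `d_d_d`), and **X-talk** (the 20 remaining codes — evidence of
non-trivial pathway interaction). A culture-effect filter retains only genes
with the same triad code in tail-explant and whole-animal data and at least a
two-fold change (|log₂FC| ≥ 1) in the whole-animal context.

**DMR calling.** Per-condition read pileups are normalized to reads per
million, per-treatment differentials (treatment − CTRL) smoothed with a 10 bp
sliding mean, and candidate peaks taken as maximal same-sign runs. Null
thresholds come from a permutation scheme: two pseudo-samples drawn without
biological contrast from the pooled reads, differential profile rebuilt, and
the largest peak width and height recorded over 100 iterations. A peak is a
DMR only if it exceeds **both** null maxima (strict, conservative). DMRs are
then classified into the same u/d/n triads from their per-treatment
methylation deltas.

**NRBS HMM.** Nuclear receptors bind two AGGTCA half-sites in direct (DR),
everted (ER) or inverted (IR) orientation with a 0–8 bp spacer (DR4/ER6:
thyroid receptor; IR3: glucocorticoid receptor). The HMM models each topology
explicitly — background, first half-site in either orientation, an explicit
equal-probability link per spacer length, second half-site, background — with
every state's outgoing transition probabilities auditable to sum to 1.
Decoding is Viterbi; hits are scored in nats against the stay-in-background
path.

**Pathway networks.** Pathways (generic edge lists) containing at least one
DE gene are merged into one undirected network; hubs are nodes with degree
> 20; betweenness centrality is normalized to [0, 1]; the degree distribution
is checked for scale-free behavior by log–log regression; category degree
differences are assessed with a label-shuffling permutation test.

## Worked example

```
$ python analysis/01_simulate_data.py --seed 1
expression: 2000 genes x 12 samples per context, 2000 with planted responses
genome: 100 kb, 20 genes, 30 TEs, 30 planted motifs
methylome: 4 x 100,000 reads, 8 planted regions (8 demethylation)

$ python analysis/02_cluster_expression.py
1997 DE genes; 1914 retained after the consistency filter (t* = 1.44 explant, 1.47 whole)
   level     name  count  percent
category       T3    728     38.0
category     CORT     74      3.9
category ADDITIVE    853     44.6
category    XTALK    259     13.5
planted-code recovery: 1914/2000 (95.7%)

$ python analysis/03_call_dmrs.py
null thresholds T3: width > 490 bp, height > 725.0 RPM
...
recovery: 8/8 planted regions (Jaccard >= 0.5), 7 with the planted triad code

$ python analysis/07_published_tables.py
transcriptome (845 genes):
  T3: 328 (38.8%)
  CORT: 38 (4.5%)
  ADDITIVE: 376 (44.5%)
  XTALK: 103 (12.2%)
...
DMRs overlapping genes: 27.7%
```

The first three commands simulate a study with known planted responses and
show that the clustering recovers 95.7% of the planted triad codes and the
DMR caller finds every planted demethylation region while calling nothing on
contrast-free data. The last command re-derives the published category
percentages from the classified gene and DMR tables: most transcriptional
responses are T3-driven or additive, while the methylome is dominated by
X-talk responses — the pipeline's central contrast.

There is also a CLI (`xtalk simulate|cluster|dmr|scan-nrbs|network|run|report`)
over the same library; `xtalk run --seed 1 --outdir out/` executes all stages
from one configuration.

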