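# Methods

This note documents the models and procedures implemented in `xtalk`, the
parameters that matter, the synthetic data the pipeline is validated on, and
the numerical and design choices made where more than one reasonable option
existed.

## Ternary response clustering

A gene observed under CTRL, T3, CORT and T3+CORT is reduced to a three-letter
code over {u, d, n}. The profile is standardized per gene (mean 0, variance 1;
population variance, i.e. ddof = 0 — the four conditions are the entire
profile, not a sample from a larger one). Letters are assigned by comparing
each treatment's standardized value to CTRL with an inclusive threshold:
u if Δ ≥ t, d if Δ ≤ −t, else n. Standardization removes expression-level
scale, so genes spanning orders of magnitude of abundance are compared on the
same footing, and the call is invariant under any affine rescaling of the raw
profile.

**Threshold selection.** The rule "the smallest threshold at which the
`n_n_n` cluster is empty" is degenerate read literally: the `n_n_n` cluster
is empty for *every* sufficiently small t and only grows as t increases, so
the infimum is 0. We implement the boundary of the empty region instead: the
*largest* grid value at which no gene is `n_n_n` — equivalently the grid
value just below min over genes of maxᵢ |Δᵢ|. This matches the stated intent
("zero genes that are not DE at least once") while maximizing stringency.
The grid defaults to 0.01–3.0 standardized units in steps of 0.01.

**Categories.** T3 = {u_n_u, d_n_d}; CORT = {n_u_u, n_d_d}; ADDITIVE =
{u_u_u, d_d_d}; the remaining 20 codes are X-talk. Reported percentages are
rounded half-up to one decimal, matching the reporting convention of the
worked example.

**Upstream DE calling is pluggable.** The module accepts any externally
produced DE gene list; for synthetic runs a fold-change surrogate is used
(gene is DE if max over treatments of |log₂FC| ≥ 1 on log₂(count+1) condition
means). The cross-context culture filter requires an identical triad code in
both contexts (strictest reading of "similar expression profiles"; a
`compatible` mode relaxing this to "no u-vs-d contradiction" is available)
and a whole-animal |log₂FC| ≥ 1.

**ΔΔCt.** The qPCR utility returns
−[(Ct_target,treated − Ct_ref,treated) − (Ct_target,control − Ct_ref,control)],
the log₂ fold change versus the untreated control (one cycle = one doubling).

## DMR detection

Coverage tracks are per-base read counts scaled to reads per million (RPM);
"normalized for sequencing depth" admits several readings and RPM is the
simplest. Reads may optionally be extended 3′ (default 0 bp: the mapped span
is used, since the post-capture fragment size is not fixed). Differential
profiles (treatment − CTRL) are smoothed with a centered 10 bp sliding mean
whose window shrinks at sequence edges. Candidate peaks are maximal runs of
strictly positive (or strictly negative) smoothed signal; runs of opposite
sign are never merged.

**Permutation null.** For each contrast, two disjoint pseudo-samples of sizes
equal to the two compared libraries are drawn without replacement from the
pool of all reads of all four samples, their smoothed differential profile is
built exactly as for the real contrast, and the maximum candidate-peak width
and height are recorded (independently — they may come from different
peaks). The thresholds are the maxima over 100 iterations. Because the null
reproduces the data-generating process without biological contrast, an
effect-free data set exceeds both maxima only with probability on the order
of 1/(iterations+1) per contrast, and in practice the caller returns zero
DMRs on null data in ≥ 19/20 seeds.

**Retention.** A peak becomes a DMR only if width > w_max AND height > h_max
(both strict). The AND rule is the conservative reading of a "fairly
conservative" strategy; OR is available behind a flag. DMRs from the three
contrasts are merged by ≥ 1 bp overlap (interval union) into a non-redundant
set. The permutation pool is per analyzed sequence.

**Classification.** Each DMR's three deltas are the mean smoothed
differential over its interval; the 4-value profile (CTRL ≡ 0, then the three
deltas) is standardized and thresholded exactly like an expression profile,
with the threshold selected over the whole DMR set. A known knife-edge
follows from the geometry: the code class with the smallest standardized
delta magnitude (e.g. `d_n_u`, magnitude √2, versus 2 for `d_n_d` and 2.31
for single- or triple-response codes) sits closest to the selected threshold
and is the most likely to lose a letter to noise. This is intrinsic to the
procedure, not to this implementation.

## Synthetic data

The generators are first-class, tested code; their defaults are the study
conditions for all validation.

**Expression.** Negative-binomial counts with variance = μ + μ²·φ (φ =
dispersion, default 0.05; φ = 0 degenerates to Poisson). Baselines are
log-normal (median ≈ 200 reads, log-sd 1.5), typical of gene-level counts at
bulk RNA-seq depth. Planted effects are ±2 log₂ per the u/d letters of each
gene's code; the same truth is realized with independent noise in the explant
and whole-animal contexts (3 replicates each), so the consistency filter
retains planted genes. Per-code gene counts are apportioned by largest
remainder so totals are exact. The default code mix mirrors the observed
transcriptome proportions (≈44% additive, ≈39% T3, ≈4% CORT, ≈12% X-talk).

**Methylome.** Fixed-length fragments (default 50 bp, matching short-read
spans) are placed with probability proportional to a per-region weight:
1 in background, 1 + e (capture enrichment, default e = 3) inside planted
methylated regions, multiplied by (1 + effect) per treatment. Local coverage
expectations are therefore analytic: a −0.8 effect yields 20% of the CTRL
coverage inside the region. Background fragments are placed only in the
complement of the planted regions so region coverage tracks the region weight
alone. Read count per sample is exactly `depth`. Because each library has a
fixed read total, large planted effects slightly re-scale all densities of a
sample (composition effect) — as in real enrichment-based assays. Defaults
plant 8 regions of 800 bp on a 100 kb sequence (≈6% of the genome; the real
assay's DMR mass fraction is far smaller, which is why composition bias is
modest there) at ~100× mean coverage, demethylation-dominated with a mix of
triad codes. The CTRL methylome shape (fraction of genome methylated) is
deliberately a parameter, not a constant.

**Genome fixture.** A uniform-random sequence with non-overlapping genes
(with exons), TE intervals (five families) and CpG-enriched intervals placed
on a slot grid. CpG enrichment uses a first-order Markov chain with
P(G | C) = fold × 0.25 (capped at 0.95); for a 3-fold request the measured
CG-frequency ratio versus exons lands near 2.5, inside the expected [2, 4]
band (the stationary distribution shifts slightly toward G). Planted motifs
are written into the sequence last, so the declared substrings are guaranteed
verbatim; spacer filler is random to avoid homopolymer aliasing with the
A-rich half-site consensus.

**What the generators do not model:** sequencing error, PCR duplicates,
mappability, GC bias, bisulfite chemistry, biological replicate structure in
the methylome (one read set per condition), and correlated gene-gene
expression. Passing tests therefore demonstrate correctness of the
computations under the stated statistical model, not robustness to every
artifact of real libraries.

## NRBS HMM

States: background; two first half-sites (forward AGGTCA and its reverse
complement, position-specific emissions, consensus probability 1 − m with
m = 0.05 split equally over the other bases); a shared descending spacer
chain; two second half-sites; 1 + 12 + max_spacer + 12 states in total.
Architecture choices that matter:

* **Flat spacer cost.** The end of the first half-site carries one
  equal-probability link per choice: direct entry to either second-site
  orientation (spacer 0) or entry into the spacer chain at depth k
  (spacer k). Every spacer length therefore costs the same ≈ log(1/10)
  rather than a geometric per-step penalty — without this, exact spacer-8
  motifs score below two-mismatch spacer-0 alternatives and are mis-decoded.
* **Normalization audit.** Every state's outgoing mass is checked to sum to
  1 ± 1e-9 at construction (the property whose violation in a published
  model of this kind motivated rebuilding it; repaired links split their
  probability equally).
* **Topology from orientation pairs.** (F,F) and (R,R) are DRs on the two
  strands; (F,R) is IR (head-to-head); (R,F) is ER (tail-to-tail). Scanning
  a reverse-complemented sequence yields the mirrored hit set with labels
  preserved.
* **Decoding.** Viterbi, starting in background and terminating with a
  virtual exit to background so the best path never ends inside a truncated
  motif. Hit score is the log-odds (nats) of the decoded segment against
  staying in background; default p_enter = 0.05 and min_score = 3.0, at
  which consensus plants score ≈ 9–10 and chance 10-of-12 arrangements
  (≈ 2–2.3) are excluded. N emits uniformly in every state.

Overlapping hits cannot arise within one Viterbi path; a greedy resolver
(higher score wins, ties to the leftmost start) is provided for merged hit
sets. Motif-class enrichment between DMR and background hits uses Pearson's
chi-square on the 2×2 class-versus-rest table, 1 df, no continuity
correction.

## Pathway networks

Pathways are generic named edge lists; all pathways containing ≥ 1 DE gene
are merged into one simple undirected graph (duplicate edges collapsed,
self-loops dropped). Betweenness is normalized by (n−1)(n−2)/2 with the
global node count — the simpler of the two conventions that map onto
"ranging from 0 to 1". Hubs are degree > 20 (strict). The scale-free check is
a least-squares fit of log frequency versus log degree (R² as the
diagnostic); maximum-likelihood exponent estimation is out of scope. The
degree permutation test uses the difference in mean degree as its statistic
(a rank-sum variant is available), a shuffled label vector as the null, and
the add-one estimator p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + iterations); with
integer degrees ties make the test slightly conservative. Quantiles of degree
sets use the inclusive empirical (inverted-CDF) estimator. The synthetic
pathway universe is a Barabási–Albert graph (500 nodes, attachment 2) sliced
into 25 overlapping 120-node pathways, giving a merged network with a heavy
degree tail and a handful of hubs.

## Problem sizes and reproducibility

Validation uses 2,000-gene expression designs, 100 kb genomes at ~100× local
methylation coverage with 100 permutation iterations, and 120 planted motifs
— sizes at which every stage's statistical behavior (null calibration,
recovery rates) is measurable in seconds per run. Every stochastic component
takes an explicit seed and is a pure function of its arguments; the pipeline
re-run with the same configuration reproduces byte-identical outputs.

## Known limitations

* The DMR triad knife-edge described above caps code agreement below 100%
  when a low-magnitude code class (e.g. `d_n_u`) is present; on the default
  plant one of eight regions is typically affected.
* Null width thresholds grow with coverage (sign runs of a correlated noise
  process lengthen as zero-crossings rarefy), so planted regions much
  narrower than ~500 bp are not reliably recoverable at 100× on a 100 kb
  sequence with the conservative AND rule.
* The worked-example tables reproduce printed totals exactly, but per-code
  counts that were only published in aggregate are apportioned
  deterministically and are not individually meaningful.
* The HMM emissions are consensus-plus-uniform-mismatch, not trained from
  binding data; IR3-versus-DR4 discrimination on degenerate real sites will
  be weaker than on consensus plants.
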