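"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline is exercised on data produced here:

* :func:`simulate_expression` — negative-binomial RNA-seq counts for the four
  hormone conditions in two experimental contexts (tail-explant culture and
  whole animal), with per-gene planted triad responses;
* :func:`simulate_methylome` — capture-based methylation read intervals with
  planted methylation-loss/gain regions;
* :func:`simulate_genome` — a small genome fixture (FASTA/GFF3/BED) with
  CpG-enriched candidate DMR intervals and planted nuclear-receptor binding
  motifs;
* :func:`paper_counts_fixture` — deterministic classified gene and DMR tables
  whose category arithmetic reproduces the published worked example.

All generators are pure functions of their arguments, including ``seed``.
Negative-binomial counts use the mean/dispersion parameterization with
``variance = mu + mu**2 * dispersion`` (dispersion 0 degenerates to Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ALL_CODES, CATEGORY_MAP, XTALK_CODES, categorize

CONDITIONS = ("CTRL", "T3", "CORT", "T3CORT")
TREATMENTS = ("T3", "CORT", "T3CORT")

HALF_SITE = "AGGTCA"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --------------------------------------------------------------------------
# expression counts
# --------------------------------------------------------------------------

#: default planted code mix, mirroring the observed transcriptome proportions
DEFAULT_CODE_PROPORTIONS: Mapping[str, float] = {
    "u_u_u": 0.22,
    "d_d_d": 0.22,
    "u_n_u": 0.20,
    "d_n_d": 0.19,
    "n_u_u": 0.02,
    "n_d_d": 0.02,
    "n_n_u": 0.04,
    "n_n_d": 0.04,
    "u_n_n": 0.02,
    "d_n_n": 0.02,
    "n_u_n": 0.005,
    "n_d_n": 0.005,
}


def largest_remainder(total: int, fractions: Sequence[float]) -> np.ndarray:
    """Apportion ``total`` into integers proportional to ``fractions``.

    Largest-remainder rule so the parts always sum exactly to ``total``;
    remainder ties are broken by position (earlier entries win).
    """
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    quota = total * f / f.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    # stable sort: equal remainders resolved by original order
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def _code_effects(code: str, effect: float) -> np.ndarray:
    """Per-treatment planted log2 effects implied by a triad code."""
    sign = {"u": 1.0, "d": -1.0, "n": 0.0}
    return effect * np.array([sign[c] for c in code.split("_")])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with variance = mu + mu^2 * dispersion."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(
    n_genes: int,
    code_proportions: Mapping[str, float] | None = None,
    effect_size: float = 2.0,
    nb_dispersion: float = 0.05,
    n_reps: int = 3,
    seed: int = 0,
    baseline_log_mean: float = 5.3,
    baseline_log_sd: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate NB counts for two contexts with planted triad responses.

    ``code_proportions`` maps triad codes to gene fractions; the special key
    ``"n_n_n"`` (or fractions summing to < 1) yields unresponsive filler genes
    that are excluded from the truth table.  The same planted truth is
    realized — with independent sampling noise — in the explant and the
    whole-animal context, so the cross-context consistency filter retains the
    planted genes.  Baselines are log-normal (median ``exp(5.3) ~ 200`` reads).

    Returns ``(explant_counts, whole_counts, truth)``; count frames are genes
    x samples with columns ``<condition>_<context>_<rep>``.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    props = dict(DEFAULT_CODE_PROPORTIONS if code_proportions is None else code_proportions)
    for code in props:
        if code not in ALL_CODES:
            raise ValueError(f"unknown triad code: {code!r}")
    total_prop = sum(props.values())
    if total_prop > 1 + 1e-9:
        raise ValueError(f"code proportions sum to {total_prop:.4f} > 1")
    if "n_n_n" not in props and total_prop < 1 - 1e-9:
        props["n_n_n"] = 1.0 - total_prop
    elif abs(total_prop - 1) > 1e-9 and "n_n_n" in props:
        raise ValueError(f"code proportions sum to {total_prop:.4f}, expected 1")

    codes = list(props)
    counts_per_code = largest_remainder(n_genes, [props[c] for c in codes])
    gene_codes = np.repeat(codes, counts_per_code)

    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
    baselines = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, n_genes))
    effects = np.stack(
        [
            _code_effects(c, effect_size) if c != "n_n_n" else np.zeros(3)
            for c in gene_codes
        ]
    )  # genes x 3 treatments, log2 units
    # genes x 4 conditions expected means
    means = baselines[:, None] * 2.0 ** np.column_stack([np.zeros(n_genes), effects])

    frames = {}
    for context in ("explant", "whole"):
        cols = {}
        for j, cond in enumerate(CONDITIONS):
            for rep in range(1, n_reps + 1):
                cols[f"{cond}_{context}_{rep}"] = _nb_draw(rng, means[:, j], nb_dispersion)
        frames[context] = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    responsive = gene_codes != "n_n_n"
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids[responsive],
            "triad_code": gene_codes[responsive],
            "category": [categorize(c) for c in gene_codes[responsive]],
            "baseline_mean": baselines[responsive],
            "effect_log2fc_T3": effects[responsive, 0],
            "effect_log2fc_CORT": effects[responsive, 1],
            "effect_log2fc_T3CORT": effects[responsive, 2],
            "dispersion": nb_dispersion,
        }
    ).reset_index(drop=True)
    return frames["explant"], frames["whole"], truth


# --------------------------------------------------------------------------
# methylome reads
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylationTruth:
    """A planted differentially methylated region.

    ``effect_fraction`` holds the fractional change of capture coverage under
    (T3, CORT, T3+CORT) relative to CTRL: -0.8 means the treated coverage is
    20% of control (demethylation); +0.8 means 180% (re-methylation).
    """

    seq_id: str
    start: int
    end: int
    effect_fraction: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if any(not -1.0 <= e <= 1.0 for e in self.effect_fraction):
            raise ValueError("effect fractions must lie in [-1, 1]")

    @property
    def direction(self) -> str:
        strongest = max(self.effect_fraction, key=abs)
        return "re-methylation" if strongest > 0 else "demethylation"

    @property
    def triad_code(self) -> str:
        letters = [
            "u" if e > 0 else ("d" if e < 0 else "n") for e in self.effect_fraction
        ]
        return "_".join(letters)


def simulate_methylome(
    genome_len: int,
    truth: Sequence[MethylationTruth],
    depth: int,
    fragment_len: int = 50,
    seed: int = 0,
    ctrl_enrichment: float = 4.0,
) -> dict[str, np.ndarray]:
    """Simulate capture-seq read intervals for CTRL and the three treatments.

    Fixed-length fragments are placed with probability proportional to a
    per-region weight: 1 in background, ``1 + ctrl_enrichment`` inside planted
    (CTRL-methylated) regions, further scaled by ``1 + effect_fraction`` in
    the treated samples.  The local coverage expectation is therefore analytic
    and treatment/CTRL coverage ratios equal ``1 + effect_fraction``.

    Returns a dict mapping condition to an (n_reads, 2) array of half-open
    ``[start, end)`` intervals; every sample has exactly ``depth`` reads.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if fragment_len <= 0 or fragment_len > genome_len:
        raise ValueError("fragment_len must be in (0, genome_len]")
    regions = sorted(truth, key=lambda r: r.start)
    for r in regions:
        if r.start < 0 or r.end > genome_len:
            raise ValueError(f"truth region [{r.start}, {r.end}) outside genome")
    for a, b in zip(regions, regions[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping truth regions [{a.start}, {a.end}) and "
                f"[{b.start}, {b.end}) make planted effects ambiguous"
            )

    rng = np.random.default_rng(seed)
    max_start = genome_len - fragment_len
    widths = np.array([r.end - r.start for r in regions], dtype=float)
    starts = np.array([r.start for r in regions], dtype=int)

    # background fragments start only in the complement of the truth regions,
    # so local region coverage stays proportional to the region weight alone
    gap_bounds = [0]
    for r in regions:
        gap_bounds += [r.start, r.end]
    gap_bounds.append(genome_len)
    gap_starts = np.array(gap_bounds[0::2], dtype=int)
    gap_lens = np.array(gap_bounds[1::2], dtype=int) - gap_starts
    gap_cum = np.cumsum(gap_lens)

    def place_background(n: int) -> np.ndarray:
        x = rng.integers(0, gap_cum[-1], size=n)
        idx = np.searchsorted(gap_cum, x, side="right")
        offset = x - np.concatenate([[0], gap_cum])[idx]
        return gap_starts[idx] + offset

    out: dict[str, np.ndarray] = {}
    for ci, cond in enumerate(CONDITIONS):
        if regions:
            scale = np.array(
                [
                    1.0 if cond == "CTRL" else 1.0 + r.effect_fraction[ci - 1]
                    for r in regions
                ]
            )
            region_w = widths * (1.0 + ctrl_enrichment) * scale
            bg_w = float(genome_len - widths.sum())
            weights = np.concatenate([[bg_w], region_w])
            choice = rng.choice(len(weights), size=depth, p=weights / weights.sum())
            pos = np.empty(depth, dtype=int)
            bg = choice == 0
            pos[bg] = place_background(int(bg.sum()))
            for k, r in enumerate(regions):
                sel = choice == k + 1
                n = int(sel.sum())
                if n:
                    pos[sel] = starts[k] + rng.integers(
                        0, int(widths[k]), size=n
                    )
        else:
            pos = rng.integers(0, max_start + 1, size=depth)
        pos = np.minimum(pos, max_start)
        reads = np.column_stack([pos, pos + fragment_len])
        out[cond] = reads[np.argsort(reads[:, 0], kind="stable")]
    return out


# --------------------------------------------------------------------------
# genome fixture
# --------------------------------------------------------------------------

@dataclass
class GenomeFixture:
    """A small synthetic genome with annotations and planted motifs."""

    sequences: dict[str, str]
    genes: pd.DataFrame   # seq_id, start, end, gene_id (0-based half-open)
    exons: pd.DataFrame   # seq_id, start, end, gene_id
    tes: pd.DataFrame     # seq_id, start, end, family
    dmr_intervals: pd.DataFrame  # seq_id, start, end (CpG-enriched)
    planted_motifs: list[tuple[str, int, str, int]] = field(default_factory=list)
    # (seq_id, position, topology DR|ER|IR, spacer)


def motif_sequence(topology: str, spacer: int, rng: np.random.Generator | None = None) -> str:
    """Build a consensus two-half-site motif for a DR/ER/IR topology.

    DR: both half-sites forward; IR: forward then reverse-complement
    (head-to-head); ER: reverse-complement then forward (tail-to-tail).
    """
    if topology not in ("DR", "ER", "IR"):
        raise ValueError(f"unknown topology {topology!r}")
    if not 0 <= spacer <= 8:
        raise ValueError("spacer must be between 0 and 8 bp")
    if rng is None:
        filler = "A" * spacer
    else:
        filler = "".join(rng.choice(list("ACGT"), size=spacer))
    first, second = {
        "DR": (HALF_SITE, HALF_SITE),
        "IR": (HALF_SITE, revcomp(HALF_SITE)),
        "ER": (revcomp(HALF_SITE), HALF_SITE),
    }[topology]
    return first + filler + second


def _markov_cpg_sequence(length: int, cg_fold: float, rng: np.random.Generator) -> str:
    """First-order Markov sequence with P(G | C) boosted ``cg_fold``-fold."""
    bases = np.array(list("ACGT"))
    p_cg = min(cg_fold * 0.25, 0.95)
    rest = (1.0 - p_cg) / 3.0
    from_c = np.array([rest, rest, p_cg, rest])
    uniform = np.full(4, 0.25)
    seq = np.empty(length, dtype=int)
    seq[0] = rng.integers(0, 4)
    # vectorized trick: draw uniforms once, pick transition row per step
    u = rng.random(length)
    cum_c = np.cumsum(from_c)
    cum_u = np.cumsum(uniform)
    for i in range(1, length):
        cum = cum_c if seq[i - 1] == 1 else cum_u
        seq[i] = np.searchsorted(cum, u[i])
    return "".join(bases[seq])


def simulate_genome(
    seq_len: int = 100_000,
    n_genes: int = 20,
    n_tes: int = 30,
    n_dmr_intervals: int = 20,
    dmr_cpg_enrichment: float = 3.0,
    planted_motifs: Sequence[tuple[str, int, str, int]] = (),
    seed: int = 0,
    seq_id: str = "chr1",
    gene_len: int = 1200,
    exons_per_gene: int = 3,
    te_len: int = 400,
    dmr_len: int = 800,
) -> GenomeFixture:
    """Generate a single-sequence genome fixture.

    Genes (with exons), TEs and CpG-enriched DMR intervals are placed without
    overlap on a uniform-random background; ``planted_motifs`` entries
    ``(seq_id, position, topology, spacer)`` are written verbatim into the
    sequence last, so the declared substrings are guaranteed.
    """
    for _, _, topo, spacer in planted_motifs:
        if topo not in ("DR", "ER", "IR"):
            raise ValueError(f"unknown motif topology {topo!r}")
        if not 0 <= spacer <= 8:
            raise ValueError("motif spacer must be between 0 and 8 bp")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=seq_len)

    # non-overlapping placement by slicing the sequence into a grid of slots
    slot = max(gene_len, te_len, dmr_len) + 200
    n_slots = seq_len // slot
    needed = n_genes + n_tes + n_dmr_intervals
    if needed > n_slots:
        raise ValueError(
            f"cannot place {needed} features in {n_slots} slots of {slot} bp; "
            "increase seq_len or reduce feature counts"
        )
    slots = rng.permutation(n_slots)[:needed]
    gene_slots = slots[:n_genes]
    te_slots = slots[n_genes : n_genes + n_tes]
    dmr_slots = slots[n_genes + n_tes :]

    genes, exons = [], []
    for gi, s in enumerate(sorted(gene_slots)):
        start = int(s * slot + 100)
        end = start + gene_len
        gid = f"gene{gi:03d}"
        genes.append((seq_id, start, end, gid))
        exon_len = gene_len // (2 * exons_per_gene)
        for xi in range(exons_per_gene):
            xs = start + xi * 2 * exon_len
            exons.append((seq_id, xs, xs + exon_len, gid))
    tes = []
    families = ("PTR_XL", "LINE_L1", "SINE_X", "DNA_hAT", "LTR_gypsy")
    for ti, s in enumerate(sorted(te_slots)):
        start = int(s * slot + 100)
        fam = families[ti % len(families)]
        tes.append((seq_id, start, start + te_len, fam))
    dmrs = []
    for s in sorted(dmr_slots):
        start = int(s * slot + 100)
        end = start + dmr_len
        enriched = _markov_cpg_sequence(dmr_len, dmr_cpg_enrichment, rng)
        seq[start:end] = list(enriched)
        dmrs.append((seq_id, start, end))

    planted = []
    for sid, pos, topo, spacer in planted_motifs:
        motif = motif_sequence(topo, spacer, rng)
        if pos < 0 or pos + len(motif) > seq_len:
            raise ValueError(f"motif at {pos} does not fit in sequence")
        seq[pos : pos + len(motif)] = list(motif)
        planted.append((sid, int(pos), topo, int(spacer)))

    return GenomeFixture(
        sequences={seq_id: "".join(seq)},
        genes=pd.DataFrame(genes, columns=["seq_id", "start", "end", "gene_id"]),
        exons=pd.DataFrame(exons, columns=["seq_id", "start", "end", "gene_id"]),
        tes=pd.DataFrame(tes, columns=["seq_id", "start", "end", "family"]),
        dmr_intervals=pd.DataFrame(dmrs, columns=["seq_id", "start", "end"]),
        planted_motifs=planted,
    )


# --------------------------------------------------------------------------
# pathway graphs
# --------------------------------------------------------------------------

def simulate_pathways(
    n_nodes: int = 500,
    n_pathways: int = 25,
    pathway_size: int = 120,
    attachment: int = 2,
    seed: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], list[str]]:
    """Scale-free interaction universe sliced into overlapping pathways.

    A preferential-attachment (Barabasi-Albert) graph over ``n_nodes`` gene
    products is partitioned into ``n_pathways`` random overlapping node
    subsets; each pathway's edge list is the induced subgraph.  Returns the
    named edge lists and the full node list (callers choose DE genes).
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(rng.integers(2**31)))
    names = {i: f"gp{i:04d}" for i in graph.nodes}
    nx.relabel_nodes(graph, names, copy=False)
    nodes = list(names.values())
    pathways: dict[str, list[tuple[str, str]]] = {}
    for k in range(n_pathways):
        members = rng.choice(nodes, size=min(pathway_size, n_nodes), replace=False)
        sub = graph.subgraph(members)
        pathways[f"pathway{k:02d}"] = [tuple(sorted(e)) for e in sub.edges]
    return pathways, nodes


# --------------------------------------------------------------------------
# published worked-example tables
# --------------------------------------------------------------------------

#: printed per-code DMR counts from the methylome clustering
_DMR_PRINTED_XTALK = {
    "d_n_n": 2633,
    "u_n_n": 41,
    "n_d_n": 185,
    "n_u_n": 235,
    "d_n_u": 2064,
    "n_n_u": 378,
    "n_n_d": 94,
}
_DMR_OPPOSITE_CODES = ("d_u_u", "d_d_u", "u_n_d", "u_u_d")  # printed total 1632

_DMR_CATEGORY_TOTALS = {"T3": 1263, "CORT": 1199, "ADDITIVE": 3667, "XTALK": 11576}

_GENE_CATEGORY_TOTALS = {"T3": 328, "CORT": 38, "ADDITIVE": 376, "XTALK": 103}
_GENE_COTREATMENT_ONLY = 38  # n_n_u + n_n_d, printed as 36.9% of 103

_GENE_OVERLAP_DMRS = 4913  # DMRs overlapping or within genes, of 17,705


def _split_category(total: int, codes: Sequence[str]) -> dict[str, int]:
    parts = largest_remainder(total, [1.0] * len(codes))
    return dict(zip(codes, parts))


def paper_counts_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic classified gene and DMR tables matching the published counts.

    The gene table has 845 rows; the DMR table 17,705.  Per-category totals
    and every printed per-code count are honored exactly; counts the source
    reports only in aggregate are apportioned deterministically (largest
    remainder over a fixed code order).  The DMR table carries a
    ``nearest_gene_distance`` column with 4,913 zero-distance (gene-
    overlapping) rows.
    """
    gene_code_counts: dict[str, int] = {}
    gene_code_counts.update(_split_category(_GENE_CATEGORY_TOTALS["ADDITIVE"], ["u_u_u", "d_d_d"]))
    gene_code_counts.update(_split_category(_GENE_CATEGORY_TOTALS["T3"], ["u_n_u", "d_n_d"]))
    gene_code_counts.update(_split_category(_GENE_CATEGORY_TOTALS["CORT"], ["n_u_u", "n_d_d"]))
    gene_code_counts.update(_split_category(_GENE_COTREATMENT_ONLY, ["n_n_u", "n_n_d"]))
    other_x = [c for c in XTALK_CODES if c not in ("n_n_u", "n_n_d")]
    gene_code_counts.update(
        _split_category(_GENE_CATEGORY_TOTALS["XTALK"] - _GENE_COTREATMENT_ONLY, other_x)
    )

    gene_rows = []
    i = 0
    for code in ALL_CODES:
        for _ in range(gene_code_counts.get(code, 0)):
            gene_rows.append((f"gene{i:04d}", code, categorize(code)))
            i += 1
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "code", "category"])
    assert len(gene_table) == 845

    dmr_code_counts: dict[str, int] = {}
    dmr_code_counts.update(_split_category(_DMR_CATEGORY_TOTALS["T3"], ["d_n_d", "u_n_u"]))
    dmr_code_counts.update(_split_category(_DMR_CATEGORY_TOTALS["CORT"], ["n_d_d", "n_u_u"]))
    dmr_code_counts.update(_split_category(_DMR_CATEGORY_TOTALS["ADDITIVE"], ["d_d_d", "u_u_u"]))
    dmr_code_counts.update(_DMR_PRINTED_XTALK)
    dmr_code_counts.update(_split_category(1632, _DMR_OPPOSITE_CODES))
    leftover_codes = [
        c
        for c in XTALK_CODES
        if c not in _DMR_PRINTED_XTALK and c not in _DMR_OPPOSITE_CODES
    ]
    leftover = _DMR_CATEGORY_TOTALS["XTALK"] - sum(_DMR_PRINTED_XTALK.values()) - 1632
    dmr_code_counts.update(_split_category(leftover, leftover_codes))

    dmr_rows = []
    i = 0
    for code in ALL_CODES:
        for _ in range(dmr_code_counts.get(code, 0)):
            dmr_rows.append((f"dmr{i:05d}", code, categorize(code)))
            i += 1
    dmr_table = pd.DataFrame(dmr_rows, columns=["dmr_id", "code", "category"])
    assert len(dmr_table) == 17705
    # gene-overlap flags: deterministic, spread across the table
    distance = np.full(len(dmr_table), 0, dtype=int)
    stride = len(dmr_table) / _GENE_OVERLAP_DMRS
    overlap_idx = np.floor(np.arange(_GENE_OVERLAP_DMRS) * stride).astype(int)
    mask = np.ones(len(dmr_table), dtype=bool)
    mask[overlap_idx] = False
    # non-overlapping DMRs sit 10-100 kb away, the typical reported range
    distance[mask] = 10_000 + 7 * np.flatnonzero(mask)
    dmr_table["nearest_gene_distance"] = distance
    return gene_table, dmr_table
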