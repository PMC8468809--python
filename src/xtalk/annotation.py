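"""Genomic context of DMRs: gene distances, TE overlap, dinucleotide content."""

from __future__ import annotations

import math
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DINUCLEOTIDES = tuple(a + b for a, b in product("ACGT", repeat=2))


def _check_interval(start: int, end: int) -> None:
    if end <= start or start < 0:
        raise ValueError(f"malformed half-open interval [{start}, {end})")


def nearest_gene_distance(
    dmr: tuple[int, int], genes: Sequence[tuple[int, int, str]]
) -> tuple[str | None, float]:
    """Nearest gene and its gap distance in bp (0 when intervals overlap).

    Distance is measured between interval boundaries under the half-open
    convention, ignoring strand.  Ties are broken by the smaller gene start.
    Returns ``(None, inf)`` when no genes are supplied.
    """
    start, end = dmr
    _check_interval(start, end)
    best: tuple[float, int, str] | None = None
    for gs, ge, gid in genes:
        _check_interval(gs, ge)
        if gs < end and ge > start:
            d = 0
        elif ge <= start:
            d = start - ge
        else:
            d = gs - end
        key = (d, gs, gid)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return None, math.inf
    return best[2], float(best[0])


def annotate_distances(
    dmrs: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Nearest-gene annotation for a DMR table (columns seq_id, start, end)."""
    gene_by_seq: dict[str, list[tuple[int, int, str]]] = {}
    for row in genes.itertuples(index=False):
        gene_by_seq.setdefault(row.seq_id, []).append(
            (int(row.start), int(row.end), str(row.gene_id))
        )
    ids, dists = [], []
    for row in dmrs.itertuples(index=False):
        gid, d = nearest_gene_distance(
            (int(row.start), int(row.end)), gene_by_seq.get(row.seq_id, [])
        )
        ids.append(gid)
        dists.append(d)
    out = dmrs.copy()
    out["nearest_gene_id"] = ids
    out["nearest_gene_distance"] = dists
    return out


def overlap_fraction(
    dmrs: Sequence[tuple[int, int]],
    features: Sequence[tuple[int, int, str]],
) -> tuple[float, dict[str, int]]:
    """Fraction of DMRs overlapping >= 1 bp with any feature, plus per-family counts.

    A DMR overlapping features of several families is counted once in the
    fraction but once per family in the breakdown, so family counts may sum
    to more than the overall overlap count.
    """
    if not dmrs:
        return 0.0, {}
    n_overlap = 0
    families: dict[str, int] = {}
    for start, end in dmrs:
        _check_interval(start, end)
        hit_families = set()
        for fs, fe, fam in features:
            if fs < end and fe > start:
                hit_families.add(fam)
        if hit_families:
            n_overlap += 1
            for fam in hit_families:
                families[fam] = families.get(fam, 0) + 1
    return n_overlap / len(dmrs), families


def dinucleotide_profile(sequences: Iterable[str]) -> pd.Series:
    """Overlapping dinucleotide frequencies over a set of sequences.

    Dinucleotides containing N (or any non-ACGT base) are skipped; the 16
    returned frequencies sum to 1.
    """
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    total = 0
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - 1):
            di = s[i : i + 2]
            if di in counts:
                counts[di] += 1
                total += 1
    if total == 0:
        raise ValueError("no countable dinucleotides (all-N or empty input)")
    return pd.Series({k: v / total for k, v in counts.items()})


def cpg_enrichment(dmr_profile: pd.Series, exon_profile: pd.Series) -> dict[str, float]:
    """CpG content comparison between DMR and exon sequence sets.

    Reports the raw CG frequencies, their ratio, and each set's CG frequency
    relative to the mean of its other 15 dinucleotide frequencies.
    """
    others = [d for d in DINUCLEOTIDES if d != "CG"]
    return {
        "cg_freq_dmr": float(dmr_profile["CG"]),
        "cg_freq_exon": float(exon_profile["CG"]),
        "cg_ratio": float(dmr_profile["CG"] / exon_profile["CG"]),
        "cg_vs_rest_dmr": float(dmr_profile["CG"] / dmr_profile[others].mean()),
        "cg_vs_rest_exon": float(exon_profile["CG"] / exon_profile[others].mean()),
    }


def extract_sequences(
    sequences: dict[str, str], intervals: pd.DataFrame
) -> list[str]:
    """Slice interval sequences (columns seq_id, start, end) out of a genome."""
    out = []
    for row in intervals.itertuples(index=False):
        seq = sequences[row.seq_id]
        if row.end > len(seq):
            raise ValueError(
                f"interval [{row.start}, {row.end}) outside {row.seq_id}"
            )
        out.append(seq[int(row.start) : int(row.end)])
    return out
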