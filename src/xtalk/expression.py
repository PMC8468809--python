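"""From count matrices to classified transcriptional responses.

Differential-expression testing proper is upstream of this package (any DE
caller's gene list can be supplied); for synthetic data a fold-change
surrogate (``max |log2FC| >= 1`` in some treatment) stands in.  The steps here
are: per-condition log-scale expression profiles, the ternary clustering of
:mod:`xtalk.clustering`, and the cross-context culture-effect filter.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import (
    CONDITIONS,
    TriadCall,
    classify_deltas,
    consistency_filter,
    standardize_profiles,
    treatment_deltas,
)


def condition_log_means(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-condition mean of log2(count + 1) across replicates.

    Sample columns must be named ``<condition>_<context>_<replicate>`` with
    condition one of CTRL/T3/CORT/T3CORT.
    """
    cond_of = {}
    for col in counts.columns:
        cond = col.split("_")[0]
        if cond not in CONDITIONS:
            raise ValueError(f"column {col!r} does not start with a known condition")
        cond_of.setdefault(cond, []).append(col)
    missing = [c for c in CONDITIONS if c not in cond_of]
    if missing:
        raise ValueError(f"conditions missing from count matrix: {missing}")
    log = np.log2(counts.astype(float) + 1.0)
    return pd.DataFrame(
        {cond: log[cols].mean(axis=1) for cond, cols in cond_of.items()},
        index=counts.index,
    )[list(CONDITIONS)]


def log2_fold_changes(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment log2 fold change vs CTRL from log-scale profiles."""
    return pd.DataFrame(
        {t: profiles[t] - profiles["CTRL"] for t in CONDITIONS[1:]},
        index=profiles.index,
    )


def surrogate_de_genes(profiles: pd.DataFrame, min_abs_log2fc: float = 1.0) -> pd.Index:
    """Fold-change surrogate DE rule: ``max |log2FC| >= threshold``."""
    fc = log2_fold_changes(profiles)
    return profiles.index[fc.abs().max(axis=1) >= min_abs_log2fc]


def classify_profiles(
    profiles: pd.DataFrame,
    grid: Sequence[float] | None = None,
) -> tuple[list[TriadCall], float]:
    """Standardize 4-condition profiles, select the threshold, call triads.

    Zero-variance (flat) profiles are excluded; returns the calls and the
    selected threshold.
    """
    z, ok = standardize_profiles(profiles.to_numpy())
    deltas = treatment_deltas(z[ok])
    ids = profiles.index[ok].astype(str)
    return classify_deltas(list(ids), deltas, grid)


def classify_counts(
    explant_counts: pd.DataFrame,
    whole_counts: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    grid: Sequence[float] | None = None,
    filter_mode: str = "identical",
) -> dict:
    """Full transcriptome classification across both experimental contexts.

    DE genes are selected in the explant data by the fold-change surrogate,
    classified independently in both contexts, and retained only when their
    triad codes agree and the whole-animal response reaches two-fold.

    Returns a dict with ``calls`` (retained :class:`TriadCall` list),
    ``threshold_explant``, ``threshold_whole``, ``n_de`` and ``n_retained``.
    """
    explant_prof = condition_log_means(explant_counts)
    whole_prof = condition_log_means(whole_counts)
    de = surrogate_de_genes(explant_prof, min_abs_log2fc)
    if len(de) == 0:
        return {
            "calls": [],
            "threshold_explant": None,
            "threshold_whole": None,
            "n_de": 0,
            "n_retained": 0,
        }
    common = de.intersection(whole_prof.index)
    explant_calls, t_explant = classify_profiles(explant_prof.loc[common], grid)
    whole_calls, t_whole = classify_profiles(whole_prof.loc[common], grid)
    whole_fc = log2_fold_changes(whole_prof.loc[common])
    retained = consistency_filter(
        explant_calls,
        whole_calls,
        {str(g): whole_fc.loc[g].to_numpy() for g in common},
        min_abs_log2fc=min_abs_log2fc,
        mode=filter_mode,
    )
    return {
        "calls": retained,
        "threshold_explant": t_explant,
        "threshold_whole": t_whole,
        "n_de": int(len(common)),
        "n_retained": len(retained),
    }
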