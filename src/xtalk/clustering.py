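"""Ternary response clustering of expression changes across hormone treatments.

Each gene is observed under four conditions (CTRL, T3, CORT, T3+CORT).  Its
profile is standardized to mean 0 / variance 1, and each treatment is compared
to CTRL to call the gene up- (``u``), down- (``d``) or not- (``n``) regulated,
yielding a three-letter *triad code* in T3, CORT, T3+CORT order (e.g.
``u_n_u``).  The u/d threshold is selected globally as the most stringent value
at which every gene is differentially regulated at least once (empty ``n_n_n``
cluster).  Codes map onto four biological categories:

* ``T3``       — response driven by T3 alone (``u_n_u``, ``d_n_d``)
* ``CORT``     — response driven by CORT alone (``n_u_u``, ``n_d_d``)
* ``ADDITIVE`` — both hormones act in the same direction (``u_u_u``, ``d_d_d``)
* ``XTALK``    — every other pattern, evidence of pathway interaction

The same machinery classifies differentially methylated regions, whose
per-treatment methylation deltas are treated exactly like expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("CTRL", "T3", "CORT", "T3CORT")
TREATMENTS = ("T3", "CORT", "T3CORT")

#: all 27 triad codes in a fixed, deterministic order
ALL_CODES = tuple("_".join(p) for p in product("udn", repeat=3))

CATEGORY_MAP = {
    "u_n_u": "T3",
    "d_n_d": "T3",
    "n_u_u": "CORT",
    "n_d_d": "CORT",
    "u_u_u": "ADDITIVE",
    "d_d_d": "ADDITIVE",
}

CATEGORIES = ("T3", "CORT", "ADDITIVE", "XTALK")

#: the 20 cross-talk codes (everything except n_n_n and the six above)
XTALK_CODES = tuple(
    c for c in ALL_CODES if c != "n_n_n" and c not in CATEGORY_MAP
)

DEFAULT_GRID = np.round(np.arange(0.01, 3.001, 0.01), 2)


class ZeroVarianceError(ValueError):
    """Raised when a profile with zero variance cannot be standardized."""


@dataclass(frozen=True)
class TriadCall:
    """A classified gene or DMR: triad code plus response category."""

    gene_id: str
    code: str
    category: str

    def __post_init__(self) -> None:
        if self.code == "n_n_n":
            raise ValueError("retained calls must not carry the n_n_n code")
        if self.category != categorize(self.code):
            raise ValueError(
                f"category {self.category!r} inconsistent with code {self.code!r}"
            )


def standardize_gene(values: Sequence[float]) -> np.ndarray:
    """Standardize a 4-condition profile to mean 0, population variance 1.

    Raises :class:`ZeroVarianceError` for flat profiles, which carry no
    directional information and are excluded upstream.
    """
    x = np.asarray(values, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"expected exactly 4 condition values, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")
    sd = x.std()  # population (ddof=0) convention
    if sd == 0:
        raise ZeroVarianceError("profile has zero variance; cannot standardize")
    return (x - x.mean()) / sd


def standardize_profiles(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized standardization of a genes x 4 matrix.

    Returns ``(z, ok)`` where rows with zero variance are left as NaN and
    flagged ``False`` in ``ok``.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    z = np.full_like(x, np.nan)
    z[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    return z, ok


def treatment_deltas(z: np.ndarray) -> np.ndarray:
    """Per-treatment standardized difference to CTRL (columns T3, CORT, T3CORT)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return z[:, 1:] - z[:, :1]


def call_triad(deltas: Sequence[float], t: float) -> str:
    """Call one u/d/n triad from three standardized treatment deltas.

    A treatment is ``u`` when its delta is >= ``t``, ``d`` when <= ``-t``,
    ``n`` otherwise.  The boundary is inclusive.
    """
    if t <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(deltas, dtype=float)
    if d.shape != (3,):
        raise ValueError("expected 3 treatment deltas")
    letters = np.where(d >= t, "u", np.where(d <= -t, "d", "n"))
    return "_".join(letters)


def call_triads(deltas: np.ndarray, t: float) -> list[str]:
    """Vectorized :func:`call_triad` over a genes x 3 delta matrix."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    d = np.atleast_2d(np.asarray(deltas, dtype=float))
    letters = np.where(d >= t, "u", np.where(d <= -t, "d", "n"))
    return ["_".join(row) for row in letters]


def select_threshold(deltas: np.ndarray, grid: Sequence[float] | None = None) -> float:
    """Select the u/d call threshold from the candidate grid.

    The chosen ``t*`` is the most stringent (largest) grid value at which the
    ``n_n_n`` cluster is empty, i.e. every gene is differentially regulated at
    least once.  Under the inclusive call rule a gene is non-``n_n_n`` at
    threshold ``t`` iff ``max_i |delta_i| >= t``, so the empty-``n_n_n`` region
    is exactly ``t <= min_genes max_i |delta_i|`` and ``t*`` is its boundary on
    the grid.
    """
    d = np.atleast_2d(np.asarray(deltas, dtype=float))
    if d.shape[1] != 3:
        raise ValueError("delta matrix must have 3 columns (T3, CORT, T3CORT)")
    g = DEFAULT_GRID if grid is None else np.asarray(sorted(grid), dtype=float)
    if np.any(g <= 0):
        raise ValueError("grid thresholds must be positive")
    max_abs = np.abs(d).max(axis=1)
    ceiling = max_abs.min()
    admissible = g[g <= ceiling]
    if admissible.size == 0:
        worst = int(np.argmin(max_abs))
        raise ValueError(
            "no grid threshold empties the n_n_n cluster; "
            f"gene index {worst} has max |delta| = {ceiling:.4g} "
            f"below the smallest grid value {g[0]:.4g}"
        )
    return float(admissible[-1])


def categorize(code: str) -> str:
    """Map a triad code onto its response category (T3/CORT/ADDITIVE/XTALK)."""
    if code == "n_n_n":
        raise ValueError("n_n_n profiles are not differentially regulated")
    if code not in ALL_CODES:
        raise ValueError(f"unknown triad code: {code!r}")
    return CATEGORY_MAP.get(code, "XTALK")


def classify_deltas(
    gene_ids: Sequence[str],
    deltas: np.ndarray,
    grid: Sequence[float] | None = None,
) -> tuple[list[TriadCall], float]:
    """Select a threshold for a delta matrix and call/categorize every row."""
    t = select_threshold(deltas, grid)
    codes = call_triads(deltas, t)
    calls = [
        TriadCall(gene_id=g, code=c, category=categorize(c))
        for g, c in zip(gene_ids, codes)
    ]
    return calls, t


def consistency_filter(
    explant_calls: Iterable[TriadCall],
    whole_calls: Iterable[TriadCall],
    whole_log2fc: Mapping[str, Sequence[float]],
    min_abs_log2fc: float = 1.0,
    mode: str = "identical",
) -> list[TriadCall]:
    """Remove culture artifacts by requiring cross-context agreement.

    A gene is retained iff its triad code agrees between tail-explant and
    whole-animal data sets, and the whole-animal response reaches at least a
    two-fold change (``max |log2FC| >= 1`` by default) in some treatment.

    ``mode='identical'`` requires byte-equal codes; ``mode='compatible'``
    relaxes to profiles without a direct u-vs-d contradiction in any treatment.
    Genes present in only one context are dropped.
    """
    if mode not in ("identical", "compatible"):
        raise ValueError(f"unknown filter mode: {mode!r}")
    whole_by_id = {c.gene_id: c for c in whole_calls}
    retained = []
    for call in explant_calls:
        other = whole_by_id.get(call.gene_id)
        if other is None:
            continue
        if mode == "identical":
            agree = call.code == other.code
        else:
            agree = not any(
                {a, b} == {"u", "d"}
                for a, b in zip(call.code.split("_"), other.code.split("_"))
            )
        if not agree:
            continue
        fc = whole_log2fc.get(call.gene_id)
        if fc is None:
            continue
        if np.max(np.abs(np.asarray(fc, dtype=float))) >= min_abs_log2fc:
            retained.append(call)
    return retained


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the reporting convention), not banker's."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_categories(calls: Sequence[TriadCall]) -> pd.DataFrame:
    """Per-category and per-code counts with half-up one-decimal percentages.

    Returns a tidy frame with columns ``level`` (category|code), ``name``,
    ``count`` and ``percent`` (of total calls).
    """
    if len(calls) == 0:
        raise ValueError("cannot summarize an empty call set")
    total = len(calls)
    cat_counts = {c: 0 for c in CATEGORIES}
    code_counts: dict[str, int] = {}
    for call in calls:
        cat_counts[call.category] += 1
        code_counts[call.code] = code_counts.get(call.code, 0) + 1
    rows = [
        {
            "level": "category",
            "name": cat,
            "count": n,
            "percent": round_half_up(100.0 * n / total),
        }
        for cat, n in cat_counts.items()
    ]
    rows += [
        {
            "level": "code",
            "name": code,
            "count": n,
            "percent": round_half_up(100.0 * n / total),
        }
        for code, n in sorted(code_counts.items())
    ]
    return pd.DataFrame(rows)


def ddct_log2fc(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Log2 fold change from qPCR cycle thresholds (-ddCt method).

    The target Ct is normalized on the endogenous reference gene (dCt) in both
    the treated and the control sample; the negated difference of the two dCt
    values is the log2 expression fold change versus the untreated control
    (one PCR cycle = one doubling).
    """
    dct_treated = ct_target_treated - ct_ref_treated
    dct_control = ct_target_control - ct_ref_control
    return -(dct_treated - dct_control)
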