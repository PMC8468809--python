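"""Differentially methylated region (DMR) detection from capture-seq reads.

The caller follows a conservative, permutation-calibrated design:

1. per-condition read pileups normalized to reads per million (RPM);
2. per-treatment differential profiles (treatment - CTRL) smoothed with a
   10 bp sliding mean;
3. candidate peaks = maximal same-sign runs of the smoothed differential;
4. null thresholds = the largest peak width and height seen when comparing
   two pseudo-samples drawn *without biological contrast* from the combined
   read pool, over (by default) 100 iterations;
5. peaks exceeding BOTH the null width and null height are called DMRs,
   merged across treatments into a non-redundant set, and classified into
   u/d/n triad codes with the same clustering procedure used for expression.

Because the thresholds are maxima over a null that matches the data
generating process, a contrast-free data set yields (almost always) zero
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clustering import call_triads, categorize, select_threshold, standardize_profiles, treatment_deltas

CONDITIONS = ("CTRL", "T3", "CORT", "T3CORT")
TREATMENTS = ("T3", "CORT", "T3CORT")


@dataclass(frozen=True)
class Peak:
    """A maximal same-sign run of the smoothed differential profile."""

    start: int
    end: int  # half-open
    height: float  # max |smoothed signal| within the run, RPM
    sign: int  # +1 methylation gain, -1 loss

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NullThresholds:
    """Permutation-null maxima used as DMR retention thresholds."""

    w_max: int
    h_max: float
    iterations: int
    seed: int


@dataclass
class DMR:
    """A called differentially methylated region."""

    start: int
    end: int
    height: float
    sign: int
    treatments: tuple[str, ...]  # contrasts in which it exceeded the null
    deltas: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mean smoothed diff, RPM
    code: str | None = None
    category: str | None = None

    @property
    def width(self) -> int:
        return self.end - self.start


def coverage_track(
    reads: np.ndarray,
    seq_len: int,
    extend: int = 0,
    library_size: int | None = None,
) -> np.ndarray:
    """Depth-normalized per-base read density (RPM).

    ``reads`` is an (n, 2) array of half-open intervals; each read may be
    extended 3' by ``extend`` bp (clipped at the sequence end).  The library
    size defaults to the number of reads supplied.
    """
    reads = np.asarray(reads, dtype=int).reshape(-1, 2)
    if library_size is None:
        library_size = len(reads)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if len(reads) and (reads[:, 0].min() < 0 or reads[:, 1].max() > seq_len):
        bad = reads[(reads[:, 0] < 0) | (reads[:, 1] > seq_len)][0]
        raise ValueError(
            f"read interval [{bad[0]}, {bad[1]}) outside sequence of length {seq_len}"
        )
    delta = np.zeros(seq_len + 1)
    if len(reads):
        ends = np.minimum(reads[:, 1] + extend, seq_len)
        np.add.at(delta, reads[:, 0], 1.0)
        np.add.at(delta, ends, -1.0)
    return np.cumsum(delta[:-1]) * 1e6 / library_size


def sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with windows truncated at the sequence edges.

    For window ``w`` the value at position ``i`` averages positions
    ``[i - (w-1)//2, i + w//2]`` intersected with the sequence.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    n = v.size
    left = (window - 1) // 2
    right = window // 2
    cs = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.clip(np.arange(n) - left, 0, n)
    hi = np.clip(np.arange(n) + right + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def smoothed_differential(
    treat: np.ndarray, ctrl: np.ndarray, window: int = 10
) -> np.ndarray:
    """Smoothed per-base differential (treatment - CTRL) of two RPM tracks."""
    treat = np.asarray(treat, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if treat.shape != ctrl.shape:
        raise ValueError(
            f"track length mismatch: {treat.shape} vs {ctrl.shape}"
        )
    return sliding_mean(treat - ctrl, window)


def find_candidate_peaks(profile: np.ndarray, epsilon: float = 0.0) -> list[Peak]:
    """Maximal runs of consecutive positions above +epsilon or below -epsilon.

    Runs of opposite sign are never merged; height is the max absolute
    smoothed signal within the run.
    """
    v = np.asarray(profile, dtype=float)
    state = np.where(v > epsilon, 1, np.where(v < -epsilon, -1, 0))
    if not state.any():
        return []
    boundaries = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [v.size]])
    peaks = []
    for s, e in zip(starts, ends):
        sign = int(state[s])
        if sign == 0:
            continue
        seg = v[s:e]
        peaks.append(Peak(int(s), int(e), float(np.abs(seg).max()), sign))
    return peaks


def permutation_thresholds(
    pool: np.ndarray,
    n1: int,
    n2: int,
    seq_len: int,
    extend: int = 0,
    window: int = 10,
    iterations: int = 100,
    seed: int = 0,
    epsilon: float = 0.0,
) -> NullThresholds:
    """Null width/height thresholds from contrast-free pseudo-sample pairs.

    Each iteration draws two disjoint pseudo-samples of sizes ``n1`` and
    ``n2`` without replacement from the combined read pool, builds their
    smoothed differential profile and records the maximum candidate-peak
    width and height (taken independently; they may come from different
    peaks).  The returned thresholds are the maxima over all iterations.
    """
    pool = np.asarray(pool, dtype=int).reshape(-1, 2)
    if n1 + n2 > len(pool):
        raise ValueError(
            f"pool of {len(pool)} reads cannot supply disjoint samples of "
            f"{n1} + {n2} reads"
        )
    rng = np.random.default_rng(seed)
    w_max, h_max = 0, 0.0
    for _ in range(iterations):
        idx = rng.choice(len(pool), size=n1 + n2, replace=False)
        t1 = coverage_track(pool[idx[:n1]], seq_len, extend)
        t2 = coverage_track(pool[idx[n1:]], seq_len, extend)
        diff = smoothed_differential(t1, t2, window)
        for p in find_candidate_peaks(diff, epsilon):
            if p.width > w_max:
                w_max = p.width
            if p.height > h_max:
                h_max = p.height
    return NullThresholds(w_max=w_max, h_max=float(h_max), iterations=iterations, seed=seed)


def call_dmrs(
    peaks: Sequence[Peak], thresholds: NullThresholds, rule: str = "and"
) -> list[Peak]:
    """Retain peaks exceeding the null thresholds.

    ``rule='and'`` (default, conservative) requires width > w_max AND
    height > h_max, both strict; ``rule='or'`` retains peaks exceeding
    either.
    """
    if rule not in ("and", "or"):
        raise ValueError(f"unknown retention rule {rule!r}")
    if rule == "and":
        return [
            p for p in peaks if p.width > thresholds.w_max and p.height > thresholds.h_max
        ]
    return [p for p in peaks if p.width > thresholds.w_max or p.height > thresholds.h_max]


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals overlapping by >= 1 bp."""
    if not intervals:
        return []
    srt = sorted(intervals)
    merged = [list(srt[0])]
    for s, e in srt[1:]:
        if s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def classify_dmrs(
    dmrs: Sequence[DMR],
    profiles: Mapping[str, np.ndarray],
    grid: Sequence[float] | None = None,
) -> list[DMR]:
    """Attach per-treatment deltas, triad codes and categories to DMRs.

    Each DMR's three deltas are the mean smoothed differential over its
    interval.  The 4-value profile (CTRL implicitly 0, then the three deltas)
    is standardized and thresholded exactly like an expression profile, with
    the threshold selected over the whole DMR set.
    """
    if not dmrs:
        return []
    raw = np.array(
        [
            [float(np.mean(profiles[t][d.start : d.end])) for t in TREATMENTS]
            for d in dmrs
        ]
    )
    values = np.column_stack([np.zeros(len(dmrs)), raw])
    z, ok = standardize_profiles(values)
    if not ok.all():
        flat = [i for i, good in enumerate(ok) if not good]
        raise ValueError(f"DMRs with flat differential profiles cannot be classified: {flat}")
    deltas = treatment_deltas(z)
    t = select_threshold(deltas, grid)
    codes = call_triads(deltas, t)
    out = []
    for d, row, code in zip(dmrs, raw, codes):
        out.append(
            DMR(
                start=d.start,
                end=d.end,
                height=d.height,
                sign=d.sign,
                treatments=d.treatments,
                deltas=tuple(float(x) for x in row),
                code=code,
                category=categorize(code),
            )
        )
    return out


@dataclass
class DMRResult:
    """Full caller output: non-redundant classified DMRs plus provenance."""

    dmrs: list[DMR]
    thresholds: dict[str, NullThresholds]
    per_treatment_counts: dict[str, int]
    profiles: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def detect_dmrs(
    reads: Mapping[str, np.ndarray],
    seq_len: int,
    window: int = 10,
    extend: int = 0,
    iterations: int = 100,
    seed: int = 0,
    epsilon: float = 0.0,
    rule: str = "and",
    grid: Sequence[float] | None = None,
) -> DMRResult:
    """Run the complete DMR caller on one sequence.

    ``reads`` maps each condition (CTRL, T3, CORT, T3CORT) to an (n, 2) read
    interval array.  Null thresholds are computed per contrast from the pool
    of all reads, with pseudo-sample sizes equal to the two compared
    libraries; DMRs from the three contrasts are merged (union of intervals
    overlapping >= 1 bp) into a non-redundant set and classified.
    """
    missing = [c for c in CONDITIONS if c not in reads]
    if missing:
        raise ValueError(f"read sets missing for conditions: {missing}")
    tracks = {c: coverage_track(reads[c], seq_len, extend) for c in CONDITIONS}
    profiles = {
        t: smoothed_differential(tracks[t], tracks["CTRL"], window) for t in TREATMENTS
    }
    pool = np.concatenate([np.asarray(reads[c], dtype=int).reshape(-1, 2) for c in CONDITIONS])
    n_ctrl = len(reads["CTRL"])

    thresholds: dict[str, NullThresholds] = {}
    cache: dict[tuple[int, int], NullThresholds] = {}
    retained: list[DMR] = []
    per_treatment_counts: dict[str, int] = {}
    for t in TREATMENTS:
        sizes = (len(reads[t]), n_ctrl)
        if sizes not in cache:
            cache[sizes] = permutation_thresholds(
                pool,
                sizes[0],
                sizes[1],
                seq_len,
                extend=extend,
                window=window,
                iterations=iterations,
                seed=seed,
                epsilon=epsilon,
            )
        thresholds[t] = cache[sizes]
        peaks = find_candidate_peaks(profiles[t], epsilon)
        called = call_dmrs(peaks, thresholds[t], rule)
        per_treatment_counts[t] = len(called)
        retained.extend(
            DMR(start=p.start, end=p.end, height=p.height, sign=p.sign, treatments=(t,))
            for p in called
        )

    merged_spans = merge_intervals([(d.start, d.end) for d in retained])
    merged: list[DMR] = []
    for s, e in merged_spans:
        members = [d for d in retained if d.start < e and d.end > s]
        height = max(d.height for d in members)
        # sign of the strongest contributing peak
        sign = max(members, key=lambda d: d.height).sign
        treatments = tuple(sorted({t for d in members for t in d.treatments}))
        merged.append(DMR(start=s, end=e, height=height, sign=sign, treatments=treatments))

    classified = classify_dmrs(merged, profiles, grid) if merged else []
    return DMRResult(
        dmrs=classified,
        thresholds=thresholds,
        per_treatment_counts=per_treatment_counts,
        profiles=profiles,
    )
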