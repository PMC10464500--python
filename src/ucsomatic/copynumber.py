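"""Ploidy-relative copy-number calling, chromothripsis-like scoring,
penetrance profiles, and permutation recurrence testing.

Segment-based copy-number callers report absolute total copy number (CN) and
mean B-allele frequency (BAF) per segment.  Tumor ploidy is taken as the
length-weighted modal CN over allelically balanced segments (BAF > 0.3);
gains and losses are then called relative to that ploidy, which avoids
mislabelling whole-genome-duplicated tumors.

Chromothripsis-like regions are scored by counting CN state switches:
10+/8-9/6-7 switches within 50 Mb give high/intermediate/low confidence,
with thresholds scaled proportionally (and rounded to the nearest whole
number) for chromosomes shorter than 50 Mb, and classified canonical when
the oscillation involves only 2-3 distinct CN states.

Cohort recurrence of gains/losses is summarized as penetrance (per-window
fraction of altered samples, events >= 5 Mb, 1-Mb windows) and tested by a
permutation null that relocates each sample's altered intervals uniformly
along the chromosome, size-preserved, using the chromosome-wide maximum
count as the reference statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CnSegment",
    "PloidyEstimate",
    "ChromothripsisCall",
    "infer_ploidy",
    "call_relative_cna",
    "count_cn_switches",
    "scaled_thresholds",
    "detect_chromothripsis",
    "penetrance_profile",
    "recurrence_test",
]

#: unscaled minimum switch counts for high/intermediate/low confidence in 50 Mb
BASE_THRESHOLDS = (10, 8, 6)
WINDOW_BP = 50_000_000
BAF_BALANCED_MIN = 0.3


@dataclass(frozen=True)
class CnSegment:
    """A genomic segment with integer total CN and mean B-allele frequency.

    Coordinates are 1-based inclusive.  BAF is folded to the minor-allele
    convention [0, 0.5].
    """

    chrom: str
    start: int
    end: int
    total_cn: int
    baf: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: start > end")
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")
        if not (0.0 <= self.baf <= 1.0):
            raise ValueError(f"BAF {self.baf} outside [0, 1]")
        if self.baf > 0.5:
            object.__setattr__(self, "baf", 1.0 - self.baf)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PloidyEstimate:
    sample_id: str
    ploidy: int
    supporting_fraction: float


@dataclass(frozen=True)
class ChromothripsisCall:
    sample_id: str
    chrom: str
    tier: str  # high | intermediate | low | none
    cn_class: str  # canonical | non-canonical | n/a
    switch_count: int
    window: tuple[int, int] | None


def _check_sorted(segments: Sequence[CnSegment]) -> None:
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(
                f"segments overlap or are unsorted: "
                f"{a.chrom}:{a.start}-{a.end} then {b.chrom}:{b.start}-{b.end}"
            )


def infer_ploidy(segments: Sequence[CnSegment], sample_id: str | None = None) -> PloidyEstimate:
    """Length-weighted modal CN over balanced segments (BAF > 0.3).

    Ties between CN states with equal supporting length break toward the
    lower CN.  Raises ``ValueError`` when no segment qualifies.
    """
    segments = list(segments)
    balanced = [s for s in segments if s.baf > BAF_BALANCED_MIN]
    if not balanced:
        raise ValueError("no segment with BAF > 0.3; cannot infer ploidy")
    weight: dict[int, int] = {}
    for s in balanced:
        weight[s.total_cn] = weight.get(s.total_cn, 0) + s.length
    total = sum(weight.values())
    ploidy = min(weight, key=lambda cn: (-weight[cn], cn))
    sid = sample_id if sample_id is not None else (segments[0].sample_id if segments else "")
    return PloidyEstimate(sample_id=sid, ploidy=ploidy, supporting_fraction=weight[ploidy] / total)


def call_relative_cna(
    segments: Iterable[CnSegment], ploidy: int
) -> list[tuple[CnSegment, str]]:
    """Call each segment gain/loss/neutral relative to tumor ploidy."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    out = []
    for s in segments:
        if s.total_cn > ploidy:
            call = "gain"
        elif s.total_cn < ploidy:
            call = "loss"
        else:
            call = "neutral"
        out.append((s, call))
    return out


def _merge_equal_cn(segments: Sequence[CnSegment]) -> list[CnSegment]:
    """Merge consecutive segments with equal CN (segment splits are neutral)."""
    merged: list[CnSegment] = []
    for s in segments:
        if merged and merged[-1].chrom == s.chrom and merged[-1].total_cn == s.total_cn:
            prev = merged.pop()
            merged.append(
                CnSegment(
                    chrom=prev.chrom,
                    start=prev.start,
                    end=s.end,
                    total_cn=prev.total_cn,
                    baf=prev.baf,
                    sample_id=prev.sample_id,
                )
            )
        else:
            merged.append(s)
    return merged


def count_cn_switches(segments: Sequence[CnSegment]) -> int:
    """Number of CN state switches between adjacent segments (merge-first)."""
    segments = sorted(segments, key=lambda s: (s.chrom, s.start))
    _check_sorted(segments)
    merged = _merge_equal_cn(segments)
    return sum(
        1
        for a, b in zip(merged, merged[1:])
        if a.chrom == b.chrom and a.total_cn != b.total_cn
    )


def scaled_thresholds(chrom_length: int) -> tuple[int, int, int]:
    """Confidence thresholds (high, intermediate, low), scaled below 50 Mb.

    Chromosomes shorter than 50 Mb scale the 10/8/6 switch thresholds by
    length/50 Mb, rounded half-up to the nearest whole number (e.g. a 30-Mb
    chromosome gives 6/5/4).
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if chrom_length >= WINDOW_BP:
        return BASE_THRESHOLDS
    factor = chrom_length / WINDOW_BP
    return tuple(int(math.floor(t * factor + 0.5)) for t in BASE_THRESHOLDS)


def _tier(switches: int, thresholds: tuple[int, int, int]) -> str:
    high, inter, low = thresholds
    if switches >= high:
        return "high"
    if switches >= inter:
        return "intermediate"
    if switches >= low:
        return "low"
    return "none"


def detect_chromothripsis(
    segments: Sequence[CnSegment],
    chrom_length: int,
    sample_id: str | None = None,
    step_bp: int = 1_000_000,
) -> ChromothripsisCall:
    """Score one chromosome of one sample for a chromothripsis-like pattern.

    For chromosomes >= 50 Mb, switch counts are maximized over 50-Mb sliding
    windows (1-Mb step) and tiered against 10/8/6; shorter chromosomes are
    evaluated whole against proportionally scaled thresholds.  The CN-state
    class (canonical = 2-3 distinct states) is evaluated over the qualifying
    window.
    """
    segments = sorted(segments, key=lambda s: s.start)
    if any(s.chrom != segments[0].chrom for s in segments[1:]):
        raise ValueError("detect_chromothripsis expects segments from a single chromosome")
    _check_sorted(segments)
    merged = _merge_equal_cn(segments)
    chrom = merged[0].chrom if merged else ""
    sid = sample_id if sample_id is not None else (merged[0].sample_id if merged else "")
    thresholds = scaled_thresholds(chrom_length)

    # switch coordinates: boundary position at the start of the right segment
    switch_pos = [
        b.start
        for a, b in zip(merged, merged[1:])
        if a.total_cn != b.total_cn
    ]

    if chrom_length < WINDOW_BP:
        window = (1, chrom_length)
        n_switches = len(switch_pos)
    else:
        best_start, n_switches = 1, 0
        if switch_pos:
            last_start = max(1, chrom_length - WINDOW_BP + 1)
            starts = range(1, last_start + 1, step_bp)
            pos = np.asarray(switch_pos)
            for s in starts:
                c = int(((pos >= s) & (pos < s + WINDOW_BP)).sum())
                if c > n_switches:
                    best_start, n_switches = s, c
        window = (best_start, min(best_start + WINDOW_BP - 1, chrom_length))

    tier = _tier(n_switches, thresholds)
    if tier == "none":
        cn_class = "n/a"
    else:
        states = {
            s.total_cn
            for s in merged
            if s.start <= window[1] and s.end >= window[0]
        }
        cn_class = "canonical" if 2 <= len(states) <= 3 else "non-canonical"
    return ChromothripsisCall(
        sample_id=sid,
        chrom=chrom,
        tier=tier,
        cn_class=cn_class,
        switch_count=n_switches,
        window=window,
    )


def penetrance_profile(
    cohort_calls: Mapping[str, Sequence[tuple[CnSegment, str]]],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 1_000_000,
    min_event_bp: int = 5_000_000,
) -> pd.DataFrame:
    """Cohort penetrance of gains/losses >= ``min_event_bp`` in fixed windows.

    ``cohort_calls`` maps sample id to ``(segment, call)`` pairs as produced
    by :func:`call_relative_cna`.  Returns a DataFrame with one row per
    (chrom, window) and the fraction of samples carrying a qualifying gain
    (resp. loss) overlapping the window.
    """
    if not cohort_calls:
        raise ValueError("empty cohort")
    n_samples = len(cohort_calls)
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_windows = int(math.ceil(length / window_bp))
        gain = np.zeros(n_windows)
        loss = np.zeros(n_windows)
        for calls in cohort_calls.values():
            sample_gain = np.zeros(n_windows, dtype=bool)
            sample_loss = np.zeros(n_windows, dtype=bool)
            for seg, call in calls:
                if seg.chrom != chrom or call == "neutral" or seg.length < min_event_bp:
                    continue
                w0 = (seg.start - 1) // window_bp
                w1 = min((seg.end - 1) // window_bp, n_windows - 1)
                target = sample_gain if call == "gain" else sample_loss
                target[w0 : w1 + 1] = True
            gain += sample_gain
            loss += sample_loss
        for w in range(n_windows):
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * window_bp + 1,
                    "end": min((w + 1) * window_bp, length),
                    "gain_freq": gain[w] / n_samples,
                    "loss_freq": loss[w] / n_samples,
                }
            )
    return pd.DataFrame(rows)


def recurrence_test(
    alteration_matrix: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.Series:
    """Permutation test of per-window alteration recurrence on one chromosome.

    ``alteration_matrix`` is samples x windows (boolean); the statistic per
    window is the altered-sample count.  The null relocates each sample's
    altered runs (maximal blocks of consecutive altered windows) uniformly
    and independently along the chromosome, preserving run sizes.  The
    chromosome-wide maximum count per permutation controls multiplicity:
    p(w) = (1 + #{perm max >= observed count at w}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(alteration_matrix, pd.DataFrame):
        windows = list(alteration_matrix.columns)
        M = alteration_matrix.to_numpy(dtype=bool)
    else:
        M = np.asarray(alteration_matrix, dtype=bool)
        windows = list(range(M.shape[1]))
    n_samples, n_windows = M.shape
    if n_windows == 0 or n_samples == 0:
        raise ValueError("empty alteration matrix")
    observed = M.sum(axis=0)

    # run-length encode each sample's altered blocks
    sample_runs: list[list[int]] = []
    for i in range(n_samples):
        runs, length = [], 0
        for j in range(n_windows):
            if M[i, j]:
                length += 1
            elif length:
                runs.append(length)
                length = 0
        if length:
            runs.append(length)
        sample_runs.append(runs)

    rng = np.random.default_rng(seed)
    perm_max = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        counts = np.zeros(n_windows, dtype=int)
        for runs in sample_runs:
            covered = np.zeros(n_windows, dtype=bool)
            for run in runs:
                start = int(rng.integers(0, n_windows - run + 1))
                covered[start : start + run] = True
            counts += covered
        perm_max[p] = counts.max() if n_windows else 0

    pvals = [
        (1 + int((perm_max >= obs).sum())) / (n_perm + 1) if obs > 0 else 1.0
        for obs in observed
    ]
    return pd.Series(pvals, index=windows, name="p_value")
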