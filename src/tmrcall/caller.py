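"""Signed significance scores, smoothing, and TMR segmentation.

The pipeline per transcript: BH-adjusted correlation q-values are turned
into signed scores (``log10(q)`` for negative correlations, ``-log10(q)``
for positive ones, so magnitude always equals ``-log10(q)``); scores are
smoothed with a symmetric exponentially-weighted moving average over a
window of ``2 * n_flank + 1`` CpGs (weight ``smoothing_factor ** |k|`` at
CpG offset ``k``, renormalized over window members that exist and are
non-missing); maximal runs of CpGs whose smoothed score exceeds a
threshold (``<= log10(0.05)`` for negative, ``>= -log10(0.05)`` for
positive) are grouped into TMRs; and the refinement filters (minimum 5
CpGs, full containment in maximal-mappability regions) are applied.

"Exceeds" is inclusive: a CpG whose smoothed score sits exactly on a
threshold is part of a run.  Missing smoothed values break runs -- there
is no evidence to bridge across.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, build_search_region
from .correlation import CorrelationTrack, build_correlation_track
from .expression import ExpressionMatrix
from .intervals import GenomicInterval, covered_fraction, merge_intervals
from .methylome import MethylomeMatrix, mask_low_coverage

__all__ = [
    "SmoothingParams",
    "Thresholds",
    "CallerConfig",
    "TMR",
    "signed_score",
    "signed_scores",
    "smooth_scores",
    "call_tmrs",
    "filter_min_cpgs",
    "filter_mappability",
    "discover_tmrs",
    "tmrs_to_dataframe",
    "write_tmr_bed",
]

#: Cohort size below which few regions tend to be recovered; a warning is
#: emitted (not an error) when the usable cohort is smaller.
SMALL_COHORT_WARNING = 60


@dataclass(frozen=True)
class SmoothingParams:
    """Exponential moving-average smoothing over CpG windows.

    ``smoothing_factor`` in [0, 1] sets the geometric weight decay per CpG
    of distance from the window center; ``n_flank`` CpGs are included on
    each side, so the window holds ``2 * n_flank + 1`` CpGs.
    """

    smoothing_factor: float = 0.75
    n_flank: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.smoothing_factor <= 1.0:
            raise ValueError("smoothing_factor must lie in [0, 1]")
        if self.n_flank < 0:
            raise ValueError("n_flank must be >= 0")

    @property
    def window_size(self) -> int:
        return 2 * self.n_flank + 1


@dataclass(frozen=True)
class Thresholds:
    """Symmetric significance thresholds on the smoothed signed score."""

    negative: float = math.log10(0.05)
    positive: float = -math.log10(0.05)

    def __post_init__(self) -> None:
        if not (self.negative < 0.0 < self.positive):
            raise ValueError("need negative < 0 < positive")


@dataclass(frozen=True)
class CallerConfig:
    """All tunable parameters of the discovery pipeline."""

    min_reads: int = 10  # coverage mask: beta blanked below this many reads
    min_samples: int = 30  # complete pairs required per CpG correlation
    upstream_pad: int = 5000
    downstream_pad: int = 5000
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_cpgs: int = 5
    mappability_min_score: float = 1.0
    mappability_mode: str = "full_containment"  # or "any_overlap"


@dataclass(frozen=True)
class TMR:
    """A called transcript-proximal methylation-associated region."""

    interval: GenomicInterval
    direction: str  # "negative" | "positive"
    transcript_id: str
    gene_id: str
    cpg_count: int
    peak_score: float
    distance_to_tss: float
    start_index: int  # first/last member CpG index within the source track
    end_index: int
    filters_passed: frozenset = frozenset()


def signed_score(q: float, rho_sign: float) -> float:
    """Signed score of one adjusted p-value: magnitude -log10(q), sign of rho."""
    if not (0.0 < q <= 1.0):
        raise ValueError("q must lie in (0, 1] (floor tiny values upstream)")
    mag = -math.log10(q)
    return -mag if rho_sign < 0 else mag


def signed_scores(q, rho) -> np.ndarray:
    """Vectorized :func:`signed_score`; NaN q or rho stays NaN."""
    q = np.asarray(q, dtype=float)
    rho = np.asarray(rho, dtype=float)
    out = np.full(q.shape, np.nan)
    ok = np.isfinite(q) & np.isfinite(rho)
    if np.any((q[ok] <= 0) | (q[ok] > 1)):
        raise ValueError("q must lie in (0, 1]")
    mag = -np.log10(q[ok])
    out[ok] = np.where(rho[ok] < 0, -mag, mag)
    return out


def smooth_scores(scores, params: SmoothingParams = SmoothingParams()) -> np.ndarray:
    """Symmetric exponentially-weighted moving average over CpG windows.

    Window members that fall off the track edge or are missing are dropped
    and the remaining weights renormalized to sum to one, so edge windows
    are truncated rather than padded.  A missing center with non-missing
    neighbors still receives a smoothed value; an all-missing window stays
    missing.  ``smoothing_factor = 0`` is the identity (only the center has
    weight).
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n == 0:
        return s.copy()
    finite = np.isfinite(s)
    vals = np.where(finite, s, 0.0)
    num = np.zeros(n)
    den = np.zeros(n)
    for k in range(-params.n_flank, params.n_flank + 1):
        if abs(k) >= n:
            continue
        w = params.smoothing_factor ** abs(k) if k != 0 else 1.0
        if w == 0.0:
            continue
        # contribution of neighbor at offset k to each center position
        if k >= 0:
            num[: n - k] += w * vals[k:]
            den[: n - k] += w * finite[k:]
        else:
            num[-k:] += w * vals[:k]
            den[-k:] += w * finite[:k]
    out = np.full(n, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def _runs(mask: np.ndarray):
    """Yield (start, end) index pairs of maximal True runs (end inclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, ends):
        yield int(idx[a]), int(idx[b])


def call_tmrs(track: CorrelationTrack, thresholds: Thresholds = Thresholds()) -> list[TMR]:
    """Segment threshold exceedances of the smoothed score into TMRs.

    Maximal runs of consecutive CpGs with smoothed score at or below the
    negative threshold become one negative TMR each; runs at or above the
    positive threshold one positive TMR each.  A TMR spans
    ``[first member CpG, last member CpG + 1)``.
    """
    sm = np.asarray(track.smoothed_score, dtype=float)
    tmrs: list[TMR] = []
    specs = [
        ("negative", np.isfinite(sm) & (sm <= thresholds.negative), np.argmin),
        ("positive", np.isfinite(sm) & (sm >= thresholds.positive), np.argmax),
    ]
    for direction, mask, peak_fn in specs:
        for a, b in _runs(mask):
            members = sm[a : b + 1]
            peak = float(members[peak_fn(members)])
            start = int(track.positions[a])
            end = int(track.positions[b]) + 1
            dist = float((track.distance_to_tss[a] + track.distance_to_tss[b]) / 2.0)
            tmrs.append(
                TMR(
                    interval=GenomicInterval(track.chrom, start, end, strand=track.strand),
                    direction=direction,
                    transcript_id=track.transcript_id,
                    gene_id=track.gene_id,
                    cpg_count=b - a + 1,
                    peak_score=peak,
                    distance_to_tss=dist,
                    start_index=a,
                    end_index=b,
                )
            )
    tmrs.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.direction))
    return tmrs


def filter_min_cpgs(tmrs: Iterable[TMR], min_cpgs: int = 5) -> list[TMR]:
    """Keep TMRs containing at least ``min_cpgs`` CpG sites (boundary inclusive)."""
    return [
        replace(t, filters_passed=t.filters_passed | {"min_cpgs"})
        for t in tmrs
        if t.cpg_count >= min_cpgs
    ]


def filter_mappability(
    tmrs: Sequence[TMR],
    mappability: Sequence[GenomicInterval],
    min_score: float = 1.0,
    mode: str = "full_containment",
) -> list[TMR]:
    """Keep TMRs supported by highly mappable sequence.

    ``full_containment`` (default, conservative): every base of the TMR must
    lie in mappability intervals scoring at least ``min_score``.
    ``any_overlap``: one overlapping base suffices.
    """
    if not mappability:
        raise ValueError("mappability filtering requested with an empty track")
    if mode not in ("full_containment", "any_overlap"):
        raise ValueError(f"unknown mappability mode {mode!r}")
    good = merge_intervals(
        [iv for iv in mappability if iv.score is not None and iv.score >= min_score]
    )
    kept: list[TMR] = []
    for t in tmrs:
        frac = covered_fraction(t.interval, good)
        ok = frac >= 1.0 if mode == "full_containment" else frac > 0.0
        if ok:
            kept.append(replace(t, filters_passed=t.filters_passed | {"mappability"}))
    return kept


def discover_tmrs(
    methylome: MethylomeMatrix,
    expression: ExpressionMatrix,
    models: Sequence[TranscriptModel],
    config: CallerConfig = CallerConfig(),
    mappability: Optional[Sequence[GenomicInterval]] = None,
) -> tuple[list[TMR], dict[str, CorrelationTrack], dict]:
    """Run the full discovery pipeline over a set of transcripts.

    Returns the final TMR list, the per-transcript correlation tracks (with
    scores and smoothed scores filled in), and a summary dict of per-stage
    counts.  Deterministic given identical inputs and config.
    """
    samples = [s for s in methylome.samples if s in set(expression.sample_ids)]
    if len(samples) < config.min_samples:
        raise ValueError(
            f"only {len(samples)} shared samples; at least {config.min_samples} "
            "complete pairs are required per CpG, so no correlation can be computed"
        )
    if len(samples) < SMALL_COHORT_WARNING:
        warnings.warn(
            f"cohort of {len(samples)} samples; discovery yields few regions "
            f"below ~{SMALL_COHORT_WARNING} samples"
        )
    masked = mask_low_coverage(methylome, config.min_reads)
    tracks: dict[str, CorrelationTrack] = {}
    called: list[TMR] = []
    n_pre_filter = 0
    for model in models:
        region = build_search_region(model, config.upstream_pad, config.downstream_pad)
        track = build_correlation_track(
            masked, expression, model, region, min_samples=config.min_samples, samples=samples
        )
        track.score = signed_scores(track.q, track.rho)
        track.smoothed_score = smooth_scores(track.score, config.smoothing)
        tracks[model.transcript_id] = track
        raw = call_tmrs(track, config.thresholds)
        n_pre_filter += len(raw)
        called.extend(raw)
    filtered = filter_min_cpgs(called, config.min_cpgs)
    n_post_min_cpgs = len(filtered)
    if mappability is not None:
        filtered = filter_mappability(
            filtered, mappability, config.mappability_min_score, config.mappability_mode
        )
    summary = {
        "n_transcripts": len(models),
        "n_samples": len(samples),
        "n_tmrs_raw": n_pre_filter,
        "n_tmrs_min_cpgs": n_post_min_cpgs,
        "n_tmrs_final": len(filtered),
        "n_negative": sum(t.direction == "negative" for t in filtered),
        "n_positive": sum(t.direction == "positive" for t in filtered),
    }
    return filtered, tracks, summary


def tmrs_to_dataframe(tmrs: Sequence[TMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [t.interval.chrom for t in tmrs],
            "start": [t.interval.start for t in tmrs],
            "end": [t.interval.end for t in tmrs],
            "transcript_id": [t.transcript_id for t in tmrs],
            "gene_id": [t.gene_id for t in tmrs],
            "direction": [t.direction for t in tmrs],
            "cpg_count": [t.cpg_count for t in tmrs],
            "peak_score": [t.peak_score for t in tmrs],
            "distance_to_tss": [t.distance_to_tss for t in tmrs],
            "strand": [t.interval.strand for t in tmrs],
        }
    )


def write_tmr_bed(tmrs: Sequence[TMR], path, header: Optional[str] = None) -> None:
    """Write TMRs as BED6: name = transcript:index, score = |peak| capped at 1000."""
    with open(path, "wt") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        counters: dict[str, int] = {}
        for t in tmrs:
            k = counters.get(t.transcript_id, 0) + 1
            counters[t.transcript_id] = k
            score = min(1000, int(round(abs(t.peak_score))))
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"{t.transcript_id}:{k}\t{score}\t{t.interval.strand}\n"
            )
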