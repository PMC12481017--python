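"""Per-transcript CpG methylation vs expression correlation tracks.

For every CpG in a transcript's search region the engine computes the
pairwise-complete Spearman correlation between that CpG's beta values and
the transcript's normalized expression across samples, a two-sided p-value
from the t approximation, and Benjamini--Hochberg adjusted q-values over
the CpGs of the track.  CpGs with fewer complete pairs than ``min_samples``
(default 30) are left missing.

The multiple-testing universe is the single transcript's track: each TSS's
CpG set is the unit that gets transformed into signed significance scores,
and a genome-wide correction would couple unrelated transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SearchRegion, TranscriptModel, signed_distance_to_tss
from .expression import ExpressionMatrix
from .methylome import MethylomeMatrix

__all__ = [
    "P_FLOOR",
    "CorrelationTrack",
    "spearman",
    "correlation_p_value",
    "benjamini_hochberg",
    "build_correlation_track",
]

#: Lower clamp for p-values; prevents infinite -log10 scores at |rho| = 1.
P_FLOOR = 1e-300


def spearman(x, y) -> tuple[float, int]:
    """Pairwise-complete Spearman correlation.

    Only indices where both vectors are finite are used; ties receive
    average ranks.  Returns ``(rho, n_used)`` with ``rho = NaN`` when fewer
    than two complete pairs exist or either vector is constant on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n_used = int(ok.sum())
    if n_used < 2:
        return float("nan"), n_used
    xo, yo = x[ok], y[ok]
    if np.all(xo == xo[0]) or np.all(yo == yo[0]):
        return float("nan"), n_used
    rx = stats.rankdata(xo)
    ry = stats.rankdata(yo)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, n_used


def correlation_p_value(rho: float, n_used: int) -> float:
    """Two-sided p-value for a Spearman rho via the Student-t approximation.

    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` with ``n - 2`` degrees of
    freedom.  Degenerate |rho| = 1 is clamped to :data:`P_FLOOR`; fewer than
    three pairs yield NaN.
    """
    if not np.isfinite(rho) or n_used < 3:
        return float("nan")
    if abs(rho) >= 1.0:
        return P_FLOOR
    df = n_used - 2
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(min(1.0, max(p, P_FLOOR)))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini--Hochberg step-up adjustment with NaN pass-through.

    Values must lie in (0, 1]; NaNs are ignored (returned as NaN) and do not
    count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return out
    vals = p[ok]
    if np.any((vals <= 0) | (vals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = vals.size
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


@dataclass
class CorrelationTrack:
    """Ordered per-CpG correlation statistics for one transcript."""

    transcript_id: str
    chrom: str
    positions: np.ndarray  # genomically ordered CpG positions
    distance_to_tss: np.ndarray  # signed bp, positive downstream
    rho: np.ndarray
    n_used: np.ndarray
    p: np.ndarray
    q: np.ndarray
    score: np.ndarray = field(default=None)  # signed -log10(q), sign of rho
    smoothed_score: np.ndarray = field(default=None)
    strand: str = "."
    gene_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.score is None:
            self.score = np.full(n, np.nan)
        if self.smoothed_score is None:
            self.smoothed_score = np.full(n, np.nan)
        for arr in (self.distance_to_tss, self.rho, self.n_used, self.p, self.q,
                    self.score, self.smoothed_score):
            assert len(arr) == n

    def __len__(self) -> int:
        return len(self.positions)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_id,
                "chrom": self.chrom,
                "pos": self.positions,
                "distance_to_tss": self.distance_to_tss,
                "n_used": self.n_used,
                "rho": self.rho,
                "p": self.p,
                "q": self.q,
                "score": self.score,
                "smoothed_score": self.smoothed_score,
            }
        )


def build_correlation_track(
    methylome: MethylomeMatrix,
    expression: ExpressionMatrix,
    model: TranscriptModel,
    search_region: SearchRegion,
    min_samples: int = 30,
    samples: Optional[Sequence[str]] = None,
) -> CorrelationTrack:
    """Correlate every search-region CpG's methylation with the transcript's expression.

    The methylome is expected to be coverage-masked already.  CpGs with
    fewer than ``min_samples`` complete (methylation AND expression) pairs
    get missing statistics; BH adjustment runs over the finite p-values of
    this track only.
    """
    if samples is None:
        samples = [s for s in methylome.samples if s in set(expression.sample_ids)]
    meth = methylome.subset_samples(samples) if list(samples) != methylome.samples else methylome
    y = expression.expression_vector(model.transcript_id, samples)
    idx = meth.site_indices(search_region.interval)
    n_cpg = len(idx)
    positions = meth.positions[idx]
    rho = np.full(n_cpg, np.nan)
    n_used = np.zeros(n_cpg, dtype=np.int64)
    p = np.full(n_cpg, np.nan)
    for k, i in enumerate(idx):
        r, n = spearman(meth.beta[i], y)
        n_used[k] = n
        if n < min_samples or not np.isfinite(r):
            continue
        rho[k] = r
        p[k] = correlation_p_value(r, n)
    q = benjamini_hochberg(p)
    dist = np.array([signed_distance_to_tss(int(pos), model) for pos in positions], dtype=np.int64)
    return CorrelationTrack(
        transcript_id=model.transcript_id,
        chrom=search_region.interval.chrom,
        positions=positions.astype(np.int64),
        distance_to_tss=dist,
        rho=rho,
        n_used=n_used,
        p=p,
        q=q,
        strand=model.strand,
        gene_id=model.gene_id,
    )
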