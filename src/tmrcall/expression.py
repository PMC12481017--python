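"""Transcript expression matrices and median-of-ratios normalization.

Raw (possibly non-integer) transcript counts are scaled by per-sample size
factors computed with the median-of-ratios method: the reference for each
transcript is its geometric mean across samples, computed only over
transcripts with strictly positive counts in every sample, and a sample's
size factor is the median ratio of its counts to those references (median
taken in log space, as in the reference differential-expression
implementations).  Size factors are reported relative to the median
sample (median factor = 1), so rescaling a single non-median sample's
library scales its factor by exactly the same amount and leaves every
normalized value unchanged.  Within-sample transcript ranks are unchanged
by normalization, which is what the downstream Spearman correlations
consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "median_of_ratios_normalize", "read_counts_tsv"]


@dataclass
class ExpressionMatrix:
    transcript_ids: list[str]
    sample_ids: list[str]
    raw_counts: np.ndarray  # (n_transcripts, n_samples), float64
    size_factors: np.ndarray  # (n_samples,)
    normalized: np.ndarray  # raw / size_factor per column

    def expression_vector(self, transcript_id: str, samples: Optional[Sequence[str]] = None) -> np.ndarray:
        """Normalized abundances of one transcript, in the requested sample order."""
        try:
            i = self.transcript_ids.index(transcript_id)
        except ValueError:
            raise KeyError(f"unknown transcript {transcript_id!r}") from None
        if samples is None:
            return self.normalized[i].copy()
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [lookup[s] for s in samples]
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None
        return self.normalized[i, cols].copy()


def read_counts_tsv(path, sep: str = "\t") -> pd.DataFrame:
    """Read a transcripts x samples count table (first column = transcript ID)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise ValueError("count table has no sample columns")
    return df


def median_of_ratios_normalize(
    raw_counts,
    transcript_ids: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence[str]] = None,
    pseudocount: float = 0.0,
) -> ExpressionMatrix:
    """Normalize a count matrix with per-sample median-of-ratios size factors.

    Parameters
    ----------
    raw_counts
        (n_transcripts, n_samples) array or DataFrame of non-negative counts.
    pseudocount
        Added to all counts *for size-factor estimation only*; use when no
        transcript has all-positive counts.

    Raises
    ------
    ValueError
        If counts are negative or no transcript has strictly positive counts
        in every sample (and no pseudocount was given).
    """
    if isinstance(raw_counts, pd.DataFrame):
        transcript_ids = list(raw_counts.index.astype(str))
        sample_ids = list(raw_counts.columns.astype(str))
        raw = raw_counts.to_numpy(dtype=float)
    else:
        raw = np.asarray(raw_counts, dtype=float)
        if transcript_ids is None:
            transcript_ids = [f"T{i}" for i in range(raw.shape[0])]
        if sample_ids is None:
            sample_ids = [f"S{j}" for j in range(raw.shape[1])]
    if raw.ndim != 2 or raw.shape[1] < 1:
        raise ValueError("raw_counts must be a 2-D transcripts x samples matrix")
    if np.any(raw < 0):
        raise ValueError("counts must be non-negative")

    est = raw + pseudocount
    all_positive = np.all(est > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no transcript has all-positive counts; pass pseudocount > 0 to "
            "estimate size factors on shifted counts"
        )
    log_est = np.log(est[all_positive])
    log_ref = np.mean(log_est, axis=1)  # log geometric mean per transcript
    # median of ratios taken in log space (geometric interpolation at even
    # reference counts), then anchored so the median sample has factor 1 --
    # this makes normalized values invariant to rescaling a single sample
    size_factors = np.exp(np.median(log_est - log_ref[:, None], axis=0))
    size_factors = size_factors / np.median(size_factors)
    if np.any(size_factors <= 0) or not np.all(np.isfinite(size_factors)):
        raise ValueError("non-positive size factor; input degenerate")
    normalized = raw / size_factors[None, :]
    return ExpressionMatrix(
        transcript_ids=list(transcript_ids),
        sample_ids=list(sample_ids),
        raw_counts=raw,
        size_factors=size_factors,
        normalized=normalized,
    )
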