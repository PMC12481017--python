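"""Enrichment statistics for called regions.

Three tests, matching the three kinds of annotation the pipeline is
compared against:

- annotation interval sets (CpG islands, chromatin states, ...) via a
  location-shuffling permutation test: each query region is relocated,
  length-preserved, to a uniformly random position inside the universe
  (the union of search regions), and observed overlap base pairs are
  compared to the permuted distribution;
- transcription-regulator binding sites via a two-sided Pearson
  chi-squared on the proportion of CpG sites overlapping binding sites in
  the query vs the background CpG set;
- gene sets via the one-sided (greater) Fisher exact test against a
  protein-coding background.

BH adjustment across annotation labels / regulators / gene sets is the
caller's job (the tests here are single comparisons).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, merge_intervals, total_overlap_bp

__all__ = [
    "EnrichmentResult",
    "shuffle_enrichment",
    "cpg_proportion_chisq",
    "fisher_overrepresentation",
    "read_gmt",
]


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


@dataclass
class EnrichmentResult:
    annotation_label: str
    observed_overlap_bp: float
    expected_mean: float
    enrichment_ratio: float
    empirical_p: float
    q: float = float("nan")
    n_perm: int = 0


def shuffle_enrichment(
    query: Sequence[GenomicInterval],
    annotation: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    n_perm: int = 1000,
    rng: "np.random.Generator | int | None" = None,
    label: str = "",
    alternative: str = "greater",
) -> EnrichmentResult:
    """Permutation enrichment of query intervals in an annotation set.

    Each of ``n_perm`` permutations independently relocates every query
    interval, preserving its length, to a uniformly random position within
    the universe: a universe interval is chosen with probability
    proportional to its number of eligible start positions, then a start is
    drawn uniformly.  Shuffled intervals may overlap each other.  The
    empirical p uses the add-one rule ``(1 + #{perm >= obs}) / (n_perm + 1)``
    (``alternative="two-sided"`` doubles the smaller tail).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observed = float(total_overlap_bp(query, list(annotation)))
    if not annotation:
        return EnrichmentResult(label, 0.0, 0.0, 0.0, 1.0, n_perm=n_perm)
    lengths = np.array([iv.length for iv in query], dtype=np.int64)
    uni = list(universe)
    uni_len = np.array([iv.length for iv in uni], dtype=np.int64)
    for L in np.unique(lengths):
        if not np.any(uni_len >= L):
            bad = next(iv for iv in query if iv.length == L)
            raise ValueError(
                f"query interval {bad.chrom}:{bad.start}-{bad.end} (len {L}) "
                "is longer than every universe interval"
            )
    perm_overlaps = np.empty(n_perm)
    for p in range(n_perm):
        placed: list[GenomicInterval] = []
        for L in lengths:
            slots = uni_len - L + 1
            slots = np.where(slots > 0, slots, 0)
            weights = slots / slots.sum()
            u = uni[rng.choice(len(uni), p=weights)]
            start = int(u.start + rng.integers(0, u.length - L + 1))
            placed.append(GenomicInterval(u.chrom, start, start + int(L)))
        perm_overlaps[p] = total_overlap_bp(placed, list(annotation))
    expected = float(perm_overlaps.mean())
    ratio = observed / expected if expected > 0 else (0.0 if observed == 0 else float("inf"))
    p_ge = (1.0 + float(np.sum(perm_overlaps >= observed))) / (n_perm + 1.0)
    p_le = (1.0 + float(np.sum(perm_overlaps <= observed))) / (n_perm + 1.0)
    if alternative == "greater":
        emp_p = p_ge
    elif alternative == "less":
        emp_p = p_le
    elif alternative == "two-sided":
        emp_p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(
        annotation_label=label,
        observed_overlap_bp=observed,
        expected_mean=expected,
        enrichment_ratio=ratio,
        empirical_p=emp_p,
        n_perm=n_perm,
    )


def _count_in_intervals(
    sites: Sequence[tuple[str, int]], intervals: Sequence[GenomicInterval]
) -> int:
    merged = merge_intervals(list(intervals))
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for iv in merged:
        starts, ends = by_chrom.setdefault(iv.chrom, ([], []))
        starts.append(iv.start)
        ends.append(iv.end)
    count = 0
    for chrom, pos in sites:
        se = by_chrom.get(chrom)
        if se is None:
            continue
        starts, ends = se
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            count += 1
    return count


def cpg_proportion_chisq(
    tmr_cpgs: Sequence[tuple[str, int]],
    background_cpgs: Sequence[tuple[str, int]],
    binding_sites: Sequence[GenomicInterval],
    yates: bool = False,
) -> tuple[float, float, str]:
    """Two-sided chi-squared comparing binding-site overlap proportions of CpG sets.

    Rows of the 2x2 table are the query (TMR) CpGs and the background CpGs
    (typically all search-region CpGs, a superset of the query); columns
    split each set by overlap with the binding-site intervals.  Pearson
    chi-squared with 1 df, no continuity correction by default.

    Returns ``(chi2, p, direction)`` with direction "enriched"/"depleted"/
    "equal" by the sign of the proportion difference; a zero table margin
    yields ``(nan, nan, reason)``.
    """
    a = _count_in_intervals(tmr_cpgs, binding_sites)
    b = len(tmr_cpgs) - a
    c = _count_in_intervals(background_cpgs, binding_sites)
    d = len(background_cpgs) - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return float("nan"), float("nan"), "zero margin"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    pa = a / (a + b)
    pc = c / (c + d)
    direction = "enriched" if pa > pc else ("depleted" if pa < pc else "equal")
    return float(chi2), float(p), direction


def fisher_overrepresentation(
    query_genes: Iterable[str],
    gene_set: Iterable[str],
    background_genes: Iterable[str],
) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test of gene-set overrepresentation.

    The query must be a subset of the background; the gene set is
    intersected with the background before testing.  Returns
    ``(odds_ratio, p)``.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene universe")
    query = set(query_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    gset = set(gene_set) & background
    a = len(query & gset)
    b = len(query - gset)
    c = len(gset - query)
    d = len(background) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
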