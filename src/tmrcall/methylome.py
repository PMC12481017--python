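"""CpG-level methylation matrices from per-sample WGBS call files.

A :class:`MethylomeMatrix` holds, for every CpG site (identified by
chromosome and 0-based position of the C) and every sample, the number of
methylated reads, the total read count, and the derived beta value
(methylated / total).  A site absent from a sample's file is *missing*
(total reads 0, beta NaN) -- absence of evidence, not evidence of zero
methylation.  Coverage masking blanks beta values at under-covered cells
but always retains the raw read counts, because region-level differential
tests work on summed reads rather than betas.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "MethylomeMatrix",
    "read_methylome",
    "write_methylome",
    "mask_low_coverage",
]

#: Supported per-sample file dialects.
#:
#: - ``counts``:  chrom, pos, meth_reads, total_reads          (pos 0-based)
#: - ``beta``:    chrom, start, end, beta, meth_reads, total_reads
#: - ``percent``: chrom, start, end, percent_methylated, total_reads
#: - ``bismark``: chrom, start, end, percent, meth_reads, unmeth_reads
DIALECTS = ("counts", "beta", "percent", "bismark")


@dataclass
class MethylomeMatrix:
    """CpG sites x samples methylation counts and beta values.

    Sites are unique and sorted by (chrom, pos).  ``beta`` is NaN wherever a
    cell is missing or has been coverage-masked; ``meth`` and ``total`` are
    never altered by masking.
    """

    chroms: np.ndarray  # (n_sites,) str
    positions: np.ndarray  # (n_sites,) int64
    samples: list[str]
    meth: np.ndarray  # (n_sites, n_samples) int64
    total: np.ndarray  # (n_sites, n_samples) int64
    beta: np.ndarray  # (n_sites, n_samples) float64, NaN = missing

    def __post_init__(self) -> None:
        n, s = self.meth.shape
        assert self.total.shape == (n, s) and self.beta.shape == (n, s)
        assert len(self.chroms) == n and len(self.positions) == n
        assert len(self.samples) == s
        if np.any(self.meth > self.total):
            raise ValueError("meth_reads exceeds total_reads")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def site_indices(self, interval: GenomicInterval) -> np.ndarray:
        """Indices of CpG sites falling in a half-open interval (sorted)."""
        mask = self.chroms == interval.chrom
        idx = np.flatnonzero(mask)
        pos = self.positions[idx]
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="left")
        return idx[lo:hi]

    def subset_samples(self, samples: Sequence[str]) -> "MethylomeMatrix":
        j = self.sample_index(samples)
        return MethylomeMatrix(
            chroms=self.chroms,
            positions=self.positions,
            samples=list(samples),
            meth=self.meth[:, j],
            total=self.total[:, j],
            beta=self.beta[:, j],
        )


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_sample_file(path, dialect: str) -> dict[tuple[str, int], tuple[int, int]]:
    calls: dict[tuple[str, int], tuple[int, int]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                if dialect == "counts":
                    chrom, pos = f[0], int(f[1])
                    meth, total = int(f[2]), int(f[3])
                elif dialect == "beta":
                    chrom, pos = f[0], int(f[1])
                    meth, total = int(f[4]), int(f[5])
                elif dialect == "percent":
                    chrom, pos = f[0], int(f[1])
                    total = int(f[4])
                    meth = int(round(float(f[3]) / 100.0 * total))
                elif dialect == "bismark":
                    chrom, pos = f[0], int(f[1])
                    meth, unmeth = int(f[4]), int(f[5])
                    total = meth + unmeth
                else:
                    raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and "unknown dialect" in str(exc):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed {dialect} record") from exc
            if meth > total:
                raise ValueError(f"{path}:{lineno}: meth_reads {meth} > total_reads {total}")
            key = (chrom, pos)
            if key in calls:
                # duplicate position (e.g. per-strand calls of one CpG): sum counts
                m0, t0 = calls[key]
                calls[key] = (m0 + meth, t0 + total)
            else:
                calls[key] = (meth, total)
    return calls


def read_methylome(
    sample_files: Mapping[str, "str | Path"],
    dialect: str = "beta",
    site_universe: Optional[Sequence[tuple[str, int]]] = None,
) -> MethylomeMatrix:
    """Load per-sample CpG call files into a site x sample matrix.

    Parameters
    ----------
    sample_files
        Mapping of sample ID -> file path; sample order is preserved.
    dialect
        File layout, one of :data:`DIALECTS`.
    site_universe
        Optional explicit (chrom, pos) site list; defaults to the union of
        sites observed across samples.  Cells without a record are missing.
    """
    per_sample = {s: _parse_sample_file(p, dialect) for s, p in sample_files.items()}
    if site_universe is not None:
        sites = sorted(set(site_universe))
    else:
        sites = sorted({k for calls in per_sample.values() for k in calls})
    site_index = {k: i for i, k in enumerate(sites)}
    samples = list(sample_files)
    n, s = len(sites), len(samples)
    meth = np.zeros((n, s), dtype=np.int64)
    total = np.zeros((n, s), dtype=np.int64)
    for j, sample in enumerate(samples):
        for key, (m, t) in per_sample[sample].items():
            i = site_index.get(key)
            if i is not None:
                meth[i, j] = m
                total[i, j] = t
    beta = np.full((n, s), np.nan)
    np.divide(meth, total, out=beta, where=total > 0)
    chroms = np.array([c for c, _ in sites], dtype=object)
    positions = np.array([p for _, p in sites], dtype=np.int64)
    return MethylomeMatrix(chroms, positions, samples, meth, total, beta)


def write_methylome(matrix: MethylomeMatrix, out_dir, dialect: str = "beta") -> dict[str, Path]:
    """Write one per-sample call file (``beta`` or ``counts`` dialect) per sample.

    Only cells with at least one read are written; masked betas are
    recomputed from counts on re-reading, so a write/read round trip
    reproduces the unmasked matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for j, sample in enumerate(matrix.samples):
        path = out_dir / f"{sample}.{dialect}.tsv"
        with open(path, "wt") as fh:
            for i in np.flatnonzero(matrix.total[:, j] > 0):
                m, t = int(matrix.meth[i, j]), int(matrix.total[i, j])
                chrom, pos = matrix.chroms[i], int(matrix.positions[i])
                if dialect == "beta":
                    fh.write(f"{chrom}\t{pos}\t{pos + 2}\t{m / t:.9f}\t{m}\t{t}\n")
                elif dialect == "counts":
                    fh.write(f"{chrom}\t{pos}\t{m}\t{t}\n")
                else:
                    raise ValueError("write_methylome supports 'beta' and 'counts' dialects")
        paths[sample] = path
    return paths


def mask_low_coverage(matrix: MethylomeMatrix, min_reads: int = 10) -> MethylomeMatrix:
    """Blank beta values at cells covered by fewer than ``min_reads`` reads.

    Read counts are untouched, so region-level tests on summed reads still
    see the full data.  Idempotent.
    """
    beta = matrix.beta.copy()
    beta[matrix.total < min_reads] = np.nan
    return MethylomeMatrix(
        chroms=matrix.chroms,
        positions=matrix.positions,
        samples=list(matrix.samples),
        meth=matrix.meth,
        total=matrix.total,
        beta=beta,
    )
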