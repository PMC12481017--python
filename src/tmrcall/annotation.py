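"""Transcript models, CAGE-supported TSS selection and search regions.

Transcript records are read from GTF (1-based inclusive) and stored in the
package-wide 0-based half-open convention.  The TSS is the first transcribed
base of a transcript, the TES its last; both are strand-aware, so on the
minus strand the TSS is the highest coordinate of the transcript body.

The *search region* of a transcript is its body extended by a fixed pad
upstream of the TSS and downstream of the TES (default 5 kb each); every
methylation--expression correlation for the transcript is computed over the
CpGs in this region.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval

__all__ = [
    "TranscriptModel",
    "SearchRegion",
    "load_transcript_models",
    "write_transcript_models",
    "filter_tss_by_cage",
    "build_search_region",
    "signed_distance_to_tss",
    "read_ctss_bed",
]

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware transcript span with derived TSS/TES positions."""

    transcript_id: str
    gene_id: str
    body: GenomicInterval
    gene_name: str = ""
    biotype: str = ""
    cage_tags: Optional[int] = None

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        """Position of the first transcribed base (0-based)."""
        return self.body.start if self.strand != "-" else self.body.end - 1

    @property
    def tes(self) -> int:
        """Position of the last transcribed base (0-based)."""
        return self.body.end - 1 if self.strand != "-" else self.body.start


@dataclass(frozen=True)
class SearchRegion:
    transcript_id: str
    interval: GenomicInterval


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_transcript_models(
    gtf_source,
    biotypes: Optional[Sequence[str]] = None,
    transcript_ids: Optional[Iterable[str]] = None,
) -> list[TranscriptModel]:
    """Parse transcript-level GTF records into :class:`TranscriptModel` objects.

    Parameters
    ----------
    gtf_source
        Path to a GTF file (Gencode attribute dialect), optionally gzipped.
    biotypes
        Keep only transcripts whose ``transcript_type``/``transcript_biotype``
        attribute is in this list (e.g. ``["protein_coding"]``).
    transcript_ids
        Optional allowlist of transcript IDs (e.g. a MANE-select subset).

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open on the way in.  Records without a ``transcript_id`` attribute
    are skipped with a single summary warning.
    """
    allow = set(transcript_ids) if transcript_ids is not None else None
    biotype_set = set(biotypes) if biotypes is not None else None
    models: list[TranscriptModel] = []
    skipped = 0
    with _open_text(gtf_source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "transcript":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                skipped += 1
                continue
            if allow is not None and tid not in allow:
                continue
            biotype = attr.get("transcript_type", attr.get("transcript_biotype", ""))
            if biotype_set is not None and biotype not in biotype_set:
                continue
            body = GenomicInterval(chrom, start1 - 1, end1, strand=strand if strand in "+-" else ".")
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=attr.get("gene_id", ""),
                    gene_name=attr.get("gene_name", ""),
                    biotype=biotype,
                    body=body,
                )
            )
    if skipped:
        warnings.warn(f"skipped {skipped} transcript record(s) without transcript_id")
    return models


def write_transcript_models(models: Iterable[TranscriptModel], path) -> None:
    """Write models back out as transcript-level GTF records (1-based inclusive)."""
    with open(path, "wt") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_name}"; transcript_type "{m.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        m.body.chrom,
                        "tmrcall",
                        "transcript",
                        str(m.body.start + 1),
                        str(m.body.end),
                        ".",
                        m.strand if m.strand in "+-" else ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_ctss_bed(path) -> list[tuple[str, int, str, int]]:
    """Read a CTSS BED file into (chrom, pos, strand, tag_count) tuples.

    CTSS records are single-base BED intervals whose score column carries the
    CAGE tag count at that 5' end.
    """
    records: list[tuple[str, int, str, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: CTSS BED needs 6 columns")
            chrom, start, _end, _name, score, strand = fields[:6]
            records.append((chrom, int(start), strand, int(float(score))))
    return records


def filter_tss_by_cage(
    models: Sequence[TranscriptModel],
    ctss_records: Sequence[tuple[str, int, str, int]],
    min_tags: int = 10,
    tolerance_bp: int = 0,
) -> list[TranscriptModel]:
    """Keep transcripts whose TSS is supported by at least ``min_tags`` CAGE tags.

    A model is retained when a same-strand CTSS position within
    ``tolerance_bp`` of its TSS carries ``tag_count >= min_tags``; the
    maximal qualifying tag count is recorded on the model.  ``tolerance_bp=0``
    requires support at the exact TSS base.
    """
    if not ctss_records:
        warnings.warn("empty CTSS input: no TSS retained")
        return []
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, pos, strand, tags in ctss_records:
        by_key.setdefault((chrom, strand), []).append((pos, tags))
    for lst in by_key.values():
        lst.sort()
    import bisect

    kept: list[TranscriptModel] = []
    for m in models:
        candidates = by_key.get((m.body.chrom, m.strand), [])
        lo = bisect.bisect_left(candidates, (m.tss - tolerance_bp, -1))
        hi = bisect.bisect_right(candidates, (m.tss + tolerance_bp, 1 << 62))
        best = None
        for pos, tags in candidates[lo:hi]:
            if abs(pos - m.tss) <= tolerance_bp and tags >= min_tags:
                best = tags if best is None else max(best, tags)
        if best is not None:
            kept.append(replace(m, cage_tags=best))
    return kept


def build_search_region(
    model: TranscriptModel,
    upstream_pad: int = 5000,
    downstream_pad: int = 5000,
) -> SearchRegion:
    """Extend the transcript body by pads upstream of the TSS and downstream of the TES.

    The pads follow the direction of transcription: on the minus strand the
    upstream pad extends to higher coordinates.  Clipped at position 0.
    """
    if upstream_pad < 0 or downstream_pad < 0:
        raise ValueError("pads must be >= 0")
    if model.strand == "-":
        start = model.body.start - downstream_pad
        end = model.body.end + upstream_pad
    else:
        start = model.body.start - upstream_pad
        end = model.body.end + downstream_pad
    return SearchRegion(
        transcript_id=model.transcript_id,
        interval=GenomicInterval(model.body.chrom, max(0, start), end, strand=model.strand),
    )


def signed_distance_to_tss(position: int, model: TranscriptModel) -> int:
    """Signed distance from the TSS, positive in the direction of transcription."""
    d = position - model.tss
    return -d if model.strand == "-" else d
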