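"""Transcript models and GTF input/output.

The pipeline consumes a transcript annotation rather than raw reads: every
transcript is an :class:`ExonChain` (ordered, non-overlapping exons on one
strand) attached to a gene.  Coordinates are half-open, 0-based internally;
GTF files are written and read with the conventional 1-based inclusive
coordinates.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .errors import DataError

Interval = tuple[int, int]


@dataclass(frozen=True)
class ExonChain:
    """An ordered chain of exons on one strand.

    intervals are half-open 0-based ``(start, end)`` pairs, sorted by start
    and non-overlapping; ``strand`` is ``"+"`` or ``"-"``.
    """

    intervals: tuple[Interval, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"invalid strand {self.strand!r}")
        if not self.intervals:
            raise DataError("exon chain must contain at least one exon")
        prev_end = None
        for start, end in self.intervals:
            if end <= start:
                raise DataError(f"empty or inverted exon ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise DataError("exons must be sorted and non-overlapping")
            prev_end = end

    @property
    def length(self) -> int:
        """Total exonic length in bp (the transcript length used for FPKM)."""
        return sum(e - s for s, e in self.intervals)

    @property
    def span(self) -> Interval:
        return self.intervals[0][0], self.intervals[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Intron intervals, i.e. the junction chain between adjacent exons."""
        return tuple(
            (self.intervals[i][1], self.intervals[i + 1][0])
            for i in range(len(self.intervals) - 1)
        )

    @property
    def is_multi_exon(self) -> bool:
        return len(self.intervals) > 1


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chain: ExonChain
    chrom: str = "chr1"

    @property
    def length(self) -> int:
        return self.chain.length


def transcript_lengths(models: Iterable[TranscriptModel]) -> dict[str, int]:
    return {m.transcript_id: m.length for m in models}


def tx2gene(models: Iterable[TranscriptModel]) -> dict[str, str]:
    return {m.transcript_id: m.gene_id for m in models}


def genes_of(models: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    """Group transcripts by gene, preserving input order."""
    out: dict[str, list[TranscriptModel]] = {}
    for m in models:
        out.setdefault(m.gene_id, []).append(m)
    return out


# ---------------------------------------------------------------------------
# GTF serialization


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write a 9-column GTF (1-based inclusive) with transcript + exon rows."""
    lines = []
    for m in models:
        s0, e0 = m.chain.span
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        lines.append(
            f"{m.chrom}\tisofunnel\ttranscript\t{s0 + 1}\t{e0}\t.\t"
            f"{m.chain.strand}\t.\t{attrs}"
        )
        for s, e in m.chain.intervals:
            lines.append(
                f"{m.chrom}\tisofunnel\texon\t{s + 1}\t{e}\t.\t"
                f"{m.chain.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (exon features only are used)."""
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path),
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        by_tx: dict[str, dict] = {}
        order: list[str] = []
        for exon in db.features_of_type("exon", order_by="start"):
            tid = exon.attributes["transcript_id"][0]
            gid = exon.attributes["gene_id"][0]
            if tid not in by_tx:
                by_tx[tid] = {"gene": gid, "chrom": exon.seqid,
                              "strand": exon.strand, "exons": []}
                order.append(tid)
            by_tx[tid]["exons"].append((exon.start - 1, exon.end))
    models = []
    for tid in order:
        rec = by_tx[tid]
        exons = tuple(sorted(rec["exons"]))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene"],
                chain=ExonChain(intervals=exons, strand=rec["strand"]),
                chrom=rec["chrom"],
            )
        )
    return models
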