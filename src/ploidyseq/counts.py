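"""Count tables and read weighting.

A :class:`CountTable` holds per-gene read counts for one RNA-seq sample
together with the library total used as the denominator when counts are
converted to transcriptome frequencies.  Counts are stored as reals
because a read aligning to *n* genomic locations contributes a fractional
weight of 1/*n* to each feature it falls in; uniquely mapped reads
contribute 1.

The expressed-gene filter (count >= 15 in at least one sample) defines
the background gene list used by the enrichment stage.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import Feature

DEFAULT_EXPRESSED_THRESHOLD = 15.0


@dataclass(frozen=True)
class AlignmentRecord:
    """All genomic hits of one read; multiplicity n = number of hits."""

    read_id: str
    hits: tuple[tuple[str, int, int, str], ...]  # (contig, start, end, strand)

    def __post_init__(self) -> None:
        if len(self.hits) < 1:
            raise ValueError(f"read {self.read_id!r}: needs at least one hit")
        for contig, start, end, strand in self.hits:
            if start >= end:
                raise ValueError(
                    f"read {self.read_id!r}: malformed interval [{start}, {end})"
                )

    @property
    def multiplicity(self) -> int:
        return len(self.hits)


@dataclass
class CountTable:
    """Per-gene counts for one sample plus the frequency denominator."""

    sample_id: str
    ploidy: str
    counts: dict[str, float] = field(default_factory=dict)
    library_total: int = 0

    def __post_init__(self) -> None:
        if self.library_total <= 0:
            raise ValueError("library_total must be a positive integer")
        total = 0.0
        for gene, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for gene {gene!r}: {c}")
            total += c
        if total > self.library_total * (1 + 1e-9):
            raise ValueError(
                f"sum of counts ({total}) exceeds library_total "
                f"({self.library_total})"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(self.counts)

    def count(self, gene_id: str) -> float:
        try:
            return self.counts[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r} in sample "
                           f"{self.sample_id!r}") from None


def frequency(table: CountTable, gene_id: str) -> float:
    """Expression frequency of a gene: count / library_total, in [0, 1]."""
    return table.count(gene_id) / table.library_total


def write_count_table(table: CountTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id={table.sample_id}\n")
        fh.write(f"# ploidy={table.ploidy}\n")
        fh.write(f"# library_total={table.library_total}\n")
        fh.write("gene_id\tcount\n")
        for gene in sorted(table.counts):
            fh.write(f"{gene}\t{table.counts[gene]:.10g}\n")


def read_count_table(path: str | os.PathLike) -> CountTable:
    """Read a TSV count table written by :func:`write_count_table`.

    Raises ``ValueError`` on negative counts, duplicate gene ids, unknown
    columns or a missing library_total header.
    """
    meta: dict[str, str] = {}
    counts: dict[str, float] = {}
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            cols = line.split("\t")
            if not header_seen:
                if cols != ["gene_id", "count"]:
                    raise ValueError(
                        f"unexpected columns {cols!r}; expected gene_id, count"
                    )
                header_seen = True
                continue
            if len(cols) != 2:
                raise ValueError(f"malformed row: {line!r}")
            gene, raw = cols
            if gene in counts:
                raise ValueError(f"duplicate gene id {gene!r}")
            value = float(raw)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"invalid count for gene {gene!r}: {raw}")
            counts[gene] = value
    if "library_total" not in meta:
        raise ValueError(f"{path}: missing library_total header")
    return CountTable(
        sample_id=meta.get("sample_id", os.path.basename(str(path))),
        ploidy=meta.get("ploidy", "?"),
        counts=counts,
        library_total=int(meta["library_total"]),
    )


def read_alignment_hits(path: str | os.PathLike) -> list[AlignmentRecord]:
    """Read alignment hits from a BED-like TSV.

    Columns: read_id, contig, start, end, strand (0-based half-open);
    multiple rows with the same read_id form one multi-mapped record.
    Full SAM/BAM parsing is out of scope; convert with e.g.::

        samtools view aln.bam | awk -v OFS='\\t' \\
          '{print $1, $3, $4-1, $4-1+length($10), ($2%32>=16)?"-":"+"}'
    """
    by_read: dict[str, list[tuple[str, int, int, str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, contig, start, end, strand = line.split("\t")[:5]
            if read_id not in by_read:
                by_read[read_id] = []
                order.append(read_id)
            by_read[read_id].append((contig, int(start), int(end), strand))
    return [AlignmentRecord(r, tuple(by_read[r])) for r in order]


def weight_multimapped(
    alignments: Sequence[AlignmentRecord],
    annotation: Sequence[Feature],
    sample_id: str = "sample",
    ploidy: str = "?",
    library_total: int | None = None,
) -> CountTable:
    """Convert alignments to per-feature counts with 1/n multi-map weights.

    A read with *n* genomic hits contributes 1/n to every feature that
    contains a hit's midpoint (strand-agnostic); a uniquely mapped read
    contributes 1.  ``library_total`` defaults to the number of reads, so
    the total-weight invariant (sum of counts <= library_total) holds.

    Raises ``ValueError`` for a hit on a contig absent from the annotation.
    """
    known_contigs = {f.contig for f in annotation}
    by_contig: dict[str, list[Feature]] = {}
    for f in annotation:
        by_contig.setdefault(f.contig, []).append(f)
    counts: dict[str, float] = {f.feature_id: 0.0 for f in annotation}
    for rec in alignments:
        w = 1.0 / rec.multiplicity
        for contig, start, end, _strand in rec.hits:
            if contig not in known_contigs:
                raise ValueError(
                    f"read {rec.read_id!r}: hit on unknown contig {contig!r}"
                )
            mid = start + (end - start) // 2
            for feat in by_contig[contig]:
                if feat.contains(mid):
                    counts[feat.feature_id] += w
    if library_total is None:
        library_total = len(alignments)
    return CountTable(sample_id=sample_id, ploidy=ploidy, counts=counts,
                      library_total=library_total)


def filter_expressed(
    tables: Iterable[CountTable],
    threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
) -> list[str]:
    """Genes with count >= threshold in at least one sample, sorted.

    The permissive at-least-one rule keeps genes silenced in one ploidy
    (e.g. mating genes absent in tetraploids), which are exactly the
    strongest differential-expression candidates.  The result is the
    background gene list for enrichment.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("filter_expressed needs at least one count table")
    expressed: set[str] = set()
    for t in tables:
        for gene, c in t.counts.items():
            if c >= threshold:
                expressed.add(gene)
    return sorted(expressed)
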