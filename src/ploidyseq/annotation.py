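"""Genome feature annotation: a light container plus GFF3 round-trip.

Internally all coordinates are 0-based, half-open ``[start, end)``.
GFF3 input/output converts to and from the 1-based inclusive convention.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils


@dataclass(frozen=True)
class Feature:
    """One annotated genomic feature (ORF, Ty, tRNA, ...).

    Coordinates are 0-based half-open; ``strand`` is ``+`` or ``-``.
    """

    feature_id: str
    contig: str
    start: int
    end: int
    strand: str
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def coding_start(self) -> int:
        """0-based position of the first coding base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def write_gff3(features: Iterable[Feature], path: str | os.PathLike,
               contig_lengths: dict[str, int] | None = None) -> None:
    """Write features as GFF3 (1-based, inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig in sorted(contig_lengths):
                fh.write(f"##sequence-region {contig} 1 {contig_lengths[contig]}\n")
        for f in features:
            fh.write(
                "\t".join(
                    (
                        f.contig,
                        "ploidyseq",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id}",
                    )
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike,
              kinds: Sequence[str] | None = None) -> list[Feature]:
    """Read a GFF3 file into :class:`Feature` records.

    Parameters
    ----------
    kinds
        Feature types to keep (GFF3 column 3); ``None`` keeps everything.
    """
    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            str(path), dbpath, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        out: list[Feature] = []
        for rec in db.all_features():
            if kinds is not None and rec.featuretype not in kinds:
                continue
            fid = rec.attributes.get("ID", [rec.id])[0]
            strand = rec.strand if rec.strand in ("+", "-") else "+"
            out.append(
                Feature(
                    feature_id=fid,
                    contig=rec.seqid,
                    start=rec.start - 1,
                    end=rec.end,
                    strand=strand,
                    kind=rec.featuretype,
                )
            )
        return out
    finally:
        if os.path.exists(dbpath):
            os.unlink(dbpath)
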