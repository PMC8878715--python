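"""Read-pair extraction from SAM alignments over the IGH locus.

The pipeline keeps every read pair in which at least one mate's reference
span intersects the configured IGH interval, and carries the mate along
even when it maps elsewhere or is unmapped.  A fixed-length trim then
removes random-hexamer bases from the 5' end of each mate before
annotation.

Coordinates are 0-based half-open internally; SAM's 1-based POS is
converted on ingest.  The parser is deliberately minimal — it reads the
six mandatory columns the extractor needs, streams lazily, accepts
headerless records, and reports parse errors with line numbers; pysam is
used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from os import PathLike
from typing import Iterable, Iterator

from .simulate import reverse_complement

UNMAPPED_POS = -1
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")
_QUERY_CONSUMING = set("MIS=X")


@dataclass(frozen=True)
class LocusInterval:
    """A named genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval for {self.name}")

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        return contig == self.contig and start < self.end and self.start < end


#: Default Ig locus intervals on GRCh38 (overridable via BED or config).
DEFAULT_IG_LOCI = [
    LocusInterval("chr14", 105_586_437, 106_879_844, "IGH"),
    LocusInterval("chr2", 88_857_361, 90_235_368, "IGK"),
    LocusInterval("chr22", 22_026_076, 22_922_913, "IGL"),
]


@dataclass
class AlignmentRecord:
    qname: str
    flag: int
    rname: str
    pos: int  # 0-based leftmost; UNMAPPED_POS when unmapped
    cigar: str
    seq: str
    qual: str = "*"

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4) or self.rname == "*"

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & 0x40)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & 0x80)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    def reference_span(self) -> tuple[int, int] | None:
        """0-based half-open reference interval consumed by the alignment."""
        if self.is_unmapped or self.cigar == "*" or self.pos == UNMAPPED_POS:
            return None
        consumed = sum(
            int(n) for n, op in _CIGAR_RE.findall(self.cigar)
            if op in _REF_CONSUMING
        )
        return (self.pos, self.pos + consumed)


class SamParseError(ValueError):
    pass


def read_sam(source) -> Iterator[AlignmentRecord]:
    """Lazily yield alignment records from SAM text.

    ``source`` may be a path or an open text handle.  Header lines are
    skipped; headerless files are accepted.  A record with fewer than the
    11 mandatory columns raises :class:`SamParseError` naming the line.
    """
    if isinstance(source, (str, PathLike)):
        with open(source) as handle:
            yield from _parse_sam(handle)
    else:
        yield from _parse_sam(source)


def _parse_sam(handle) -> Iterator[AlignmentRecord]:
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise SamParseError(
                f"line {lineno}: expected 11 mandatory SAM columns, "
                f"found {len(fields)}"
            )
        try:
            flag = int(fields[1])
            pos1 = int(fields[3])
        except ValueError as exc:
            raise SamParseError(f"line {lineno}: non-integer FLAG/POS") from exc
        unmapped = bool(flag & 0x4) or fields[2] == "*" or pos1 == 0
        yield AlignmentRecord(
            qname=fields[0],
            flag=flag,
            rname=fields[2],
            pos=UNMAPPED_POS if unmapped else pos1 - 1,
            cigar=fields[5],
            seq=fields[9],
            qual=fields[10],
        )


@dataclass
class ReadPairRecord:
    """Both mates of a kept pair, in original read orientation."""

    pair_id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str = ""
    mate2_qual: str = ""
    mate1_trimmed: bool = False
    mate2_trimmed: bool = False
    provenance: str | None = None


def extract_locus_pairs(
    records: Iterable[AlignmentRecord], locus: LocusInterval
) -> list[ReadPairRecord]:
    """Keep pairs where >=1 mate's reference span intersects ``locus``.

    Both mates of a kept pair are emitted (mate rescue): a mate mapping
    to another contig, or unmapped, rides along with its IGH-overlapping
    partner.  Secondary and supplementary alignments are ignored; more
    than two primary records for one name is an error.  Reverse-strand
    SEQ fields are reverse-complemented back to read orientation.
    """
    pairs: dict[str, dict[int, AlignmentRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        mate = 2 if rec.is_read2 else 1
        if rec.qname not in pairs:
            order.append(rec.qname)
        slot = pairs.setdefault(rec.qname, {})
        if mate in slot:
            raise ValueError(
                f"more than two primary records for read {rec.qname!r}"
            )
        slot[mate] = rec

    kept: list[ReadPairRecord] = []
    for qname in sorted(order):
        slot = pairs[qname]
        if 1 not in slot or 2 not in slot:
            continue  # orphan: mate not recoverable
        overlap = False
        for rec in slot.values():
            span = rec.reference_span()
            if span and locus.overlaps(rec.rname, *span):
                overlap = True
                break
        if not overlap:
            continue
        m1, m2 = slot[1], slot[2]
        kept.append(ReadPairRecord(
            pair_id=qname,
            mate1_seq=_read_orientation(m1),
            mate2_seq=_read_orientation(m2),
            mate1_qual=m1.qual[::-1] if m1.is_reverse else m1.qual,
            mate2_qual=m2.qual[::-1] if m2.is_reverse else m2.qual,
            provenance=qname,
        ))
    return kept


def _read_orientation(rec: AlignmentRecord) -> str:
    return reverse_complement(rec.seq) if rec.is_reverse else rec.seq


def trim_hexamer(pair: ReadPairRecord, trim_len: int = 6) -> ReadPairRecord:
    """Remove the first ``trim_len`` bases of each mate exactly once.

    Random-hexamer priming corrupts the 5' end of each mate; a fixed
    trim removes it.  Trimming an already-trimmed pair is a warned no-op.
    """
    if pair.mate1_trimmed and pair.mate2_trimmed:
        warnings.warn(f"pair {pair.pair_id} already trimmed; skipping")
        return pair
    for label, seq in (("mate1", pair.mate1_seq), ("mate2", pair.mate2_seq)):
        if len(seq) <= trim_len:
            raise ValueError(
                f"pair {pair.pair_id} {label} is <= {trim_len} nt; "
                "cannot trim a degenerate read"
            )
    return replace(
        pair,
        mate1_seq=pair.mate1_seq[trim_len:],
        mate2_seq=pair.mate2_seq[trim_len:],
        mate1_qual=pair.mate1_qual[trim_len:],
        mate2_qual=pair.mate2_qual[trim_len:],
        mate1_trimmed=True,
        mate2_trimmed=True,
    )


def read_loci_bed(path) -> list[LocusInterval]:
    """Read locus intervals from a BED file (contig, start, end, name)."""
    loci = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs 4 columns")
            loci.append(LocusInterval(
                fields[0], int(fields[1]), int(fields[2]), fields[3]
            ))
    return loci
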