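"""File IO: FASTA/FASTQ writers, germline FASTA reader, AIRR-style TSV."""

from __future__ import annotations

import gzip
import re
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import VdjCall
from .simulate import FastqRead, GermlineReference, GermlineSegment

AIRR_COLUMNS = (
    "sequence_id", "v_call", "d_call", "j_call",
    "v_identity", "v_mutations", "pass", "fail_reasons",
)


def _open_text(path, mode="wt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""))


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in records]
    with _open_text(path) as handle:
        SeqIO.write(seq_records, handle, "fasta")


def write_fastq(path, reads: Sequence[FastqRead]) -> None:
    with _open_text(path) as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


_CLASS_RE = re.compile(r"IGH([VDJ])", re.IGNORECASE)


def read_germline_fasta(path, igh_contig_name: str = "igh_synth") -> GermlineReference:
    """Load a germline reference from FASTA.

    The locus class of each segment is inferred from its name (IMGT
    convention: IGHV*/IGHD*/IGHJ*).  Contig offsets are laid out in file
    order, matching the simulator's synthetic-contig convention.
    """
    from .simulate import CONTIG_SPACER

    segments: dict[str, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _CLASS_RE.search(rec.id)
        if not m:
            raise ValueError(
                f"cannot infer V/D/J class from segment name {rec.id!r}"
            )
        cls = m.group(1).upper()
        segments[cls].append(GermlineSegment(rec.id, cls, str(rec.seq).upper()))
    offsets = {}
    cursor = CONTIG_SPACER
    for cls in ("V", "D", "J"):
        for seg in segments[cls]:
            offsets[seg.name] = (cursor, cursor + len(seg.sequence))
            cursor += len(seg.sequence) + CONTIG_SPACER
    return GermlineReference(segments, igh_contig_name, offsets)


def write_calls_tsv(path, calls: Sequence[VdjCall]) -> None:
    """AIRR-style rearrangement TSV, one row per read pair."""
    rows = []
    for call in calls:
        rows.append({
            "sequence_id": call.pair_id,
            "v_call": call.v_gene or "",
            "d_call": call.d_gene or "",
            "j_call": call.j_gene or "",
            "v_identity": (round(call.v_identity, 3)
                           if call.v_identity is not None else ""),
            "v_mutations": ",".join(map(str, call.per_read_v_mutations)),
            "pass": call.passed_filters,
            "fail_reasons": ";".join(call.fail_reasons),
        })
    pd.DataFrame(rows, columns=list(AIRR_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_calls_tsv(path) -> list[VdjCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    calls = []
    for _, row in df.iterrows():
        muts = [int(x) for x in str(row["v_mutations"]).split(",") if x != ""]
        fails = [f for f in str(row["fail_reasons"]).split(";") if f]
        calls.append(VdjCall(
            pair_id=str(row["sequence_id"]),
            v_gene=row["v_call"] or None,
            d_gene=row["d_call"] or None,
            j_gene=row["j_call"] or None,
            v_identity=float(row["v_identity"]) if row["v_identity"] != "" else None,
            per_read_v_mutations=muts,
            fail_reasons=fails,
        ))
    return calls
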