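"""Local alignment of reads against germline segments.

A thin, deterministic wrapper around :class:`Bio.Align.PairwiseAligner`
(Smith-Waterman local mode with affine gaps).  Identity is computed over
aligned columns, with gap columns counted as non-matching; ``N`` never
matches anything, including itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring. A gap of length L scores gap_open + (L-1)*gap_extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


@dataclass
class SegmentHit:
    """One read-vs-germline-segment local alignment result.

    ``identity`` is 100 * matches / aligned_columns where aligned_columns
    include internal gap columns.  ``mismatch_positions`` are 0-based
    segment coordinates of substituted columns; gap columns are tallied
    separately in ``gap_columns``.
    """

    segment_name: str
    locus_class: str
    score: float
    identity: float
    aligned_len: int
    read_interval: tuple[int, int]
    segment_interval: tuple[int, int]
    mismatch_positions: list[int] = field(default_factory=list)
    gap_columns: int = 0
    matches: int = 0
    aligned_columns: int = 0
    strand: str = "+"

    @property
    def mutations(self) -> int:
        """Substitutions plus gap columns — the per-hit mutation count."""
        return len(self.mismatch_positions) + self.gap_columns


@lru_cache(maxsize=8)
def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            matrix[a, b] = scoring.match if (a == b and a != "N") else scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def local_align(
    read_seq: str,
    segment_seq: str,
    scoring: AlignScoring = AlignScoring(),
    *,
    segment_name: str = "",
    locus_class: str = "",
    strand: str = "+",
) -> SegmentHit:
    """Optimal local alignment of ``read_seq`` against ``segment_seq``.

    Returns a :class:`SegmentHit`; a hit with ``aligned_len == 0`` means no
    positively scoring local alignment exists.
    """
    if not read_seq or not segment_seq:
        raise ValueError("sequences must be non-empty")
    read_seq = read_seq.upper()
    segment_seq = segment_seq.upper()
    for seq in (read_seq, segment_seq):
        if any(c not in ALPHABET for c in seq):
            raise ValueError("sequence alphabet must be ACGTN")

    alignments = _aligner(scoring).align(read_seq, segment_seq)
    if alignments.score <= 0:
        return SegmentHit(segment_name, locus_class, 0.0, 0.0, 0, (0, 0), (0, 0),
                          strand=strand)
    aln = alignments[0]  # deterministic first traceback
    blocks_read, blocks_seg = aln.aligned

    matches = 0
    mismatch_positions: list[int] = []
    for (r0, r1), (s0, s1) in zip(blocks_read, blocks_seg):
        for i in range(r1 - r0):
            if read_seq[r0 + i] == segment_seq[s0 + i] and read_seq[r0 + i] != "N":
                matches += 1
            else:
                mismatch_positions.append(int(s0 + i))
    read_span = (int(blocks_read[0][0]), int(blocks_read[-1][1]))
    seg_span = (int(blocks_seg[0][0]), int(blocks_seg[-1][1]))
    block_cols = int(sum(r1 - r0 for r0, r1 in blocks_read))
    # internal gap columns = total span advance not covered by aligned blocks
    gap_cols = ((read_span[1] - read_span[0]) - block_cols) + (
        (seg_span[1] - seg_span[0]) - block_cols
    )
    aligned_columns = block_cols + gap_cols
    identity = 100.0 * matches / aligned_columns if aligned_columns else 0.0
    return SegmentHit(
        segment_name=segment_name,
        locus_class=locus_class,
        score=float(alignments.score),
        identity=identity,
        aligned_len=read_span[1] - read_span[0],
        read_interval=read_span,
        segment_interval=seg_span,
        mismatch_positions=mismatch_positions,
        gap_columns=gap_cols,
        matches=matches,
        aligned_columns=aligned_columns,
        strand=strand,
    )


def longest_exact_run(hit: SegmentHit, read_seq: str, segment_seq: str) -> int:
    """Length of the longest run of consecutive matching aligned columns."""
    read_seq = read_seq.upper()
    segment_seq = segment_seq.upper()
    best = run = 0
    # re-derive columns from the recorded intervals and mismatches
    mism = set(hit.mismatch_positions)
    s0, s1 = hit.segment_interval
    r0, r1 = hit.read_interval
    # walk the segment interval; a gap anywhere breaks the run, so recompute
    # runs only over contiguous match columns using the stored alignment shape
    # via a fresh comparison of the two spans when they are gap-free
    if hit.gap_columns == 0 and (s1 - s0) == (r1 - r0):
        for i in range(s1 - s0):
            if (s0 + i) not in mism:
                run += 1
                best = max(best, run)
            else:
                run = 0
        return best
    # gapped: fall back to longest common substring within the aligned spans
    a = read_seq[r0:r1]
    b = segment_seq[s0:s1]
    return _longest_common_substring(a, b)


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1] and ai != "N":
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best
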