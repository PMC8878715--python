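"""Synthetic B-cell repertoire and count-matrix generator.

Emulates the data the analysis pipeline consumes: a germline V/D/J
reference, rearranged and somatically hypermutated IGH transcripts from a
mixed naive/memory population, 100 x 2 paired-end reads with SAM
placements on a synthetic IGH contig, and negative-binomial count
matrices over a three-timepoint, three-replicate design with labelled
biotypes and spiked differential expression.  Every generator is a pure
function of its arguments and seed, and records ground truth so that each
downstream stage can be verified against what was planted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# simulator-generated segment length ranges (nt), loosely matching human IGH
SEGMENT_LENGTH_RANGES = {"V": (250, 320), "D": (10, 37), "J": (40, 65)}
CONSTANT_STUB_LEN = 120
CONTIG_SPACER = 100


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GermlineSegment:
    name: str
    locus_class: str  # "V", "D" or "J"
    sequence: str

    def __post_init__(self) -> None:
        if self.locus_class not in ("V", "D", "J"):
            raise ValueError(f"locus_class must be V/D/J, got {self.locus_class!r}")
        if not self.sequence:
            raise ValueError("segment sequence must be non-empty")


@dataclass
class GermlineReference:
    """Named V/D/J segments plus their placement on a synthetic IGH contig."""

    segments: dict[str, list[GermlineSegment]]
    igh_contig_name: str = "igh_synth"
    segment_offsets: dict[str, tuple[int, int]] = field(default_factory=dict)
    constant_stub: str = ""

    def __post_init__(self) -> None:
        names = [s.name for segs in self.segments.values() for s in segs]
        if len(names) != len(set(names)):
            raise ValueError("segment names must be unique within a reference")
        for cls in ("V", "D", "J"):
            if not self.segments.get(cls):
                raise ValueError(f"reference has no {cls} segments")

    def by_class(self, locus_class: str) -> list[GermlineSegment]:
        return self.segments[locus_class]

    def get(self, name: str) -> GermlineSegment:
        for segs in self.segments.values():
            for s in segs:
                if s.name == name:
                    return s
        raise KeyError(name)

    @property
    def contig_length(self) -> int:
        end = max(e for _, e in self.segment_offsets.values())
        return end + CONTIG_SPACER

    def contig_sequence(self) -> str:
        """Synthetic IGH contig: segments at their offsets, A-filled gaps."""
        seq = ["A"] * self.contig_length
        for name, (start, _end) in self.segment_offsets.items():
            s = self.get(name).sequence
            seq[start:start + len(s)] = list(s)
        return "".join(seq)

    def to_fasta(self, path) -> None:
        from . import io as _io
        _io.write_fasta(
            path,
            [(s.name, s.sequence)
             for cls in ("V", "D", "J") for s in self.segments[cls]],
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_germline_reference(
    n_v: int, n_d: int, n_j: int, seed: int, igh_contig_name: str = "igh_synth"
) -> GermlineReference:
    """Random germline reference with ``n_v``/``n_d``/``n_j`` segments.

    Deterministic for a fixed seed.  Segment lengths are drawn uniformly
    from class-specific ranges; names follow IMGT-like conventions
    (IGHV1-1, IGHD2-2, ...) and are unique.
    """
    for label, n in (("n_v", n_v), ("n_d", n_d), ("n_j", n_j)):
        if n < 1:
            raise ValueError(f"{label} must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    segments: dict[str, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
    for cls, n in (("V", n_v), ("D", n_d), ("J", n_j)):
        lo, hi = SEGMENT_LENGTH_RANGES[cls]
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            name = f"IGH{cls}{1 + i % 7}-{i + 1}"
            segments[cls].append(GermlineSegment(name, cls, _random_seq(rng, length)))
    offsets: dict[str, tuple[int, int]] = {}
    cursor = CONTIG_SPACER
    for cls in ("V", "D", "J"):
        for s in segments[cls]:
            offsets[s.name] = (cursor, cursor + len(s.sequence))
            cursor += len(s.sequence) + CONTIG_SPACER
    stub = _random_seq(rng, CONSTANT_STUB_LEN)
    return GermlineReference(segments, igh_contig_name, offsets, stub)


@dataclass
class SimulatedRearrangement:
    """One rearranged IGH transcript with full generative truth."""

    v_name: str
    d_name: str
    j_name: str
    v_trim: int
    d_trim5: int
    d_trim3: int
    j_trim: int
    n1_insert: str
    n2_insert: str
    shm_positions: frozenset[int]  # 0-based positions within the V portion
    transcript_seq: str
    is_mutated_lineage: bool
    v_portion_len: int = 0

    def reconstruct(self, ref: GermlineReference) -> str:
        """Rebuild the transcript from recorded truth (conservation check)."""
        v = ref.get(self.v_name).sequence
        d = ref.get(self.d_name).sequence
        j = ref.get(self.j_name).sequence
        v_part = list(v[: len(v) - self.v_trim])
        for pos in self.shm_positions:
            v_part[pos] = self.transcript_seq[pos]
        d_part = d[self.d_trim5: len(d) - self.d_trim3]
        j_part = j[self.j_trim:]
        return "".join(v_part) + self.n1_insert + d_part + self.n2_insert + \
            j_part + ref.constant_stub


def _weighted_choice(rng, segments: Sequence[GermlineSegment], weights):
    if weights is None:
        idx = rng.integers(len(segments))
        return segments[int(idx)]
    w = np.array([weights.get(s.name, 0.0) for s in segments], dtype=float)
    if w.sum() <= 0:
        raise ValueError("usage weights put no mass on this segment class")
    return segments[int(rng.choice(len(segments), p=w / w.sum()))]


def simulate_rearrangement(
    ref: GermlineReference,
    shm_rate: float,
    mutated: bool,
    seed: int,
    usage_weights: dict[str, float] | None = None,
    max_trim: int = 5,
    max_insert: int = 10,
) -> SimulatedRearrangement:
    """Draw one V(D)J rearrangement with junctional diversity and SHM.

    Trims are uniform on [0, max_trim] nt per junction end and N-insert
    lengths uniform on [0, max_insert] nt, exercising short surviving D
    segments.  If ``mutated``, each base of the V portion is substituted
    independently with probability ``shm_rate`` (somatic hypermutation is
    restricted to the V region, the region whose mutations the pipeline
    counts); unmutated lineages carry no mutations at all.
    """
    if not 0 <= shm_rate <= 0.15:
        raise ValueError("shm_rate must be in [0, 0.15]")
    rng = np.random.default_rng(seed)
    v = _weighted_choice(rng, ref.by_class("V"), usage_weights)
    d = _weighted_choice(rng, ref.by_class("D"), usage_weights)
    j = _weighted_choice(rng, ref.by_class("J"), usage_weights)

    v_trim = int(rng.integers(0, max_trim + 1))
    d_trim5 = int(rng.integers(0, max_trim + 1))
    d_trim3 = int(rng.integers(0, max_trim + 1))
    j_trim = int(rng.integers(0, max_trim + 1))
    n1 = _random_seq(rng, int(rng.integers(0, max_insert + 1)))
    n2 = _random_seq(rng, int(rng.integers(0, max_insert + 1)))

    v_part = list(v.sequence[: len(v.sequence) - v_trim])
    shm_positions: set[int] = set()
    if mutated and shm_rate > 0:
        hits = np.nonzero(rng.random(len(v_part)) < shm_rate)[0]
        for pos in hits:
            orig = v_part[pos]
            alternatives = [b for b in "ACGT" if b != orig]
            v_part[pos] = alternatives[int(rng.integers(3))]
            shm_positions.add(int(pos))
    d_part = d.sequence[d_trim5: len(d.sequence) - d_trim3]
    j_part = j.sequence[j_trim:]
    transcript = "".join(v_part) + n1 + d_part + n2 + j_part + ref.constant_stub
    return SimulatedRearrangement(
        v_name=v.name, d_name=d.name, j_name=j.name,
        v_trim=v_trim, d_trim5=d_trim5, d_trim3=d_trim3, j_trim=j_trim,
        n1_insert=n1, n2_insert=n2,
        shm_positions=frozenset(shm_positions),
        transcript_seq=transcript,
        is_mutated_lineage=bool(mutated),
        v_portion_len=len(v_part),
    )


def simulate_population(
    ref: GermlineReference,
    n_cells: int,
    frac_mutated: float,
    shm_rate: float,
    seed: int,
    usage_weights: dict[str, float] | None = None,
) -> list[SimulatedRearrangement]:
    """A mixed naive/memory population of independent rearrangements.

    Exactly ``round(n_cells * frac_mutated)`` cells (round-half-even) are
    mutated lineages; lineage labels are shuffled so mutation status is
    not confounded with cell index.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 <= frac_mutated <= 1:
        raise ValueError("frac_mutated must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mut = round(n_cells * frac_mutated)
    labels = np.zeros(n_cells, dtype=bool)
    labels[:n_mut] = True
    rng.shuffle(labels)
    cell_seeds = rng.integers(0, 2**31 - 1, size=n_cells)
    return [
        simulate_rearrangement(
            ref, shm_rate, bool(labels[i]), int(cell_seeds[i]),
            usage_weights=usage_weights,
        )
        for i in range(n_cells)
    ]


class FastqRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str


def simulate_paired_reads(
    population: Sequence[SimulatedRearrangement],
    seed: int,
    read_len: int = 100,
    frag_mean: float = 200.0,
    frag_sd: float = 30.0,
    depth_per_cell: int = 2,
    error_rate: float = 0.0,
    add_hexamer: bool = False,
) -> tuple[list[FastqRead], list[FastqRead], pd.DataFrame]:
    """Paired-end reads from transcript fragments, FR orientation.

    Mate 1 is the forward fragment end; mate 2 is the reverse complement
    of the reverse end (the common Illumina convention).  When
    ``add_hexamer`` is set, a random 6-mer replaces the first six bases of
    each raw mate, emulating random-hexamer priming artifacts.  The truth
    table maps every read pair to its source cell, segments, per-mate
    covered V interval (in germline V coordinates) and the number of
    planted V mutations each mate covers.
    """
    if not population:
        raise ValueError("population is empty")
    if read_len < 50:
        raise ValueError("read_len must be >= 50")
    rng = np.random.default_rng(seed)
    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []
    truth_rows = []
    qual = "I" * read_len

    for cell_idx, cell in enumerate(population):
        tlen = len(cell.transcript_seq)
        vlen = cell.v_portion_len
        for rep in range(depth_per_cell):
            frag_len = int(round(rng.normal(frag_mean, frag_sd)))
            frag_len = min(max(frag_len, read_len), tlen)
            start = int(rng.integers(0, tlen - frag_len + 1))
            end = start + frag_len
            m1 = cell.transcript_seq[start:start + read_len]
            m2 = reverse_complement(cell.transcript_seq[end - read_len:end])
            m1, m2 = list(m1), list(m2)
            if error_rate > 0:
                for mate in (m1, m2):
                    errs = np.nonzero(rng.random(read_len) < error_rate)[0]
                    for pos in errs:
                        alt = [b for b in "ACGT" if b != mate[pos]]
                        mate[pos] = alt[int(rng.integers(3))]
            if add_hexamer:
                for mate in (m1, m2):
                    mate[:6] = list(_random_seq(rng, 6))
            read_id = f"cell{cell_idx}_frag{rep}"
            reads1.append(FastqRead(read_id, "".join(m1), qual))
            reads2.append(FastqRead(read_id, "".join(m2), qual))

            m1_v = (min(start, vlen), min(start + read_len, vlen))
            m2_v = (min(end - read_len, vlen), min(end, vlen))
            m1_mut = sum(1 for p in cell.shm_positions if m1_v[0] <= p < m1_v[1])
            m2_mut = sum(1 for p in cell.shm_positions if m2_v[0] <= p < m2_v[1])
            truth_rows.append({
                "read_id": read_id, "cell_index": cell_idx,
                "v_call": cell.v_name, "d_call": cell.d_name,
                "j_call": cell.j_name,
                "is_mutated_lineage": cell.is_mutated_lineage,
                "frag_start": start, "frag_end": end,
                "mate1_v_start": m1_v[0], "mate1_v_end": max(m1_v[0], m1_v[1]),
                "mate2_v_start": m2_v[0], "mate2_v_end": max(m2_v[0], m2_v[1]),
                "mate1_v_mutations": m1_mut, "mate2_v_mutations": m2_mut,
                "total_shm": len(cell.shm_positions),
            })
    return reads1, reads2, pd.DataFrame(truth_rows)


DECOY_CONTIG = "decoy"
DECOY_LENGTH = 10_000


def simulate_sam(
    reads1: Sequence[FastqRead],
    reads2: Sequence[FastqRead],
    truth: pd.DataFrame,
    ref: GermlineReference,
    seed: int = 0,
    decoy_fraction: float = 0.0,
    split_fraction: float = 0.0,
) -> str:
    """Minimal valid SAM text placing simulated pairs on the IGH contig.

    A ``decoy_fraction`` of pairs is placed entirely on a decoy contig
    (both mates), and a further ``split_fraction`` has mate 1 on IGH and
    mate 2 on the decoy — the case where mate rescue must keep both.
    Positions on the IGH contig approximate the fragment's V-segment
    placement; the extractor only needs reference spans, not base-exact
    alignment.
    """
    if len(reads1) != len(reads2) or len(reads1) != len(truth):
        raise ValueError("reads and truth table are inconsistent")
    rng = np.random.default_rng(seed)
    contig_len = ref.contig_length
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{ref.igh_contig_name}\tLN:{contig_len}",
        f"@SQ\tSN:{DECOY_CONTIG}\tLN:{DECOY_LENGTH}",
    ]
    placement = rng.random(len(reads1))
    for i, (r1, r2) in enumerate(zip(reads1, reads2)):
        row = truth.iloc[i]
        v_start, v_end = ref.segment_offsets[row["v_call"]]
        read_len = len(r1.sequence)
        on_decoy = placement[i] < decoy_fraction
        split = (not on_decoy) and placement[i] < decoy_fraction + split_fraction
        if on_decoy:
            rname1 = rname2 = DECOY_CONTIG
            pos1 = int(rng.integers(0, DECOY_LENGTH - 2 * read_len))
            pos2 = pos1 + read_len
        else:
            rname1 = ref.igh_contig_name
            frag_start = int(row["frag_start"])
            pos1 = min(v_start + frag_start, contig_len - 2 * read_len)
            if split:
                rname2 = DECOY_CONTIG
                pos2 = int(rng.integers(0, DECOY_LENGTH - read_len))
            else:
                rname2 = ref.igh_contig_name
                pos2 = pos1 + read_len
        cigar = f"{read_len}M"
        # FR pair: mate1 forward (mate reverse), mate2 reverse
        flag1 = 0x1 | 0x2 | 0x20 | 0x40
        flag2 = 0x1 | 0x2 | 0x10 | 0x80
        rnext1 = "=" if rname1 == rname2 else rname2
        rnext2 = "=" if rname1 == rname2 else rname1
        lines.append("\t".join([
            r1.read_id, str(flag1), rname1, str(pos1 + 1), "60", cigar,
            rnext1, str(pos2 + 1), "0", r1.sequence, r1.quality,
        ]))
        # mate2 SEQ is stored on the forward reference strand
        lines.append("\t".join([
            r2.read_id, str(flag2), rname2, str(pos2 + 1), "60", cigar,
            rnext2, str(pos1 + 1), "0",
            reverse_complement(r2.sequence), r2.quality[::-1],
        ]))
    return "\n".join(lines) + "\n"


# --- count-matrix simulation -------------------------------------------------

#: Default biotype mixture, GENCODE vocabulary, loosely matching the
#: composition of a poly-A bulk transcriptome over a B-cell differentiation
#: time course.
DEFAULT_BIOTYPE_MIX = {
    "protein_coding": 0.60,
    "antisense": 0.09,
    "lincRNA": 0.05,
    "lncRNA": 0.03,
    "miRNA": 0.015,
    "snRNA": 0.005,
    "processed_pseudogene": 0.05,
    "unprocessed_pseudogene": 0.02,
    "IG_V_gene": 0.03,
    "IG_C_gene": 0.01,
    "IG_V_pseudogene": 0.01,
    "misc_RNA": 0.08,
    "TEC": 0.01,
}

TIMEPOINTS = ("D0", "D4", "D10")
CONTRASTS = ("D4_vs_D0", "D10_vs_D0", "D10_vs_D4")


@dataclass
class CountSimTruth:
    de_genes: set[str]
    logfc_truth: dict[str, dict[str, float]]
    dispersion: float
    library_sizes: dict[str, int]


def simulate_count_matrix(
    n_genes: int,
    seed: int,
    biotype_mix: dict[str, float] | None = None,
    n_groups: int = 3,
    n_reps: int = 3,
    de_fraction: float = 0.1,
    logfc_magnitude: float = 2.0,
    dispersion: float = 0.1,
    mean_log2_expression: float = 6.0,
    libsize_log2_sd: float = 0.25,
    ig_locus_fraction: float = 0.01,
):
    """Negative-binomial counts over a timepoint x replicate design.

    DE genes (a ``de_fraction`` of all genes) receive a progressive group
    effect of magnitude ``logfc_magnitude`` log2 units from the first to
    the last timepoint (half the effect at the middle timepoint), with
    random sign per gene.  Counts are Gamma-Poisson draws so that the
    variance is mu + dispersion * mu^2; ``dispersion == 0`` gives exact
    Poisson counts.  Gene coordinates are drawn over autosomes, with an
    ``ig_locus_fraction`` of genes placed inside the configured Ig locus
    intervals (IGH/IGK/IGL).
    """
    from .extract import DEFAULT_IG_LOCI
    from .expression import CountMatrix

    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    mix = dict(biotype_mix) if biotype_mix is not None else dict(DEFAULT_BIOTYPE_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("biotype_mix proportions must sum to 1")
    if n_groups > len(TIMEPOINTS):
        raise ValueError(f"at most {len(TIMEPOINTS)} timepoints supported")

    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    timepoints = TIMEPOINTS[:n_groups]
    samples = pd.DataFrame([
        {"sample_id": f"{tp}_r{r + 1}", "timepoint": tp, "donor": f"r{r + 1}"}
        for tp in timepoints for r in range(n_reps)
    ])

    base_mu = 2.0 ** rng.normal(mean_log2_expression, 2.0, size=n_genes)
    lib_factor = 2.0 ** rng.normal(0.0, libsize_log2_sd, size=len(samples))

    n_de = int(round(n_genes * de_fraction))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    # progressive effect over the time course: 0, 1/2, 1 of the magnitude
    effect_profile = np.linspace(0.0, 1.0, n_groups)
    log2_effect = np.zeros((n_genes, n_groups))
    for k, g in enumerate(de_idx):
        log2_effect[g] = signs[k] * logfc_magnitude * effect_profile

    group_of_sample = np.array([
        timepoints.index(tp) for tp in samples["timepoint"]
    ])
    mu = (base_mu[:, None]
          * 2.0 ** log2_effect[:, group_of_sample]
          * lib_factor[None, :])
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    biotypes = rng.choice(list(mix.keys()), size=n_genes, p=list(mix.values()))
    contigs = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n_genes)])
    starts = rng.integers(1_000_000, 200_000_000, size=n_genes)
    lengths = rng.integers(1_000, 100_000, size=n_genes)
    n_ig = int(round(n_genes * ig_locus_fraction))
    ig_idx = rng.choice(n_genes, size=n_ig, replace=False)
    for g in ig_idx:
        locus = DEFAULT_IG_LOCI[int(rng.integers(len(DEFAULT_IG_LOCI)))]
        contigs[g] = locus.contig
        span = locus.end - locus.start
        starts[g] = locus.start + int(rng.integers(0, max(span - 50_000, 1)))
        lengths[g] = min(int(lengths[g]), locus.end - starts[g])
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "biotype": biotypes,
        "contig": contigs,
        "start": starts,
        "end": starts + lengths,
    })

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids,
                            columns=samples["sample_id"].tolist()),
        samples=samples,
        genes=genes,
    )
    de_genes = {gene_ids[g] for g in de_idx}
    logfc_truth = {}
    for gid, g in zip(gene_ids, range(n_genes)):
        if gid in de_genes:
            eff = log2_effect[g]
            per_contrast = {}
            if n_groups >= 2:
                per_contrast["D4_vs_D0"] = float(eff[1] - eff[0])
            if n_groups >= 3:
                per_contrast["D10_vs_D0"] = float(eff[2] - eff[0])
                per_contrast["D10_vs_D4"] = float(eff[2] - eff[1])
            logfc_truth[gid] = per_contrast
        else:
            logfc_truth[gid] = {}
    truth = CountSimTruth(
        de_genes=de_genes,
        logfc_truth=logfc_truth,
        dispersion=dispersion,
        library_sizes={
            s: int(matrix.counts[s].sum()) for s in matrix.counts.columns
        },
    )
    return matrix, truth
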