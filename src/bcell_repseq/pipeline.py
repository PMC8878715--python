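"""End-to-end orchestration of the synthetic pipeline stages.

Wires the stages together: simulate a germline reference and population,
sequence it, place reads in SAM, extract IGH pairs, annotate and filter
VDJ calls, and summarize repertoires — plus the count-matrix expression
summary.  Each stage remains independently usable; this module only
provides the plumbing and a manifest recording config hash and seeds.
"""

from __future__ import annotations

import io as _stdio
import json
from pathlib import Path

import pandas as pd

from . import io as _io
from .annotate import annotate_pair
from .config import PipelineConfig
from .expression import classify_biotypes, annotate_ig_locus, de_table
from .extract import LocusInterval, extract_locus_pairs, read_sam, trim_hexamer
from .repertoire import (
    SampleRepertoire, frequency_table, mutation_status, unique_vdj_count,
)
from .simulate import (
    GermlineReference, generate_germline_reference, simulate_count_matrix,
    simulate_paired_reads, simulate_population, simulate_sam,
)

__version__ = "0.1.0"


def synthetic_locus(ref: GermlineReference) -> LocusInterval:
    """The whole synthetic IGH contig as the extraction interval."""
    return LocusInterval(ref.igh_contig_name, 0, ref.contig_length, "IGH")


def calls_from_sam(sam_text: str, ref: GermlineReference,
                   config: PipelineConfig, hexamer_trimmed_input: bool = False):
    """SAM text -> extracted pairs -> collapsed, filtered VDJ calls."""
    records = read_sam(_stdio.StringIO(sam_text))
    pairs = extract_locus_pairs(records, synthetic_locus(ref))
    if hexamer_trimmed_input and config.hexamer_trim_len > 0:
        pairs = [trim_hexamer(p, config.hexamer_trim_len) for p in pairs]
    calls = [
        annotate_pair(
            p.mate1_seq, p.mate2_seq, ref, pair_id=p.pair_id,
            scoring=config.scoring(), min_d_match=config.min_d_match,
            min_hit_score=config.min_hit_score,
            min_read_cov=config.min_read_cov, require_d=config.require_d,
        )
        for p in pairs
    ]
    from .annotate import filter_calls
    return filter_calls(calls, config.min_v_identity)


def simulate_sample(
    ref: GermlineReference,
    config: PipelineConfig,
    n_cells: int,
    frac_mutated: float,
    shm_rate: float,
    seed: int,
    depth_per_cell: int = 1,
    error_rate: float = 0.0,
    add_hexamer: bool = False,
):
    """Simulate one sample end to end; returns (passing, failing, truth)."""
    pop = simulate_population(ref, n_cells, frac_mutated, shm_rate, seed)
    reads1, reads2, truth = simulate_paired_reads(
        pop, seed=seed + 1, depth_per_cell=depth_per_cell,
        error_rate=error_rate, add_hexamer=add_hexamer,
    )
    sam = simulate_sam(reads1, reads2, truth, ref, seed=seed + 2)
    passing, failing = calls_from_sam(
        sam, ref, config, hexamer_trimmed_input=add_hexamer
    )
    return passing, failing, truth


#: The simulated study conditions: UM fraction of the population at each
#: timepoint.  D0 resting B cells are mostly naive (unmutated); the
#: differentiation steps preferentially expand mutated (memory) lineages.
DEFAULT_UM_FRACTIONS = {"D0": 0.8, "D4": 0.3, "D10": 0.15}
DEFAULT_SHM_RATE = 0.04


def run_pipeline(
    config: PipelineConfig,
    outdir,
    n_cells: int = 120,
    n_donors: int = 3,
    shm_rate: float = DEFAULT_SHM_RATE,
    um_fractions: dict[str, float] | None = None,
    n_genes: int = 400,
    n_segments: tuple[int, int, int] = (8, 6, 4),
) -> dict:
    """All-synthetic demo run writing every output file plus a manifest.

    Simulates ``n_donors`` donors at three timepoints with a shrinking
    unmutated fraction, runs extraction/annotation/repertoire summaries,
    and an NB count matrix through the expression summary.  Deterministic
    for a fixed config seed; returns the summary dict it also writes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    um_fractions = dict(um_fractions or DEFAULT_UM_FRACTIONS)
    seed = config.seed

    ref = generate_germline_reference(*n_segments, seed=seed)
    ref.to_fasta(outdir / "germline.fasta")

    reps = []
    sample_rows = []
    for d in range(n_donors):
        for t, (tp, um) in enumerate(um_fractions.items()):
            sample_id = f"{tp}_donor{d + 1}"
            sample_seed = seed + 1000 * (d + 1) + 10 * t
            passing, failing, _ = simulate_sample(
                ref, config, n_cells, 1.0 - um, shm_rate, sample_seed,
            )
            _io.write_calls_tsv(outdir / f"calls_{sample_id}.tsv",
                                passing + failing)
            rep = SampleRepertoire(sample_id, tp, f"donor{d + 1}", passing)
            reps.append(rep)
            status = mutation_status(rep, config.um_threshold)
            sample_rows.append({
                "sample_id": sample_id, "timepoint": tp,
                "donor": f"donor{d + 1}",
                "n_passing": len(passing), "n_failing": len(failing),
                "unique_vdj": unique_vdj_count(rep),
                "pct_um": status.pct_um, "pct_m": status.pct_m,
            })
    summary = pd.DataFrame(sample_rows)
    summary.to_csv(outdir / "repertoire_summary.tsv", sep="\t", index=False)
    freq = frequency_table(reps)
    freq.freq.rename_axis("combination").to_csv(
        outdir / "vdj_frequencies.tsv", sep="\t"
    )

    matrix, truth = simulate_count_matrix(n_genes=n_genes, seed=seed + 77)
    de = de_table(matrix, config.fc_threshold, config.fdr_threshold)
    de.rename_axis("gene_id").to_csv(outdir / "de_table.tsv", sep="\t")
    de_genes = matrix.genes.set_index("gene_id").loc[de.index[de["is_de"]]]
    biotype = classify_biotypes(de_genes["biotype"])
    biotype.to_frame().to_csv(outdir / "biotype_summary.tsv", sep="\t",
                              index=False)
    ig_anno = annotate_ig_locus(matrix.genes, config.loci)
    ig_anno.to_csv(outdir / "ig_locus_annotation.tsv", sep="\t", index=False)

    manifest = {
        "config_hash": config.content_hash(),
        "seed": seed,
        "version": __version__,
        "n_cells": n_cells,
        "n_donors": n_donors,
        "n_genes": n_genes,
        "um_fractions": um_fractions,
        "shm_rate": shm_rate,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)

    return {
        "samples": summary,
        "n_de": int(de["is_de"].sum()),
        "n_truth_de": len(truth.de_genes),
        "biotype": biotype,
        "manifest": manifest,
    }
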