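"""Repertoire statistics across a differentiation time course.

Simulates three timepoints (resting B cells, plasmablasts, plasma
cells) for three donors with a shrinking unmutated fraction, and
computes the repertoire summaries: unique VDJ combinations, percent
unmutated (UM) transcripts, and a per-combination paired t-test for
frequency shifts between the first and last timepoint.
"""

from bcell_repseq import PipelineConfig, generate_germline_reference
from bcell_repseq.pipeline import simulate_sample
from bcell_repseq.repertoire import (
    SampleRepertoire, frequency_shift_test, frequency_table,
    mutation_status, unique_vdj_count,
)

config = PipelineConfig()
ref = generate_germline_reference(8, 6, 4, seed=1)
um_by_timepoint = {"D0": 0.8, "D4": 0.3, "D10": 0.15}

reps = []
for d in range(3):
    for i, (tp, um) in enumerate(um_by_timepoint.items()):
        passing, _, _ = simulate_sample(
            ref, config, n_cells=120, frac_mutated=1.0 - um, shm_rate=0.04,
            seed=1000 * (d + 1) + i, depth_per_cell=1,
        )
        reps.append(SampleRepertoire(f"{tp}_donor{d+1}", tp,
                                     f"donor{d+1}", passing))

print("sample            calls  uniqueVDJ  pct_UM")
for rep in reps:
    status = mutation_status(rep, config.um_threshold)
    print(f"{rep.sample_id:<17} {len(rep.calls):>5} "
          f"{unique_vdj_count(rep):>9}  {status.pct_um:>6}")
print("(pct_UM decreases with differentiation: mutated/memory lineages "
      "dominate the later timepoints)")

table = frequency_table(reps)
result = frequency_shift_test(table, "D0", "D10",
                              alpha=config.alpha, min_shift=config.min_shift)
flagged = result[result["flagged"]]
print(f"\nfrequency shift D0 -> D10: {len(result)} combinations tested, "
      f"{len(flagged)} with a significant shift > "
      f"{100 * config.min_shift:.0f}%")
print("(segment usage is uniform at every timepoint, so no individual "
      "combination should change its relative frequency)")
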