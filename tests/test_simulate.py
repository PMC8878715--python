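"""Generator tests: determinism, conservation, and moment checks."""

import numpy as np
import pandas as pd
import pytest

from bcell_repseq.extract import extract_locus_pairs, read_sam
from bcell_repseq.pipeline import synthetic_locus
from bcell_repseq.simulate import (
    SEGMENT_LENGTH_RANGES, generate_germline_reference, reverse_complement,
    simulate_count_matrix, simulate_paired_reads, simulate_population,
    simulate_rearrangement, simulate_sam,
)
import io as stdio


class TestGermlineReference:
    def test_counts_names_and_length_ranges(self):
        ref = generate_germline_reference(5, 3, 2, seed=1)
        names = [s.name for c in "VDJ" for s in ref.by_class(c)]
        assert len(names) == 10 and len(set(names)) == 10
        for cls in "VDJ":
            lo, hi = SEGMENT_LENGTH_RANGES[cls]
            for seg in ref.by_class(cls):
                assert lo <= len(seg.sequence) <= hi

    def test_seeded_determinism_byte_identical_fasta(self, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        generate_germline_reference(5, 3, 2, seed=9).to_fasta(p1)
        generate_germline_reference(5, 3, 2, seed=9).to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()
        p3 = tmp_path / "c.fasta"
        generate_germline_reference(5, 3, 2, seed=10).to_fasta(p3)
        assert p1.read_bytes() != p3.read_bytes()

    @pytest.mark.parametrize("nv,nd,nj", [(0, 3, 2), (5, 0, 2), (5, 3, -1)])
    def test_nonpositive_counts_rejected(self, nv, nd, nj):
        with pytest.raises(ValueError):
            generate_germline_reference(nv, nd, nj, seed=1)

    def test_offsets_non_overlapping(self):
        ref = generate_germline_reference(6, 4, 3, seed=3)
        spans = sorted(ref.segment_offsets.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestRearrangement:
    def test_unmutated_has_exact_germline_v_prefix(self, ref):
        r = simulate_rearrangement(ref, shm_rate=0.05, mutated=False, seed=4)
        assert r.shm_positions == frozenset()
        v = ref.get(r.v_name).sequence
        assert r.transcript_seq.startswith(v[: len(v) - r.v_trim])

    def test_usage_weights_force_combination(self, ref):
        v = ref.by_class("V")[0].name
        d = ref.by_class("D")[0].name
        j = ref.by_class("J")[0].name
        w = {v: 1.0, d: 1.0, j: 1.0}
        for seed in range(10):
            r = simulate_rearrangement(ref, 0.0, False, seed, usage_weights=w)
            assert (r.v_name, r.d_name, r.j_name) == (v, d, j)

    def test_shm_count_matches_binomial_mean(self, ref):
        """Mean planted mutation count ~ Binomial(v_len, rate) within 3 SE."""
        rate, n_draws = 0.05, 2000
        counts, v_lens = [], []
        for seed in range(n_draws):
            r = simulate_rearrangement(ref, rate, True, seed)
            counts.append(len(r.shm_positions))
            v_lens.append(r.v_portion_len)
        expected = rate * np.mean(v_lens)
        se = np.sqrt(np.mean(v_lens) * rate * (1 - rate) / n_draws)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_conservation_reconstruct(self, ref):
        """Recorded trims/inserts/mutations rebuild the transcript exactly."""
        for seed in range(50):
            r = simulate_rearrangement(ref, 0.08, seed % 2 == 0, seed)
            assert r.reconstruct(ref) == r.transcript_seq

    def test_shm_rate_bounds(self, ref):
        with pytest.raises(ValueError):
            simulate_rearrangement(ref, 0.2, True, seed=1)


class TestPopulation:
    def test_frac_mutated_zero_all_um(self, ref):
        pop = simulate_population(ref, 20, 0.0, 0.05, seed=1)
        assert not any(r.is_mutated_lineage for r in pop)
        assert all(r.shm_positions == frozenset() for r in pop)

    def test_rounding_rule(self, ref):
        pop = simulate_population(ref, 10, 0.7, 0.05, seed=1)
        assert sum(r.is_mutated_lineage for r in pop) == 7
        # round-half-even: 0.5 * 5 = 2.5 -> 2
        pop = simulate_population(ref, 5, 0.5, 0.05, seed=1)
        assert sum(r.is_mutated_lineage for r in pop) == 2

    def test_all_mutated_mean_matches_binomial(self, ref):
        rate = 0.04
        pop = simulate_population(ref, 1000, 1.0, rate, seed=2)
        counts = [len(r.shm_positions) for r in pop]
        v_lens = [r.v_portion_len for r in pop]
        expected = rate * np.mean(v_lens)
        se = np.sqrt(np.mean(v_lens) * rate * (1 - rate) / len(pop))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_bad_args(self, ref):
        with pytest.raises(ValueError):
            simulate_population(ref, 0, 0.5, 0.04, seed=1)
        with pytest.raises(ValueError):
            simulate_population(ref, 10, 1.5, 0.04, seed=1)


class TestPairedReads:
    def test_error_free_mates_are_exact_substrings(self, ref):
        pop = simulate_population(ref, 10, 0.5, 0.04, seed=3)
        r1, r2, truth = simulate_paired_reads(pop, seed=4, depth_per_cell=2)
        for a, b, (_, row) in zip(r1, r2, truth.iterrows()):
            t = pop[row["cell_index"]].transcript_seq
            assert a.sequence in t
            assert reverse_complement(b.sequence) in t

    def test_pair_count(self, ref):
        pop = simulate_population(ref, 4, 0.0, 0.0, seed=5)
        r1, r2, truth = simulate_paired_reads(pop, seed=6, depth_per_cell=3)
        assert len(r1) == len(r2) == len(truth) == 12

    def test_hexamer_replacement_rate(self, ref):
        """Each of the first six positions differs from source w.p. 3/4."""
        pop = simulate_population(ref, 100, 0.0, 0.0, seed=7)
        r1, _, truth = simulate_paired_reads(
            pop, seed=8, depth_per_cell=2, add_hexamer=True
        )
        diffs = total = 0
        for a, (_, row) in zip(r1, truth.iterrows()):
            t = pop[row["cell_index"]].transcript_seq
            src = t[row["frag_start"]: row["frag_start"] + 6]
            diffs += sum(x != y for x, y in zip(a.sequence[:6], src))
            total += 6
        p = diffs / total
        se = np.sqrt(0.75 * 0.25 / total)
        assert abs(p - 0.75) < 3 * se

    def test_truth_mutation_counts_consistent(self, ref):
        pop = simulate_population(ref, 50, 1.0, 0.05, seed=9)
        _, _, truth = simulate_paired_reads(pop, seed=10, depth_per_cell=1)
        for _, row in truth.iterrows():
            cell = pop[row["cell_index"]]
            planted = {p for p in cell.shm_positions
                       if row["mate1_v_start"] <= p < row["mate1_v_end"]}
            assert row["mate1_v_mutations"] == len(planted)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            simulate_paired_reads([], seed=1)


class TestSimulatedSam:
    def _pairs_kept(self, ref, decoy_fraction, split_fraction):
        pop = simulate_population(ref, 20, 0.0, 0.0, seed=11)
        r1, r2, truth = simulate_paired_reads(pop, seed=12, depth_per_cell=1)
        sam = simulate_sam(r1, r2, truth, ref, seed=13,
                           decoy_fraction=decoy_fraction,
                           split_fraction=split_fraction)
        records = read_sam(stdio.StringIO(sam))
        return extract_locus_pairs(records, synthetic_locus(ref)), len(r1)

    def test_all_on_igh_all_kept(self, ref):
        kept, n = self._pairs_kept(ref, 0.0, 0.0)
        assert len(kept) == n

    def test_all_on_decoy_none_kept(self, ref):
        kept, _ = self._pairs_kept(ref, 1.0, 0.0)
        assert kept == []

    def test_split_pairs_rescued_with_both_mates(self, ref):
        """One mate on IGH, one on the decoy: the pair is kept whole."""
        kept, n = self._pairs_kept(ref, 0.0, 1.0)
        assert len(kept) == n
        assert all(p.mate1_seq and p.mate2_seq for p in kept)

    def test_extracted_sequences_round_trip(self, ref):
        pop = simulate_population(ref, 10, 0.0, 0.0, seed=14)
        r1, r2, truth = simulate_paired_reads(pop, seed=15, depth_per_cell=1)
        sam = simulate_sam(r1, r2, truth, ref, seed=16)
        kept = extract_locus_pairs(read_sam(stdio.StringIO(sam)),
                                   synthetic_locus(ref))
        by_id = {p.pair_id: p for p in kept}
        for a, b in zip(r1, r2):
            assert by_id[a.read_id].mate1_seq == a.sequence
            assert by_id[a.read_id].mate2_seq == b.sequence


class TestCountMatrix:
    def test_de_fraction_zero_empty_truth(self):
        _, truth = simulate_count_matrix(100, seed=1, de_fraction=0.0)
        assert truth.de_genes == set()
        assert all(v == {} for v in truth.logfc_truth.values())

    def test_poisson_limit_variance_close_to_mean(self):
        """dispersion -> 0: per-gene sample variance tracks the mean."""
        m, _ = simulate_count_matrix(
            2000, seed=2, de_fraction=0.0, dispersion=0.0,
            libsize_log2_sd=0.0, mean_log2_expression=7.0,
        )
        counts = m.counts.to_numpy(dtype=float)
        mean = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        big = mean > 50
        # regression of var on mean should have slope ~ 1 with no mu^2 term
        ratio = np.median(var[big] / mean[big])
        assert 0.9 < ratio < 1.1

    def test_biotype_mix_all_ncrna(self):
        m, _ = simulate_count_matrix(200, seed=3, biotype_mix={"lncRNA": 1.0})
        assert set(m.genes["biotype"]) == {"lncRNA"}

    def test_bad_args(self):
        with pytest.raises(ValueError):
            simulate_count_matrix(100, seed=1, dispersion=-0.1)
        with pytest.raises(ValueError):
            simulate_count_matrix(100, seed=1,
                                  biotype_mix={"protein_coding": 0.5})

    def test_nb_variance_includes_overdispersion(self):
        m, truth = simulate_count_matrix(
            2000, seed=4, de_fraction=0.0, dispersion=0.2,
            libsize_log2_sd=0.0, mean_log2_expression=7.0,
        )
        counts = m.counts.to_numpy(dtype=float)
        mean = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        big = mean > 50
        # var ~ mu + phi mu^2  =>  (var - mu) / mu^2 ~ phi
        phi_hat = np.median((var[big] - mean[big]) / mean[big] ** 2)
        assert 0.1 < phi_hat < 0.3
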