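"""TMM, pseudo-counts, NB test, BH, DE thresholds, biotypes, Ig loci."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from bcell_repseq.expression import (
    CountMatrix, annotate_ig_locus, bh_fdr, call_de, classify_biotypes,
    nb_timecourse_test, pseudo_counts, tmm_factors,
)
from bcell_repseq.extract import LocusInterval
from bcell_repseq.simulate import simulate_count_matrix


def nb_matrix(seed=1, n_genes=300, **kw):
    m, _ = simulate_count_matrix(n_genes, seed=seed, **kw)
    return m


class TestTmm:
    def test_identical_samples_factor_one(self):
        col = np.random.default_rng(1).poisson(50, size=500)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_absorbs_into_library_size(self):
        """2x the same composition: M values all log2(2) relative to raw
        counts but identical relative to library size, so factors stay 1."""
        rng = np.random.default_rng(2)
        col = rng.poisson(100, size=400) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col, "c": col})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_geometric_mean_one_on_random_matrices(self):
        for seed in (3, 4, 5):
            m = nb_matrix(seed=seed, de_fraction=0.3, logfc_magnitude=3.0)
            f = tmm_factors(m.counts)
            assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)

    def test_gene_order_invariance(self):
        m = nb_matrix(seed=6, de_fraction=0.2)
        f1 = tmm_factors(m.counts)
        shuffled = m.counts.sample(frac=1.0, random_state=0)
        f2 = tmm_factors(shuffled)
        assert np.allclose(f1, f2.reindex(f1.index))

    def test_agrees_with_edger_reference(self, tmp_path):
        """Cross-check against edgeR's calcNormFactors on one matrix."""
        m = nb_matrix(seed=9, n_genes=500, de_fraction=0.2,
                      logfc_magnitude=3.0)
        path = tmp_path / "counts.tsv"
        m.counts.to_csv(path, sep="\t")
        res = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(edgeR));'
             f'x <- read.delim("{path}", row.names=1);'
             'cat(calcNormFactors(as.matrix(x), method="TMM"), sep=",")'],
            capture_output=True, text=True, timeout=120,
        )
        assert res.returncode == 0, res.stderr
        edger = np.array([float(v) for v in res.stdout.strip().split(",")])
        ours = tmm_factors(m.counts).to_numpy()
        # implementations differ in trimming details; agree within 5%
        assert np.allclose(ours, edger, rtol=0.05)


class TestPseudoCounts:
    def test_equal_libraries_unchanged(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [30, 20, 10]})
        factors = pd.Series({"a": 1.0, "b": 1.0})
        out = pseudo_counts(counts, factors)
        assert np.allclose(out, counts)

    def test_doubled_library_scaled_back_to_parity(self):
        base = np.array([10, 20, 30, 40])
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        factors = pd.Series({"a": 1.0, "b": 1.0})
        out = pseudo_counts(counts, factors)
        assert np.allclose(out["a"], out["b"])

    def test_row_order_preserved(self):
        m = nb_matrix(seed=7)
        out = pseudo_counts(m.counts, tmm_factors(m.counts))
        assert list(out.index) == list(m.counts.index)


class TestNbTimecourse:
    def test_constant_gene_p_near_one(self):
        counts = pd.DataFrame(
            {f"{tp}_r{r}": [100, 5, 80] for tp in ("D0", "D4", "D10")
             for r in range(3)}
        )
        groups = pd.Series({c: c.split("_")[0] for c in counts.columns})
        res = nb_timecourse_test(counts, groups)
        assert (res["p_value"] > 0.9).all()

    def test_all_zero_gene_p_one(self):
        m = nb_matrix(seed=8, n_genes=50, de_fraction=0.0)
        counts = m.counts.copy()
        counts.iloc[0] = 0
        res = nb_timecourse_test(counts, m.groups())
        assert res["p_value"].iloc[0] == 1.0

    def test_newton_fit_matches_statsmodels_glm(self):
        """The group-means NB fit agrees with statsmodels' GLM."""
        import statsmodels.api as sm
        from bcell_repseq.expression import _fit_group_means

        rng = np.random.default_rng(10)
        y = rng.poisson([40, 50, 45, 90, 110, 100, 20, 25, 30]).astype(float)
        offsets = np.log(rng.uniform(0.8, 1.2, size=9))
        groups_idx = np.repeat([0, 1, 2], 3)
        phi = 0.1
        beta = _fit_group_means(y, offsets, groups_idx, 3, phi)
        X = pd.get_dummies(pd.Series(groups_idx)).to_numpy(dtype=float)
        glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=phi),
                     offset=offsets).fit()
        assert np.allclose(beta, glm.params, atol=1e-5)

    def test_strong_effect_detected(self):
        m, truth = simulate_count_matrix(
            300, seed=11, de_fraction=0.1, logfc_magnitude=4.0,
            dispersion=0.1,
        )
        res = nb_timecourse_test(m.counts, m.groups())
        de_p = res.loc[sorted(truth.de_genes), "p_value"]
        assert (de_p < 0.01).mean() > 0.9


class TestBhFdr:
    def brute_force_bh(self, p):
        """Textbook step-up: q_i = min over j>=i of p_(j) * n / j."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adjusted = np.empty(n)
        running_min = 1.0
        for rank in range(n, 0, -1):
            idx = order[rank - 1]
            running_min = min(running_min, p[idx] * n / rank)
            adjusted[idx] = running_min
        return adjusted

    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.42])[0] == pytest.approx(0.42)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), self.brute_force_bh(p))

    def test_bounds_property(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert (q >= p).all() and (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestCallDe:
    @pytest.mark.parametrize("fc,fdr,expected", [
        (2.0, 0.05, True),    # both boundaries inclusive
        (-2.0, 0.05, True),   # two-sided fold change
        (1.99, 0.001, False),
        (5.0, 0.06, False),
    ])
    def test_threshold_boundaries(self, fc, fdr, expected):
        log2fc = pd.DataFrame({"log2fc_D10_vs_D0": [fc]}, index=["g"])
        assert call_de(log2fc, np.array([fdr]))["g"] == expected


class TestBiotypes:
    def test_category_partition_and_percentages(self):
        biotypes = (["protein_coding"] * 50 + ["antisense"] * 20 +
                    ["IG_V_gene"] * 10 + ["processed_pseudogene"] * 15 +
                    ["misc_RNA"] * 5)
        summary = classify_biotypes(biotypes)
        assert summary.total == 100
        assert sum(n for n, _ in summary.categories.values()) == 100
        assert summary.count("non_Ig_protein_coding") == 50
        assert summary.percent("ncRNA") == 20.0
        assert summary.ncrna_sub["antisense"] == (20, 100.0)
        pct_sum = sum(p for _, p in summary.categories.values())
        assert abs(pct_sum - 100.0) <= 0.3

    def test_ig_pseudogene_is_ig_related_not_pseudogene(self):
        summary = classify_biotypes(["IG_V_pseudogene"])
        assert summary.count("Ig_related") == 1
        assert summary.count("pseudogene") == 0

    def test_unknown_biotype_routed_to_misc_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            summary = classify_biotypes(["weird_biotype"])
        assert summary.count("misc_RNA") == 1
        assert "weird_biotype" in caplog.text

    def test_empty_input_explicit_empty_summary(self):
        summary = classify_biotypes([])
        assert summary.total == 0
        assert all(n == 0 for n, _ in summary.categories.values())


class TestIgLocusAnnotation:
    LOCI = [LocusInterval("chr14", 1000, 2000, "IGH"),
            LocusInterval("chr22", 500, 900, "IGL")]

    def test_inside_and_abutting(self):
        genes = pd.DataFrame([
            {"gene_id": "in", "contig": "chr14", "start": 1500, "end": 1600},
            {"gene_id": "abut", "contig": "chr14", "start": 2000, "end": 2100},
            {"gene_id": "off", "contig": "chr5", "start": 1500, "end": 1600},
        ])
        out = annotate_ig_locus(genes, self.LOCI).set_index("gene_id")
        assert out.loc["in", "in_ig_locus"] and \
            out.loc["in", "ig_locus"] == "IGH"
        assert not out.loc["abut", "in_ig_locus"]  # half-open
        assert not out.loc["off", "in_ig_locus"]

    def test_brute_force_oracle_on_random_intervals(self):
        rng = np.random.default_rng(14)
        contigs = rng.choice(["chr14", "chr22", "chr5"], size=1000)
        starts = rng.integers(0, 3000, size=1000)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(1000)],
            "contig": contigs,
            "start": starts,
            "end": starts + rng.integers(1, 500, size=1000),
        })
        out = annotate_ig_locus(genes, self.LOCI)
        for _, gene, res in zip(range(1000), genes.itertuples(),
                                out.itertuples()):
            expected = any(
                locus.contig == gene.contig and gene.start < locus.end
                and locus.start < gene.end
                for locus in self.LOCI
            )
            assert res.in_ig_locus == expected


def test_count_matrix_validation():
    counts = pd.DataFrame({"a": [1, -2]}, index=["g1", "g2"])
    samples = pd.DataFrame([{"sample_id": "a", "timepoint": "D0",
                             "donor": "d1"}])
    genes = pd.DataFrame([{"gene_id": g, "biotype": "protein_coding",
                           "contig": "chr1", "start": 0, "end": 10}
                          for g in ("g1", "g2")])
    with pytest.raises(ValueError, match="non-negative"):
        CountMatrix(counts, samples, genes)
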