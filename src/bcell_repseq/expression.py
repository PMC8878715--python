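"""Count-matrix expression summary.

Implements the expression side of the pipeline: TMM (trimmed mean of
M-values) between-sample normalization, pseudo-counts at a common
effective library size, a negative-binomial likelihood-ratio test across
the three timepoints, Benjamini-Hochberg FDR, differential-expression
thresholding (|log2 FC| >= 2 and FDR <= 0.05 by default), transcript
biotype classification, and Ig-locus overlap annotation.

The NB time-course test is a deliberate simplification of edgeR's
quasi-likelihood F-test: per-gene method-of-moments dispersions shrunk
toward the matrix median, then a likelihood-ratio chi-square test of the
group-means model against the intercept model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .extract import LocusInterval

logger = logging.getLogger(__name__)

CONTRAST_COLUMNS = ("log2fc_D4_vs_D0", "log2fc_D10_vs_D0", "log2fc_D10_vs_D4")


@dataclass
class CountMatrix:
    """Genes x samples integer counts with sample and gene annotation.

    ``samples`` carries (sample_id, timepoint, donor); ``genes`` carries
    (gene_id, biotype, contig, start, end) and must cover every row of
    ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if set(self.counts.columns) != set(self.samples["sample_id"]):
            raise ValueError("sample annotation does not match count columns")
        if not set(self.counts.index).issubset(set(self.genes["gene_id"])):
            raise ValueError("gene annotation must cover every gene")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def groups(self) -> pd.Series:
        """timepoint label per sample, aligned with count columns."""
        lookup = self.samples.set_index("sample_id")["timepoint"]
        return lookup.reindex(self.counts.columns)

    def write_tsv(self, counts_path, genes_path=None, samples_path=None) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        if genes_path is not None:
            self.genes.to_csv(genes_path, sep="\t", index=False)
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path, genes_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        genes = pd.read_csv(genes_path, sep="\t")
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(counts=counts, samples=samples, genes=genes)


# --- TMM normalization -------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (Robinson-Oshlack).

    The reference sample is the one whose upper quartile of scaled counts
    is closest to the mean upper quartile.  For each sample, per-gene
    log2 ratios (M) and average log2 abundances (A) are computed against
    the reference over genes positive in both; the most extreme
    ``trim_m`` of M values and ``trim_a`` of A values are discarded, and
    the factor is the precision-weighted mean of the remaining M values,
    exponentiated.  Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")

    scaled = counts.div(lib, axis=1)
    if reference is None:
        uq = scaled.apply(lambda col: col[col > 0].quantile(0.75))
        reference = (uq - uq.mean()).abs().idxmin()
    ref_col = counts[reference].to_numpy(dtype=float)
    ref_lib = lib[reference]

    factors = {}
    for sample in counts.columns:
        obs = counts[sample].to_numpy(dtype=float)
        if sample == reference:
            factors[sample] = 1.0
            continue
        both = (obs > 0) & (ref_col > 0)
        o, r = obs[both], ref_col[both]
        p_obs, p_ref = o / lib[sample], r / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M — precision weights
        w = (lib[sample] - o) / (lib[sample] * o) + (ref_lib - r) / (ref_lib * r)

        lo_m, hi_m = np.quantile(m, [trim_m / 2, 1 - trim_m / 2])
        lo_a, hi_a = np.quantile(a, [trim_a / 2, 1 - trim_a / 2])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            factors[sample] = 1.0
            continue
        factors[sample] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))

    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())  # geometric mean 1


def effective_library_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    return counts.sum(axis=0) * factors


def pseudo_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Counts rescaled to a common effective library size.

    The target is the geometric mean of the effective library sizes
    (library size x TMM factor), i.e. the equivalent counts had all
    samples been sequenced to the same normalized depth.
    """
    eff = effective_library_sizes(counts, factors).astype(float)
    target = np.exp(np.log(eff).mean())
    return counts.div(eff, axis=1) * target


# --- NB time-course test -----------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    if phi <= 1e-12:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    ))


def _fit_group_means(y, offsets, groups_idx, n_groups, phi, n_iter=25):
    """NB MLE of per-group means with log link and offsets (Newton/IRLS)."""
    beta = np.zeros(n_groups)
    for g in range(n_groups):
        sel = groups_idx == g
        beta[g] = np.log((y[sel].sum() + 0.5) / np.exp(offsets[sel]).sum())
    for _ in range(n_iter):
        mu = np.exp(beta[groups_idx] + offsets)
        w = mu / (1.0 + phi * mu)
        score = np.array([np.sum(((y - mu) / (1 + phi * mu))[groups_idx == g])
                          for g in range(n_groups)])
        info = np.array([np.sum(w[groups_idx == g]) for g in range(n_groups)])
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
    shrink: float = 0.8,
) -> pd.Series:
    """Per-gene NB dispersions, method of moments, shrunk to the median.

    The moment estimate uses the pooled within-group variance of
    normalized counts (residual df = n - g); each gene's estimate is
    averaged with the matrix-median dispersion with weight ``shrink``
    toward the median.  Heavy shrinkage (default 0.8) stabilizes the
    small-sample moment estimates, whose underestimation otherwise makes
    the likelihood-ratio test liberal.
    """
    if factors is None:
        factors = tmm_factors(counts)
    norm = pseudo_counts(counts, factors)
    group_labels = groups.to_numpy()
    uniq = pd.unique(group_labels)
    n, g = norm.shape[1], len(uniq)
    if n - g < 1:
        raise ValueError("need residual degrees of freedom to estimate dispersion")
    mean_all = norm.mean(axis=1).to_numpy()
    ss = np.zeros(len(norm))
    for lab in uniq:
        sub = norm.loc[:, group_labels == lab].to_numpy()
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var_within = ss / (n - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var_within - mean_all) / mean_all**2
    phi = np.where(np.isfinite(phi), phi, 0.0)
    phi = np.clip(phi, 1e-8, 10.0)
    median_phi = float(np.median(phi[mean_all > 1]) if (mean_all > 1).any()
                       else np.median(phi))
    phi_shrunk = (1 - shrink) * phi + shrink * median_phi
    return pd.Series(phi_shrunk, index=norm.index)


def nb_timecourse_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
    dispersion_shrink: float = 0.8,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of group means vs intercept.

    Tests differential expression across all timepoints at once:
    for each gene, the NB model with one mean per group (offset by the
    effective library size) is compared to the intercept-only model by a
    likelihood-ratio chi-square test with (n_groups - 1) degrees of
    freedom.  Genes with all-zero counts get p = 1 by convention.

    Returns a DataFrame with ``p_value`` and per-contrast ``log2fc``
    columns (from moderated group means, prior count 0.5).
    """
    groups = groups.reindex(counts.columns)
    uniq = [g for g in ("D0", "D4", "D10") if g in set(groups)] or \
        sorted(set(groups))
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("need >= 2 replicates per group")
    if factors is None:
        factors = tmm_factors(counts)

    eff = effective_library_sizes(counts, factors).to_numpy(dtype=float)
    offsets = np.log(eff / np.exp(np.log(eff).mean()))
    groups_idx = np.array([uniq.index(g) for g in groups])
    phis = estimate_dispersions(counts, groups, factors,
                                shrink=dispersion_shrink).to_numpy()

    y_all = counts.to_numpy(dtype=float)
    p_values = np.ones(len(counts))
    group_means = np.zeros((len(counts), n_groups))
    for i in range(len(counts)):
        y = y_all[i]
        if y.sum() == 0:
            group_means[i] = 0.0
            continue
        phi = float(phis[i])
        beta_full = _fit_group_means(y, offsets, groups_idx, n_groups, phi)
        beta_null = _fit_group_means(y, offsets, np.zeros(len(y), dtype=int),
                                     1, phi)
        ll_full = _nb_loglik(y, np.exp(beta_full[groups_idx] + offsets), phi)
        ll_null = _nb_loglik(y, np.exp(beta_null[0] + offsets), phi)
        lrt = max(0.0, 2.0 * (ll_full - ll_null))
        p_values[i] = stats.chi2.sf(lrt, df=n_groups - 1)
        group_means[i] = np.exp(beta_full)

    out = pd.DataFrame({"p_value": p_values}, index=counts.index)
    log_means = np.log2(group_means + 0.5)
    contrasts = []
    if n_groups >= 2:
        contrasts.append(("log2fc_D4_vs_D0", 1, 0))
    if n_groups >= 3:
        contrasts.append(("log2fc_D10_vs_D0", 2, 0))
        contrasts.append(("log2fc_D10_vs_D4", 2, 1))
    for name, a, b in contrasts:
        out[name] = log_means[:, a] - log_means[:, b]
    return out


# --- FDR and DE calls --------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    log2fc: pd.DataFrame,
    fdr: pd.Series | np.ndarray,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.Series:
    """DE flag: max |log2FC| over contrasts >= fc AND FDR <= threshold.

    Both boundaries are inclusive; the fold-change rule is two-sided
    (a gene down-regulated by 2 log2 units is differentially expressed).
    """
    max_abs_fc = log2fc.abs().max(axis=1)
    fdr = pd.Series(np.asarray(fdr, dtype=float), index=log2fc.index)
    return (max_abs_fc >= fc_threshold) & (fdr <= fdr_threshold)


def de_table(
    matrix: CountMatrix,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full DE analysis: TMM -> NB test -> BH -> thresholding."""
    factors = tmm_factors(matrix.counts)
    res = nb_timecourse_test(matrix.counts, matrix.groups(), factors)
    res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    fc_cols = [c for c in res.columns if c.startswith("log2fc_")]
    res["is_de"] = call_de(res[fc_cols], res["fdr"], fc_threshold, fdr_threshold)
    return res


# --- biotype classification --------------------------------------------------

CATEGORY_ORDER = (
    "non_Ig_protein_coding", "Ig_related", "ncRNA", "pseudogene", "misc_RNA",
)
NCRNA_SUB_ORDER = ("antisense", "lincRNA", "other_lncRNA", "miRNA", "other")

#: GENCODE biotype -> (category, ncRNA subcategory or None).  Editable.
BIOTYPE_MAP: dict[str, tuple[str, str | None]] = {
    "protein_coding": ("non_Ig_protein_coding", None),
    "antisense": ("ncRNA", "antisense"),
    "lincRNA": ("ncRNA", "lincRNA"),
    "lncRNA": ("ncRNA", "other_lncRNA"),
    "bidirectional_promoter_lncRNA": ("ncRNA", "other_lncRNA"),
    "sense_intronic": ("ncRNA", "other_lncRNA"),
    "sense_overlapping": ("ncRNA", "other_lncRNA"),
    "3prime_overlapping_ncRNA": ("ncRNA", "other_lncRNA"),
    "macro_lncRNA": ("ncRNA", "other_lncRNA"),
    "miRNA": ("ncRNA", "miRNA"),
    "snRNA": ("ncRNA", "other"),
    "snoRNA": ("ncRNA", "other"),
    "scaRNA": ("ncRNA", "other"),
    "misc_RNA": ("misc_RNA", None),
    "TEC": ("misc_RNA", None),
    "ribozyme": ("misc_RNA", None),
    "rRNA": ("misc_RNA", None),
}


def _categorize(biotype: str) -> tuple[str, str | None]:
    if biotype.startswith("IG_") or biotype.startswith("TR_"):
        return ("Ig_related", None)
    if biotype in BIOTYPE_MAP:
        return BIOTYPE_MAP[biotype]
    if biotype.endswith("_pseudogene") or biotype == "pseudogene":
        return ("pseudogene", None)
    logger.warning("unknown biotype %r routed to misc_RNA", biotype)
    return ("misc_RNA", None)


@dataclass
class BiotypeSummary:
    """Category counts and percentages over a DE transcript set."""

    total: int
    categories: dict[str, tuple[int, float]] = field(default_factory=dict)
    ncrna_sub: dict[str, tuple[int, float]] = field(default_factory=dict)

    def count(self, category: str) -> int:
        return self.categories.get(category, (0, 0.0))[0]

    def percent(self, category: str) -> float:
        return self.categories.get(category, (0, 0.0))[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": c, "count": n, "percent": p}
                for c, (n, p) in self.categories.items()]
        return pd.DataFrame(rows)


def classify_biotypes(biotypes) -> BiotypeSummary:
    """Summarize DE transcripts into five biotype categories.

    Percentages are of the total DE set, to one decimal; ncRNA
    subcategory percentages are of the ncRNA subset.  An empty input
    yields an explicit empty summary with zero counts.
    """
    if isinstance(biotypes, pd.DataFrame):
        biotypes = biotypes["biotype"]
    biotypes = list(biotypes)
    total = len(biotypes)
    cat_counts = {c: 0 for c in CATEGORY_ORDER}
    sub_counts = {s: 0 for s in NCRNA_SUB_ORDER}
    for b in biotypes:
        cat, sub = _categorize(str(b))
        cat_counts[cat] += 1
        if sub is not None:
            sub_counts[sub] += 1
    if total == 0:
        return BiotypeSummary(total=0,
                              categories={c: (0, 0.0) for c in CATEGORY_ORDER},
                              ncrna_sub={s: (0, 0.0) for s in NCRNA_SUB_ORDER})
    n_ncrna = cat_counts["ncRNA"]
    categories = {
        c: (n, round(100.0 * n / total, 1)) for c, n in cat_counts.items()
    }
    ncrna_sub = {
        s: (n, round(100.0 * n / n_ncrna, 1) if n_ncrna else 0.0)
        for s, n in sub_counts.items()
    }
    return BiotypeSummary(total=total, categories=categories,
                          ncrna_sub=ncrna_sub)


# --- Ig-locus overlap --------------------------------------------------------

def annotate_ig_locus(
    genes: pd.DataFrame, loci: list[LocusInterval]
) -> pd.DataFrame:
    """Flag genes whose interval intersects an Ig locus (half-open).

    Returns (gene_id, in_ig_locus, ig_locus); genes on contigs without a
    configured locus are simply not in any Ig locus.
    """
    rows = []
    for _, gene in genes.iterrows():
        hit = None
        for locus in loci:
            if locus.overlaps(gene["contig"], int(gene["start"]),
                              int(gene["end"])):
                hit = locus.name
                break
        rows.append({
            "gene_id": gene["gene_id"],
            "in_ig_locus": hit is not None,
            "ig_locus": hit,
        })
    return pd.DataFrame(rows)
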