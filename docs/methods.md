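# Methods

## Scope and model

The package infers the expressed IGH repertoire of a bulk RNA-seq sample
from read pairs overlapping the IGH locus, and summarizes count matrices
from the same experiment. Its statistical object is the *read pair*, not
the cell: bulk RNA-seq cannot attribute transcripts to cells, so all
repertoire statistics (unique VDJ combinations, relative frequencies,
UM/M fractions) are computed over passing calls. Where plasma cells
transcribe far more immunoglobulin per cell than resting B cells, a
combination count is therefore a transcript-detection count, not a clone
count — unique-combination totals are expected to rise with
differentiation for detection reasons alone.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with full truth recording so each stage is verifiable.

**Germline reference.** `n_v`/`n_d`/`n_j` random segments with lengths
drawn uniformly per class: V 250–320 nt, D 10–37 nt, J 40–65 nt (human
IGH ranges). Segments are placed at non-overlapping offsets on a
synthetic contig with 100-nt spacers so that SAM placements and
interval extraction can be exercised end to end.

**Rearrangement.** A transcript is trimmed-V + N1 + trimmed-D + N2 +
trimmed-J + a 120-nt constant-region stub. Junctional trims are uniform
on 0–5 nt per end and N-insert lengths uniform on 0–10 nt with uniform
bases. No published junctional model is assumed; these ranges
deliberately produce short surviving D segments (down to 0 nt), the edge
case that stresses D calling. Somatic hypermutation applies only to the
V portion — the region whose mutations the pipeline counts — as
independent per-base substitution with probability `shm_rate`
(domain [0, 0.15]); unmutated lineages carry exactly zero mutations. The
constant stub exists so that, as in real data, most fragments originate
outside the V(D)J junction.

**Population.** `round(n_cells * frac_mutated)` cells (Python's
round-half-even) are mutated lineages; labels are shuffled against cell
index. Default study conditions for the demo time course are UM
fractions 0.8 / 0.3 / 0.15 at D0 / D4 / D10 with `shm_rate = 0.04` — a
mostly-naive resting compartment whose mutated (memory) lineages are
preferentially expanded by differentiation.

**Reads.** 100 × 2 paired-end reads in FR orientation (mate 1 forward,
mate 2 reverse-complement — the common Illumina convention) from
fragments of Normal(200, 30) nt, clipped to [read_len, transcript];
fragment start uniform. Poly-A RNA libraries of this type have insert
sizes near 200 nt, and the results are insensitive to this choice
within realistic ranges. Optional uniform substitution errors and a
random-hexamer artifact modeled as replacement of the first 6 nt of
each mate (motivating the fixed 6-nt trim downstream). Not modeled:
quality-dependent errors, indels, light chains, isotypes.

**SAM placement.** Minimal valid SAM with the synthetic IGH contig and
one decoy contig; a configurable fraction of pairs is placed wholly on
the decoy and another fraction split IGH/decoy (the mate-rescue case).
Positions approximate the fragment's V-segment placement — the
extractor consumes reference spans, not base-level alignments.

**Count matrices.** Gamma–Poisson (negative binomial) counts with
per-gene lognormal baselines (log2 mean 6, sd 2), lognormal library-size
jitter (log2 sd 0.25), and gene-wise dispersion `phi` so that
Var = mu + phi mu². A `de_fraction` of genes receives a progressive
group effect (0, ½, 1 × `logfc_magnitude` log2 units across the three
timepoints, random sign), mimicking monotone differentiation
trajectories. Biotypes are drawn from a GENCODE-vocabulary mixture
(60 % protein-coding, 19 % ncRNA classes, 7 % pseudogene, 4 % Ig, 9 %
miscellaneous by default) and coordinates over autosomes with a
configurable fraction inside the shipped GRCh38 IGH/IGK/IGL intervals.

## Extraction

Coordinates are 0-based half-open internally; SAM POS is converted on
ingest. A pair is kept iff at least one mate's reference span
(CIGAR M/D/N/=/X consume reference) intersects the locus interval; both
mates are then emitted, including unmapped or other-contig mates.
Secondary (0x100) and supplementary (0x800) records are ignored; more
than two primary records per name is an error. Default Ig intervals
(GRCh38 chr14/chr2/chr22) ship in `extract.DEFAULT_IG_LOCI` and are
fully overridable via BED. The hexamer trim removes a fixed 6 nt from
the 5' end of **both** mates exactly once (guarded by per-mate flags);
whether the original protocol trimmed one or both mates is not
documented, so both-mates is the default and the length is configurable.

## Annotation and filtering

**Alignment.** Smith–Waterman local alignment with affine gaps via
Biopython's `PairwiseAligner`; default scoring +1 / −2 match/mismatch,
−4 gap open, −1 extend (a gap of length L costs open + (L−1)·extend).
`N` matches nothing. Identity is 100 · matches / aligned columns with
internal gap columns counted as non-matching; gap columns also count as
mutations. This is the conservative choice — IMGT-style identity
treats gaps differently — and both the trim and the scoring are
configurable.

**Orientation.** Libraries are treated as unstranded: each mate is
aligned in both orientations against the V set and annotated in the
better strand (ties go forward).

**Confidence.** A class call is confident iff the top hit's score
strictly exceeds the runner-up's — the simplest rule that makes "only
one confident gene per class" checkable; exact ties (e.g. duplicated
segments) are never confident.

**Evidence floor.** V and J hits scoring below 20 (the score of a
perfect 20-nt match) are discarded. Chance local alignments between a
~100-nt read and an unrelated segment score in the low teens; without
the floor, a mate that merely grazes a segment regularly produced
confident-but-wrong calls that contradicted its partner (ambiguity
failures) or matched the wrong segment outright.

**D calling.** D segments are 10–37 nt and junctional trimming erodes
both ends, so two gates apply: a hit must contain a contiguous exact
match ≥ 8 nt (`min_d_match`), and D is searched only in the junction
window between the top V alignment's end and the top J alignment's
start on that mate (IgBLAST-style masking). A mate with neither V nor J
evidence gets no D call. Without the window, segments sharing a chance
8-mer with the constant region or a germline V/J produced systematic
miscalls in whole read sets; with it, simulated error-free calls match
planted truth in ≥ 99 % of pairs across seeds.

**Collapsing.** Per class the call takes the union of the two mates'
confident genes; conflicting confident genes → `AMBIGUOUS_<class>`; a
required class with no confident gene → `INCOMPLETE` (a complete call
requires V, D and J by default; a permissive VJ-only mode exists but is
off). Coverage below 40 aligned nt on either mate → `SHORT_READ`
("aligned coverage" is the union of per-class top-hit read intervals;
the alternative reading — raw read length — would make the filter
vacuous at 100-nt reads). Pooled V identity is total matches over total
aligned V columns across mates whose top V hit is the called gene, and
the 95 % threshold is inclusive (94.9 fails, 95.0 passes). Per-read
V-mutation counts are the substitution-plus-gap columns of each such
mate; a mate without V coverage is omitted, not counted as zero.

## Repertoire statistics

UM is defined as zero pooled V mutations (threshold configurable; the
CLL literature's 98 %-germline-identity convention is an alternative the
threshold can emulate). `mutation_status` partitions calls into
UM + M + excluded (no mutation data). The frequency-shift screen runs a
per-combination paired t-test across donors on (freq_to − freq_from),
flagging combinations with p < alpha **and** |mean shift| > 1 %
absolute; zero-variance differences report p = NA and flag on the mean
alone. No multiple-testing correction is applied by default (it is a
descriptive screen; a BH option exists). Combinations absent from both
timepoints are dropped.

## Expression summary

**TMM.** Reference sample = upper quartile closest to the mean upper
quartile; per-gene M/A values against the reference over genes positive
in both; 30 % M-trim and 5 % A-trim (two-sided); factor =
precision-weighted mean of surviving M values (delta-method weights),
exponentiated; factors rescaled to geometric mean 1. Agreement with the
R reference implementation is within ~3 % on simulated matrices (the
remaining difference is rank-based vs quantile-based trimming).
Pseudo-counts rescale counts to the geometric mean of effective library
sizes (library size × factor).

**NB time-course test.** Per gene, a likelihood-ratio chi-square test
(df = groups − 1) of the NB group-means model against the intercept
model, both fit by Newton iteration on the log scale with effective
library sizes as offsets. Dispersions are per-gene method-of-moments
(pooled within-group variance, df = n − g) clipped to [1e-8, 10] and
shrunk with weight 0.8 toward the matrix median — a deliberate
simplification of quasi-likelihood F-testing; the heavy shrinkage
compensates the downward bias of nine-sample moment estimates, which
would otherwise make the test clearly liberal. At 3 × 3 designs the
chi-square approximation remains mildly liberal (null rejection
≈ 0.06–0.07 at the 0.05 level in simulation) but detects
|log2 FC| = 4 effects with power > 0.95 at FDR 0.05. Genes with all-zero counts get p = 1.

**DE calling.** BH step-up FDR (statsmodels); DE iff max |log2 FC| over
the three contrasts ≥ 2 **and** FDR ≤ 0.05, both inclusive; the
fold-change rule is two-sided because down-regulation counts. Fold
changes come from moderated fitted group means (prior count 0.5).

**Biotypes.** GENCODE strings map to five categories (protein-coding;
IG_*/TR_* → Ig-related, including Ig pseudogenes; antisense / lincRNA /
other lncRNA / miRNA / small RNAs → ncRNA with subcategory; remaining
*_pseudogene → pseudogene; everything else → miscellaneous, with a
warning for unknown strings). Percentages are reported to one decimal;
category counts always partition the input set.

## What passing tests do and do not show

The simulator draws segments uniformly, mutations uniformly within V,
and reads uniformly within transcripts. Real repertoires have heavily
skewed gene usage, hotspot-concentrated SHM, allelic variation between
donor and reference, indel errors and coverage biases — none of which
are modeled. Tests therefore demonstrate that the *pipeline logic* is
correct (extraction, orientation, collapsing, filtering, counting,
normalization, calibration), not that the method is robust to every
artifact of real libraries.

A known property worth stating explicitly: the percent-mutated statistic
is a **biased** estimator of the mutated-lineage fraction. Three
mechanisms thin mutated calls under default conditions
(`shm_rate = 0.04`, 95 % identity filter, ~40–190 covered V columns per
call): the identity filter rejects mutated calls whose covered window
happens to exceed 5 % mismatch (~20–25 % of them); mutations push
marginal alignments below the evidence floor or coverage threshold; and
a mutated transcript whose covered window contains no mutation is
counted unmutated (probability ≈ e^(−0.04·C)). In simulation a
70 %-mutated population reads out at ≈ 61–63 % mutated. The same
mechanisms act on real data processed with these filters, so UM/M
time-course *trends* are faithful while absolute fractions
underestimate mutated prevalence; the acceptance report states the
recovered value rather than correcting it.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `hexamer_trim_len` | 6 nt | 5'-trim per mate before annotation |
| `min_read_cov` | 40 nt | minimum aligned coverage per mate |
| `min_v_identity` | 95 % | pooled V identity floor (inclusive) |
| `min_d_match` | 8 nt | exact contiguous D match floor |
| `min_hit_score` | 20 | V/J alignment evidence floor |
| `um_threshold` | 0 | max pooled V mutations for UM |
| `fc_threshold` | 2 | |log2 FC| floor for DE |
| `fdr_threshold` | 0.05 | BH FDR ceiling for DE |
| `alpha`, `min_shift` | 0.05, 0.01 | frequency-shift screen |
| scoring | +1/−2/−4/−1 | match/mismatch/gap open/extend |

All of these live in `PipelineConfig` (YAML-serializable, content-hashed
into the run manifest) and surface as CLI flags where relevant.
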