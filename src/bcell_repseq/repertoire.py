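"""Repertoire statistics over passing VDJ calls.

Aggregates per-sample calls into unique-VDJ-combination counts, relative
frequency tables, mutated/unmutated (M/UM) fractions, and a per-combination
paired t-test for frequency shifts between timepoints.  Calls — not
cells — are the counting unit: bulk RNA-seq cannot resolve individual
cells, so a combination's frequency is its share of passing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import VdjCall

TIMEPOINT_ORDER = ("D0", "D4", "D10")


@dataclass
class SampleRepertoire:
    sample_id: str
    timepoint: str
    donor_id: str
    calls: list[VdjCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [c.pair_id for c in self.calls if not c.passed_filters]
        if bad:
            raise ValueError(
                f"repertoire {self.sample_id} contains non-passing calls: "
                f"{bad[:3]}..."
            )


@dataclass
class MutationStatusSummary:
    """UM/M partition of a repertoire's calls.

    A call is unmutated (UM) when its pooled V mutation count is at or
    below ``threshold_mutations`` (default 0 — any V mutation makes the
    call M).  Calls without mutation data are excluded and tallied.
    """

    n_um: int
    n_m: int
    n_excluded: int
    threshold_mutations: int

    @property
    def total(self) -> int:
        return self.n_um + self.n_m

    @property
    def pct_um(self) -> float:
        return round(100.0 * self.n_um / self.total, 1) if self.total else float("nan")

    @property
    def pct_m(self) -> float:
        return round(100.0 * self.n_m / self.total, 1) if self.total else float("nan")


def unique_vdj_count(rep: SampleRepertoire) -> int:
    """Number of distinct (V, D, J) combinations among the calls."""
    if not rep.calls:
        warnings.warn(f"repertoire {rep.sample_id} has no calls")
        return 0
    return len({c.combination for c in rep.calls})


def mutation_status(
    rep: SampleRepertoire, threshold_mutations: int = 0
) -> MutationStatusSummary:
    """Partition calls into unmutated (UM) and mutated (M)."""
    n_um = n_m = n_excluded = 0
    for call in rep.calls:
        if not call.per_read_v_mutations:
            n_excluded += 1
        elif sum(call.per_read_v_mutations) <= threshold_mutations:
            n_um += 1
        else:
            n_m += 1
    return MutationStatusSummary(n_um, n_m, n_excluded, threshold_mutations)


@dataclass
class VdjFrequencyTable:
    """Per-sample relative frequency of each VDJ combination.

    ``freq`` is combinations x samples; combinations absent from a
    sample have frequency 0, and every sample column sums to 1.
    """

    freq: pd.DataFrame
    samples: pd.DataFrame  # sample_id, timepoint, donor

    def __post_init__(self) -> None:
        sums = self.freq.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-sample frequencies must sum to 1")


def frequency_table(reps: list[SampleRepertoire]) -> VdjFrequencyTable:
    """Relative frequency of every VDJ combination in every sample."""
    if not reps:
        raise ValueError("no repertoires given")
    counts: dict[str, pd.Series] = {}
    meta = []
    for rep in reps:
        if not rep.calls:
            raise ValueError(f"repertoire {rep.sample_id} has no calls")
        combos = pd.Series([
            "|".join(str(g) for g in c.combination) for c in rep.calls
        ])
        counts[rep.sample_id] = combos.value_counts()
        meta.append({
            "sample_id": rep.sample_id,
            "timepoint": rep.timepoint,
            "donor": rep.donor_id,
        })
    table = pd.DataFrame(counts).fillna(0.0)
    table = table / table.sum(axis=0)
    table = table.sort_index()
    return VdjFrequencyTable(freq=table, samples=pd.DataFrame(meta))


def frequency_shift_test(
    table: VdjFrequencyTable,
    from_timepoint: str = "D0",
    to_timepoint: str = "D10",
    alpha: float = 0.05,
    min_shift: float = 0.01,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Paired t-test per combination for frequency change across donors.

    For each VDJ combination, frequencies are paired by donor between
    the two timepoints and a paired t-test is run on the differences.  A
    combination is flagged when p < alpha AND |mean delta| > min_shift
    (by default a 1% absolute shift).  Zero-variance differences give
    p = NaN and the flag is decided by the mean delta alone.
    Combinations absent from both timepoints of every donor are dropped.
    """
    meta = table.samples
    donors_from = meta.loc[meta["timepoint"] == from_timepoint]
    donors_to = meta.loc[meta["timepoint"] == to_timepoint]
    shared = sorted(set(donors_from["donor"]) & set(donors_to["donor"]))
    if len(shared) < 2:
        raise ValueError(
            "need >= 2 donors sampled at both timepoints for a paired test"
        )
    col_from = {d: donors_from.set_index("donor").loc[d, "sample_id"]
                for d in shared}
    col_to = {d: donors_to.set_index("donor").loc[d, "sample_id"]
              for d in shared}

    rows = []
    for combo, freqs in table.freq.iterrows():
        f_from = np.array([freqs[col_from[d]] for d in shared])
        f_to = np.array([freqs[col_to[d]] for d in shared])
        if np.all(f_from == 0) and np.all(f_to == 0):
            continue
        delta = f_to - f_from
        mean_delta = float(delta.mean())
        if np.ptp(delta) == 0:
            p = float("nan")
            flagged = abs(mean_delta) > min_shift
        else:
            p = float(stats.ttest_rel(f_to, f_from).pvalue)
            flagged = (p < alpha) and (abs(mean_delta) > min_shift)
        rows.append({
            "combination": combo,
            "mean_delta": mean_delta,
            "p_value": p,
            "flagged": flagged,
        })
    result = pd.DataFrame(rows).set_index("combination")
    if bh_correct and len(result):
        from .expression import bh_fdr
        mask = result["p_value"].notna()
        fdr = pd.Series(np.nan, index=result.index)
        if mask.any():
            fdr[mask] = bh_fdr(result.loc[mask, "p_value"].to_numpy())
        result["fdr"] = fdr
        result["flagged"] = (
            (result["fdr"] < alpha) & (result["mean_delta"].abs() > min_shift)
        ).where(mask, result["flagged"])
    return result
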