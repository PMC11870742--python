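"""Differential autoantigen selection and the reproducibility cascade.

The cascade mirrors the discovery analysis: antigens selected by at least
1% of case donors are tested case-vs-control with a tie-corrected
Kruskal-Wallis rank test on log-normalized counts, Benjamini-Hochberg
correction is applied within the tested universe, the case cohort is
split into stratified halves whose hit sets are intersected, and the
reproducible hits can be further filtered by prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._setops import venn_partition
from . import profiles as _profiles

DEFAULT_THRESHOLDS = {
    "min_prevalence": 0.01,
    "p_threshold": 0.05,
    "q_threshold": 0.2,
}

CASE_ENRICHED = "case-enriched"
CONTROL_ENRICHED = "control-enriched"


def kw_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-squared p value.

    Degenerate inputs where every observation is identical return
    ``(0.0, 1.0)``.
    """
    if len(groups) < 2:
        raise ValueError("kw_test needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("kw_test groups must be non-empty")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("kw_test needs at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values.

    ``q_i = min_{j : p_j >= p_i} p_j * m / rank_j``, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p values must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _mean_ranks(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    ranks = stats.rankdata(np.concatenate([case, control]))
    return float(ranks[: len(case)].mean()), float(ranks[len(case) :].mean())


def differential_selection(
    log2cpm: pd.DataFrame,
    calls: _profiles.SelectionCalls,
    meta: pd.DataFrame,
    case_samples: list[str],
    control_samples: list[str],
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Run the filtered Kruskal-Wallis / BH comparison for one contrast.

    Antigens selected by fewer than ``min_prevalence`` of case donors are
    excluded before testing, and BH runs over the tested antigens only.
    Direction is assigned by the higher mean rank; ties count as
    control-enriched.  Returns one row per tested antigen with H, p, q,
    direction, prevalences, and threshold flags.
    """
    opts = dict(DEFAULT_THRESHOLDS)
    opts.update(thresholds or {})
    if not case_samples or not control_samples:
        raise ValueError("both case and control sample lists must be non-empty")

    donor_of = meta.set_index("sample_id")["donor_id"]
    case_donors = donor_of.loc[case_samples].unique()
    control_donors = donor_of.loc[control_samples].unique()

    case_calls = (
        calls.matrix[case_samples].T.groupby(donor_of.loc[case_samples]).max()
    )
    control_calls = (
        calls.matrix[control_samples].T.groupby(donor_of.loc[control_samples]).max()
    )
    case_prev = case_calls.sum(axis=0) / len(case_donors)
    control_prev = control_calls.sum(axis=0) / len(control_donors)

    tested = case_prev.index[case_prev >= opts["min_prevalence"]]
    if len(tested) == 0:
        warnings.warn("no antigens survive the prevalence pre-filter", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "H", "p", "q", "direction", "case_prevalence",
                "control_prevalence", "significant",
            ]
        )

    case_values = log2cpm.loc[tested, case_samples].to_numpy()
    control_values = log2cpm.loc[tested, control_samples].to_numpy()
    rows = []
    for i, antigen in enumerate(tested):
        h, p = kw_test([case_values[i], control_values[i]])
        case_rank, control_rank = _mean_ranks(case_values[i], control_values[i])
        direction = CASE_ENRICHED if case_rank > control_rank else CONTROL_ENRICHED
        rows.append((antigen, h, p, direction))
    result = pd.DataFrame(
        rows, columns=["antigen", "H", "p", "direction"]
    ).set_index("antigen")
    result["q"] = bh_fdr(result["p"].to_numpy())
    result["case_prevalence"] = case_prev.loc[result.index]
    result["control_prevalence"] = control_prev.loc[result.index]
    result["significant"] = (result["p"] < opts["p_threshold"]) & (
        result["q"] < opts["q_threshold"]
    )
    return result[
        ["H", "p", "q", "direction", "case_prevalence", "control_prevalence", "significant"]
    ]


def summarize_significant(result: pd.DataFrame) -> dict[str, int]:
    """Counts of significant antigens by direction plus the total."""
    sig = result[result["significant"]]
    n_case = int((sig["direction"] == CASE_ENRICHED).sum())
    n_control = int((sig["direction"] == CONTROL_ENRICHED).sum())
    return {"case_enriched": n_case, "control_enriched": n_control, "total": n_case + n_control}


def case_hits(result: pd.DataFrame) -> set[str]:
    """Significant case-direction antigens from a differential table."""
    sig = result[result["significant"] & (result["direction"] == CASE_ENRICHED)]
    return set(sig.index)


def reproducibility_partition(hits_1: set, hits_2: set) -> dict[str, set]:
    """Partition two hit sets into unique-to-1 / shared / unique-to-2."""
    hits_1, hits_2 = set(hits_1), set(hits_2)
    return {
        "unique_to_1": hits_1 - hits_2,
        "shared": hits_1 & hits_2,
        "unique_to_2": hits_2 - hits_1,
    }


def split_cohort(
    donors: pd.Series,
    seed: int,
) -> dict[str, int]:
    """Stratified random halves of a donor->subgroup series.

    Within each subgroup donors are shuffled and alternately assigned, so
    an odd subgroup sends its extra donor to set 1; which donor that is
    depends only on the seed.  Returns donor -> set index (1 or 2).
    """
    counts = donors.value_counts()
    if (counts < 2).any():
        raise ValueError("each subgroup needs at least 2 donors to split")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for subgroup in sorted(counts.index):
        members = sorted(donors.index[donors == subgroup])
        rng.shuffle(members)
        for i, donor in enumerate(members):
            assignment[donor] = 1 if i % 2 == 0 else 2
    return assignment


def split_set_reproducibility(
    log2cpm: pd.DataFrame,
    calls: _profiles.SelectionCalls,
    meta: pd.DataFrame,
    case_donor_subgroups: pd.Series,
    control_samples: list[str],
    seed: int = 0,
    month: int | None = 0,
    thresholds: dict | None = None,
) -> tuple[dict[str, int], dict[str, set], dict[str, pd.DataFrame]]:
    """Split cases into stratified halves and intersect their hit sets.

    Each half is compared against the same control samples with
    :func:`differential_selection`; only case-direction hits found by both
    halves are reproducible.  Returns the donor assignment, the
    unique/shared partition, and the per-half result tables.
    """
    assignment = split_cohort(case_donor_subgroups, seed)
    serum = meta[~meta["is_control"]]
    if month is not None:
        serum = serum[serum["month"] == month]
    halves: dict[int, list[str]] = {1: [], 2: []}
    for _, row in serum.iterrows():
        if row["donor_id"] in assignment:
            halves[assignment[row["donor_id"]]].append(row["sample_id"])
    results = {}
    hit_sets = {}
    for half in (1, 2):
        result = differential_selection(
            log2cpm, calls, meta, halves[half], control_samples, thresholds
        )
        results[f"set{half}"] = result
        hit_sets[half] = case_hits(result)
    partition = reproducibility_partition(hit_sets[1], hit_sets[2])
    return assignment, partition, results


def prevalence_filter(
    hits: set, prevalence: pd.Series, min_prevalence: float
) -> set:
    """Retain hits whose case prevalence meets the threshold."""
    return {h for h in hits if prevalence.get(h, 0.0) >= min_prevalence}


@dataclass
class OverlapPartition:
    """Exclusive Venn regions over up to four named antigen sets."""

    set_names: list[str]
    region_counts: dict[frozenset, int]
    region_members: dict[frozenset, set]

    def unique_to(self, name: str) -> set:
        return set(self.region_members.get(frozenset({name}), set()))

    def shared_by_all(self) -> set:
        return set(self.region_members.get(frozenset(self.set_names), set()))

    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def to_dict(self) -> dict:
        return {
            "set_names": self.set_names,
            "regions": {
                "+".join(sorted(k)): sorted(map(str, v))
                for k, v in self.region_members.items()
            },
        }


def subgroup_overlap(hit_sets: dict[str, set]) -> OverlapPartition:
    """Full Venn partition of 2-4 named hit sets."""
    if not (2 <= len(hit_sets) <= 4):
        raise ValueError("subgroup_overlap supports 2 to 4 sets")
    regions = venn_partition(hit_sets)
    return OverlapPartition(
        set_names=list(hit_sets),
        region_counts={k: len(v) for k, v in regions.items()},
        region_members=regions,
    )


def rank_bias_diagnostic(
    hits: set, representation: pd.Series
) -> dict[str, float]:
    """Median and range of hit ranks in the input-library representation.

    Rank 1 is the most represented antigen; ties receive average ranks.
    An unbiased hit set has a median near the middle of the ranking.
    """
    missing = set(hits) - set(representation.index)
    if missing:
        raise KeyError(f"hits absent from the representation ranking: {sorted(missing)[:5]}")
    ranks = pd.Series(
        stats.rankdata(-representation.to_numpy()), index=representation.index
    )
    hit_ranks = ranks.loc[sorted(hits)]
    if hit_ranks.empty:
        raise ValueError("rank_bias_diagnostic needs a non-empty hit set")
    return {
        "median_rank": float(hit_ranks.median()),
        "min_rank": float(hit_ranks.min()),
        "max_rank": float(hit_ranks.max()),
        "n_antigens": int(len(representation)),
    }


def longitudinal_paired(
    log2cpm: pd.DataFrame,
    meta: pd.DataFrame,
    group: str,
    month_pairs: list[tuple[int, int]],
    q_threshold: float = 0.2,
) -> tuple[dict[tuple[int, int], pd.DataFrame], pd.DataFrame]:
    """Paired Wilcoxon signed-rank tests and per-donor R² across visits.

    For each month pair, donors with samples at both visits contribute a
    paired observation per antigen; zero differences are excluded
    (Wilcoxon zero handling) and BH runs within the pair.  The second
    return value tabulates each donor's between-visit scatter R².
    """
    serum = meta[(~meta["is_control"]) & (meta["group"] == group)]
    results: dict[tuple[int, int], pd.DataFrame] = {}
    r2_rows = []
    for month_a, month_b in month_pairs:
        sub_a = serum[serum["month"] == month_a].set_index("donor_id")["sample_id"]
        sub_b = serum[serum["month"] == month_b].set_index("donor_id")["sample_id"]
        donors = sorted(set(sub_a.index) & set(sub_b.index))
        dropped = (set(sub_a.index) | set(sub_b.index)) - set(donors)
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} unpaired donors for months "
                f"{month_a}/{month_b}",
                stacklevel=2,
            )
        if len(donors) < 5:
            raise ValueError(
                f"need >=5 paired donors for months {month_a}/{month_b}, "
                f"got {len(donors)}"
            )
        a = log2cpm[[sub_a[d] for d in donors]].to_numpy()
        b = log2cpm[[sub_b[d] for d in donors]].to_numpy()
        p_values = np.ones(a.shape[0])
        for i in range(a.shape[0]):
            diff = a[i] - b[i]
            if np.any(diff != 0):
                p_values[i] = stats.wilcoxon(
                    a[i], b[i], zero_method="wilcox", method="auto"
                )[1]
        table = pd.DataFrame(
            {"p": p_values, "q": bh_fdr(p_values)}, index=log2cpm.index
        )
        table["significant"] = table["q"] < q_threshold
        results[(month_a, month_b)] = table
        for j, donor in enumerate(donors):
            r2_rows.append(
                {
                    "donor_id": donor,
                    "month_a": month_a,
                    "month_b": month_b,
                    "r2": _profiles.replicate_r2(a[:, j], b[:, j], log_transform=False),
                }
            )
    return results, pd.DataFrame(r2_rows)
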