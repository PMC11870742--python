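"""Count-matrix handling: aggregation, normalization, selection calls, QC.

Count matrices are pandas DataFrames with antigen (or fragment) IDs as
rows and sample IDs as columns; sample metadata is a DataFrame with one
row per column of the matrix.  Binary "selected" calls compare each serum
sample against the unselected input library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse
from scipy.stats import pearsonr

META_COLUMNS = ["sample_id", "donor_id", "group", "month", "batch", "is_control"]

#: pseudocount added inside fold ratios (CPM units)
FOLD_EPSILON = 0.5
DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_MIN_COUNT = 10


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("count matrix IDs must be unique")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix must be non-negative")


def validate_meta(meta: pd.DataFrame, counts: pd.DataFrame | None = None) -> None:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    if counts is not None:
        extra = set(counts.columns) - set(meta["sample_id"])
        if extra:
            raise ValueError(f"count columns without metadata: {sorted(extra)[:5]}")


@dataclass
class NormalizedMatrix:
    """CPM and log2(CPM+pseudocount) views of a count matrix."""

    cpm: pd.DataFrame
    log2: pd.DataFrame
    pseudocount: float


@dataclass
class SelectionCalls:
    """Binary antigen-by-sample selection matrix plus group prevalence."""

    matrix: pd.DataFrame  # 0/1 ints
    fold_threshold: float
    min_count: int
    prevalence: pd.DataFrame | None = None  # antigen x group, fraction of donors

    def __post_init__(self) -> None:
        values = self.matrix.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("selection calls must be 0/1")


# --------------------------------------------------------------------------
# IO


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(counts)
    return counts


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """Write a sparse MatrixMarket triple: prefix.mtx, .rows.txt, .cols.txt."""
    prefix = Path(prefix)
    scipy_io.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    matrix = scipy_io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    counts = pd.DataFrame(matrix, index=rows, columns=cols).astype(np.int64)
    validate_counts(counts)
    return counts


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    validate_meta(meta)
    return meta


def read_fragment_map(path: str | Path) -> pd.DataFrame:
    fmap = pd.read_csv(path, sep="\t")
    if "fragment_id" not in fmap.columns or "protein_id" not in fmap.columns:
        raise ValueError("fragment map needs fragment_id and protein_id columns")
    return fmap


# --------------------------------------------------------------------------
# operations


def aggregate_fragments_to_antigens(
    fragment_counts: pd.DataFrame, fragment_map: pd.DataFrame
) -> pd.DataFrame:
    """Sum fragment counts into antigen (protein) counts.

    Column sums are preserved exactly.  Every fragment in the matrix must
    appear in the map.
    """
    validate_counts(fragment_counts)
    mapping = fragment_map.set_index("fragment_id")["protein_id"]
    unmapped = fragment_counts.index.difference(mapping.index)
    if len(unmapped):
        raise ValueError(
            f"{len(unmapped)} fragments missing from the map, e.g. "
            f"{list(unmapped[:5])}"
        )
    grouped = fragment_counts.groupby(mapping.reindex(fragment_counts.index)).sum()
    grouped.index.name = "antigen_id"
    return grouped.sort_index()


def normalize(counts: pd.DataFrame, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Counts-per-million and log2(CPM + pseudocount) per sample."""
    validate_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero count column(s): {list(zero.index)}")
    cpm = counts / totals * 1e6
    log2 = np.log2(cpm + pseudocount)
    return NormalizedMatrix(cpm=cpm, log2=log2, pseudocount=pseudocount)


def estimate_batch_factors(
    cpm: pd.DataFrame,
    meta: pd.DataFrame,
    r2_threshold: float = 0.8,
    epsilon: float = FOLD_EPSILON,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-batch per-antigen correction factors from input-library controls.

    The factor for a batch is the ratio of its control CPM (median across
    that batch's controls) to the across-batch reference (median of
    per-batch control CPM), with a pseudocount.  Returns ``(factors,
    corrected_cpm, drift_report)``; the report flags batches whose control
    correlates poorly with the reference on the log scale.
    """
    validate_meta(meta, cpm)
    controls = meta[meta["is_control"]]
    batches = sorted(meta["batch"].unique())
    missing = [b for b in batches if b not in set(controls["batch"])]
    if missing:
        raise ValueError(f"batches without an input-library control: {missing}")

    control_cpm = {}
    for batch in batches:
        samples = controls.loc[controls["batch"] == batch, "sample_id"]
        control_cpm[batch] = cpm[list(samples)].median(axis=1)
    control_table = pd.DataFrame(control_cpm)
    reference = control_table.median(axis=1)
    factors = (control_table + epsilon).div(reference + epsilon, axis=0)

    batch_of = meta.set_index("sample_id")["batch"]
    corrected = cpm.copy()
    for sample in cpm.columns:
        corrected[sample] = cpm[sample] / factors[batch_of[sample]]

    report_rows = []
    log_ref = np.log10(reference + 1.0)
    for batch in batches:
        log_ctrl = np.log10(control_table[batch] + 1.0)
        if log_ctrl.std() == 0 or log_ref.std() == 0:
            r2 = float("nan")
        else:
            r2 = float(pearsonr(log_ctrl, log_ref)[0] ** 2)
        report_rows.append(
            {"batch": batch, "control_r2": r2, "flagged": bool(r2 < r2_threshold)}
        )
    report = {"threshold": r2_threshold, "batches": report_rows}
    return factors, corrected, report


def call_selected(
    sample_cpm: pd.Series,
    input_cpm: pd.Series,
    raw_counts: pd.Series,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_count: int = DEFAULT_MIN_COUNT,
    epsilon: float = FOLD_EPSILON,
) -> pd.Series:
    """Binary selection call for one sample against the input library.

    An antigen is selected iff its raw count reaches ``min_count`` and its
    CPM exceeds ``fold_threshold`` times the input-library CPM (both sides
    offset by ``epsilon``).
    """
    if not sample_cpm.index.equals(input_cpm.index) or not sample_cpm.index.equals(
        raw_counts.index
    ):
        raise ValueError("sample, input, and raw count indices must match")
    fold = (sample_cpm + epsilon) / (input_cpm + epsilon)
    return ((raw_counts >= min_count) & (fold >= fold_threshold)).astype(int)


def make_selection_calls(
    counts: pd.DataFrame,
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_count: int = DEFAULT_MIN_COUNT,
    epsilon: float = FOLD_EPSILON,
    prevalence_month: int | None = None,
) -> SelectionCalls:
    """Selection calls for every non-control sample plus group prevalence.

    The input reference is the mean CPM of the control samples.  Group
    prevalence is the fraction of distinct donors in each group with at
    least one selected sample (restricted to ``prevalence_month`` when
    given).
    """
    validate_meta(meta, counts)
    controls = meta.loc[meta["is_control"], "sample_id"]
    if controls.empty:
        raise ValueError("selection calls need at least one input-library control")
    input_cpm = norm.cpm[list(controls)].mean(axis=1)
    serum = meta[~meta["is_control"]]
    calls = {}
    for sample in serum["sample_id"]:
        calls[sample] = call_selected(
            norm.cpm[sample], input_cpm, counts[sample], fold_threshold, min_count, epsilon
        )
    matrix = pd.DataFrame(calls)
    prevalence = compute_prevalence(matrix, meta, month=prevalence_month)
    return SelectionCalls(
        matrix=matrix,
        fold_threshold=fold_threshold,
        min_count=min_count,
        prevalence=prevalence,
    )


def compute_prevalence(
    call_matrix: pd.DataFrame, meta: pd.DataFrame, month: int | None = None
) -> pd.DataFrame:
    """Fraction of donors per group selecting each antigen."""
    serum = meta[~meta["is_control"]]
    if month is not None:
        serum = serum[serum["month"] == month]
    columns = {}
    for group, sub in serum.groupby("group"):
        donors = sub["donor_id"].unique()
        selected = (
            call_matrix[list(sub["sample_id"])]
            .T.groupby(sub.set_index("sample_id")["donor_id"])
            .max()
        )
        columns[group] = selected.sum(axis=0) / len(donors)
    return pd.DataFrame(columns)


def replicate_r2(
    sample_a: pd.Series | np.ndarray,
    sample_b: pd.Series | np.ndarray,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> float:
    """Squared Pearson correlation between two replicate profiles.

    By default values are transformed to log10(x + 1) first; this is the
    scatter-plot R² used for replicate and longitudinal agreement.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    if log_transform:
        a = np.log10(a + pseudocount)
        b = np.log10(b + pseudocount)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("replicate R2 is undefined for a zero-variance vector")
    r, _ = pearsonr(a, b)
    return float(r**2)


def binary_agreement(calls_a, calls_b) -> float:
    """Percent of antigens with identical binary call in two samples."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    if a.size == 0:
        raise ValueError("call vectors are empty")
    return float((a == b).mean() * 100.0)
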