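"""Protein sequence property scales and rank-based set enrichment.

Implements the antigenicity-adjacent calculators (sliding-window residue
scales, Emini surface probability, Chou-Fasman secondary-structure
fractions, Henderson-Hasselbalch isoelectric point) and an unweighted
Kolmogorov-Smirnov running-sum enrichment of a hit set within a
property-ranked proteome, with a set-size-matched permutation null.

Residue tables and the EMBOSS pKa set ship in ``data/scales.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: default sliding-window widths (residues); IEDB-style conventions
DEFAULT_WINDOWS = {"parker_hydrophilicity": 7, "chou_fasman_turn": 7, "kyte_doolittle": 7}
EMINI_WINDOW = 6
EMINI_NORMALISER = 0.37
TURN_PRODUCT_THRESHOLD = 7.5e-5
SHEET_PROPENSITY_THRESHOLD = 1.05
SHEET_WINDOW = 5


class ResidueError(ValueError):
    """Raised for sequences containing nonstandard residues."""


def _load_tables() -> dict[str, dict[str, float]]:
    with resources.files("antigenome.data").joinpath("scales.json").open() as handle:
        return json.load(handle)


_TABLES = _load_tables()


def available_scales() -> list[str]:
    return [k for k in _TABLES if k != "pka_emboss"]


def get_scale(name: str) -> dict[str, float]:
    if name not in _TABLES:
        raise KeyError(f"unknown scale {name!r}; available: {sorted(_TABLES)}")
    return dict(_TABLES[name])


def _check_sequence(sequence: str, skip_invalid: bool = False) -> str:
    if not sequence:
        raise ResidueError("sequence is empty")
    for i, residue in enumerate(sequence):
        if residue not in STANDARD_RESIDUES:
            if skip_invalid:
                return "".join(r for r in sequence if r in STANDARD_RESIDUES)
            raise ResidueError(f"nonstandard residue {residue!r} at position {i}")
    return sequence


def scale_profile(
    sequence: str,
    scale: str | Mapping[str, float],
    window: int = 7,
    skip_invalid: bool = False,
) -> tuple[np.ndarray, float]:
    """Sliding-window mean of a per-residue scale, plus the protein mean.

    The window is centred and truncated at the edges (edge residues
    average over the part of the window that exists).  ``window=1``
    returns the raw lookups.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    table = get_scale(scale) if isinstance(scale, str) else dict(scale)
    sequence = _check_sequence(sequence, skip_invalid)
    if window > len(sequence):
        raise ValueError("window exceeds sequence length")
    raw = np.array([table[residue] for residue in sequence], dtype=float)
    half = window // 2
    cumulative = np.concatenate([[0.0], np.cumsum(raw)])
    n = len(raw)
    starts = np.maximum(np.arange(n) - half, 0)
    ends = np.minimum(np.arange(n) + half + 1, n)
    smoothed = (cumulative[ends] - cumulative[starts]) / (ends - starts)
    return smoothed, float(smoothed.mean())


def emini_accessibility(
    sequence: str,
    table: Mapping[str, float] | None = None,
    skip_invalid: bool = False,
) -> tuple[np.ndarray, float]:
    """Per-hexapeptide surface probability and the protein mean.

    Each window of 6 residues scores the product of fractional surface
    probabilities normalised by 0.37**6, so a hexapeptide of exactly
    average-surface residues scores 1.
    """
    table = dict(table) if table is not None else get_scale("emini_surface_fraction")
    sequence = _check_sequence(sequence, skip_invalid)
    if len(sequence) < EMINI_WINDOW:
        raise ValueError(f"sequence must be at least {EMINI_WINDOW} residues")
    logs = np.log([table[residue] for residue in sequence])
    cumulative = np.concatenate([[0.0], np.cumsum(logs)])
    window_logs = cumulative[EMINI_WINDOW:] - cumulative[:-EMINI_WINDOW]
    scores = np.exp(window_logs - EMINI_WINDOW * np.log(EMINI_NORMALISER))
    return scores, float(scores.mean())


def chou_fasman_fractions(
    sequence: str,
    turn_product_threshold: float = TURN_PRODUCT_THRESHOLD,
    sheet_threshold: float = SHEET_PROPENSITY_THRESHOLD,
    sheet_window: int = SHEET_WINDOW,
    skip_invalid: bool = False,
) -> dict[str, float]:
    """Fractions of residues assigned to beta-turns and beta-sheets.

    Turns use the classic tetrapeptide criterion: the product of the four
    positional turn frequencies must exceed the threshold, the mean turn
    propensity over the tetrad must exceed 1.0 and also exceed the mean
    helix and sheet propensities.  Sheets are assigned where the windowed
    mean sheet propensity reaches ``sheet_threshold`` and exceeds the
    windowed helix propensity.  A residue belonging to any qualifying
    window is assigned; fractions are assigned residues over length.
    """
    sequence = _check_sequence(sequence, skip_invalid)
    n = len(sequence)
    if n < 4:
        raise ValueError("sequence must be at least 4 residues")
    p_turn = np.array([_TABLES["chou_fasman_turn"][r] for r in sequence])
    p_helix = np.array([_TABLES["chou_fasman_helix"][r] for r in sequence])
    p_sheet = np.array([_TABLES["chou_fasman_sheet"][r] for r in sequence])
    freq = [
        np.array([_TABLES[f"turn_frequency_{k}"][r] for r in sequence])
        for k in ("i", "i1", "i2", "i3")
    ]

    def _window_mean(values: np.ndarray, width: int) -> np.ndarray:
        cumulative = np.concatenate([[0.0], np.cumsum(values)])
        return (cumulative[width:] - cumulative[:-width]) / width

    product = freq[0][: n - 3] * freq[1][1 : n - 2] * freq[2][2 : n - 1] * freq[3][3:]
    mean_turn = _window_mean(p_turn, 4)
    tetrad_ok = (
        (product > turn_product_threshold)
        & (mean_turn > 1.0)
        & (mean_turn > _window_mean(p_helix, 4))
        & (mean_turn > _window_mean(p_sheet, 4))
    )
    turn_mask = np.zeros(n, dtype=bool)
    starts = np.flatnonzero(tetrad_ok)
    for offset in range(4):
        turn_mask[starts + offset] = True

    w = min(sheet_window, n)
    mean_sheet = _window_mean(p_sheet, w)
    window_ok = (mean_sheet >= sheet_threshold) & (mean_sheet > _window_mean(p_helix, w))
    sheet_mask = np.zeros(n, dtype=bool)
    starts = np.flatnonzero(window_ok)
    for offset in range(w):
        sheet_mask[starts + offset] = True

    return {
        "fraction_beta_turn": float(turn_mask.mean()),
        "fraction_beta_sheet": float(sheet_mask.mean()),
    }


def _ionizable_terms(
    sequence: str, pka: Mapping[str, float] | None
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(count, pKa) pairs for positively and negatively ionizable groups."""
    pka = dict(pka) if pka is not None else dict(_TABLES["pka_emboss"])
    positive = [(1.0, pka["n_terminus"])]
    negative = [(1.0, pka["c_terminus"])]
    for residue in ("K", "R", "H"):
        count = sequence.count(residue)
        if count:
            positive.append((float(count), pka[residue]))
    for residue in ("D", "E", "C", "Y"):
        count = sequence.count(residue)
        if count:
            negative.append((float(count), pka[residue]))
    return positive, negative


def net_charge(sequence: str, ph: float, pka: Mapping[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    positive, negative = _ionizable_terms(sequence, pka)
    charge = sum(c / (1.0 + 10 ** (ph - k)) for c, k in positive)
    charge -= sum(c / (1.0 + 10 ** (k - ph)) for c, k in negative)
    return charge


def isoelectric_point(
    sequence: str,
    pka: Mapping[str, float] | None = None,
    tolerance: float = 1e-4,
    max_iterations: int = 60,
) -> float:
    """pI by bisection of the net-charge curve over pH (0, 14)."""
    sequence = _check_sequence(sequence)
    positive, negative = _ionizable_terms(sequence, pka)

    def charge(ph: float) -> float:
        total = sum(c / (1.0 + 10 ** (ph - k)) for c, k in positive)
        return total - sum(c / (1.0 + 10 ** (k - ph)) for c, k in negative)

    low, high = 0.0, 14.0
    ph = 7.0
    for _ in range(max_iterations):
        ph = (low + high) / 2.0
        value = charge(ph)
        if abs(value) < tolerance:
            break
        if value > 0:
            low = ph
        else:
            high = ph
    return float(ph)


# --------------------------------------------------------------------------
# GSEA-style running-sum enrichment


@dataclass
class EnrichmentResult:
    scale_name: str
    es: float
    nes: float
    p_value: float
    leading_edge: list[str]
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "scale": self.scale_name,
            "es": self.es,
            "nes": self.nes,
            "p_value": self.p_value,
            "leading_edge": self.leading_edge,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _es_from_positions(positions: np.ndarray, n: int, n_hits: int) -> tuple[float, int]:
    """Signed extremum of the unweighted KS running sum.

    ``positions`` are the sorted 0-based ranks of the hits.  Hits step the
    sum up by 1/n_hits, misses step down by 1/(n - n_hits); the extrema
    can only occur just after a hit (maxima) or just before one (minima).
    """
    up = 1.0 / n_hits
    down = 1.0 / (n - n_hits)
    i = np.arange(1, n_hits + 1)
    after_hit = i * up - (positions + 1 - i) * down
    before_hit = (i - 1) * up - (positions - (i - 1)) * down
    max_idx = int(np.argmax(after_hit))
    min_idx = int(np.argmin(before_hit))
    es_max = float(after_hit[max_idx])
    es_min = float(before_hit[min_idx])
    if es_max >= -es_min:
        return es_max, int(positions[max_idx])
    return es_min, int(positions[min_idx])


def gsea_enrichment(
    scores: pd.Series,
    hits: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    scale_name: str = "",
    descending: bool = True,
) -> EnrichmentResult:
    """Enrichment of a hit set within a score-ranked protein universe.

    Proteins are ranked by score (descending by default); the enrichment
    score is the signed extremum of the unweighted Kolmogorov-Smirnov
    running sum.  The null distribution comes from ``n_perm`` random hit
    sets of the same size; NES divides ES by the mean |null ES| of
    matching sign, and the permutation p value is two-sided with +1
    smoothing.
    """
    hits = set(hits)
    if not hits:
        raise ValueError("hit set is empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    missing = hits - set(scores.index)
    if missing:
        raise KeyError(f"hits outside the ranked universe: {sorted(missing)[:5]}")
    n = len(scores)
    n_hits = len(hits)
    if n_hits >= n:
        raise ValueError("hit set must be a strict subset of the universe")

    values = scores.to_numpy(dtype=float)
    order = np.argsort(-values if descending else values, kind="mergesort")
    ranked_ids = scores.index.to_numpy()[order]
    hit_mask = np.isin(ranked_ids, list(hits))
    positions = np.flatnonzero(hit_mask)
    es, pivot = _es_from_positions(positions, n, n_hits)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    for k in range(n_perm):
        perm = np.sort(rng.choice(n, size=n_hits, replace=False))
        null_es[k], _ = _es_from_positions(perm, n, n_hits)
    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null_es).mean()
    nes = es / denom if denom > 0 else 0.0
    p_value = (1.0 + np.sum(np.abs(null_es) >= abs(es))) / (1.0 + n_perm)

    if es >= 0:
        leading = [str(x) for x in ranked_ids[: pivot + 1] if x in hits]
    else:
        leading = [str(x) for x in ranked_ids[pivot:] if x in hits]
    return EnrichmentResult(
        scale_name=scale_name,
        es=float(es),
        nes=float(nes),
        p_value=float(p_value),
        leading_edge=leading,
        n_permutations=n_perm,
        seed=seed,
    )


# --------------------------------------------------------------------------
# property tables over a proteome

PROPERTY_SCALES = (
    "chou_fasman_turn",
    "emini_accessibility",
    "parker_hydrophilicity",
    "gravy_hydrophobicity",
    "isoelectric_point",
    "fraction_beta_turn",
    "fraction_beta_sheet",
)


def protein_property(sequence: str, scale: str) -> float:
    """Scalar property score for one protein under a named scale."""
    if scale == "chou_fasman_turn":
        return scale_profile(sequence, "chou_fasman_turn", DEFAULT_WINDOWS["chou_fasman_turn"])[1]
    if scale == "emini_accessibility":
        return emini_accessibility(sequence)[1]
    if scale == "parker_hydrophilicity":
        return scale_profile(
            sequence, "parker_hydrophilicity", DEFAULT_WINDOWS["parker_hydrophilicity"]
        )[1]
    if scale == "gravy_hydrophobicity":
        return scale_profile(sequence, "kyte_doolittle", DEFAULT_WINDOWS["kyte_doolittle"])[1]
    if scale == "isoelectric_point":
        return isoelectric_point(sequence)
    if scale in ("fraction_beta_turn", "fraction_beta_sheet"):
        return chou_fasman_fractions(sequence)[scale]
    raise KeyError(f"unknown property scale {scale!r}")


def property_table(
    sequences: Mapping[str, str], scales: Sequence[str] = PROPERTY_SCALES
) -> pd.DataFrame:
    """Protein-by-scale score table for a set of sequences."""
    data = {
        scale: {pid: protein_property(seq, scale) for pid, seq in sequences.items()}
        for scale in scales
    }
    table = pd.DataFrame(data)
    table.index.name = "protein_id"
    return table
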