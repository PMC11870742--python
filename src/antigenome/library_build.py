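"""In-silico two-plasmid ORF screening and fragment-library QC.

The cloning system only tolerates inserts that read through without a
stop codon in the vector's translation register: the first plasmid ties
read-through to antibiotic resistance, the phagemid ties it to coat
protein production.  :func:`screen_orf` reproduces that contract for a
single insert; the remaining functions summarise screened pools
(complexity, insert-size statistics, per-protein tiling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._setops import venn_partition

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
N_SENSE_CODONS = 61
N_CODONS = 64

#: classification labels returned by :func:`screen_orf`
PASS = "pass"
WRONG_ORIENTATION = "wrong_orientation"
STOP_IN_FRAME = "stop_in_frame"

_VALID_BASES = frozenset("ACGT")


class OrfInputError(ValueError):
    """Raised for sequences containing characters outside {A,C,G,T}."""


@dataclass(frozen=True)
class Fragment:
    """A cloned nucleotide insert linked to its parent protein.

    ``start``/``end`` are 0-based half-open coordinates on the protein's
    coding sequence.  ``frame`` is the phase of ``start`` relative to the
    protein's codons (``start % 3``); the cloning vector itself always
    translates from insert position 0.
    """

    fragment_id: str
    protein_id: str
    source: str
    sequence: str
    orientation: str  # "+" or "-"
    frame: int
    start: int
    end: int


@dataclass
class FragmentPool:
    """A pooled, ORF-screened fragment library with input abundances."""

    fragments: list[Fragment]
    input_abundance: np.ndarray
    protein_lengths: dict[str, int] = field(default_factory=dict)  # aa lengths
    screen_stats: pd.DataFrame | None = None  # per-candidate funnel record

    def __post_init__(self) -> None:
        self.input_abundance = np.asarray(self.input_abundance, dtype=float)
        if len(self.input_abundance) != len(self.fragments):
            raise ValueError("abundance length does not match fragment count")
        if len(self.fragments) and not math.isclose(
            float(self.input_abundance.sum()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("input abundance must sum to 1 within 1e-9")
        for frag in self.fragments:
            if frag.frame != frag.start % 3:
                raise ValueError(
                    f"fragment {frag.fragment_id}: frame {frag.frame} inconsistent "
                    f"with start {frag.start}"
                )

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def fragment_ids(self) -> list[str]:
        return [f.fragment_id for f in self.fragments]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per fragment) including input abundance."""
        rows = [
            {
                "fragment_id": f.fragment_id,
                "protein_id": f.protein_id,
                "source": f.source,
                "start": f.start,
                "end": f.end,
                "orientation": f.orientation,
                "frame": f.frame,
                "input_abundance": a,
            }
            for f, a in zip(self.fragments, self.input_abundance)
        ]
        return pd.DataFrame(rows)


@dataclass
class LibraryQCReport:
    insert_size_stats: pd.DataFrame  # per source: n, mean, median, sd
    insert_size_histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    fragments_per_protein_mean: float
    fragments_per_protein_range: tuple[int, int]
    rank_abundance: pd.Series  # per-protein abundance, descending
    complexity: dict | None = None
    orf_screen: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "insert_size_stats": self.insert_size_stats.to_dict(orient="index"),
            "fragments_per_protein_mean": self.fragments_per_protein_mean,
            "fragments_per_protein_range": list(self.fragments_per_protein_range),
            "n_proteins": int(len(self.rank_abundance)),
        }
        if self.complexity is not None:
            out["complexity"] = {
                "per_source": self.complexity["per_source"],
                "union": self.complexity["union"],
                "unique_contributions": self.complexity["unique_contributions"],
                "venn_counts": {
                    "+".join(sorted(k)): v
                    for k, v in self.complexity["venn_counts"].items()
                },
            }
        if self.orf_screen is not None:
            out["orf_screen"] = self.orf_screen
        return out


def _validate_sequence(sequence: str) -> None:
    for i, base in enumerate(sequence):
        if base not in _VALID_BASES:
            raise OrfInputError(f"non-ACGT character {base!r} at position {i}")


def screen_orf(
    sequence: str, orientation: str = "+", frame_offset: int = 0
) -> tuple[bool, str]:
    """Apply the two-plasmid read-through contract to a single insert.

    An insert passes iff it is in the forward orientation and translating
    from ``frame_offset`` to the insert end meets no stop codon (any
    trailing partial codon is ignored).  Reverse-orientation inserts fail
    unconditionally: read-through selection removes them.

    Returns ``(passed, classification)`` with classification one of
    ``pass``, ``wrong_orientation``, ``stop_in_frame``.
    """
    if len(sequence) < 3:
        raise ValueError("sequence must be at least 3 nt")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    _validate_sequence(sequence)
    if orientation not in ("+", "-"):
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    if orientation == "-":
        return False, WRONG_ORIENTATION
    for i in range(frame_offset, len(sequence) - 2, 3):
        if sequence[i : i + 3] in STOP_CODONS:
            return False, STOP_IN_FRAME
    return True, PASS


def _stop_free_codons(sequence: str, offset: int) -> int:
    """Number of codons read from ``offset`` before the first stop."""
    n = 0
    for i in range(offset, len(sequence) - 2, 3):
        if sequence[i : i + 3] in STOP_CODONS:
            break
        n += 1
    return n


def is_orf(sequence: str, min_translatable: float = 0.8) -> bool:
    """Whether the best forward frame translates ``min_translatable`` of the insert.

    This is the looser of the two validation denominators: a fragment can
    be an ORF in some forward frame without passing read-through in its
    recorded cloning frame.
    """
    _validate_sequence(sequence)
    best = max(_stop_free_codons(sequence, f) for f in (0, 1, 2))
    return 3 * best >= min_translatable * len(sequence)


def clone_validation_stats(
    inserts: Sequence[tuple[str, str, int]], min_translatable: float = 0.8
) -> dict:
    """Sanger-style validation fractions over sampled clones.

    ``inserts`` is a sequence of ``(sequence, orientation, frame_offset)``
    tuples.  Returns fractions for: any forward ORF covering at least
    ``min_translatable`` of the insert; pass in the recorded cloning frame
    (in-frame and stop-free); correct (forward) orientation.  All three
    share the same denominator, the number of clones sampled.
    """
    if not inserts:
        raise ValueError("clone_validation_stats requires a non-empty insert list")
    n = len(inserts)
    n_orf = 0
    n_inframe = 0
    n_forward = 0
    for sequence, orientation, frame_offset in inserts:
        if orientation == "+":
            n_forward += 1
            if is_orf(sequence, min_translatable):
                n_orf += 1
        passed, _ = screen_orf(sequence, orientation, frame_offset)
        if passed:
            n_inframe += 1
    return {
        "n": n,
        "orf_fraction": n_orf / n,
        "inframe_stop_free_fraction": n_inframe / n,
        "correct_orientation_fraction": n_forward / n,
    }


def expected_inframe_probability(
    n_codons: int,
    include_orientation: bool = False,
    include_frame: bool = False,
) -> float:
    """Closed-form probability that a random insert is stop-free.

    The base model assumes independent uniform codons, so the chance of no
    stop over ``n_codons`` codons is ``(61/64)**n_codons``.  Optional
    factors multiply by 1/2 (random orientation) and 1/3 (random reading
    register).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    p = (N_SENSE_CODONS / N_CODONS) ** n_codons
    if include_orientation:
        p *= 0.5
    if include_frame:
        p /= 3.0
    return p


def library_complexity(fragment_map: pd.DataFrame) -> dict:
    """Per-source protein counts and the full Venn partition across sources.

    ``fragment_map`` needs ``protein_id`` and ``source`` columns.  Returns
    per-source distinct protein counts, the exclusive Venn region counts,
    union size, and per-source unique contributions.
    """
    if fragment_map.empty:
        raise ValueError("fragment map is empty")
    for col in ("protein_id", "source"):
        if col not in fragment_map.columns:
            raise ValueError(f"fragment map lacks required column {col!r}")
    sets = {
        str(source): set(sub["protein_id"])
        for source, sub in fragment_map.groupby("source")
    }
    regions = venn_partition(sets)
    union = sum(len(v) for v in regions.values())
    unique = {
        name: len(regions.get(frozenset({name}), ())) for name in sets
    }
    return {
        "per_source": {name: len(members) for name, members in sets.items()},
        "venn_counts": {k: len(v) for k, v in regions.items()},
        "venn_members": {k: sorted(v) for k, v in regions.items()},
        "union": union,
        "unique_contributions": unique,
    }


def library_qc_summary(pool: FragmentPool, n_bins: int = 30) -> LibraryQCReport:
    """Insert-size statistics, fragments-per-protein, and rank abundance."""
    table = pool.to_frame()
    if table.empty:
        raise ValueError("cannot summarise an empty pool")
    table["length"] = table["end"] - table["start"]
    stats = table.groupby("source")["length"].agg(["count", "mean", "median", "std"])
    stats = stats.rename(columns={"count": "n", "std": "sd"}).fillna(0.0)
    histograms = {
        str(source): np.histogram(sub["length"].to_numpy(), bins=n_bins)
        for source, sub in table.groupby("source")
    }
    per_protein = table.groupby("protein_id").size()
    abundance = (
        table.assign(a=pool.input_abundance)
        .groupby("protein_id")["a"]
        .sum()
        .sort_values(ascending=False)
    )
    complexity = library_complexity(table)
    orf = None
    if pool.screen_stats is not None and len(pool.screen_stats):
        ss = pool.screen_stats
        orf = {
            "n_candidates": int(len(ss)),
            "pass_fraction": float(ss["passed"].mean()),
            "classification_counts": ss["classification"].value_counts().to_dict(),
        }
    return LibraryQCReport(
        insert_size_stats=stats,
        insert_size_histograms=histograms,
        fragments_per_protein_mean=float(per_protein.mean()),
        fragments_per_protein_range=(int(per_protein.min()), int(per_protein.max())),
        rank_abundance=abundance,
        complexity=complexity,
        orf_screen=orf,
    )


def fragment_coverage(
    protein_id: str, pool: FragmentPool
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Tiling of a protein by its fragments, in amino-acid coordinates.

    Returns the fragment intervals (0-based half-open, aa units) and a
    per-residue depth vector of length equal to the protein length.
    Residue ``r`` is covered by a fragment iff its codon interval
    ``[3r, 3r+3)`` overlaps the fragment's nucleotide span.
    """
    if protein_id not in pool.protein_lengths:
        raise KeyError(f"unknown protein {protein_id!r}")
    length = pool.protein_lengths[protein_id]
    depth = np.zeros(length, dtype=int)
    intervals: list[tuple[int, int]] = []
    for frag in pool.fragments:
        if frag.protein_id != protein_id:
            continue
        aa_start = frag.start // 3
        aa_end = min(length, -(-frag.end // 3))  # ceil division, clipped
        if aa_end <= aa_start:
            continue
        intervals.append((aa_start, aa_end))
        depth[aa_start:aa_end] += 1
    return intervals, depth
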