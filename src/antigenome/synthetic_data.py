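"""Synthetic proteomes, phage fragment libraries, and serological screens.

Everything the downstream analysis consumes can be generated here with
known ground truth: a multi-source proteome with heavy-tailed expression,
an ORF-screened fragment pool, per-donor serum reactivity profiles
(background polyreactivity, idiosyncratic targets, and optionally planted
group-shared disease antigens), and multinomial sequencing counts at a
fixed depth.

The selection model is multiplicative enrichment over input abundance: a
fragment's post-selection weight is its input abundance times
``background + sum of reactivities of overlapping epitopes``, optionally
times a per-batch log-normal factor.  Epitopes are contiguous amino-acid
intervals; a fragment is reactive iff its translated interval overlaps an
epitope by at least one residue.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .library_build import (
    Fragment,
    FragmentPool,
    expected_inframe_probability,
    screen_orf,
)

DEFAULT_SOURCES = ("hep2", "astrocyte", "brain", "pbmc")

#: default insert-size (mean, sd) in bp per source; means follow the
#: observed per-library range of roughly 306-482 bp
DEFAULT_INSERT_SIZES = {
    "hep2": (482.0, 120.0),
    "astrocyte": (400.0, 120.0),
    "brain": (306.0, 100.0),
    "pbmc": (350.0, 110.0),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Protein:
    protein_id: str
    aa_sequence: str
    cds: str


@dataclass
class SimulatedProteome:
    """Proteins plus per-source relative expression (0 where absent)."""

    proteins: list[Protein]
    source_expression: pd.DataFrame  # index protein_id, columns sources

    def __post_init__(self) -> None:
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError("protein IDs must be unique")
        if (self.source_expression.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if (self.source_expression.to_numpy() > 0).sum(axis=1).min() < 1:
            raise ValueError("every protein must be expressed in >=1 source")

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def by_id(self) -> dict[str, Protein]:
        return {p.protein_id: p for p in self.proteins}

    def protein_lengths(self) -> dict[str, int]:
        return {p.protein_id: len(p.aa_sequence) for p in self.proteins}

    def write_fasta(self, path: str | Path, kind: str = "protein") -> None:
        if kind not in ("protein", "cds"):
            raise ValueError("kind must be 'protein' or 'cds'")
        with open(path, "w") as handle:
            for protein in self.proteins:
                seq = protein.aa_sequence if kind == "protein" else protein.cds
                handle.write(f">{protein.protein_id}\n{seq}\n")


@dataclass(frozen=True)
class Target:
    """One serum reactivity: an epitope interval (aa, half-open) on a protein."""

    protein_id: str
    start: int
    end: int
    strength: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("epitope interval must be non-empty and non-negative")
        if not (math.isfinite(self.strength) and self.strength >= 0):
            raise ValueError("reactivity strength must be finite and non-negative")


@dataclass
class SerumProfile:
    donor_id: str
    group: str
    month: int
    batch: str
    targets: list[Target]
    background: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.background <= 1.0):
            raise ValueError("background polyreactivity rate must be in [0, 1]")

    @property
    def sample_id(self) -> str:
        return f"{self.donor_id}_m{self.month}"


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests; JSON round-trippable."""

    pools: list[dict]  # each: groups, prevalence, effect, antigens
    carriers: dict[str, list[str]]  # donor -> planted protein ids carried
    donor_groups: dict[str, str]
    batch_factors: dict[str, dict[str, float]]
    seed: int

    def planted_antigens(self, group: str | None = None) -> set[str]:
        out: set[str] = set()
        for pool in self.pools:
            if group is None or group in pool["groups"]:
                out.update(a["protein_id"] for a in pool["antigens"])
        return out

    def realized_prevalence(self, group: str) -> dict[str, float]:
        donors = [d for d, g in self.donor_groups.items() if g == group]
        if not donors:
            return {}
        out = {}
        for antigen in self.planted_antigens():
            n = sum(antigen in self.carriers.get(d, ()) for d in donors)
            out[antigen] = n / len(donors)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pools": self.pools,
            "carriers": self.carriers,
            "donor_groups": self.donor_groups,
            "batch_factors": self.batch_factors,
            "seed": self.seed,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(**payload)


# --------------------------------------------------------------------------
# proteome generation

_CODON_TABLE: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODON_TABLE.setdefault(aa, []).append(codon)
for aa in _CODON_TABLE:
    _CODON_TABLE[aa].sort()

_CODON_COUNTS = np.array([len(_CODON_TABLE[aa]) for aa in AMINO_ACIDS])
_CODON_MATRIX = np.full((len(AMINO_ACIDS), int(_CODON_COUNTS.max())), "", dtype="U3")
for i, aa in enumerate(AMINO_ACIDS):
    for j, codon in enumerate(_CODON_TABLE[aa]):
        _CODON_MATRIX[i, j] = codon


def _sample_lengths(n: int, length_dist: Mapping, rng: np.random.Generator) -> np.ndarray:
    kind = length_dist.get("kind", "normal")
    min_aa = int(length_dist.get("min_aa", 60))
    if min_aa < 1:
        raise ConfigurationError("length_dist.min_aa must be >= 1")
    if kind == "normal":
        mean = float(length_dist.get("mean_aa", 250.0))
        sd = float(length_dist.get("sd_aa", 80.0))
        if mean <= 0:
            raise ConfigurationError("length_dist.mean_aa must be positive")
        if sd < 0:
            raise ConfigurationError("length_dist.sd_aa must be non-negative")
        lengths = rng.normal(mean, sd, size=n)
    elif kind == "lognormal":
        mu = float(length_dist.get("mean_log", math.log(250.0)))
        sigma = float(length_dist.get("sigma_log", 0.5))
        if sigma < 0:
            raise ConfigurationError("length_dist.sigma_log must be non-negative")
        lengths = rng.lognormal(mu, sigma, size=n)
    else:
        raise ConfigurationError(f"length_dist.kind {kind!r} is not supported")
    return np.maximum(np.round(lengths).astype(int), min_aa)


def _backtranslate(aa_indices: np.ndarray, rng: np.random.Generator) -> str:
    choice = (rng.random(len(aa_indices)) * _CODON_COUNTS[aa_indices]).astype(int)
    return "".join(_CODON_MATRIX[aa_indices, choice])


def generate_proteome(
    n_proteins: int,
    length_dist: Mapping | None = None,
    overlap_config: Mapping | None = None,
    seed: int = 0,
    sources: Sequence[str] = DEFAULT_SOURCES,
    expression_sigma: float = 1.5,
) -> SimulatedProteome:
    """Generate a random proteome shared across cell sources.

    ``overlap_config`` controls how proteins distribute over sources: a
    ``shared_fraction`` of proteins is expressed everywhere, per-source
    ``exclusive`` counts are expressed in one source only, and the
    remainder lands in a random non-empty source subset.  Expression
    levels are log-normal (heavy-tailed) where present.
    """
    if n_proteins < 1:
        raise ConfigurationError("n_proteins must be >= 1")
    length_dist = dict(length_dist or {})
    overlap_config = dict(overlap_config or {})
    shared_fraction = float(overlap_config.get("shared_fraction", 1.0))
    exclusive = dict(overlap_config.get("exclusive", {}))
    if not (0.0 <= shared_fraction <= 1.0):
        raise ConfigurationError("overlap_config.shared_fraction must be in [0, 1]")
    for source, count in exclusive.items():
        if source not in sources:
            raise ConfigurationError(f"overlap_config.exclusive: unknown source {source!r}")
        if count < 0:
            raise ConfigurationError("overlap_config.exclusive counts must be >= 0")
    n_shared = int(round(shared_fraction * n_proteins))
    n_exclusive = sum(exclusive.values())
    if n_shared + n_exclusive > n_proteins:
        raise ConfigurationError(
            "overlap_config: shared_fraction plus exclusive counts exceed n_proteins"
        )

    rng = np.random.default_rng(seed)
    lengths = _sample_lengths(n_proteins, length_dist, rng)
    width = max(5, len(str(n_proteins)))
    proteins = []
    for i, length in enumerate(lengths):
        aa_idx = rng.integers(0, len(AMINO_ACIDS), size=int(length))
        aa_seq = "".join(AMINO_ACIDS[j] for j in aa_idx)
        cds = _backtranslate(aa_idx, rng)
        proteins.append(Protein(f"P{i:0{width}d}", aa_seq, cds))

    # membership matrix: shared core, per-source exclusives, random remainder
    member = np.zeros((n_proteins, len(sources)), dtype=bool)
    order = rng.permutation(n_proteins)
    cursor = 0
    member[order[:n_shared], :] = True
    cursor = n_shared
    for j, source in enumerate(sources):
        count = int(exclusive.get(source, 0))
        member[order[cursor : cursor + count], j] = True
        cursor += count
    for idx in order[cursor:]:
        # remainder proteins span >=2 sources so exclusive counts stay exact
        row = rng.random(len(sources)) < 0.5
        while row.sum() < 2:
            row[rng.integers(len(sources))] = True
        member[idx] = row

    expression = np.where(
        member, rng.lognormal(0.0, expression_sigma, size=member.shape), 0.0
    )
    table = pd.DataFrame(
        expression, index=[p.protein_id for p in proteins], columns=list(sources)
    )
    return SimulatedProteome(proteins=proteins, source_expression=table)


# --------------------------------------------------------------------------
# fragment library construction


def candidate_pass_probability(length_nt: int, orientation_flip_p: float) -> float:
    """Analytic funnel pass probability for one candidate insert.

    Forward-orientation candidates land in the vector register in the
    protein's frame with probability 1/3 (stop-free by construction) and
    off-frame otherwise, where the stop-free chance follows the
    uniform-codon closed form.  Reverse candidates always fail.
    """
    n_codons = max(1, length_nt // 3)
    p_off = expected_inframe_probability(n_codons)
    return (1.0 - orientation_flip_p) * (1.0 / 3.0 + 2.0 / 3.0 * p_off)


def build_fragment_library(
    proteome: SimulatedProteome,
    insert_size_spec: Mapping[str, tuple[float, float]] | None = None,
    orientation_flip_p: float = 0.01,
    candidates_per_source: int = 2000,
    min_insert: int = 30,
    abundance_jitter_sigma: float = 0.5,
    seed: int = 0,
) -> FragmentPool:
    """Draw candidate inserts, apply the ORF funnel, and pool survivors.

    Candidates are substrings of coding sequences with per-source size
    distributions; each candidate enters the pool iff it passes
    :func:`antigenome.library_build.screen_orf` in the vector register
    (translation from insert position 0).  Surviving fragments from each
    source are pooled with equal total phage weight per source.
    """
    if min_insert < 30:
        raise ConfigurationError("min_insert must be >= 30 bp")
    if not (0.0 <= orientation_flip_p <= 1.0):
        raise ConfigurationError("orientation_flip_p must be in [0, 1]")
    if len(proteome) == 0:
        raise ConfigurationError("proteome is empty")
    sizes = dict(insert_size_spec or DEFAULT_INSERT_SIZES)
    sources = list(proteome.source_expression.columns)
    rng = np.random.default_rng(seed)

    cds_by_id = {p.protein_id: p.cds for p in proteome.proteins}
    cds_len = np.array([len(p.cds) for p in proteome.proteins])
    protein_ids = np.array([p.protein_id for p in proteome.proteins])
    usable = cds_len >= min_insert
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} proteins shorter than the minimum insert "
            f"({min_insert} bp) were skipped",
            stacklevel=2,
        )

    fragments: list[Fragment] = []
    weights: list[float] = []
    stats_rows: list[dict] = []
    frag_counter = 0
    for source in sources:
        mean, sd = sizes.get(source, (380.0, 110.0))
        expr = proteome.source_expression[source].to_numpy() * usable
        total = expr.sum()
        if total <= 0:
            continue
        probs = expr / total
        chosen = rng.choice(len(protein_ids), size=candidates_per_source, p=probs)
        lengths = np.round(rng.normal(mean, sd, size=candidates_per_source)).astype(int)
        lengths = np.clip(lengths, min_insert, cds_len[chosen])
        starts = (rng.random(candidates_per_source) * (cds_len[chosen] - lengths + 1)).astype(int)
        flips = rng.random(candidates_per_source) < orientation_flip_p
        jitter = rng.lognormal(0.0, abundance_jitter_sigma, size=candidates_per_source)

        source_fragments: list[Fragment] = []
        source_weights: list[float] = []
        for k in range(candidates_per_source):
            pid = protein_ids[chosen[k]]
            start, length = int(starts[k]), int(lengths[k])
            end = start + length
            seq = cds_by_id[pid][start:end]
            orientation = "-" if flips[k] else "+"
            if orientation == "-":
                seq = str(Seq(seq).reverse_complement())
            passed, classification = screen_orf(seq, orientation, 0)
            stats_rows.append(
                {
                    "source": source,
                    "protein_id": pid,
                    "length": length,
                    "start": start,
                    "orientation": orientation,
                    "in_frame": start % 3 == 0 and orientation == "+",
                    "passed": passed,
                    "classification": classification,
                }
            )
            if not passed:
                continue
            frag = Fragment(
                fragment_id=f"FRAG{frag_counter:07d}",
                protein_id=str(pid),
                source=source,
                sequence=seq,
                orientation=orientation,
                frame=start % 3,
                start=start,
                end=end,
            )
            frag_counter += 1
            source_fragments.append(frag)
            source_weights.append(expr[chosen[k]] * jitter[k])

        if source_fragments:  # pool sources equally by phage number
            w = np.asarray(source_weights)
            w = w / w.sum() / len(sources)
            fragments.extend(source_fragments)
            weights.extend(w.tolist())

    abundance = np.asarray(weights, dtype=float)
    if abundance.size:
        abundance = abundance / abundance.sum()
    return FragmentPool(
        fragments=fragments,
        input_abundance=abundance,
        protein_lengths=proteome.protein_lengths(),
        screen_stats=pd.DataFrame(stats_rows),
    )


# --------------------------------------------------------------------------
# serum cohort generation

DEFAULT_DESIGN = {
    "groups": {"HC": 43, "PBO-NA": 21, "PBO-A": 27, "RNF-NA": 27, "RNF-A": 27},
    "time_points": [0, 6, 24],
    "n_batches": 4,
    "background_rate": 1e-4,
    "idiosyncratic_targets_mean": 10.0,
    "idiosyncratic_strength_log_mean": math.log(5.0),
    "idiosyncratic_strength_log_sigma": 1.0,
    "epitope_length_aa": 30,
    "batch_sigma": 0.15,
    "drift_rate": 0.0,
}

CONTROL_GROUP = "CONTROL"


def _normalise_pools(disease_pool, rng, available, n_proteins):
    """Expand pool specs: draw antigen IDs when given as a count, attach epitopes."""
    if disease_pool is None:
        return []
    pools = disease_pool if isinstance(disease_pool, list) else [disease_pool]
    out = []
    for spec in pools:
        prevalence = float(spec.get("prevalence", 0.0))
        if not (0.0 <= prevalence <= 1.0):
            raise ConfigurationError("disease_pool.prevalence must be in [0, 1]")
        effect = float(spec.get("effect", 1.0))
        antigens = spec.get("antigens", [])
        if isinstance(antigens, int):
            if antigens > len(available):
                raise ConfigurationError(
                    "disease_pool.antigens exceeds the available protein count"
                )
            antigens = list(rng.choice(sorted(available), size=antigens, replace=False))
        if prevalence > 0 and len(antigens) == 0:
            raise ConfigurationError(
                "disease_pool.antigens is empty while prevalence > 0"
            )
        out.append(
            {
                "groups": list(spec.get("groups", [])),
                "prevalence": prevalence,
                "effect": effect,
                "antigen_ids": [str(a) for a in antigens],
            }
        )
    return out


def _calibrate_strengths(pools, design, n_proteins):
    """Solve planted reactivity strengths so carriers reach the target fold
    enrichment over the input library, under an equal-share approximation."""
    background = float(design["background_rate"])
    idio = (
        float(design["idiosyncratic_targets_mean"])
        * math.exp(
            design["idiosyncratic_strength_log_mean"]
            + design["idiosyncratic_strength_log_sigma"] ** 2 / 2.0
        )
        / n_proteins
    )
    strengths = [max(p["effect"] - 1.0, 0.0) * background for p in pools]
    for _ in range(30):
        for i, pool in enumerate(pools):
            planted = sum(
                q["prevalence"] * len(q["antigen_ids"]) * s / n_proteins
                for q, s in zip(pools, strengths)
            )
            z = background + idio + planted
            strengths[i] = max(pool["effect"] * z - background, 0.0)
    return strengths


def generate_serum_cohort(
    design: Mapping | None = None,
    proteome: SimulatedProteome | None = None,
    disease_pool: Mapping | list | None = None,
    seed: int = 0,
    pool: FragmentPool | None = None,
) -> tuple[list[SerumProfile], TruthTable]:
    """Generate donor serum profiles plus the ground-truth table.

    Healthy controls carry only background polyreactivity and random
    idiosyncratic targets; donors in a pool's case groups additionally
    carry each planted antigen with probability ``prevalence``.  Targets
    persist across time points (up to ``drift_rate`` per visit) and
    samples are assigned round-robin to batches.
    """
    if proteome is None:
        raise ConfigurationError("generate_serum_cohort requires a proteome")
    full_design = dict(DEFAULT_DESIGN)
    full_design.update(design or {})
    groups = dict(full_design["groups"])
    if any(n < 0 for n in groups.values()):
        raise ConfigurationError("group sizes must be >= 0")
    time_points = list(full_design["time_points"])
    n_batches = int(full_design["n_batches"])
    if n_batches < 1:
        raise ConfigurationError("n_batches must be >= 1")

    rng = np.random.default_rng(seed)
    lengths = proteome.protein_lengths()
    if pool is not None:
        available = {f.protein_id for f in pool.fragments}
    else:
        available = set(lengths)
    pools = _normalise_pools(disease_pool, rng, available, len(proteome))
    strengths = _calibrate_strengths(pools, full_design, len(proteome))
    epi_len = int(full_design["epitope_length_aa"])

    # one fixed epitope per planted antigen, shared by every carrier
    for pool_spec, strength in zip(pools, strengths):
        antigens = []
        for pid in pool_spec["antigen_ids"]:
            protein_len = lengths[pid]
            span = min(epi_len, protein_len)
            start = int(rng.integers(0, protein_len - span + 1))
            antigens.append(
                {
                    "protein_id": pid,
                    "start": start,
                    "end": start + span,
                    "strength": float(strength),
                }
            )
        pool_spec["antigens"] = antigens
        del pool_spec["antigen_ids"]

    available_sorted = sorted(available)
    background = float(full_design["background_rate"])
    drift = float(full_design["drift_rate"])
    profiles: list[SerumProfile] = []
    carriers: dict[str, list[str]] = {}
    donor_groups: dict[str, str] = {}
    sample_counter = 0
    for group, n_donors in groups.items():
        for i in range(int(n_donors)):
            donor_id = f"{group}-{i:03d}"
            donor_groups[donor_id] = group
            targets: list[Target] = []
            n_idio = rng.poisson(float(full_design["idiosyncratic_targets_mean"]))
            for _ in range(int(n_idio)):
                pid = available_sorted[int(rng.integers(len(available_sorted)))]
                protein_len = lengths[pid]
                span = min(epi_len, protein_len)
                start = int(rng.integers(0, protein_len - span + 1))
                strength = float(
                    rng.lognormal(
                        full_design["idiosyncratic_strength_log_mean"],
                        full_design["idiosyncratic_strength_log_sigma"],
                    )
                )
                targets.append(Target(pid, start, start + span, strength))
            carried: list[str] = []
            for pool_spec in pools:
                if group not in pool_spec["groups"]:
                    continue
                for antigen in pool_spec["antigens"]:
                    if rng.random() < pool_spec["prevalence"]:
                        targets.append(
                            Target(
                                antigen["protein_id"],
                                antigen["start"],
                                antigen["end"],
                                antigen["strength"],
                            )
                        )
                        carried.append(antigen["protein_id"])
            carriers[donor_id] = carried

            visit_targets = list(targets)
            for month in time_points:
                if drift > 0 and month != time_points[0]:
                    visit_targets = [
                        t for t in visit_targets if rng.random() >= drift
                    ]
                batch = f"B{sample_counter % n_batches + 1}"
                sample_counter += 1
                profiles.append(
                    SerumProfile(
                        donor_id=donor_id,
                        group=group,
                        month=int(month),
                        batch=batch,
                        targets=list(visit_targets),
                        background=background,
                    )
                )

    batch_sigma = float(full_design["batch_sigma"])
    batch_factors: dict[str, dict[str, float]] = {}
    for b in range(n_batches):
        batch = f"B{b + 1}"
        if batch_sigma > 0:
            factors = rng.lognormal(0.0, batch_sigma, size=len(proteome))
        else:
            factors = np.ones(len(proteome))
        batch_factors[batch] = {
            p.protein_id: float(f) for p, f in zip(proteome.proteins, factors)
        }

    truth = TruthTable(
        pools=pools,
        carriers=carriers,
        donor_groups=donor_groups,
        batch_factors=batch_factors,
        seed=int(seed),
    )
    return profiles, truth


# --------------------------------------------------------------------------
# sequencing simulation


def _protein_index(pool: FragmentPool):
    index = getattr(pool, "_protein_index_cache", None)
    if index is None:
        index = {}
        for i, frag in enumerate(pool.fragments):
            aa_start = frag.start // 3
            aa_end = -(-frag.end // 3)
            index.setdefault(frag.protein_id, []).append((i, aa_start, aa_end))
        index = {
            pid: (
                np.array([t[0] for t in triples]),
                np.array([t[1] for t in triples]),
                np.array([t[2] for t in triples]),
            )
            for pid, triples in index.items()
        }
        pool._protein_index_cache = index  # type: ignore[attr-defined]
    return index


def selection_weights(
    pool: FragmentPool,
    profile: SerumProfile,
    fragment_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Unnormalised expected post-selection fragment weights for one serum."""
    index = _protein_index(pool)
    multiplier = np.full(len(pool), profile.background, dtype=float)
    for target in profile.targets:
        if target.protein_id not in pool.protein_lengths:
            raise ValueError(
                f"epitope refers to protein {target.protein_id!r} absent from the pool"
            )
        entry = index.get(target.protein_id)
        if entry is None:
            continue  # protein known but no fragment survived the funnel
        idx, aa_start, aa_end = entry
        overlap = (aa_start < target.end) & (aa_end > target.start)
        multiplier[idx[overlap]] += target.strength
    weights = pool.input_abundance * multiplier
    if fragment_factors is not None:
        weights = weights * fragment_factors
    return weights


def simulate_screen(
    pool: FragmentPool,
    profile: SerumProfile,
    depth: int,
    dispersion: float = 0.0,
    seed: int | np.random.Generator = 0,
    fragment_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Draw fragment counts for one immunoselection at the stated depth.

    Counts are multinomial over the normalised selection weights, or
    Dirichlet-multinomial with concentration ``1/dispersion`` when
    ``dispersion > 0``.  Counts always sum exactly to ``depth``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    weights = selection_weights(pool, profile, fragment_factors)
    if depth == 0:
        return np.zeros(len(pool), dtype=np.int64)
    total = weights.sum()
    if total <= 0:
        raise ValueError("selection weights sum to zero; cannot sample counts")
    p = weights / total
    if dispersion > 0:
        positive = p > 0
        alpha = p[positive] / dispersion
        drawn = rng.dirichlet(alpha)
        p = np.zeros_like(p)
        p[positive] = drawn
    return rng.multinomial(depth, p)


def simulate_cohort(
    pool: FragmentPool,
    profiles: Sequence[SerumProfile],
    truth: TruthTable,
    depth: int = 200_000,
    dispersion: float = 0.0,
    seed: int = 0,
    include_controls: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the whole screen: one count column per serum sample.

    Batch effects from the truth table multiply fragment weights before
    sampling.  When ``include_controls`` is set, one unselected
    input-library sample is sequenced per batch (flagged in the metadata),
    mirroring the per-experiment controls used for batch correction.

    Returns ``(fragment_counts, sample_meta)``.
    """
    protein_of = np.array([f.protein_id for f in pool.fragments])
    factor_by_batch = {
        batch: np.array([factors[p] for p in protein_of])
        for batch, factors in truth.batch_factors.items()
    }
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(profiles) + len(factor_by_batch))
    for child, profile in zip(children, profiles):
        rng = np.random.default_rng(child)
        counts = simulate_screen(
            pool,
            profile,
            depth,
            dispersion=dispersion,
            seed=rng,
            fragment_factors=factor_by_batch.get(profile.batch),
        )
        columns[profile.sample_id] = counts
        meta_rows.append(
            {
                "sample_id": profile.sample_id,
                "donor_id": profile.donor_id,
                "group": profile.group,
                "month": profile.month,
                "batch": profile.batch,
                "is_control": False,
            }
        )
    if include_controls:
        for child, (batch, factors) in zip(
            children[len(profiles) :], sorted(factor_by_batch.items())
        ):
            rng = np.random.default_rng(child)
            weights = pool.input_abundance * factors
            counts = rng.multinomial(depth, weights / weights.sum())
            sample_id = f"INPUT_{batch}"
            columns[sample_id] = counts
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "donor_id": "input",
                    "group": CONTROL_GROUP,
                    "month": -1,
                    "batch": batch,
                    "is_control": True,
                }
            )
    counts = pd.DataFrame(columns, index=pool.fragment_ids)
    counts.index.name = "fragment_id"
    meta = pd.DataFrame(meta_rows)
    return counts, meta


# --------------------------------------------------------------------------
# dataset emission


def emit_dataset(
    out_dir: str | Path,
    proteome: SimulatedProteome,
    pool: FragmentPool,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    truth: TruthTable,
) -> dict[str, Path]:
    """Write the full simulated dataset as plain-text files.

    Emits protein and fragment FASTA, the fragment-to-protein map,
    fragment- and antigen-level count tables, sample metadata, and the
    truth JSON.  All files round-trip through :mod:`antigenome.profiles`
    readers.
    """
    from . import profiles as _profiles

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    paths = {
        "proteins_fasta": out / "proteins.fasta",
        "fragments_fasta": out / "fragments.fasta",
        "fragment_map": out / "fragment_map.tsv",
        "fragment_counts": out / "fragment_counts.tsv",
        "antigen_counts": out / "antigen_counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    proteome.write_fasta(paths["proteins_fasta"], kind="protein")
    with open(paths["fragments_fasta"], "w") as handle:
        for frag in pool.fragments:
            handle.write(f">{frag.fragment_id}\n{frag.sequence}\n")
    pool.to_frame().to_csv(paths["fragment_map"], sep="\t", index=False)
    _profiles.write_counts_tsv(counts, paths["fragment_counts"])
    fmap = pool.to_frame()[["fragment_id", "protein_id"]]
    antigen_counts = _profiles.aggregate_fragments_to_antigens(counts, fmap)
    _profiles.write_counts_tsv(antigen_counts, paths["antigen_counts"])
    meta.to_csv(paths["samples"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
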