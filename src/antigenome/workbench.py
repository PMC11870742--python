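"""Pipeline orchestration: configuration, seeded runs, report assembly.

A single run executes simulate -> qc -> normalize -> call -> diff ->
enrich -> model, writing plain-text artifacts (TSV/JSON/FASTA) into a run
directory stamped with the configuration hash.  A single top-level seed
fans out deterministically to per-stage child seeds so stages can be
rerun in isolation.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import differential as _differential
from . import library_build as _library
from . import predictor as _predictor
from . import profiles as _profiles
from . import seqfeatures as _seqfeatures
from . import synthetic_data as _synthetic


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "qc": True,
        "normalize": True,
        "call": True,
        "diff": True,
        "enrich": True,
        "model": True,
    },
    "inputs": {"dir": None},
    "simulate": {
        "n_proteins": 2000,
        "length_dist": {"kind": "normal", "mean_aa": 250, "sd_aa": 80, "min_aa": 60},
        "overlap_config": {"shared_fraction": 0.6, "exclusive": {}},
        "candidates_per_source": 2000,
        "orientation_flip_p": 0.01,
        "min_insert": 30,
        "design": dict(_synthetic.DEFAULT_DESIGN),
        "disease_pool": [
            {
                "groups": ["PBO-A", "PBO-NA", "RNF-A", "RNF-NA"],
                "antigens": 40,
                "prevalence": 0.35,
                "effect": 10.0,
            },
            {
                "groups": ["PBO-A", "RNF-A"],
                "antigens": 12,
                "prevalence": 0.55,
                "effect": 10.0,
            },
        ],
        "depth": 200000,
        "dispersion": 0.0,
    },
    "selection": {
        "fold_threshold": 5.0,
        "min_count": 10,
        "epsilon": 0.5,
    },
    "differential": {
        "min_prevalence": 0.01,
        "p_threshold": 0.05,
        "q_threshold": 0.2,
        "reproducible_min_prevalence": 0.10,
        "month": 0,
        "control_group": "HC",
        "case_groups": ["PBO-A", "PBO-NA", "RNF-A", "RNF-NA"],
    },
    "enrichment": {
        "scales": list(_seqfeatures.PROPERTY_SCALES),
        "n_perm": 200,
    },
    "model": {
        "response_groups": {"PBO-A": 1, "PBO-NA": 0},
        "outer_folds": 4,
        "inner_folds": 5,
        "n_lambda": 100,
        "lambda_min_ratio": 1e-3,
        "q_threshold": 0.05,
        "prevalence_threshold": 0.30,
    },
}

#: subtrees whose keys are data, not schema, and skip unknown-key checking
_FREEFORM_PATHS = {
    "simulate.length_dist",
    "simulate.overlap_config",
    "simulate.design",
    "simulate.disease_pool",
    "model.response_groups",
}

_BOUNDS = [
    ("differential.min_prevalence", lambda v: 0 <= v <= 1, "must be in [0, 1]"),
    ("differential.p_threshold", lambda v: 0 < v <= 1, "must be in (0, 1]"),
    ("differential.q_threshold", lambda v: 0 < v <= 1, "must be in (0, 1]"),
    (
        "differential.reproducible_min_prevalence",
        lambda v: 0 <= v <= 1,
        "must be in [0, 1]",
    ),
    ("selection.fold_threshold", lambda v: v > 0, "must be positive"),
    ("selection.min_count", lambda v: v >= 0, "must be >= 0"),
    ("model.q_threshold", lambda v: 0 < v <= 1, "must be in (0, 1]"),
    ("model.prevalence_threshold", lambda v: 0 <= v <= 1, "must be in [0, 1]"),
    ("model.outer_folds", lambda v: v >= 2, "must be >= 2"),
    ("model.inner_folds", lambda v: v >= 2, "must be >= 2"),
    ("simulate.n_proteins", lambda v: v >= 1, "must be >= 1"),
    ("simulate.depth", lambda v: v >= 0, "must be >= 0"),
    ("enrichment.n_perm", lambda v: v >= 100, "must be >= 100"),
]


def _merge(defaults: dict, overrides: dict, path: str, errors: list[str]) -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            errors.append(f"unknown configuration key: {here}")
            continue
        if (
            isinstance(defaults[key], dict)
            and isinstance(value, dict)
            and here not in _FREEFORM_PATHS
        ):
            merged[key] = _merge(defaults[key], value, here, errors)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def _get_path(config: dict, dotted: str):
    node = config
    for part in dotted.split("."):
        node = node[part]
    return node


def validate_config(source: str | Path | dict | None = None) -> dict:
    """Normalize a config mapping or YAML file against the schema.

    Fills every default, rejects unknown keys, and checks numeric bounds;
    all violations are reported together, each naming its field.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must contain a mapping")
    errors: list[str] = []
    config = _merge(DEFAULT_CONFIG, raw, "", errors)
    for dotted, predicate, message in _BOUNDS:
        value = _get_path(config, dotted)
        try:
            ok = predicate(value)
        except TypeError:
            ok = False
        if not ok:
            errors.append(f"{dotted} = {value!r} {message}")
    if errors:
        raise ConfigError("; ".join(errors))
    return config


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _dump_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n")


def load_dataset(data_dir: str | Path):
    """Reload an emitted dataset (counts, metadata, map, truth, sequences)."""
    from Bio import SeqIO

    data_dir = Path(data_dir)
    counts = _profiles.read_counts_tsv(data_dir / "fragment_counts.tsv")
    meta = _profiles.read_meta_tsv(data_dir / "samples.tsv")
    fmap = _profiles.read_fragment_map(data_dir / "fragment_map.tsv")
    truth = _synthetic.TruthTable.from_json(data_dir / "truth.json")
    sequences = {
        record.id: str(record.seq)
        for record in SeqIO.parse(str(data_dir / "proteins.fasta"), "fasta")
    }
    return counts, meta, fmap, truth, sequences


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path) -> dict:
    """Execute the enabled stages in order and write all artifacts.

    Reruns with an identical configuration and seed reproduce every
    artifact byte-for-byte (the timing log aside).  A stage failure raises
    :class:`PipelineStageError` naming the stage; artifacts written by
    earlier stages are preserved.
    """
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    run_hash = config_hash(config)
    (out / "config_hash.txt").write_text(run_hash + "\n")
    stages = config["stages"]
    seed = int(config["seed"])
    log_lines: list[str] = [f"config_hash={run_hash}"]
    artifacts: dict[str, Path] = {}

    def _run(stage: str, func):
        if not stages.get(stage, False):
            log_lines.append(f"{stage}: skipped")
            return
        start = time.perf_counter()
        try:
            func()
        except Exception as exc:
            log_lines.append(f"{stage}: FAILED ({exc})")
            (out / "log.txt").write_text("\n".join(log_lines) + "\n")
            raise PipelineStageError(stage, exc) from exc
        log_lines.append(f"{stage}: ok ({time.perf_counter() - start:.2f}s)")

    state: dict = {}

    def stage_simulate():
        sim = config["simulate"]
        s = child_seed(seed, "simulate")
        proteome = _synthetic.generate_proteome(
            sim["n_proteins"], sim["length_dist"], sim["overlap_config"], seed=s
        )
        pool = _synthetic.build_fragment_library(
            proteome,
            orientation_flip_p=sim["orientation_flip_p"],
            candidates_per_source=sim["candidates_per_source"],
            min_insert=sim["min_insert"],
            seed=child_seed(seed, "library"),
        )
        profiles_list, truth = _synthetic.generate_serum_cohort(
            sim["design"], proteome, sim["disease_pool"],
            seed=child_seed(seed, "cohort"), pool=pool,
        )
        counts, meta = _synthetic.simulate_cohort(
            pool, profiles_list, truth,
            depth=sim["depth"], dispersion=sim["dispersion"],
            seed=child_seed(seed, "screen"),
        )
        data_dir = out / "data"
        paths = _synthetic.emit_dataset(data_dir, proteome, pool, counts, meta, truth)
        artifacts.update(paths)
        state.update(
            proteome=proteome, pool=pool, counts=counts, meta=meta, truth=truth,
            fmap=pool.to_frame()[["fragment_id", "protein_id"]],
            sequences={p.protein_id: p.aa_sequence for p in proteome.proteins},
        )

    def _ensure_inputs():
        if "counts" not in state:
            data_dir = config["inputs"]["dir"]
            if data_dir is None:
                raise ValueError(
                    "simulate stage disabled and no inputs.dir configured"
                )
            counts, meta, fmap, truth, sequences = load_dataset(data_dir)
            state.update(
                counts=counts, meta=meta, truth=truth, sequences=sequences,
                fmap=fmap[["fragment_id", "protein_id"]],
            )
            state["input_abundance"] = fmap.set_index("fragment_id")["input_abundance"]

    def stage_qc():
        _ensure_inputs()
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        if "pool" in state:
            report = _library.library_qc_summary(state["pool"])
            _dump_json(report.to_dict(), qc_dir / "library_qc.json")
            artifacts["library_qc"] = qc_dir / "library_qc.json"

    def stage_normalize():
        _ensure_inputs()
        antigen_counts = _profiles.aggregate_fragments_to_antigens(
            state["counts"], state["fmap"]
        )
        norm = _profiles.normalize(antigen_counts)
        factors, corrected, drift = _profiles.estimate_batch_factors(
            norm.cpm, state["meta"]
        )
        state.update(antigen_counts=antigen_counts, norm=norm, corrected_cpm=corrected)
        norm_dir = out / "normalized"
        norm_dir.mkdir(exist_ok=True)
        _profiles.write_counts_tsv(antigen_counts, norm_dir / "antigen_counts.tsv")
        corrected.round(4).to_csv(norm_dir / "antigen_cpm_corrected.tsv", sep="\t")
        _dump_json(drift, norm_dir / "batch_qc.json")
        artifacts["antigen_counts"] = norm_dir / "antigen_counts.tsv"

    def stage_call():
        sel = config["selection"]
        calls = _profiles.make_selection_calls(
            state["antigen_counts"], state["norm"], state["meta"],
            fold_threshold=sel["fold_threshold"], min_count=sel["min_count"],
            epsilon=sel["epsilon"],
            prevalence_month=config["differential"]["month"],
        )
        state["calls"] = calls
        calls_dir = out / "calls"
        calls_dir.mkdir(exist_ok=True)
        calls.matrix.to_csv(calls_dir / "calls.tsv", sep="\t")
        calls.prevalence.round(6).to_csv(calls_dir / "prevalence.tsv", sep="\t")
        artifacts["calls"] = calls_dir / "calls.tsv"

    def stage_diff():
        diff_cfg = config["differential"]
        meta = state["meta"]
        month = diff_cfg["month"]
        thresholds = {
            "min_prevalence": diff_cfg["min_prevalence"],
            "p_threshold": diff_cfg["p_threshold"],
            "q_threshold": diff_cfg["q_threshold"],
        }
        log2 = state["norm"].log2
        serum = meta[~meta["is_control"]]
        control_samples = list(
            serum[(serum["group"] == diff_cfg["control_group"]) & (serum["month"] == month)][
                "sample_id"
            ]
        )
        case_meta = serum[serum["group"].isin(diff_cfg["case_groups"])]
        donor_subgroups = (
            case_meta.drop_duplicates("donor_id").set_index("donor_id")["group"]
        )
        assignment, partition, results = _differential.split_set_reproducibility(
            log2, state["calls"], meta, donor_subgroups, control_samples,
            seed=child_seed(seed, "split"), month=month, thresholds=thresholds,
        )
        case_month_samples = list(case_meta[case_meta["month"] == month]["sample_id"])
        all_case_prev = (
            state["calls"]
            .matrix[case_month_samples]
            .T.groupby(case_meta[case_meta["month"] == month].set_index("sample_id")["donor_id"])
            .max()
            .mean(axis=0)
        )
        reproducible = partition["shared"]
        filtered = _differential.prevalence_filter(
            reproducible, all_case_prev, diff_cfg["reproducible_min_prevalence"]
        )

        subgroup_hits = {}
        for group in diff_cfg["case_groups"]:
            samples = list(
                serum[(serum["group"] == group) & (serum["month"] == month)]["sample_id"]
            )
            result = _differential.differential_selection(
                log2, state["calls"], meta, samples, control_samples, thresholds
            )
            subgroup_hits[group] = _differential.case_hits(result) & reproducible
        overlap = _differential.subgroup_overlap(subgroup_hits)

        if "pool" in state:
            representation = (
                state["pool"].to_frame().assign(a=state["pool"].input_abundance)
                .groupby("protein_id")["a"].sum()
            )
        else:
            representation = (
                state["input_abundance"]
                .groupby(state["fmap"].set_index("fragment_id")["protein_id"])
                .sum()
            )
        representation = representation.reindex(log2.index, fill_value=0.0)
        rank_bias = (
            _differential.rank_bias_diagnostic(reproducible, representation)
            if reproducible
            else None
        )

        diff_dir = out / "differential"
        diff_dir.mkdir(exist_ok=True)
        for name, result in results.items():
            result.round(6).to_csv(diff_dir / f"{name}.tsv", sep="\t")
        _dump_json(
            {
                "assignment": assignment,
                "partition": {k: sorted(map(str, v)) for k, v in partition.items()},
                "n_reproducible": len(reproducible),
                "n_reproducible_min_prevalence": len(filtered),
                "rank_bias": rank_bias,
            },
            diff_dir / "partition.json",
        )
        _dump_json(overlap.to_dict(), diff_dir / "subgroup_overlap.json")
        state.update(reproducible=reproducible, filtered_hits=filtered)
        artifacts["partition"] = diff_dir / "partition.json"

    def stage_enrich():
        enr = config["enrichment"]
        table = _seqfeatures.property_table(state["sequences"], enr["scales"])
        enrich_dir = out / "enrichment"
        enrich_dir.mkdir(exist_ok=True)
        table.round(6).to_csv(enrich_dir / "properties.tsv", sep="\t")
        hits = state.get("filtered_hits") or state.get("reproducible") or set()
        reports = {}
        if hits:
            for scale in enr["scales"]:
                result = _seqfeatures.gsea_enrichment(
                    table[scale], set(hits) & set(table.index),
                    n_perm=enr["n_perm"],
                    seed=child_seed(seed, f"gsea:{scale}"), scale_name=scale,
                )
                reports[scale] = result.to_dict()
        _dump_json(reports, enrich_dir / "enrichment.json")
        artifacts["enrichment"] = enrich_dir / "enrichment.json"

    def stage_model():
        mdl = config["model"]
        meta = state["meta"]
        month = config["differential"]["month"]
        response_groups = dict(mdl["response_groups"])
        serum = meta[
            (~meta["is_control"])
            & meta["group"].isin(response_groups)
            & (meta["month"] == month)
        ]
        labels = pd.Series(
            [response_groups[g] for g in serum["group"]],
            index=serum["sample_id"].to_list(),
        )
        control_samples = list(
            meta[
                (~meta["is_control"])
                & (meta["group"] == config["differential"]["control_group"])
                & (meta["month"] == month)
            ]["sample_id"]
        )
        result = _differential.differential_selection(
            state["norm"].log2, state["calls"], meta,
            list(labels.index), control_samples,
            {"min_prevalence": config["differential"]["min_prevalence"]},
        )
        X, y = _predictor.build_design_matrix(
            state["norm"].log2, result, labels,
            q_threshold=mdl["q_threshold"],
            prevalence_threshold=mdl["prevalence_threshold"],
        )
        model_config = _predictor.ModelConfig(
            outer_folds=mdl["outer_folds"], inner_folds=mdl["inner_folds"],
            n_lambda=mdl["n_lambda"], lambda_min_ratio=mdl["lambda_min_ratio"],
            q_threshold=mdl["q_threshold"],
            prevalence_threshold=mdl["prevalence_threshold"],
            seed=child_seed(seed, "model") % (2**31),
        )
        report = _predictor.nested_cv(X, y, model_config)
        model_dir = out / "model"
        model_dir.mkdir(exist_ok=True)
        _dump_json(report.to_dict(), model_dir / "model.json")
        if report.shap_values is not None:
            report.shap_values.round(6).to_csv(model_dir / "shap.tsv", sep="\t")
        artifacts["model"] = model_dir / "model.json"

    _run("simulate", stage_simulate)
    _run("qc", stage_qc)
    _run("normalize", stage_normalize)
    _run("call", stage_call)
    _run("diff", stage_diff)
    _run("enrich", stage_enrich)
    _run("model", stage_model)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = out / "log.txt"
    return artifacts
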