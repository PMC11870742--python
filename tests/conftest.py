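import numpy as np
import pytest

from antigenome import profiles as pf
from antigenome import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_proteome():
    """60 long proteins so inserts are never clipped to full length."""
    return sd.generate_proteome(
        60,
        length_dist={"mean_aa": 400, "sd_aa": 40, "min_aa": 320},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pool(small_proteome):
    return sd.build_fragment_library(small_proteome, candidates_per_source=600, seed=12)


@pytest.fixture(scope="session")
def sim_bundle():
    """A small but complete screen shared by profile/differential tests."""
    proteome = sd.generate_proteome(
        300,
        length_dist={"mean_aa": 200, "sd_aa": 40, "min_aa": 80},
        seed=21,
        expression_sigma=1.0,
    )
    pool = sd.build_fragment_library(proteome, candidates_per_source=900, seed=22)
    design = {
        "groups": {"HC": 12, "PBO-A": 8, "PBO-NA": 8},
        "time_points": [0, 24],
        "n_batches": 2,
        "idiosyncratic_targets_mean": 6.0,
        "batch_sigma": 0.1,
    }
    rng = np.random.default_rng(23)
    available = sorted({f.protein_id for f in pool.fragments})
    planted = list(rng.choice(available, size=8, replace=False))
    disease_pool = {
        "groups": ["PBO-A", "PBO-NA"],
        "antigens": planted,
        "prevalence": 0.6,
        "effect": 10.0,
    }
    profiles_list, truth = sd.generate_serum_cohort(
        design, proteome, disease_pool, seed=24, pool=pool
    )
    counts, meta = sd.simulate_cohort(pool, profiles_list, truth, depth=100_000, seed=25)
    fmap = pool.to_frame()[["fragment_id", "protein_id"]]
    antigen_counts = pf.aggregate_fragments_to_antigens(counts, fmap)
    norm = pf.normalize(antigen_counts)
    calls = pf.make_selection_calls(antigen_counts, norm, meta, prevalence_month=0)
    return {
        "proteome": proteome,
        "pool": pool,
        "profiles": profiles_list,
        "truth": truth,
        "counts": counts,
        "meta": meta,
        "fmap": fmap,
        "antigen_counts": antigen_counts,
        "norm": norm,
        "calls": calls,
    }
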