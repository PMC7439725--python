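"""Shared fixtures: one small simulated study reused across test modules."""

from dataclasses import dataclass

import pytest

from cistrans import activity as act
from cistrans import differential as diff
from cistrans import simulate as sim
from cistrans.config import SimulationConfig


@dataclass
class Study:
    config: SimulationConfig
    catalog: object
    truth: object
    dna: object
    rna: object
    observations: object
    activities: object
    tested: object
    null_pairs: object
    results: object
    calibration: dict
    assigned: object


def build_study(config: SimulationConfig, n_null_per_tile: int = 50) -> Study:
    catalog, truth = sim.simulate_truth(config)
    dna, rna = sim.simulate_counts(truth, config)
    kept = act.filter_by_dna_representation(dna, truth.barcode_map)
    obs = act.compute_log_ratios(dna, rna, kept)
    activities = act.estimate_activity(obs)
    negatives = set(catalog.loc[catalog["class"] == "negative", "element_id"])
    tested = act.test_active(activities, negatives)
    positives = sorted(catalog.loc[catalog["class"] == "positive", "element_id"])
    nulls = diff.build_null_pairs(
        truth.barcode_map, positives, n_null_per_tile, seed=config.seed + 1
    )
    results = diff.run_effect_scans(obs, catalog, nulls)
    calibration = diff.calibrate_empirical_fdr(results)
    results = diff.apply_significance(results, calibration)
    assigned = diff.assign_effects(results)
    return Study(
        config=config,
        catalog=catalog,
        truth=truth,
        dna=dna,
        rna=rna,
        observations=obs,
        activities=activities,
        tested=tested,
        null_pairs=nulls,
        results=results,
        calibration=calibration,
        assigned=assigned,
    )


@pytest.fixture(scope="session")
def small_study() -> Study:
    """A 120-pair study at default depths, run through the differential stage."""
    cfg = SimulationConfig(n_pairs=120, n_negative_controls=80, seed=7)
    return build_study(cfg)
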