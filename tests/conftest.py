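"""Shared fixtures: synthetic cohorts at two scales and a trained scorer.

The session-scoped ``default_bundle`` carries the full default-scale
(~300-family) simulate -> load -> train -> run -> prune chain used by the
acceptance-style tests; ``small_bundle`` is a 60-family cohort for cheaper
integration checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pytest

import pgr.pipeline as pipe
from pgr.scoring import ModelConfig, VariantScoringModel, VariantScoringResults
from pgr.simulate import SimulationConfig, SyntheticCohort, simulate_cohort


@dataclass
class CohortBundle:
    paths: SyntheticCohort
    loaded: pipe.LoadedInputs
    reported: dict[tuple[str, str], str]
    results: VariantScoringResults
    run: pipe.RunResult
    pruning: pipe.PruningResult


def reported_from_truth(truth: dict) -> dict[tuple[str, str], str]:
    out = {}
    for proband, entry in truth.items():
        if entry:
            for key in entry["causal_keys"]:
                out[(proband, key)] = entry["label"]
    return out


def build_bundle(out_dir: Path, config: SimulationConfig) -> CohortBundle:
    paths = simulate_cohort(config, out_dir)
    loaded = pipe.load_inputs(out_dir)
    reported = reported_from_truth(paths.truth)
    dataset = pipe.build_training_dataset(loaded, reported)
    results = VariantScoringModel(dataset, ModelConfig(seed=0)).fit()
    run = pipe.run_pgr(loaded, results.model, out_dir=out_dir / "report", seed=config.seed)
    pruning = pipe.pruning_experiment(loaded, results)
    return CohortBundle(
        paths=paths, loaded=loaded, reported=reported,
        results=results, run=run, pruning=pruning,
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory) -> CohortBundle:
    """The default study conditions: seed 1, 300 families."""
    out = tmp_path_factory.mktemp("cohort300")
    return build_bundle(out, SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> CohortBundle:
    out = tmp_path_factory.mktemp("cohort60")
    return build_bundle(out, SimulationConfig(n_families=60, seed=1))


@pytest.fixture(scope="session")
def tiny_obo(tmp_path_factory) -> Path:
    """Hand-built DAG: root -> A,B (level 2); A -> A1,A2; B -> B1;
    A1,B1 -> D (diamond, level 4); A1 -> A1a (level 4) -> A1a1 (level 5);
    plus one obsolete term."""
    text = """format-version: 1.2
ontology: tiny

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000002
name: A
is_a: HP:0000001

[Term]
id: HP:0000003
name: B
is_a: HP:0000001

[Term]
id: HP:0000004
name: A1
is_a: HP:0000002

[Term]
id: HP:0000005
name: A2
is_a: HP:0000002

[Term]
id: HP:0000006
name: B1
is_a: HP:0000003

[Term]
id: HP:0000007
name: D
is_a: HP:0000004
is_a: HP:0000006

[Term]
id: HP:0000008
name: A1a
is_a: HP:0000004

[Term]
id: HP:0000009
name: A1a1
is_a: HP:0000008

[Term]
id: HP:0000010
name: gone
is_obsolete: true
"""
    path = tmp_path_factory.mktemp("obo") / "tiny.obo"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def tiny_ontology(tiny_obo):
    from pgr.ontology import load_obo

    return load_obo(tiny_obo)
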