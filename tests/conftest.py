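import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from bruxhmm.evaluate import extract_observations, run_study
from bruxhmm.pipeline import prepare_observations
from bruxhmm.simulate import GeneratorConfig, generate_dataset, generate_recordings

#: Master seed pinning the default synthetic study used across the suite.
STUDY_SEED = 7


@pytest.fixture(scope="session")
def small_config():
    """Compact protocol (3 subjects, 2 reps, short rests) for unit tests
    that only need a structurally complete dataset."""
    return GeneratorConfig(
        n_subjects=3,
        reps_per_task=2,
        inter_rep_gap=1.0,
        inter_task_rest=2.0,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_segments(small_config):
    return generate_recordings(small_config)


@pytest.fixture(scope="session")
def small_observations(small_segments):
    return extract_observations(small_segments)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """A 2-subject, 1-rep dataset written to disk (manifest + CSV/WAV)."""
    cfg = GeneratorConfig(
        n_subjects=2,
        reps_per_task=1,
        inter_rep_gap=1.0,
        inter_task_rest=1.0,
        master_seed=23,
    )
    root = tmp_path_factory.mktemp("tiny_dataset")
    manifest = generate_dataset(cfg, root)
    return root, manifest, cfg


@pytest.fixture(scope="session")
def study_observations():
    """The default synthetic study corpus: 12 subjects, 600 segments,
    features for all 7 channels."""
    return prepare_observations(GeneratorConfig(master_seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_report(study_observations):
    """Full leave-one-subject-out study over all 12 stream sets."""
    return run_study(study_observations, seed=STUDY_SEED)
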